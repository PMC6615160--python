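# Methods

This note records what the package computes, the modeling assumptions
behind the synthetic cohort generator, the default parameter values and
why they were chosen, and the known limitations.

## 1. Atlas

The built-in parcellation has 19 spherical regions of interest in three
visual intrinsic connectivity networks: primary visual (PVN: lV1, rV1),
higher visual (HVN: lV3v, rV3v, rV4, rV2), and visuospatial (VSN: 13
frontoparietal and lateral nodes). Node order is
fixed (VSN, then HVN, then PVN) so matrices are comparable across
subjects. Masks are spheres of radius 6 mm on a synthetic MNI-like 3 mm
grid (61 × 73 × 61 voxels, origin (−90, −126, −72)); the minimum pairwise
center distance is 13.1 mm, so 6 mm spheres never overlap
(`attach_spherical_masks` raises if a configuration would).

## 2. Temporal preprocessing

Per subject, in order:

1. **Polynomial detrend**, order 3, via an orthonormal Legendre basis
   (conditioning; residuals exactly orthogonal to the basis).
2. **Motion censoring**: framewise displacement in the Power convention —
   sum of absolute backward differences of the 3 translations (mm) plus
   the 3 rotations (radians) × 50 mm head radius; frames with FD > 0.2 mm
   are deleted. A floor of 50 surviving frames is enforced (the distance
   correlation estimator degrades badly below that).
3. **Band-pass** 0.01–0.10 Hz, zero-phase Butterworth (`sosfiltfilt`,
   effective order 4), applied to the concatenated kept frames. Filtering
   a gappy series is ill-posed; filtering before censoring is available
   behind `filter_before_censor=True`.
4. **Nuisance regression** on the 6 motion parameters and their backward-
   difference derivatives, censored and filtered identically to the data.

## 3. Distance-correlation connectivity

Voxels are z-scored over time; `t × t` Euclidean distance matrices between
time points are U-centered:

```
U[j,k] = d[j,k] − row_j/(t−2) − col_k/(t−2) + total/((t−1)(t−2)),  U[j,j] = 0
```

Then `dCov = Σ (U_A ∘ U_B) / (t(t−3))`, `dVar` analogously, and
`dCor = sqrt(dCov / sqrt(dVar_A dVar_B))` when `dCov > 0`, else 0 (the
U-centered estimator is unbiased and can go slightly negative under
independence; truncation at zero is standard). Edges are Fisher
z-transformed (`arctanh`, argument clamped at 1 − 1e−7). The per-subject
matrix computes each region's centered matrix once and reuses it across
the 171 pairs.

## 4. Graph metrics

At each sparsity `s` in the default grid 0.20–0.80 step 0.05 (13 points),
the strongest `round(s · 171)` edges are kept (deterministic tie-break on
node indices; grids are nested). Nodal local efficiency of node *i* is the
mean inverse shortest-path length among *i*'s neighbors in the subgraph
they induce, with edge length `w_max / w` (lengths ≥ 1 keeps efficiencies
in [0, 1]). The area under the efficiency-vs-sparsity curve (trapezoidal,
width 0.6) gives the per-node aLE.

## 5. Group statistics

- **Block means**: mean Fisher-z over upper-triangle edges within each
  network (PVN contributes its single edge) and over all cross edges for
  each network pair.
- **Split-plot mixed ANOVA** (group between, network/node within): the
  group F is tested against the subjects-within-group mean square, the
  within and interaction Fs against the residual. At the default design
  (18 + 18 × 3 networks) the df pattern is (1, 34) and (2, 68). The
  implementation is direct sums-of-squares; tests cross-check it against
  pingouin and a loop-based oracle.
- **Pooled two-sample t-tests** per block / node, df = n₁ + n₂ − 2.
- **Storey q-values**, λ = 0.5: π̂0 = min(1, #{p > λ} / ((1 − λ) m)),
  q_(j) = cummin over decreasing p of π̂0 · m · p_(j) / j. Each family
  (3 intra, 3 inter, 19 nodes) is corrected separately. A finite-sample
  pFDR variant is available behind `pfdr=True`.
- **Acuity correlations**: Pearson r between each patient block mean and
  amblyopic-eye logMAR acuity.

## 6. Synthetic cohort generator

Each subject's ROI voxel signal is

```
voxel = a · f_net + b · g + sqrt(1 − a² − b²) · noise
```

where `f_net` is a network-specific latent signal, `g` a global signal,
and all components are band-limited (0.01–0.10 Hz zero-phase filtered)
Gaussian noise, so simulated data have realistic autocorrelation. The
intra-network coupling `a` is drawn per subject around a group mean with
SD 0.08 (between-subject variability), and the patient group's HVN and
VSN means are reduced:

| parameter | control | patient |
|---|---|---|
| intra coupling, HVN and VSN | 0.60 | 0.49 |
| intra coupling, PVN | 0.60 | 0.60 |
| inter (global) coupling b | 0.25 | 0.25 |

The 0.11 gap was calibrated once, before the recovery tests were written,
to produce a measured block-mean Cohen's d near 0.9–1.0 at the reduced
simulation size used in testing (96 frames, 8 voxels/ROI) and then frozen.
At the full default acquisition size (240 frames, 33 voxels/ROI) the
measured d is larger (≈ 1.6–1.8) because estimation noise in the block
means shrinks with more data while the programmed between-subject gap is
unchanged; this is expected behavior, not drift.

Motion is a Gaussian random walk (SD 0.02 per frame per parameter) with
occasional spikes (rate 0.02, 0.5 mm) so FD censoring is exercised.
Acuity is drawn per group with patient amblyopic-eye acuity worse and
correlated with nothing by construction (the generator programs no
acuity–connectivity link). Seeding is hierarchical
(`SeedSequence([seed, subject, group])`): per-subject streams are
independent and the whole cohort is reproducible from one integer.

## 7. Simulation sizes in tests

The test suite validates the statistical machinery at sizes chosen to
keep the full suite within a laptop-scale budget:

- Replicate recovery: 200 cohorts of 18 + 18 subjects at 96 frames and
  8 voxels/ROI (≈ 4 minutes); asserts the programmed HVN/VSN deficit is
  detected with correct sign in > 95 % of replicates, VSN power ≥ 60 %,
  and the null PVN false-positive rate stays within binomial bounds of 5 %.
- FDR calibration: 500 fully-null cohorts at the statistics level
  (per-subject node summaries), exercising the t-test + q-value path.
- Estimator oracles (distance correlation, local efficiency, ANOVA,
  q-values) run against independent brute-force implementations in
  `tests/oracles.py` at tolerances 1e−10 to 1e−12.

## 8. Limitations

- The generator produces stationary Gaussian band-limited signals; it
  does not model hemodynamic response shape, physiological noise,
  spatial autocorrelation within an ROI beyond a shared latent factor, or
  scanner drift (drift is exercised separately in preprocessing tests).
- The atlas grid is a synthetic MNI-like stand-in; no real template or
  published parcellation volume ships with the package.
- Storey's plug-in π̂0 is unstable for very small families: with m = 3
  tests and λ = 0.5, π̂0 = 0 whenever all three p-values are below 0.5,
  which drives every q in that family to 0. This is a property of the
  estimator, kept as specified; interpret the 3-test family q-values
  together with their raw p-values (the 19-node family is large enough
  for the estimate to behave).
- Zero-phase filtering is non-circular, so circular-shift surrogate tests
  on generator output are only approximate; the test suite builds its
  calibration nulls with circular (FFT-mask) band-limiting where exact
  exchangeability is required.
- The mixed ANOVA requires a balanced, complete design; unbalanced groups
  or missing cells are rejected rather than approximated.
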