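"""Synthetic two-group rs-fMRI cohorts over the 19-node visual atlas.

The generator emulates the statistical structure the connectivity analysis
assumes: band-limited (0.01-0.10 Hz at TR = 2 s) voxel time series
organized into ROIs, with a shared global factor, one latent factor per
network, and group-dependent intra-network coupling.  The ROI signal is

    s_i(t) = a * f_net(i)(t) + b * g(t) + sqrt(1 - a^2 - b^2) * e_i(t)

where ``a`` is the subject's intra-network coupling (drawn around the
group mean for its network), ``b`` the global coupling, and ``e_i`` an ROI
idiosyncratic factor; every voxel of ROI i is ``s_i`` plus white voxel
noise.  By default the patient group has reduced coupling in the higher
visual (HVN) and visuospatial (VSN) networks and identical coupling in the
primary visual network (PVN), sized so the group contrast on mean
intra-network connectivity has a Cohen's d near 0.9 — the effect size
implied by a pooled t of -2.64 with 18 subjects per group.

Motion traces are slow Gaussian random walks with occasional spike
displacements, so framewise-displacement censoring has something to do.
Visual acuity (logMAR, per eye) is drawn per group from clinically
realistic distributions.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .atlas import RoiAtlas, load_builtin_atlas
from .preprocess import bandpass

GROUPS = ("patient", "control")


@dataclass
class CohortConfig:
    n_per_group: int = 18
    t_frames: int = 240
    tr: float = 2.0                  # s
    voxels_per_roi: int = 33         # ~6 mm sphere on a 3 mm grid
    # network -> (control coupling, patient coupling), each in [0, 1)
    intra_coupling: dict = field(default_factory=lambda: {
        "HVN": (0.60, 0.49),
        "PVN": (0.60, 0.60),
        "VSN": (0.60, 0.49),
    })
    inter_coupling: float = 0.25     # shared-global-factor weight
    subject_coupling_sd: float = 0.08
    voxel_noise_sd: float = 1.0
    band: tuple[float, float] = (0.01, 0.10)  # Hz
    drift_amplitude: float = 0.0     # optional linear+quadratic trend
    motion_walk_sd: float = 0.02     # mm per frame
    motion_spike_rate: float = 0.02  # probability per frame
    motion_spike_mm: float = 0.5
    # group -> eye -> (mean, sd) logMAR
    acuity_params: dict = field(default_factory=lambda: {
        "patient": {"amblyopic": (0.59, 0.23), "fellow": (0.01, 0.06)},
        "control": {"amblyopic": (0.02, 0.04), "fellow": (0.00, 0.03)},
    })
    acuity_bounds: tuple[float, float] = (-0.1, 1.3)
    seed: int = 0

    def validate(self) -> None:
        if self.t_frames < 10:
            raise ValueError("t_frames must be >= 10")
        b = self.inter_coupling
        for net, (ac, ap) in self.intra_coupling.items():
            for a in (ac, ap):
                if not 0 <= a < 1:
                    raise ValueError(f"{net}: coupling {a} outside [0, 1)")
                if a * a + b * b >= 1:
                    raise ValueError(
                        f"{net}: intra^2 + inter^2 = {a * a + b * b:.3f} >= 1; "
                        "no residual variance left"
                    )

    def coupling(self, network: str, group: str) -> float:
        ac, ap = self.intra_coupling[network]
        return ap if group == "patient" else ac


@dataclass
class SubjectScan:
    subject_id: str
    group: str
    roi_data: dict[str, np.ndarray]   # label -> voxels x time
    motion: np.ndarray                # t x 6 (mm, mm, mm, rad, rad, rad)
    acuity: dict[str, float]          # eye -> logMAR
    tr: float = 2.0
    meta: dict | None = None

    def __post_init__(self):
        lengths = {m.shape[1] for m in self.roi_data.values()}
        if len(lengths) > 1:
            raise ValueError(f"ROI matrices disagree on length: {lengths}")
        if self.motion.shape[0] != next(iter(lengths)):
            raise ValueError("motion trace length does not match ROI data")

    @property
    def n_frames(self) -> int:
        return next(iter(self.roi_data.values())).shape[1]


def _band_limited(rng: np.random.Generator, t: int, tr: float,
                  band: tuple[float, float], n: int = 1) -> np.ndarray:
    """n x t unit-variance noise band-limited by zero-phase filtering."""
    x = rng.standard_normal((n, t))
    y = bandpass(x, band[0], band[1], tr)
    sd = y.std(axis=1, keepdims=True)
    sd[sd == 0] = 1.0
    return y / sd


def _truncated_normal(rng, mean, sd, lo, hi) -> float:
    for _ in range(1000):
        v = rng.normal(mean, sd)
        if lo <= v <= hi:
            return float(v)
    return float(np.clip(mean, lo, hi))


def simulate_subject(
    config: CohortConfig,
    group: str,
    subject_seed: int,
    atlas: RoiAtlas | None = None,
) -> SubjectScan:
    """One subject's ROI voxel time series, motion trace and acuity.

    Deterministic in (config, group, subject_seed).
    """
    config.validate()
    if group not in GROUPS:
        raise ValueError(f"group must be one of {GROUPS}, got {group!r}")
    atlas = atlas or load_builtin_atlas()
    rng = np.random.default_rng(np.random.SeedSequence([config.seed, subject_seed,
                                                        GROUPS.index(group)]))
    t, tr = config.t_frames, config.tr
    b = config.inter_coupling

    g_factor = _band_limited(rng, t, tr, config.band)[0]
    net_factors = {net: _band_limited(rng, t, tr, config.band)[0]
                   for net in ("HVN", "PVN", "VSN")}
    a_max = np.sqrt(1.0 - b * b) - 1e-3
    subj_coupling = {
        net: float(np.clip(
            rng.normal(config.coupling(net, group), config.subject_coupling_sd),
            0.0, a_max))
        for net in net_factors
    }

    roi_data = {}
    for node in atlas.nodes:
        a = subj_coupling[node.network]
        resid = np.sqrt(max(0.0, 1.0 - a * a - b * b))
        e = _band_limited(rng, t, tr, config.band)[0]
        s = a * net_factors[node.network] + b * g_factor + resid * e
        vox = s[None, :] + config.voxel_noise_sd * rng.standard_normal(
            (config.voxels_per_roi, t))
        if config.drift_amplitude:
            u = np.linspace(-1, 1, t)
            trend = config.drift_amplitude * (
                rng.normal() * u + rng.normal() * (u * u - 1 / 3))
            vox = vox + trend[None, :]
        roi_data[node.label] = vox

    motion = np.cumsum(
        rng.normal(0.0, config.motion_walk_sd, size=(t, 6)), axis=0)
    motion[:, 3:] /= 50.0  # rotations walk ~walk_sd/50 rad per frame
    spikes = rng.random(t) < config.motion_spike_rate
    spikes[0] = False
    for k in np.nonzero(spikes)[0]:
        axis = rng.integers(0, 3)
        motion[k, axis] += config.motion_spike_mm * rng.choice([-1.0, 1.0])

    params = config.acuity_params[group]
    lo, hi = config.acuity_bounds
    acuity = {eye: _truncated_normal(rng, m, sd, lo, hi)
              for eye, (m, sd) in params.items()}

    return SubjectScan(
        subject_id=f"sub-{group[:3]}{subject_seed:03d}",
        group=group,
        roi_data=roi_data,
        motion=motion,
        acuity=acuity,
        tr=tr,
        meta={"subject_seed": int(subject_seed),
              "coupling": subj_coupling},
    )


def simulate_cohort(config: CohortConfig, atlas: RoiAtlas | None = None
                    ) -> list[SubjectScan]:
    """n_per_group subjects per group; per-subject seeds derive from
    ``config.seed`` so the whole cohort is reproducible."""
    config.validate()
    atlas = atlas or load_builtin_atlas()
    scans = []
    for group in GROUPS:
        for i in range(config.n_per_group):
            scans.append(simulate_subject(config, group, i, atlas=atlas))
    return scans


# ---------------------------------------------------------------------------
# on-disk round trip


def _toml_escape(v) -> str:
    if isinstance(v, bool):
        return "true" if v else "false"
    if isinstance(v, (int, float)):
        return repr(v)
    return '"' + str(v).replace('"', '\\"') + '"'


def config_to_toml(config: CohortConfig) -> str:
    lines = ["[cohort]"]
    for key in ("n_per_group", "t_frames", "tr", "voxels_per_roi",
                "inter_coupling", "subject_coupling_sd", "voxel_noise_sd",
                "drift_amplitude", "motion_walk_sd", "motion_spike_rate",
                "motion_spike_mm", "seed"):
        lines.append(f"{key} = {_toml_escape(getattr(config, key))}")
    lines.append(f"band = [{config.band[0]}, {config.band[1]}]")
    lines.append("")
    lines.append("[cohort.intra_coupling]")
    for net, (ac, ap) in config.intra_coupling.items():
        lines.append(f"{net} = [{ac}, {ap}]")
    return "\n".join(lines) + "\n"


def write_cohort(cohort: list[SubjectScan], directory,
                 atlas: RoiAtlas | None = None,
                 config: CohortConfig | None = None,
                 format: str = "tsv") -> Path:
    """Write a cohort as a file tree: per-subject ROI data (TSV per ROI, or
    one packed 4D NIfTI when masks are attached), a 6-column motion text
    file, and a cohort-level participants TSV."""
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    atlas = atlas or load_builtin_atlas()
    rows = []
    for scan in cohort:
        sdir = directory / scan.subject_id
        sdir.mkdir(exist_ok=True)
        if format == "tsv":
            for label, mat in scan.roi_data.items():
                np.savetxt(sdir / f"roi-{label}.tsv", mat.T, delimiter="\t")
        elif format == "nifti":
            from .atlas import pack_roi_volume
            img = pack_roi_volume(scan.roi_data, atlas)
            img.to_filename(str(sdir / "bold.nii"))
        else:
            raise ValueError(f"unknown format {format!r}")
        np.savetxt(sdir / "motion.1D", scan.motion, fmt="%.6f")
        rows.append({
            "subject_id": scan.subject_id,
            "group": scan.group,
            "tr": scan.tr,
            **{f"acuity_{eye}": v for eye, v in scan.acuity.items()},
        })
    pd.DataFrame(rows).to_csv(directory / "participants.tsv",
                              sep="\t", index=False)
    atlas.to_tsv(directory / "atlas.tsv")
    if config is not None:
        (directory / "config.toml").write_text(config_to_toml(config))
    return directory


def read_cohort(directory, atlas: RoiAtlas | None = None) -> list[SubjectScan]:
    """Read back a cohort written by :func:`write_cohort` (TSV or NIfTI)."""
    directory = Path(directory)
    atlas = atlas or load_builtin_atlas()
    participants = pd.read_csv(directory / "participants.tsv", sep="\t")
    scans = []
    for row in participants.itertuples():
        sdir = directory / row.subject_id
        nii = sdir / "bold.nii"
        if nii.exists():
            import nibabel as nib
            from .atlas import extract_roi_timeseries
            roi_data = extract_roi_timeseries(nib.load(str(nii)), atlas)
        else:
            roi_data = {
                node.label: np.loadtxt(sdir / f"roi-{node.label}.tsv",
                                       delimiter="\t", ndmin=2).T
                for node in atlas.nodes
            }
        motion = np.loadtxt(sdir / "motion.1D", ndmin=2)
        acuity = {c.removeprefix("acuity_"): float(getattr(row, c))
                  for c in participants.columns if c.startswith("acuity_")}
        scans.append(SubjectScan(
            subject_id=row.subject_id,
            group=row.group,
            roi_data=roi_data,
            motion=motion,
            acuity=acuity,
            tr=float(row.tr),
        ))
    return scans
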