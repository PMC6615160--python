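"""Group-level statistics on connectivity and local-efficiency summaries.

Per subject, the connectivity matrix is collapsed into six block means:
intra-network means for HVN, PVN and VSN (upper-triangle edges among the
nodes of one network) and inter-network means for the three network pairs
(all cross edges).  Group comparisons use:

* a mixed-design (split-plot) repeated-measures ANOVA with group as the
  between-subject factor and network/condition as the within-subject
  factor — the between-group F is tested against the subjects-within-group
  mean square, the within and interaction Fs against the residual;
* pooled-variance two-sample t-tests per condition (df = n1 + n2 - 2);
* Storey q-values for multiplicity, with the null proportion estimated as
  pi0 = #{p > lambda} / ((1 - lambda) m) at lambda = 0.5, each test family
  (3 intra, 3 inter, 19 nodes) corrected separately;
* Pearson correlation of each patient block mean with amblyopic-eye
  visual acuity (logMAR).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .atlas import NETWORKS, RoiAtlas
from .distcorr import ConnectivityMatrix
from .graphmetrics import LEProfile

INTER_PAIRS = (("HVN", "PVN"), ("HVN", "VSN"), ("PVN", "VSN"))


@dataclass
class BlockSummary:
    subject_id: str
    group: str
    intra: dict[str, float]
    inter: dict[tuple[str, str], float]


@dataclass
class AnovaTable:
    """F, (df1, df2), p for the three split-plot effects."""

    effects: dict[str, tuple[float, tuple[int, int], float]]

    def to_frame(self) -> pd.DataFrame:
        rows = [
            {"effect": k, "F": f, "df1": d[0], "df2": d[1], "p": p}
            for k, (f, d, p) in self.effects.items()
        ]
        return pd.DataFrame(rows)


@dataclass
class NodeTestResult:
    unit: str
    mean_patient: float
    mean_control: float
    t: float
    df: int
    p: float
    q: float | None = None


@dataclass
class GroupReport:
    mean_matrix: dict[str, np.ndarray]
    diff_matrix: np.ndarray
    labels: list[str]
    intra_anova: AnovaTable
    inter_anova: AnovaTable
    ale_anova: AnovaTable
    intra_tests: list[NodeTestResult]
    inter_tests: list[NodeTestResult]
    node_tests: list[NodeTestResult]
    acuity_corr: dict[str, tuple[float, float]]

    def tests_frame(self, family: str) -> pd.DataFrame:
        tests = {"intra": self.intra_tests, "inter": self.inter_tests,
                 "node": self.node_tests}[family]
        return pd.DataFrame([{
            "unit": r.unit, "mean_patient": r.mean_patient,
            "mean_control": r.mean_control, "t": r.t, "df": r.df,
            "p": r.p, "q": r.q,
        } for r in tests])


def block_means(matrix: ConnectivityMatrix, atlas: RoiAtlas,
                subject_id: str | None = None, group: str | None = None
                ) -> BlockSummary:
    """Mean Fisher-z within each network block and between each pair.

    Intra means average the upper-triangle edges among one network's nodes
    (PVN, with two nodes, contributes its single edge); inter means average
    all cross-network edges.
    """
    if matrix.labels != atlas.labels:
        raise ValueError("matrix labels do not match atlas node order")
    v = matrix.values
    idx = {net: atlas.network_indices(net) for net in NETWORKS}
    intra = {}
    for net, ii in idx.items():
        if len(ii) < 2:
            raise ValueError(f"network {net} has < 2 nodes; no intra edges")
        sub = v[np.ix_(ii, ii)]
        iu = np.triu_indices(len(ii), k=1)
        intra[net] = float(sub[iu].mean())
    inter = {}
    for a, b in INTER_PAIRS:
        inter[(a, b)] = float(v[np.ix_(idx[a], idx[b])].mean())
    return BlockSummary(subject_id=subject_id or (matrix.subject_id or ""),
                        group=group or "", intra=intra, inter=inter)


def mixed_anova(values: np.ndarray, groups) -> AnovaTable:
    """Split-plot ANOVA of a subjects x conditions table with a two-level
    between-subject grouping.

    The table must be complete and the design balanced (equal group sizes).
    Returns F, df and p for the between-group effect, the within-subject
    (condition) effect, and their interaction.
    """
    y = np.asarray(values, dtype=float)
    groups = np.asarray(groups)
    if y.ndim != 2:
        raise ValueError("values must be a subjects x conditions table")
    if not np.all(np.isfinite(y)):
        raise ValueError("ANOVA table contains missing values")
    if groups.shape[0] != y.shape[0]:
        raise ValueError("group labels do not match number of subjects")
    levels, counts = np.unique(groups, return_counts=True)
    g = len(levels)
    if g < 2:
        raise ValueError("need at least 2 groups")
    if len(set(counts)) != 1:
        raise ValueError(f"unbalanced design: group sizes {dict(zip(levels, counts))}")
    n = int(counts[0])
    if n < 2:
        raise ValueError("need >= 2 subjects per group")
    k = y.shape[1]

    grand = y.mean()
    subj_mean = y.mean(axis=1)
    cond_mean = y.mean(axis=0)
    group_mean = np.array([y[groups == lv].mean() for lv in levels])
    cell_mean = np.array([y[groups == lv].mean(axis=0) for lv in levels])

    ss_between_subj = k * ((subj_mean - grand) ** 2).sum()
    ss_group = n * k * ((group_mean - grand) ** 2).sum()
    ss_subj_within = ss_between_subj - ss_group
    ss_cond = g * n * ((cond_mean - grand) ** 2).sum()
    ss_inter = n * ((cell_mean - group_mean[:, None] - cond_mean[None, :]
                     + grand) ** 2).sum()
    ss_total = ((y - grand) ** 2).sum()
    ss_resid = ss_total - ss_group - ss_subj_within - ss_cond - ss_inter

    df_group = g - 1
    df_subj = g * (n - 1)
    df_cond = k - 1
    df_inter = (g - 1) * (k - 1)
    df_resid = g * (n - 1) * (k - 1)

    def f_and_p(ss, df1, ms_err, df2):
        f = (ss / df1) / ms_err
        return float(f), (df1, df2), float(stats.f.sf(f, df1, df2))

    ms_subj = ss_subj_within / df_subj
    ms_resid = ss_resid / df_resid
    return AnovaTable(effects={
        "group": f_and_p(ss_group, df_group, ms_subj, df_subj),
        "condition": f_and_p(ss_cond, df_cond, ms_resid, df_resid),
        "interaction": f_and_p(ss_inter, df_inter, ms_resid, df_resid),
    })


def two_sample_t(x, y) -> tuple[float, int, float]:
    """Pooled-variance Student t (two-sided); df = n1 + n2 - 2."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size < 2 or y.size < 2:
        raise ValueError("each group needs >= 2 observations")
    res = stats.ttest_ind(x, y, equal_var=True)
    df = x.size + y.size - 2
    if not np.isfinite(res.statistic):
        raise ValueError("zero pooled variance; t undefined")
    return float(res.statistic), df, float(res.pvalue)


def storey_q(pvals, lam: float = 0.5, *, pfdr: bool = False) -> np.ndarray:
    """Storey q-values with fixed-lambda pi0 estimation.

    pi0 = min(1, #{p > lam} / ((1 - lam) m)); q_(i) = min_{j >= i}
    pi0 * m * p_(j) / j, returned in the input order.  With ``pfdr=True``
    each term carries the positive-FDR finite-sample factor
    1 / (1 - (1 - p)^m).
    """
    p = np.asarray(pvals, dtype=float)
    if p.size == 0:
        raise ValueError("empty p-value list")
    if np.any((p < 0) | (p > 1)):
        raise ValueError("p-values must lie in [0, 1]")
    if not 0 <= lam < 1:
        raise ValueError(f"lambda must lie in [0, 1), got {lam}")
    m = p.size
    pi0 = min(1.0, np.sum(p > lam) / ((1.0 - lam) * m))
    order = np.argsort(p, kind="stable")
    ps = p[order]
    raw = pi0 * m * ps / np.arange(1, m + 1)
    if pfdr:
        with np.errstate(divide="ignore"):
            denom = 1.0 - (1.0 - ps) ** m
        raw = np.where(denom > 0, raw / denom, 1.0)
    q_sorted = np.minimum.accumulate(raw[::-1])[::-1]
    q_sorted = np.minimum(q_sorted, 1.0)
    q = np.empty(m)
    q[order] = q_sorted
    return q


def pearson_acuity(values: dict[str, np.ndarray], acuity
                   ) -> dict[str, tuple[float, float]]:
    """Pearson r and two-sided p of each block measure against acuity.

    ``values`` maps a block name to a per-patient vector aligned with the
    ``acuity`` vector (amblyopic-eye logMAR).
    """
    acuity = np.asarray(acuity, dtype=float)
    if acuity.size < 3:
        raise ValueError("need >= 3 patients for a correlation")
    if np.ptp(acuity) == 0:
        raise ValueError("acuity values are constant; correlation undefined")
    out = {}
    for name, v in values.items():
        v = np.asarray(v, dtype=float)
        if v.size != acuity.size:
            raise ValueError(f"{name}: length {v.size} != {acuity.size}")
        if np.ptp(v) == 0:
            raise ValueError(f"{name}: constant values; correlation undefined")
        r, p = stats.pearsonr(v, acuity)
        out[name] = (float(r), float(p))
    return out


def _family_tests(values_by_unit: dict[str, tuple[np.ndarray, np.ndarray]],
                  lam: float = 0.5) -> list[NodeTestResult]:
    """Patient-vs-control t-test per unit, q-corrected within the family."""
    results = []
    for unit, (pat, ctl) in values_by_unit.items():
        t, df, p = two_sample_t(pat, ctl)
        results.append(NodeTestResult(
            unit=unit, mean_patient=float(np.mean(pat)),
            mean_control=float(np.mean(ctl)), t=t, df=df, p=p))
    q = storey_q([r.p for r in results], lam=lam)
    for r, qv in zip(results, q):
        r.q = float(qv)
    return results


def analyze_cohort(
    matrices: list[ConnectivityMatrix],
    profiles: list[LEProfile],
    participants: pd.DataFrame,
    atlas: RoiAtlas,
    lam: float = 0.5,
) -> GroupReport:
    """Full group-level analysis of a processed cohort.

    ``participants`` needs columns subject_id, group and (optionally)
    acuity_amblyopic; ``matrices`` and ``profiles`` are matched to subjects
    by ``subject_id``.  Produces group mean/difference matrices, the three
    ANOVAs, the three t-test families with Storey q-values, and acuity
    correlations for the patient group.
    """
    part = participants.set_index("subject_id")
    groups = {sid: part.loc[sid, "group"] for sid in part.index}
    mats = {m.subject_id: m for m in matrices}
    profs = {p.subject_id: p for p in profiles}
    sids = [s for s in part.index if s in mats]
    if len(sids) < 4:
        raise ValueError("need at least 2 subjects per group")

    summaries = [block_means(mats[s], atlas, subject_id=s, group=groups[s])
                 for s in sids]
    is_pat = np.array([groups[s] == "patient" for s in sids])

    # group mean / difference matrices
    stack = np.stack([mats[s].values for s in sids])
    mean_matrix = {
        "patient": stack[is_pat].mean(axis=0),
        "control": stack[~is_pat].mean(axis=0),
    }
    diff_matrix = mean_matrix["patient"] - mean_matrix["control"]

    # intra-network family
    intra_tab = np.array([[s.intra[n] for n in NETWORKS] for s in summaries])
    glabels = np.where(is_pat, "patient", "control")
    intra_anova = mixed_anova(intra_tab, glabels)
    intra_tests = _family_tests({
        net: (intra_tab[is_pat, j], intra_tab[~is_pat, j])
        for j, net in enumerate(NETWORKS)
    }, lam=lam)

    # inter-network family
    inter_tab = np.array([[s.inter[p] for p in INTER_PAIRS] for s in summaries])
    inter_anova = mixed_anova(inter_tab, glabels)
    inter_tests = _family_tests({
        f"{a}-{b}": (inter_tab[is_pat, j], inter_tab[~is_pat, j])
        for j, (a, b) in enumerate(INTER_PAIRS)
    }, lam=lam)

    # nodal aLE family
    if any(profs[s].ale is None for s in sids if s in profs):
        raise ValueError("LE profiles lack aLE; run graphmetrics.auc first")
    ale_tab = np.array([profs[s].ale for s in sids])
    ale_anova = mixed_anova(ale_tab, glabels)
    node_tests = _family_tests({
        lab: (ale_tab[is_pat, j], ale_tab[~is_pat, j])
        for j, lab in enumerate(atlas.labels)
    }, lam=lam)

    # acuity correlations (patients only)
    acuity_corr = {}
    if "acuity_amblyopic" in part.columns:
        ac = np.array([part.loc[s, "acuity_amblyopic"] for s in sids])[is_pat]
        blocks = {f"intra_{n}": intra_tab[is_pat, j]
                  for j, n in enumerate(NETWORKS)}
        blocks.update({f"inter_{a}-{b}": inter_tab[is_pat, j]
                       for j, (a, b) in enumerate(INTER_PAIRS)})
        try:
            acuity_corr = pearson_acuity(blocks, ac)
        except ValueError:
            acuity_corr = {}

    return GroupReport(
        mean_matrix=mean_matrix,
        diff_matrix=diff_matrix,
        labels=atlas.labels,
        intra_anova=intra_anova,
        inter_anova=inter_anova,
        ale_anova=ale_anova,
        intra_tests=intra_tests,
        inter_tests=inter_tests,
        node_tests=node_tests,
        acuity_corr=acuity_corr,
    )
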