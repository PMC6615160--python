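"""End-to-end orchestration: simulate -> preprocess -> connectivity ->
graph metrics -> group statistics, with a run manifest for reproducibility.

All randomness flows from one root seed.  Re-running a stage with identical
config and seed reproduces byte-identical TSV outputs; the manifest records
per-file SHA-256 hashes so completed stages can be skipped.
"""

from __future__ import annotations

import hashlib
import json
import logging
import time
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import graphmetrics
from .atlas import RoiAtlas, load_builtin_atlas
from .cohort import CohortConfig, read_cohort, simulate_cohort, write_cohort
from .distcorr import ConnectivityMatrix, connectivity_matrix
from .graphmetrics import DEFAULT_SPARSITY_GRID, LEProfile
from .groupstats import GroupReport, analyze_cohort
from .preprocess import PreprocConfig, preprocess_subject

log = logging.getLogger("visconn")


@dataclass
class PipelineConfig:
    cohort: CohortConfig = field(default_factory=CohortConfig)
    preproc: PreprocConfig = field(default_factory=PreprocConfig)
    sparsity_grid: tuple = DEFAULT_SPARSITY_GRID
    fdr_lambda: float = 0.5
    seed: int = 0

    def __post_init__(self):
        self.cohort.seed = self.seed
        self.validate()

    def validate(self) -> None:
        self.cohort.validate()
        self.preproc.validate(self.cohort.tr)
        grid = np.asarray(self.sparsity_grid, float)
        if len(grid) < 2 or np.any(np.diff(grid) <= 0):
            raise ValueError("sparsity grid must be increasing with >= 2 points")
        if not 0 <= self.fdr_lambda < 1:
            raise ValueError("fdr lambda must lie in [0, 1)")


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    h.update(path.read_bytes())
    return h.hexdigest()


class Manifest:
    """Append-only record of stages, output hashes and counts."""

    def __init__(self, path: Path):
        self.path = Path(path)
        self.stages: dict = {}
        if self.path.exists():
            self.stages = json.loads(self.path.read_text()).get("stages", {})

    def record(self, stage: str, outputs: list[Path], **counts) -> None:
        self.stages[stage] = {
            "timestamp": time.strftime("%Y-%m-%dT%H:%M:%S"),
            "outputs": {str(p): _sha256(p) for p in sorted(outputs)},
            **counts,
        }
        self.path.write_text(json.dumps({"stages": self.stages}, indent=2))

    def up_to_date(self, stage: str) -> bool:
        info = self.stages.get(stage)
        if not info:
            return False
        return all(Path(p).exists() and _sha256(Path(p)) == h
                   for p, h in info["outputs"].items())


def run_pipeline(
    config: PipelineConfig,
    outdir,
    atlas: RoiAtlas | None = None,
    write_files: bool = True,
) -> GroupReport:
    """Run the full workflow on a freshly simulated cohort.

    Writes per-subject connectivity matrices and LE profiles, the group
    report (JSON + TSV tables) and a run manifest under ``outdir`` unless
    ``write_files`` is False.
    """
    config.validate()
    if outdir is None and write_files:
        raise ValueError("outdir is required when write_files=True")
    outdir = Path(outdir) if outdir is not None else None
    atlas = atlas or load_builtin_atlas()

    log.info("simulating cohort: %d subjects per group, %d frames",
             config.cohort.n_per_group, config.cohort.t_frames)
    cohort = simulate_cohort(config.cohort, atlas=atlas)

    matrices: list[ConnectivityMatrix] = []
    profiles: list[LEProfile] = []
    for scan in cohort:
        prepared = preprocess_subject(scan, config.preproc)
        log.info("%s: kept %d/%d frames", scan.subject_id,
                 prepared.meta["n_frames_kept"], prepared.meta["n_frames_in"])
        cm = connectivity_matrix(prepared.roi_data, atlas,
                                 subject_id=scan.subject_id)
        matrices.append(cm)
        prof = graphmetrics.auc(
            graphmetrics.le_curve(cm, config.sparsity_grid,
                                  subject_id=scan.subject_id))
        profiles.append(prof)

    participants = pd.DataFrame([{
        "subject_id": s.subject_id, "group": s.group,
        **{f"acuity_{eye}": v for eye, v in s.acuity.items()},
    } for s in cohort])

    report = analyze_cohort(matrices, profiles, participants, atlas,
                            lam=config.fdr_lambda)
    if write_files:
        outdir.mkdir(parents=True, exist_ok=True)
        write_report(report, matrices, profiles, participants, outdir)
        manifest = Manifest(outdir / "manifest.json")
        outputs = sorted(outdir.rglob("*.tsv")) + [outdir / "report.json"]
        manifest.record("run_all", outputs,
                        n_subjects=len(cohort),
                        n_edges_total=atlas and len(atlas) * (len(atlas) - 1) // 2)
    return report


def write_report(report: GroupReport, matrices, profiles, participants,
                 outdir: Path) -> None:
    outdir = Path(outdir)
    (outdir / "matrices").mkdir(parents=True, exist_ok=True)
    (outdir / "profiles").mkdir(exist_ok=True)
    for m in matrices:
        m.to_tsv(outdir / "matrices" / f"{m.subject_id}.tsv")
    for p in profiles:
        p.to_tsv(outdir / "profiles" / f"{p.subject_id}.tsv")
    participants.to_csv(outdir / "participants.tsv", sep="\t", index=False)

    labels = report.labels
    for name, mat in report.mean_matrix.items():
        pd.DataFrame(mat, index=labels, columns=labels).to_csv(
            outdir / f"mean_matrix_{name}.tsv", sep="\t")
    pd.DataFrame(report.diff_matrix, index=labels, columns=labels).to_csv(
        outdir / "diff_matrix.tsv", sep="\t")
    for family in ("intra", "inter", "node"):
        report.tests_frame(family).to_csv(
            outdir / f"tests_{family}.tsv", sep="\t", index=False)

    payload = {
        "anova": {
            name: {k: {"F": f, "df": list(d), "p": p}
                   for k, (f, d, p) in tab.effects.items()}
            for name, tab in (("intra", report.intra_anova),
                              ("inter", report.inter_anova),
                              ("ale", report.ale_anova))
        },
        "tests": {family: report.tests_frame(family).to_dict("records")
                  for family in ("intra", "inter", "node")},
        "acuity_correlation": {k: {"r": r, "p": p}
                               for k, (r, p) in report.acuity_corr.items()},
    }
    (outdir / "report.json").write_text(json.dumps(payload, indent=2))


def render_figures(results_dir, outdir=None, sparsity: float = 0.35) -> list[Path]:
    """Heatmaps of the group mean/difference matrices, a node-size network
    rendering at one sparsity (default 0.35), and group bar charts."""
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    results_dir = Path(results_dir)
    outdir = Path(outdir) if outdir else results_dir / "figures"
    needed = [results_dir / f"mean_matrix_{g}.tsv" for g in ("patient", "control")]
    needed += [results_dir / "diff_matrix.tsv", results_dir / "tests_node.tsv"]
    missing = [str(p) for p in needed if not p.exists()]
    if missing:
        raise FileNotFoundError(f"missing result files: {missing}")
    outdir.mkdir(parents=True, exist_ok=True)

    mats = {g: pd.read_csv(results_dir / f"mean_matrix_{g}.tsv",
                           sep="\t", index_col=0) for g in ("patient", "control")}
    diff = pd.read_csv(results_dir / "diff_matrix.tsv", sep="\t", index_col=0)
    figures = []

    fig, axes = plt.subplots(1, 3, figsize=(15, 4.5))
    for ax, (name, df) in zip(axes, [*mats.items(), ("difference", diff)]):
        im = ax.imshow(df.to_numpy(), cmap="coolwarm")
        ax.set_title(name)
        ax.set_xticks(range(len(df)), df.columns, rotation=90, fontsize=5)
        ax.set_yticks(range(len(df)), df.index, fontsize=5)
        fig.colorbar(im, ax=ax, shrink=0.8)
    path = outdir / "matrices.png"
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)
    figures.append(path)

    # node-size rendering at the illustration sparsity
    import networkx as nx
    from .graphmetrics import sparsity_threshold
    node_tests = pd.read_csv(results_dir / "tests_node.tsv", sep="\t")
    fig, axes = plt.subplots(1, 2, figsize=(12, 5.5))
    for ax, group in zip(axes, ("patient", "control")):
        w = mats[group].to_numpy()
        g = sparsity_threshold(w, sparsity).to_networkx()
        pos = nx.circular_layout(g)
        sizes = 3000 * node_tests[f"mean_{group}"].to_numpy()
        nx.draw_networkx(g, pos=pos, ax=ax, node_size=sizes,
                         labels=dict(enumerate(mats[group].index)),
                         font_size=6, width=0.5)
        ax.set_title(f"{group} (sparsity {sparsity})")
        ax.axis("off")
    path = outdir / "network.png"
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)
    figures.append(path)

    fig, axes = plt.subplots(1, 2, figsize=(10, 4))
    for ax, family in zip(axes, ("intra", "inter")):
        df = pd.read_csv(results_dir / f"tests_{family}.tsv", sep="\t")
        x = np.arange(len(df))
        ax.bar(x - 0.2, df["mean_patient"], width=0.4, label="patient")
        ax.bar(x + 0.2, df["mean_control"], width=0.4, label="control")
        ax.set_xticks(x, df["unit"], rotation=30, fontsize=7)
        ax.set_ylabel("mean Fisher-z")
        ax.set_title(f"{family}-network connectivity")
        ax.legend(fontsize=7)
    path = outdir / "block_means.png"
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)
    figures.append(path)
    return figures
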