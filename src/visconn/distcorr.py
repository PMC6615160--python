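"""Multivariate distance-correlation functional connectivity.

Connectivity between two regions A and B with voxel x time matrices is
measured by the bias-corrected (U-centered) distance correlation:

1. each voxel time course is z-scored (mean 0, SD 1);
2. the t x t Euclidean distance matrix between time points is formed per
   region, using all voxels of that region as the feature vector;
3. the distance matrices are U-centered, so all row and column sums vanish
   and the diagonal is zero;
4. dCov(A, B) = 1/(t(t-3)) * sum of the elementwise product of the two
   U-centered matrices; dVar(A) = dCov(A, A);
5. dCor = sqrt(dCov / sqrt(dVar_A * dVar_B)) when dCov > 0, else 0.

The U-centered estimator of dCov is unbiased and may be negative under
independence; the square root is only taken on the positive part, so dCor
lies in [0, 1].  Edges of the subject connectivity matrix are the Fisher
z-transform of dCor.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .atlas import RoiAtlas

#: dCor values are clamped just below 1 before the Fisher transform.
FISHER_CLAMP = 1.0 - 1e-7


@dataclass
class ConnectivityMatrix:
    """Symmetric N x N matrix of Fisher-z distance-correlation edges."""

    values: np.ndarray
    labels: list[str]
    subject_id: str | None = None

    def __post_init__(self):
        v = np.asarray(self.values, dtype=float)
        if v.ndim != 2 or v.shape[0] != v.shape[1]:
            raise ValueError(f"connectivity matrix must be square, got {v.shape}")
        if len(self.labels) != v.shape[0]:
            raise ValueError("label count does not match matrix size")
        if not np.allclose(v, v.T):
            raise ValueError("connectivity matrix must be symmetric")
        if not np.all(np.isfinite(v)):
            raise ValueError("connectivity matrix contains non-finite entries")
        self.values = v

    @property
    def n(self) -> int:
        return self.values.shape[0]

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.values, index=self.labels, columns=self.labels)

    def to_tsv(self, path) -> None:
        self.to_frame().to_csv(path, sep="\t")

    @classmethod
    def from_tsv(cls, path, subject_id: str | None = None) -> "ConnectivityMatrix":
        df = pd.read_csv(path, sep="\t", index_col=0)
        return cls(df.to_numpy(), list(df.index), subject_id=subject_id)


def ztransfer_voxels(roi_matrix: np.ndarray) -> np.ndarray:
    """Z-score each voxel row by its own mean and SD.

    Constant rows have no variance to scale by; they are mapped to all-zero
    rows with a warning so a degenerate voxel cannot poison a whole run.
    """
    x = np.asarray(roi_matrix, dtype=float)
    if x.ndim != 2:
        raise ValueError(f"expected voxels x time matrix, got shape {x.shape}")
    if x.shape[1] < 2:
        raise ValueError("need at least 2 time points to standardize")
    mu = x.mean(axis=1, keepdims=True)
    sd = x.std(axis=1, keepdims=True)
    flat = (sd == 0).ravel()
    if flat.any():
        warnings.warn(
            f"{int(flat.sum())} constant voxel row(s) mapped to zero", stacklevel=2
        )
        sd = np.where(sd == 0, 1.0, sd)
    out = (x - mu) / sd
    out[flat, :] = 0.0
    return out


def time_distance_matrix(roi_matrix: np.ndarray) -> np.ndarray:
    """Euclidean distances between all pairs of time points.

    ``roi_matrix`` is voxels x time (already standardized); column ``t`` is
    the multivoxel pattern at time ``t``.  Returns a symmetric t x t matrix
    with zero diagonal.
    """
    from scipy.spatial.distance import pdist, squareform

    x = np.asarray(roi_matrix, dtype=float)
    if x.ndim != 2:
        raise ValueError(f"expected voxels x time matrix, got shape {x.shape}")
    return squareform(pdist(x.T, metric="euclidean"))


def u_center(d: np.ndarray) -> np.ndarray:
    """U-centering of a distance matrix.

    Off-diagonal entries become
    ``d_ij - rowsum_i/(t-2) - colsum_j/(t-2) + total/((t-1)(t-2))``;
    the diagonal is forced to zero.  Every row and column of the result sums
    to zero, which makes the derived distance covariance unbiased.
    """
    d = np.asarray(d, dtype=float)
    t = d.shape[0]
    if d.ndim != 2 or d.shape[1] != t:
        raise ValueError(f"distance matrix must be square, got {d.shape}")
    if t < 4:
        raise ValueError(f"U-centering needs t >= 4 time points, got {t}")
    row = d.sum(axis=1, keepdims=True)
    col = d.sum(axis=0, keepdims=True)
    total = d.sum()
    out = d - row / (t - 2) - col / (t - 2) + total / ((t - 1) * (t - 2))
    np.fill_diagonal(out, 0.0)
    return out


def dcov(da: np.ndarray, db: np.ndarray) -> float:
    """Unbiased distance covariance from two U-centered matrices (signed)."""
    da = np.asarray(da, dtype=float)
    db = np.asarray(db, dtype=float)
    if da.shape != db.shape:
        raise ValueError(f"shape mismatch: {da.shape} vs {db.shape}")
    t = da.shape[0]
    return float((da * db).sum() / (t * (t - 3)))


def dvar(da: np.ndarray) -> float:
    """Distance variance; dcov of a U-centered matrix with itself (>= 0)."""
    return dcov(da, da)


def dcor(a: np.ndarray, b: np.ndarray, *, standardize: bool = True) -> float:
    """Distance correlation between two voxel x time matrices, in [0, 1].

    Negative dCov (possible for the unbiased estimator under independence)
    is clamped to 0.  A region with zero distance variance (all time points
    identical) yields 0 with a warning.
    """
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if a.shape[-1] != b.shape[-1]:
        raise ValueError(
            f"time length mismatch: {a.shape[-1]} vs {b.shape[-1]}"
        )
    if a.shape[-1] < 4:
        raise ValueError("distance correlation needs t >= 4 time points")
    if standardize:
        a = ztransfer_voxels(a)
        b = ztransfer_voxels(b)
    da = u_center(time_distance_matrix(a))
    db = u_center(time_distance_matrix(b))
    return dcor_from_centered(da, db)


def dcor_from_centered(da: np.ndarray, db: np.ndarray) -> float:
    """dCor from precomputed U-centered matrices (shared by the cohort path)."""
    va = dvar(da)
    vb = dvar(db)
    if va <= 0 or vb <= 0:
        warnings.warn("zero distance variance; dCor set to 0", stacklevel=2)
        return 0.0
    c = dcov(da, db)
    if c <= 0:
        return 0.0
    return float(np.sqrt(c / np.sqrt(va * vb)))


def fisher_z(r: float) -> float:
    """Fisher transform z = 0.5*ln((1+r)/(1-r)) of a dCor value in [0, 1].

    Values at (or within 1e-7 of) 1 are clamped so the edge stays finite.
    """
    r = float(r)
    if not 0.0 <= r <= 1.0:
        raise ValueError(f"dCor value must lie in [0, 1], got {r}")
    if r >= FISHER_CLAMP:
        warnings.warn(f"dCor {r} clamped to {FISHER_CLAMP} before Fisher transform",
                      stacklevel=2)
        r = FISHER_CLAMP
    return float(np.arctanh(r))


def connectivity_matrix(
    roi_data: dict[str, np.ndarray],
    atlas: RoiAtlas,
    subject_id: str | None = None,
) -> ConnectivityMatrix:
    """Fisher-z distance-correlation matrix over all atlas node pairs.

    ``roi_data`` maps node label -> prepared voxels x time matrix.  The
    U-centered distance matrix of each region is computed once and reused
    for all pairs; the result is symmetric with a zero diagonal and rows in
    atlas node order.
    """
    labels = atlas.labels
    missing = [lab for lab in labels if lab not in roi_data]
    if missing:
        raise KeyError(f"missing ROI data for nodes: {missing}")
    t = roi_data[labels[0]].shape[1]
    if t < 4:
        raise ValueError(f"need >= 4 time points for distance correlation, got {t}")

    centered = {}
    for lab in labels:
        mat = roi_data[lab]
        if mat.shape[1] != t:
            raise ValueError(f"node {lab}: time length {mat.shape[1]} != {t}")
        centered[lab] = u_center(time_distance_matrix(ztransfer_voxels(mat)))

    n = len(labels)
    z = np.zeros((n, n))
    for i in range(n):
        for j in range(i + 1, n):
            try:
                r = dcor_from_centered(centered[labels[i]], centered[labels[j]])
                z[i, j] = z[j, i] = fisher_z(r)
            except ValueError as exc:
                raise ValueError(
                    f"edge {labels[i]}-{labels[j]}: {exc}"
                ) from exc
    return ConnectivityMatrix(z, labels, subject_id=subject_id)
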