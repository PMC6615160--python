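"""Temporal preprocessing of per-ROI voxel time series.

Stages, in pipeline order: polynomial detrend, framewise-displacement
censoring (frame deletion), zero-phase band-pass filtering of the kept
frames, and nuisance regression against the 6 rigid-body motion parameters
and their backward-difference derivatives.  Motion confounds are censored
and filtered identically to the data before regression.

Framewise displacement follows the Power convention: the sum of absolute
backward differences of the three translations (mm) plus the three
rotations (radians) scaled by a 50 mm head radius.  Frames whose FD exceeds
the threshold (default 0.2 mm) are deleted.  Band-pass filtering of a
censored series is ill-posed on the gappy grid, so the filter runs on the
concatenated kept frames; set ``filter_before_censor=True`` to filter the
full-length series first instead.
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from functools import lru_cache

import numpy as np
from scipy import signal


@dataclass
class CensorMask:
    keep: np.ndarray  # boolean per frame
    threshold: float  # mm

    def __post_init__(self):
        self.keep = np.asarray(self.keep, dtype=bool)
        if self.threshold <= 0:
            raise ValueError(f"FD threshold must be > 0 mm, got {self.threshold}")

    @property
    def n_kept(self) -> int:
        return int(self.keep.sum())


@dataclass
class PreprocConfig:
    fd_threshold: float = 0.2       # mm
    detrend_order: int = 3
    bandpass: tuple[float, float] = (0.01, 0.10)  # Hz
    head_radius: float = 50.0       # mm, rotation -> displacement
    min_kept_frames: int = 50
    filter_order: int = 4           # effective Butterworth order (zero-phase)
    filter_before_censor: bool = False

    def validate(self, tr: float) -> None:
        low, high = self.bandpass
        nyq = 1.0 / (2.0 * tr)
        if not 0 < low < high < nyq:
            raise ValueError(
                f"band ({low}, {high}) Hz invalid for TR {tr} s (Nyquist {nyq} Hz)"
            )
        if self.detrend_order < 0:
            raise ValueError("detrend order must be >= 0")


def framewise_displacement(motion: np.ndarray, head_radius: float = 50.0) -> np.ndarray:
    """Per-frame FD (mm) from a t x 6 motion trace.

    Columns 0-2 are translations in mm, columns 3-5 rotations in radians;
    rotations are converted to arc displacement on a sphere of
    ``head_radius`` mm.  FD[0] = 0 by convention (backward differences).
    """
    motion = np.asarray(motion, dtype=float)
    if motion.ndim != 2 or motion.shape[1] < 6:
        raise ValueError(f"motion trace must be t x 6, got {motion.shape}")
    if motion.shape[0] < 2:
        raise ValueError("need at least 2 frames for framewise displacement")
    diffs = np.abs(np.diff(motion[:, :6], axis=0))
    fd = diffs[:, :3].sum(axis=1) + head_radius * diffs[:, 3:6].sum(axis=1)
    return np.concatenate([[0.0], fd])


def censor(fd: np.ndarray, threshold: float = 0.2,
           min_kept_frames: int = 0) -> CensorMask:
    """Mark frames with FD above ``threshold`` for deletion."""
    fd = np.asarray(fd, dtype=float)
    keep = fd <= threshold
    n_kept = int(keep.sum())
    if n_kept < min_kept_frames:
        raise ValueError(
            f"only {n_kept} of {fd.size} frames survive FD censoring at "
            f"{threshold} mm (minimum {min_kept_frames})"
        )
    return CensorMask(keep=keep, threshold=threshold)


def detrend_poly(series_matrix: np.ndarray, order: int = 3) -> np.ndarray:
    """Remove a least-squares polynomial trend of given order from each row.

    Uses a Legendre-style orthonormal basis on [-1, 1] for conditioning.
    Residuals are orthogonal to every polynomial of degree <= order.
    """
    x = np.atleast_2d(np.asarray(series_matrix, dtype=float))
    t = x.shape[1]
    if t <= order + 1:
        raise ValueError(f"need t > order + 1 frames (t={t}, order={order})")
    grid = np.linspace(-1.0, 1.0, t)
    basis = np.polynomial.legendre.legvander(grid, order)
    q, _ = np.linalg.qr(basis)
    coef = x @ q
    return x - coef @ q.T


def regress_confounds(series_matrix: np.ndarray, motion: np.ndarray) -> np.ndarray:
    """OLS residuals of each row on [intercept, 6 motion, 6 derivatives].

    Derivatives are backward differences with a leading zero row.  Constant
    confound columns (e.g. all-zero motion) are dropped rather than treated
    as rank deficiency; any remaining collinearity raises with the offending
    columns named.
    """
    x = np.atleast_2d(np.asarray(series_matrix, dtype=float))
    motion = np.asarray(motion, dtype=float)
    if motion.ndim != 2 or motion.shape[1] < 6:
        raise ValueError(f"motion trace must be t x 6, got {motion.shape}")
    if motion.shape[0] != x.shape[1]:
        raise ValueError(
            f"motion length {motion.shape[0]} != series length {x.shape[1]}"
        )
    deriv = np.vstack([np.zeros((1, 6)), np.diff(motion[:, :6], axis=0)])
    names = (["intercept"]
             + [f"motion{k}" for k in range(6)]
             + [f"dmotion{k}" for k in range(6)])
    conf = np.column_stack([np.ones(x.shape[1]), motion[:, :6], deriv])
    keep = [0] + [j for j in range(1, conf.shape[1])
                  if np.ptp(conf[:, j]) > 0]
    conf = conf[:, keep]
    rank = np.linalg.matrix_rank(conf)
    if rank < conf.shape[1]:
        kept_names = [names[j] for j in keep]
        raise ValueError(
            f"confound matrix rank deficient ({rank} < {conf.shape[1]}); "
            f"columns: {kept_names}"
        )
    beta, *_ = np.linalg.lstsq(conf, x.T, rcond=None)
    return x - (conf @ beta).T


@lru_cache(maxsize=32)
def _butter_sos(design_order: int, wlow: float, whigh: float) -> np.ndarray:
    return signal.butter(design_order, [wlow, whigh],
                         btype="bandpass", output="sos")


def bandpass(series_matrix: np.ndarray, low: float, high: float,
             tr: float, order: int = 4) -> np.ndarray:
    """Zero-phase Butterworth band-pass along rows.

    ``order`` is the effective order after forward-backward filtering
    (``sosfiltfilt`` doubles the design order, so the filter is designed at
    order/2).
    """
    x = np.atleast_2d(np.asarray(series_matrix, dtype=float))
    nyq = 1.0 / (2.0 * tr)
    if not 0 < low < high < nyq:
        raise ValueError(f"invalid band ({low}, {high}) Hz for TR {tr} s")
    if order % 2:
        raise ValueError("effective filter order must be even")
    sos = _butter_sos(order // 2, low / nyq, high / nyq)
    padlen = min(x.shape[1] - 1, 3 * (order + 1) * 10)
    return signal.sosfiltfilt(sos, x, axis=1, padlen=padlen)


def preprocess_subject(scan, config: PreprocConfig | None = None):
    """Full temporal preprocessing of one subject scan.

    Order: polynomial detrend -> FD censoring (frame deletion) -> band-pass
    on kept frames -> regression of motion + derivative confounds (confounds
    identically censored and filtered).  Returns a new scan whose ``meta``
    records the censor mask and kept-frame count.
    """
    from .cohort import SubjectScan

    config = config or PreprocConfig()
    config.validate(scan.tr)
    t = scan.n_frames
    fd = framewise_displacement(scan.motion, config.head_radius)
    mask = censor(fd, config.fd_threshold, config.min_kept_frames)

    deriv_full = np.vstack([np.zeros((1, 6)), np.diff(scan.motion[:, :6], axis=0)])
    conf_full = np.column_stack([scan.motion[:, :6], deriv_full])

    def prepare(mat: np.ndarray) -> np.ndarray:
        out = detrend_poly(mat, config.detrend_order)
        if config.filter_before_censor:
            out = bandpass(out, *config.bandpass, scan.tr, config.filter_order)
            out = out[:, mask.keep]
        else:
            out = out[:, mask.keep]
            out = bandpass(out, *config.bandpass, scan.tr, config.filter_order)
        return out

    conf_prep = prepare(conf_full.T).T
    roi_out = {}
    for label, mat in scan.roi_data.items():
        prepared = prepare(mat)
        # regression re-uses the generic path but with pre-filtered confounds
        conf = np.column_stack([np.ones(prepared.shape[1]), conf_prep])
        keep_cols = [0] + [j for j in range(1, conf.shape[1])
                           if np.ptp(conf[:, j]) > 1e-12]
        conf = conf[:, keep_cols]
        beta, *_ = np.linalg.lstsq(conf, prepared.T, rcond=None)
        roi_out[label] = prepared - (conf @ beta).T

    meta = dict(scan.meta or {})
    meta.update(
        n_frames_in=t,
        n_frames_kept=mask.n_kept,
        fd_threshold=config.fd_threshold,
        censor_mask=mask.keep.astype(int).tolist(),
    )
    return replace(
        scan,
        roi_data=roi_out,
        motion=scan.motion[mask.keep],
        meta=meta,
    )
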