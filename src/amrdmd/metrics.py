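"""Accuracy metrics for snapshot reconstructions.

η_F is the overall relative Frobenius error of the reconstructed snapshot
matrix; η(t) is the per-snapshot relative L2 error.  Both are scale invariant.
Wall-clock speedups are deliberately not computed here (hardware dependent).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .dmd import SnapshotSeries, evaluate, fit_dmd

__all__ = [
    "ErrorReport",
    "overall_relative_error",
    "snapshot_relative_error",
    "error_report",
    "rank_study",
]


def _values(Y) -> np.ndarray:
    return Y.values if isinstance(Y, SnapshotSeries) else np.asarray(Y, dtype=float)


@dataclass
class ErrorReport:
    """η_F plus the η(t) series; columns at or after ``split_index`` are forecast."""

    eta_F: float
    eta_t: np.ndarray
    times: np.ndarray
    split_index: int

    @property
    def eta_F_reconstruction(self) -> float:
        return _eta_f_slice(self, slice(None, self.split_index))

    @property
    def eta_F_prediction(self) -> float:
        return _eta_f_slice(self, slice(self.split_index, None))

    def to_frame(self) -> pd.DataFrame:
        phase = np.where(np.arange(len(self.eta_t)) < self.split_index,
                         "reconstruction", "prediction")
        return pd.DataFrame({
            "k": np.arange(len(self.eta_t)),
            "t": self.times,
            "eta_k": self.eta_t,
            "phase": phase,
        })

    _ref_norms: np.ndarray | None = None
    _err_norms: np.ndarray | None = None


def _eta_f_slice(rep: ErrorReport, sl: slice) -> float:
    if rep._ref_norms is None:
        raise ValueError("phase-wise errors need the norms recorded by error_report()")
    ref = rep._ref_norms[sl]
    err = rep._err_norms[sl]
    denom = np.sqrt(np.sum(ref**2))
    if denom == 0:
        return float("nan")
    return float(np.sqrt(np.sum(err**2)) / denom)


def overall_relative_error(Y, Y_dmd) -> float:
    """η_F = ||Y − Y_dmd||_F / ||Y||_F."""
    A, B = _values(Y), _values(Y_dmd)
    if A.shape != B.shape:
        raise ValueError(f"shape mismatch {A.shape} vs {B.shape}")
    denom = np.linalg.norm(A)
    if denom == 0:
        raise ValueError("reference snapshot matrix has zero Frobenius norm")
    return float(np.linalg.norm(A - B) / denom)


def snapshot_relative_error(Y, Y_dmd) -> np.ndarray:
    """Per-column η_k = ||u_k − u_k_dmd||_2 / ||u_k||_2 (NaN where ||u_k|| = 0)."""
    A, B = _values(Y), _values(Y_dmd)
    if A.shape != B.shape:
        raise ValueError(f"shape mismatch {A.shape} vs {B.shape}")
    ref = np.linalg.norm(A, axis=0)
    err = np.linalg.norm(A - B, axis=0)
    out = np.full(A.shape[1], np.nan)
    nz = ref > 0
    if not np.all(nz):
        warnings.warn(
            f"{np.count_nonzero(~nz)} snapshot(s) with zero norm skipped", stacklevel=2
        )
    out[nz] = err[nz] / ref[nz]
    return out


def error_report(Y: SnapshotSeries, Y_dmd: SnapshotSeries, split_time: float | None = None) -> ErrorReport:
    """Full report against the reference series; ``split_time`` marks the first
    forecast instant (columns at t >= split_time count as prediction)."""
    if Y.values.shape != Y_dmd.values.shape:
        raise ValueError("series must share shape")
    t = Y.times
    if split_time is None:
        split_index = len(t)
    else:
        split_index = int(np.searchsorted(t, split_time - 1e-9 * Y.dt_o))
    rep = ErrorReport(
        eta_F=overall_relative_error(Y, Y_dmd),
        eta_t=snapshot_relative_error(Y, Y_dmd),
        times=t,
        split_index=split_index,
    )
    rep._ref_norms = np.linalg.norm(Y.values, axis=0)
    rep._err_norms = np.linalg.norm(Y.values - Y_dmd.values, axis=0)
    return rep


def rank_study(Y: SnapshotSeries, ranks, svd_method: str = "deterministic",
               seed: int | None = None) -> pd.DataFrame:
    """Fit one model per rank on the given (training) series and score its
    reconstruction there; larger ranks retain more singular directions and the
    training error decreases accordingly."""
    rows = []
    for r in ranks:
        model = fit_dmd(Y, r=r, svd_method=svd_method, seed=seed)
        rec = evaluate(model, Y.times)
        rows.append({"r": int(r), "eta_F": overall_relative_error(Y.values, rec)})
    return pd.DataFrame(rows)
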