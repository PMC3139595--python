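"""From ROI time series to Pearson functional-connectivity matrices.

Nodes of a resting-state functional brain network are atlas regions of
interest (ROIs); an edge is the Pearson correlation between the two ROIs'
mean time courses after nuisance regression and band-pass filtering.  This
module holds the pipeline's rawest containers (:class:`TimeSeriesMatrix`,
:class:`CorrelationMatrix`), the preprocessing steps that act on them, and
Fisher-z utilities used for variance-stabilised averaging of scans.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np
import pandas as pd
from scipy import signal, stats

__all__ = [
    "TimeSeriesMatrix",
    "NuisanceSet",
    "CorrelationMatrix",
    "bandpass_filter",
    "regress_nuisance",
    "correlation_matrix",
    "fisher_z",
    "fisher_z_inv",
    "average_matrices",
    "matrix_similarity",
    "read_timeseries_tsv",
    "write_timeseries_tsv",
    "read_matrix_tsv",
    "write_matrix_tsv",
]


# ---------------------------------------------------------------------------
# containers
# ---------------------------------------------------------------------------

@dataclass
class TimeSeriesMatrix:
    """T timepoints x N ROIs of one subject-scan.

    ``sampling_interval`` is the repetition time in seconds (2.0 for a
    TR of 2000 ms).
    """

    values: np.ndarray
    roi_labels: list[str]
    subject_id: str = ""
    scan_id: str = ""
    sampling_interval: float = 2.0

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 2:
            raise ValueError("time series must be a 2-D (T x N) array")
        if self.values.shape[0] < 4:
            raise ValueError("need at least 4 timepoints")
        if self.values.shape[1] != len(self.roi_labels):
            raise ValueError("number of ROI labels must match columns")
        if not np.all(np.isfinite(self.values)):
            raise ValueError("time series contain non-finite values")
        if self.sampling_interval <= 0:
            raise ValueError("sampling_interval must be positive")

    @property
    def n_timepoints(self) -> int:
        return self.values.shape[0]

    @property
    def n_rois(self) -> int:
        return self.values.shape[1]

    def constant_rois(self, tol: float = 0.0) -> list[str]:
        """Labels of ROIs whose time course has (near-)zero variance."""
        sd = self.values.std(axis=0)
        return [lab for lab, s in zip(self.roi_labels, sd) if s <= tol]


@dataclass
class NuisanceSet:
    """T x p nuisance regressors (head motion, global signal, ...)."""

    regressors: np.ndarray
    names: list[str]

    def __post_init__(self) -> None:
        self.regressors = np.asarray(self.regressors, dtype=float)
        if self.regressors.size == 0:
            self.regressors = self.regressors.reshape(0, 0)
        if self.regressors.ndim != 2:
            raise ValueError("regressors must be 2-D (T x p)")
        if self.regressors.shape[1] != len(self.names):
            raise ValueError("number of names must match regressor columns")

    @classmethod
    def empty(cls, n_timepoints: int) -> "NuisanceSet":
        return cls(np.empty((n_timepoints, 0)), [])


@dataclass
class CorrelationMatrix:
    """Symmetric N x N Pearson connectivity matrix for one subject-scan.

    The diagonal is fixed at 1 and excluded from every downstream
    statistic: "all connections" always means the strict upper triangle,
    N(N-1)/2 entries.
    """

    r: np.ndarray
    roi_labels: list[str]
    subject_id: str = ""
    scan_id: str = ""

    def __post_init__(self) -> None:
        self.r = np.asarray(self.r, dtype=float)
        n = self.r.shape[0]
        if self.r.ndim != 2 or self.r.shape[1] != n:
            raise ValueError("correlation matrix must be square")
        if len(self.roi_labels) != n:
            raise ValueError("number of ROI labels must match matrix size")
        if not np.allclose(self.r, self.r.T, atol=1e-10):
            raise ValueError("correlation matrix must be symmetric")
        off = self.r[~np.eye(n, dtype=bool)]
        if off.size and (off.min() < -1 - 1e-12 or off.max() > 1 + 1e-12):
            raise ValueError("off-diagonal correlations must lie in [-1, 1]")
        # enforce the exact-diagonal / exact-symmetry invariant
        self.r = (self.r + self.r.T) / 2.0
        np.clip(self.r, -1.0, 1.0, out=self.r)
        np.fill_diagonal(self.r, 1.0)

    @property
    def n_rois(self) -> int:
        return self.r.shape[0]

    def upper_values(self) -> np.ndarray:
        """Strict upper-triangle entries in row-major (i<j) order."""
        iu = np.triu_indices(self.n_rois, k=1)
        return self.r[iu]


# ---------------------------------------------------------------------------
# preprocessing
# ---------------------------------------------------------------------------

def bandpass_filter(ts: TimeSeriesMatrix, low_hz: float = 0.01,
                    high_hz: float = 0.1, order: int = 2) -> TimeSeriesMatrix:
    """Zero-phase Butterworth band-pass of every ROI time course.

    The low-frequency band 0.01-0.1 Hz is the standard window for
    spontaneous BOLD fluctuations.  Each column is demeaned and filtered
    forward-backward (``filtfilt``), so the output has zero phase shift
    and zero mean.
    """
    nyquist = 1.0 / (2.0 * ts.sampling_interval)
    if not (0 <= low_hz < high_hz):
        raise ValueError("need 0 <= low_hz < high_hz")
    if high_hz >= nyquist:
        raise ValueError(
            f"high_hz={high_hz} must be below the Nyquist frequency "
            f"{nyquist} Hz for sampling interval {ts.sampling_interval}s")
    x = ts.values - ts.values.mean(axis=0)
    if low_hz > 0:
        wn = [low_hz / nyquist, high_hz / nyquist]
        sos = signal.butter(order, wn, btype="bandpass", output="sos")
    else:
        sos = signal.butter(order, high_hz / nyquist, btype="lowpass",
                            output="sos")
    padlen = 3 * (2 * order + 1)
    if ts.n_timepoints <= padlen:
        raise ValueError(
            f"series too short ({ts.n_timepoints} timepoints) for a "
            f"zero-phase order-{order} filter (needs > {padlen})")
    y = signal.sosfiltfilt(sos, x, axis=0)
    y = y - y.mean(axis=0)
    return replace(ts, values=y)


def regress_nuisance(ts: TimeSeriesMatrix, nuis: NuisanceSet) -> TimeSeriesMatrix:
    """Least-squares removal of nuisance regressors (plus intercept).

    Every output column is the residual of the input column on
    ``[intercept | regressors]``; residuals are orthogonal to every
    regressor column and have zero mean.
    """
    t = ts.n_timepoints
    if nuis.regressors.shape[0] not in (0, t):
        raise ValueError("nuisance regressors must have the same number of "
                         "timepoints as the series")
    ones = np.ones((t, 1))
    if nuis.regressors.size:
        design = np.hstack([ones, nuis.regressors])
    else:
        design = ones
    rank = np.linalg.matrix_rank(design)
    if rank < design.shape[1]:
        # identify which added columns break full rank
        bad = []
        kept = ones
        for j, name in enumerate(nuis.names):
            cand = np.hstack([kept, nuis.regressors[:, [j]]])
            if np.linalg.matrix_rank(cand) == kept.shape[1]:
                bad.append(name)
            else:
                kept = cand
        raise ValueError(f"rank-deficient nuisance design; collinear "
                         f"columns: {bad}")
    beta, *_ = np.linalg.lstsq(design, ts.values, rcond=None)
    resid = ts.values - design @ beta
    return replace(ts, values=resid)


def correlation_matrix(ts: TimeSeriesMatrix) -> CorrelationMatrix:
    """Pearson correlation between every pair of ROI time courses."""
    const = ts.constant_rois(tol=0.0)
    if const:
        raise ValueError(f"constant time course for ROI(s): {const}")
    r = np.corrcoef(ts.values, rowvar=False)
    r = np.clip((r + r.T) / 2.0, -1.0, 1.0)
    np.fill_diagonal(r, 1.0)
    return CorrelationMatrix(r, list(ts.roi_labels), ts.subject_id, ts.scan_id)


# ---------------------------------------------------------------------------
# Fisher-z utilities and matrix-level operations
# ---------------------------------------------------------------------------

def fisher_z(r):
    """Fisher r-to-z transform, z = atanh(r).  Requires |r| < 1."""
    r = np.asarray(r, dtype=float)
    if np.any(np.abs(r) >= 1):
        raise ValueError("fisher_z requires |r| < 1 (handle the diagonal "
                         "separately)")
    out = np.arctanh(r)
    return float(out) if out.ndim == 0 else out


def fisher_z_inv(z):
    """Inverse Fisher transform, r = tanh(z)."""
    out = np.tanh(np.asarray(z, dtype=float))
    return float(out) if out.ndim == 0 else out


def average_matrices(ms: list[CorrelationMatrix],
                     space: str = "z") -> CorrelationMatrix:
    """Average connectivity matrices entrywise across scans.

    By default the off-diagonal entries are averaged in Fisher-z space
    and transformed back (variance-stabilised averaging); ``space="r"``
    averages raw correlations instead.
    """
    if len(ms) < 2:
        raise ValueError("need at least 2 matrices to average")
    labels = ms[0].roi_labels
    n = ms[0].n_rois
    for m in ms[1:]:
        if m.n_rois != n or m.roi_labels != labels:
            raise ValueError("matrices must share shape and ROI labels")
    stack = np.stack([m.r for m in ms])
    mask = ~np.eye(n, dtype=bool)
    if space == "z":
        z = np.zeros_like(stack)
        # clip to the open interval; |r|=1 off-diagonal would be infinite z
        z[:, mask] = np.arctanh(np.clip(stack[:, mask], -1 + 1e-15, 1 - 1e-15))
        avg = np.tanh(z.mean(axis=0))
    elif space == "r":
        avg = stack.mean(axis=0)
    else:
        raise ValueError("space must be 'z' or 'r'")
    np.fill_diagonal(avg, 1.0)
    sid = ms[0].subject_id
    return CorrelationMatrix(avg, list(labels), sid, "avg")


def matrix_similarity(a: CorrelationMatrix,
                      b: CorrelationMatrix) -> tuple[float, float]:
    """Spatial similarity of two connectivity matrices.

    Pearson correlation (with two-sided p-value) over the strict upper
    triangles, the paper-style check that mean connectivity patterns are
    stable across scans.
    """
    if a.n_rois != b.n_rois or a.roi_labels != b.roi_labels:
        raise ValueError("matrices must share shape and ROI labels")
    if a.n_rois < 3:
        raise ValueError("need at least 3 ROIs (>= 3 upper-triangle entries)")
    r, p = stats.pearsonr(a.upper_values(), b.upper_values())
    return float(r), float(p)


# ---------------------------------------------------------------------------
# plain-text I/O
# ---------------------------------------------------------------------------

def write_timeseries_tsv(ts: TimeSeriesMatrix, path) -> None:
    pd.DataFrame(ts.values, columns=ts.roi_labels).to_csv(
        path, sep="\t", index=False)


def read_timeseries_tsv(path, subject_id: str = "", scan_id: str = "",
                        sampling_interval: float = 2.0) -> TimeSeriesMatrix:
    df = pd.read_csv(path, sep="\t")
    return TimeSeriesMatrix(df.to_numpy(float), [str(c) for c in df.columns],
                            subject_id, scan_id, sampling_interval)


def write_matrix_tsv(m: CorrelationMatrix, path) -> None:
    pd.DataFrame(m.r, index=m.roi_labels, columns=m.roi_labels).to_csv(
        path, sep="\t")


def read_matrix_tsv(path, subject_id: str = "",
                    scan_id: str = "") -> CorrelationMatrix:
    df = pd.read_csv(path, sep="\t", index_col=0)
    return CorrelationMatrix(df.to_numpy(float), [str(c) for c in df.columns],
                             subject_id, scan_id)


def read_nuisance_tsv(path) -> NuisanceSet:
    df = pd.read_csv(path, sep="\t")
    return NuisanceSet(df.to_numpy(float), [str(c) for c in df.columns])
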