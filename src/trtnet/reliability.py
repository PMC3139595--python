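"""Test-retest reliability via the intraclass correlation coefficient.

The reliability statistic is the one-way random-effects, single-measurement
ICC: a one-way ANOVA with random subject effects splits the total sum of
squares into between-subject and within-subject (residual) parts, and

    ICC = (MS_b - MS_w) / (MS_b + (k - 1) MS_w),

where k is the number of repeated observations per subject.  Equivalently
ICC = (F - 1)/(F + k - 1) with F = MS_b / MS_w.  ICC approaches 1 when
within-subject variance is small relative to between-subject variance and
0 (or negative) otherwise.  Values are graded poor (< 0.25), low
(0.25-0.4), fair (0.4-0.6), good (0.6-0.75) and excellent (0.75-1).

Because networks are built over a continuous sparsity range, a metric's
ICC is a function of the threshold; the area under the metric-versus-
sparsity curve (AUC) gives each subject a single threshold-independent
value whose ICC summarises reliability in one scalar.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .connectivity import CorrelationMatrix
from .construction import SparsityGrid

__all__ = [
    "SHORT_TERM",
    "LONG_TERM",
    "GRADE_NAMES",
    "PairedMeasurements",
    "ICCResult",
    "MetricCurve",
    "EdgewiseReliability",
    "icc",
    "icc_from_f",
    "grade",
    "auc",
    "edgewise_reliability",
    "metric_reliability",
    "strength_vs_reliability",
    "paired_t",
    "pearson",
]

SHORT_TERM = "short_term"
LONG_TERM = "long_term"
GRADE_NAMES = ["poor", "low", "fair", "good", "excellent"]
_GRADE_EDGES = [0.25, 0.4, 0.6, 0.75]  # lower-inclusive band boundaries


@dataclass
class PairedMeasurements:
    """n_subjects x k repeated measurements of one measure."""

    values: np.ndarray
    condition: str = "custom"

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 2:
            raise ValueError("values must be 2-D (subjects x observations)")
        n, k = self.values.shape
        if n < 3:
            raise ValueError("need at least 3 subjects")
        if k < 2:
            raise ValueError("need at least 2 repeated observations")
        if not np.all(np.isfinite(self.values)):
            raise ValueError("missing/flagged cells must be dropped listwise "
                             "before constructing PairedMeasurements")

    @property
    def n_subjects(self) -> int:
        return self.values.shape[0]

    @property
    def k(self) -> int:
        return self.values.shape[1]


@dataclass
class ICCResult:
    icc: float
    f_value: float
    ms_between: float
    ms_within: float
    grade: str


def _icc_core(values: np.ndarray):
    """One-way random-effects decomposition, vectorised.

    ``values`` has shape (n, k) or (n, k, m) for m measures at once;
    returns (icc, f, ms_b, ms_w) with the trailing shape.
    """
    n, k = values.shape[0], values.shape[1]
    subj_mean = values.mean(axis=1)
    grand = values.mean(axis=(0, 1))
    ss_b = k * ((subj_mean - grand) ** 2).sum(axis=0)
    ss_w = ((values - subj_mean[:, None]) ** 2).sum(axis=(0, 1))
    ms_b = ss_b / (n - 1)
    ms_w = ss_w / (n * (k - 1))
    with np.errstate(invalid="ignore", divide="ignore"):
        icc_v = np.where(
            (ms_b == 0) & (ms_w == 0), np.nan,
            (ms_b - ms_w) / (ms_b + (k - 1) * ms_w))
        f_v = np.where(ms_w > 0, ms_b / np.where(ms_w > 0, ms_w, 1.0), np.inf)
        f_v = np.where((ms_b == 0) & (ms_w == 0), np.nan, f_v)
    return icc_v, f_v, ms_b, ms_w


def icc(pm: PairedMeasurements) -> ICCResult:
    """ICC of one measure across subjects between repeated observations.

    Negative estimates are returned as computed (not truncated) and
    graded poor.  A table with zero total variance is degenerate and
    flagged NaN.
    """
    icc_v, f_v, ms_b, ms_w = _icc_core(pm.values)
    icc_f = float(icc_v)
    g = grade(icc_f) if np.isfinite(icc_f) else "poor"
    return ICCResult(icc_f, float(f_v), float(ms_b), float(ms_w), g)


def icc_from_f(f_value: float, k: int) -> float:
    """ICC recovered from the one-way ANOVA F statistic,
    ICC = (F - 1)/(F + k - 1)."""
    if k < 2:
        raise ValueError("k must be >= 2")
    if not f_value > 0:
        raise ValueError("f_value must be positive")
    if np.isinf(f_value):
        return 1.0
    return float((f_value - 1.0) / (f_value + k - 1.0))


def grade(icc_value: float) -> str:
    """Reliability band of an ICC value; negatives grade as poor,
    band boundaries are lower-inclusive."""
    if icc_value > 1 + 1e-12:
        raise ValueError(f"ICC {icc_value} exceeds 1")
    if np.isnan(icc_value):
        return "poor"
    idx = int(np.searchsorted(_GRADE_EDGES, icc_value, side="right"))
    return GRADE_NAMES[idx]


@dataclass
class MetricCurve:
    """One metric's values over the sparsity grid for one subject."""

    metric: str
    grid: SparsityGrid
    values: np.ndarray
    subject_id: str = ""
    condition: str = "custom"

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.shape != (len(self.grid),):
            raise ValueError("one value per grid level required")

    @property
    def auc(self) -> float:
        return auc(self)


def auc(curve) -> float:
    """Trapezoidal area under a metric-versus-sparsity curve.

    Accepts a :class:`MetricCurve` or an ``(x, y)`` pair.  Grid points
    with flagged (NaN) values are excluded together with their abscissae
    before integration; at least 2 usable points are required.
    """
    if isinstance(curve, MetricCurve):
        x, y = np.asarray(curve.grid.values), curve.values
    else:
        x, y = (np.asarray(c, dtype=float) for c in curve)
    ok = np.isfinite(y)
    x, y = x[ok], y[ok]
    if x.size < 2:
        raise ValueError("need at least 2 usable grid points for AUC")
    return float(np.trapezoid(y, x))


# ---------------------------------------------------------------------------
# edgewise connectivity reliability
# ---------------------------------------------------------------------------

@dataclass
class EdgewiseReliability:
    """Per-connection ICC between two scan conditions."""

    icc_matrix: np.ndarray  # N x N symmetric, zero diagonal
    f_matrix: np.ndarray
    roi_labels: list[str]
    mean_icc: float
    grade_counts: dict[str, int]
    n_edges: int

    def upper_icc(self) -> np.ndarray:
        iu = np.triu_indices(self.icc_matrix.shape[0], k=1)
        return self.icc_matrix[iu]


def edgewise_reliability(scans_a: list[CorrelationMatrix],
                         scans_b: list[CorrelationMatrix],
                         use_fisher_z: bool = True) -> EdgewiseReliability:
    """ICC of every individual connection across subjects between two
    scan conditions (e.g. scan 2 vs scan 3 for short-term reliability).

    Connection values enter the ANOVA after the Fisher r-to-z transform
    by default, matching the variance-stabilised treatment of
    correlations elsewhere in the pipeline.
    """
    if len(scans_a) != len(scans_b):
        raise ValueError("conditions must have the same subjects")
    if len(scans_a) < 3:
        raise ValueError("need at least 3 subjects")
    labels = scans_a[0].roi_labels
    for m in (*scans_a, *scans_b):
        if m.roi_labels != labels:
            raise ValueError("all matrices must share ROI labels")
    subj_a = [m.subject_id for m in scans_a]
    subj_b = [m.subject_id for m in scans_b]
    if any(a and b and a != b for a, b in zip(subj_a, subj_b)):
        raise ValueError("subject order mismatch between conditions")
    ua = np.stack([m.upper_values() for m in scans_a])  # n x m_edges
    ub = np.stack([m.upper_values() for m in scans_b])
    if use_fisher_z:
        clip = lambda r: np.arctanh(np.clip(r, -1 + 1e-15, 1 - 1e-15))
        ua, ub = clip(ua), clip(ub)
    values = np.stack([ua, ub], axis=1)  # n x 2 x m_edges
    icc_v, f_v, _, _ = _icc_core(values)
    n = len(labels)
    iu = np.triu_indices(n, k=1)
    icc_m = np.zeros((n, n))
    f_m = np.zeros((n, n))
    icc_m[iu] = icc_v
    f_m[iu] = f_v
    icc_m = icc_m + icc_m.T
    f_m = f_m + f_m.T
    finite = icc_v[np.isfinite(icc_v)]
    counts = {g: 0 for g in GRADE_NAMES}
    for v in finite:
        counts[grade(min(v, 1.0))] += 1
    return EdgewiseReliability(icc_m, f_m, list(labels),
                               float(finite.mean()) if finite.size else
                               float("nan"), counts, icc_v.size)


# ---------------------------------------------------------------------------
# metric-level reliability tables
# ---------------------------------------------------------------------------

def _pivot(table: pd.DataFrame) -> pd.DataFrame:
    required = {"subject", "metric", "sparsity", "value"}
    missing = required - set(table.columns)
    if missing:
        raise ValueError(f"metric table missing columns: {sorted(missing)}")
    t = table.copy()
    if "node" not in t.columns:
        t["node"] = ""
    t["node"] = t["node"].fillna("")
    return t


def metric_reliability(table_a: pd.DataFrame, table_b: pd.DataFrame,
                       mode: str = "auc") -> pd.DataFrame:
    """ICC per metric (and per node for nodal metrics) between two
    conditions.

    ``table_a`` / ``table_b`` are long-format metric tables (columns:
    subject, metric, node [optional, empty for global], sparsity, value)
    holding the same subjects on the same sparsity grid.  ``mode
    = "per_threshold"`` gives an ICC at every sparsity level; ``"auc"``
    first collapses each subject's curve to its area under the curve.
    Subjects with flagged (NaN) values are excluded listwise per measure;
    rows record how many were used.
    """
    if mode not in ("auc", "per_threshold"):
        raise ValueError("mode must be 'auc' or 'per_threshold'")
    ta, tb = _pivot(table_a), _pivot(table_b)
    ga = ta.groupby(["metric", "node"], sort=True)
    gb = tb.groupby(["metric", "node"], sort=True)
    keys = sorted(set(ga.groups) & set(gb.groups))
    rows = []
    for metric, node in keys:
        a = ga.get_group((metric, node)).pivot_table(
            index="subject", columns="sparsity", values="value",
            dropna=False)
        b = gb.get_group((metric, node)).pivot_table(
            index="subject", columns="sparsity", values="value",
            dropna=False)
        common = a.index.intersection(b.index)
        a, b = a.loc[common], b.loc[common]
        if not np.array_equal(a.columns.to_numpy(float),
                              b.columns.to_numpy(float)):
            raise ValueError(f"sparsity grid mismatch for {metric}/{node}")
        grid_vals = a.columns.to_numpy(float)
        if mode == "per_threshold":
            for j, s in enumerate(grid_vals):
                pair = np.stack([a.iloc[:, j], b.iloc[:, j]], axis=1)
                rows.append(_icc_row(metric, node, f"{s:g}", pair))
        else:
            aucs = []
            for subj in common:
                ya, yb = a.loc[subj].to_numpy(), b.loc[subj].to_numpy()
                try:
                    aucs.append((auc((grid_vals, ya)), auc((grid_vals, yb))))
                except ValueError:
                    aucs.append((np.nan, np.nan))
            pair = np.asarray(aucs)
            rows.append(_icc_row(metric, node, "AUC", pair))
    return pd.DataFrame(rows, columns=["measure", "node", "sparsity", "icc",
                                       "f", "grade", "n_used"])


def _icc_row(metric: str, node: str, sparsity: str,
             pair: np.ndarray) -> tuple:
    ok = np.all(np.isfinite(pair), axis=1)
    used = pair[ok]
    if used.shape[0] < 3:
        return (metric, node, sparsity, np.nan, np.nan, "poor", used.shape[0])
    res = icc(PairedMeasurements(used))
    return (metric, node, sparsity, res.icc, res.f_value, res.grade,
            used.shape[0])


# ---------------------------------------------------------------------------
# consistency and strength analyses
# ---------------------------------------------------------------------------

@dataclass
class StrengthReliabilityFit:
    r: float
    p: float
    slope: float
    intercept: float
    r_squared: float
    n_edges: int


def strength_vs_reliability(mean_strength: np.ndarray,
                            icc_values: np.ndarray,
                            sign: str = "positive") -> StrengthReliabilityFit:
    """Linear relation between connection strength and its reliability,
    fitted separately for positive and negative connections."""
    mean_strength = np.asarray(mean_strength, dtype=float).ravel()
    icc_values = np.asarray(icc_values, dtype=float).ravel()
    if mean_strength.shape != icc_values.shape:
        raise ValueError("strength and ICC arrays must match")
    if sign == "positive":
        sel = mean_strength > 0
    elif sign == "negative":
        sel = mean_strength < 0
    else:
        raise ValueError("sign must be 'positive' or 'negative'")
    sel &= np.isfinite(icc_values)
    x, y = mean_strength[sel], icc_values[sel]
    if x.size < 3:
        raise ValueError(f"need at least 3 {sign} connections, got {x.size}")
    if np.ptp(y) == 0 or np.ptp(x) == 0:
        return StrengthReliabilityFit(float("nan"), float("nan"),
                                      float("nan"), float("nan"),
                                      float("nan"), int(x.size))
    fit = stats.linregress(x, y)
    return StrengthReliabilityFit(float(fit.rvalue), float(fit.pvalue),
                                  float(fit.slope), float(fit.intercept),
                                  float(fit.rvalue ** 2), int(x.size))


def paired_t(a: np.ndarray, b: np.ndarray) -> tuple[float, int, float]:
    """Paired t statistic with df = n - 1 and two-sided p; degenerate
    (zero-variance differences) results are flagged NaN."""
    a = np.asarray(a, dtype=float).ravel()
    b = np.asarray(b, dtype=float).ravel()
    if a.shape != b.shape or a.size < 3:
        raise ValueError("need matched samples of length >= 3")
    d = a - b
    n = d.size
    sd = d.std(ddof=1)
    if sd == 0:
        return (0.0 if d.mean() == 0 else float("nan"), n - 1, float("nan"))
    t = d.mean() / (sd / np.sqrt(n))
    p = 2 * stats.t.sf(abs(t), n - 1)
    return float(t), n - 1, float(p)


def pearson(a: np.ndarray, b: np.ndarray) -> tuple[float, float]:
    """Pearson correlation with two-sided p (t-distribution transform)."""
    a = np.asarray(a, dtype=float).ravel()
    b = np.asarray(b, dtype=float).ravel()
    if a.shape != b.shape or a.size < 3:
        raise ValueError("need matched samples of length >= 3")
    if np.std(a) == 0 or np.std(b) == 0:
        return float("nan"), float("nan")
    r, p = stats.pearsonr(a, b)
    return float(r), float(p)
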