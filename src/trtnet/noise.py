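"""Robustness of network metrics to connectivity noise.

The experiment asks how numerically stable each graph metric is when the
underlying correlation matrix is perturbed: independent zero-mean Gaussian
noise is added to every connection, with variance set to a fixed fraction
of that subject's own connectivity variance (so every matrix receives the
same *proportion* of noise), the full thresholding + metrics pipeline is
re-run, and the ICC between the clean reference values and the noisy
values across subjects quantifies robustness.  The default design uses six
equally spaced fractions from 8.3% to 50% of the connectivity variance and
5 repetitions of the noise draw.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .connectivity import CorrelationMatrix
from .construction import (ABSOLUTE_BOTH, BINARIZED, BrainNetwork,
                           SparsityGrid, build_over_grid, max_sparsity)
from .metrics import (GLOBAL_METRIC_NAMES, NODAL_METRIC_NAMES, global_metrics,
                      nodal_metrics)
from .reliability import PairedMeasurements, auc, icc

__all__ = [
    "NoiseConfig",
    "NoiseExperimentResult",
    "noise_levels",
    "add_noise",
    "run_noise_experiment",
]


def noise_levels(n: int = 6, max_fraction: float = 0.5) -> list[float]:
    """``n`` equally spaced noise-variance fractions, i*max/n for i=1..n.

    The default (n=6, max 0.5) gives 8.3%, 16.7%, 25.0%, 33.3%, 41.7%
    and 50.0% of the connectivity variance.
    """
    if n < 1:
        raise ValueError("n must be >= 1")
    if not 0 < max_fraction <= 1:
        raise ValueError("max_fraction must be in (0, 1]")
    return [i * max_fraction / n for i in range(1, n + 1)]


@dataclass
class NoiseConfig:
    """Design of one noise-robustness experiment."""

    levels: list = field(default_factory=noise_levels)
    n_reps: int = 5
    seed: int = 0
    grid: SparsityGrid = field(
        default_factory=lambda: SparsityGrid.regular(0.05, 0.5, 0.05))
    membership: str = ABSOLUTE_BOTH
    kind: str = BINARIZED
    n_random: int = 5  # surrogate ensemble size for gamma/lambda/sigma
    include_normalized: bool = True

    def __post_init__(self) -> None:
        if not self.levels:
            raise ValueError("need at least one noise level")
        if any(not 0 <= f <= 1 for f in self.levels):
            raise ValueError("noise fractions must lie in [0, 1]")
        if self.n_reps < 1:
            raise ValueError("n_reps must be >= 1")


@dataclass
class NoiseExperimentResult:
    """Per-(metric, level, rep) ICC against the noise-free reference."""

    table: pd.DataFrame  # columns: metric, scope, level, rep, icc
    matrix_count: int
    config: NoiseConfig

    def mean_table(self) -> pd.DataFrame:
        """Mean ICC over repetitions, per metric and level."""
        return (self.table.groupby(["metric", "scope", "level"],
                                   as_index=False)["icc"].mean())

    def mean_icc(self, metric: str, level: float) -> float:
        t = self.table
        sel = (t["metric"] == metric) & np.isclose(t["level"], level)
        return float(t.loc[sel, "icc"].mean())


def add_noise(m: CorrelationMatrix, fraction: float,
              seed: int | np.random.Generator = 0) -> CorrelationMatrix:
    """Add symmetric Gaussian noise scaled to the matrix's own variance.

    The noise variance is ``fraction`` times the variance of the strict
    upper-triangle entries, drawn once per unordered pair and mirrored,
    so the perturbed matrix stays symmetric; results are clipped into
    [-1, 1] and the diagonal stays 1.
    """
    if not 0 <= fraction <= 1:
        raise ValueError("fraction must be in [0, 1]")
    if fraction == 0:
        return CorrelationMatrix(m.r.copy(), list(m.roi_labels),
                                 m.subject_id, m.scan_id)
    v = float(np.var(m.upper_values()))
    if v == 0:
        raise ValueError("degenerate matrix: zero connectivity variance")
    rng = (seed if isinstance(seed, np.random.Generator)
           else np.random.default_rng(seed))
    n = m.n_rois
    iu = np.triu_indices(n, k=1)
    noise = rng.standard_normal(iu[0].size) * np.sqrt(fraction * v)
    r = m.r.copy()
    r[iu] += noise
    r = np.triu(r, k=1)
    r = r + r.T
    np.clip(r, -1.0, 1.0, out=r)
    np.fill_diagonal(r, 1.0)
    return CorrelationMatrix(r, list(m.roi_labels), m.subject_id, m.scan_id)


def _metric_values(m: CorrelationMatrix, cfg: NoiseConfig,
                   seed: int) -> dict[str, tuple[str, np.ndarray]]:
    """AUC of every metric curve over the (possibly truncated) grid.

    Global metrics yield one AUC scalar per subject; nodal metrics yield
    one AUC per node (reliability is later computed per node and averaged
    over nodes).  Grid levels above the matrix's attainable sparsity are
    flagged NaN and pruned by the AUC.
    """
    s_max = max_sparsity(m, cfg.membership)
    grid_vals = np.asarray(cfg.grid.values)
    n = m.n_rois
    glob = {name: np.full(grid_vals.size, np.nan)
            for name in GLOBAL_METRIC_NAMES}
    nod = {name: np.full((grid_vals.size, n), np.nan)
           for name in NODAL_METRIC_NAMES}
    for j, s in enumerate(grid_vals):
        if s > s_max + 1e-12:
            continue
        net = build_over_grid(m, SparsityGrid(np.array([s])),
                              cfg.membership, cfg.kind)[0]
        gm = global_metrics(net, n_random=cfg.n_random, seed=seed + j,
                            include_normalized=cfg.include_normalized)
        for name, val in gm.to_dict().items():
            glob[name][j] = val
        nm = nodal_metrics(net)
        for name, arr in nm.to_dict().items():
            nod[name][j] = arr
    out: dict[str, tuple[str, np.ndarray]] = {}
    for name, curve in glob.items():
        try:
            val = np.array([auc((grid_vals, curve))])
        except ValueError:
            val = np.array([np.nan])
        out[name] = ("global", val)
    for name, curves in nod.items():
        vals = np.empty(n)
        for i in range(n):
            try:
                vals[i] = auc((grid_vals, curves[:, i]))
            except ValueError:
                vals[i] = np.nan
        out[name] = ("nodal", vals)
    return out


def run_noise_experiment(matrices: list[CorrelationMatrix],
                         cfg: NoiseConfig) -> NoiseExperimentResult:
    """Reference-versus-noisy reliability of every metric.

    For each subject the clean matrix provides reference AUC metric
    values; for every (level, rep) a fresh noise draw perturbs each
    subject's matrix, the pipeline is re-run, and the ICC across subjects
    between reference and noisy values (paired as k = 2 observations)
    is recorded.  ``matrix_count`` totals the simulated matrices,
    n_subjects * n_levels * n_reps.
    """
    if len(matrices) < 3:
        raise ValueError("need at least 3 subjects")
    n_sub = len(matrices)
    reference = [_metric_values(m, cfg, seed=cfg.seed) for m in matrices]
    metric_names = list(reference[0].keys())
    rows = []
    count = 0
    for li, level in enumerate(cfg.levels):
        for rep in range(cfg.n_reps):
            noisy_vals = []
            for si, m in enumerate(matrices):
                rng = np.random.default_rng(
                    [cfg.seed, li + 1, rep + 1, si + 1])
                noisy = add_noise(m, level, rng)
                count += 1
                noisy_vals.append(_metric_values(noisy, cfg, seed=cfg.seed))
            for name in metric_names:
                scope = reference[0][name][0]
                # (n_sub, n_units): one unit for globals, one per node
                ref = np.stack([reference[s][name][1] for s in range(n_sub)])
                new = np.stack([noisy_vals[s][name][1] for s in range(n_sub)])
                unit_iccs = []
                for u in range(ref.shape[1]):
                    ok = np.isfinite(ref[:, u]) & np.isfinite(new[:, u])
                    if ok.sum() < 3:
                        continue
                    a, b = ref[ok, u], new[ok, u]
                    if np.allclose(a, b) and np.std(a) > 0:
                        unit_iccs.append(1.0)  # noiseless identity
                    else:
                        unit_iccs.append(icc(PairedMeasurements(
                            np.stack([a, b], axis=1))).icc)
                val = (float(np.nanmean(unit_iccs)) if unit_iccs
                       else np.nan)
                rows.append((name, scope, level, rep, val))
    table = pd.DataFrame(rows, columns=["metric", "scope", "level", "rep",
                                        "icc"])
    return NoiseExperimentResult(table, count, cfg)
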