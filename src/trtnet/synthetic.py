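"""Synthetic multi-subject, multi-scan cohorts with known reliability.

Test-retest designs decompose the variance of every connection into a
between-subject part (stable individual differences) and a within-subject
part (scan-to-scan fluctuation); the intraclass correlation of an edge is
then sigma_b^2 / (sigma_b^2 + sigma_w^2).  The generator works in Fisher-z
space, where that decomposition is exact and additive::

    z_ijst = mu_ij + b_ijs + w_ijst,   b ~ N(0, sigma_b^2), w ~ N(0, sigma_w^2)
    r_ijst = tanh(z_ijst)

so every downstream stage — thresholding, graph metrics, ICC — can be
validated against an analytically known ground truth without any data
download.  ``ts_length > 0`` additionally draws multivariate-Gaussian time
series whose population correlation equals the (PSD-projected) generated
matrix, emulating the raw-time-series entry point of the pipeline.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from pathlib import Path

import numpy as np

from .connectivity import CorrelationMatrix, TimeSeriesMatrix, write_matrix_tsv

__all__ = [
    "CohortConfig",
    "SyntheticCohort",
    "generate_cohort",
    "ground_truth_icc",
    "nearest_correlation",
    "write_cohort",
]


@dataclass
class CohortConfig:
    """Design of a synthetic test-retest cohort.

    ``mu`` is the population-mean connectivity in Fisher-z units (scalar
    broadcast or full N x N symmetric matrix, zero diagonal); ``sigma_b``
    and ``sigma_w`` are between-subject and within-subject (between-scan)
    standard deviations in z units, scalar or per-edge.  ``ts_length = 0``
    selects matrix mode (correlation matrices drawn exactly from the
    generative model); a positive value selects time-series mode.
    """

    n_subjects: int = 25
    n_scans: int = 3
    n_rois: int = 30
    ts_length: int = 0
    mu: float | np.ndarray = 0.3
    sigma_b: float | np.ndarray = 0.25
    sigma_w: float | np.ndarray = 0.2
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_subjects < 2:
            raise ValueError("n_subjects must be >= 2")
        if self.n_scans < 2:
            raise ValueError("n_scans must be >= 2")
        if self.n_rois < 3:
            raise ValueError("n_rois must be >= 3")
        if self.ts_length < 0:
            raise ValueError("ts_length must be >= 0 (0 = matrix mode)")
        mu_raw = np.asarray(self.mu, dtype=float)
        if mu_raw.ndim == 2 and not np.allclose(mu_raw, mu_raw.T):
            raise ValueError("mu must be symmetric")
        self.mu = self._expand(self.mu, "mu", allow_negative=True)
        self.sigma_b = self._expand(self.sigma_b, "sigma_b")
        self.sigma_w = self._expand(self.sigma_w, "sigma_w")

    def _expand(self, v, name: str, allow_negative: bool = False) -> np.ndarray:
        n = self.n_rois
        arr = np.asarray(v, dtype=float)
        if arr.ndim == 0:
            arr = np.full((n, n), float(arr))
        if arr.shape != (n, n):
            raise ValueError(f"{name} must be scalar or {n}x{n}")
        if not allow_negative and np.any(arr < 0):
            raise ValueError(f"{name} must be >= 0 elementwise")
        out = (arr + arr.T) / 2.0
        np.fill_diagonal(out, 0.0)
        return out

    @property
    def roi_labels(self) -> list[str]:
        return [f"ROI{i + 1:03d}" for i in range(self.n_rois)]


@dataclass
class SyntheticCohort:
    """Generated cohort: one CorrelationMatrix per (subject, scan)."""

    matrices: dict  # (subject_idx, scan_idx) -> CorrelationMatrix
    true_subject_matrices: list  # per subject, scan-free latent CorrelationMatrix
    config: CohortConfig
    timeseries: dict | None = None  # (subject, scan) -> TimeSeriesMatrix

    def scan(self, scan_idx: int) -> list[CorrelationMatrix]:
        """All subjects' matrices for one scan, ordered by subject."""
        return [self.matrices[(s, scan_idx)]
                for s in range(self.config.n_subjects)]


def _edge_rng(seed: int, subject: int, scan: int) -> np.random.Generator:
    # one shared stream per cohort, split per subject/scan by counter so the
    # draw is independent of iteration order
    return np.random.default_rng([seed, subject + 1, scan + 1])


def nearest_correlation(a: np.ndarray, floor: float = 1e-8,
                        max_iter: int = 100, tol: float = 1e-10) -> np.ndarray:
    """Nearest positive-semidefinite correlation matrix.

    Alternates eigenvalue clipping (at a small positive floor) with
    re-normalisation to unit diagonal until the matrix is PSD; a standard
    deterministic repair for indefinite correlation matrices.
    """
    x = (a + a.T) / 2.0
    np.fill_diagonal(x, 1.0)
    for _ in range(max_iter):
        w, v = np.linalg.eigh(x)
        if w[0] >= floor * 0.5:
            break
        w = np.clip(w, floor, None)
        x = (v * w) @ v.T
        d = np.sqrt(np.clip(np.diag(x), floor, None))
        x = x / np.outer(d, d)
        x = (x + x.T) / 2.0
        np.fill_diagonal(x, 1.0)
        if np.max(np.abs(x - x.T)) < tol and np.linalg.eigvalsh(x)[0] >= 0:
            break
    else:
        raise RuntimeError("nearest-correlation projection did not converge")
    np.clip(x, -1.0, 1.0, out=x)
    np.fill_diagonal(x, 1.0)
    return x


def generate_cohort(config: CohortConfig) -> SyntheticCohort:
    """Draw a cohort from the Fisher-z variance-decomposition model.

    Deterministic given ``config.seed``: every (subject, scan) cell uses
    its own counter-derived substream of the cohort's seed.
    """
    n = config.n_rois
    iu = np.triu_indices(n, k=1)
    mu_u = config.mu[iu]
    sb_u = config.sigma_b[iu]
    sw_u = config.sigma_w[iu]
    labels = config.roi_labels

    matrices: dict = {}
    timeseries: dict | None = {} if config.ts_length > 0 else None
    true_mats = []
    for s in range(config.n_subjects):
        rng_b = _edge_rng(config.seed, s, 0)
        b = rng_b.standard_normal(mu_u.size) * sb_u
        z_subj = mu_u + b
        true_r = np.eye(n)
        true_r[iu] = np.tanh(z_subj)
        true_r = true_r + np.triu(true_r, k=1).T
        np.fill_diagonal(true_r, 1.0)
        true_mats.append(CorrelationMatrix(true_r, labels, f"sub-{s + 1:03d}",
                                           "latent"))
        for t in range(config.n_scans):
            rng_w = _edge_rng(config.seed, s, t + 1)
            w = rng_w.standard_normal(mu_u.size) * sw_u
            r_u = np.tanh(z_subj + w)
            r = np.eye(n)
            r[iu] = r_u
            r = r + np.triu(r, k=1).T
            np.fill_diagonal(r, 1.0)
            sid, tid = f"sub-{s + 1:03d}", f"scan-{t + 1}"
            if config.ts_length == 0:
                matrices[(s, t)] = CorrelationMatrix(r, labels, sid, tid)
            else:
                try:
                    target = nearest_correlation(r)
                except RuntimeError as exc:
                    raise RuntimeError(
                        f"PSD projection failed for subject {sid}, "
                        f"scan {tid}") from exc
                chol_w, chol_v = np.linalg.eigh(target)
                factor = chol_v * np.sqrt(np.clip(chol_w, 0, None))
                x = _edge_rng(config.seed, s, t + 1 + config.n_scans
                              ).standard_normal((config.ts_length, n))
                series = x @ factor.T
                ts = TimeSeriesMatrix(series, labels, sid, tid)
                timeseries[(s, t)] = ts
                emp = np.corrcoef(series, rowvar=False)
                emp = np.clip((emp + emp.T) / 2.0, -1, 1)
                np.fill_diagonal(emp, 1.0)
                matrices[(s, t)] = CorrelationMatrix(emp, labels, sid, tid)
    return SyntheticCohort(matrices, true_mats, config, timeseries)


def ground_truth_icc(config: CohortConfig) -> np.ndarray:
    """Theoretical per-edge ICC, sigma_b^2 / (sigma_b^2 + sigma_w^2).

    Defined in Fisher-z space where the decomposition is exact; edges with
    zero total variance get ICC 0.  Matrix-mode quantity (time-series mode
    adds Pearson sampling noise to the within-subject part).
    """
    if config.ts_length != 0:
        raise ValueError("ground-truth ICC is defined for matrix mode "
                         "(ts_length = 0)")
    vb = config.sigma_b ** 2
    vw = config.sigma_w ** 2
    tot = vb + vw
    with np.errstate(invalid="ignore", divide="ignore"):
        icc = np.where(tot > 0, vb / np.where(tot > 0, tot, 1.0), 0.0)
    np.fill_diagonal(icc, 0.0)
    return icc


def write_cohort(cohort: SyntheticCohort, out_dir) -> Path:
    """Write one square TSV per subject-scan plus a JSON manifest."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    cfg = cohort.config
    for (s, t), m in cohort.matrices.items():
        write_matrix_tsv(m, out / f"sub-{s + 1:03d}_scan-{t + 1}.tsv")
    manifest = {
        "n_subjects": cfg.n_subjects,
        "n_scans": cfg.n_scans,
        "n_rois": cfg.n_rois,
        "ts_length": cfg.ts_length,
        "seed": cfg.seed,
        "mu_mean": float(cfg.mu[np.triu_indices(cfg.n_rois, 1)].mean()),
        "sigma_b_mean": float(cfg.sigma_b[np.triu_indices(cfg.n_rois, 1)].mean()),
        "sigma_w_mean": float(cfg.sigma_w[np.triu_indices(cfg.n_rois, 1)].mean()),
        "file_pattern": "sub-<s>_scan-<t>.tsv",
    }
    (out / "cohort_manifest.json").write_text(json.dumps(manifest, indent=2))
    return out
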