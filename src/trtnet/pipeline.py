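"""Configuration-driven orchestration of the full reliability study.

One :class:`StudyConfig` describes the whole experiment: where the cohort
comes from (synthetic generator, correlation-matrix TSVs, or raw time
series), how scans pair into the short-term (scan 2 vs scan 3) and
long-term (scan 1 vs the Fisher-z average of scans 2-3) conditions, which
cells of the network-membership x network-type factor grid to run, the
sparsity grid, the surrogate-ensemble sizes, and an optional
noise-robustness experiment.  :func:`run_study` executes every stage and
writes plain-text tables plus a JSON manifest; re-running with the same
config and master seed reproduces the outputs.
"""

from __future__ import annotations

import json
import logging
import zlib
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .connectivity import (CorrelationMatrix, average_matrices,
                           bandpass_filter, correlation_matrix,
                           read_matrix_tsv, read_timeseries_tsv,
                           regress_nuisance, write_matrix_tsv)
from .construction import (ABSOLUTE_BOTH, BINARIZED, POSITIVE_ONLY, WEIGHTED,
                           SparsityGrid, build_over_grid, max_sparsity)
from .metrics import (GLOBAL_METRIC_NAMES, NODAL_METRIC_NAMES,
                      global_metrics, nodal_metrics)
from .noise import NoiseConfig, run_noise_experiment
from .reliability import (LONG_TERM, SHORT_TERM, edgewise_reliability,
                          metric_reliability, strength_vs_reliability)
from .synthetic import CohortConfig, generate_cohort

__all__ = ["StudyConfig", "validate_config", "run_study",
           "metric_curves_table", "stage_seed"]

log = logging.getLogger("trtnet")


def stage_seed(master_seed: int, stage: str) -> int:
    """Derive a stable per-stage seed from the master seed.

    CRC32 of the stage name mixed with the master seed; stable across
    runs and platforms so every factor cell is independently
    reproducible.
    """
    return (zlib.crc32(stage.encode()) ^ (master_seed * 2654435761)) % (2**31)


@dataclass
class StudyConfig:
    """Full study description (YAML-mappable field for field)."""

    mode: str = "synthetic"  # synthetic | matrices | timeseries
    cohort: CohortConfig | None = None
    input_dir: str | None = None
    sampling_interval: float = 2.0
    bandpass: tuple[float, float] | None = None
    memberships: list = field(
        default_factory=lambda: [POSITIVE_ONLY, ABSOLUTE_BOTH])
    kinds: list = field(default_factory=lambda: [BINARIZED, WEIGHTED])
    sparsity_start: float = 0.05
    sparsity_stop: float = 0.5
    sparsity_step: float = 0.05
    n_random: int = 100
    n_iterations: int | None = None
    noise: NoiseConfig | None = None
    out_dir: str = "study_out"
    seed: int = 0
    # scan indices (0-based) entering each condition
    short_term_scans: tuple[int, int] = (1, 2)
    long_term_reference: int = 0

    @classmethod
    def from_yaml(cls, path) -> "StudyConfig":
        raw = yaml.safe_load(Path(path).read_text()) or {}
        if "cohort" in raw and raw["cohort"] is not None:
            raw["cohort"] = CohortConfig(**raw["cohort"])
        if "noise" in raw and raw["noise"] is not None:
            noise_raw = dict(raw["noise"])
            if "grid" in noise_raw:
                g = noise_raw["grid"]
                noise_raw["grid"] = SparsityGrid.regular(
                    g.get("start", 0.05), g.get("stop", 0.5),
                    g.get("step", 0.05))
            raw["noise"] = NoiseConfig(**noise_raw)
        if "short_term_scans" in raw:
            raw["short_term_scans"] = tuple(raw["short_term_scans"])
        return cls(**raw)

    def grid(self) -> SparsityGrid:
        return SparsityGrid.regular(self.sparsity_start, self.sparsity_stop,
                                    self.sparsity_step)


def validate_config(cfg: StudyConfig,
                    matrices: list[CorrelationMatrix] | None = None) -> list:
    """Static checks; returns (severity, message) findings, never raises."""
    findings: list[tuple[str, str]] = []
    if not cfg.memberships or not cfg.kinds:
        findings.append(("error", "factor grid is empty: need at least one "
                                  "membership and one network type"))
    for mem in cfg.memberships:
        if mem not in (POSITIVE_ONLY, ABSOLUTE_BOTH):
            findings.append(("error", f"unknown membership {mem!r}"))
    for kind in cfg.kinds:
        if kind not in (BINARIZED, WEIGHTED):
            findings.append(("error", f"unknown network type {kind!r}"))
    if cfg.mode == "synthetic":
        coh = cfg.cohort or CohortConfig()
        n_scans = coh.n_scans
        needed = max(*cfg.short_term_scans, cfg.long_term_reference) + 1
        if n_scans < needed:
            findings.append(("error", f"scan pairing references scan index "
                                      f"{needed - 1} but cohort has only "
                                      f"{n_scans} scans"))
    elif cfg.mode in ("matrices", "timeseries"):
        if not cfg.input_dir:
            findings.append(("error", f"mode {cfg.mode!r} requires input_dir"))
    else:
        findings.append(("error", f"unknown mode {cfg.mode!r}"))
    try:
        cfg.grid()
    except ValueError as exc:
        findings.append(("error", f"invalid sparsity grid: {exc}"))
    if matrices is not None and POSITIVE_ONLY in cfg.memberships:
        s_max = min(max_sparsity(m, POSITIVE_ONLY) for m in matrices)
        if cfg.sparsity_stop > s_max:
            findings.append(("warning",
                             f"sparsity grid up to {cfg.sparsity_stop} "
                             f"exceeds the group-wise positive-only maximum "
                             f"{s_max:.3f}; grid will be truncated"))
    return findings


# ---------------------------------------------------------------------------
# stage helpers
# ---------------------------------------------------------------------------

def metric_curves_table(matrices: list[CorrelationMatrix],
                        grid: SparsityGrid, membership: str, kind: str,
                        n_random: int = 100,
                        n_iterations: int | None = None,
                        seed: int = 0,
                        include_nodal: bool = True) -> pd.DataFrame:
    """Long-format metric table for one set of subject matrices.

    Columns: subject, metric, node (empty for global metrics), sparsity,
    value.  Grid levels above a matrix's attainable sparsity are emitted
    as NaN so downstream AUC pruning applies.
    """
    rows = []
    for m in matrices:
        s_max = max_sparsity(m, membership)
        for s in grid:
            if s > s_max + 1e-12:
                for name in GLOBAL_METRIC_NAMES:
                    rows.append((m.subject_id, name, "", s, np.nan))
                if include_nodal:
                    for name in NODAL_METRIC_NAMES:
                        for lab in m.roi_labels:
                            rows.append((m.subject_id, name, lab, s, np.nan))
                continue
            net = build_over_grid(m, SparsityGrid(np.array([s])),
                                  membership, kind)[0]
            gm = global_metrics(net, n_random=n_random,
                                n_iterations=n_iterations,
                                seed=stage_seed(seed, f"{m.subject_id}:{s}"))
            for name, val in gm.to_dict().items():
                rows.append((m.subject_id, name, "", s, val))
            if include_nodal:
                nm = nodal_metrics(net)
                for name, arr in nm.to_dict().items():
                    for lab, val in zip(net.roi_labels, arr):
                        rows.append((m.subject_id, name, lab, s, val))
    return pd.DataFrame(rows, columns=["subject", "metric", "node",
                                       "sparsity", "value"])


def _load_matrices(cfg: StudyConfig) -> dict:
    """(subject_idx, scan_idx) -> CorrelationMatrix from any input mode."""
    if cfg.mode == "synthetic":
        cohort = generate_cohort(cfg.cohort or CohortConfig(seed=cfg.seed))
        return dict(cohort.matrices)
    paths = sorted(Path(cfg.input_dir).glob("sub-*_scan-*.tsv"))
    if not paths:
        raise FileNotFoundError(
            f"no sub-*_scan-*.tsv files under {cfg.input_dir}")
    out: dict = {}
    subs = sorted({p.name.split("_")[0] for p in paths})
    for p in paths:
        sub_tag, scan_tag = p.stem.split("_")
        s = subs.index(sub_tag)
        t = int(scan_tag.split("-")[1]) - 1
        if cfg.mode == "matrices":
            out[(s, t)] = read_matrix_tsv(p, sub_tag, scan_tag)
        else:
            ts = read_timeseries_tsv(p, sub_tag, scan_tag,
                                     cfg.sampling_interval)
            ts = regress_nuisance(ts, _empty_nuisance(ts))
            if cfg.bandpass:
                ts = bandpass_filter(ts, *cfg.bandpass)
            out[(s, t)] = correlation_matrix(ts)
    return out


def _empty_nuisance(ts):
    from .connectivity import NuisanceSet
    return NuisanceSet.empty(ts.n_timepoints)


def _conditions(cfg: StudyConfig, matrices: dict) -> dict:
    """Condition name -> (scans_a, scans_b) subject-ordered matrix lists."""
    n_sub = max(k[0] for k in matrices) + 1
    s2, s3 = cfg.short_term_scans
    ref = cfg.long_term_reference
    short_a = [matrices[(s, s2)] for s in range(n_sub)]
    short_b = [matrices[(s, s3)] for s in range(n_sub)]
    long_a = [matrices[(s, ref)] for s in range(n_sub)]
    long_b = [average_matrices([matrices[(s, s2)], matrices[(s, s3)]])
              for s in range(n_sub)]
    return {SHORT_TERM: (short_a, short_b), LONG_TERM: (long_a, long_b)}


def run_study(cfg: StudyConfig) -> Path:
    """Execute every configured stage and write the study report files."""
    findings = validate_config(cfg)
    errors = [msg for lvl, msg in findings if lvl == "error"]
    if errors:
        raise ValueError("invalid study config: " + "; ".join(errors))
    for lvl, msg in findings:
        log.warning("config: %s", msg)

    out = Path(cfg.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    manifest: dict = {"version": __version__, "seed": cfg.seed,
                      "stages": {}, "stage_seeds": {}}

    log.info("loading cohort (mode=%s)", cfg.mode)
    matrices = _load_matrices(cfg)
    conds = _conditions(cfg, matrices)
    for (s, t), m in matrices.items():
        write_matrix_tsv(m, out / f"sub-{s + 1:03d}_scan-{t + 1}.tsv")
    manifest["stages"]["cohort"] = {"n_matrices": len(matrices)}

    base_grid = cfg.grid()
    for membership in cfg.memberships:
        for kind in cfg.kinds:
            cell = f"{membership}_{kind}"
            cell_seed = stage_seed(cfg.seed, cell)
            manifest["stage_seeds"][cell] = cell_seed
            log.info("factor cell %s", cell)
            for cond_name, (scans_a, scans_b) in conds.items():
                # group-wise grid truncation over the two compared scan sets
                s_max = min(max_sparsity(m, membership)
                            for m in (*scans_a, *scans_b))
                grid = base_grid.truncate(s_max)
                tag = f"{cell}_{cond_name}"

                edge = edgewise_reliability(scans_a, scans_b)
                pd.DataFrame(edge.icc_matrix, index=edge.roi_labels,
                             columns=edge.roi_labels).to_csv(
                    out / f"edgewise_icc_{cond_name}.tsv", sep="\t")
                (out / f"edgewise_summary_{cond_name}.json").write_text(
                    json.dumps({"mean_icc": edge.mean_icc,
                                "n_edges": edge.n_edges,
                                "grade_counts": edge.grade_counts}, indent=2))

                mean_r = np.mean(
                    [np.stack([m.upper_values() for m in scans_a]).mean(0),
                     np.stack([m.upper_values() for m in scans_b]).mean(0)],
                    axis=0)
                fits = {}
                for sign in ("positive", "negative"):
                    try:
                        fit = strength_vs_reliability(mean_r,
                                                      edge.upper_icc(), sign)
                        fits[sign] = {"r": fit.r, "p": fit.p,
                                      "slope": fit.slope, "R2": fit.r_squared,
                                      "n_edges": fit.n_edges}
                    except ValueError as exc:
                        fits[sign] = {"skipped": str(exc)}
                (out / f"strength_vs_icc_{cond_name}.json").write_text(
                    json.dumps(fits, indent=2))

                tab_a = metric_curves_table(scans_a, grid, membership, kind,
                                            cfg.n_random, cfg.n_iterations,
                                            cell_seed)
                tab_b = metric_curves_table(scans_b, grid, membership, kind,
                                            cfg.n_random, cfg.n_iterations,
                                            cell_seed)
                tab_a.to_csv(out / f"metrics_{tag}_a.tsv", sep="\t",
                             index=False)
                tab_b.to_csv(out / f"metrics_{tag}_b.tsv", sep="\t",
                             index=False)
                for mode in ("per_threshold", "auc"):
                    rel = metric_reliability(tab_a, tab_b, mode)
                    rel.insert(0, "condition", cond_name)
                    rel.to_csv(out / f"icc_{tag}_{mode}.tsv", sep="\t",
                               index=False)
                manifest["stages"][tag] = {
                    "grid_max": float(grid.values[-1]),
                    "n_grid": len(grid),
                    "edgewise_mean_icc": edge.mean_icc,
                }

    if cfg.noise is not None:
        log.info("noise experiment")
        ref_scans = [matrices[(s, cfg.long_term_reference)]
                     for s in range(max(k[0] for k in matrices) + 1)]
        res = run_noise_experiment(ref_scans, cfg.noise)
        res.table.to_csv(out / "noise_icc.tsv", sep="\t", index=False)
        res.mean_table().to_csv(out / "noise_icc_mean.tsv", sep="\t",
                                index=False)
        (out / "noise_config.json").write_text(json.dumps(
            {"levels": list(cfg.noise.levels), "n_reps": cfg.noise.n_reps,
             "seed": cfg.noise.seed, "matrix_count": res.matrix_count},
            indent=2))
        manifest["stages"]["noise"] = {"matrix_count": res.matrix_count}

    cfg_dict = asdict(cfg)
    cfg_dict["noise"] = None if cfg.noise is None else {
        "levels": list(cfg.noise.levels), "n_reps": cfg.noise.n_reps}
    if cfg.cohort is not None:
        cfg_dict["cohort"] = {k: (v.tolist() if isinstance(v, np.ndarray)
                                  else v)
                              for k, v in asdict(cfg.cohort).items()}
    manifest["config_hash"] = zlib.crc32(
        json.dumps(cfg_dict, sort_keys=True, default=str).encode())
    manifest["config"] = cfg_dict
    (out / "manifest.json").write_text(json.dumps(manifest, indent=2,
                                                  default=str))
    log.info("study complete: %s", out)
    return out
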