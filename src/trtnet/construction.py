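"""Sparsity-thresholded network construction from correlation matrices.

Sparsity S is the fraction of possible edges retained, E / (N(N-1)/2).
Thresholding at a fixed S rather than a fixed correlation gives every
subject and scan the same number of edges, so group comparisons of graph
metrics are not confounded by edge count.  Two membership rules are
supported: ``positive_only`` (negative correlations zeroed before ranking)
and ``absolute_both`` (ranking by |r|); and two network types: binarized
(0/1 edges) and weighted (edges carry the correlation magnitude).
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from .connectivity import CorrelationMatrix

__all__ = [
    "POSITIVE_ONLY",
    "ABSOLUTE_BOTH",
    "BINARIZED",
    "WEIGHTED",
    "SparsityGrid",
    "BrainNetwork",
    "round_half_up",
    "max_sparsity",
    "threshold_at_sparsity",
    "build_over_grid",
]

POSITIVE_ONLY = "positive_only"
ABSOLUTE_BOTH = "absolute_both"
BINARIZED = "binarized"
WEIGHTED = "weighted"


def _check_membership(membership: str) -> None:
    if membership not in (POSITIVE_ONLY, ABSOLUTE_BOTH):
        raise ValueError(f"unknown membership {membership!r}")


def _check_kind(kind: str) -> None:
    if kind not in (BINARIZED, WEIGHTED):
        raise ValueError(f"unknown kind {kind!r}")


@dataclass
class SparsityGrid:
    """Ordered sparsity levels over which networks are built."""

    values: np.ndarray
    step: float = float("nan")

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 1 or self.values.size == 0:
            raise ValueError("grid must be a non-empty 1-D sequence")
        if np.any(self.values <= 0) or np.any(self.values >= 1):
            raise ValueError("sparsity levels must lie in (0, 1)")
        if np.any(np.diff(self.values) <= 0):
            raise ValueError("sparsity levels must be strictly increasing")
        if math.isnan(self.step) and self.values.size > 1:
            self.step = float(np.median(np.diff(self.values)))

    @classmethod
    def regular(cls, start: float = 0.01, stop: float = 0.99,
                step: float = 0.01) -> "SparsityGrid":
        n = int(round((stop - start) / step))
        vals = start + step * np.arange(n + 1)
        vals = vals[(vals > 0) & (vals < 1)]
        return cls(np.round(vals, 10), step)

    def truncate(self, s_max: float) -> "SparsityGrid":
        """Keep only levels attainable at the group-wise maximum sparsity."""
        keep = self.values <= s_max + 1e-12
        if not keep.any():
            raise ValueError(f"no grid level at or below S_max={s_max}")
        return SparsityGrid(self.values[keep], self.step)

    def __len__(self) -> int:
        return self.values.size

    def __iter__(self):
        return iter(self.values)


@dataclass
class BrainNetwork:
    """Thresholded adjacency at one sparsity level."""

    adjacency: np.ndarray
    kind: str
    membership: str
    sparsity: float
    threshold_used: float
    roi_labels: list[str]
    subject_id: str = ""
    scan_id: str = ""

    def __post_init__(self) -> None:
        self.adjacency = np.asarray(self.adjacency, dtype=float)
        _check_kind(self.kind)
        _check_membership(self.membership)
        n = self.adjacency.shape[0]
        if self.adjacency.ndim != 2 or self.adjacency.shape[1] != n:
            raise ValueError("adjacency must be square")
        if not np.allclose(self.adjacency, self.adjacency.T):
            raise ValueError("adjacency must be symmetric")
        if np.any(np.diag(self.adjacency) != 0):
            raise ValueError("adjacency diagonal must be zero")
        if np.any(self.adjacency < 0):
            raise ValueError("edge weights must be non-negative")
        if self.kind == BINARIZED and not np.all(
                np.isin(self.adjacency, (0.0, 1.0))):
            raise ValueError("binarized adjacency must be 0/1")

    @property
    def n_nodes(self) -> int:
        return self.adjacency.shape[0]

    @property
    def n_edges(self) -> int:
        return int(np.count_nonzero(np.triu(self.adjacency, k=1)))

    def edge_set(self) -> set:
        i, j = np.nonzero(np.triu(self.adjacency, k=1))
        return set(zip(i.tolist(), j.tolist()))

    def write_edgelist_tsv(self, path) -> None:
        i, j = np.nonzero(np.triu(self.adjacency, k=1))
        df = pd.DataFrame({
            "i_label": [self.roi_labels[a] for a in i],
            "j_label": [self.roi_labels[b] for b in j],
            "weight": self.adjacency[i, j],
        })
        df.to_csv(path, sep="\t", index=False)
        sidecar = {"kind": self.kind, "membership": self.membership,
                   "sparsity": self.sparsity,
                   "threshold_used": self.threshold_used}
        Path(str(path) + ".json").write_text(json.dumps(sidecar, indent=2))


def round_half_up(x: float) -> int:
    """Deterministic, monotone edge-count rounding (0.5 rounds up)."""
    return int(math.floor(x + 0.5))


def _salience(m: CorrelationMatrix, membership: str) -> np.ndarray:
    """Upper-triangle ranking scores under the given membership rule."""
    u = m.upper_values()
    if membership == ABSOLUTE_BOTH:
        return np.abs(u)
    return np.where(u > 0, u, 0.0)


def max_sparsity(m: CorrelationMatrix, membership: str) -> float:
    """Data-specific maximum attainable sparsity.

    Under ``absolute_both`` every connection is eligible (S_max = 1);
    under ``positive_only`` only strictly positive correlations can become
    edges.
    """
    _check_membership(membership)
    if membership == ABSOLUTE_BOTH:
        return 1.0
    u = m.upper_values()
    return float(np.count_nonzero(u > 0) / u.size)


def _ranked_edges(m: CorrelationMatrix, membership: str):
    """Upper-triangle pairs ordered by decreasing salience.

    Ties broken by lexicographic (i, j) so the ranking — and therefore the
    nesting of edge sets across sparsity levels — is deterministic.
    """
    n = m.n_rois
    iu, ju = np.triu_indices(n, k=1)
    sal = _salience(m, membership)
    order = np.lexsort((ju, iu, -sal))
    return iu[order], ju[order], sal[order]


def threshold_at_sparsity(m: CorrelationMatrix, sparsity: float,
                          membership: str = POSITIVE_ONLY,
                          kind: str = BINARIZED) -> BrainNetwork:
    """Threshold one correlation matrix to an exact edge count.

    Keeps the top ``E = round_half_up(S * N(N-1)/2)`` connections ranked
    by salience (|r| under absolute_both; positive r under positive_only);
    the subject-specific correlation threshold r0 is the smallest kept
    salience.  Binarized networks carry 0/1 edges; weighted networks carry
    the salience as weight.
    """
    _check_membership(membership)
    _check_kind(kind)
    s_max = max_sparsity(m, membership)
    if not (0 < sparsity <= s_max + 1e-12):
        raise ValueError(f"sparsity {sparsity} outside (0, S_max={s_max:.4f}] "
                         f"under {membership}")
    n = m.n_rois
    e_max = n * (n - 1) // 2
    n_edges = round_half_up(sparsity * e_max)
    if n_edges == 0:
        raise ValueError(f"sparsity {sparsity} yields zero edges at N={n}")
    iu, ju, sal = _ranked_edges(m, membership)
    keep_i, keep_j, keep_s = iu[:n_edges], ju[:n_edges], sal[:n_edges]
    if membership == POSITIVE_ONLY and keep_s[-1] <= 0:
        raise ValueError("not enough positive connections for requested "
                         "sparsity")
    adj = np.zeros((n, n))
    adj[keep_i, keep_j] = 1.0 if kind == BINARIZED else keep_s
    adj = adj + adj.T
    return BrainNetwork(adj, kind, membership, float(sparsity),
                        float(keep_s[-1]), list(m.roi_labels),
                        m.subject_id, m.scan_id)


def build_over_grid(m: CorrelationMatrix, grid: SparsityGrid,
                    membership: str = POSITIVE_ONLY,
                    kind: str = BINARIZED) -> list[BrainNetwork]:
    """One network per grid level; edge sets are nested across levels."""
    return [threshold_at_sparsity(m, s, membership, kind) for s in grid]
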