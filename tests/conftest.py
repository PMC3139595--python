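import numpy as np
import pytest

from trtnet.connectivity import CorrelationMatrix
from trtnet.construction import ABSOLUTE_BOTH, BINARIZED, BrainNetwork


def make_network(adj, kind=BINARIZED, membership=ABSOLUTE_BOTH,
                 labels=None) -> BrainNetwork:
    """Wrap a raw adjacency matrix as a BrainNetwork for metric tests."""
    adj = np.asarray(adj, dtype=float)
    n = adj.shape[0]
    e = int(np.count_nonzero(np.triu(adj, k=1)))
    e_max = n * (n - 1) // 2
    s = e / e_max if e_max else 0.0
    s = min(max(s, 1e-6), 1 - 1e-9)
    return BrainNetwork(adj, kind, membership, s, 0.0,
                        labels or [f"n{i}" for i in range(n)])


def random_correlation(n_rois: int, seed: int, subject_id: str = "",
                       scan_id: str = "") -> CorrelationMatrix:
    rng = np.random.default_rng(seed)
    x = rng.standard_normal((4 * n_rois, n_rois))
    r = np.corrcoef(x, rowvar=False)
    np.fill_diagonal(r, 1.0)
    return CorrelationMatrix(r, [f"ROI{i}" for i in range(n_rois)],
                             subject_id, scan_id)


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture
def small_cohort():
    from trtnet.synthetic import CohortConfig, generate_cohort
    return generate_cohort(CohortConfig(n_subjects=6, n_scans=3, n_rois=10,
                                        seed=42))
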