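import numpy as np
import pytest
from hypothesis import settings

from ripscore.riprank import CountMatrix

settings.register_profile("deterministic", derandomize=True, deadline=None)
settings.load_profile("deterministic")


@pytest.fixture
def small_counts() -> CountMatrix:
    """3 genes x 4 samples, two IP and two input replicates, all positive."""
    counts = np.array(
        [
            [10, 12, 100, 110],
            [20, 18, 25, 30],
            [5, 7, 4, 6],
        ]
    )
    return CountMatrix(
        gene_ids=["g1", "g2", "g3"],
        counts=counts,
        samples=["IP_1", "IP_2", "input_1", "input_2"],
        condition=["IP", "IP", "input", "input"],
        replicate=[1, 2, 1, 2],
    )


def brute_force_size_factors(mat: np.ndarray) -> np.ndarray:
    """Independent median-of-ratios implementation: loops, no shared code."""
    mat = np.asarray(mat, float)
    refs, rows = [], []
    for i in range(mat.shape[0]):
        if all(mat[i, j] > 0 for j in range(mat.shape[1])):
            prod = 1.0
            for j in range(mat.shape[1]):
                prod *= mat[i, j]
            refs.append(prod ** (1.0 / mat.shape[1]))
            rows.append(i)
    factors = []
    for j in range(mat.shape[1]):
        ratios = sorted(mat[i, j] / r for i, r in zip(rows, refs))
        m = len(ratios)
        med = ratios[m // 2] if m % 2 else 0.5 * (ratios[m // 2 - 1] + ratios[m // 2])
        factors.append(med)
    g = 1.0
    for f in factors:
        g *= f
    g = g ** (1.0 / len(factors))
    return np.array([f / g for f in factors])


def brute_force_bh(p: np.ndarray) -> np.ndarray:
    """Textbook BH by definition: padj_i = min over j with p_j >= p_i of m*p_j/rank_j."""
    p = np.asarray(p, float)
    m = len(p)
    order = np.argsort(p, kind="mergesort")
    adj = np.empty(m)
    running_min = np.inf
    for rank in range(m, 0, -1):
        i = order[rank - 1]
        running_min = min(running_min, m * p[i] / rank)
        adj[i] = min(running_min, 1.0)
    return adj
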