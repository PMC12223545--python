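import numpy as np
import pytest

import deltafuse as df


def amari_index(p: np.ndarray) -> float:
    """Permutation/scale-invariant separation error of a gain matrix.

    0 when p is a scaled permutation (perfect separation); up to ~1 for a
    random matrix. Used as an independent oracle on ICA unmixing quality.
    """
    p = np.abs(np.asarray(p, float))
    k = p.shape[0]
    row = (p / p.max(axis=1, keepdims=True)).sum(axis=1) - 1
    col = (p / p.max(axis=0, keepdims=True)).sum(axis=0) - 1
    return float((row.sum() + col.sum()) / (2 * k * (k - 1)))


def greedy_match(s_est: np.ndarray, s_true: np.ndarray) -> tuple[list[tuple[int, int]], np.ndarray]:
    """Greedy one-to-one matching of estimated to true source rows by |r|.

    Returns the (est, true) index pairs and their absolute correlations.
    """
    k = s_true.shape[0]
    r = np.abs(np.corrcoef(np.vstack([s_est, s_true]))[:k, k:])
    pairs, vals = [], []
    work = r.copy()
    for _ in range(k):
        i, j = np.unravel_index(np.argmax(work), work.shape)
        pairs.append((int(i), int(j)))
        vals.append(work[i, j])
        work[i, :] = -1
        work[:, j] = -1
    return pairs, np.array(vals)


def brute_force_bh(p: np.ndarray, q: float) -> tuple[np.ndarray, np.ndarray]:
    """Literal step-up evaluation of Benjamini–Hochberg, as the oracle."""
    p = np.asarray(p, float)
    m = p.size
    order = np.argsort(p, kind="stable")
    sorted_p = p[order]
    # adjusted values with enforced monotonicity from the largest rank down
    adj = np.empty(m)
    running = 1.0
    for rank in range(m, 0, -1):
        running = min(running, sorted_p[rank - 1] * m / rank)
        adj[rank - 1] = running
    # step-up rejection: largest rank with p_(i) <= i*q/m, reject all below
    passing = [rank for rank in range(1, m + 1) if sorted_p[rank - 1] <= rank * q / m]
    cutoff = max(passing) if passing else 0
    reject_sorted = np.arange(1, m + 1) <= cutoff
    q_adj = np.empty(m)
    reject = np.empty(m, dtype=bool)
    q_adj[order] = adj
    reject[order] = reject_sorted
    return q_adj, reject


@pytest.fixture(scope="session")
def small_cohort() -> df.SyntheticCohort:
    """Default-condition cohort at a test-friendly size."""
    return df.simulate_cohort(n_subjects=300, seed=42)


@pytest.fixture
def rng() -> np.random.Generator:
    return np.random.default_rng(1234)
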