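import numpy as np
import pytest


@pytest.fixture
def rng():
    return np.random.default_rng(20260927)


def brute_force_mann_whitney_p(a, b):
    """Definitional two-sided rank-sum p: full enumeration of all group
    assignments of the pooled (tie-free) data, doubling the lower tail of
    min(U_ab, U_ba)."""
    from itertools import combinations

    from scipy.stats import rankdata

    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    pooled = np.concatenate([a, b])
    ranks = rankdata(pooled)
    n, N = len(a), len(pooled)
    u_obs = ranks[:n].sum() - n * (n + 1) / 2.0
    u_min = min(u_obs, n * (N - n) - u_obs)
    count = total = 0
    for idx in combinations(range(N), n):
        u = ranks[list(idx)].sum() - n * (n + 1) / 2.0
        total += 1
        if u <= u_min + 1e-9:
            count += 1
    return min(1.0, 2.0 * count / total)
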