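import itertools

import numpy as np
import pytest
from scipy import stats as sst

import envwhiten as ew


@pytest.fixture(scope="session")
def six_frequencies():
    return np.asarray(ew.SINUSOIDAL_ENVELOPE_FREQUENCIES)


def brute_force_signed_rank_p(diffs) -> float:
    """Exact two-sided signed-rank p by enumerating all 2**n sign patterns."""
    d = np.asarray(diffs, dtype=float)
    d = d[d != 0.0]
    ranks = sst.rankdata(np.abs(d))
    w_obs = float(ranks[d > 0].sum())
    n = d.size
    ws = np.array([float(np.dot(ranks, mask))
                   for mask in itertools.product([0.0, 1.0], repeat=n)])
    p_le = np.mean(ws <= w_obs + 1e-9)
    p_ge = np.mean(ws >= w_obs - 1e-9)
    return float(min(1.0, 2.0 * min(p_le, p_ge)))


@pytest.fixture(scope="session")
def signed_rank_oracle():
    return brute_force_signed_rank_p


def poisson_spikes_from_rate(rate_fn, duration, rmax, seed):
    """Independent inhomogeneous-Poisson oracle (thinning done by hand)."""
    rng = np.random.default_rng(seed)
    n = rng.poisson(rmax * duration)
    cand = np.sort(rng.uniform(0.0, duration, n))
    keep = rng.uniform(0.0, 1.0, n) < rate_fn(cand) / rmax
    return ew.SpikeTrain(times=cand[keep], duration=duration)


@pytest.fixture(scope="session")
def poisson_oracle():
    return poisson_spikes_from_rate
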