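import logging

import numpy as np
import pytest

from indelmark import RepeatTrack, SimulationConfig, simulate_panel
from indelmark.io import RunConfig

logging.getLogger("indelmark").setLevel(logging.ERROR)


@pytest.fixture(scope="session")
def rng():
    return np.random.default_rng(20260101)


@pytest.fixture(scope="session")
def small_panel():
    """Compact panel (2 chromosomes x 400 kb) for fast end-to-end tests."""
    cfg = SimulationConfig(n_chromosomes=2, chromosome_length=400_000, rng_seed=11)
    panel, truth = simulate_panel(cfg)
    return cfg, panel, truth


@pytest.fixture(scope="session")
def small_design(small_panel):
    from indelmark import design_markers

    cfg, panel, truth = small_panel
    run = RunConfig(interval=100_000, shift_limit=40_000)
    repeats = RepeatTrack.from_intervals(truth.repeat_tracts)
    result = design_markers(panel, repeats, run)
    return panel, truth, result


def slow_gotoh(a, b, match=1, mismatch=-1, go=-4, ge=-1):
    """Unbanded full-matrix affine-gap DP (score only): the alignment oracle."""
    n, m = len(a), len(b)
    NEG = float("-inf")
    M = [[NEG] * (m + 1) for _ in range(n + 1)]
    X = [[NEG] * (m + 1) for _ in range(n + 1)]
    Y = [[NEG] * (m + 1) for _ in range(n + 1)]
    M[0][0] = 0
    for i in range(1, n + 1):
        X[i][0] = go + (i - 1) * ge
    for j in range(1, m + 1):
        Y[0][j] = go + (j - 1) * ge
    for i in range(1, n + 1):
        ai = a[i - 1]
        for j in range(1, m + 1):
            s = match if (ai == b[j - 1] and ai != "N") else mismatch
            M[i][j] = max(M[i - 1][j - 1], X[i - 1][j - 1], Y[i - 1][j - 1]) + s
            X[i][j] = max(M[i - 1][j] + go, X[i - 1][j] + ge, Y[i - 1][j] + go)
            Y[i][j] = max(M[i][j - 1] + go, X[i][j - 1] + go, Y[i][j - 1] + ge)
    return max(M[n][m], X[n][m], Y[n][m])


def random_dna(rng, length):
    return "".join("ACGT"[i] for i in rng.integers(0, 4, length))
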