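import dataclasses

import pytest

from sineburst import pipeline, simgen
from sineburst.pipeline import RunConfig
from sineburst.simgen import SimConfig


def affine_local_score(a: str, b: str, match: int = 2, mismatch: int = -3,
                       gap_open: int = -5, gap_extend: int = -1) -> float:
    """Brute-force quadratic-space Gotoh local alignment score.

    Independent scalar-loop oracle: a gap of length L costs
    -(gap_open) - (L-1) * -(gap_extend).
    """
    n, m = len(a), len(b)
    NEG = float("-inf")
    H = [[0.0] * (m + 1) for _ in range(n + 1)]
    E = [[NEG] * (m + 1) for _ in range(n + 1)]   # gap in a (consumes b)
    F = [[NEG] * (m + 1) for _ in range(n + 1)]   # gap in b (consumes a)
    best = 0.0
    for i in range(1, n + 1):
        for j in range(1, m + 1):
            E[i][j] = max(H[i][j - 1] + gap_open, E[i][j - 1] + gap_extend)
            F[i][j] = max(H[i - 1][j] + gap_open, F[i - 1][j] + gap_extend)
            s = match if a[i - 1] == b[j - 1] else mismatch
            H[i][j] = max(0.0, H[i - 1][j - 1] + s, E[i][j], F[i][j])
            best = max(best, H[i][j])
    return best


@pytest.fixture(scope="session")
def founder_library():
    return simgen.make_founder_library(1)


@pytest.fixture(scope="session")
def small_trio(founder_library):
    cfg = SimConfig(seed=7, genome_length=120_000, n_call=20, n_sag=20,
                    n_ls_a=30, n_ls_b=30, n_ls_c=10, n_parallel=3)
    return simgen.simulate_trio(cfg, founder_library)


@pytest.fixture(scope="session")
def small_run(tmp_path_factory):
    cfg = RunConfig(outdir=str(tmp_path_factory.mktemp("run_small")), seed=7,
                    sim=SimConfig(genome_length=120_000, n_call=20, n_sag=20,
                                  n_ls_a=30, n_ls_b=30, n_ls_c=10, n_parallel=3))
    result = pipeline.run_all(cfg)
    metrics = pipeline.evaluate_against_truth(result)
    return result, metrics


@pytest.fixture(scope="session")
def default_run(tmp_path_factory):
    """The default study conditions: ~1 Mb genomes, ~1,600 insertions."""
    cfg = RunConfig(outdir=str(tmp_path_factory.mktemp("run_default")), seed=1)
    result = pipeline.run_all(cfg)
    metrics = pipeline.evaluate_against_truth(result)
    return result, metrics


@pytest.fixture()
def tiny_sim_config():
    return dataclasses.replace(SimConfig(), genome_length=60_000, n_call=5,
                               n_sag=5, n_ls_a=8, n_ls_b=8, n_ls_c=3, seed=5)
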