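import numpy as np
import pytest

from embryocnv.genome import build_default_genome
from embryocnv.sim import SimulationConfig


@pytest.fixture(scope="session")
def genome():
    return build_default_genome(bin_size=1_000_000)


@pytest.fixture(scope="session")
def coarse_genome():
    # 10 Mb bins: 10x fewer bins, for pipeline-level tests where per-bin
    # resolution is irrelevant
    return build_default_genome(bin_size=10_000_000)


@pytest.fixture()
def small_config():
    return SimulationConfig(n_patients=12, seed=7)


def make_counts(genome, arm_copies, depth=5040.0):
    """Noise-free binned counts for given per-(chromosome, arm) copy numbers.

    ``arm_copies`` is a (24, 2) array of mean copy numbers across the sampled
    cells; the expected count depth * copy / 2 is used directly as the
    observed count (integer by construction for depth 5040 and cell counts
    up to 10).
    """
    from embryocnv.sim import BinnedCounts

    arm_copies = np.asarray(arm_copies, dtype=float)
    mu = depth * arm_copies[genome.bin_chrom, genome.bin_arm] / 2.0
    return BinnedCounts("synthetic", np.round(mu).astype(np.int64), qc_pass=True)


def disomic_arm_copies(sex="XX"):
    c = np.full((24, 2), 2.0)
    if sex == "XY":
        c[22] = 1.0
        c[23] = 1.0
    else:
        c[23] = 0.0
    return c


@pytest.fixture(scope="session")
def rng():
    return np.random.default_rng(20230)
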