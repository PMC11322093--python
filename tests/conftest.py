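import numpy as np
import pandas as pd
import pytest

from netmr.summary_io import SummaryStats, summary_stats_from_frame
from netmr.synthetic_data import SimConfig, simulate_gwas_triplet


def make_stats(trait_id="trait", **columns):
    """Build a SummaryStats from keyword columns with sensible defaults."""
    n = max(len(v) for v in columns.values() if hasattr(v, "__len__"))
    base = {
        "snp_id": [f"rs{i}" for i in range(1, n + 1)],
        "chrom": ["1"] * n,
        "pos": list(range(1000, 1000 + n * 1000, 1000)),
        "effect_allele": ["A"] * n,
        "other_allele": ["G"] * n,
        "eaf": [0.3] * n,
        "beta": [0.1] * n,
        "se": [0.02] * n,
        "n": [10_000] * n,
    }
    base.update(columns)
    return summary_stats_from_frame(pd.DataFrame(base), trait_id)


@pytest.fixture
def rng():
    return np.random.default_rng(20240901)


@pytest.fixture(scope="session")
def triplet():
    """A deterministic simulated exposure/mediator/outcome triplet with a
    null outcome leg suitable for exercising the selection cascade."""
    cfg = SimConfig(n_snps=60, target_mean_f=60.0, beta_em=0.0, beta_mo=0.0,
                    beta_eo_direct=0.0, seed=11)
    return simulate_gwas_triplet(cfg)


def random_instance(rng, n=20, beta=0.2, sx=0.02, sy=0.01):
    """A clean strong-instrument dataset with known causal effect."""
    gamma = rng.uniform(0.1, 0.5, n) * rng.choice([-1, 1], n)
    bxse = np.full(n, sx)
    byse = np.full(n, sy)
    bx = gamma + rng.normal(0, sx, n)
    by = beta * gamma + rng.normal(0, sy, n)
    return bx, bxse, by, byse
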