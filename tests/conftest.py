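import numpy as np
import pytest

from cnvrkit.simulate import CnvrArchetype, MapDiscrepancyRates, SimConfig
from cnvrkit.types import CnvCall


def small_sim_config(seed: int = 11, **overrides) -> SimConfig:
    """A scaled-down cohort (5 x 2 Mb chromosomes, 60 samples) for fast tests."""
    defaults = dict(
        seed=seed,
        n_autosomes=5,
        chrom_length_bp=2_000_000,
        n_samples=60,
        snp_spacing_bp=5_000,
        archetypes=(
            CnvrArchetype("1", 500_001, 700_000, "loss", 0.5),
            CnvrArchetype("2", 1_000_001, 1_300_000, "gain", 0.4),
            CnvrArchetype("3", 200_001, 400_000, "mixed", 0.3),
            CnvrArchetype("4", 1_500_001, 1_600_000, "loss", 0.05),
        ),
        n_background_genes=10,
        map_rates=MapDiscrepancyRates(
            different_chromosomes=0.01,
            both_unknown=0.01,
            unknown_in_a=0.05,
            unknown_in_b=0.02,
            missing_from_a=0.02,
            missing_from_b=0.01,
            local_shuffle=0.05,
        ),
    )
    defaults.update(overrides)
    return SimConfig(**defaults)


@pytest.fixture
def small_config():
    return small_sim_config()


def random_calls(rng: np.random.Generator, n: int, *, n_samples: int = 10,
                 n_chroms: int = 2, chrom_len: int = 100_000,
                 max_len: int = 8_000, caller: str = "penncnv") -> list:
    """Uniform random calls on a small genome, for oracle comparisons."""
    out = []
    for _ in range(n):
        length = int(rng.integers(50, max_len))
        start = int(rng.integers(1, chrom_len - length))
        out.append(
            CnvCall(
                sample_id=f"S{int(rng.integers(1, n_samples + 1)):03d}",
                chrom=str(int(rng.integers(1, n_chroms + 1))),
                start=start,
                end=start + length - 1,
                cn=int(rng.choice([0, 1, 3, 4])),
                n_snp=3,
                caller=caller,
            )
        )
    return out
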