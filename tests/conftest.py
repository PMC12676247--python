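import numpy as np
import pytest

from phagekit.synthetic import CommunityConfig, generate_community


@pytest.fixture(scope="session")
def exact_community():
    """Mutation-free community: every recovery task must be exact."""
    cfg = CommunityConfig(
        n_phages=16,
        n_hosts=4,
        phage_len=(6000, 8000),
        host_len=(12000, 15000),
        n_species_groups=5,
        within_species_sub_rate=0.0,
        divergent_genus_frac=0.0,
        frac_recode=0.25,
        frac_phage_with_array=0.25,
        spacers_per_host_array=4,
        seed=42,
    )
    return generate_community(cfg)


@pytest.fixture(scope="session")
def diverged_community():
    """2% within-species divergence, distinct species backbones."""
    cfg = CommunityConfig(
        n_phages=18,
        n_hosts=0,
        phage_len=(6000, 8000),
        n_species_groups=6,
        within_species_sub_rate=0.02,
        divergent_genus_frac=0.0,
        seed=7,
    )
    return generate_community(cfg)


@pytest.fixture
def rng():
    return np.random.default_rng(1234)


def random_dna(rng, n: int) -> str:
    return "".join("ACGT"[b] for b in rng.integers(0, 4, n))
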