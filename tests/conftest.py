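import pytest

from cernet.synthetic_fixtures import (
    FixtureConfig,
    PlantedSponge,
    planted_pair_specs,
    simulate_universe,
)
from cernet.target_discovery import MirnaFamily, MirnaRecord

MIR21 = "UAGCUUAUCAGACUGAUGUUGA"  # hsa-miR-21-5p mature sequence


@pytest.fixture(scope="session")
def mir21_family() -> MirnaFamily:
    rec = MirnaRecord("hsa-miR-21-5p", MIR21, "miR-21-5p")
    return MirnaFamily("miR-21-5p", frozenset({rec.mirna_id}), rec.seed7)


@pytest.fixture(scope="session")
def small_bundle(tmp_path_factory):
    """A small planted bundle shared by fixture/pipeline tests (written once)."""
    out = tmp_path_factory.mktemp("bundle")
    config = FixtureConfig(
        rng_seed=11,
        n_families=40,
        n_null_genes=25,
        families_per_gene=5,
        transcript_length=(300, 600),
        n_experiments=3,
        p_support=1.0,
        planted_pairs=planted_pair_specs(2, 4),
        planted_sponges=(PlantedSponge("FAM001", "SPNG1", 9),),
    )
    return simulate_universe(config, out)
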