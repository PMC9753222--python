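import pytest

from arlnc.synthetic import SimulationConfig, simulate_bundle


@pytest.fixture(scope="session")
def bundle():
    """The default synthetic study at a fixed seed, shared across tests."""
    return simulate_bundle(SimulationConfig(seed=1))


@pytest.fixture(scope="session")
def small_annotation():
    """A compact annotation (fewer loci) for geometry-heavy tests."""
    cfg = SimulationConfig(
        seed=5,
        n_coding_genes=40,
        n_lncrnas_per_category={
            "intergenic": 4, "antisense": 4, "intronic": 2,
            "divergent": 2, "convergent": 2,
        },
        n_coding_pair_blocks={"APP": 2, "DPP": 2, "CPP": 2},
        n_planted_cerna_triplets=2,
        n_planted_duplex_pairs=2,
        n_planted_sorf_lncrnas=2,
        n_planted_srna_precursors=2,
        n_dual_function=1,
    )
    return simulate_bundle(cfg)
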