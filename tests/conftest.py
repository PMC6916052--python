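import pytest

from rcre_kit import synth


@pytest.fixture(scope="session")
def query():
    return synth.make_query(seed=101)


@pytest.fixture(scope="session")
def implanted_genome(query):
    """A 50-kb genome with five implants straddling the 94% threshold."""
    genome = synth.make_genome(50_000, seed=102)
    specs = [
        synth.ImplantSpec(98.0, "+", 3_000),
        synth.ImplantSpec(96.5, "-", 12_000),
        synth.ImplantSpec(95.0, "+", 25_000),
        synth.ImplantSpec(94.2, "-", 35_000),
        synth.ImplantSpec(90.0, "+", 45_000),
    ]
    return synth.implant_many(genome, query, specs, seed=103)


@pytest.fixture(scope="session")
def two_locus_sim():
    """Repetitive two-locus alignment fixture: unique + shared segments."""
    loci = [
        synth.SimLocus("provA", "chrP", 1_000, 6_000, "+",
                       n_unique_fragments=100, n_shared_fragments=50),
        synth.SimLocus("provB", "chrP", 10_000, 15_000, "-",
                       n_unique_fragments=60, n_shared_fragments=30),
    ]
    spec = synth.SimAlignmentSpec(loci, n_improper=5, n_secondary=5)
    sam_text, truth = synth.simulate_alignments(spec, seed=104)
    return loci, spec, sam_text, truth
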