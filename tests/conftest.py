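import pytest

from mitocam import CodingGene, SyntheticSpec, generate_cds_set, get_code


@pytest.fixture(scope="session")
def code2():
    return get_code(2)


@pytest.fixture(scope="session")
def code1():
    return get_code(1)


@pytest.fixture
def make_gene(code2):
    """Factory for a CodingGene from a plain CDS string."""

    def _make(cds: str, species: str = "sp", gene: str = "MT-ND2") -> CodingGene:
        codons = tuple(cds[i:i + 3] for i in range(0, len(cds) - len(cds) % 3, 3))
        return CodingGene(species=species, gene_name=gene, cds=cds,
                          codons=codons,
                          has_complete_stop=bool(codons) and code2.is_stop(codons[-1]))

    return _make


@pytest.fixture(scope="session")
def small_spec():
    """A 5-species, 4-gene bundle small enough for fast end-to-end runs."""
    return SyntheticSpec(
        n_species=5,
        gene_lengths_codons={"MT-ND2": 347, "MT-CO1": 517, "MT-ATP8": 56,
                             "MT-ND6": 173},
        seed=11,
    )


@pytest.fixture(scope="session")
def small_bundle(small_spec):
    return generate_cds_set(small_spec)


@pytest.fixture(scope="session")
def study_spec():
    """Default study conditions: 10 species, the 13 genes at published lengths."""
    return SyntheticSpec(seed=7)


@pytest.fixture(scope="session")
def study_bundle(study_spec):
    return generate_cds_set(study_spec)
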