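from collections import Counter

import pytest

from mitocam import (
    CamMotif,
    CamProfile,
    CodonCounts,
    aversion_count_summary,
    aversion_set,
    build_profile,
    count_codons,
    eligible_genes,
    identify_species,
    uniqueness_matrix,
)
from mitocam.reference import PCG_LENGTHS_BP


def _counts(mapping, unit=("sp", "g")):
    return CodonCounts(unit=unit, counts=Counter(mapping))


class TestAversionSet:
    def test_all_codons_used_gives_empty_motif(self, code2):
        motif = aversion_set(_counts({c: 1 for c in code2.sense_codons}), code2)
        assert motif.absent_codons == frozenset()
        assert motif.motif_string == ""

    def test_missing_codons_form_motif(self, code2):
        counts = {c: 1 for c in code2.sense_codons if c not in ("CGC", "CGG")}
        motif = aversion_set(_counts(counts), code2)
        assert motif.absent_codons == {"CGC", "CGG"}
        assert motif.motif_string == "CGC-CGG"

    def test_absent_and_used_partition_sense_codons(self, code2, make_gene):
        gene = make_gene("ATG" + "AAAGGCTTACAT" * 4 + "TAA")
        counts = count_codons(gene, code=code2)
        motif = aversion_set(counts, code2)
        used = {c for c, n in counts.counts.items() if n > 0}
        assert used | motif.absent_codons == set(code2.sense_codons)
        assert used.isdisjoint(motif.absent_codons)

    def test_more_observations_never_enlarge_motif(self, code2):
        base = {"AAA": 1, "GGC": 2}
        bigger = dict(base, TTA=1)
        m1 = aversion_set(_counts(base), code2)
        m2 = aversion_set(_counts(bigger), code2)
        assert m2.absent_codons <= m1.absent_codons

    def test_planted_aversion_recovered_exactly(self):
        # High concentration + long gene: every non-planted codon appears.
        from mitocam import SyntheticSpec, generate_cds_set

        planted = {"species_01": frozenset({"CGC", "GCC"}),
                   "species_02": frozenset({"TTG", "ACG"})}
        spec = SyntheticSpec(n_species=2, gene_lengths_codons={"MT-ND5": 6000},
                             family_concentration=50.0, gene_concentration=500.0,
                             planted_aversion=planted, divergence_p=0.01, seed=5)
        _, sets, _ = generate_cds_set(spec)
        for sp, want in planted.items():
            counts = count_codons(sets[sp]["MT-ND5"])
            assert aversion_set(counts).absent_codons == want


class TestEligibility:
    def test_published_lengths_yield_eleven_genes(self):
        eligible = eligible_genes(PCG_LENGTHS_BP)
        assert len(eligible) == 11
        assert "MT-ATP8" not in eligible  # 168 bp
        assert "MT-ND4L" not in eligible  # 297 bp

    def test_threshold_extremes(self):
        assert len(eligible_genes(PCG_LENGTHS_BP, min_length=1)) == 13
        assert eligible_genes(PCG_LENGTHS_BP, min_length=2000) == []


def _motif(species, gene, codons):
    return CamMotif(species=species, gene_name=gene,
                    absent_codons=frozenset(codons))


class TestUniqueness:
    def test_identical_profiles_nothing_distinct(self):
        p1 = CamProfile("a", {"g1": _motif("a", "g1", {"AAA"})})
        p2 = CamProfile("b", {"g1": _motif("b", "g1", {"AAA"})})
        report = uniqueness_matrix([p1, p2])
        assert report.genes_fully_distinct == []
        assert report.pairwise["g1"][("a", "b")] is False

    def test_disjoint_motifs_fully_distinct(self):
        p1 = CamProfile("a", {"g1": _motif("a", "g1", {"AAA"})})
        p2 = CamProfile("b", {"g1": _motif("b", "g1", {"GGC"})})
        report = uniqueness_matrix([p1, p2])
        assert report.genes_fully_distinct == ["g1"]

    def test_missing_gene_marked_incomparable(self):
        p1 = CamProfile("a", {"g1": _motif("a", "g1", {"AAA"})})
        p2 = CamProfile("b", {})
        report = uniqueness_matrix([p1, p2], genes=["g1"])
        assert report.incomparable == [("g1", "a", "b")]
        assert report.genes_fully_distinct == []

    def test_planted_distinct_synthetic_bundle(self, small_bundle, small_spec):
        _, sets, truth = small_bundle
        profiles = [build_profile(sp, genes.values())
                    for sp, genes in sorted(sets.items())]
        report = uniqueness_matrix(profiles)
        # pairwise-distinct planted sets force every eligible gene distinct
        assert set(report.genes_fully_distinct) == set(report.genes)
        planted = truth.planted
        assert len({planted[sp] for sp in planted}) == small_spec.n_species


@pytest.fixture(scope="module")
def panel(small_bundle):
    _, sets, _ = small_bundle
    return [build_profile(sp, genes.values())
            for sp, genes in sorted(sets.items())]


class TestIdentify:

    def test_self_query_ranks_first_with_full_count(self, panel):
        for profile in panel:
            ranking = identify_species(profile, panel)
            assert ranking[0] == (profile.species, len(profile.motifs))

    def test_single_perturbed_gene_still_identified(self, panel):
        query = panel[0]
        gene = sorted(query.motifs)[0]
        mutated = dict(query.motifs)
        mutated[gene] = _motif(query.species, gene,
                               query.motifs[gene].absent_codons ^ {"AAA"})
        perturbed = CamProfile(query.species, mutated)
        ranking = identify_species(perturbed, panel)
        assert ranking[0][0] == query.species
        assert ranking[0][1] == len(query.motifs) - 1

    def test_held_out_species_scores_below_full(self, panel):
        from mitocam import SyntheticSpec, generate_cds_set

        spec = SyntheticSpec(
            n_species=6,
            gene_lengths_codons={"MT-ND2": 347, "MT-CO1": 517,
                                 "MT-ATP8": 56, "MT-ND6": 173},
            seed=11)
        _, sets, _ = generate_cds_set(spec)
        held_out = build_profile("species_06", sets["species_06"].values())
        ranking = identify_species(held_out, panel)
        assert ranking[0][1] < len(held_out.motifs)

    def test_empty_query_returns_empty(self, panel):
        assert identify_species(CamProfile("x", {}), panel) == []

    def test_empty_reference_rejected(self, panel):
        with pytest.raises(ValueError):
            identify_species(panel[0], [])


class TestAversionCountSummary:
    def test_identical_groups_identical_summaries(self):
        p = CamProfile("a", {"g1": _motif("a", "g1", {"AAA", "AAG"})})
        q = CamProfile("b", {"g1": _motif("b", "g1", {"AAA", "AAG"})})
        df = aversion_count_summary({"fam1": [p], "fam2": [q]})
        g1 = df[df.group == "fam1"].drop(columns="group").reset_index(drop=True)
        g2 = df[df.group == "fam2"].drop(columns="group").reset_index(drop=True)
        assert g1.equals(g2)

    def test_single_species_group_equals_profile_counts(self, code2):
        p = CamProfile("a", {"g1": _motif("a", "g1", {"GCC", "GCA"}),
                             "g2": _motif("a", "g2", {"GCT"})})
        df = aversion_count_summary({"solo": [p]})
        row = df.set_index("amino_acid")["absent_codons"]
        assert row["A"] == 3  # all three absent codons are Ala

    def test_planted_difference_localized_to_planted_amino_acids(self, code2):
        shared = {"g1": _motif("a", "g1", {"AAA"})}
        p = CamProfile("a", dict(shared))
        q = CamProfile("b", {"g1": _motif("b", "g1", {"AAA", "GGC"})})
        df = aversion_count_summary({"f1": [p], "f2": [q]})
        pivot = df.pivot(index="amino_acid", columns="group",
                         values="absent_codons").fillna(0)
        differing = pivot[pivot.f1 != pivot.f2].index.tolist()
        assert differing == ["G"]
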