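import math

import numpy as np
import pytest

from mitocam import (
    GeneMatrix,
    build_gene_matrix,
    diversity_stats,
    ng86_dnds,
    ng86_pair,
    nucleotide_diversity,
    selection_classification,
    ts_tv,
    variable_sites,
)
from mitocam.divergence import _codon_sites

from .oracles import brute_force_ng86, random_sense_codon_pairs


def _matrix(rows, gene="MT-ND2", species=None):
    species = species or tuple(f"sp{i}" for i in range(len(rows)))
    return GeneMatrix(gene_name=gene, species_order=tuple(species),
                      rows=tuple(rows))


class TestBuildMatrix:
    def test_equal_rows_valid(self, make_gene):
        g1 = make_gene("ATGAAATAA", species="a")
        g2 = make_gene("ATGAAATAA", species="b")
        m = build_gene_matrix([g1, g2])
        assert m.length == 9 and m.n == 2

    def test_length_mismatch_names_offender(self, make_gene):
        g1 = make_gene("ATG" + "AAA" * 99 + "TAA", species="a")
        g2 = make_gene("ATG" + "AAA" * 100 + "TAA", species="b")
        with pytest.raises(ValueError, match="alignment required.*b"):
            build_gene_matrix([g1, g2])

    def test_single_row_rejected(self, make_gene):
        with pytest.raises(ValueError):
            build_gene_matrix([make_gene("ATGAAATAA")])

    def test_trim_terminal_stop(self, make_gene, code2):
        g1 = make_gene("ATGAAATAA", species="a")
        g2 = make_gene("ATGAAGTAA", species="b")
        m = build_gene_matrix([g1, g2], trim_terminal_stop=True, code=code2)
        assert m.length == 6


class TestVariableSites:
    def test_identical_rows_zero(self):
        count, pct = variable_sites(_matrix(["ACGT", "ACGT"]))
        assert (count, pct) == (0, 0.0)

    def test_three_of_ten(self):
        count, pct = variable_sites(_matrix(["AAAAAAAAAA", "CCCAAAAAAA"]))
        assert (count, pct) == (3, 30.0)

    def test_ambiguous_bases_ignored(self):
        count, _ = variable_sites(_matrix(["AN", "AN", "AA"]))
        assert count == 0


class TestPi:
    def test_identical_rows(self):
        assert nucleotide_diversity(_matrix(["ACGT", "ACGT"])) == 0.0

    def test_two_rows_closed_form(self):
        m = _matrix(["AAAAAAAAAA", "CCAAAAAAAA"])
        assert nucleotide_diversity(m) == pytest.approx(0.2)

    def test_bounded_by_variable_site_fraction(self):
        rng = np.random.default_rng(0)
        rows = ["".join(rng.choice(list("ACGT"), size=30)) for _ in range(5)]
        m = _matrix(rows)
        pi = nucleotide_diversity(m)
        var, _ = variable_sites(m)
        assert pi <= var / m.length + 1e-12

    def test_row_permutation_invariance(self):
        rng = np.random.default_rng(1)
        rows = ["".join(rng.choice(list("ACGT"), size=24)) for _ in range(4)]
        m1 = _matrix(rows)
        m2 = _matrix(rows[::-1])
        assert nucleotide_diversity(m1) == pytest.approx(nucleotide_diversity(m2))
        assert variable_sites(m1) == variable_sites(m2)
        assert ts_tv(m1) == ts_tv(m2)

    def test_pairwise_vs_complete_deletion(self):
        m = _matrix(["ACGTN", "ACGTA", "TCGTA"])
        pairwise = nucleotide_diversity(m)
        complete = nucleotide_diversity(m, complete_deletion=True)
        # one N: complete deletion shortens every pair to 4 sites
        assert complete == pytest.approx((1 / 4 + 0 + 1 / 4) / 3)
        assert pairwise == pytest.approx((1 / 4 + 0 + 1 / 5) / 3)


class TestTsTv:
    @pytest.mark.parametrize("rows, expected", [
        (["AAAA", "GGGG"], (4, 0, None)),
        (["AAAA", "CCCC"], (0, 4, 0.0)),
        (["AAGC", "GAAC"], (2, 0, None)),
    ])
    def test_hand_tallies(self, rows, expected):
        assert ts_tv(_matrix(rows)) == expected

    def test_ts_plus_tv_equals_pairwise_differences(self):
        rng = np.random.default_rng(7)
        rows = ["".join(rng.choice(list("ACGT"), size=40)) for _ in range(4)]
        m = _matrix(rows)
        ts, tv, _ = ts_tv(m)
        from itertools import combinations
        diffs = sum(sum(x != y for x, y in zip(a, b))
                    for a, b in combinations(rows, 2))
        assert ts + tv == diffs


class TestNg86:
    def test_identical_rows(self, code2):
        codons = ("ATG", "AAA", "GGC")
        dn, ds = ng86_pair(codons, codons, code2)
        assert dn == 0.0 and ds == 0.0

    def test_pure_synonymous_difference(self, code2):
        from mitocam.divergence import _codon_path_diffs
        # ATT vs ATC is Ile vs Ile: one synonymous, zero nonsynonymous
        assert _codon_path_diffs("ATT", "ATC", code2) == (1.0, 0.0)
        # embedded in a longer identical context the corrected ds is positive
        context = ("AAA",) * 10
        dn, ds = ng86_pair(context + ("ATT",), context + ("ATC",), code2)
        assert dn == 0.0
        assert ds > 0.0

    def test_sites_sum_to_three_per_codon(self, code2):
        for codon in code2.sense_codons:
            s = _codon_sites(codon, code2)
            assert 0.0 <= s <= 3.0
            # nonsynonymous sites are 3 - s by construction; verify s is
            # the stop-excluded synonymous fraction summed over positions
        # Ile is two-fold (ATT/ATC) under table 2: one of three third-position
        # changes is synonymous, first and second positions none.
        assert _codon_sites("ATT", code2) == pytest.approx(1 / 3)

    def test_matches_brute_force_oracle(self, code2):
        rng = np.random.default_rng(99)
        for _ in range(20):
            c1, c2 = random_sense_codon_pairs(rng, code2, n_codons=30)
            dn, ds = ng86_pair(c1, c2, code2)
            bf_dn, bf_ds = brute_force_ng86(c1, c2, code2)
            assert dn == pytest.approx(bf_dn, abs=1e-9)
            assert ds == pytest.approx(bf_ds, abs=1e-9)

    def test_internal_stop_is_error(self, code2):
        with pytest.raises(ValueError, match="stop"):
            ng86_pair(("ATG", "TAA", "AAA"), ("ATG", "AAA", "AAA"), code2)

    def test_matrix_interface_trims_terminal_stop(self, make_gene, code2):
        g1 = make_gene("ATGATTGGCTAA", species="a")
        g2 = make_gene("ATGATCGGCTAA", species="b")
        m = build_gene_matrix([g1, g2])
        dn, ds, ratio = ng86_dnds(m, code2)
        assert dn == 0.0 and ds > 0.0 and ratio == 0.0

    def test_saturated_pair_dropped(self, make_gene, code2):
        # maximally different rows push p beyond the Jukes-Cantor domain
        g1 = make_gene("ATG" + "AAA" * 30, species="a")
        g2 = make_gene("ATG" + "CCC" * 30, species="b")
        m = build_gene_matrix([g1, g2])
        with pytest.raises(ValueError, match="no usable pairs"):
            ng86_dnds(m, code2)


class TestSelectionClassification:
    @pytest.mark.parametrize("value, label", [
        (0.25631, "purifying"), (1.0, "neutral"), (2.5, "positive")])
    def test_thresholds(self, value, label):
        assert selection_classification(value) == label

    def test_nan_rejected(self):
        with pytest.raises(ValueError):
            selection_classification(math.nan)


def test_diversity_stats_bundles_everything(make_gene, code2):
    # enough identical context that the Jukes-Cantor correction is defined
    g1 = make_gene("ATGATTGGCAAA" + "GGC" * 6 + "TAA", species="a")
    g2 = make_gene("ATGATCGGCAAG" + "GGC" * 6 + "TAA", species="b")
    st = diversity_stats(build_gene_matrix([g1, g2]), code2)
    assert st.var_sites == 2
    assert st.pi == pytest.approx(2 / 33)
    assert st.method_tag == "NG86"
    assert st.ts + st.tv == 2
    assert st.dn == 0.0 and st.ds > 0.0  # both differences are synonymous
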