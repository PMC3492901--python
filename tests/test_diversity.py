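"""Diversity and divergence estimators against brute-force oracles."""

import math
from itertools import combinations

import pytest

from divscan.alignment import filter_sites, outgroup_consensus
from divscan.annotation import CodingInterval, classify_sites
from divscan.diversity import (
    category_diversity,
    compute_gene_diversity,
    dxy,
    ka_ks,
    segregating_sites,
    theta_pi,
    theta_pi_locus,
    theta_w,
)

from conftest import make_alignment


def brute_force_pi_locus(matrix):
    n = matrix.shape[0]
    pairs = list(combinations(range(n), 2))
    return sum((matrix[i] != matrix[j]).sum() for i, j in pairs) / len(pairs)


class TestSegregatingSites:
    def test_monomorphic(self):
        f = filter_sites(make_alignment(["AAAA", "AAAA", "AAAA"], ["AAAA"]))
        assert segregating_sites(f) == 0

    def test_worked_matrix(self, worked_matrix):
        _, f = worked_matrix
        assert segregating_sites(f) == 2


class TestThetaPi:
    def test_single_pair(self):
        f = filter_sites(make_alignment(["A" * 100, "A" * 99 + "T"], ["A" * 100]))
        assert theta_pi(f) == pytest.approx(0.01)

    def test_worked_matrix(self, worked_matrix):
        _, f = worked_matrix
        assert theta_pi_locus(f) == pytest.approx(7 / 6, abs=1e-12)
        assert theta_pi(f) == pytest.approx(7 / 60, abs=1e-12)

    def test_matches_brute_force(self, worked_matrix):
        _, f = worked_matrix
        assert theta_pi_locus(f) == pytest.approx(
            brute_force_pi_locus(f.matrix), abs=1e-12
        )

    def test_identical_sequences(self):
        f = filter_sites(make_alignment(["ACGT"] * 4, ["ACGT"]))
        assert theta_pi(f) == 0.0

    def test_row_permutation_invariant(self, worked_matrix):
        aln, f = worked_matrix
        rows = [r.tobytes().decode() for r in aln.ingroup]
        shuffled = make_alignment(rows[::-1], ["A" * 10])
        assert theta_pi(filter_sites(shuffled)) == pytest.approx(theta_pi(f))


class TestThetaW:
    def test_n2(self):
        f = filter_sites(make_alignment(["A" * 100, "A" * 99 + "T"], ["A" * 100]))
        assert theta_w(f) == pytest.approx(0.01)
        assert theta_w(f) == pytest.approx(theta_pi(f))  # n=2 identity

    def test_n4_closed_form(self, worked_matrix):
        _, f = worked_matrix
        assert theta_w(f) == pytest.approx(2 / ((11 / 6) * 10), abs=1e-12)

    def test_no_variation(self):
        f = filter_sites(make_alignment(["AAAA"] * 5, ["AAAA"]))
        assert theta_w(f) == 0.0


class TestDxy:
    def test_row_averaged(self):
        # rows differ from the consensus by 0,1,2,2 over 10 usable sites
        aln = make_alignment(
            ["AAAAAAAAAA", "AAAAAAAAAT", "AAAAAAAATT", "AAAAAAAATT"],
            ["AAAAAAAAAA"],
        )
        f = filter_sites(aln)
        assert dxy(f, outgroup_consensus(aln)) == pytest.approx(5 / 40)

    def test_zero_when_identical(self):
        aln = make_alignment(["ACGT", "ACGT"], ["ACGT"])
        f = filter_sites(aln)
        assert dxy(f, outgroup_consensus(aln)) == 0.0

    def test_renormalizes_by_usable_sites(self):
        aln = make_alignment(["ACGT", "ACGT"], ["NNNT"])
        f = filter_sites(aln)
        assert dxy(f, outgroup_consensus(aln)) == 0.0  # single usable matching site

    def test_all_unresolved_is_na(self):
        aln = make_alignment(["ACGT", "ACGT"], ["NNNN"])
        f = filter_sites(aln)
        assert math.isnan(dxy(f, outgroup_consensus(aln)))


class TestCategoryDiversity:
    def test_all_variation_noncoding(self):
        # coding codon GGG monomorphic, noncoding tail variable
        aln = make_alignment(["GGGAT", "GGGAA", "GGGAA"], ["GGGAA"])
        f = filter_sites(aln)
        ann = classify_sites(f, [CodingInterval(0, 3, 0)])
        pi, tw = category_diversity(f, ann)
        assert pi["nonsynonymous"] == 0.0 and pi["synonymous"] == 0.0
        assert pi["noncoding"] > 0

    def test_weighted_recombination_oracle(self):
        """Category pi values recombine to the pairwise total over the
        categorized columns, weighted by fractional site counts."""
        from divscan.synthetic import SyntheticGeneSpec, generate_gene

        spec = SyntheticGeneSpec(gene_id="w", n=10, L=330, theta_site=0.02,
                                 coding_fraction=0.6, seed=17)
        aln, intervals, _ = generate_gene(spec)
        f = filter_sites(aln)
        ann = classify_sites(f, intervals)
        pi, _ = category_diversity(f, ann)
        sites = {
            "noncoding": ann.noncoding_sites,
            "synonymous": ann.syn_sites,
            "nonsynonymous": ann.nonsyn_sites,
        }
        recombined = sum(pi[c] * sites[c] for c in sites if sites[c] > 0)
        n = f.n
        npairs = n * (n - 1) / 2
        from divscan.diversity import pairwise_diff_sums

        keep = ann.site_category != "mixed_excluded"
        direct = pairwise_diff_sums(f)[keep].sum() / npairs
        assert recombined == pytest.approx(direct, abs=1e-9)

    def test_category_without_variants_is_zero(self):
        aln = make_alignment(["GGGA", "GGGA"], ["GGGA"])
        f = filter_sites(aln)
        ann = classify_sites(f, [CodingInterval(0, 3, 0)])
        pi, tw = category_diversity(f, ann)
        assert pi["noncoding"] == 0.0 and tw["noncoding"] == 0.0


class TestKaKs:
    def test_single_synonymous_fixed_difference(self):
        """25 codons of GGx (Gly): third positions are fully synonymous
        sites (25 of them), one fixed GGA->GGG difference gives Ks = 1/25."""
        ing = "GGA" * 25
        out = "GGG" + "GGA" * 24
        aln = make_alignment([ing, ing], [out])
        f = filter_sites(aln)
        res = ka_ks(f, [CodingInterval(0, 75, 0)], outgroup_consensus(aln))
        assert res.syn_sites == pytest.approx(25.0)
        assert res.ks == pytest.approx(0.04)
        assert res.ka == 0.0

    def test_no_divergence_ratio_na(self):
        ing = "GGAATG" * 5
        aln = make_alignment([ing, ing], [ing])
        f = filter_sites(aln)
        res = ka_ks(f, [CodingInterval(0, 30, 0)], outgroup_consensus(aln))
        assert res.ka == 0.0 and res.ks == 0.0
        assert math.isnan(res.ratio)

    def test_nonsynonymous_fixed_difference(self):
        # AAA (Lys) vs GAA (Glu): one nonsynonymous difference
        ing = "AAA" + "GGA" * 9
        out = "GAA" + "GGA" * 9
        aln = make_alignment([ing, ing], [out])
        f = filter_sites(aln)
        res = ka_ks(f, [CodingInterval(0, 30, 0)], outgroup_consensus(aln))
        assert res.nonsyn_diffs == pytest.approx(1.0)
        assert res.syn_diffs == 0.0
        assert res.ka == pytest.approx(1.0 / res.nonsyn_sites)
        assert math.isnan(res.ratio)  # Ks = 0


class TestGeneDiversityAssembly:
    def test_na_policy(self):
        aln = make_alignment(["NN", "NN"], ["AA"])
        f = filter_sites(aln)
        gd = compute_gene_diversity(f)
        assert gd.L == 0 and gd.S == 0
        assert math.isnan(gd.theta_pi) and math.isnan(gd.theta_w)

    def test_zero_iff_no_segregation(self, worked_matrix):
        aln, f = worked_matrix
        gd = compute_gene_diversity(f, None, outgroup_consensus(aln))
        assert gd.S == 2 and gd.theta_pi > 0
        mono = filter_sites(make_alignment(["AAAA"] * 3, ["AAAA"]))
        gd0 = compute_gene_diversity(mono)
        assert gd0.theta_pi == 0.0 and gd0.theta_w == 0.0
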