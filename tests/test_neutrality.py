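"""The four neutrality statistics and outgroup polarization."""

import math

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from divscan.alignment import filter_sites, outgroup_consensus
from divscan.diversity import harmonic, theta_pi_locus
from divscan.neutrality import (
    PolarizedSpectrum,
    ewens_watterson_f,
    fay_wu_h,
    fay_wu_h_var,
    gene_neutrality,
    kelly_zns,
    polarize,
    tajima_d,
    theta_l,
)

from conftest import make_alignment


class TestPolarize:
    def test_consensus_matches_one_allele(self):
        aln = make_alignment(["AAAA", "AAAA", "TAAA", "TAAA"], ["AAAA"])
        spec = polarize(filter_sites(aln), outgroup_consensus(aln))
        assert list(spec.counts) == [2]
        assert spec.unpolarized == 0

    def test_third_allele_unpolarizable(self):
        aln = make_alignment(["AAAA", "AAAA", "TAAA", "TAAA"], ["GAAA"])
        spec = polarize(filter_sites(aln), outgroup_consensus(aln))
        assert spec.n_polarized == 0 and spec.unpolarized == 1

    def test_unresolved_consensus_unpolarizable(self):
        aln = make_alignment(["AAAA", "TAAA"], ["GAAA", "CAAA"])
        spec = polarize(filter_sites(aln), outgroup_consensus(aln))
        assert spec.unpolarized == 1

    def test_synthetic_truth_recovery(self):
        """Derived counts recovered via the outgroup match the simulator's
        truth at >= 99% of polarizable sites across many genes."""
        from divscan.synthetic import SyntheticGeneSpec, generate_gene

        hits = total = 0
        for g in range(60):
            spec_g = SyntheticGeneSpec(
                gene_id=f"pol{g}", n=8, L=400, theta_site=0.008,
                outgroup_divergence=0.01, seed=1000 + g,
            )
            aln, _, truth = generate_gene(spec_g)
            f = filter_sites(aln)
            cons = outgroup_consensus(aln)
            truth_by_col = dict(
                zip(truth.variant_positions.tolist(), truth.derived_counts.tolist())
            )
            counts4 = f.allele_counts()
            variant_cols = f.retained_columns[f.variant_mask()]
            spec = polarize(f, cons)
            it = iter(spec.counts.tolist())
            bases = np.frombuffer(b"ACGT", dtype="S1")
            cons_ret = cons[f.retained_columns]
            for j, col in zip(np.flatnonzero(f.variant_mask()), variant_cols):
                present = np.flatnonzero(counts4[:, j])
                if cons_ret[j] not in bases[present]:
                    continue  # unpolarizable
                inferred = next(it)
                if int(col) in truth_by_col:
                    total += 1
                    hits += int(inferred == truth_by_col[int(col)])
        assert total > 100
        assert hits / total >= 0.99


class TestTajimaD:
    def test_worked_matrix(self, worked_matrix):
        _, f = worked_matrix
        d = tajima_d(2, theta_pi_locus(f), 4)
        assert d == pytest.approx(0.5916, abs=5e-4)

    def test_independent_constants_oracle(self):
        """Recompute D from scratch with independently coded Tajima
        constants for several (n, S) combinations."""
        for n, S, pi in ((4, 2, 7 / 6), (10, 5, 4.0), (12, 8, 9.5)):
            a1 = sum(1 / i for i in range(1, n))
            a2 = sum(1 / i**2 for i in range(1, n))
            b1 = (n + 1) / (3 * (n - 1))
            b2 = 2 * (n**2 + n + 3) / (9 * n * (n - 1))
            c1 = b1 - 1 / a1
            c2 = b2 - (n + 2) / (a1 * n) + a2 / a1**2
            e1 = c1 / a1
            e2 = c2 / (a1**2 + a2)
            expected = (pi - S / a1) / math.sqrt(e1 * S + e2 * S * (S - 1))
            assert tajima_d(S, pi, n) == pytest.approx(expected, abs=1e-12)

    def test_zero_numerator(self):
        n, S = 6, 3
        assert tajima_d(S, S / harmonic(n), n) == pytest.approx(0.0, abs=1e-12)

    def test_undefined_without_segregation(self):
        assert math.isnan(tajima_d(0, 0.0, 8))


class TestFayWuH:
    def test_worked_numerator(self, worked_matrix):
        aln, f = worked_matrix
        spec = polarize(f, outgroup_consensus(aln))
        assert theta_l(spec.counts, 4) == pytest.approx(5 / 3)
        assert fay_wu_h(spec, normalized=False) == pytest.approx(-0.5)

    def test_zero_when_pi_equals_theta_l(self):
        # derived count n/2 makes the per-site pi and theta_L terms equal,
        # so the numerator (and normalized H) is exactly zero
        spec = PolarizedSpectrum(n=4, counts=np.array([2, 2, 2]))
        assert fay_wu_h(spec) == pytest.approx(0.0, abs=1e-12)

    def test_variance_positive_and_zero_at_n2(self):
        assert fay_wu_h_var(2, 5) == pytest.approx(0.0, abs=1e-12)
        for n, S in ((3, 2), (12, 10), (6, 4)):
            assert fay_wu_h_var(n, S) > 0

    def test_unpolarized_sites_do_not_move_theta_l(self):
        spec_a = PolarizedSpectrum(n=6, counts=np.array([1, 4]), unpolarized=0)
        spec_b = PolarizedSpectrum(n=6, counts=np.array([1, 4]), unpolarized=3)
        assert theta_l(spec_a.counts, 6) == theta_l(spec_b.counts, 6)
        assert fay_wu_h(spec_a) == fay_wu_h(spec_b)

    def test_na_without_polarizable_sites(self):
        spec = PolarizedSpectrum(n=6, counts=np.array([], dtype=int), unpolarized=2)
        assert math.isnan(fay_wu_h(spec))


class TestEwensWatterson:
    def test_all_identical(self):
        f = filter_sites(make_alignment(["ACGT"] * 4, ["ACGT"]))
        assert ewens_watterson_f(f) == 1.0

    def test_all_distinct(self):
        f = filter_sites(make_alignment(["AAAA", "TAAA", "ATAA", "AATA"], ["AAAA"]))
        assert ewens_watterson_f(f) == 0.25

    def test_worked_matrix(self, worked_matrix):
        _, f = worked_matrix
        assert ewens_watterson_f(f) == pytest.approx(0.375)

    def test_bounds(self, worked_matrix):
        _, f = worked_matrix
        assert 1 / f.n <= ewens_watterson_f(f) <= 1

    def test_strictly_decreases_on_haplotype_split(self):
        base = ["AAAA", "AAAA", "TAAA", "TAAA"]
        split = ["AAAA", "AAAT", "TAAA", "TAAA"]  # one duplicate mutated
        f0 = ewens_watterson_f(filter_sites(make_alignment(base, ["AAAA"])))
        f1 = ewens_watterson_f(filter_sites(make_alignment(split, ["AAAA"])))
        assert f1 < f0


class TestKellyZns:
    def test_complete_association(self):
        f = filter_sites(make_alignment(["AATT", "AATT", "TTAA", "TTAA"], ["AATT"]))
        assert kelly_zns(f) == pytest.approx(1.0)

    def test_worked_matrix(self, worked_matrix):
        _, f = worked_matrix
        assert kelly_zns(f) == pytest.approx(1 / 3)

    def test_r2_from_haplotype_table(self, worked_matrix):
        # independent 2x2 haplotype-table computation at the two sites
        _, f = worked_matrix
        pT1, pT2 = 0.5, 0.75
        pTT = 0.5
        D = pTT - pT1 * pT2
        r2 = D**2 / (pT1 * (1 - pT1) * pT2 * (1 - pT2))
        assert kelly_zns(f) == pytest.approx(r2)

    def test_undefined_below_two_sites(self):
        f = filter_sites(make_alignment(["AAAA", "TAAA"], ["AAAA"]))
        assert math.isnan(kelly_zns(f))

    def test_label_swap_invariance(self):
        m = np.array(
            [[0, 1, 0], [1, 0, 0], [1, 1, 1], [0, 0, 1]], dtype=float
        )
        swapped = m.copy()
        swapped[:, 1] = 1 - swapped[:, 1]
        assert kelly_zns(m) == pytest.approx(kelly_zns(swapped))


class TestPermutationInvariance:
    @settings(max_examples=20, derandomize=True)
    @given(st.integers(0, 2**31 - 1))
    def test_row_and_column_permutation(self, seed):
        """D and H are row-permutation invariant; F and Zns additionally
        column-permutation invariant."""
        rng = np.random.default_rng(seed)
        mat = rng.integers(0, 2, size=(6, 5)).astype(float)
        rp = rng.permutation(6)
        cp = rng.permutation(5)
        f0, z0 = ewens_watterson_f(mat), kelly_zns(mat)
        f1, z1 = ewens_watterson_f(mat[rp][:, cp]), kelly_zns(mat[rp][:, cp])
        assert f0 == pytest.approx(f1)
        if not (math.isnan(z0) and math.isnan(z1)):
            assert z0 == pytest.approx(z1)


def test_gene_neutrality_assembles_all_stats(worked_matrix):
    aln, f = worked_matrix
    res = gene_neutrality(f, outgroup_consensus(aln))
    assert res.S == 2
    assert res.D == pytest.approx(0.5916, abs=5e-4)
    assert res.F == pytest.approx(0.375)
    assert res.Zns == pytest.approx(1 / 3)
    assert not math.isnan(res.H)
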