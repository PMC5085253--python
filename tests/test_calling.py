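"""ML allele-fraction estimation, filters, power and false-positive rate."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st
from scipy import stats

from mthet import calling
from mthet.calling import (AlleleCounts, call_heteroplasmy, call_homoplasmy,
                           detection_power, estimate_maf,
                           llr_false_positive_rate, loglik10,
                           strand_balance_test, valid_sites)
from mthet.pileup import ReadObservation, SitePileup, phred_to_eps

from test_pileup import make_pileup


def grid_oracle(minor_eps, major_eps, step=1e-5):
    """Dense grid search over [0, 0.5]; the independent reference."""
    grid = np.arange(0.0, 0.5 + step / 2, step)
    minor_eps = np.asarray(minor_eps)
    major_eps = np.asarray(major_eps)
    ll = np.zeros_like(grid)
    if minor_eps.size:
        ll += np.log10((1 - grid[:, None]) * minor_eps
                       + grid[:, None] * (1 - minor_eps)).sum(axis=1)
    if major_eps.size:
        ll += np.log10((1 - grid[:, None]) * (1 - major_eps)
                       + grid[:, None] * major_eps).sum(axis=1)
    k = int(np.argmax(ll))
    return grid[k], max(0.0, ll[k] - ll[0])


class TestEstimateMaf:
    def test_no_minor_reads_gives_zero(self):
        f, llr = estimate_maf(np.empty(0), np.full(50, 0.01))
        assert f == 0.0 and llr == 0.0

    def test_noiseless_limit_is_binomial_mle(self):
        # eps -> 0: f-hat converges to n/(n+m)
        f, llr = estimate_maf(np.full(10, 1e-12), np.full(90, 1e-12))
        assert abs(f - 0.100) < 1e-4
        assert llr > 5

    def test_matches_grid_oracle_on_spec_example(self):
        minor = np.full(8, 0.01)
        major = np.full(133, 0.01)
        f, llr = estimate_maf(minor, major)
        f0, llr0 = grid_oracle(minor, major)
        assert abs(f - f0) < 1e-4
        assert abs(llr - llr0) < 1e-3

    def test_matches_grid_oracle_with_varying_eps(self, rng):
        for _ in range(25):
            n = int(rng.integers(0, 15))
            m = int(rng.integers(10, 80))
            minor = 10 ** (-rng.uniform(1, 4, n))
            major = 10 ** (-rng.uniform(1, 4, m))
            f, llr = estimate_maf(minor, major)
            f0, llr0 = grid_oracle(minor, major)
            assert abs(f - f0) < 1e-4
            assert abs(llr - llr0) < 1e-3

    def test_empty_input_rejected(self):
        with pytest.raises(ValueError):
            estimate_maf(np.empty(0), np.empty(0))

    def test_bad_eps_rejected(self):
        with pytest.raises(ValueError):
            estimate_maf(np.array([0.0]), np.array([0.01]))
        with pytest.raises(ValueError):
            estimate_maf(np.array([0.5]), np.array([1.0]))

    @given(n=st.integers(1, 30), m=st.integers(0, 200),
           q=st.integers(13, 40))
    @settings(max_examples=60, deadline=None, derandomize=True)
    def test_equal_eps_depends_only_on_counts(self, n, m, q):
        """With all eps equal, f-hat is a function of (n, m) alone."""
        eps = float(phred_to_eps(q))
        f1, llr1 = estimate_maf(np.full(n, eps), np.full(m, eps))
        f2, llr2 = calling._estimate_maf_counts(n, m, eps)
        assert f1 == f2 and llr1 == llr2
        assert 0.0 <= f1 <= 0.5 and llr1 >= 0.0

    def test_llr_nondecreasing_in_minor_count(self):
        eps = 0.01
        llrs = [estimate_maf(np.full(n, eps), np.full(100, eps))[1]
                for n in range(1, 15)]
        assert all(b >= a - 1e-9 for a, b in zip(llrs, llrs[1:]))


class TestStrandBalance:
    @staticmethod
    def fisher_oracle(a, b, c, d):
        """Two-sided Fisher by hypergeometric enumeration."""
        n1, n2 = a + b, c + d
        k = a + c
        total = n1 + n2
        pmf_obs = stats.hypergeom.pmf(a, total, n1, k)
        ks = np.arange(max(0, k - n2), min(k, n1) + 1)
        pmf = stats.hypergeom.pmf(ks, total, n1, k)
        return pmf[pmf <= pmf_obs * (1 + 1e-9)].sum()

    def counts(self, mf, mr, nf, nr):
        bases = "A" * (mf + mr) + "G" * (nf + nr)
        strands = (["fwd"] * mf + ["rev"] * mr + ["fwd"] * nf + ["rev"] * nr)
        return AlleleCounts.from_pileup(
            make_pileup(bases, strands, [30] * len(bases)))

    def test_perfectly_balanced_p_one(self):
        assert strand_balance_test(self.counts(50, 50, 5, 5)) == 1.0

    def test_one_sided_minor_matches_oracle(self):
        p = strand_balance_test(self.counts(70, 70, 10, 0))
        assert p == pytest.approx(self.fisher_oracle(70, 70, 10, 0), abs=1e-9)

    def test_zero_minor_degenerate(self):
        assert strand_balance_test(self.counts(30, 40, 0, 0)) == 1.0


class TestCallHeteroplasmy:
    def het_pileup(self, depth=141, minor=12, minor_fwd=None, q=20, ref="A",
                   minor_base="G"):
        if minor_fwd is None:
            minor_fwd = minor // 2
        major = depth - minor
        bases = minor_base * minor + ref * major
        strands = (["fwd"] * minor_fwd + ["rev"] * (minor - minor_fwd)
                   + ["fwd"] * (major // 2) + ["rev"] * (major - major // 2))
        return make_pileup(bases, strands, [q] * depth, ref=ref)

    def test_depth_exactly_40_rejected(self):
        call = call_heteroplasmy(self.het_pileup(depth=40, minor=8))
        assert not call.depth_ok and not call.candidate

    def test_spec_example_high_confidence(self):
        # depth 141, 12 minor reads 6/6 by strand, eps=0.01
        call = call_heteroplasmy(self.het_pileup())
        assert call.candidate and call.high_confidence
        assert call.maf_mle == pytest.approx(0.0766, abs=2e-3)
        assert call.llr > 5
        f0, llr0 = grid_oracle(np.full(12, 0.01), np.full(129, 0.01))
        assert call.maf_mle == pytest.approx(f0, abs=1e-4)
        assert call.llr == pytest.approx(llr0, abs=1e-3)

    def test_single_strand_minor_rejected(self):
        call = call_heteroplasmy(self.het_pileup(minor=20, minor_fwd=20))
        assert not call.both_strands and not call.candidate
        assert not call.high_confidence

    def test_no_minor_allele_returns_none(self):
        p = make_pileup("A" * 100, ["fwd", "rev"] * 50, [30] * 100)
        assert call_heteroplasmy(p) is None

    def test_strand_imbalance_rejected(self):
        call = call_heteroplasmy(self.het_pileup(minor=20, minor_fwd=19))
        assert call.strand_p < 0.01 and not call.candidate

    def test_maf_below_threshold_not_high_confidence(self):
        call = call_heteroplasmy(self.het_pileup(minor=5, q=30))
        assert call.candidate
        assert call.maf_mle < 0.05
        assert not call.high_confidence

    def test_invalid_site_blocks_high_confidence(self):
        call = call_heteroplasmy(self.het_pileup(), valid_site=False)
        assert call.candidate and not call.high_confidence

    def test_triallelic_flagged(self):
        p = make_pileup("G" * 10 + "T" * 3 + "A" * 128,
                        ["fwd", "rev"] * 70 + ["fwd"], [30] * 141)
        call = call_heteroplasmy(p)
        assert call.triallelic
        assert call.major == "A" and call.minor == "G"


class TestCallHomoplasmy:
    def hom_pileup(self, alt_reads, ref_reads, ref="A", alt="G"):
        bases = alt * alt_reads + ref * ref_reads
        n = alt_reads + ref_reads
        return make_pileup(bases, ["fwd", "rev"] * (n // 2) + ["fwd"] * (n % 2),
                           [30] * n, ref=ref)

    def test_nine_alt_reads_below_threshold(self):
        assert call_homoplasmy(self.hom_pileup(9, 0), heteroplasmic=False) is None

    def test_alt_homoplasmy(self):
        call = call_homoplasmy(self.hom_pileup(100, 0), heteroplasmic=False)
        assert call.allele == "G" and call.supporting_reads == 100

    def test_heteroplasmic_site_excluded(self):
        assert call_homoplasmy(self.hom_pileup(100, 20),
                               heteroplasmic=True) is None

    def test_reference_homoplasmy_reported(self):
        call = call_homoplasmy(self.hom_pileup(0, 8), heteroplasmic=False)
        assert call.allele == "A"


class TestValidSites:
    def test_boundaries(self):
        import pandas as pd
        median = pd.Series({1: 70.0, 2: 71.0, 3: 0.0})
        mask = valid_sites(median)
        assert not mask[1] and mask[2] and not mask[3]

    def test_all_zero_panel(self):
        import pandas as pd
        assert not valid_sites(pd.Series({1: 0.0, 2: 0.0})).any()


class TestDetectionPower:
    @staticmethod
    def exact_binomial_power(depth, maf, p0, alpha=0.05):
        ks = np.arange(depth + 1)
        tail0 = stats.binom.sf(ks - 1, depth, p0)
        k_crit = int(ks[tail0 <= alpha][0])
        return float(stats.binom.sf(k_crit - 1, depth, maf))

    def test_exceeds_90pct_at_valid_site_depth(self):
        assert detection_power(71, 0.05, 0.0033, 0.05) > 0.90

    def test_null_equals_alpha(self):
        assert detection_power(100, 0.0033, 0.0033, 0.05) == \
            pytest.approx(0.05, abs=1e-9)

    def test_agrees_with_exact_binomial(self):
        approx = detection_power(141, 0.05, 0.0033, 0.05)
        exact = self.exact_binomial_power(141, 0.05, 0.0033, 0.05)
        assert abs(approx - exact) < 0.05

    def test_monotone_in_depth_and_maf(self):
        powers_d = [detection_power(d, 0.05, 0.0033) for d in (41, 71, 141, 300)]
        assert all(b >= a for a, b in zip(powers_d, powers_d[1:]))
        powers_f = [detection_power(100, f, 0.0033)
                    for f in (0.01, 0.02, 0.05, 0.1)]
        assert all(b >= a for a, b in zip(powers_f, powers_f[1:]))

    def test_maf_below_null_power_below_alpha(self):
        assert detection_power(100, 0.001, 0.0033, 0.05) <= 0.05


class TestFalsePositiveRate:
    def test_zero_error_zero_fpr(self):
        assert llr_false_positive_rate(141, 0.0) == 0.0

    def test_below_1e5_at_study_depth(self):
        assert llr_false_positive_rate(141, 0.01, 0.05, 5) < 1e-5

    def test_worst_case_aggregation_larger_but_still_small(self):
        per_sub = llr_false_positive_rate(141, 0.01)
        worst = llr_false_positive_rate(141, 0.01, per_substitution=False)
        assert worst >= per_sub
        assert worst < 1e-5

    def test_monotone_nonincreasing_in_min_llr(self):
        fprs = [llr_false_positive_rate(141, 0.02, min_maf=0.02, min_llr=t)
                for t in (0, 1, 2, 5)]
        assert all(b <= a for a, b in zip(fprs, fprs[1:]))

    def test_shallow_depth_cannot_call(self):
        assert llr_false_positive_rate(40, 0.01) == 0.0
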