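"""Family consensus, mutation derivation, burden, odds ratios, stratification."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

from mthet import families
from mthet.calling import HeteroplasmyCall, HomoplasmyCall
from mthet.families import (burden_compare, carrier_table, derive_mutations,
                            family_reference, odds_ratio, private_mutations,
                            sensitivity_ratio, site_summary, stratify)
from test_pileup import make_pileup


def summary_from(rows):
    """rows: position -> (depth, fA, fC, fG, fT)."""
    df = pd.DataFrame(
        [(pos, d, a, c, g, t) for pos, (d, a, c, g, t) in rows.items()],
        columns=["position", "depth", "A", "C", "G", "T"])
    return df.set_index("position")


def het_call(pos, major, minor, maf, high_confidence=True):
    return HeteroplasmyCall(
        sample="s", position=pos, ref=major, major=major, minor=minor,
        maf_raw=maf, maf_mle=maf, llr=10.0, strand_p=1.0, depth=141,
        minor_fwd=5, minor_rev=5, depth_ok=True, both_strands=True,
        strand_ok=True, valid_site=True, high_confidence=high_confidence)


class TestSiteSummary:
    def test_fractions(self):
        p = make_pileup("GGAA", ["fwd", "rev"] * 2, [30] * 4, ref="A",
                        position=3)
        s = site_summary([p])
        assert s.at[3, "depth"] == 4
        assert s.at[3, "G"] == 0.5 and s.at[3, "A"] == 0.5


class TestFamilyReference:
    def test_all_reference(self):
        s = summary_from({1: (100, 1.0, 0, 0, 0)})
        cons = family_reference({"mother": s, "proband": s, "sibling": s})
        assert cons.at[1, "consensus"] == "A"
        assert cons.at[1, "family_valid"]

    def test_inherited_alt_homoplasmy_is_consensus(self):
        s = summary_from({1: (100, 0, 0, 1.0, 0)})
        cons = family_reference({"mother": s, "proband": s, "sibling": s})
        assert cons.at[1, "consensus"] == "G"

    def test_max_mean_fraction_wins(self):
        mother = summary_from({1: (100, 0.6, 0, 0.4, 0)})
        child = summary_from({1: (100, 1.0, 0, 0, 0)})
        cons = family_reference({"mother": mother, "proband": child,
                                 "sibling": child})
        assert cons.at[1, "consensus"] == "A"

    def test_tie_broken_toward_rcrs_reference(self):
        s = summary_from({1: (100, 0.5, 0, 0.5, 0)})
        trio = {"mother": s, "proband": s, "sibling": s}
        assert family_reference(trio, ref={1: "G"}).at[1, "consensus"] == "G"
        assert family_reference(trio, ref={1: "T"}).at[1, "consensus"] == "A"

    def test_family_valid_requires_all_above_40(self):
        deep = summary_from({1: (100, 1.0, 0, 0, 0)})
        shallow = summary_from({1: (39, 1.0, 0, 0, 0)})
        cons = family_reference({"mother": deep, "proband": deep,
                                 "sibling": shallow})
        assert not cons.at[1, "family_valid"]


class TestDeriveMutations:
    def trio(self, child_maf=0.10, depth=100):
        base = {1: (depth, 1.0, 0, 0, 0)}
        child = {1: (depth, 1 - child_maf, 0, child_maf, 0)}
        return ({"mother": summary_from(base), "proband": summary_from(child),
                 "sibling": summary_from(base)},
                {"proband": {1: het_call(1, "A", "G", child_maf)}},
                {})

    def test_child_heteroplasmy_recorded(self):
        summaries, hets, homs = self.trio()
        cons = family_reference(summaries)
        rec = derive_mutations("f", summaries, hets, homs, cons)
        assert len(rec) == 1
        row = rec.iloc[0]
        assert row.role == "proband" and row.allele == "G"
        assert row.daf == pytest.approx(0.10)
        assert row.heteroplasmic

    def test_min_daf_threshold_sweepable(self):
        summaries, hets, homs = self.trio(child_maf=0.04)
        cons = family_reference(summaries)
        assert derive_mutations("f", summaries, hets, homs, cons,
                                min_daf=0.05).empty
        assert len(derive_mutations("f", summaries, hets, homs, cons,
                                    min_daf=0.02)) == 1

    def test_low_depth_member_invalidates_site(self):
        summaries, hets, homs = self.trio()
        summaries["sibling"] = summary_from({1: (39, 1.0, 0, 0, 0)})
        cons = family_reference(summaries)
        rec = derive_mutations("f", summaries, hets, homs, cons)
        assert rec.empty

    def test_homoplasmic_mutation_daf_one(self):
        base = {1: (100, 1.0, 0, 0, 0)}
        alt = {1: (100, 0, 0, 1.0, 0)}
        summaries = {"mother": summary_from(base),
                     "proband": summary_from(alt),
                     "sibling": summary_from(base)}
        cons = family_reference(summaries)
        homs = {"proband": {1: HomoplasmyCall("s", 1, "G", 100)}}
        rec = derive_mutations("f", summaries, {}, homs, cons)
        assert len(rec) == 1
        assert rec.iloc[0].daf == pytest.approx(1.0)
        assert rec.iloc[0].homoplasmic

    @given(daf=st.floats(0.02, 0.4))
    @settings(max_examples=25, deadline=None, derandomize=True)
    def test_monotone_in_threshold(self, daf):
        summaries, hets, homs = self.trio(child_maf=daf)
        cons = family_reference(summaries)
        sizes = [len(derive_mutations("f", summaries, hets, homs, cons,
                                      min_daf=t))
                 for t in (0.02, 0.05, 0.08)]
        assert sizes == sorted(sizes, reverse=True)


class TestPrivateMutations:
    def records(self, sib_frac):
        rec = pd.DataFrame([("f", "proband", 1, "G", 0.10, True, False)],
                           columns=["family", "role", "position", "allele",
                                    "daf", "heteroplasmic", "homoplasmic"])
        summaries = {"f": {
            "proband": summary_from({1: (100, 0.9, 0, 0.1, 0)}),
            "sibling": summary_from({1: (100, 1 - sib_frac, 0, sib_frac, 0)}),
            "mother": summary_from({1: (100, 1.0, 0, 0, 0)})}}
        return rec, summaries

    @pytest.mark.parametrize("sib_frac,expected", [
        (0.0, True), (0.019, True), (0.02, False), (0.10, False)])
    def test_two_percent_boundary(self, sib_frac, expected):
        rec, summaries = self.records(sib_frac)
        out = private_mutations(rec, summaries)
        assert bool(out.iloc[0].private) == expected

    def test_uncovered_other_child_is_private(self):
        rec, summaries = self.records(0.0)
        summaries["f"]["sibling"] = summary_from({2: (100, 1.0, 0, 0, 0)})
        out = private_mutations(rec, summaries)
        assert bool(out.iloc[0].private)


class TestBurdenCompare:
    def test_identical_counts(self):
        res = burden_compare([1, 2, 0, 1], [1, 2, 0, 1])
        assert res.p >= 0.5

    def test_constant_shift_degenerate(self):
        res = burden_compare([2] * 10, [1] * 10)
        assert res.degenerate and res.p == 0.0

    def test_enriched_probands_significant(self, rng):
        sib = rng.poisson(0.25, 500)
        pro = sib + rng.binomial(1, 0.3, 500)
        res = burden_compare(pro, sib)
        assert res.p < 0.001
        assert res.mean_proband > res.mean_sibling

    def test_mismatched_lengths_rejected(self):
        with pytest.raises(ValueError):
            burden_compare([1, 2], [1])


class TestOddsRatio:
    def test_symmetric_table_or_one(self):
        res = odds_ratio(10, 90, 10, 90)
        assert res.odds_ratio == pytest.approx(1.0)

    def test_reciprocal_under_group_swap(self):
        res = odds_ratio(51, 852, 28, 875)
        swapped = odds_ratio(28, 875, 51, 852)
        assert res.odds_ratio * swapped.odds_ratio == pytest.approx(1.0)

    def test_zero_cell_haldane_flagged(self):
        res = odds_ratio(5, 95, 0, 100)
        assert res.haldane and np.isfinite(res.odds_ratio)

    def test_negative_counts_rejected(self):
        with pytest.raises(ValueError):
            odds_ratio(-1, 10, 5, 10)

    def test_one_tailed_direction(self):
        enriched = odds_ratio(30, 70, 10, 90)
        depleted = odds_ratio(10, 90, 30, 70)
        assert enriched.p_one_tailed < 0.05 < depleted.p_one_tailed

    @given(a=st.integers(1, 50), b=st.integers(1, 50),
           c=st.integers(1, 50), d=st.integers(1, 50))
    @settings(max_examples=40, deadline=None, derandomize=True)
    def test_or_formula_and_ci_order(self, a, b, c, d):
        res = odds_ratio(a, b, c, d)
        assert res.odds_ratio == pytest.approx(a * d / (b * c))
        assert res.ci_low <= res.odds_ratio <= res.ci_high


class TestCarrierTable:
    def test_carrier_counts_individuals_not_mutations(self):
        rec = pd.DataFrame(
            [("f1", "proband", 1, "G", 0.1, True, False, True, True),
             ("f1", "proband", 2, "G", 0.1, True, False, True, True),
             ("f2", "sibling", 3, "G", 0.1, True, False, True, True)],
            columns=["family", "role", "position", "allele", "daf",
                     "heteroplasmic", "homoplasmic", "private", "cat"])
        res = carrier_table(rec, ["f1", "f2"], "cat")
        assert (res.a, res.c) == (1, 1)  # f1 proband counted once


class TestStratify:
    def phenotypes(self):
        return pd.DataFrame({
            "family": ["f1", "f2", "f3", "f4"],
            "proband_iq": [85, 86, np.nan, 70],
            "proband_srs": [76, 75, 80, np.nan],
            "sibling_srs": [49, 49, 30, 40],
            "lgd": [True, False, False, True],
        })

    def test_iq_85_is_diminished(self):
        strata = stratify(self.phenotypes())
        assert "f1" in strata["diminished_iq"]
        assert "f2" in strata["normal_iq"]

    def test_missing_phenotype_excluded(self):
        strata = stratify(self.phenotypes())
        assert "f3" not in strata["normal_iq"] + strata["diminished_iq"]
        assert "f4" not in strata["discordant_srs"] + strata["concordant_srs"]

    def test_srs_discordance_boundaries(self):
        strata = stratify(self.phenotypes())
        assert "f1" in strata["discordant_srs"]   # 76 > 75 and 49 < 50
        assert "f2" in strata["concordant_srs"]   # 75 is not > 75

    def test_no_lgd_subset(self):
        strata = stratify(self.phenotypes())
        assert set(strata["no_lgd"]) == {"f2", "f3"}


class TestSensitivityRatio:
    def records(self, ratio=1, n_fam=30):
        rows = []
        for i in range(n_fam):
            fam = f"f{i}"
            for _ in range(ratio):
                rows.append((fam, "proband", 1, "G", 0.10, True, False))
            rows.append((fam, "sibling", 2, "G", 0.10, True, False))
        return pd.DataFrame(rows, columns=["family", "role", "position",
                                           "allele", "daf", "heteroplasmic",
                                           "homoplasmic"])

    def test_identical_records_ratio_one(self):
        rec = self.records(ratio=1)
        fams = rec.family.unique().tolist()
        out = sensitivity_ratio(rec, fams, n_boot=500, seed=1)
        assert np.allclose(out.loc[out.ratio.notna(), "ratio"], 1.0)
        assert ((out.ci_low <= 1.0) & (1.0 <= out.ci_high)).all()

    def test_twofold_enrichment_in_band(self):
        rec = self.records(ratio=2, n_fam=100)
        fams = rec.family.unique().tolist()
        out = sensitivity_ratio(rec, fams, n_boot=500, seed=2)
        assert np.allclose(out["ratio"].dropna(), 2.0)
        assert ((out.ci_low <= 2.0) & (2.0 <= out.ci_high)).all()

    def test_no_bootstrap_point_estimates_only(self):
        rec = self.records()
        out = sensitivity_ratio(rec, rec.family.unique().tolist(), n_boot=0)
        assert out["ci_low"].isna().all()
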