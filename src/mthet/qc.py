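"""Sample-level quality control: coverage exclusion and contamination detection.

Samples with mean mtDNA depth ≤40X are excluded outright.  Cross-sample DNA
contamination inflates the apparent heteroplasmy load of the contaminated
sample with the *homoplasmic* alleles of the contaminating sample, so it is
flagged when either

  (1) the sample carries >5 heteroplasmies at population-polymorphic mtDNA
      sites, or
  (2) >50% of its heteroplasmies are detectable as homoplasmies in another
      (donor) sample, and those shared sites also account for >50% of the
      donor's homoplasmic sites that are distinct from the homoplasmies of
      the sample under investigation.

Contamination checks run on high-confidence heteroplasmies with MAF ≥2%.
Polymorphic sites are population-relative: sites with ≥2 distinct homoplasmic
alleles among the retained samples.  A family is retained only if the mother,
proband and sibling all pass.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import pandas as pd

VERDICT_PASS = "pass"
VERDICT_LOW_COVERAGE = "low_coverage"
VERDICT_CONTAMINATED = "contaminated"

MAX_MEAN_DEPTH_EXCLUDED = 40.0  # "average mtDNA coverage ≤40X" is excluded
MAX_POLY_HETS = 5               # rule (1): strictly more than 5
SHARING_FRACTION = 0.5          # rule (2): strictly more than 50%


@dataclass
class SampleQCReport:
    sample: str
    mean_depth: float
    n_polymorphic_hets: int = 0
    verdict: str = VERDICT_PASS
    donor: str | None = None     # implicated sample for rule (2)
    evidence: dict = field(default_factory=dict)


def coverage_filter(mean_depths: pd.Series) -> dict[str, SampleQCReport]:
    """Verdicts from per-sample mean mtDNA depth (≤40X excluded, inclusive)."""
    out = {}
    for sample, depth in mean_depths.items():
        verdict = (VERDICT_LOW_COVERAGE if (pd.isna(depth) or depth <= MAX_MEAN_DEPTH_EXCLUDED)
                   else VERDICT_PASS)
        out[sample] = SampleQCReport(sample=sample, mean_depth=float(depth or 0),
                                     verdict=verdict)
    return out


def polymorphic_sites(homoplasmies: pd.DataFrame) -> set[int]:
    """Sites with ≥2 distinct homoplasmic alleles across retained samples.

    ``homoplasmies`` columns: sample, position, allele.
    """
    n_alleles = homoplasmies.groupby("position")["allele"].nunique()
    return set(n_alleles[n_alleles >= 2].index)


def contamination_check(sample: str,
                        heteroplasmies: pd.DataFrame,
                        homoplasmies: pd.DataFrame,
                        poly_sites: set[int] | None = None) -> SampleQCReport:
    """Apply contamination rules (1) and (2) to one sample.

    ``heteroplasmies``: high-confidence MAF≥2% calls with columns
    (sample, position, minor); ``homoplasmies``: (sample, position, allele)
    for all samples.  Rule (2) is asymmetric: the donor contributes
    homoplasmic alleles to the recipient's heteroplasmies, not vice versa.
    """
    if poly_sites is None:
        poly_sites = polymorphic_sites(homoplasmies)
    my_hets = heteroplasmies[heteroplasmies["sample"] == sample]
    my_homs = homoplasmies[homoplasmies["sample"] == sample]
    my_hom_alleles = set(zip(my_homs["position"], my_homs["allele"]))
    mean_depth = float("nan")

    n_poly = int(my_hets["position"].isin(poly_sites).sum())
    report = SampleQCReport(sample=sample, mean_depth=mean_depth,
                            n_polymorphic_hets=n_poly)
    if n_poly > MAX_POLY_HETS:
        report.verdict = VERDICT_CONTAMINATED
        report.evidence["rule"] = 1
        return report

    if len(my_hets) == 0:
        return report
    het_pairs = set(zip(my_hets["position"], my_hets["minor"]))
    for donor, donor_homs in homoplasmies.groupby("sample"):
        if donor == sample:
            continue
        donor_pairs = set(zip(donor_homs["position"], donor_homs["allele"]))
        shared = het_pairs & donor_pairs
        frac_hets = len(shared) / len(het_pairs)
        donor_distinct = donor_pairs - my_hom_alleles
        if not donor_distinct:
            continue
        frac_donor = len(shared & donor_distinct) / len(donor_distinct)
        if frac_hets > SHARING_FRACTION and frac_donor > SHARING_FRACTION:
            report.verdict = VERDICT_CONTAMINATED
            report.donor = str(donor)
            report.evidence.update(rule=2, shared=len(shared),
                                   frac_hets=frac_hets, frac_donor=frac_donor)
            return report
    return report


def family_verdicts(reports: dict[str, SampleQCReport],
                    families: dict[str, list[str]]) -> dict[str, bool]:
    """A family passes iff mother, proband and sibling all pass QC."""
    return {
        fam: all(reports.get(s) is not None
                 and reports[s].verdict == VERDICT_PASS for s in members)
        for fam, members in families.items()
    }


def reports_to_dataframe(reports: dict[str, SampleQCReport]) -> pd.DataFrame:
    rows = [(r.sample, r.mean_depth, r.n_polymorphic_hets, r.verdict, r.donor)
            for r in reports.values()]
    return pd.DataFrame(rows, columns=["sample", "mean_depth",
                                       "n_polymorphic_hets", "verdict", "donor"])
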