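"""Family-consensus mutations, burden comparisons, odds ratios, stratification.

Within each mother–proband–sibling trio the *family reference* allele at a
site is the allele with the highest (mean) fraction across the three members;
a *mutation* is a high-confidence heteroplasmic or homoplasmic derived allele
(relative to that consensus) with derived-allele fraction (DAF) above the
reporting threshold (default 5%), restricted to sites where all three
members have >40X depth.  A child's mutation is *private* when the derived
allele is undetectable or below 2% in the other child.

Proband/sibling burden is compared per family with a one-tailed paired t-test
(alternative: probands carry more), and carrier counts with Fisher's exact
test as an odds ratio (carrier = child with ≥1 private mutation of the
category, matching a per-individual carrier definition rather than mutation
counts).  The OR confidence interval is the Woolf log-based interval.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .calling import HeteroplasmyCall, HomoplasmyCall
from .pileup import BASES, SitePileup

CHILD_ROLES = ("proband", "sibling")
PRIVATE_MAX_OTHER_DAF = 0.02   # strict: other child's fraction < 2%
FAMILY_VALID_MIN_DEPTH = 41    # all three members > 40X


def site_summary(pileups: Iterable[SitePileup]) -> pd.DataFrame:
    """Per-site depth and per-allele raw fractions for one sample.

    Columns: position, depth, A, C, G, T (fractions of quality-filtered
    reads).  Fraction columns are 0 at uncovered sites.
    """
    rows = []
    for p in pileups:
        counts = p.allele_strand_counts().sum(axis=1)
        depth = counts.sum()
        fracs = counts / depth if depth else np.zeros(4)
        rows.append((p.position, int(depth), *fracs))
    return (pd.DataFrame(rows, columns=["position", "depth", *BASES])
            .set_index("position").sort_index())


def family_reference(summaries: Mapping[str, pd.DataFrame],
                     ref: Mapping[int, str] | None = None) -> pd.DataFrame:
    """Family consensus per site from the trio's allele-fraction summaries.

    The consensus allele maximises the mean fraction across the members
    covering the site; ties break toward the rCRS reference allele (``ref``,
    position → base) when supplied, then alphabetically.  ``family_valid``
    requires all three members to have >40X depth at the site.
    """
    if set(summaries) != set(("mother",) + CHILD_ROLES):
        raise ValueError("summaries must be keyed by mother/proband/sibling")
    positions = sorted(set().union(*(s.index for s in summaries.values())))
    rows = []
    for pos in positions:
        fracs = np.zeros(4)
        n_cov = 0
        depths = []
        for s in summaries.values():
            if pos in s.index and s.at[pos, "depth"] > 0:
                fracs += s.loc[pos, list(BASES)].to_numpy(dtype=float)
                n_cov += 1
                depths.append(int(s.at[pos, "depth"]))
            else:
                depths.append(0)
        if n_cov == 0:
            continue
        fracs /= n_cov
        best = fracs.max()
        tied = [b for b, f in zip(BASES, fracs) if f == best]
        ref_base = ref.get(pos) if ref else None
        consensus = ref_base if ref_base in tied else tied[0]
        family_valid = all(d >= FAMILY_VALID_MIN_DEPTH for d in depths)
        rows.append((pos, consensus, family_valid))
    return (pd.DataFrame(rows, columns=["position", "consensus", "family_valid"])
            .set_index("position"))


def derive_mutations(family: str,
                     summaries: Mapping[str, pd.DataFrame],
                     het_calls: Mapping[str, Mapping[int, HeteroplasmyCall]],
                     hom_calls: Mapping[str, Mapping[int, HomoplasmyCall]],
                     consensus: pd.DataFrame,
                     min_daf: float = 0.05) -> pd.DataFrame:
    """Mutation records (derived alleles vs family consensus) for one family.

    One row per (individual, family-valid site, derived allele) where the
    individual carries the allele as a high-confidence heteroplasmy (DAF from
    the ML estimate) or as a homoplasmy differing from the consensus
    (DAF = observed fraction, ~1).  ``min_daf`` is sweepable (2–8%) for
    threshold-sensitivity analyses; raising it never adds records.
    """
    rows = []
    for role, summary in summaries.items():
        hets = het_calls.get(role, {})
        homs = hom_calls.get(role, {})
        for pos in summary.index:
            if pos not in consensus.index or not consensus.at[pos, "family_valid"]:
                continue
            cons = consensus.at[pos, "consensus"]
            call = hets.get(pos)
            if call is not None and call.high_confidence:
                for allele, daf in ((call.minor, call.maf_mle),
                                    (call.major, 1 - call.maf_mle)):
                    if allele != cons and daf >= min_daf:
                        rows.append((family, role, pos, allele, float(daf),
                                     True, False))
            else:
                hom = homs.get(pos)
                if hom is not None and hom.allele != cons:
                    daf = float(summary.at[pos, hom.allele])
                    if daf >= min_daf:
                        rows.append((family, role, pos, hom.allele, daf,
                                     False, True))
    return pd.DataFrame(rows, columns=["family", "role", "position", "allele",
                                       "daf", "heteroplasmic", "homoplasmic"])


def private_mutations(records: pd.DataFrame,
                      summaries_by_family: Mapping[str, Mapping[str, pd.DataFrame]]
                      ) -> pd.DataFrame:
    """Flag child mutations private to that child within the family.

    Private: the derived allele is undetectable (site uncovered / fraction 0)
    or has raw fraction strictly <2% in the other child.  Mother records get
    private = False.
    """
    other = {"proband": "sibling", "sibling": "proband"}
    flags = []
    for row in records.itertuples():
        if row.role not in other:
            flags.append(False)
            continue
        sib = summaries_by_family[row.family][other[row.role]]
        if row.position not in sib.index or sib.at[row.position, "depth"] == 0:
            flags.append(True)
            continue
        frac = float(sib.at[row.position, row.allele])
        flags.append(frac < PRIVATE_MAX_OTHER_DAF)
    out = records.copy()
    out["private"] = flags
    return out


@dataclass
class BurdenResult:
    mean_proband: float
    mean_sibling: float
    t: float
    p: float
    n_families: int
    degenerate: bool = False


def burden_compare(proband_counts: Sequence[float],
                   sibling_counts: Sequence[float]) -> BurdenResult:
    """One-tailed paired t-test of per-family mutation counts (proband > sibling).

    Families with zero counts in both children are retained — the design is
    paired.  A zero-variance nonzero difference is a degenerate t (p → 0 or
    1 by sign, flagged).
    """
    a = np.asarray(proband_counts, dtype=float)
    b = np.asarray(sibling_counts, dtype=float)
    if a.shape != b.shape or a.size == 0:
        raise ValueError("need equal-length, non-empty count vectors")
    d = a - b
    mean_d = d.mean()
    if np.allclose(d.std(ddof=1) if d.size > 1 else 0.0, 0.0):
        if mean_d == 0:
            return BurdenResult(a.mean(), b.mean(), 0.0, 0.5, a.size, degenerate=True)
        p = 0.0 if mean_d > 0 else 1.0
        t = np.inf if mean_d > 0 else -np.inf
        return BurdenResult(a.mean(), b.mean(), t, p, a.size, degenerate=True)
    t, p = stats.ttest_rel(a, b, alternative="greater")
    return BurdenResult(a.mean(), b.mean(), float(t), float(p), a.size)


@dataclass
class ORResult:
    a: int  # carriers among probands
    b: int  # non-carriers among probands
    c: int  # carriers among siblings
    d: int  # non-carriers among siblings
    odds_ratio: float
    ci_low: float
    ci_high: float
    p_one_tailed: float
    haldane: bool = False


def odds_ratio(a: int, b: int, c: int, d: int, ci: float = 0.95) -> ORResult:
    """Odds ratio ad/bc with Woolf CI and one-tailed Fisher exact p.

    The one-tailed alternative is proband enrichment (fixed a priori).  Zero
    cells get the Haldane–Anscombe 0.5 correction for the OR/CI (flagged);
    the Fisher p always uses the raw counts.
    """
    if min(a, b, c, d) < 0:
        raise ValueError("counts must be nonnegative")
    if a + b == 0 or c + d == 0:
        raise ValueError("both margins must be positive")
    p = float(stats.fisher_exact([[a, b], [c, d]], alternative="greater")[1])
    haldane = 0 in (a, b, c, d)
    aa, bb, cc, dd = ((x + 0.5 for x in (a, b, c, d)) if haldane
                      else (a, b, c, d))
    orr = (aa * dd) / (bb * cc)
    se = np.sqrt(1 / aa + 1 / bb + 1 / cc + 1 / dd)
    z = stats.norm.ppf(0.5 + ci / 2)
    return ORResult(a, b, c, d, float(orr),
                    float(orr * np.exp(-z * se)), float(orr * np.exp(z * se)),
                    p, haldane)


def carrier_table(records: pd.DataFrame, families: Sequence[str],
                  category: str | None = None) -> ORResult:
    """Carrier-based 2×2 OR: children with ≥1 private mutation of a category.

    ``records`` must carry a ``private`` column; ``category`` names a boolean
    column to further restrict (None = all private mutations).
    """
    rec = records[records["private"]]
    if category is not None:
        rec = rec[rec[category]]
    carriers = rec.groupby(["family", "role"]).size()
    n = len(families)
    a = sum(carriers.get((f, "proband"), 0) > 0 for f in families)
    c = sum(carriers.get((f, "sibling"), 0) > 0 for f in families)
    return odds_ratio(a, n - a, c, n - c)


def stratify(phenotypes: pd.DataFrame) -> dict[str, list[str]]:
    """Partition families by phenotype criteria (missing values excluded).

    Criteria: full-scale proband IQ >85 (normal) vs ≤85 (diminished);
    SRS-discordant = proband SRS >75 and sibling SRS <50, otherwise
    concordant; no_lgd = families without a nuclear de novo LGD variant.
    """
    df = phenotypes
    out: dict[str, list[str]] = {"all": df["family"].tolist()}
    iq = df[df["proband_iq"].notna()]
    out["normal_iq"] = iq.loc[iq["proband_iq"] > 85, "family"].tolist()
    out["diminished_iq"] = iq.loc[iq["proband_iq"] <= 85, "family"].tolist()
    srs = df[df["proband_srs"].notna() & df["sibling_srs"].notna()]
    disc = (srs["proband_srs"] > 75) & (srs["sibling_srs"] < 50)
    out["discordant_srs"] = srs.loc[disc, "family"].tolist()
    out["concordant_srs"] = srs.loc[~disc, "family"].tolist()
    if "lgd" in df.columns:
        out["no_lgd"] = df.loc[df["lgd"].notna() & ~df["lgd"].astype(bool),
                               "family"].tolist()
    return out


def sensitivity_ratio(records: pd.DataFrame, families: Sequence[str],
                      min_daf_grid: Sequence[float] = (0.02, 0.03, 0.04, 0.05,
                                                       0.06, 0.07, 0.08),
                      category: str | None = None,
                      n_boot: int = 10_000, ci: float = 0.90,
                      seed: int | None = 0) -> pd.DataFrame:
    """Proband/sibling mutation-count ratio across DAF thresholds with
    family-bootstrap confidence bands.

    The resampling unit is the family; ``n_boot = 0`` returns point estimates
    only (CI columns NaN).  Undefined ratios (no sibling mutations) are NaN.
    """
    rng = np.random.default_rng(seed)
    rec = records if category is None else records[records[category]]
    fam_list = list(families)
    fam_index = {f: i for i, f in enumerate(fam_list)}
    rows = []
    for thr in min_daf_grid:
        sub = rec[rec["daf"] >= thr]
        counts = np.zeros((len(fam_list), 2))
        for (fam, role), k in sub.groupby(["family", "role"]).size().items():
            if fam in fam_index and role in CHILD_ROLES:
                counts[fam_index[fam], CHILD_ROLES.index(role)] = k
        tot_p, tot_s = counts.sum(axis=0)
        ratio = tot_p / tot_s if tot_s > 0 else np.nan
        lo = hi = np.nan
        if n_boot > 0 and len(fam_list) > 0:
            idx = rng.integers(0, len(fam_list), size=(n_boot, len(fam_list)))
            boot_p = counts[:, 0][idx].sum(axis=1)
            boot_s = counts[:, 1][idx].sum(axis=1)
            with np.errstate(divide="ignore", invalid="ignore"):
                boot = boot_p / boot_s
            boot = boot[np.isfinite(boot)]
            if boot.size:
                lo, hi = np.quantile(boot, [(1 - ci) / 2, (1 + ci) / 2])
        rows.append((thr, ratio, lo, hi, int(tot_p), int(tot_s)))
    return pd.DataFrame(rows, columns=["min_daf", "ratio", "ci_low", "ci_high",
                                       "n_proband", "n_sibling"])
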