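"""Variant annotation joins and selection/mutation-spectrum statistics.

Pathogenicity resources are external TSV inputs keyed by (position, alt):
CADD-style scaled (Phred) scores, PolyPhen-2 and Mutation Assessor class
calls, MutPred scores, and a curated disease-association list (ambiguous
entries pre-filtered by the input preparer).  A variant is "predicted
pathogenic, combined" when at least 2 of the 5 categories fire:
CADD>15, PolyPhen-2 possibly/probably damaging, Mutation Assessor
medium/high, MutPred>0.6, disease-associated.  CADD>20 is the stringent
subset of CADD>15.

Selection statistic: hN is the number of observed nonsynonymous
substitutions divided by the number of possible nonsynonymous substitutions
on the genome; hS likewise for synonymous.  hN/hS significantly below one
indicates purifying selection.  Each substitution (position, alt) is counted
at most once; RNA-gene variants carry no syn/nonsyn class and are excluded.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .reference import (EFFECT_NONSYNONYMOUS, EFFECT_SYNONYMOUS,
                        GeneFeature, MitoGenome, classify_substitution,
                        is_transition)

logger = logging.getLogger(__name__)

CADD_PATHOGENIC = 15.0   # recommended scaled-CADD cutoff (strictly >)
CADD_STRINGENT = 20.0
MUTPRED_CUTOFF = 0.6
POLYPHEN_DAMAGING = {"possibly_damaging", "probably_damaging"}
ASSESSOR_DAMAGING = {"medium", "high"}


@dataclass
class AnnotatedVariant:
    """A substitution with effect class, polymorphism and pathogenicity flags."""

    position: int
    ref: str
    alt: str
    region: str
    effect: str
    polymorphic: bool = False
    cadd_phred: float | None = None
    cadd15: bool = False
    cadd20: bool = False
    polyphen_damaging: bool = False
    assessor_damaging: bool = False
    mutpred_damaging: bool = False
    disease_associated: bool = False
    combined_prediction: bool = False

    @property
    def is_transition(self) -> bool:
        return is_transition(self.ref, self.alt)

    def recompute_combined(self) -> None:
        votes = sum([self.cadd15, self.polyphen_damaging, self.assessor_damaging,
                     self.mutpred_damaging, self.disease_associated])
        self.combined_prediction = votes >= 2


def annotate(variants: Iterable[tuple[int, str]],
             genome: MitoGenome, features: Sequence[GeneFeature],
             scores: pd.DataFrame | None = None,
             disease: pd.DataFrame | None = None,
             polymorphic: set[int] | None = None) -> list[AnnotatedVariant]:
    """Annotate (position, alt) substitutions with effect and pathogenicity.

    ``scores`` columns (all optional beyond pos/alt): pos, alt, cadd_phred,
    polyphen_class, assessor_class, mutpred_score.  ``disease`` columns:
    pos, alt[, phenotype].  Variants absent from a table simply get False
    flags; the count of missing joins is logged.
    """
    score_idx = {}
    if scores is not None:
        score_idx = {(int(r.pos), r.alt): r for r in scores.itertuples()}
    disease_idx = set()
    if disease is not None:
        disease_idx = set(zip(disease["pos"].astype(int), disease["alt"]))
    polymorphic = polymorphic or set()

    out = []
    missing = 0
    for position, alt in variants:
        eff = classify_substitution(genome, features, position, alt)
        av = AnnotatedVariant(position=eff.position, ref=eff.ref, alt=alt,
                              region=eff.region, effect=eff.effect,
                              polymorphic=position in polymorphic)
        row = score_idx.get((position, alt))
        if row is not None:
            cadd = getattr(row, "cadd_phred", None)
            if cadd is not None and not pd.isna(cadd):
                av.cadd_phred = float(cadd)
                av.cadd15 = av.cadd_phred > CADD_PATHOGENIC
                av.cadd20 = av.cadd_phred > CADD_STRINGENT
            pp = getattr(row, "polyphen_class", None)
            av.polyphen_damaging = (isinstance(pp, str)
                                    and pp in POLYPHEN_DAMAGING)
            ma = getattr(row, "assessor_class", None)
            av.assessor_damaging = (isinstance(ma, str)
                                    and ma in ASSESSOR_DAMAGING)
            mp = getattr(row, "mutpred_score", None)
            av.mutpred_damaging = (mp is not None and not pd.isna(mp)
                                   and float(mp) > MUTPRED_CUTOFF)
        elif scores is not None:
            missing += 1
        av.disease_associated = (position, alt) in disease_idx
        av.recompute_combined()
        out.append(av)
    if missing:
        logger.info("annotate: %d variants missing from the score table", missing)
    return out


@dataclass
class SelectionStats:
    """hN/hS selection statistic for one variant set."""

    n_nonsyn: int
    n_syn: int
    possible_nonsyn: int
    possible_syn: int

    @property
    def hn(self) -> float:
        return self.n_nonsyn / self.possible_nonsyn

    @property
    def hs(self) -> float:
        return self.n_syn / self.possible_syn

    @property
    def undefined(self) -> bool:
        return self.n_syn == 0

    @property
    def ratio(self) -> float:
        if self.undefined:
            return float("nan")
        return self.hn / self.hs


def hn_hs(observed: Iterable[AnnotatedVariant],
          possible: dict[str, int]) -> tuple[SelectionStats, float]:
    """hN/hS for a variant set plus a chi-squared p against neutrality.

    ``possible`` maps 'synonymous'/'nonsynonymous' to the possible-substitution
    counts from :func:`mthet.reference.enumerate_possible_substitutions`.
    Observed variants are deduplicated by (position, alt); the p-value
    compares the observed syn/nonsyn split with the possible split (2×2
    chi-squared), the construction used for the "ratio significantly less
    than one" claims.
    """
    ps, pn = possible.get(EFFECT_SYNONYMOUS, 0), possible.get(EFFECT_NONSYNONYMOUS, 0)
    if ps <= 0 or pn <= 0:
        raise ValueError("possible substitution counts must be positive")
    seen = set()
    n_syn = n_nonsyn = 0
    for v in observed:
        key = (v.position, v.alt)
        if key in seen:
            continue
        seen.add(key)
        if v.effect == EFFECT_SYNONYMOUS:
            n_syn += 1
        elif v.effect == EFFECT_NONSYNONYMOUS:
            n_nonsyn += 1
    st = SelectionStats(n_nonsyn=n_nonsyn, n_syn=n_syn,
                        possible_nonsyn=pn, possible_syn=ps)
    if n_syn + n_nonsyn == 0:
        return st, float("nan")
    table = np.array([[n_nonsyn, n_syn], [pn, ps]])
    p = float(stats.chi2_contingency(table)[1])
    return st, p


def hn_hs_compare(set_a: Iterable[AnnotatedVariant],
                  set_b: Iterable[AnnotatedVariant]) -> float:
    """Chi-squared p comparing the syn/nonsyn split of two variant sets."""
    def split(vs):
        dedup = {(v.position, v.alt): v for v in vs}
        ns = sum(v.effect == EFFECT_NONSYNONYMOUS for v in dedup.values())
        s = sum(v.effect == EFFECT_SYNONYMOUS for v in dedup.values())
        return ns, s
    a, b = split(set_a), split(set_b)
    return float(stats.chi2_contingency(np.array([a, b]))[1])


def titv(substitutions: Iterable[tuple[str, str]]) -> float:
    """Transition/transversion ratio; inf when no transversions are present."""
    ti = tv = 0
    for ref, alt in substitutions:
        if is_transition(ref, alt):
            ti += 1
        else:
            tv += 1
    if tv == 0:
        return float("inf")
    return ti / tv


def classify_polymorphic(position: int, homoplasmies: pd.DataFrame) -> bool:
    """Polymorphic iff ≥2 distinct homoplasmic alleles segregate at the site.

    Sites variable only in the heteroplasmic state are NOT polymorphic.
    ``homoplasmies`` columns: sample, position, allele.
    """
    alleles = homoplasmies.loc[homoplasmies["position"] == position, "allele"]
    return alleles.nunique() >= 2


def variants_to_dataframe(variants: Iterable[AnnotatedVariant]) -> pd.DataFrame:
    cols = ["position", "ref", "alt", "region", "effect", "polymorphic",
            "cadd_phred", "cadd15", "cadd20", "polyphen_damaging",
            "assessor_damaging", "mutpred_damaging", "disease_associated",
            "combined_prediction"]
    return pd.DataFrame([[getattr(v, c) for c in cols] for v in variants],
                        columns=cols)
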