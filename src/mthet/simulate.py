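"""Synthetic mother–proband–sibling trio pileups with known ground truth.

The generator emulates the statistical structure of off-target mtDNA reads in
exome data: ~141X mean per-site depth (Poisson by default), per-read base
qualities with a Phred 20 floor (error ≤1%), population homoplasmy backbones
that define polymorphic sites, maternal heteroplasmies at 2–50% minor
fraction, maternal transmission with bottleneck drift, and strongly
transition-biased de novo mutations.

Drift model: the child's true derived-allele fraction is drawn from a Normal
centred on the maternal fraction with s.d. ``sigma_b`` and truncated to
[0, 1]; draws that truncate model fixation of the major (0) or minor (1)
allele.  Every non-reference read excess in the output traces either to a
:class:`TruthTable` entry or to sequencing error.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from .pileup import BASES, SitePileup
from .reference import (GeneFeature, MitoGenome, complement, is_transition)

ROLES = ("mother", "proband", "sibling")

#: weight of a transition relative to the two transversions combined; the
#: expected Ti/Tv among generated de novo events equals this weight
DEFAULT_TI_WEIGHT = 30.0


def toy_mito_genome(seed: int = 0, n_protein: int = 3, gene_len: int = 120,
                    spacer: int = 20, dloop_len: int = 150,
                    rna_len: int = 70) -> tuple[MitoGenome, list[GeneFeature]]:
    """A small circular genome with D-loop, RNA genes, and protein genes.

    Protein genes start with ATG, have internal codons free of in-frame
    stops, and end with TAA; one protein gene and one tRNA are placed on the
    light strand so reverse-complement classification is exercised.  Gene
    lengths are multiples of 3.
    """
    rng = np.random.default_rng(seed)
    if gene_len % 3:
        raise ValueError("gene_len must be a multiple of 3")
    from .reference import MITO_TABLE
    sense_codons = sorted(set(MITO_TABLE.forward_table) - set(MITO_TABLE.stop_codons))

    def random_bases(k):
        return "".join(rng.choice(list("ACGT"), size=k))

    def random_cds(length):
        n_codon = length // 3 - 2
        body = "".join(rng.choice(sense_codons, size=n_codon))
        return "ATG" + body + "TAA"

    parts: list[str] = []
    features: list[GeneFeature] = []
    pos = 1

    def append(seq: str, feature: GeneFeature | None):
        nonlocal pos
        parts.append(seq)
        if feature is not None:
            features.append(feature)
        pos += len(seq)

    append(random_bases(dloop_len), None)  # D-loop body; declared circular below
    append(random_bases(rna_len),
           GeneFeature("toy-tRNA1", pos, pos + rna_len - 1, "heavy", "trna"))
    append(random_bases(spacer), None)
    for g in range(n_protein):
        strand = "light" if g == n_protein - 1 else "heavy"
        cds = random_cds(gene_len)
        if strand == "light":
            cds = "".join(complement(b) for b in reversed(cds))
        append(cds, GeneFeature(f"toy-P{g + 1}", pos, pos + gene_len - 1,
                                strand, "protein"))
        append(random_bases(spacer), None)
    append(random_bases(rna_len),
           GeneFeature("toy-rRNA1", pos, pos + rna_len - 1, "light", "rrna"))
    sequence = "".join(parts)
    L = len(sequence)
    # D-loop wraps across the origin: last spacer/2 bases .. dloop_len
    features.insert(0, GeneFeature("toy-Dloop", L - spacer // 2, dloop_len,
                                   "heavy", "dloop"))
    return MitoGenome(sequence), features


@dataclass(frozen=True)
class TrioScenario:
    """Generative conditions for a panel of mother–proband–sibling trios."""

    n_families: int = 50
    depth_mean: dict = field(default_factory=lambda: dict(
        mother=141.0, proband=141.0, sibling=141.0))
    depth_sd: float = 35.0            # used only by the "normal" depth model
    depth_model: str = "poisson"      # "poisson" | "normal"
    phred_floor: int = 20             # reads below the floor never generated
    phred_span: int = 20              # Q = floor + Binomial(span, 0.65)
    het_rate_per_mother: float = 0.3  # Poisson number of maternal heteroplasmies
    daf_choices: tuple = (0.05, 0.1, 0.2, 0.4)
    daf_weights: tuple | None = None  # None = uniform over daf_choices
    sigma_b: float = 0.05             # bottleneck drift s.d. of child DAF
    de_novo_rate: float = 0.12        # per child per genome
    ti_weight: float = DEFAULT_TI_WEIGHT
    n_backbone_sites: int = 20        # population polymorphic homoplasmy sites
    backbone_freq_alpha: float = 0.3  # Beta(alpha, 3): mostly-rare minor alleles
    n_background_sites: int = 30      # reference-only sites (errors only)
    maternal_heteroplasmies: tuple | None = None  # ((position, alt, daf), ...)
    seed: int = 0

    def __post_init__(self):
        if self.maternal_heteroplasmies:
            for _, _, daf in self.maternal_heteroplasmies:
                if not 0 <= daf <= 1:
                    raise ValueError("maternal DAF must lie in [0, 1]")
        if any(v < 0 for v in self.depth_mean.values()):
            raise ValueError("depths must be ≥ 0")
        if self.ti_weight < 0:
            raise ValueError("transition bias must be ≥ 0")


@dataclass
class TruthTable:
    """Ground truth for a generated panel.

    ``heteroplasmies``: one row per (individual, site) derived-allele event —
    family, sample, role, position, allele, true_daf, origin
    (inherited | de_novo).  ``consensus``: the true family consensus allele
    per simulated site.
    """

    heteroplasmies: pd.DataFrame
    consensus: pd.DataFrame

    def to_tsv(self, het_path, consensus_path) -> None:
        self.heteroplasmies.to_csv(het_path, sep="\t", index=False)
        self.consensus.to_csv(consensus_path, sep="\t", index=False)


def _draw_alt(rng: np.random.Generator, ref: str, ti_weight: float) -> str:
    """An alternative base with transition weight ``ti_weight`` : 1 (both Tv)."""
    alts = [b for b in BASES if b != ref]
    weights = np.array([ti_weight if is_transition(ref, b) else 0.5 for b in alts])
    weights /= weights.sum()
    return alts[rng.choice(3, p=weights)]


def _sample_depth(rng, scenario: TrioScenario, role: str) -> int:
    mean = scenario.depth_mean[role]
    if scenario.depth_model == "poisson":
        return int(rng.poisson(mean))
    d = rng.normal(mean, scenario.depth_sd)
    return max(0, int(round(d)))


def _simulate_site_pileup(rng, scenario: TrioScenario, sample: str, position: int,
                          ref: str, true_allele: str, derived: str | None,
                          daf: float, role: str) -> SitePileup:
    """Reads at one site: true base Bernoulli(daf) derived, then error flips."""
    depth = _sample_depth(rng, scenario, role)
    codes = np.full(depth, BASES.index(true_allele), dtype=np.int8)
    if derived is not None and daf > 0:
        k = rng.binomial(depth, daf)
        if k:
            codes[:k] = BASES.index(derived)
    quals = scenario.phred_floor + rng.binomial(scenario.phred_span, 0.65, size=depth)
    eps = 10.0 ** (-quals / 10.0)
    flip = rng.random(depth) < eps
    if flip.any():
        # error flips to a uniformly chosen other base
        shift = rng.integers(1, 4, size=int(flip.sum()))
        codes[flip] = (codes[flip] + shift) % 4
    strands = rng.integers(0, 2, size=depth).astype(np.int8)
    order = rng.permutation(depth)
    return SitePileup(sample=sample, position=position, ref=ref,
                      base_codes=codes[order], strands=strands, eps=eps)


def generate_trio_pileups(scenario: TrioScenario,
                          genome: MitoGenome | None = None
                          ) -> tuple[dict, TruthTable]:
    """Generate per-individual SitePileups and the matching TruthTable.

    Returns ``(pileups, truth)`` where ``pileups`` maps sample id →
    list[SitePileup].  Sites simulated per family: the population homoplasmy
    backbone, all maternal-heteroplasmy and de novo sites, and
    ``n_background_sites`` reference-only sites.  Reproducible per seed.
    """
    rng = np.random.default_rng(scenario.seed)
    if genome is None:
        genome, _ = toy_mito_genome(seed=scenario.seed)
    L = len(genome)

    n_special = scenario.n_backbone_sites + scenario.n_background_sites
    if n_special > L:
        raise ValueError("genome too short for requested site counts")
    fixed_hets = scenario.maternal_heteroplasmies or ()
    reserved = {p for p, _, _ in fixed_hets}
    pool = [p for p in rng.permutation(np.arange(1, L + 1)) if p not in reserved]
    backbone_pos = sorted(int(p) for p in pool[:scenario.n_backbone_sites])
    background_pos = sorted(int(p) for p in
                            pool[scenario.n_backbone_sites:n_special])
    free_pool = [int(p) for p in pool[n_special:]]

    backbone = []
    for p in backbone_pos:
        ref = genome.base(p)
        alt = _draw_alt(rng, ref, scenario.ti_weight)
        freq = float(rng.beta(scenario.backbone_freq_alpha, 3.0))
        backbone.append((p, ref, alt, freq))
    backbone_alleles = {p: (ref, alt) for p, ref, alt, _ in backbone}

    _TRANSITION = {"A": "G", "G": "A", "C": "T", "T": "C"}
    resolved_hets = []
    for p, alt, daf in fixed_hets:
        if alt is None:
            alt = _TRANSITION[genome.base(p)]
        if alt == genome.base(p) and p not in backbone_alleles:
            raise ValueError(f"derived allele equals the reference base at {p}")
        if p in backbone_alleles and backbone_alleles[p][1] == alt:
            raise ValueError(
                f"scenario inconsistent: heteroplasmy at backbone site {p} "
                f"with the same allele {alt}")
        resolved_hets.append((p, alt, daf))
    fixed_hets = tuple(resolved_hets)

    pileups: dict[str, list[SitePileup]] = {}
    truth_rows = []
    consensus_rows = []
    daf_choices = np.asarray(scenario.daf_choices, dtype=float)
    daf_weights = (np.asarray(scenario.daf_weights, dtype=float)
                   if scenario.daf_weights is not None else None)

    for fam_idx in range(scenario.n_families):
        family = f"fam{fam_idx:04d}"
        samples = {role: f"{family}-{role}" for role in ROLES}
        for s in samples.values():
            pileups[s] = []

        # family homoplasmy backbone: maternal-lineage fixed alleles
        family_allele: dict[int, str] = {}
        for p, ref, alt, freq in backbone:
            family_allele[p] = alt if rng.random() < freq else ref
        for p in background_pos:
            family_allele[p] = genome.base(p)

        # maternal heteroplasmies
        mat_hets: list[tuple[int, str, float]] = list(fixed_hets)
        n_extra = rng.poisson(scenario.het_rate_per_mother)
        used = {p for p, _, _ in mat_hets}

        def draw_position():
            while True:
                p = free_pool[int(rng.integers(len(free_pool)))]
                if p not in used and p not in family_allele:
                    return p

        for _ in range(n_extra):
            p = draw_position()
            used.add(p)
            base = genome.base(p)
            alt = _draw_alt(rng, base, scenario.ti_weight)
            daf = float(rng.choice(daf_choices, p=daf_weights))
            mat_hets.append((p, alt, daf))

        # child DAFs: truncated-normal drift around the maternal fraction
        child_daf: dict[str, dict[int, tuple[str, float]]] = {
            "proband": {}, "sibling": {}}
        for p, alt, daf in mat_hets:
            for child in ("proband", "sibling"):
                d = (daf if scenario.sigma_b == 0
                     else float(np.clip(rng.normal(daf, scenario.sigma_b), 0.0, 1.0)))
                child_daf[child][p] = (alt, d)

        # de novo mutations per child
        for child in ("proband", "sibling"):
            for _ in range(rng.poisson(scenario.de_novo_rate)):
                p = draw_position()
                used.add(p)
                base = genome.base(p)
                alt = _draw_alt(rng, base, scenario.ti_weight)
                daf = float(rng.choice(daf_choices, p=daf_weights))
                child_daf[child][p] = (alt, daf)

        sites = sorted(set(family_allele) | {p for p, _, _ in mat_hets}
                       | set(child_daf["proband"]) | set(child_daf["sibling"]))
        mat_daf = {p: (alt, daf) for p, alt, daf in mat_hets}
        for p in sites:
            ref = genome.base(p)
            true_allele = family_allele.get(p, ref)
            consensus_rows.append((family, p, true_allele))
            for role in ROLES:
                if role == "mother":
                    derived, daf = mat_daf.get(p, (None, 0.0))
                else:
                    derived, daf = child_daf[role].get(p, (None, 0.0))
                pileups[samples[role]].append(_simulate_site_pileup(
                    rng, scenario, samples[role], p, ref, true_allele,
                    derived, daf, role))
                if derived is not None and daf > 0:
                    origin = ("inherited" if role == "mother" or p in mat_daf
                              else "de_novo")
                    if role == "mother":
                        origin = "maternal"
                    truth_rows.append((family, samples[role], role, p, derived,
                                       daf, origin))

    truth = TruthTable(
        heteroplasmies=pd.DataFrame(
            truth_rows, columns=["family", "sample", "role", "position",
                                 "allele", "true_daf", "origin"]),
        consensus=pd.DataFrame(
            consensus_rows, columns=["family", "position", "allele"]),
    )
    return pileups, truth


def generate_error_only_sites(n_sites: int, depth: int, eps: float,
                              rng: np.random.Generator | int | None = None,
                              ref: str = "A", sample: str = "errsim"
                              ) -> list[SitePileup]:
    """Sites with no true minor allele: every non-reference read is an error.

    Errors flip the reference base to a uniformly chosen one of the 3 other
    bases with probability ``eps``; all reads carry ε = ``eps`` and strands
    are fair-coin.  Used for empirical false-positive-rate checks.
    """
    if n_sites <= 0:
        raise ValueError("n_sites must be > 0")
    rng = np.random.default_rng(rng)
    ref_code = BASES.index(ref)
    out = []
    batch = 50_000
    made = 0
    pos = 1
    while made < n_sites:
        b = min(batch, n_sites - made)
        if eps > 0:
            flips = rng.random((b, depth)) < eps
            shift = rng.integers(1, 4, size=(b, depth), dtype=np.int8)
        else:
            flips = np.zeros((b, depth), dtype=bool)
            shift = None
        strands = rng.integers(0, 2, size=(b, depth), dtype=np.int8)
        for i in range(b):
            codes = np.full(depth, ref_code, dtype=np.int8)
            if eps > 0 and flips[i].any():
                codes[flips[i]] = (ref_code + shift[i][flips[i]]) % 4
            out.append(SitePileup(sample=sample, position=pos, ref=ref,
                                  base_codes=codes, strands=strands[i],
                                  eps=np.full(depth, eps) if eps > 0
                                  else np.full(depth, 1e-12)))
            pos += 1
        made += b
    return out


def generate_score_table(genome: MitoGenome, features,
                         seed: int | None = 0) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Synthetic pathogenicity-score and disease tables for a toy genome.

    Stands in for CADD/MitImpact/MITOMAP inputs in end-to-end runs on
    simulated data (synthetic — scores carry no biological meaning).
    Nonsynonymous substitutions draw higher CADD-style scores than
    synonymous/noncoding ones; predictor class calls and MutPred scores are
    correlated with CADD; a small subset of damaging changes is marked
    disease-associated.  Returns ``(scores, disease)``.
    """
    from .reference import classify_substitution, EFFECT_NONSYNONYMOUS
    rng = np.random.default_rng(seed)
    rows = []
    disease_rows = []
    for pos in range(1, len(genome) + 1):
        ref = genome.base(pos)
        for alt in BASES:
            if alt == ref:
                continue
            eff = classify_substitution(genome, features, pos, alt)
            nonsyn = eff.effect == EFFECT_NONSYNONYMOUS
            cadd = rng.normal(18 if nonsyn else 6, 5)
            damaging = cadd > 15
            polyphen = ("probably_damaging" if damaging and rng.random() < 0.7
                        else "benign")
            assessor = "medium" if damaging and rng.random() < 0.6 else "low"
            mutpred = float(np.clip(rng.normal(0.7 if damaging else 0.3, 0.15),
                                    0, 1))
            rows.append((pos, ref, alt, round(float(cadd), 2), polyphen,
                         assessor, round(mutpred, 3)))
            if damaging and rng.random() < 0.1:
                disease_rows.append((pos, alt, "synthetic-phenotype"))
    scores = pd.DataFrame(rows, columns=["pos", "ref", "alt", "cadd_phred",
                                         "polyphen_class", "assessor_class",
                                         "mutpred_score"])
    disease = pd.DataFrame(disease_rows, columns=["pos", "alt", "phenotype"])
    return scores, disease


def generate_phenotypes(n_families: int, carrier_effect: float = 1.0,
                        seed: int | None = 0,
                        sibling_carrier_rate: float = 0.03) -> pd.DataFrame:
    """Family phenotype table with a known carrier→ASD-group effect size.

    Carrier status (carrying a private pathogenic mutation) is assigned per
    child with baseline probability ``sibling_carrier_rate`` for siblings and
    odds multiplied by ``carrier_effect`` for probands, so the proband/sibling
    carrier odds ratio recovers ``carrier_effect`` in expectation.  IQ is
    Normal(95, 20) minus 8 points for carrier probands; SRS scores follow the
    proband-high/sibling-low pattern of simplex families; ``lgd`` marks
    families whose ASD is attributed to a nuclear de novo LGD variant.
    """
    rng = np.random.default_rng(seed)
    if n_families == 0:
        return pd.DataFrame(columns=[
            "family", "proband_carrier", "sibling_carrier", "proband_iq",
            "proband_srs", "sibling_srs", "lgd"])
    odds0 = sibling_carrier_rate / (1 - sibling_carrier_rate)
    odds1 = carrier_effect * odds0
    p_proband = odds1 / (1 + odds1)
    proband_carrier = rng.random(n_families) < p_proband
    sibling_carrier = rng.random(n_families) < sibling_carrier_rate
    proband_iq = rng.normal(95, 20, n_families) - 8 * proband_carrier
    proband_srs = rng.normal(78, 12, n_families)
    sibling_srs = rng.normal(45, 10, n_families)
    lgd = rng.random(n_families) < 0.34
    return pd.DataFrame({
        "family": [f"fam{i:04d}" for i in range(n_families)],
        "proband_carrier": proband_carrier,
        "sibling_carrier": sibling_carrier,
        "proband_iq": np.round(proband_iq, 1),
        "proband_srs": np.round(proband_srs, 1),
        "sibling_srs": np.round(sibling_srs, 1),
        "lgd": lgd,
    })
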