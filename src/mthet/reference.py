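"""Mitochondrial reference genome, gene model, and substitution classification.

The human mitochondrial genome is a circular molecule of 16,569 bp (revised
Cambridge Reference Sequence, rCRS), carrying 13 protein-coding genes, 22 tRNAs,
2 rRNAs and the non-coding D-loop control region, which wraps across the
sequence origin (16024..576 in rCRS coordinates).  Coordinates are 1-based
inclusive throughout, the rCRS convention.

Protein-coding genes are translated with the vertebrate mitochondrial genetic
code (NCBI table 2: AGA/AGG are stops, ATA is Met, TGA is Trp); genes on the
light strand are read from the reverse complement.  A terminal codon truncated
by the gene boundary is padded with A, mirroring the post-transcriptional
polyadenylation that completes the stop codon of several human mt mRNAs.
"""

from __future__ import annotations

import importlib.resources
from dataclasses import dataclass, field
from typing import Iterable, Sequence

import pandas as pd
from Bio.Data import CodonTable
from Bio.Seq import Seq
from Bio import SeqIO

BASES = "ACGT"
_COMPLEMENT = {"A": "T", "C": "G", "G": "C", "T": "A"}

#: NCBI translation table 2 (vertebrate mitochondrial)
MITO_TABLE = CodonTable.unambiguous_dna_by_id[2]

REGION_DLOOP = "dloop"
REGION_RNA = "rna"
REGION_CODING = "coding"
REGION_INTERGENIC = "intergenic"

EFFECT_SYNONYMOUS = "synonymous"
EFFECT_NONSYNONYMOUS = "nonsynonymous"
EFFECT_RNA = "rna"
EFFECT_NONCODING = "noncoding"

RCRS_LENGTH = 16569


def complement(base: str) -> str:
    return _COMPLEMENT[base]


def is_transition(ref: str, alt: str) -> bool:
    """True for purine<->purine or pyrimidine<->pyrimidine substitutions."""
    return {ref, alt} in ({"A", "G"}, {"C", "T"})


def translate_codon(codon: str) -> str:
    """One-letter amino acid (or '*' for stop) under the vertebrate mt code."""
    if codon in MITO_TABLE.stop_codons:
        return "*"
    return MITO_TABLE.forward_table[codon]


@dataclass(frozen=True)
class MitoGenome:
    """A (toy or real) mitochondrial reference sequence.

    Positions are 1-based; when ``circular`` they wrap modulo the length.
    """

    sequence: str
    circular: bool = True
    name: str = "MT"

    def __post_init__(self):
        if len(self.sequence) == 0:
            raise ValueError("genome sequence must be non-empty")
        seq = self.sequence.upper()
        if set(seq) - set(BASES + "N"):
            raise ValueError("genome sequence contains non-ACGTN characters")
        object.__setattr__(self, "sequence", seq)

    def __len__(self) -> int:
        return len(self.sequence)

    def wrap(self, position: int) -> int:
        """Map an arbitrary 1-based position into [1, L] (circular only)."""
        L = len(self)
        if 1 <= position <= L:
            return position
        if not self.circular:
            raise IndexError(f"position {position} outside linear genome of length {L}")
        return (position - 1) % L + 1

    def base(self, position: int) -> str:
        return self.sequence[self.wrap(position) - 1]

    @classmethod
    def from_fasta(cls, path, circular: bool = True) -> "MitoGenome":
        record = next(SeqIO.parse(str(path), "fasta"))
        return cls(sequence=str(record.seq), circular=circular, name=record.id)


@dataclass(frozen=True)
class GeneFeature:
    """One annotated feature: protein gene, tRNA/rRNA gene, or the D-loop.

    ``start``..``end`` are 1-based inclusive and may wrap across the origin
    (start > end), as the rCRS D-loop does (16024..576).
    """

    name: str
    start: int
    end: int
    strand: str = "heavy"  # heavy = reference orientation, light = reverse
    kind: str = "protein"  # protein | trna | rrna | dloop

    def __post_init__(self):
        if self.strand not in ("heavy", "light"):
            raise ValueError(f"bad strand {self.strand!r}")
        if self.kind not in ("protein", "trna", "rrna", "dloop"):
            raise ValueError(f"bad feature kind {self.kind!r}")

    def positions(self, genome_length: int) -> range | list:
        if self.start <= self.end:
            return range(self.start, self.end + 1)
        # wraps across the origin
        return list(range(self.start, genome_length + 1)) + list(range(1, self.end + 1))

    def contains(self, position: int, genome_length: int) -> bool:
        if self.start <= self.end:
            return self.start <= position <= self.end
        return position >= self.start or position <= self.end

    def length(self, genome_length: int) -> int:
        if self.start <= self.end:
            return self.end - self.start + 1
        return (genome_length - self.start + 1) + self.end


@dataclass(frozen=True)
class SubstitutionEffect:
    """Functional classification of one single-nucleotide substitution."""

    position: int
    ref: str
    alt: str
    region: str
    effect: str
    codon_change: str | None = None
    is_transition: bool = False
    overlapping_genes: tuple = ()


def read_gene_table(path) -> list[GeneFeature]:
    """Read a tab-separated gene table (name, start, end, strand, kind)."""
    df = pd.read_csv(path, sep="\t", comment="#")
    required = {"name", "start", "end", "strand", "kind"}
    if not required.issubset(df.columns):
        raise ValueError(f"gene table must have columns {sorted(required)}")
    return [
        GeneFeature(
            name=row["name"],
            start=int(row["start"]),
            end=int(row["end"]),
            strand=row["strand"],
            kind=row["kind"],
        )
        for _, row in df.iterrows()
    ]


def rcrs_gene_table() -> list[GeneFeature]:
    """The bundled rCRS gene annotation (37 genes + D-loop, MITOMAP coordinates)."""
    ref = importlib.resources.files("mthet.data").joinpath("rcrs_genes.tsv")
    with importlib.resources.as_file(ref) as path:
        return read_gene_table(path)


def region_of(features: Sequence[GeneFeature], position: int,
              genome_length: int = RCRS_LENGTH) -> str:
    """Region label for a 1-based position: dloop > coding > rna > intergenic.

    Coding takes precedence over RNA when a position falls in both (does not
    occur in rCRS); the D-loop interval wraps across the origin.
    """
    hits = [f for f in features if f.contains(position, genome_length)]
    kinds = {f.kind for f in hits}
    if "dloop" in kinds:
        return REGION_DLOOP
    if "protein" in kinds:
        return REGION_CODING
    if kinds & {"trna", "rrna"}:
        return REGION_RNA
    return REGION_INTERGENIC


def _codon_at(genome: MitoGenome, feature: GeneFeature, position: int,
              override_base: str | None = None) -> tuple[str, int]:
    """The codon containing ``position`` in the reading frame of ``feature``.

    Returns (codon, offset-within-codon) in the coding orientation.  A codon
    truncated at the gene 3' end is padded with A (polyadenylation rule).
    """
    positions = list(feature.positions(len(genome)))
    if feature.strand == "light":
        positions = positions[::-1]
    idx = positions.index(position)  # index in coding orientation
    codon_start = idx - idx % 3
    codon = []
    for i in range(codon_start, codon_start + 3):
        if i < len(positions):
            p = positions[i]
            b = override_base if (override_base is not None and p == position) else genome.base(p)
            codon.append(b if feature.strand == "heavy" else complement(b))
        else:
            codon.append("A")
    return "".join(codon), idx % 3


def classify_substitution(genome: MitoGenome, features: Sequence[GeneFeature],
                          position: int, alt: str) -> SubstitutionEffect:
    """Classify a single-nucleotide substitution at ``position`` to ``alt``.

    In coding regions the effect is synonymous/nonsynonymous under the
    vertebrate mitochondrial code; a position inside two or more overlapping
    protein genes is nonsynonymous if the change is nonsynonymous in ANY of
    the frames (conservative, the convention of common mtDNA annotators).
    """
    if alt not in BASES:
        raise ValueError(f"alt allele {alt!r} not one of A/C/G/T")
    L = len(genome)
    if not genome.circular and not (1 <= position <= L):
        raise IndexError(f"position {position} out of range 1..{L}")
    position = genome.wrap(position)
    ref = genome.base(position)
    if alt == ref:
        raise ValueError(f"alt equals reference base {ref} at position {position}")

    region = region_of(features, position, L)
    overlapping = tuple(
        f.name for f in features
        if f.kind == "protein" and f.contains(position, L)
    )
    if region != REGION_CODING:
        effect = EFFECT_RNA if region == REGION_RNA else EFFECT_NONCODING
        return SubstitutionEffect(position, ref, alt, region, effect,
                                  is_transition=is_transition(ref, alt),
                                  overlapping_genes=overlapping)

    changes = []
    any_nonsyn = False
    for feat in features:
        if feat.kind != "protein" or not feat.contains(position, L):
            continue
        ref_codon, _ = _codon_at(genome, feat, position)
        alt_codon, _ = _codon_at(genome, feat, position, override_base=alt)
        aa_ref = translate_codon(ref_codon)
        aa_alt = translate_codon(alt_codon)
        changes.append(f"{feat.name}:{ref_codon}>{alt_codon}({aa_ref}>{aa_alt})")
        if aa_ref != aa_alt:
            any_nonsyn = True
    effect = EFFECT_NONSYNONYMOUS if any_nonsyn else EFFECT_SYNONYMOUS
    return SubstitutionEffect(position, ref, alt, region, effect,
                              codon_change=";".join(changes) or None,
                              is_transition=is_transition(ref, alt),
                              overlapping_genes=overlapping)


def enumerate_possible_substitutions(genome: MitoGenome,
                                     features: Sequence[GeneFeature]) -> pd.DataFrame:
    """Count every possible single-nucleotide substitution by region and effect.

    Each position admits exactly 3 substitutions, so counts sum to 3L.  The
    coding region is split into synonymous and nonsynonymous; other regions
    carry their single effect class.
    """
    counts: dict[tuple[str, str], int] = {}
    for position in range(1, len(genome) + 1):
        ref = genome.base(position)
        if ref == "N":
            continue
        for alt in BASES:
            if alt == ref:
                continue
            eff = classify_substitution(genome, features, position, alt)
            key = (eff.region, eff.effect)
            counts[key] = counts.get(key, 0) + 1
    df = pd.DataFrame(
        [(r, e, n) for (r, e), n in sorted(counts.items())],
        columns=["region", "effect", "count"],
    )
    return df


def possible_counts(table: pd.DataFrame) -> dict[str, int]:
    """Convenience: {'synonymous': n, 'nonsynonymous': n} from the enumeration."""
    coding = table[table.region == REGION_CODING]
    out = {EFFECT_SYNONYMOUS: 0, EFFECT_NONSYNONYMOUS: 0}
    for _, row in coding.iterrows():
        out[row["effect"]] = int(row["count"])
    return out
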