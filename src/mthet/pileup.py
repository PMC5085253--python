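"""Read pileup containers, mpileup parsing, quality filtering, down-sampling.

A :class:`SitePileup` holds the read-level observations (called base, strand,
per-read error probability) for one sample at one mtDNA position — the unit
all heteroplasmy calling starts from.  Observations are stored as parallel
numpy arrays so that large simulated panels stay cheap; the iterator view
yields :class:`ReadObservation` tuples.

Input dialects: the 6-column samtools mpileup text format (chrom, pos, ref,
depth, bases, quals) and an equivalent columnar TSV (sample, pos, ref, base,
strand, phred).  Base qualities are Phred+33; ε = 10^(−Q/10).  Indel tokens
and 'N' base calls carry no point-substitution information and are dropped
with a logged count — the analysis targets point variants only.  Mapping
quality filtering is assumed applied upstream of the pileup.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Iterable, Iterator, NamedTuple, Sequence

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

BASES = "ACGT"
BASE_TO_CODE = {b: i for i, b in enumerate(BASES)}
CODE_TO_BASE = np.array(list(BASES))

FWD, REV = 0, 1


class ReadObservation(NamedTuple):
    """One read's evidence at a site: base call, strand, error probability."""

    base: str
    strand: str  # "fwd" | "rev"
    error_prob: float


def phred_to_eps(q) -> np.ndarray:
    return 10.0 ** (-np.asarray(q, dtype=float) / 10.0)


def eps_to_phred(eps) -> np.ndarray:
    return -10.0 * np.log10(np.asarray(eps, dtype=float))


@dataclass
class SitePileup:
    """All quality-annotated reads for one sample at one 1-based position."""

    sample: str
    position: int
    ref: str
    base_codes: np.ndarray  # int8, 0..3 = A,C,G,T
    strands: np.ndarray     # int8, 0 = fwd, 1 = rev
    eps: np.ndarray         # float64 error probabilities in (0, 1]

    def __post_init__(self):
        self.base_codes = np.asarray(self.base_codes, dtype=np.int8)
        self.strands = np.asarray(self.strands, dtype=np.int8)
        self.eps = np.asarray(self.eps, dtype=float)
        if not (len(self.base_codes) == len(self.strands) == len(self.eps)):
            raise ValueError("observation arrays must have equal length")

    @classmethod
    def from_observations(cls, sample: str, position: int, ref: str,
                          observations: Iterable[ReadObservation]) -> "SitePileup":
        obs = list(observations)
        return cls(
            sample=sample, position=position, ref=ref,
            base_codes=np.array([BASE_TO_CODE[o.base] for o in obs], dtype=np.int8),
            strands=np.array([0 if o.strand == "fwd" else 1 for o in obs], dtype=np.int8),
            eps=np.array([o.error_prob for o in obs], dtype=float),
        )

    @property
    def depth(self) -> int:
        return len(self.base_codes)

    def __len__(self) -> int:
        return self.depth

    def __iter__(self) -> Iterator[ReadObservation]:
        for code, strand, e in zip(self.base_codes, self.strands, self.eps):
            yield ReadObservation(BASES[code], "fwd" if strand == FWD else "rev", float(e))

    def allele_strand_counts(self) -> np.ndarray:
        """4x2 array of read counts: rows A,C,G,T; columns fwd,rev."""
        counts = np.zeros((4, 2), dtype=np.int64)
        np.add.at(counts, (self.base_codes, self.strands), 1)
        return counts

    def subset(self, mask_or_index) -> "SitePileup":
        return SitePileup(
            sample=self.sample, position=self.position, ref=self.ref,
            base_codes=self.base_codes[mask_or_index],
            strands=self.strands[mask_or_index],
            eps=self.eps[mask_or_index],
        )


def filter_reads(pileup: SitePileup, min_phred: float = 20) -> SitePileup:
    """Keep observations with base quality Phred ≥ ``min_phred`` (inclusive).

    Phred ≥20 corresponds to a per-base error probability ≤1%, the read-level
    screen applied before any calling.  Order is preserved; idempotent.
    """
    max_eps = phred_to_eps(min_phred) * (1 + 1e-12)  # inclusive boundary
    return pileup.subset(pileup.eps <= max_eps)


def _parse_mpileup_bases(bases: str, quals: str, ref: str, line_no: int
                         ) -> tuple[list[int], list[int], list[float], int]:
    """Decode one mpileup base string; returns codes, strands, eps, n_dropped."""
    codes: list[int] = []
    strands: list[int] = []
    eps: list[float] = []
    dropped = 0
    qi = 0  # index into quals: one qual per base-consuming token
    i = 0
    n = len(bases)
    ref = ref.upper()
    while i < n:
        c = bases[i]
        if c == "^":
            i += 2  # read start marker + mapping quality char
            continue
        if c == "$":
            i += 1
            continue
        if c in "+-":
            # indel token: sign, length digits, then that many bases
            j = i + 1
            while j < n and bases[j].isdigit():
                j += 1
            length = int(bases[i + 1:j])
            i = j + length
            continue
        # base-consuming tokens
        if qi >= len(quals):
            raise ValueError(f"mpileup line {line_no}: more bases than qualities")
        q = ord(quals[qi]) - 33
        qi += 1
        i += 1
        if c == ".":
            base, strand = ref, FWD
        elif c == ",":
            base, strand = ref, REV
        elif c in "ACGT":
            base, strand = c, FWD
        elif c in "acgt":
            base, strand = c.upper(), REV
        elif c in "*nN<>":
            dropped += 1
            continue
        else:
            raise ValueError(f"mpileup line {line_no}: unexpected token {c!r}")
        if base not in BASES:  # reference N
            dropped += 1
            continue
        codes.append(BASE_TO_CODE[base])
        strands.append(strand)
        eps.append(10.0 ** (-q / 10.0))
    if qi != len(quals):
        raise ValueError(f"mpileup line {line_no}: bases/qualities length mismatch")
    return codes, strands, eps, dropped


def read_mpileup(stream, sample: str = "sample") -> list[SitePileup]:
    """Parse samtools-mpileup 6-column text into SitePileups.

    '.'/',' decode to the reference base on the forward/reverse strand,
    upper/lower case letters to alternative bases; '^'/'$' read boundary
    markers and indel tokens are consumed (indels skipped with a logged
    count).  Malformed lines raise with their line number.
    """
    if isinstance(stream, (str, bytes)):
        import io
        stream = io.StringIO(stream if isinstance(stream, str) else stream.decode())
    pileups = []
    total_dropped = 0
    for line_no, line in enumerate(stream, start=1):
        line = line.rstrip("\n")
        if not line:
            continue
        fields = line.split("\t")
        if len(fields) < 4:
            raise ValueError(f"mpileup line {line_no}: expected ≥4 tab fields")
        chrom, pos, ref, depth = fields[:4]
        try:
            pos, depth = int(pos), int(depth)
        except ValueError as exc:
            raise ValueError(f"mpileup line {line_no}: bad position/depth") from exc
        if depth == 0 or len(fields) < 6:
            pileups.append(SitePileup(sample, pos, ref.upper(),
                                      np.empty(0, np.int8), np.empty(0, np.int8),
                                      np.empty(0, float)))
            continue
        codes, strands, eps, dropped = _parse_mpileup_bases(
            fields[4], fields[5], ref, line_no)
        total_dropped += dropped
        pileups.append(SitePileup(sample, pos, ref.upper(),
                                  np.array(codes, np.int8), np.array(strands, np.int8),
                                  np.array(eps, float)))
    if total_dropped:
        logger.info("read_mpileup: dropped %d indel/N/gap observations", total_dropped)
    return pileups


def write_mpileup(pileups: Sequence[SitePileup], chrom: str = "MT") -> str:
    """Render SitePileups back to 6-column mpileup text (inverse of parsing)."""
    lines = []
    for p in pileups:
        tokens, quals = [], []
        for obs in p:
            if obs.base == p.ref:
                tokens.append("." if obs.strand == "fwd" else ",")
            else:
                tokens.append(obs.base if obs.strand == "fwd" else obs.base.lower())
            q = int(round(float(eps_to_phred(obs.error_prob))))
            quals.append(chr(min(93, max(0, q)) + 33))
        if p.depth == 0:
            lines.append(f"{chrom}\t{p.position}\t{p.ref}\t0\t*\t*")
        else:
            lines.append(f"{chrom}\t{p.position}\t{p.ref}\t{p.depth}\t"
                         f"{''.join(tokens)}\t{''.join(quals)}")
    return "\n".join(lines) + "\n"


def read_pileup_tsv(path_or_buf) -> list[SitePileup]:
    """Read the columnar dialect: sample, pos, ref, base, strand, phred."""
    df = pd.read_csv(path_or_buf, sep="\t")
    pileups = []
    for (sample, pos, ref), grp in df.groupby(["sample", "pos", "ref"], sort=True):
        pileups.append(SitePileup(
            sample=str(sample), position=int(pos), ref=str(ref),
            base_codes=np.array([BASE_TO_CODE[b] for b in grp["base"]], np.int8),
            strands=np.where(grp["strand"].to_numpy() == "fwd", FWD, REV).astype(np.int8),
            eps=phred_to_eps(grp["phred"].to_numpy()),
        ))
    return pileups


def write_pileup_tsv(pileups: Sequence[SitePileup], path) -> None:
    rows = []
    for p in pileups:
        for obs in p:
            rows.append((p.sample, p.position, p.ref, obs.base, obs.strand,
                         float(eps_to_phred(obs.error_prob))))
    pd.DataFrame(rows, columns=["sample", "pos", "ref", "base", "strand", "phred"]) \
        .to_csv(path, sep="\t", index=False)


def downsample_trio(trio_pileups: Sequence[SitePileup],
                    rng: np.random.Generator | int | None = None
                    ) -> list[SitePileup]:
    """Down-sample a trio's pileups at one site to the lowest depth of the three.

    Sampling is without replacement (a subset of the real reads), so allele
    fractions are preserved in expectation (hypergeometric).  Reproducible for
    a given generator/seed; different seeds give independent replicates.
    """
    if len(trio_pileups) != 3:
        raise ValueError("downsample_trio expects exactly three pileups")
    positions = {p.position for p in trio_pileups}
    if len(positions) != 1:
        raise ValueError("trio pileups must share one position")
    rng = np.random.default_rng(rng)
    target = min(p.depth for p in trio_pileups)
    out = []
    for p in trio_pileups:
        if p.depth == target:
            out.append(p)
        else:
            idx = rng.choice(p.depth, size=target, replace=False)
            out.append(p.subset(np.sort(idx)))
    return out


def depth_summary(pileups: Iterable[SitePileup]) -> tuple[pd.Series, pd.Series]:
    """Per-sample mean depth and per-site median depth across the population."""
    rows = [(p.sample, p.position, p.depth) for p in pileups]
    df = pd.DataFrame(rows, columns=["sample", "position", "depth"])
    per_sample_mean = df.groupby("sample")["depth"].mean()
    per_site_median = df.groupby("position")["depth"].median()
    return per_sample_mean, per_site_median
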