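"""Homoplasmy/heteroplasmy calling with ML minor-allele-fraction estimation.

For a site with n minor-allele reads and m major-allele reads, each read i
carrying a sequencing-error probability ε_i derived from its base quality,
the likelihood of a minor-allele fraction f is

    L(f) = ∏_{i=1..n} [(1−f)ε_i + f(1−ε_i)] · ∏_{i=1..m} [(1−f)(1−ε_i) + fε_i]

The estimate f̂ maximises L over [0, 0.5] (the estimand is a minor fraction)
and the confidence score is the log10 likelihood ratio against the
homoplasmic model, LLR = log10 L(f̂) − log10 L(0), floored at 0.  LLR is in
log base 10 so that the conventional LLR>5 cutoff corresponds to a ~1e−5
false-positive equivalence.

A heteroplasmy candidate further requires >40X post-filter depth, the minor
allele observed on both strands, and strand-balanced allele fractions
(two-sided Fisher exact P ≥ 0.01 on the major/minor × strand table); a
high-confidence call additionally has f̂ ≥ min_maf and LLR > min_llr.  All
boundary comparisons are strict as stated (>40X, >70X median, LLR>5, P≥0.01,
≥10 reads, MAF≥5%).
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from functools import lru_cache
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from scipy import optimize, stats

from .pileup import BASES, SitePileup

DEFAULT_MIN_DEPTH = 41      # ">40X depth of coverage"
DEFAULT_MIN_MAF = 0.05
DEFAULT_MIN_LLR = 5.0
DEFAULT_MIN_STRAND_P = 0.01
DEFAULT_MIN_HOM_READS = 10
DEFAULT_MIN_SITE_MEDIAN = 70  # valid site: median depth strictly >70X

_LOG10E = math.log10(math.e)


def _check_eps(eps: np.ndarray) -> np.ndarray:
    eps = np.asarray(eps, dtype=float)
    if eps.size and (np.any(eps <= 0) or np.any(eps >= 1)):
        raise ValueError("error probabilities must lie strictly in (0, 1)")
    return eps


def loglik10(f: float, minor_eps: np.ndarray, major_eps: np.ndarray) -> float:
    """log10 L(f) for given per-read error probabilities."""
    ll = 0.0
    if minor_eps.size:
        ll += np.log10((1 - f) * minor_eps + f * (1 - minor_eps)).sum()
    if major_eps.size:
        ll += np.log10((1 - f) * (1 - major_eps) + f * major_eps).sum()
    return float(ll)


def estimate_maf(minor_eps, major_eps) -> tuple[float, float]:
    """ML minor-allele fraction f̂ over [0, 0.5] and its log10 LLR vs f=0.

    ``minor_eps``/``major_eps`` are the error probabilities of the n minor-
    and m major-allele reads.  The maximiser is located by a coarse grid
    followed by bounded scalar optimisation (tolerance 1e−7 in f, well inside
    the 1e−5 contract); L is log-concave in f so the refinement is safe.
    """
    minor_eps = _check_eps(minor_eps)
    major_eps = _check_eps(major_eps)
    n, m = minor_eps.size, major_eps.size
    if n + m == 0:
        raise ValueError("estimate_maf requires at least one read")
    if n == 0:
        return 0.0, 0.0
    # uniform-ε fast path: closed-form maximiser (see _estimate_maf_counts)
    if (np.ptp(minor_eps) == 0 and (m == 0 or np.ptp(major_eps) == 0)
            and (m == 0 or minor_eps[0] == major_eps[0])):
        return _estimate_maf_counts(n, m, float(minor_eps[0]))

    grid = np.linspace(0.0, 0.5, 257)
    vals = [loglik10(f, minor_eps, major_eps) for f in grid]
    k = int(np.argmax(vals))
    lo = grid[max(k - 1, 0)]
    hi = grid[min(k + 1, len(grid) - 1)]
    res = optimize.minimize_scalar(
        lambda f: -loglik10(f, minor_eps, major_eps),
        bounds=(lo, hi), method="bounded",
        options={"xatol": 1e-7},
    )
    fhat = float(np.clip(res.x, 0.0, 0.5))
    # boundary candidates: the optimizer cannot land exactly on 0 or 0.5
    cands = [(loglik10(f, minor_eps, major_eps), f) for f in (0.0, fhat, 0.5)]
    llmax, fhat = max(cands)
    llr = max(0.0, llmax - loglik10(0.0, minor_eps, major_eps))
    return fhat, llr


@lru_cache(maxsize=100_000)
def _estimate_maf_counts(n: int, m: int, eps: float) -> tuple[float, float]:
    """Closed-form f̂ and LLR when every read shares the same ε.

    Setting dL/df = 0 gives f* = (n(1−ε) − mε) / ((n+m)(1−2ε)), clamped to
    [0, 0.5]; with equal ε the likelihood depends on the reads only through
    (n, m), which makes the result memoizable.
    """
    if n == 0:
        return 0.0, 0.0
    if eps != 0.5:
        fstar = (n * (1 - eps) - m * eps) / ((n + m) * (1 - 2 * eps))
    else:
        fstar = 0.0
    fhat = float(np.clip(fstar, 0.0, 0.5))

    def ll(f):
        a = (1 - f) * eps + f * (1 - eps)
        b = (1 - f) * (1 - eps) + f * eps
        return n * math.log10(a) + (m * math.log10(b) if m else 0.0)

    llmax, fhat = max((ll(f), f) for f in (0.0, fhat, 0.5))
    return fhat, max(0.0, llmax - ll(0.0))


@lru_cache(maxsize=100_000)
def _fisher_two_sided(a: int, b: int, c: int, d: int) -> float:
    return float(stats.fisher_exact([[a, b], [c, d]], alternative="two-sided")[1])


@dataclass(frozen=True)
class AlleleCounts:
    """Per-allele forward/reverse read counts with major/minor assignment."""

    counts: np.ndarray  # 4x2: rows A,C,G,T; columns fwd,rev
    ref: str
    major: str
    minor: str | None

    @classmethod
    def from_pileup(cls, pileup: SitePileup) -> "AlleleCounts":
        counts = pileup.allele_strand_counts()
        totals = counts.sum(axis=1)
        ref_code = BASES.index(pileup.ref) if pileup.ref in BASES else -1
        # major: highest count; ties prefer the reference base, then A<C<G<T
        order = sorted(range(4), key=lambda i: (-totals[i], i != ref_code, i))
        major = order[0]
        rest = [i for i in order[1:] if totals[i] > 0]
        minor = rest[0] if rest else None
        return cls(counts=counts, ref=pileup.ref, major=BASES[major],
                   minor=None if minor is None else BASES[minor])

    def total(self, allele: str) -> int:
        return int(self.counts[BASES.index(allele)].sum())

    def by_strand(self, allele: str) -> tuple[int, int]:
        fwd, rev = self.counts[BASES.index(allele)]
        return int(fwd), int(rev)

    @property
    def n(self) -> int:
        return 0 if self.minor is None else self.total(self.minor)

    @property
    def m(self) -> int:
        return self.total(self.major)


def strand_balance_test(counts: AlleleCounts) -> float:
    """Two-sided Fisher exact p for major/minor allele balance across strands.

    Degenerate margins (no minor reads) give p = 1.
    """
    if counts.minor is None:
        return 1.0
    maj_f, maj_r = counts.by_strand(counts.major)
    min_f, min_r = counts.by_strand(counts.minor)
    return _fisher_two_sided(maj_f, maj_r, min_f, min_r)


@dataclass
class HeteroplasmyCall:
    """Per-sample per-site heteroplasmy call with ML estimate and filters."""

    sample: str
    position: int
    ref: str
    major: str
    minor: str
    maf_raw: float
    maf_mle: float
    llr: float
    strand_p: float
    depth: int
    minor_fwd: int
    minor_rev: int
    depth_ok: bool
    both_strands: bool
    strand_ok: bool
    valid_site: bool
    high_confidence: bool
    triallelic: bool = False

    @property
    def candidate(self) -> bool:
        return self.depth_ok and self.both_strands and self.strand_ok


@dataclass(frozen=True)
class HomoplasmyCall:
    """A site effectively fixed for one allele in one sample."""

    sample: str
    position: int
    allele: str
    supporting_reads: int


def call_heteroplasmy(pileup: SitePileup,
                      min_maf: float = DEFAULT_MIN_MAF,
                      min_llr: float = DEFAULT_MIN_LLR,
                      min_depth: int = DEFAULT_MIN_DEPTH,
                      min_strand_p: float = DEFAULT_MIN_STRAND_P,
                      valid_site: bool = True) -> HeteroplasmyCall | None:
    """Call a heteroplasmy from a quality-filtered pileup; None if no minor allele.

    Tri-allelic sites: the top two alleles are analysed and the remainder
    flagged (``triallelic``) and excluded from the likelihood.
    """
    counts = AlleleCounts.from_pileup(pileup)
    if counts.minor is None:
        return None
    depth = pileup.depth
    minor_code = BASES.index(counts.minor)
    major_code = BASES.index(counts.major)
    minor_mask = pileup.base_codes == minor_code
    major_mask = pileup.base_codes == major_code
    n, m = counts.n, counts.m

    depth_ok = depth >= min_depth
    min_f, min_r = counts.by_strand(counts.minor)
    both_strands = min_f >= 1 and min_r >= 1

    fhat, llr = estimate_maf(pileup.eps[minor_mask], pileup.eps[major_mask])
    # strand balance only decides candidacy; skip the (exact-test) cost when
    # the call is already rejected by cheaper filters
    if depth_ok and both_strands:
        strand_p = strand_balance_test(counts)
    else:
        strand_p = 1.0
    strand_ok = strand_p >= min_strand_p
    candidate = depth_ok and both_strands and strand_ok
    high_confidence = bool(candidate and valid_site
                           and fhat >= min_maf and llr > min_llr)
    return HeteroplasmyCall(
        sample=pileup.sample, position=pileup.position, ref=pileup.ref,
        major=counts.major, minor=counts.minor,
        maf_raw=n / (n + m), maf_mle=fhat, llr=llr, strand_p=strand_p,
        depth=depth, minor_fwd=min_f, minor_rev=min_r,
        depth_ok=depth_ok, both_strands=both_strands, strand_ok=strand_ok,
        valid_site=valid_site, high_confidence=high_confidence,
        triallelic=(n + m) < depth,
    )


def call_homoplasmy(pileup: SitePileup, heteroplasmic: bool,
                    min_alt_reads: int = DEFAULT_MIN_HOM_READS
                    ) -> HomoplasmyCall | None:
    """Call the sample's homoplasmic allele at a site.

    An alternative (non-reference) homoplasmy requires the alternative allele
    to be the majority base, supported by ≥10 reads, at a site not in the
    heteroplasmic state for this sample.  A reference-allele homoplasmy is
    reported whenever the site is covered and not heteroplasmic, so that
    population homoplasmy tables (polymorphic-site and consensus logic) are
    complete.
    """
    if heteroplasmic or pileup.depth == 0:
        return None
    counts = AlleleCounts.from_pileup(pileup)
    allele = counts.major
    support = counts.total(allele)
    if allele != pileup.ref and support < min_alt_reads:
        return None
    return HomoplasmyCall(sample=pileup.sample, position=pileup.position,
                          allele=allele, supporting_reads=support)


def valid_sites(per_site_median: pd.Series,
                min_median: float = DEFAULT_MIN_SITE_MEDIAN) -> pd.Series:
    """Boolean mask of sites whose population median depth is strictly >70X."""
    return per_site_median > min_median


def detection_power(depth: int, maf: float, per_sub_error: float = 0.0033,
                    alpha: float = 0.05) -> float:
    """One-tailed power of a one-sample proportion test (normal approximation).

    Tests the alternative proportion ``maf`` against the null error proportion
    ``per_sub_error`` (1% base-call error spread over the 3 possible
    substitutions gives ~0.33% each) at significance ``alpha`` and sample size
    ``depth``.  Monotone nondecreasing in depth and in maf; equals alpha when
    maf == per_sub_error.
    """
    if depth < 1:
        raise ValueError("depth must be ≥ 1")
    z = stats.norm.ppf(1 - alpha)
    se0 = math.sqrt(per_sub_error * (1 - per_sub_error) / depth)
    se1 = math.sqrt(maf * (1 - maf) / depth)
    return float(stats.norm.cdf((maf - per_sub_error - z * se0) / se1))


def llr_false_positive_rate(depth: int, eps: float,
                            min_maf: float = DEFAULT_MIN_MAF,
                            min_llr: float = DEFAULT_MIN_LLR,
                            min_depth: int = DEFAULT_MIN_DEPTH,
                            per_substitution: bool = True) -> float:
    """Exact per-site false-positive rate of the filter chain under errors only.

    Minor-read counts k = 0..depth are enumerated with Binomial(depth, ε/3)
    weights (errors split uniformly over the 3 alternative bases; set
    ``per_substitution=False`` for the worst-case aggregation Binomial(depth,
    ε)).  Each k is pushed through the depth, both-strand (fair-strand
    probability 1 − 2·(1/2)^k), MAF and LLR filters with all ε_i = ε.  The
    strand-balance test is not enumerated, so the value is a (slightly
    conservative) upper bound.
    """
    if eps == 0:
        return 0.0
    if depth < min_depth:
        return 0.0
    rate = eps / 3 if per_substitution else eps
    ks = np.arange(2, depth + 1)  # k<2 cannot appear on both strands
    pmf = stats.binom.pmf(ks, depth, rate)
    fpr = 0.0
    for k, w in zip(ks, pmf):
        if w < 1e-300:
            continue
        fhat, llr = _estimate_maf_counts(int(k), int(depth - k), eps)
        if fhat >= min_maf and llr > min_llr:
            fpr += w * (1.0 - 2.0 * 0.5 ** k)
    return float(fpr)


def calls_to_dataframe(calls: Iterable[HeteroplasmyCall]) -> pd.DataFrame:
    cols = ["sample", "position", "ref", "major", "minor", "maf_raw", "maf_mle",
            "llr", "strand_p", "depth", "minor_fwd", "minor_rev", "depth_ok",
            "both_strands", "strand_ok", "valid_site", "high_confidence",
            "triallelic"]
    rows = [[getattr(c, k) for k in cols] for c in calls if c is not None]
    return pd.DataFrame(rows, columns=cols)


def calls_to_vcf(calls: Iterable[HeteroplasmyCall], chrom: str = "MT") -> str:
    """Minimal single-sample VCF with AF (ML MAF), DP and SB INFO fields."""
    lines = [
        "##fileformat=VCFv4.2",
        '##INFO=<ID=AF,Number=1,Type=Float,Description="ML minor allele fraction">',
        '##INFO=<ID=DP,Number=1,Type=Integer,Description="Filtered read depth">',
        '##INFO=<ID=SB,Number=1,Type=Float,Description="Strand balance Fisher p">',
        '##INFO=<ID=LLR,Number=1,Type=Float,Description="log10 likelihood ratio">',
        "#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO",
    ]
    for c in calls:
        if c is None:
            continue
        alt = c.minor if c.minor != c.ref else c.major
        filt = "PASS" if c.high_confidence else "lowconf"
        lines.append(
            f"{chrom}\t{c.position}\t.\t{c.ref}\t{alt}\t.\t{filt}\t"
            f"AF={c.maf_mle:.5f};DP={c.depth};SB={c.strand_p:.4g};LLR={c.llr:.3f}"
        )
    return "\n".join(lines) + "\n"
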