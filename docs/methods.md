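# Methods

## Heteroplasmy model and estimation

A site in one sample is summarised by the reads covering it: called base,
strand, and error probability ε_i = 10^(−Q_i/10) from the (recalibrated)
base quality.  Only reads with Phred ≥20 (ε ≤ 1%) enter calling.  With n
minor-allele and m major-allele reads, the minor-allele fraction f has
likelihood

    L(f) = ∏_{i=1..n} [(1−f)ε_i + f(1−ε_i)] · ∏_{i=1..m} [(1−f)(1−ε_i) + fε_i]

Each factor is the probability that read i shows its observed allele given
the true molecule is minor (probability f) or major (1−f) and may have been
miscalled.  log L is concave in f (a sum of logs of affine functions), so
the maximiser over [0, 0.5] is unique; it is located by a 257-point coarse
grid plus bounded scalar minimisation to 10⁻⁷, well inside the 10⁻⁵
contract.  When every read shares one ε the maximiser has the closed form
f* = (n(1−ε) − mε)/((n+m)(1−2ε)) clamped to [0, 0.5], and the result depends
on the reads only through (n, m); this path is memoised and is what makes
million-site error panels cheap.

The confidence score is LLR = log₁₀ L(f̂) − log₁₀ L(0), floored at 0.  The
null is the literal homoplasmic model f₀ = 0.  Log base 10 is used so that
the conventional LLR > 5 cutoff corresponds to the ~10⁻⁵ false-positive
equivalence.

### Filter chain

A candidate heteroplasmy requires, with all boundaries strict as stated:
site depth >40X after quality filtering; the minor allele on both strands
(≥1 read per strand); strand-balanced allele fractions (two-sided Fisher
exact P ≥ 0.01 on the major/minor × strand 2×2 table).  High confidence
additionally requires f̂ ≥ 5% (2% in extended analyses) and LLR > 5.  A site
is *valid* for calling when its median depth across the study population
exceeds 70X.  Homoplasmies: the majority allele, requiring ≥10 supporting
reads when it differs from the reference and the site is not heteroplasmic
in that sample; reference-allele homoplasmies are recorded too so that
population polymorphism and family consensus are well defined.
Tri-allelic pileups analyse the top two alleles and flag the remainder.
Major/minor ties break toward the reference base, then alphabetically.

### Power and false-positive rate

Detection power uses the one-tailed one-sample proportion test (normal
approximation): power = Φ((p₁ − p₀ − z₁₋α·SE₀)/SE₁) with p₀ the
per-substitution error (1% total error split over 3 alternative bases →
0.33%), p₁ the target MAF, and α = 0.05 (the conventional level; assumed).
At depth 71 — the valid-site floor — power for MAF 5% is 91.5%, and it
agrees with exact binomial enumeration to <0.05.

The false-positive rate of the full chain under an error-only model is
computed exactly by enumerating minor-read counts k with Binomial(depth,
ε/3) weights (worst-case aggregation Binomial(depth, ε) available),
multiplying by the fair-strand probability 1 − 2·(1/2)^k of appearing on
both strands, and applying the MAF/LLR thresholds with all ε_i = ε.  The
strand-balance Fisher test is not enumerated, so the value is a slightly
conservative upper bound.  At depth 141, ε = 1%, the per-substitution FPR
is ~3·10⁻¹² (worst-case ~2·10⁻⁷), far below 10⁻⁵.

## Genome and effect model

Genomes are circular with 1-based inclusive coordinates; the D-loop wraps
across the origin (16024..576 in rCRS).  Protein genes are translated under
the vertebrate mitochondrial code (NCBI table 2: AGA/AGG stop, ATA Met, TGA
Trp), light-strand genes from the reverse complement.  A substitution in
overlapping protein genes is nonsynonymous if nonsynonymous in *any* frame —
a conservative convention matching common mtDNA annotators; stop-gain/loss
fold into "nonsynonymous".  Terminal codons truncated at a gene boundary are
padded with A, mirroring the polyadenylation that completes the stop codon
of several human mt mRNAs.  The bundled rCRS gene table uses the standard
MITOMAP coordinates; the rCRS sequence itself is supplied by the user as
FASTA (tests use programmatically constructed toy genomes whose protein
genes are clean open reading frames).

hN/hS normalises observed nonsynonymous and synonymous substitution counts
by the counts of *possible* substitutions of each class (3 per position,
enumerated by brute-force translation); each (position, alt) pair counts at
most once, and RNA-gene variants carry no syn/nonsyn class and are excluded.
The neutrality comparison is a 2×2 chi-squared of observed vs possible
splits; this margin choice is ours, as is the companion two-set comparison.

## Family and transmission definitions

The family reference allele at a site is the allele with the highest mean
fraction across the trio (ties toward rCRS, then alphabetical).  Mutations
are derived alleles with DAF ≥5% (threshold sweepable 2–8%) carried as
high-confidence heteroplasmies (DAF = f̂, or 1−f̂ when the derived allele is
the major one) or as non-consensus homoplasmies (DAF ≈ 1), restricted to
sites where all three members exceed 40X.  Private: the other child shows
the allele at <2% or not at all.  Burden uses one-tailed paired t-tests
(alternative fixed a priori: probands > siblings; all-zero families are
retained; a zero-variance nonzero difference is flagged degenerate).
Carrier odds ratios count individuals with ≥1 private mutation of a
category; OR = ad/bc with a Woolf log CI (the CI method is our choice — the
source tables never state theirs, so only the point OR is matched) and
one-tailed Fisher p; zero cells get Haldane–Anscombe 0.5 with a flag.
Strata: proband IQ >85 vs ≤85; SRS-discordant = proband >75 and sibling
<50; families without nuclear de novo LGD variants; missing phenotypes drop
a family from that stratification only.  Threshold-sensitivity ratio curves
bootstrap the family (10,000 resamples, 90% percentile bands).

Transmission, at sites with a high-confidence heteroplasmy (MAF ≥5%) or de
novo homoplasmy in at least one of the pair: transmitted = both ≥2%,
untransmitted = mother only, de novo = child only; "present" is uniformly
DAF ≥2% (the source material alternates between "undetectable" and "<2%";
the 2% rule is applied throughout).  ΔDAF = DAF_child − DAF_mother.  De
novo homoplasmies enter with DAF_child = 1.  The three statuses partition
the records by construction.

## Sample QC

Mean mtDNA depth ≤40X excludes a sample.  Contamination, assessed on
high-confidence MAF ≥2% calls: (1) >5 heteroplasmies at
population-polymorphic sites (sites with ≥2 homoplasmic alleles among
retained samples, recomputed after coverage filtering); or (2) >50% of the
sample's heteroplasmies detectable as homoplasmies in a donor sample which
also account for >50% of the donor's homoplasmic sites distinct from the
recipient's — an asymmetric rule, with the donor named in the evidence.
Rule (1) counts heteroplasmic sites within the sample.  A family is
retained only if mother, proband and sibling all pass.

## Synthetic panels

The generator emulates the statistical structure of off-target mtDNA exome
coverage, not its sequence content:

* **Depth** — Poisson with role-specific means, default 141X for all roles
  (a Normal(mean, 35) alternative approximates wider empirical profiles);
  per-read Phred = 20 + Binomial(20, 0.65) (floor Q20, mean ≈ Q33).
* **Errors** — each read flips to a uniformly chosen other base with
  probability ε_read; error-only panels use a single ε for all reads.
* **Population structure** — backbone polymorphic sites with Beta(0.3, 3)
  minor-allele frequencies (mostly rare) fixed per maternal lineage;
  reference-only background sites carry errors only.
* **Heteroplasmies** — Poisson(0.3) per mother by default, DAFs drawn
  uniformly from {0.05, 0.1, 0.2, 0.4} (the bulk of observed mutations sit
  in the 5–20% range; the grid spans it plus one higher fraction).
* **Transmission** — child DAF ~ Normal(maternal DAF, σ_b = 0.05) truncated
  to [0, 1]; truncation models fixation of either allele.  A truncated
  Normal is used rather than an explicit bottleneck model because the
  matched observable is simply a ΔDAF distribution centred on zero.
* **De novo** — Poisson(0.12) per child per genome (~matching the observed
  per-child rate), transition:transversion weight 30 (expected Ti/Tv ≈ 30).

What the generator does **not** model: NUMT contamination, indels, mapping
artifacts, site-specific bait-affinity coverage profiles, or linkage between
sites.  Passing tests therefore demonstrate correctness of the estimators
and rules under the stated error model, not robustness to alignment
artefacts — those are assumed handled upstream of the pileup.

Synthetic pathogenicity score tables (used only to exercise the annotation
joins end to end) draw CADD-style scores from Normal(18, 5) for
nonsynonymous and Normal(6, 5) for other changes, with correlated predictor
classes; they carry no biological meaning and are labelled synthetic.

## Problem sizes and numerical choices

Test panels use 8–400 families on toy genomes of ~700 bp, 10⁶ sites for the
empirical false-positive check, 1,000 instances for the grid-oracle
comparison (step 10⁻⁵ over [0, 0.5]), 2,000 replicates of 903 families for
the type-I-error check, and 200 trios at depth 141 for parameter recovery —
sizes chosen so each property is measured with comfortable statistical
margin while the whole suite runs in minutes.  Optimiser tolerance is 10⁻⁷
in f; Fisher tests come from scipy.stats.fisher_exact; bootstrap CIs are
percentile intervals; all randomness flows from named integer seeds.

## Known limitations

* Estimation error of f̂ at depth d is binomial-limited
  (E|f̂−f| ≈ 0.8·√(f(1−f)/d) ≈ 0.015–0.033 at d = 141 across f = 0.05–0.4);
  no per-read quality weighting can beat this floor.
* Heteroplasmies below ~2% are outside scope (indistinguishable from the
  error floor at these depths), as are indels, copy-number changes, and
  haplogroup assignment.
* The contamination rules detect pairwise mixtures among the analysed
  samples only; external contaminants reduce to rule (1) at best.
* mpileup ingestion assumes mapping-quality filtering was applied upstream;
  indel tokens and N calls are dropped with a logged count.
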