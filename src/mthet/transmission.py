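"""Mother→child transmission classification and pathogenic-fraction shifts.

At sites carrying a high-confidence heteroplasmy (MAF ≥5%) or a de novo
homoplasmy in at least one member of a mother–child pair, a derived allele is

  * transmitted   — present in both mother and child with DAF ≥2%,
  * untransmitted — present in the mother, undetectable or DAF <2% in the child,
  * de novo       — present in the child, undetectable or DAF <2% in the mother.

"Present" is operationalised uniformly as DAF ≥2%.  ΔDAF = DAF_child −
DAF_mother summarises the transmission shift; under pure drift it is centred
on zero.  A child fixed for an allele the mother lacks is a de novo
homoplasmy and enters with DAF_child = 1.  The three statuses partition the
records.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

SHARED_MIN_DAF = 0.02

STATUS_TRANSMITTED = "transmitted"
STATUS_UNTRANSMITTED = "untransmitted"
STATUS_DE_NOVO = "de_novo"
STATUSES = (STATUS_TRANSMITTED, STATUS_UNTRANSMITTED, STATUS_DE_NOVO)


@dataclass(frozen=True)
class TransmissionRecord:
    family: str
    child_role: str          # proband | sibling
    position: int
    allele: str
    daf_mother: float
    daf_child: float
    status: str

    @property
    def delta_daf(self) -> float:
        return self.daf_child - self.daf_mother


def classify_transmission(daf_mother: float, daf_child: float,
                          min_shared_daf: float = SHARED_MIN_DAF) -> str | None:
    """Status for one mother/child DAF pair; None when absent from both."""
    in_mother = daf_mother >= min_shared_daf
    in_child = daf_child >= min_shared_daf
    if in_mother and in_child:
        return STATUS_TRANSMITTED
    if in_mother:
        return STATUS_UNTRANSMITTED
    if in_child:
        return STATUS_DE_NOVO
    return None


def build_records(pairs: pd.DataFrame,
                  min_shared_daf: float = SHARED_MIN_DAF) -> list[TransmissionRecord]:
    """TransmissionRecords from a tidy pair table.

    ``pairs`` columns: family, child_role, position, allele, daf_mother,
    daf_child.  Rows absent from both members are dropped (no record).
    """
    out = []
    for row in pairs.itertuples():
        status = classify_transmission(row.daf_mother, row.daf_child,
                                       min_shared_daf)
        if status is None:
            continue
        out.append(TransmissionRecord(
            family=row.family, child_role=row.child_role,
            position=int(row.position), allele=row.allele,
            daf_mother=float(row.daf_mother), daf_child=float(row.daf_child),
            status=status))
    return out


def records_to_dataframe(records) -> pd.DataFrame:
    rows = [(r.family, r.child_role, r.position, r.allele, r.daf_mother,
             r.daf_child, r.status, r.delta_daf) for r in records]
    return pd.DataFrame(rows, columns=["family", "child_role", "position",
                                       "allele", "daf_mother", "daf_child",
                                       "status", "delta_daf"])


def pathogenic_fraction_by_status(records: pd.DataFrame, category: str,
                                  n_boot: int = 10_000, ci: float = 0.95,
                                  seed: int | None = 0) -> pd.DataFrame:
    """Per-status proportion of records in a pathogenicity category.

    Bootstrap (resampling records within status) percentile CIs plus pairwise
    two-sided Fisher p-values between statuses.  ``category`` names a boolean
    column of ``records``.
    """
    rng = np.random.default_rng(seed)
    rows = []
    flags_by_status = {}
    for status in STATUSES:
        flags = records.loc[records["status"] == status, category] \
            .to_numpy(dtype=bool)
        flags_by_status[status] = flags
        n = flags.size
        if n == 0:
            rows.append((status, 0, np.nan, np.nan, np.nan))
            continue
        prop = flags.mean()
        lo = hi = np.nan
        if n_boot > 0:
            idx = rng.integers(0, n, size=(n_boot, n))
            boots = flags[idx].mean(axis=1)
            lo, hi = np.quantile(boots, [(1 - ci) / 2, (1 + ci) / 2])
        rows.append((status, n, prop, lo, hi))
    out = pd.DataFrame(rows, columns=["status", "n", "proportion",
                                      "ci_low", "ci_high"])
    pvals = {}
    for i, s1 in enumerate(STATUSES):
        for s2 in STATUSES[i + 1:]:
            f1, f2 = flags_by_status[s1], flags_by_status[s2]
            if f1.size and f2.size:
                table = [[int(f1.sum()), int((~f1).sum())],
                         [int(f2.sum()), int((~f2).sum())]]
                pvals[(s1, s2)] = float(stats.fisher_exact(table)[1])
            else:
                pvals[(s1, s2)] = np.nan
    out.attrs["pairwise_fisher_p"] = pvals
    return out


def daf_shift_test(proband_deltas, sibling_deltas) -> tuple[float, np.ndarray]:
    """Two-sided Fisher exact on (ΔDAF>0 vs not) × (proband, sibling) pairs.

    Input: ΔDAF values for the pathogenic records of mother–proband and
    mother–sibling pairs.  Returns (p, 2×2 table).
    """
    p_d = np.asarray(proband_deltas, dtype=float)
    s_d = np.asarray(sibling_deltas, dtype=float)
    if p_d.size == 0 or s_d.size == 0:
        raise ValueError("both pair sets must be non-empty")
    table = np.array([
        [int((p_d > 0).sum()), int((p_d <= 0).sum())],
        [int((s_d > 0).sum()), int((s_d <= 0).sum())],
    ])
    return float(stats.fisher_exact(table)[1]), table


def inherited_fraction(child_records: pd.DataFrame,
                       min_child_maf_grid=(0.02, 0.05)) -> pd.DataFrame:
    """Fraction of child heteroplasmies shared with the mother (DAF ≥2%).

    ``child_records`` columns: daf_child, daf_mother.  A child heteroplasmy
    counts as inherited when the mother carries the allele at ≥2%; the
    fraction is reported across a grid of minimum child MAF thresholds
    (lowering the child threshold typically lowers the inherited fraction,
    as low-fraction heteroplasmies are mostly of developmental origin).
    """
    rows = []
    for thr in min_child_maf_grid:
        sub = child_records[child_records["daf_child"] >= thr]
        n = len(sub)
        frac = (np.nan if n == 0
                else float((sub["daf_mother"] >= SHARED_MIN_DAF).mean()))
        rows.append((thr, n, frac))
    return pd.DataFrame(rows, columns=["min_child_maf", "n", "inherited_fraction"])
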