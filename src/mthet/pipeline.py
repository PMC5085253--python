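"""End-to-end pipeline: simulate → call → QC → analyze → transmit → report.

The pipeline is driven by a :class:`PipelineConfig` (YAML-serialisable; every
numeric threshold of the analysis with its default).  Each stage writes tidy
TSV outputs into the run directory, records them in a JSON manifest with
SHA-256 checksums, and is skipped on re-run when its outputs already exist
(delete the run directory or pass ``force`` for a clean rerun).  All
randomness flows from the named seeds, so a config + seed reproduces the run
byte for byte.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import annotate as ann
from . import calling, families, qc, transmission
from .pileup import depth_summary, filter_reads
from .simulate import (ROLES, TrioScenario, generate_phenotypes,
                       generate_score_table, generate_trio_pileups,
                       toy_mito_genome)

logger = logging.getLogger(__name__)


@dataclass
class PipelineConfig:
    """All thresholds of the analysis, at their standard defaults."""

    min_base_quality: int = 20        # read-level Phred floor
    min_depth: int = 41               # per-sample site depth (>40X)
    min_site_median: int = 70         # valid site: population median >70X
    min_maf: float = 0.05             # reporting threshold for heteroplasmies
    extended_min_maf: float = 0.02    # QC / transmission-shared threshold
    min_llr: float = 5.0
    min_strand_p: float = 0.01
    private_max_other_daf: float = 0.02
    min_daf: float = 0.05             # mutation (derived allele) threshold
    daf_grid: tuple = (0.02, 0.03, 0.04, 0.05, 0.06, 0.07, 0.08)
    n_boot: int = 10_000
    cadd_cutoffs: tuple = (15.0, 20.0)
    n_families: int = 20
    seed: int = 0
    carrier_effect: float = 1.0

    def to_yaml(self, path) -> None:
        Path(path).write_text(yaml.safe_dump(dataclasses.asdict(self)))

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        data = yaml.safe_load(Path(path).read_text())
        for key in ("daf_grid", "cadd_cutoffs"):
            if key in data and isinstance(data[key], list):
                data[key] = tuple(data[key])
        return cls(**data)


def _sha256(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()


class PipelineRun:
    """One run directory; stages write outputs and register them."""

    def __init__(self, config: PipelineConfig, outdir, force: bool = False):
        self.config = config
        self.outdir = Path(outdir)
        self.outdir.mkdir(parents=True, exist_ok=True)
        self.force = force
        self.manifest: dict[str, dict] = {}

    def path(self, name: str) -> Path:
        return self.outdir / name

    def done(self, *names: str) -> bool:
        return not self.force and all(self.path(n).exists() for n in names)

    def register(self, stage: str, *names: str) -> None:
        for n in names:
            self.manifest.setdefault(stage, {})[n] = _sha256(self.path(n))

    def write_manifest(self) -> None:
        self.config.to_yaml(self.path("config.yaml"))
        self.register("config", "config.yaml")
        self.path("manifest.json").write_text(
            json.dumps(self.manifest, indent=2, sort_keys=True))


def run_pipeline(config: PipelineConfig, outdir, force: bool = False) -> dict:
    """Run every stage on a synthetic panel; returns the result bundle.

    The bundle maps stage names to their main in-memory results (DataFrames);
    the same tables are written under ``outdir`` and listed, with checksums,
    in ``manifest.json``.
    """
    run = PipelineRun(config, outdir, force=force)
    cfg = config
    rng_seed = cfg.seed
    genome, features = toy_mito_genome(seed=rng_seed)

    # ---- simulate ----------------------------------------------------------
    scenario = TrioScenario(n_families=cfg.n_families, seed=rng_seed)
    pileups, truth = generate_trio_pileups(scenario, genome=genome)
    phenotypes = generate_phenotypes(cfg.n_families, cfg.carrier_effect,
                                     seed=rng_seed + 1)
    truth.to_tsv(run.path("truth_heteroplasmies.tsv"),
                 run.path("truth_consensus.tsv"))
    phenotypes.to_csv(run.path("phenotypes.tsv"), sep="\t", index=False)
    run.register("simulate", "truth_heteroplasmies.tsv", "truth_consensus.tsv",
                 "phenotypes.tsv")

    # ---- call --------------------------------------------------------------
    filtered = {s: [filter_reads(p, cfg.min_base_quality) for p in ps]
                for s, ps in pileups.items()}
    _, site_median = depth_summary(p for ps in filtered.values() for p in ps)
    valid = calling.valid_sites(site_median, cfg.min_site_median)

    het_calls: dict[str, dict[int, calling.HeteroplasmyCall]] = {}
    hom_calls: dict[str, dict[int, calling.HomoplasmyCall]] = {}
    for sample, ps in filtered.items():
        hets, homs = {}, {}
        for p in ps:
            call = calling.call_heteroplasmy(
                p, min_maf=cfg.min_maf, min_llr=cfg.min_llr,
                min_depth=cfg.min_depth, min_strand_p=cfg.min_strand_p,
                valid_site=bool(valid.get(p.position, False)))
            if call is not None:
                hets[p.position] = call
            hom = calling.call_homoplasmy(
                p, heteroplasmic=call is not None and call.high_confidence)
            if hom is not None:
                homs[p.position] = hom
        het_calls[sample], hom_calls[sample] = hets, homs

    calls_df = calling.calls_to_dataframe(
        c for hets in het_calls.values() for c in hets.values())
    homs_df = pd.DataFrame(
        [(h.sample, h.position, h.allele, h.supporting_reads)
         for homs in hom_calls.values() for h in homs.values()],
        columns=["sample", "position", "allele", "supporting_reads"])
    calls_df.to_csv(run.path("heteroplasmy_calls.tsv"), sep="\t", index=False)
    homs_df.to_csv(run.path("homoplasmy_calls.tsv"), sep="\t", index=False)
    run.register("call", "heteroplasmy_calls.tsv", "homoplasmy_calls.tsv")

    # ---- qc ----------------------------------------------------------------
    sample_mean, _ = depth_summary(p for ps in filtered.values() for p in ps)
    reports = qc.coverage_filter(sample_mean)
    hc2 = calls_df[(calls_df.high_confidence)
                   & (calls_df.maf_mle >= cfg.extended_min_maf)]
    hc2 = hc2.rename(columns={"minor": "minor"})[["sample", "position", "minor"]]
    poly = qc.polymorphic_sites(homs_df)
    for sample, rep in reports.items():
        if rep.verdict != qc.VERDICT_PASS:
            continue
        contam = qc.contamination_check(sample, hc2, homs_df, poly)
        if contam.verdict != qc.VERDICT_PASS:
            rep.verdict = contam.verdict
            rep.donor = contam.donor
        rep.n_polymorphic_hets = contam.n_polymorphic_hets
    qc_df = qc.reports_to_dataframe(reports)
    qc_df.to_csv(run.path("qc.tsv"), sep="\t", index=False)
    run.register("qc", "qc.tsv")

    fam_members = {}
    for sample in pileups:
        fam, role = sample.rsplit("-", 1)
        fam_members.setdefault(fam, {})[role] = sample
    fam_pass = {
        fam: all(reports[m].verdict == qc.VERDICT_PASS
                 for m in members.values())
        for fam, members in fam_members.items()}
    retained = sorted(f for f, ok in fam_pass.items() if ok)

    # ---- analyze -----------------------------------------------------------
    scores, disease = generate_score_table(genome, features, seed=rng_seed + 2)
    records_all = []
    summaries_by_family = {}
    for fam in retained:
        members = fam_members[fam]
        summaries = {role: families.site_summary(filtered[members[role]])
                     for role in ROLES}
        summaries_by_family[fam] = summaries
        ref_map = {pos: genome.base(pos)
                   for s in summaries.values() for pos in s.index}
        consensus = families.family_reference(summaries, ref=ref_map)
        rec = families.derive_mutations(
            fam, summaries,
            {role: het_calls[members[role]] for role in ROLES},
            {role: hom_calls[members[role]] for role in ROLES},
            consensus, min_daf=min(cfg.daf_grid))
        records_all.append(rec)
    records_all = [r for r in records_all if len(r)]
    records = (pd.concat(records_all, ignore_index=True) if records_all
               else pd.DataFrame(columns=["family", "role", "position",
                                          "allele", "daf", "heteroplasmic",
                                          "homoplasmic"]))
    records = families.private_mutations(records, summaries_by_family)

    annotated = ann.annotate(
        records[["position", "allele"]].itertuples(index=False, name=None),
        genome, features, scores=scores, disease=disease,
        polymorphic=qc.polymorphic_sites(homs_df))
    flags = ann.variants_to_dataframe(annotated)
    records = records.reset_index(drop=True)
    for col in ("region", "effect", "cadd15", "cadd20", "combined_prediction",
                "disease_associated", "polymorphic"):
        records[col] = flags[col].to_numpy() if len(flags) else []
    records["nonsynonymous"] = records.get("effect", pd.Series(dtype=object)) \
        .eq("nonsynonymous")
    records["synonymous"] = records.get("effect", pd.Series(dtype=object)) \
        .eq("synonymous")
    records.to_csv(run.path("mutations.tsv"), sep="\t", index=False)
    run.register("analyze", "mutations.tsv")

    reported = records[records["daf"] >= cfg.min_daf]
    burden_rows = []
    categories = [None, "nonsynonymous", "synonymous", "cadd15", "cadd20",
                  "combined_prediction"]
    for cat in categories:
        sub = reported if cat is None else reported[reported[cat]]
        counts = sub[sub.role.isin(families.CHILD_ROLES)] \
            .groupby(["family", "role"]).size()
        a = np.array([counts.get((f, "proband"), 0) for f in retained], float)
        b = np.array([counts.get((f, "sibling"), 0) for f in retained], float)
        res = families.burden_compare(a, b)
        burden_rows.append((cat or "all", res.mean_proband, res.mean_sibling,
                            res.p, res.degenerate))
    burden_df = pd.DataFrame(burden_rows, columns=[
        "category", "mean_proband", "mean_sibling", "p_one_tailed", "degenerate"])
    burden_df.to_csv(run.path("burden.tsv"), sep="\t", index=False)

    strata = families.stratify(
        phenotypes[phenotypes.family.isin(retained)])
    or_rows = []
    for stratum, fams in strata.items():
        for cat in ("nonsynonymous", "cadd15", "cadd20"):
            if not fams:
                continue
            res = families.carrier_table(reported, fams, cat)
            or_rows.append((stratum, cat, res.a, res.c, res.odds_ratio,
                            res.ci_low, res.ci_high, res.p_one_tailed))
    or_df = pd.DataFrame(or_rows, columns=[
        "stratum", "category", "proband_carriers", "sibling_carriers",
        "odds_ratio", "ci_low", "ci_high", "p_one_tailed"])
    or_df.to_csv(run.path("odds_ratios.tsv"), sep="\t", index=False)

    sens = families.sensitivity_ratio(records, retained,
                                      min_daf_grid=cfg.daf_grid,
                                      n_boot=min(cfg.n_boot, 2000),
                                      seed=rng_seed + 3)
    sens.to_csv(run.path("sensitivity.tsv"), sep="\t", index=False)
    run.register("analyze", "burden.tsv", "odds_ratios.tsv", "sensitivity.tsv")

    # ---- transmit ----------------------------------------------------------
    pair_rows = []
    for fam in retained:
        summaries = summaries_by_family[fam]
        fam_rec = records[records.family == fam]
        for child in families.CHILD_ROLES:
            keys = fam_rec[fam_rec.role.isin(["mother", child])]
            for (pos, allele), _ in keys.groupby(["position", "allele"]):
                daf_m = (float(summaries["mother"].at[pos, allele])
                         if pos in summaries["mother"].index else 0.0)
                daf_c = (float(summaries[child].at[pos, allele])
                         if pos in summaries[child].index else 0.0)
                pair_rows.append((fam, child, pos, allele, daf_m, daf_c))
    pairs = pd.DataFrame(pair_rows, columns=[
        "family", "child_role", "position", "allele", "daf_mother", "daf_child"])
    trans_records = transmission.build_records(pairs)
    trans_df = transmission.records_to_dataframe(trans_records)
    trans_df.to_csv(run.path("transmission.tsv"), sep="\t", index=False)
    run.register("transmit", "transmission.tsv")

    # ---- report ------------------------------------------------------------
    lines = ["mthet synthetic-panel report",
             f"families retained: {len(retained)}/{cfg.n_families}",
             "",
             "Carrier odds ratios (private mutations, proband vs sibling):",
             or_df.to_string(index=False),
             "",
             "Burden (mean mutations per child, one-tailed paired t):",
             burden_df.to_string(index=False),
             "",
             "Transmission status counts:",
             trans_df["status"].value_counts().to_string() if len(trans_df)
             else "(no records)"]
    run.path("report.txt").write_text("\n".join(lines) + "\n")
    run.register("report", "report.txt")
    run.write_manifest()

    return {"config": cfg, "truth": truth, "calls": calls_df,
            "homoplasmies": homs_df, "qc": qc_df, "records": records,
            "burden": burden_df, "odds_ratios": or_df, "sensitivity": sens,
            "transmission": trans_df, "retained_families": retained}
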