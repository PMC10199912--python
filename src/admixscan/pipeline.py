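"""Orchestrate QC -> polarize -> scans -> combine -> LAD -> classify as one
configured, logged, reproducible run.

Every stage writes its table under the run directory and the manifest
records the configuration, library versions, seed and per-stage row counts,
so a rerun with identical inputs and seed is byte-identical.
"""

from __future__ import annotations

import dataclasses
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__, ancestryscan, genio, outliers, selstats
from .core import CandidateRegion, InvalidConfigError

log = logging.getLogger(__name__)


@dataclass
class Thresholds:
    q_fst_xpehh: float = 0.01
    q_ihs: float = 0.001
    lad: float = 4.42
    llrt: float = 15.0
    qc_max_missing: float = 0.10
    qc_hwe_min_p: float = 1e-8
    qc_maf_min: float = 0.05
    region_gap_bp: int = 200_000

    def validate(self) -> None:
        for name in ("q_fst_xpehh", "q_ihs"):
            v = getattr(self, name)
            if not (0 < v <= 0.5):
                raise InvalidConfigError(f"{name} must lie in (0, 0.5], got {v}")
        if not (0 <= self.qc_max_missing <= 1) or not (0 <= self.qc_maf_min <= 0.5):
            raise InvalidConfigError("QC thresholds out of range")
        if self.lad <= 0 or self.region_gap_bp < 0:
            raise InvalidConfigError("lad threshold and region gap must be positive")


@dataclass
class RunConfig:
    vcf: str = ""
    populations: str = ""
    groups: str = ""
    tracts: str | None = None
    genes: str | None = None
    llrt_table: str | None = None
    chrom_length_bp: int | None = None
    target_group: str = "target"
    target_subgroups: list[str] = field(default_factory=list)
    source_groups: list[str] = field(default_factory=list)
    ancestries: list[str] = field(default_factory=list)
    thresholds: Thresholds = field(default_factory=Thresholds)
    seed: int = 0
    outdir: str = "run"

    def validate(self) -> None:
        self.thresholds.validate()
        if not self.vcf or not self.populations:
            raise InvalidConfigError("vcf and populations paths are required")


def load_config(path) -> RunConfig:
    """Load a YAML run configuration; defaults fill missing thresholds and
    unknown keys are rejected."""
    with open(path) as fh:
        raw = yaml.safe_load(fh) or {}
    known = {f.name for f in dataclasses.fields(RunConfig)}
    unknown = set(raw) - known
    if unknown:
        raise InvalidConfigError(f"unknown config keys: {sorted(unknown)}")
    th_raw = raw.pop("thresholds", {}) or {}
    th_known = {f.name for f in dataclasses.fields(Thresholds)}
    th_unknown = set(th_raw) - th_known
    if th_unknown:
        raise InvalidConfigError(f"unknown threshold keys: {sorted(th_unknown)}")
    cfg = RunConfig(**raw, thresholds=Thresholds(**th_raw))
    cfg.validate()
    return cfg


def dump_config(cfg: RunConfig, path) -> None:
    d = dataclasses.asdict(cfg)
    with open(path, "w") as fh:
        yaml.safe_dump(d, fh, sort_keys=True)


def _regions_df(regions: list[CandidateRegion]) -> pd.DataFrame:
    rows = []
    for r in regions:
        rows.append(
            {
                "chrom": r.chrom,
                "start": r.start,
                "end": r.end,
                "group": r.group,
                "tests": ",".join(r.tests),
                "n_sites": len(r.sites),
                "genes": ",".join(r.genes),
                "labels": ",".join(r.labels),
            }
        )
    return pd.DataFrame(rows, columns=["chrom", "start", "end", "group", "tests", "n_sites", "genes", "labels"])


def run_full_scan(cfg: RunConfig) -> dict:
    """Execute the full scan and return the manifest dictionary."""
    cfg.validate()
    out = Path(cfg.outdir)
    out.mkdir(parents=True, exist_ok=True)
    th = cfg.thresholds
    counts: dict[str, int] = {}

    def _stage(name):
        log.info("stage: %s", name)

    _stage("load")
    hm, vt = genio.read_vcf(cfg.vcf)
    spec = genio.read_population_spec(cfg.populations, cfg.groups or None)
    counts["input_sites"] = hm.n_sites

    _stage("qc")
    qc_th = genio.QCThresholds(th.qc_max_missing, th.qc_hwe_min_p, th.qc_maf_min)
    hm, vt, qc_report = genio.apply_qc_filters(hm, vt, spec, qc_th)
    pd.DataFrame([qc_report]).to_csv(out / "qc_report.tsv", sep="\t", index=False)
    counts.update({f"qc_{k}": v for k, v in qc_report.items()})

    _stage("polarize")
    hm, vt, dropped = genio.polarize_to_ancestral(hm, vt)
    counts["polarize_dropped"] = int(dropped.size)
    counts["scanned_sites"] = hm.n_sites

    sources = cfg.source_groups or [g for g in spec.groups if g.startswith("source_")]
    target_mat = hm.take_samples(spec.group_samples(cfg.target_group))
    gap = th.region_gap_bp

    scan_results: dict[str, list[CandidateRegion]] = {cfg.target_group: []}
    _stage("differentiation scans")
    for src in sources:
        fst = selstats.weir_cockerham_fst(hm, spec, cfg.target_group, src)
        src_mat = hm.take_samples(spec.group_samples(src))
        xp = selstats.xpehh_scan(target_mat, src_mat, vt)
        fst.table.to_csv(out / f"fst_{src}.tsv", sep="\t", index=False, float_format="%.10g")
        xp.table.to_csv(out / f"xpehh_{src}.tsv", sep="\t", index=False, float_format="%.10g")
        combined = outliers.combine_differentiation_scans(fst, xp, th.q_fst_xpehh)
        combined.to_csv(out / f"combined_{src}.tsv", sep="\t", index=False, float_format="%.10g")
        counts[f"combined_{src}"] = len(combined)
        regs = outliers.merge_outliers_into_regions(
            combined["pos"].to_numpy(), hm.chrom, gap, test=f"FST-XPEHH_vs_{src}", group=cfg.target_group
        )
        scan_results[cfg.target_group].extend(regs)

    # the same F_ST + XP-EHH pair between the putative sources themselves:
    # a sweep that happened in a source shows up here, which is what lets a
    # target signal be recognized as shared rather than private
    for i, src_a in enumerate(sources):
        for src_b in sources[i + 1:]:
            fst = selstats.weir_cockerham_fst(hm, spec, src_a, src_b)
            xp = selstats.xpehh_scan(
                hm.take_samples(spec.group_samples(src_a)),
                hm.take_samples(spec.group_samples(src_b)),
                vt,
            )
            combined = outliers.combine_differentiation_scans(fst, xp, th.q_fst_xpehh)
            combined.to_csv(
                out / f"combined_{src_a}_vs_{src_b}.tsv", sep="\t", index=False, float_format="%.10g"
            )
            counts[f"combined_{src_a}_vs_{src_b}"] = len(combined)
            # which source drove the signal is not resolved by a two-way
            # comparison, so the regions are attributed to both
            for grp in (src_a, src_b):
                regs = outliers.merge_outliers_into_regions(
                    combined["pos"].to_numpy(), hm.chrom, gap,
                    test=f"FST-XPEHH_{src_a}_vs_{src_b}", group=grp,
                )
                scan_results.setdefault(grp, []).extend(regs)

    _stage("iHS scans")
    ihs_groups = (cfg.target_subgroups or [cfg.target_group]) + sources
    for grp in ihs_groups:
        mat = hm.take_samples(spec.group_samples(grp))
        ihs = selstats.ihs_scan(mat, vt)
        ihs.table.to_csv(out / f"ihs_{grp}.tsv", sep="\t", index=False, float_format="%.10g")
        top = outliers.top_fraction_outliers(ihs, "abs", th.q_ihs)
        counts[f"ihs_top_{grp}"] = len(top.table)
        regs = outliers.merge_outliers_into_regions(
            top.table["pos"].to_numpy(), hm.chrom, gap, test="iHS", group=grp
        )
        key = cfg.target_group if grp in (cfg.target_subgroups or [cfg.target_group]) else grp
        scan_results.setdefault(key, []).extend(regs)

    if cfg.llrt_table:
        _stage("external ancestry-component scan")
        llrt = outliers.load_llrt_table(cfg.llrt_table, th.llrt)
        counts["llrt_hits"] = len(llrt)
        regs = outliers.merge_outliers_into_regions(
            llrt["pos"].to_numpy(), hm.chrom, gap, test="LLRT", group=cfg.target_group
        )
        scan_results[cfg.target_group].extend(regs)

    lad_regions: list[CandidateRegion] = []
    if cfg.tracts:
        _stage("LAD")
        if cfg.chrom_length_bp is None:
            raise InvalidConfigError("chrom_length_bp required with tract input")
        tracts = genio.read_tracts(cfg.tracts, cfg.chrom_length_bp)
        labels = cfg.ancestries or sorted(set(tracts.table["ancestry"]))
        profile = ancestryscan.tracts_to_locus_dosage(tracts, hm.positions, labels, hm.chrom)
        lad = ancestryscan.lad_scan(profile)
        lad.table.to_csv(out / "lad.tsv", sep="\t", index=False, float_format="%.10g")
        lad_regions = ancestryscan.extract_lad_regions(lad, th.lad, gap)
        _regions_df(lad_regions).to_csv(out / "lad_regions.tsv", sep="\t", index=False)
        counts["lad_regions"] = len(lad_regions)

    _stage("classify")
    genes = outliers.read_genes_bed(cfg.genes) if cfg.genes else None
    classified = outliers.classify_candidate_signals(
        scan_results, lad_regions, target_groups=[cfg.target_group]
    )
    if genes is not None:
        outliers.annotate_regions_with_genes(classified, genes)
    cls_df = _regions_df(classified)
    cls_rows = []
    for r in classified:
        for lab in r.labels:
            cls_rows.append({"chrom": r.chrom, "start": r.start, "end": r.end,
                             "tests": ",".join(r.tests), "label": lab, "genes": ",".join(r.genes)})
    pd.DataFrame(cls_rows, columns=["chrom", "start", "end", "tests", "label", "genes"]).to_csv(
        out / "classification.tsv", sep="\t", index=False
    )
    counts["classified_regions"] = len(classified)
    counts["post_admixture_labels"] = sum("post_admixture" in r.labels for r in classified)
    cls_df.to_csv(out / "candidate_regions.tsv", sep="\t", index=False)

    manifest = {
        "package": "admixscan",
        "version": __version__,
        "libs": {"numpy": np.__version__, "pandas": pd.__version__},
        "seed": cfg.seed,
        "config": dataclasses.asdict(cfg),
        "counts": counts,
    }
    with open(out / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=1, sort_keys=True)
    return manifest
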