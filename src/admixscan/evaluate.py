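"""End-to-end evaluation chains on simulated scenarios.

These functions wire the simulator to the scan stack exactly the way the
pipeline does, and are used by the validation suite to measure calibration
(neutral scenarios) and power/localization (sweep scenarios) against the
simulator's ground truth.
"""

from __future__ import annotations

import dataclasses

import numpy as np

from . import ancestryscan as anc
from . import outliers as ol
from . import selstats as ss
from . import simdata as sd
from .core import CandidateRegion, HaplotypeMatrix, PopulationSpec

LOCALIZE_BP = 100_000
REGION_GAP = ol.REGION_GAP_BP


def combined_cohort(bundle: sd.ScenarioBundle) -> tuple[HaplotypeMatrix, PopulationSpec]:
    """Stack the target and all source pools into one matrix with a
    population spec (population 'target' plus one per source label)."""
    mats = [("target", bundle.target)] + list(bundle.sources.items())
    alleles = np.vstack([m.alleles for _, m in mats])
    ids: list[str] = []
    smap: dict[str, tuple[int, int]] = {}
    assign: dict[str, str] = {}
    off = 0
    for lab, m in mats:
        ids.extend(m.haplotype_ids)
        for s, (a, b) in m.sample_map.items():
            smap[s] = (a + off, b + off)
            assign[s] = "target" if lab == "target" else lab
        off += m.n_haplotypes
    hm = HaplotypeMatrix(alleles, bundle.target.positions, bundle.target.chrom, ids, smap)
    return hm, PopulationSpec(assign)


def differentiation_regions(
    bundle: sd.ScenarioBundle,
    sources: tuple[str, ...] = ("EUR", "WEA"),
    q: float = 0.01,
) -> tuple[list[CandidateRegion], dict[str, list[CandidateRegion]], list]:
    """Target-vs-source and source-vs-source combined F_ST + XP-EHH scans.

    Returns (target regions, per-source regions, combined target tables).
    """
    hm, spec = combined_cohort(bundle)
    target_regions: list[CandidateRegion] = []
    source_regions: dict[str, list[CandidateRegion]] = {s: [] for s in sources}
    tables = []
    for src in sources:
        fst = ss.weir_cockerham_fst(hm, spec, "target", src)
        xp = ss.xpehh_scan(bundle.target, bundle.sources[src], bundle.variants)
        comb = ol.combine_differentiation_scans(fst, xp, q)
        tables.append(comb)
        if len(comb):
            target_regions += ol.merge_outliers_into_regions(
                comb["pos"].to_numpy(), hm.chrom, REGION_GAP,
                test=f"FST-XPEHH_vs_{src}", group="target",
            )
    for i, a in enumerate(sources):
        for b in sources[i + 1:]:
            fst = ss.weir_cockerham_fst(hm, spec, a, b)
            xp = ss.xpehh_scan(bundle.sources[a], bundle.sources[b], bundle.variants)
            comb = ol.combine_differentiation_scans(fst, xp, q)
            if len(comb):
                for grp in (a, b):
                    source_regions[grp] += ol.merge_outliers_into_regions(
                        comb["pos"].to_numpy(), hm.chrom, REGION_GAP,
                        test=f"FST-XPEHH_{a}_vs_{b}", group=grp,
                    )
    return target_regions, source_regions, tables


def neutral_lad_and_labels(seed: int, n_sites: int = 2000) -> tuple[float, int]:
    """Neutral scenario: fraction of SNPs with |LAD| > 4.42 and the number
    of post-admixture classifications produced by the full chain."""
    cfg = sd.SimulationConfig(seed=seed, n_sites=n_sites)
    bundle = sd.simulate_scenario("neutral", cfg)
    prof = anc.tracts_to_locus_dosage(
        bundle.tracts, bundle.target.positions, list(cfg.ancestries), cfg.chrom
    )
    lad = anc.lad_scan(prof)
    frac = float((np.abs(lad.table["lad"]) > anc.LAD_THRESHOLD).mean())
    lad_regions = anc.extract_lad_regions(lad)
    target_regions, source_regions, _ = differentiation_regions(bundle)
    labeled = ol.classify_candidate_signals(
        {"target": target_regions, **source_regions}, lad_regions, ["target"]
    )
    n_post = sum("post_admixture" in r.labels for r in labeled)
    return frac, n_post


def private_sweep_localized(seed: int, q: float = 0.001, within_bp: int = LOCALIZE_BP) -> bool:
    """Private-sweep scenario: is a SNP within ``within_bp`` of the sweep
    locus among the top-``q`` |iHS| outliers of the target cohort?"""
    cfg = sd.SimulationConfig(seed=seed)
    bundle = sd.simulate_scenario("private_sweep", cfg)
    ihs = ss.ihs_scan(bundle.target, bundle.variants)
    top = ol.top_fraction_outliers(ihs, "abs", q)
    d = np.abs(top.table["pos"].to_numpy() - bundle.truth["sweep_pos"])
    return bool((d <= within_bp).any())


def post_admixture_peak_lad(seed: int, n_companions: int = 11) -> float:
    """Post-admixture scenario: peak |LAD| of the favored ancestry on the
    selected chromosome, standardized against a genome-wide background of
    additional neutral chromosomes simulated under the same demography."""
    cfg = sd.SimulationConfig(seed=seed)
    bundle = sd.simulate_scenario("post_admixture_sweep", cfg)
    sweep = sd.SweepConfig(**bundle.truth["config"]["sweep"])
    g_total = cfg.generations_since_admixture + sweep.generations
    profiles = [
        anc.tracts_to_locus_dosage(
            bundle.tracts, bundle.target.positions, list(cfg.ancestries), "1"
        )
    ]
    rng = np.random.default_rng(seed + 500_000)
    for k in range(n_companions):
        ncfg = dataclasses.replace(cfg, generations_since_admixture=g_total)
        tracts = sd.simulate_ancestry_tracts(ncfg, rng, n_haplotypes=2 * cfg.cohort_size)
        pos = np.sort(rng.choice(cfg.chrom_length_bp, cfg.n_sites, replace=False))
        profiles.append(
            anc.tracts_to_locus_dosage(tracts, pos, list(cfg.ancestries), str(k + 2))
        )
    lad = anc.lad_scan_genome(profiles)
    fav = bundle.truth["component"]
    sub = lad.table[(lad.table["ancestry"] == fav) & (lad.table["chrom"] == "1")]
    return float(np.abs(sub["lad"]).max())


def shared_sweep_detected_and_classified(seed: int) -> tuple[bool, bool]:
    """Shared-sweep scenario: (sweep region present in the combined
    F_ST/XP-EHH outlier set, overlapping target region classified shared)."""
    cfg = sd.SimulationConfig(seed=seed)
    bundle = sd.simulate_scenario("shared_sweep", cfg)
    sp = bundle.truth["sweep_pos"]
    target_regions, source_regions, tables = differentiation_regions(bundle)
    detected = any(
        len(t) and (np.abs(t["pos"].to_numpy() - sp) <= REGION_GAP).any() for t in tables
    )
    comp = bundle.truth["component"]
    ihs_src = ss.ihs_scan(bundle.sources[comp], bundle.variants)
    top = ol.top_fraction_outliers(ihs_src, "abs", 0.001)
    source_regions[comp] += ol.merge_outliers_into_regions(
        top.table["pos"].to_numpy(), "1", REGION_GAP, test="iHS", group=comp
    )
    labeled = ol.classify_candidate_signals(
        {"target": target_regions, **source_regions}, [], ["target"]
    )
    shared = any(
        any(lab.startswith("shared_with") for lab in r.labels)
        and r.start <= sp < r.end
        for r in labeled
    )
    return detected, shared
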