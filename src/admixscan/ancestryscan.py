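"""Local-ancestry deviation (LAD) scanning.

Per-SNP ancestry dosages are the fraction of haplotypes whose covering tract
carries each ancestry label. The LAD statistic standardizes each ancestry's
dosage by its genome-wide mean and empirical SD across sites; loci where an
ancestry deviates beyond ``|LAD| > 4.42`` are flagged as putative targets of
post-admixture selection. The genome-wide empirical SD treats the scanned
sites as the calibration background, so the statistic behaves as a z-score
whose threshold is inherited from the published calibration rather than
re-derived here.
"""

from __future__ import annotations

import logging

import numpy as np
import pandas as pd

from .core import AncestryTractSet, CandidateRegion, LocusAncestryProfile, ScanScores
from .outliers import REGION_GAP_BP, merge_outliers_into_regions

log = logging.getLogger(__name__)

LAD_THRESHOLD = 4.42


def tracts_to_locus_dosage(
    tracts: AncestryTractSet,
    positions: np.ndarray,
    labels: list[str],
    chrom: str = "1",
) -> LocusAncestryProfile:
    """Per-site ancestry dosage fractions from per-haplotype tracts.

    Every haplotype's tracts must tile the chromosome; a position not
    covered by some haplotype raises.
    """
    positions = np.asarray(positions, dtype=np.int64)
    haps = tracts.haplotype_ids()
    counts = np.zeros((len(labels), positions.size), dtype=np.int64)
    lab_index = {lab: k for k, lab in enumerate(labels)}
    for hap, sub in tracts.table.groupby("haplotype_id", sort=False):
        ends = sub["end"].to_numpy()
        labs = sub["ancestry"].to_numpy()
        idx = np.searchsorted(ends, positions, side="right")
        if idx.size and (idx[-1] >= ends.size or positions[0] < sub["start"].to_numpy()[0]):
            raise ValueError(f"haplotype {hap}: positions outside tract coverage")
        for k, lab in enumerate(labels):
            counts[k] += labs[idx] == lab
        unknown = set(labs) - set(labels)
        if unknown:
            raise ValueError(f"haplotype {hap}: unknown ancestry labels {sorted(unknown)}")
    alpha = counts / float(len(haps))
    return LocusAncestryProfile(list(labels), positions, alpha, len(haps), chrom)


def lad_scan(profile: LocusAncestryProfile) -> ScanScores:
    """Local ancestry deviation: ``LAD_k(s) = (alpha_k(s) - mean_k) / sd_k``.

    Ancestries with zero dosage variance across sites are skipped (logged);
    fewer than 100 sites triggers a warning because the empirical SD is then
    unstable.
    """
    if profile.positions.size < 100:
        log.warning("lad_scan: only %d sites; genome-wide SD is unstable", profile.positions.size)
    mu = profile.genome_mean
    sd = profile.genome_sd
    frames = []
    meta = {"mean": {}, "sd": {}, "skipped": []}
    for k, lab in enumerate(profile.labels):
        if sd[k] == 0:
            log.info("lad_scan: ancestry %s has zero dosage variance; skipped", lab)
            meta["skipped"].append(lab)
            continue
        z = (profile.alpha[k] - mu[k]) / sd[k]
        frames.append(
            pd.DataFrame(
                {
                    "chrom": profile.chrom,
                    "pos": profile.positions,
                    "ancestry": lab,
                    "dosage": profile.alpha[k],
                    "lad": z,
                }
            )
        )
        meta["mean"][lab] = float(mu[k])
        meta["sd"][lab] = float(sd[k])
    table = pd.concat(frames, ignore_index=True) if frames else pd.DataFrame(
        columns=["chrom", "pos", "ancestry", "dosage", "lad"]
    )
    return ScanScores("LAD", table, meta)


def lad_scan_genome(profiles: list[LocusAncestryProfile]) -> ScanScores:
    """LAD across several chromosomes standardized by the pooled genome-wide
    mean and SD per ancestry.

    The 4.42 threshold is calibrated against a genome-wide background; when
    the scanned region is a single short chromosome carrying a wide selected
    tract, that chromosome's own dosage moments are contaminated by the
    signal, so multi-chromosome standardization is the faithful usage.
    """
    if not profiles:
        raise ValueError("at least one profile required")
    labels = profiles[0].labels
    for p in profiles[1:]:
        if p.labels != labels:
            raise ValueError("profiles must share the ancestry label set")
    alpha = np.concatenate([p.alpha for p in profiles], axis=1)
    mu = alpha.mean(axis=1)
    sd = alpha.std(axis=1)
    frames = []
    meta = {"mean": {}, "sd": {}, "skipped": []}
    for k, lab in enumerate(labels):
        if sd[k] == 0:
            log.info("lad_scan_genome: ancestry %s has zero variance; skipped", lab)
            meta["skipped"].append(lab)
            continue
        for p in profiles:
            z = (p.alpha[k] - mu[k]) / sd[k]
            frames.append(
                pd.DataFrame(
                    {
                        "chrom": p.chrom,
                        "pos": p.positions,
                        "ancestry": lab,
                        "dosage": p.alpha[k],
                        "lad": z,
                    }
                )
            )
        meta["mean"][lab] = float(mu[k])
        meta["sd"][lab] = float(sd[k])
    table = pd.concat(frames, ignore_index=True) if frames else pd.DataFrame(
        columns=["chrom", "pos", "ancestry", "dosage", "lad"]
    )
    return ScanScores("LAD", table, meta)


def extract_lad_regions(
    lad: ScanScores,
    threshold: float = LAD_THRESHOLD,
    gap_bp: int = REGION_GAP_BP,
) -> list[CandidateRegion]:
    """Merge sites with ``|LAD| > threshold`` into candidate regions, one
    set per deviated ancestry, each tagged with its peak dosage and peak
    |LAD|."""
    regions: list[CandidateRegion] = []
    tab = lad.table
    for (lab, chrom), sub in tab.groupby(["ancestry", "chrom"], sort=True):
        hits = sub[np.abs(sub["lad"]) > threshold]
        if hits.empty:
            continue
        merged = merge_outliers_into_regions(
            hits["pos"].to_numpy(), chrom=str(chrom), gap_bp=gap_bp,
            test="LAD", group=str(lab),
        )
        for r in merged:
            members = hits[hits["pos"].isin(r.sites)]
            peak = members.loc[members["lad"].abs().idxmax()]
            r.info = {
                "ancestry": lab,
                "peak_lad": float(peak["lad"]),
                "peak_dosage": float(peak["dosage"]),
            }
            regions.append(r)
    return regions


def prioritize_lad_variants(
    region: CandidateRegion,
    variants: pd.DataFrame,
    freqs: dict[str, np.ndarray],
    source_a: str,
    source_b: str,
    score_table: pd.DataFrame | None = None,
    score_min: float = 10.0,
) -> pd.DataFrame:
    """Rank variants inside a LAD region by source-frequency contrast.

    Sites are ordered by ``|freq_sourceA - freq_sourceB|`` descending; when a
    functional-score table (columns ``id``, ``score``) is supplied, sites
    scoring at or below ``score_min`` are removed before ranking.
    """
    for g in (source_a, source_b):
        if g not in freqs:
            raise ValueError(f"unknown source group {g!r}")
    pos = variants["pos"].to_numpy()
    inside = (pos >= region.start) & (pos < region.end)
    df = variants.loc[inside, ["id", "chrom", "pos"]].copy()
    df["freq_a"] = np.asarray(freqs[source_a])[inside]
    df["freq_b"] = np.asarray(freqs[source_b])[inside]
    df["abs_dfreq"] = np.abs(df["freq_a"] - df["freq_b"])
    if score_table is not None:
        smap = dict(zip(score_table["id"], score_table["score"]))
        df["score"] = df["id"].map(smap)
        df = df[df["score"].notna() & (df["score"] > score_min)]
    df = df.sort_values(["abs_dfreq", "pos"], ascending=[False, True], kind="stable").reset_index(drop=True)
    return df
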