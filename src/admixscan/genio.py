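"""File I/O and data hygiene: VCF and tract round-trips, QC, pruning, polarization.

The QC defaults mirror a common array-data protocol for selection scans:
biallelic SNPs only, per-site missingness at most 10%, a per-population exact
Hardy-Weinberg test at the 1e-8 level, and a minor-allele-frequency floor of
0.05 computed on the samples actually under analysis.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass

import numpy as np
import pandas as pd
import yaml
from cyvcf2 import VCF

from .core import (
    MISSING,
    AncestryTractSet,
    HaplotypeMatrix,
    PopulationSpec,
    new_variant_table,
)

log = logging.getLogger(__name__)


# ---------------------------------------------------------------------------
# VCF
# ---------------------------------------------------------------------------

def read_vcf(path, samples: list[str] | None = None) -> tuple[HaplotypeMatrix, pd.DataFrame]:
    """Load phased biallelic SNPs from a VCF into a haplotype matrix.

    Unphased or half-missing genotypes are recorded as missing in *both*
    haplotypes of the sample. Multiallelic records and indels are skipped
    (the number skipped is logged). The ancestral allele is taken from the
    ``AA`` INFO field when present, else set to ``"N"``.
    """
    vcf = VCF(str(path), samples=samples, gts012=False)
    found = list(vcf.samples)
    if samples is not None:
        missing = [s for s in samples if s not in found]
        if missing:
            raise ValueError(f"samples absent from VCF: {missing}")
    if not found:
        raise ValueError("no samples selected from VCF")

    cols: list[np.ndarray] = []
    pos: list[int] = []
    ids: list[str] = []
    ref: list[str] = []
    alt: list[str] = []
    anc: list[str] = []
    chrom = None
    n_skipped = 0
    for v in vcf:
        if len(v.ALT) != 1 or not v.is_snp:
            n_skipped += 1
            continue
        if chrom is None:
            chrom = v.CHROM
        col = np.empty(2 * len(found), dtype=np.int8)
        for i, g in enumerate(v.genotypes):
            a, b, phased = g[0], g[1], g[-1]
            if a < 0 or b < 0 or not phased:
                col[2 * i] = MISSING
                col[2 * i + 1] = MISSING
            else:
                col[2 * i] = a
                col[2 * i + 1] = b
        cols.append(col)
        pos.append(v.POS - 1)  # to 0-based
        ids.append(v.ID or f"{v.CHROM}:{v.POS}")
        ref.append(v.REF)
        alt.append(v.ALT[0])
        aa = v.INFO.get("AA")
        anc.append(str(aa).upper() if aa is not None else "N")
    if n_skipped:
        log.info("read_vcf: skipped %d multiallelic/indel records", n_skipped)
    if chrom is None:
        chrom = "1"
    alleles = np.column_stack(cols) if cols else np.empty((2 * len(found), 0), dtype=np.int8)
    hap_ids = [f"{s}_{h}" for s in found for h in ("A", "B")]
    smap = {s: (2 * i, 2 * i + 1) for i, s in enumerate(found)}
    hm = HaplotypeMatrix(alleles, np.asarray(pos, dtype=np.int64), chrom, hap_ids, smap)
    vt = new_variant_table(chrom, np.asarray(pos, dtype=np.int64), ids, ref, alt, anc)
    return hm, vt


def write_vcf(hm: HaplotypeMatrix, vt: pd.DataFrame, path, contig_length: int | None = None) -> None:
    """Write a haplotype matrix as a phased VCF v4.2 text file.

    The ancestral allele is emitted in the ``AA`` INFO field for sites where
    it is known (``aa != "N"``); missing haplotypes become ``.|.``.
    """
    samples = hm.samples
    with open(path, "w") as fh:
        fh.write("##fileformat=VCFv4.2\n")
        fh.write('##INFO=<ID=AA,Number=1,Type=String,Description="Ancestral allele">\n')
        fh.write('##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">\n')
        if contig_length is not None:
            fh.write(f"##contig=<ID={hm.chrom},length={contig_length}>\n")
        else:
            fh.write(f"##contig=<ID={hm.chrom}>\n")
        fh.write("#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t" + "\t".join(samples) + "\n")
        rows = [hm.sample_map[s] for s in samples]
        for j in range(hm.n_sites):
            rec = vt.iloc[j]
            info = f"AA={rec['aa']}" if rec["aa"] != "N" else "."
            gts = []
            col = hm.alleles[:, j]
            for a, b in rows:
                if col[a] < 0 or col[b] < 0:
                    gts.append(".|.")
                else:
                    gts.append(f"{col[a]}|{col[b]}")
            fh.write(
                f"{hm.chrom}\t{int(hm.positions[j]) + 1}\t{rec['id']}\t{rec['ref']}\t{rec['alt']}"
                f"\t.\tPASS\t{info}\tGT\t" + "\t".join(gts) + "\n"
            )


# ---------------------------------------------------------------------------
# Population spec / tracts
# ---------------------------------------------------------------------------

def read_population_spec(assignments_path, groups_path=None) -> PopulationSpec:
    """Read sample->population TSV plus optional YAML group definitions."""
    df = pd.read_csv(assignments_path, sep="\t", header=None, names=["sample", "population"], dtype=str)
    assignments = dict(zip(df["sample"], df["population"]))
    groups: dict[str, list[str]] = {}
    if groups_path is not None:
        with open(groups_path) as fh:
            raw = yaml.safe_load(fh) or {}
        groups = {str(k): [str(p) for p in v] for k, v in raw.items()}
    return PopulationSpec(assignments, groups)


def write_population_spec(spec: PopulationSpec, assignments_path, groups_path=None) -> None:
    with open(assignments_path, "w") as fh:
        for s, p in spec.assignments.items():
            fh.write(f"{s}\t{p}\n")
    if groups_path is not None:
        with open(groups_path, "w") as fh:
            yaml.safe_dump({k: list(v) for k, v in spec.groups.items()}, fh, sort_keys=True)


def read_tracts(path, chrom_length: int) -> AncestryTractSet:
    """Read per-haplotype ancestry tracts (TSV, 0-based half-open intervals)."""
    df = pd.read_csv(
        path,
        sep="\t",
        dtype={"haplotype_id": str, "chrom": str, "start": np.int64, "end": np.int64, "ancestry": str},
    )
    return AncestryTractSet(df, chrom_length)


def write_tracts(tracts: AncestryTractSet, path) -> None:
    tracts.table.to_csv(path, sep="\t", index=False)


# ---------------------------------------------------------------------------
# Hardy-Weinberg exact test
# ---------------------------------------------------------------------------

def hwe_exact_test(n_hom_ref: int, n_het: int, n_hom_alt: int) -> float:
    """Two-sided exact Hardy-Weinberg test on diploid genotype counts.

    Conditional on the observed allele counts, the heterozygote count ``h``
    follows ``P(h) proportional to 2**h * n! / (n_AA! h! n_aa!)``; the p-value
    sums the probabilities of all ``h`` (same parity as the minor-allele
    count) whose probability does not exceed that of the observed count.
    """
    if min(n_hom_ref, n_het, n_hom_alt) < 0:
        raise ValueError("genotype counts must be non-negative")
    n = n_hom_ref + n_het + n_hom_alt
    if n < 1:
        raise ValueError("at least one genotyped individual required")
    n_alt = 2 * n_hom_alt + n_het
    n_minor = min(n_alt, 2 * n - n_alt)
    if n_minor == 0:
        return 1.0
    hs = np.arange(n_minor % 2, n_minor + 1, 2)
    # log P(h) up to the common normalizer; counts of the two homozygotes
    # follow from fixed allele totals.
    n_aa = (n_minor - hs) // 2
    n_AA = n - n_aa - hs
    logp = (
        hs * math.log(2.0)
        - _lgamma_arr(n_AA + 1)
        - _lgamma_arr(hs + 1)
        - _lgamma_arr(n_aa + 1)
    )
    logp -= logp.max()
    p = np.exp(logp)
    p /= p.sum()
    h_obs = n_het
    p_obs = p[hs == h_obs]
    if p_obs.size == 0:
        raise ValueError("observed heterozygote count inconsistent with allele counts")
    return float(min(1.0, p[p <= p_obs[0] * (1 + 1e-12)].sum()))


def _lgamma_arr(x: np.ndarray) -> np.ndarray:
    return np.array([math.lgamma(float(v)) for v in x])


# ---------------------------------------------------------------------------
# QC filters
# ---------------------------------------------------------------------------

@dataclass
class QCThresholds:
    max_missing: float = 0.10
    hwe_min_p: float = 1e-8
    maf_min: float = 0.05


def apply_qc_filters(
    hm: HaplotypeMatrix,
    vt: pd.DataFrame,
    spec: PopulationSpec,
    thresholds: QCThresholds | None = None,
) -> tuple[HaplotypeMatrix, pd.DataFrame, dict[str, int]]:
    """Apply site filters in order: missingness, per-population HWE, MAF.

    A site is counted against the *first* filter it fails. A site fails HWE
    if any population's exact test is below the threshold. MAF is computed
    over all samples in ``spec`` (the subset under analysis).
    """
    th = thresholds or QCThresholds()
    n_sites = hm.n_sites
    keep = np.ones(n_sites, dtype=bool)
    report = {"input": n_sites, "missingness": 0, "hwe": 0, "maf": 0}

    miss = (hm.alleles < 0).mean(axis=0)
    fail_miss = miss > th.max_missing

    fail_hwe = np.zeros(n_sites, dtype=bool)
    if th.hwe_min_p > 0:
        for pop in spec.populations():
            samples = [s for s, p in spec.assignments.items() if p == pop]
            rows = [hm.sample_map[s] for s in samples]
            a = hm.alleles[[r[0] for r in rows]]
            b = hm.alleles[[r[1] for r in rows]]
            ok = (a >= 0) & (b >= 0)
            dose = np.where(ok, a + b, -9)
            for j in np.flatnonzero(~fail_hwe):
                col = dose[:, j]
                n_AA = int((col == 0).sum())
                n_Aa = int((col == 1).sum())
                n_aa = int((col == 2).sum())
                if n_AA + n_Aa + n_aa == 0:
                    continue
                if hwe_exact_test(n_AA, n_Aa, n_aa) < th.hwe_min_p:
                    fail_hwe[j] = True

    with np.errstate(invalid="ignore"):
        valid = hm.alleles >= 0
        p = np.where(hm.alleles > 0, 1, 0).sum(axis=0) / np.maximum(valid.sum(axis=0), 1)
    maf = np.minimum(p, 1 - p)
    fail_maf = (maf < th.maf_min) | ((valid.sum(axis=0) == 0) & (th.maf_min > 0))

    for j in range(n_sites):
        if fail_miss[j]:
            report["missingness"] += 1
            keep[j] = False
        elif fail_hwe[j]:
            report["hwe"] += 1
            keep[j] = False
        elif fail_maf[j]:
            report["maf"] += 1
            keep[j] = False
    report["kept"] = int(keep.sum())
    if report["kept"] == 0:
        log.warning("apply_qc_filters: no sites survived QC")
    idx = np.flatnonzero(keep)
    return hm.take_sites(idx), vt.iloc[idx].reset_index(drop=True), report


# ---------------------------------------------------------------------------
# LD pruning
# ---------------------------------------------------------------------------

def ld_prune(
    hm: HaplotypeMatrix,
    window_bp: int = 50_000,
    step_snps: int = 5,
    r2_max: float = 0.5,
) -> np.ndarray:
    """Greedy LD pruning on diploid genotype-dosage correlation.

    Within any ``window_bp`` span the later site of a pair with ``r^2 >
    r2_max`` is dropped, scanning left to right, so the kept set has no
    remaining pair above the threshold within a window. ``step_snps`` is the
    stride convention of the originating tool; the greedy left-to-right scan
    evaluates every in-window pair, which subsumes any stride.

    Returns the indices of kept sites.
    """
    n = hm.n_sites
    dose = _dosage_matrix(hm)  # samples x sites, nan for missing
    keep = np.ones(n, dtype=bool)
    pos = hm.positions
    for i in range(n):
        if not keep[i]:
            continue
        j = i + 1
        while j < n and pos[j] - pos[i] <= window_bp:
            if keep[j] and _pairwise_r2(dose[:, i], dose[:, j]) > r2_max:
                keep[j] = False
            j += 1
    return np.flatnonzero(keep)


def _dosage_matrix(hm: HaplotypeMatrix) -> np.ndarray:
    rows = [hm.sample_map[s] for s in hm.samples]
    a = hm.alleles[[r[0] for r in rows]].astype(float)
    b = hm.alleles[[r[1] for r in rows]].astype(float)
    dose = a + b
    dose[(a < 0) | (b < 0)] = np.nan
    return dose


def _pairwise_r2(x: np.ndarray, y: np.ndarray) -> float:
    ok = ~(np.isnan(x) | np.isnan(y))
    if ok.sum() < 2:
        return 0.0
    xs, ys = x[ok], y[ok]
    if xs.std() == 0 or ys.std() == 0:
        return 0.0
    r = np.corrcoef(xs, ys)[0, 1]
    return float(r * r)


# ---------------------------------------------------------------------------
# Polarization
# ---------------------------------------------------------------------------

def polarize_to_ancestral(
    hm: HaplotypeMatrix, vt: pd.DataFrame
) -> tuple[HaplotypeMatrix, pd.DataFrame, np.ndarray]:
    """Recode alleles so ``1`` is the derived allele at every kept site.

    Sites where the ancestral allele matches neither REF nor ALT (or is
    unknown, ``"N"``) are dropped; their original indices are returned.
    """
    aa = vt["aa"].to_numpy()
    ref = vt["ref"].to_numpy()
    alt = vt["alt"].to_numpy()
    is_ref = aa == ref
    is_alt = aa == alt
    dropped = np.flatnonzero(~(is_ref | is_alt))
    alleles = hm.alleles.copy()
    flip = np.flatnonzero(is_alt)
    for j in flip:
        col = alleles[:, j]
        mask = col >= 0
        col[mask] = 1 - col[mask]
    vt2 = vt.copy()
    # after flipping, the derived allele is what was REF at flipped sites
    vt2.loc[vt2.index[flip], ["ref", "alt"]] = vt.loc[vt.index[flip], ["alt", "ref"]].to_numpy()
    keep = np.flatnonzero(is_ref | is_alt)
    hm2 = HaplotypeMatrix(
        alleles[:, keep], hm.positions[keep], hm.chrom, list(hm.haplotype_ids), dict(hm.sample_map)
    )
    if dropped.size:
        log.info("polarize_to_ancestral: dropped %d sites with unusable ancestral state", dropped.size)
    return hm2, vt2.iloc[keep].reset_index(drop=True), dropped
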