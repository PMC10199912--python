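"""Rank-based outlier calling, Fisher-combined differentiation scores,
region merging/annotation, haplotype LD utilities, and the private/shared
classification of candidate regions.

Rank-based p-values use ``p = rank / (N + 1)`` so the most extreme site gets
``p = 1/(N+1) > 0`` and Fisher's combined score stays finite; ties receive
their average rank. F_ST ranks by signed value (high = differentiated),
haplotype statistics by absolute standardized value.
"""

from __future__ import annotations

import logging
import math

import numpy as np
import pandas as pd
from scipy import stats as sps

from .core import CandidateRegion, HaplotypeMatrix, LDResult, OutlierSet, ScanScores

log = logging.getLogger(__name__)

REGION_GAP_BP = 200_000


# ---------------------------------------------------------------------------
# Ranks and Fisher's method
# ---------------------------------------------------------------------------

def rank_to_pvalues(scores: np.ndarray, key: str = "signed") -> np.ndarray:
    """Rank-based p-values: ``p_i = rank_i/(N+1)`` with rank 1 the most
    extreme under ``key`` ('signed': largest value; 'abs': largest
    magnitude). Ties get average ranks; NaN scores get NaN p."""
    scores = np.asarray(scores, dtype=float)
    finite = np.isfinite(scores)
    if not finite.any():
        raise ValueError("at least one finite score required")
    vals = np.abs(scores[finite]) if key == "abs" else scores[finite]
    if key not in ("signed", "abs"):
        raise ValueError("key must be 'signed' or 'abs'")
    ranks = sps.rankdata(-vals, method="average")
    p = np.full(scores.shape[0], np.nan)
    p[finite] = ranks / (finite.sum() + 1)
    return p


def fisher_combined_score(p1: float, p2: float) -> tuple[float, float]:
    """Fisher's combined score of two p-values.

    ``FCS = -2 (ln p1 + ln p2)``; the combined p-value is the upper tail of
    the chi-square distribution with 4 degrees of freedom at FCS.
    """
    if not (0 < p1 <= 1 and 0 < p2 <= 1):
        raise ValueError("p-values must lie in (0, 1]")
    fcs = -2.0 * (math.log(p1) + math.log(p2))
    return fcs, float(sps.chi2.sf(fcs, df=4))


# ---------------------------------------------------------------------------
# Outlier extraction
# ---------------------------------------------------------------------------

def top_fraction_outliers(scores: ScanScores, key: str, q: float, value_col: str = "std") -> OutlierSet:
    """Top-``q`` fraction of scored sites under the ranking key.

    The member count is ``ceil(q * N)`` over the N sites with finite scores;
    ties at the boundary are broken by site order for determinism.
    """
    if not (0 < q <= 0.5):
        raise ValueError("q must be in (0, 0.5]")
    tab = scores.table
    vals = tab[value_col].to_numpy(dtype=float)
    p = rank_to_pvalues(vals, key)
    finite = np.isfinite(vals)
    n = int(finite.sum())
    m = math.ceil(q * n)
    keyvals = np.abs(vals) if key == "abs" else vals
    order = np.lexsort((np.arange(len(vals)), -np.where(finite, keyvals, -np.inf)))
    members = np.sort(order[:m])
    table = pd.DataFrame(
        {
            "site": members,
            "chrom": tab["chrom"].to_numpy()[members],
            "pos": tab["pos"].to_numpy()[members],
            "score": vals[members],
            "p": p[members],
        }
    )
    return OutlierSet(scores.statistic, key, q, table, n)


def combine_differentiation_scans(
    fst: ScanScores, xpehh: ScanScores, q: float = 0.01
) -> pd.DataFrame:
    """Fisher-combine F_ST and XP-EHH on the intersection of their top-``q``
    outlier sets.

    Rank-based p-values are computed over *all* scored sites of each
    statistic; the returned table holds the intersection sites ordered by
    decreasing combined score. An empty intersection is legal (logged).
    """
    ftab, xtab = fst.table, xpehh.table
    if not np.array_equal(ftab["pos"].to_numpy(), xtab["pos"].to_numpy()):
        raise ValueError("scans must cover the same site map")
    fvals = ftab["fst"].to_numpy(dtype=float)
    xvals = xtab["std"].to_numpy(dtype=float)
    p_f = rank_to_pvalues(fvals, "signed")
    p_x = rank_to_pvalues(xvals, "abs")
    top_f = set(top_fraction_outliers(fst, "signed", q, value_col="fst").table["site"])
    top_x = set(top_fraction_outliers(xpehh, "abs", q, value_col="std").table["site"])
    common = sorted(top_f & top_x)
    if not common:
        log.info("combine_differentiation_scans: empty top-%g intersection", q)
    rows = []
    for j in common:
        fcs, cp = fisher_combined_score(p_f[j], p_x[j])
        rows.append(
            {
                "site": j,
                "chrom": ftab["chrom"].iloc[j],
                "pos": int(ftab["pos"].iloc[j]),
                "fst": fvals[j],
                "xpehh_std": xvals[j],
                "p_fst": p_f[j],
                "p_xpehh": p_x[j],
                "fcs": fcs,
                "combined_p": cp,
            }
        )
    out = pd.DataFrame(
        rows,
        columns=["site", "chrom", "pos", "fst", "xpehh_std", "p_fst", "p_xpehh", "fcs", "combined_p"],
    )
    if len(out):
        out = out.sort_values(["fcs", "site"], ascending=[False, True], kind="stable").reset_index(drop=True)
    return out


# ---------------------------------------------------------------------------
# Regions
# ---------------------------------------------------------------------------

def merge_outliers_into_regions(
    positions: np.ndarray,
    chrom: str = "1",
    gap_bp: int = REGION_GAP_BP,
    test: str = "",
    group: str = "",
) -> list[CandidateRegion]:
    """Single-linkage merge of outlier sites within ``gap_bp`` of each other;
    region bounds are the min/max member site padded by ``gap_bp/2``."""
    pos = np.sort(np.asarray(positions, dtype=np.int64))
    if pos.size == 0:
        return []
    regions: list[CandidateRegion] = []
    start = 0
    for i in range(1, pos.size + 1):
        if i == pos.size or pos[i] - pos[i - 1] > gap_bp:
            members = pos[start:i]
            pad = gap_bp // 2
            regions.append(
                CandidateRegion(
                    chrom,
                    max(0, int(members[0]) - pad),
                    int(members[-1]) + pad,
                    [int(x) for x in members],
                    [test] if test else [],
                    group,
                )
            )
            start = i
    return regions


def annotate_regions_with_genes(regions: list[CandidateRegion], genes: pd.DataFrame) -> None:
    """Attach names of genes whose (half-open) BED interval overlaps each
    region. ``genes`` needs columns chrom, start, end, name."""
    for r in regions:
        sub = genes[
            (genes["chrom"].astype(str) == r.chrom)
            & (genes["start"] < r.end)
            & (genes["end"] > r.start)
        ]
        r.genes = list(sub["name"])


def read_genes_bed(path) -> pd.DataFrame:
    return pd.read_csv(
        path, sep="\t", header=None, names=["chrom", "start", "end", "name"], dtype={"chrom": str}
    )


# ---------------------------------------------------------------------------
# Haplotype LD
# ---------------------------------------------------------------------------

def ld_pair_stats(
    hm: HaplotypeMatrix,
    site_i: int,
    site_j: int,
    spec=None,
    group: str | None = None,
) -> LDResult:
    """Two-locus D, D' and r-squared from phased haplotype frequencies.

    Haplotypes missing at either site are excluded (pairwise-complete).
    Raises on sites monomorphic within the selected group.
    """
    if group is not None:
        rows = hm.haplotype_rows(spec.group_samples(group))
        a = hm.alleles[rows]
    else:
        a = hm.alleles
    x = a[:, site_i]
    y = a[:, site_j]
    ok = (x >= 0) & (y >= 0)
    x, y = x[ok], y[ok]
    counts = np.zeros((2, 2), dtype=np.int64)
    for ai in (0, 1):
        for aj in (0, 1):
            counts[ai, aj] = int(((x == ai) & (y == aj)).sum())
    n = counts.sum()
    pA = counts[1].sum() / n
    pB = counts[:, 1].sum() / n
    if pA in (0.0, 1.0) or pB in (0.0, 1.0):
        raise ValueError("both sites must be polymorphic in the group")
    p11 = counts[1, 1] / n
    D = p11 - pA * pB
    if D >= 0:
        dmax = min(pA * (1 - pB), (1 - pA) * pB)
    else:
        dmax = min(pA * pB, (1 - pA) * (1 - pB))
    dprime = 0.0 if dmax == 0 else D / dmax
    r2 = D * D / (pA * (1 - pA) * pB * (1 - pB))
    return LDResult(site_i, site_j, counts, float(D), float(dprime), float(r2))


# ---------------------------------------------------------------------------
# Classification
# ---------------------------------------------------------------------------

def classify_candidate_signals(
    scan_results: dict[str, list[CandidateRegion]],
    lad_regions: list[CandidateRegion],
    target_groups: list[str] | None = None,
) -> list[CandidateRegion]:
    """Label each target-group candidate region by its overlap pattern.

    A target region overlapping (>= 1 bp) a significant local-ancestry-
    deviation region is labelled ``post_admixture``; one overlapping a
    source-group region from any test is ``shared_with_<source>`` (whether
    the shared signal reflects adaptive admixture or a residual source
    signal is not determined at this step); a region overlapping neither is
    ``private_target``. Multiple labels are allowed and reported in the
    fixed order: post_admixture, shared, private.
    """
    if target_groups is None:
        target_groups = [g for g in scan_results if g.startswith("target")]
    source_groups = [g for g in sorted(scan_results) if g not in target_groups]
    out: list[CandidateRegion] = []
    for tg in target_groups:
        for region in scan_results.get(tg, []):
            labels: list[str] = []
            if any(region.overlaps(lr) for lr in lad_regions):
                labels.append("post_admixture")
            for sg in source_groups:
                if any(region.overlaps(sr) for sr in scan_results[sg]):
                    labels.append(f"shared_with_{sg}")
            if not labels:
                labels.append("private_target")
            region.labels = labels
            out.append(region)
    return out


def load_llrt_table(path, threshold: float = 15.0) -> pd.DataFrame:
    """Ingest an external ancestry-component scan (site, log-likelihood
    ratio) and keep rows with LLRT above the threshold."""
    df = pd.read_csv(path, sep="\t")
    if not {"pos", "llrt"} <= set(df.columns):
        raise ValueError("LLRT table needs columns 'pos' and 'llrt'")
    return df[df["llrt"] > threshold].reset_index(drop=True)
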