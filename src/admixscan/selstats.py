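"""Per-SNP selection statistics: allele frequencies, Weir-Cockerham F_ST,
EHH/iHH, iHS, and XP-EHH, with their normalizations.

Distances are physical base pairs under a uniform genetic map, so iHH is in
bp x EHH; this is harmless because iHS and XP-EHH are log-ratios of iHH.
The EHH integration cutoff (0.05) and maximum inter-site gap (200 kb) follow
the defaults of the standard haplotype-scan tooling.
"""

from __future__ import annotations

import logging

import numpy as np
import pandas as pd

from ._ehh import ehh_walk, trapezoid_prefix, trapezoid_to_extent
from .core import EHHCurve, HaplotypeMatrix, PopulationSpec, ScanScores

log = logging.getLogger(__name__)

EHH_CUTOFF = 0.05
MAX_GAP_BP = 200_000
_BIG = np.int64(2**62)


# ---------------------------------------------------------------------------
# Allele frequencies
# ---------------------------------------------------------------------------

def allele_frequencies(
    hm: HaplotypeMatrix,
    spec: PopulationSpec | None = None,
    group: str | None = None,
) -> np.ndarray:
    """Per-site derived(alt)-allele frequency; missing alleles are excluded
    from both numerator and denominator. Sites with no data are NaN."""
    if group is not None:
        if spec is None:
            raise ValueError("group requires a PopulationSpec")
        samples = spec.group_samples(group)
        if not samples:
            raise ValueError(f"group {group!r} selects no samples")
        rows = hm.haplotype_rows(samples)
        a = hm.alleles[rows]
    else:
        a = hm.alleles
    valid = (a >= 0).sum(axis=0)
    derived = (a == 1).sum(axis=0)
    with np.errstate(invalid="ignore", divide="ignore"):
        return np.where(valid > 0, derived / valid, np.nan)


# ---------------------------------------------------------------------------
# Weir-Cockerham F_ST
# ---------------------------------------------------------------------------

def weir_cockerham_fst(
    hm: HaplotypeMatrix,
    spec: PopulationSpec,
    group_a: str,
    group_b: str,
) -> ScanScores:
    """Per-site two-population Weir-Cockerham (1984) F_ST.

    Returns the variance components ``a`` (among populations), ``b`` (among
    individuals within populations) and ``c`` (within individuals), with
    ``fst = a / (a + b + c)``. Sites monomorphic across both groups, or with
    fewer than two complete diploids in either group, are flagged undefined
    (``fst`` NaN) and must be excluded from outlier ranking.
    """
    sa = spec.group_samples(group_a)
    sb = spec.group_samples(group_b)
    overlap = set(sa) & set(sb)
    if overlap:
        raise ValueError(f"groups overlap: {sorted(overlap)[:5]}")
    if len(sa) < 2 or len(sb) < 2:
        raise ValueError("each group needs at least 2 diploid samples")

    stats = [_diploid_site_stats(hm, s) for s in (sa, sb)]
    n1, p1, h1 = stats[0]
    n2, p2, h2 = stats[1]

    with np.errstate(invalid="ignore", divide="ignore"):
        nbar = (n1 + n2) / 2.0
        nc = 2.0 * nbar - (n1**2 + n2**2) / (2.0 * nbar)
        pbar = (n1 * p1 + n2 * p2) / (2.0 * nbar)
        s2 = (n1 * (p1 - pbar) ** 2 + n2 * (p2 - pbar) ** 2) / nbar
        hbar = (n1 * h1 + n2 * h2) / (2.0 * nbar)
        a = (nbar / nc) * (s2 - (pbar * (1 - pbar) - s2 / 2.0 - hbar / 4.0) / (nbar - 1.0))
        b = (nbar / (nbar - 1.0)) * (pbar * (1 - pbar) - s2 / 2.0 - (2.0 * nbar - 1.0) / (4.0 * nbar) * hbar)
        c = hbar / 2.0
        fst = a / (a + b + c)

    defined = (n1 >= 2) & (n2 >= 2) & ~((s2 == 0) & ((pbar == 0) | (pbar == 1)))
    fst = np.where(defined, fst, np.nan)
    table = pd.DataFrame(
        {
            "chrom": hm.chrom,
            "pos": hm.positions,
            "a": a,
            "b": b,
            "c": c,
            "fst": fst,
            "defined": defined,
        }
    )
    return ScanScores("FST", table, {"group_a": group_a, "group_b": group_b})


def _diploid_site_stats(hm: HaplotypeMatrix, samples: list[str]):
    """Per-site (n complete diploids, alt-allele freq, observed het freq)."""
    pairs = [hm.sample_map[s] for s in samples]
    a = hm.alleles[[p[0] for p in pairs]]
    b = hm.alleles[[p[1] for p in pairs]]
    ok = (a >= 0) & (b >= 0)
    n = ok.sum(axis=0).astype(float)
    dose = np.where(ok, a + b, 0)
    het = np.where(ok, (a != b), False)
    with np.errstate(invalid="ignore", divide="ignore"):
        p = np.where(n > 0, dose.sum(axis=0) / (2 * n), np.nan)
        h = np.where(n > 0, het.sum(axis=0) / n, np.nan)
    return n, p, h


# ---------------------------------------------------------------------------
# EHH / iHH
# ---------------------------------------------------------------------------

def _carrier_rows(hm: HaplotypeMatrix, core: int, allele_mode: str) -> np.ndarray:
    col = hm.alleles[:, core]
    if allele_mode == "derived":
        return np.flatnonzero(col == 1).astype(np.int64)
    if allele_mode == "ancestral":
        return np.flatnonzero(col == 0).astype(np.int64)
    if allele_mode == "pooled":
        return np.flatnonzero(col >= 0).astype(np.int64)
    raise ValueError(f"unknown allele_mode {allele_mode!r}")


def ehh_curve(
    hm: HaplotypeMatrix,
    core: int,
    allele_mode: str = "derived",
    direction: str = "up",
    maxgap_bp: int = MAX_GAP_BP,
    stop_below: float = 0.0,
) -> EHHCurve:
    """EHH decay curve from a core site in one direction.

    ``EHH(d)`` is the fraction of carrier pairs identical over the interval
    from the core out to distance ``d``; ``EHH(0) = 1`` by definition.
    Raises if fewer than two carriers exist at the core.
    """
    if direction not in ("up", "down"):
        raise ValueError("direction must be 'up' or 'down'")
    carriers = _carrier_rows(hm, core, allele_mode)
    if carriers.size < 2:
        raise ValueError(f"fewer than 2 carriers of {allele_mode} allele at site {core}")
    step = 1 if direction == "up" else -1
    d, e, _, reached_end = ehh_walk(
        hm.alleles, hm.positions, core, carriers, step, maxgap_bp, stop_below, _BIG
    )
    return EHHCurve(core, int(hm.positions[core]), allele_mode, direction, d, e, bool(reached_end), carriers.size)


def integrate_ehh(curve: EHHCurve, cutoff: float = EHH_CUTOFF) -> tuple[float, bool]:
    """Trapezoidal iHH over the curve, truncated where EHH first drops below
    ``cutoff``. Returns ``(ihh, censored)``; ``censored`` is True when EHH
    never dropped below the cutoff before the curve ended (chromosome edge or
    max-gap truncation), in which case the iHH is a biased underestimate."""
    if curve.distances.size == 0:
        raise ValueError("empty curve")
    area = float(trapezoid_prefix(curve.distances, curve.ehh, cutoff))
    censored = bool(curve.reached_end) and bool(np.all(curve.ehh >= cutoff))
    return area, censored


# ---------------------------------------------------------------------------
# iHS
# ---------------------------------------------------------------------------

def ihs_scan(
    hm: HaplotypeMatrix,
    vt: pd.DataFrame | None = None,
    maf_min: float = 0.05,
    n_bins: int = 20,
    cutoff: float = EHH_CUTOFF,
    maxgap_bp: int = MAX_GAP_BP,
) -> ScanScores:
    """Integrated haplotype score scan on a polarized matrix (1 = derived).

    Raw ``iHS = ln(iHH_ancestral / iHH_derived)`` with both directions
    summed per allele; sites whose EHH never reaches the cutoff before the
    chromosome edge (censored) are excluded. Scores are standardized to mean
    0 / SD 1 within equal-width derived-allele-frequency bins spanning
    ``[maf_min, 1 - maf_min]``; bins holding fewer than two sites are merged
    with a neighbor (logged).
    """
    freqs = allele_frequencies(hm)
    alleles, positions = hm.alleles, hm.positions
    n_sites = hm.n_sites
    raw = np.full(n_sites, np.nan)
    n_censored = 0
    for j in range(n_sites):
        f = freqs[j]
        if not (maf_min <= f <= 1 - maf_min):
            continue
        ihh = {}
        bad = False
        for mode in ("derived", "ancestral"):
            carriers = _carrier_rows(hm, j, mode)
            if carriers.size < 2:
                bad = True
                break
            total = 0.0
            for step in (1, -1):
                d, e, _, reached_end = ehh_walk(
                    alleles, positions, j, carriers, step, maxgap_bp, cutoff, _BIG
                )
                if reached_end:
                    bad = True  # censored: EHH never fell below cutoff
                    break
                total += float(trapezoid_prefix(d, e, cutoff))
            if bad:
                break
            ihh[mode] = total
        if bad or ihh["derived"] <= 0 or ihh["ancestral"] <= 0:
            n_censored += bad
            continue
        raw[j] = np.log(ihh["ancestral"] / ihh["derived"])
    if n_censored:
        log.info("ihs_scan: excluded %d censored/degenerate sites", n_censored)

    scored = np.isfinite(raw)
    std, bin_id, bin_stats = _bin_standardize(raw, freqs, scored, maf_min, n_bins)
    table = pd.DataFrame(
        {
            "chrom": hm.chrom,
            "pos": positions,
            "freq_derived": freqs,
            "raw": raw,
            "std": std,
            "bin": bin_id,
        }
    )
    if vt is not None:
        table.insert(0, "id", vt["id"].to_numpy())
    return ScanScores("iHS", table, {"bins": bin_stats, "maf_min": maf_min, "cutoff": cutoff})


def _bin_standardize(raw, freqs, scored, maf_min, n_bins):
    """Standardize within equal-width frequency bins, merging sparse bins."""
    edges = np.linspace(maf_min, 1 - maf_min, n_bins + 1)
    bin_id = np.full(raw.shape[0], -1, dtype=int)
    idx = np.flatnonzero(scored)
    b = np.clip(np.digitize(freqs[idx], edges) - 1, 0, n_bins - 1)
    bin_id[idx] = b
    # merge bins with <2 scored sites into their left (else right) neighbor
    labels = sorted(set(b))
    merged = {lab: lab for lab in labels}
    changed = True
    while changed and len(set(merged.values())) > 1:
        changed = False
        counts: dict[int, int] = {}
        for lab in b:
            counts[merged[lab]] = counts.get(merged[lab], 0) + 1
        active = sorted(counts)
        for k, lab in enumerate(active):
            if counts[lab] < 2:
                target = active[k - 1] if k > 0 else active[k + 1]
                for src, dst in merged.items():
                    if dst == lab:
                        merged[src] = target
                log.info("ihs_scan: merged frequency bin %d into %d (<2 sites)", lab, target)
                changed = True
                break
    eff = np.array([merged[lab] for lab in b]) if idx.size else np.array([], dtype=int)
    bin_id[idx] = eff
    std = np.full(raw.shape[0], np.nan)
    bin_stats = {}
    for lab in sorted(set(eff.tolist())):
        sel = idx[eff == lab]
        mu = raw[sel].mean()
        sd = raw[sel].std()
        bin_stats[int(lab)] = {"mean": float(mu), "sd": float(sd), "n": int(sel.size)}
        std[sel] = 0.0 if sd == 0 else (raw[sel] - mu) / sd
    return std, bin_id, bin_stats


# ---------------------------------------------------------------------------
# XP-EHH
# ---------------------------------------------------------------------------

def xpehh_scan(
    hm_a: HaplotypeMatrix,
    hm_b: HaplotypeMatrix,
    vt: pd.DataFrame | None = None,
    cutoff: float = EHH_CUTOFF,
    maxgap_bp: int = MAX_GAP_BP,
) -> ScanScores:
    """Cross-population EHH scan; positive scores mean longer haplotype
    homozygosity in panel A.

    Pooled-allele iHH is computed in each panel over a common truncation
    extent per direction - the further of the two panels' first drops below
    the EHH cutoff, the joint-extent convention of the standard test. Raw
    ``XP-EHH = ln(iHH_A / iHH_B)``, standardized genome-wide. Sites censored
    in either panel (cutoff never reached before the edge) are excluded.
    """
    if not np.array_equal(hm_a.positions, hm_b.positions):
        raise ValueError("panels must share the site map")
    n_sites = hm_a.n_sites
    raw = np.full(n_sites, np.nan)
    for j in range(n_sites):
        ihh_a = ihh_b = 0.0
        bad = False
        for step in (1, -1):
            res = []
            for hm in (hm_a, hm_b):
                carriers = _carrier_rows(hm, j, "pooled")
                if carriers.size < 2:
                    bad = True
                    break
                d, e, _, reached_end = ehh_walk(
                    hm.alleles, hm.positions, j, carriers, step, maxgap_bp, cutoff, _BIG
                )
                if reached_end:
                    bad = True
                    break
                res.append((carriers, d, e))
            if bad:
                break
            extent = max(int(res[0][1][-1]), int(res[1][1][-1]))
            vals = []
            for hm, (carriers, d, e) in zip((hm_a, hm_b), res):
                if int(d[-1]) < extent:  # re-walk past its own cutoff point
                    d, e, _, _ = ehh_walk(
                        hm.alleles, hm.positions, j, carriers, step, maxgap_bp, -1.0, extent
                    )
                vals.append(float(trapezoid_to_extent(d, e, extent)))
            ihh_a += vals[0]
            ihh_b += vals[1]
        if bad or ihh_a <= 0 or ihh_b <= 0:
            continue
        raw[j] = np.log(ihh_a / ihh_b)

    scored = np.isfinite(raw)
    mu = raw[scored].mean() if scored.any() else np.nan
    sd = raw[scored].std() if scored.any() else np.nan
    std = np.full(n_sites, np.nan)
    if scored.any() and sd > 0:
        std[scored] = (raw[scored] - mu) / sd
    elif scored.any():
        std[scored] = 0.0
    table = pd.DataFrame(
        {"chrom": hm_a.chrom, "pos": hm_a.positions, "raw": raw, "std": std}
    )
    if vt is not None:
        table.insert(0, "id", vt["id"].to_numpy())
    return ScanScores("XPEHH", table, {"mean": float(mu), "sd": float(sd), "cutoff": cutoff})
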