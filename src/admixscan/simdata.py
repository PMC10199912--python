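"""Synthetic multi-population phased datasets with known admixture and sweeps.

The generator emulates the study system downstream modules are built for: an
admixed target cohort carrying four ancestry components (an autochthonous
Maghrebi-like component plus European-, West/East-African- and Middle-
Eastern-like source components), formed by a single admixture pulse ``g``
generations ago, with a selective sweep placed either before admixture (in
the autochthonous component or in a source) or after admixture (favoring
haplotypes of one ancestry at a locus).

Model summary
-------------
* Founder pools: per-site ancestral frequencies are shared across pools and
  per-pool frequencies follow a Balding-Nichols draw around them, giving a
  tunable mean pairwise F_ST. Pool haplotypes are mosaics of a small founder
  set so the pools carry linkage disequilibrium.
* Sweep: the favored-allele frequency follows the deterministic haploid
  selection recursion ``p' = p(1+s) / (1+ps)``; each generation the carrier
  class is resampled from the previous carrier generation with Poisson
  recombination (rate ``r`` per bp) onto background haplotypes drawn from
  the stationary (pre-sweep) pool, producing hitchhiking around the locus
  without whole-chromosome drift.
* Admixture: each target haplotype draws ancestry breakpoints as a Poisson
  process of rate ``g * r`` per bp, labels each tract independently with the
  configured proportions, and copies alleles from a random haplotype of the
  labelled pool. The drawn tracts are returned as ground truth.
* Post-admixture selection: Wright-Fisher resampling of the cohort for the
  configured number of generations in which haplotypes carrying the
  designated ancestry at the locus have fitness ``1 + s``; tracts are
  recombined alongside alleles and remain the ground truth.

All outputs are a pure function of the configuration (including its seed).
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from .core import (
    AncestryTractSet,
    HaplotypeMatrix,
    InvalidConfigError,
    new_variant_table,
)
from . import genio

SCENARIOS = ("neutral", "private_sweep", "shared_sweep", "post_admixture_sweep")


@dataclass
class SweepConfig:
    """Placement and strength of the selective sweep.

    ``component`` is the founder-pool label swept before admixture, or
    ``"target_post_admixture"`` for selection on the assembled cohort, in
    which case ``favored_ancestry`` names the ancestry whose carriers at the
    locus have fitness ``1 + s``.
    """

    component: str = "MAG"
    position_bp: int | None = None  # defaults to mid-chromosome
    s: float = 0.05
    generations: int = 400
    p0: float = 0.05
    favored_ancestry: str = "EUR"

    def validate(self, cfg: "SimulationConfig") -> None:
        if self.s < 0:
            raise InvalidConfigError("selection coefficient must be >= 0")
        if not (0 < self.p0 < 1):
            raise InvalidConfigError("p0 must lie in (0, 1)")
        if self.position_bp is not None and not (0 <= self.position_bp < cfg.chrom_length_bp):
            raise InvalidConfigError("sweep position outside the chromosome")
        known = set(cfg.ancestries) | {"target_post_admixture"}
        if self.component not in known:
            raise InvalidConfigError(f"unknown sweep component {self.component!r}")


@dataclass
class SimulationConfig:
    """Parameters of one simulated admixture scenario.

    Defaults follow the study conditions the package is calibrated for:
    four ancestry components with a European-like admixture proportion of
    15.3%, a single admixture pulse 10 generations ago, a 50 Mb chromosome
    with 2,000 SNPs, and a uniform recombination rate of 1e-8 Morgans/bp.
    """

    seed: int = 0
    n_sites: int = 4000
    chrom_length_bp: int = 50_000_000
    recomb_rate: float = 1e-8  # Morgans per bp
    ancestries: tuple[str, ...] = ("MAG", "EUR", "WEA", "MEA")
    pool_sizes: int = 100  # haplotypes per founder pool
    admix_proportions: tuple[float, ...] = (0.60, 0.153, 0.15, 0.097)
    generations_since_admixture: int = 10
    cohort_size: int = 100  # diploid target individuals
    sweep: SweepConfig | None = None
    founders_per_pool: int = 48
    founder_mosaic_rate: float = 5e-6  # per bp; mean founder-segment 200 kb
    fst_target: float = 0.10  # target mean pairwise F_ST between pools
    selection_pop_haplotypes: int = 1000  # post-admixture selection-phase population
    chrom: str = "1"

    def __post_init__(self) -> None:
        if self.n_sites < 2:
            raise InvalidConfigError("n_sites must be >= 2")
        if self.pool_sizes < 4:
            raise InvalidConfigError("pool_sizes must be >= 4")
        if len(self.admix_proportions) != len(self.ancestries):
            raise InvalidConfigError("one admixture proportion per ancestry required")
        if abs(sum(self.admix_proportions) - 1.0) > 1e-9:
            raise InvalidConfigError("admixture proportions must sum to 1")
        if any(q < 0 for q in self.admix_proportions):
            raise InvalidConfigError("admixture proportions must be non-negative")
        if self.sweep is not None:
            self.sweep.validate(self)

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        d["ancestries"] = list(self.ancestries)
        d["admix_proportions"] = list(self.admix_proportions)
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "SimulationConfig":
        d = dict(d)
        if d.get("sweep") is not None:
            d["sweep"] = SweepConfig(**d["sweep"])
        d["ancestries"] = tuple(d.get("ancestries", ("MAG", "EUR", "WEA", "MEA")))
        d["admix_proportions"] = tuple(d.get("admix_proportions", (0.60, 0.153, 0.15, 0.097)))
        return cls(**d)


@dataclass
class ScenarioBundle:
    """A simulated cohort plus its sources and ground truth."""

    target: HaplotypeMatrix
    tracts: AncestryTractSet
    sources: dict[str, HaplotypeMatrix]
    variants: "object"  # pandas DataFrame (VariantTable)
    truth: dict = field(default_factory=dict)


# ---------------------------------------------------------------------------
# Founder pools
# ---------------------------------------------------------------------------

def _draw_positions(rng: np.random.Generator, length: int, n: int) -> np.ndarray:
    pos = np.unique(rng.integers(0, length, size=n + max(100, n // 5)))
    while pos.size < n:
        pos = np.union1d(pos, rng.integers(0, length, size=n))
    idx = np.sort(rng.choice(pos.size, size=n, replace=False))
    return pos[idx]


def _segment_lookup(rng: np.random.Generator, rate_per_bp: float, length: int):
    """Poisson breakpoints over [0, length); returns sorted breakpoint array."""
    nb = rng.poisson(rate_per_bp * length)
    if nb == 0:
        return np.empty(0, dtype=np.int64)
    return np.sort(rng.integers(0, length, size=nb)).astype(np.int64)


def _mosaic_haplotype(
    rng: np.random.Generator,
    founders: np.ndarray,
    positions: np.ndarray,
    rate: float,
    length: int,
) -> np.ndarray:
    bps = _segment_lookup(rng, rate, length)
    k = founders.shape[0]
    fidx = rng.integers(0, k, size=bps.size + 1)
    seg_of_site = np.searchsorted(bps, positions, side="right")
    return founders[fidx[seg_of_site], np.arange(positions.size)]


def build_founder_pools(
    cfg: SimulationConfig, rng: np.random.Generator | None = None
) -> dict[str, HaplotypeMatrix]:
    """One differentiated haplotype pool per ancestry on a shared site map.

    Differentiation: per-site per-pool frequencies are Balding-Nichols draws
    around a shared ancestral frequency; the Balding-Nichols F is set below
    ``fst_target`` to offset the extra between-pool variance introduced by
    sampling a finite founder set, so the realized mean pairwise F_ST lands
    near the target (default band 0.05-0.15).
    """
    rng = rng if rng is not None else np.random.default_rng(cfg.seed)
    positions = _draw_positions(rng, cfg.chrom_length_bp, cfg.n_sites)
    p_anc = rng.uniform(0.05, 0.95, size=cfg.n_sites)
    f = max(0.01, cfg.fst_target - 1.0 / cfg.founders_per_pool)
    shape = (1.0 - f) / f
    pools: dict[str, HaplotypeMatrix] = {}
    for label in cfg.ancestries:
        p_pool = rng.beta(p_anc * shape, (1.0 - p_anc) * shape)
        founders = (rng.random((cfg.founders_per_pool, cfg.n_sites)) < p_pool).astype(np.int8)
        haps = np.empty((cfg.pool_sizes, cfg.n_sites), dtype=np.int8)
        for i in range(cfg.pool_sizes):
            haps[i] = _mosaic_haplotype(
                rng, founders, positions, cfg.founder_mosaic_rate, cfg.chrom_length_bp
            )
        ids = [f"{label}{i // 2:03d}_{'AB'[i % 2]}" for i in range(cfg.pool_sizes)]
        smap = {f"{label}{i:03d}": (2 * i, 2 * i + 1) for i in range(cfg.pool_sizes // 2)}
        pools[label] = HaplotypeMatrix(haps, positions, cfg.chrom, ids, smap)
    return pools


# ---------------------------------------------------------------------------
# Sweeps
# ---------------------------------------------------------------------------

def selection_trajectory(p0: float, s: float, generations: int) -> np.ndarray:
    """Deterministic haploid-selection recursion ``p' = p(1+s)/(1+ps)``."""
    p = np.empty(generations + 1)
    p[0] = p0
    for t in range(generations):
        p[t + 1] = p[t] * (1 + s) / (1 + p[t] * s)
    return p


def apply_sweep(
    pool: HaplotypeMatrix,
    locus: int,
    s: float,
    generations: int,
    recomb_rate: float,
    chrom_length_bp: int,
    rng: np.random.Generator,
) -> HaplotypeMatrix:
    """Sweep the derived allele at site ``locus`` through a founder pool.

    The carrier count follows the deterministic selection recursion started
    from the observed carrier frequency; each generation new carriers copy
    the locus-bearing segment from a previous-generation carrier and draw
    Poisson(``r`` per bp) recombination breakpoints against background
    haplotypes from the stationary pre-sweep pool. Haplotype order is
    reshuffled afterwards so pseudo-diploid pairing stays random.
    """
    if s < 0:
        raise InvalidConfigError("selection coefficient must be >= 0")
    M, n_sites = pool.n_haplotypes, pool.n_sites
    col = pool.alleles[:, locus]
    carriers0 = np.flatnonzero(col == 1)
    if carriers0.size == 0:
        raise ValueError("favored (derived) allele absent at the sweep locus")
    positions = pool.positions
    locus_pos = int(positions[locus])
    traj = selection_trajectory(carriers0.size / M, s, generations)

    # Two-part construction of the swept pool in the large-population limit
    # of per-generation carrier resampling against a stationary background:
    #
    # 1. founder-label genealogy at pool scale - each generation the carrier
    #    class is resampled up to the quota set by the deterministic
    #    trajectory, which captures the establishment-phase skew toward
    #    early-expanding carrier lineages;
    # 2. each final carrier copies its founder's haplotype around the locus
    #    and escapes, at an exponential distance per side with rate
    #    r x generations (one recombination opportunity per generation),
    #    onto fresh background haplotypes of the pre-sweep pool.
    #
    # Sampled carrier lineages in a large population share no recent
    # ancestor, so no closed-pool drift is introduced and the chromosome-
    # wide background keeps the pool's stationary diversity.
    labels = np.arange(carriers0.size)
    for t in range(1, generations + 1):
        n_t = min(max(int(round(traj[t] * M)), 1), M)
        labels = labels[rng.integers(0, labels.size, size=n_t)]
        if n_t == M:
            break
    n_final = min(max(int(round(traj[generations] * M)), 1), M)
    labels = labels[rng.integers(0, labels.size, size=n_final)] if labels.size != n_final else labels

    esc_rate = recomb_rate * generations
    new = np.empty((n_final, n_sites), dtype=np.int8)
    for i in range(n_final):
        hap = pool.alleles[carriers0[labels[i]]].copy()
        if esc_rate > 0:
            d_left = rng.exponential(1.0 / esc_rate)
            d_right = rng.exponential(1.0 / esc_rate)
            left = positions < locus_pos - d_left
            right = positions > locus_pos + d_right
            if left.any():
                hap[left] = pool.alleles[rng.integers(0, M)][left]
            if right.any():
                hap[right] = pool.alleles[rng.integers(0, M)][right]
        new[i] = hap
    non = np.flatnonzero(col != 1)
    fill = M - n_final
    if fill > 0:
        take = rng.choice(non.size, size=fill, replace=fill > non.size)
        stacked = np.vstack([new, pool.alleles[non[take]]])
    else:
        stacked = new
    perm = rng.permutation(M)
    return HaplotypeMatrix(
        stacked[perm], positions, pool.chrom, list(pool.haplotype_ids), dict(pool.sample_map)
    )


# ---------------------------------------------------------------------------
# Admixture
# ---------------------------------------------------------------------------

def simulate_ancestry_tracts(
    cfg: SimulationConfig,
    rng: np.random.Generator | None = None,
    n_haplotypes: int | None = None,
    chrom: str | None = None,
) -> AncestryTractSet:
    """Ancestry tracts of a neutral admixed cohort, without alleles.

    Useful for building genome-wide local-ancestry backgrounds (additional
    chromosomes) cheaply: local-ancestry statistics only need the tracts.
    """
    import pandas as pd

    rng = rng if rng is not None else np.random.default_rng(cfg.seed)
    n_hap = n_haplotypes if n_haplotypes is not None else 2 * cfg.cohort_size
    chrom = chrom if chrom is not None else cfg.chrom
    q = np.asarray(cfg.admix_proportions)
    L = cfg.chrom_length_bp
    rate = cfg.generations_since_admixture * cfg.recomb_rate
    rows = {"haplotype_id": [], "chrom": [], "start": [], "end": [], "ancestry": []}
    for h in range(n_hap):
        hap_id = f"T{h // 2:04d}_{'AB'[h % 2]}"
        bps = _segment_lookup(rng, rate, L)
        edges = np.concatenate(([0], bps, [L]))
        labs = rng.choice(len(q), size=edges.size - 1, p=q)
        for k in range(edges.size - 1):
            rows["haplotype_id"].append(hap_id)
            rows["chrom"].append(chrom)
            rows["start"].append(int(edges[k]))
            rows["end"].append(int(edges[k + 1]))
            rows["ancestry"].append(cfg.ancestries[labs[k]])
    return AncestryTractSet(pd.DataFrame(rows), L)


def simulate_admixed_cohort(
    pools: dict[str, HaplotypeMatrix],
    cfg: SimulationConfig,
    rng: np.random.Generator | None = None,
) -> tuple[HaplotypeMatrix, AncestryTractSet]:
    """Assemble the admixed target cohort under the pulse-admixture model."""
    rng = rng if rng is not None else np.random.default_rng(cfg.seed)
    for label in cfg.ancestries:
        if label not in pools:
            raise ValueError(f"missing founder pool for ancestry {label!r}")
    ref = pools[cfg.ancestries[0]]
    positions, L = ref.positions, cfg.chrom_length_bp
    q = np.asarray(cfg.admix_proportions)
    n_hap = 2 * cfg.cohort_size
    rate = cfg.generations_since_admixture * cfg.recomb_rate
    alleles = np.empty((n_hap, cfg.n_sites), dtype=np.int8)
    rows = {"haplotype_id": [], "chrom": [], "start": [], "end": [], "ancestry": []}
    hap_ids = [f"T{i // 2:04d}_{'AB'[i % 2]}" for i in range(n_hap)]
    for h in range(n_hap):
        bps = _segment_lookup(rng, rate, L)
        edges = np.concatenate(([0], bps, [L]))
        labs = rng.choice(len(q), size=edges.size - 1, p=q)
        seg_of_site = np.searchsorted(bps, positions, side="right")
        for k in range(edges.size - 1):
            label = cfg.ancestries[labs[k]]
            src = pools[label]
            donor = rng.integers(0, src.n_haplotypes)
            sel = seg_of_site == k
            alleles[h, sel] = src.alleles[donor, sel]
            rows["haplotype_id"].append(hap_ids[h])
            rows["chrom"].append(cfg.chrom)
            rows["start"].append(int(edges[k]))
            rows["end"].append(int(edges[k + 1]))
            rows["ancestry"].append(label)
    import pandas as pd

    smap = {f"T{i:04d}": (2 * i, 2 * i + 1) for i in range(cfg.cohort_size)}
    hm = HaplotypeMatrix(alleles, positions, cfg.chrom, hap_ids, smap)
    tracts = AncestryTractSet(pd.DataFrame(rows), L)
    return hm, tracts


def _tract_arrays(tracts: AncestryTractSet) -> dict[str, tuple[np.ndarray, np.ndarray]]:
    out = {}
    for hap, sub in tracts.table.groupby("haplotype_id", sort=False):
        edges = np.concatenate((sub["start"].to_numpy(), [sub["end"].to_numpy()[-1]]))
        out[hap] = (edges.astype(np.int64), sub["ancestry"].to_numpy())
    return out


def _splice(edges_a, labs_a, edges_b, labs_b, bps, L):
    """Mosaic of two tract lists alternating at ``bps`` (A first)."""
    cuts = np.concatenate(([0], bps, [L]))
    starts, ends, labs = [], [], []
    for k in range(cuts.size - 1):
        lo, hi = int(cuts[k]), int(cuts[k + 1])
        if lo == hi:
            continue
        edges, labels = (edges_a, labs_a) if k % 2 == 0 else (edges_b, labs_b)
        i0 = np.searchsorted(edges, lo, side="right") - 1
        i1 = np.searchsorted(edges, hi, side="left")
        for i in range(i0, i1):
            starts.append(max(lo, int(edges[i])))
            ends.append(min(hi, int(edges[i + 1])))
            labs.append(labels[i])
    return np.array(starts + [0])[:-1], np.array(ends + [0])[:-1], labs


def _resample_post_admixture(
    hm: HaplotypeMatrix,
    tracts: AncestryTractSet,
    cfg: SimulationConfig,
    locus: int,
    favored: str,
    s: float,
    generations: int,
    rng: np.random.Generator,
) -> tuple[HaplotypeMatrix, AncestryTractSet]:
    """Wright-Fisher resampling of the cohort with ancestry-linked fitness."""
    import pandas as pd

    positions, L = hm.positions, cfg.chrom_length_bp
    locus_pos = int(positions[locus])
    hap_ids = list(hm.haplotype_ids)
    ta = _tract_arrays(tracts)
    cur_alleles = hm.alleles.copy()
    cur_edges = [ta[h][0] for h in hap_ids]
    cur_labs = [ta[h][1] for h in hap_ids]
    n = len(hap_ids)
    for _ in range(generations):
        anc_at = np.array(
            [labs[np.searchsorted(edges[1:], locus_pos, side="right")] for edges, labs in zip(cur_edges, cur_labs)]
        )
        w = np.where(anc_at == favored, 1.0 + s, 1.0)
        prob = w / w.sum()
        new_alleles = np.empty_like(cur_alleles)
        new_edges, new_labs = [], []
        pa_idx = rng.choice(n, size=n, p=prob)
        pb_idx = rng.choice(n, size=n, p=prob)
        for i in range(n):
            a, b = pa_idx[i], pb_idx[i]
            bps = _segment_lookup(rng, cfg.recomb_rate, L)
            if bps.size == 0:
                new_alleles[i] = cur_alleles[a]
                new_edges.append(cur_edges[a].copy())
                new_labs.append(np.asarray(cur_labs[a]).copy())
                continue
            seg_of_site = np.searchsorted(bps, positions, side="right")
            from_a = seg_of_site % 2 == 0
            new_alleles[i] = np.where(from_a, cur_alleles[a], cur_alleles[b])
            st, en, lb = _splice(cur_edges[a], cur_labs[a], cur_edges[b], cur_labs[b], bps, L)
            new_edges.append(np.concatenate((st, [L])))
            new_labs.append(np.asarray(lb))
        cur_alleles = new_alleles
        cur_edges, cur_labs = new_edges, new_labs
    rows = {"haplotype_id": [], "chrom": [], "start": [], "end": [], "ancestry": []}
    for h, (edges, labs) in enumerate(zip(cur_edges, cur_labs)):
        for i in range(len(labs)):
            rows["haplotype_id"].append(hap_ids[h])
            rows["chrom"].append(cfg.chrom)
            rows["start"].append(int(edges[i]))
            rows["end"].append(int(edges[i + 1]))
            rows["ancestry"].append(labs[i])
    hm2 = HaplotypeMatrix(cur_alleles, positions, cfg.chrom, hap_ids, dict(hm.sample_map))
    return hm2, AncestryTractSet(pd.DataFrame(rows), L)


def _sample_cohort(
    hm: HaplotypeMatrix,
    tracts: AncestryTractSet,
    n_hap: int,
    rng: np.random.Generator,
) -> tuple[HaplotypeMatrix, AncestryTractSet]:
    """Draw ``n_hap`` haplotypes (with their tracts) from a larger cohort."""
    import pandas as pd

    pick = np.sort(rng.choice(hm.n_haplotypes, size=n_hap, replace=False))
    old_ids = [hm.haplotype_ids[i] for i in pick]
    new_ids = [f"T{i // 2:04d}_{'AB'[i % 2]}" for i in range(n_hap)]
    smap = {f"T{i:04d}": (2 * i, 2 * i + 1) for i in range(n_hap // 2)}
    sub = tracts.table[tracts.table["haplotype_id"].isin(old_ids)].copy()
    rename = dict(zip(old_ids, new_ids))
    sub["haplotype_id"] = sub["haplotype_id"].map(rename)
    hm2 = HaplotypeMatrix(hm.alleles[pick], hm.positions, hm.chrom, new_ids, smap)
    return hm2, AncestryTractSet(pd.DataFrame(sub), tracts.chrom_length)


# ---------------------------------------------------------------------------
# Scenarios
# ---------------------------------------------------------------------------

def _default_sweep(name: str, cfg: SimulationConfig) -> SweepConfig:
    if name == "private_sweep":
        # a single-copy (hard) sweep: the canonical model for a recent,
        # population-private adaptive variant
        return SweepConfig(component=cfg.ancestries[0], s=0.05, generations=400, p0=0.01)
    if name == "shared_sweep":
        # a hard sweep in the source that has nearly fixed there (~0.9) but
        # entered the target only through admixture
        return SweepConfig(component="EUR", s=0.05, generations=140, p0=0.01)
    if name == "post_admixture_sweep":
        return SweepConfig(
            component="target_post_admixture", favored_ancestry="EUR", s=0.10, generations=15
        )
    raise ValueError(name)


def _choose_sweep_site(
    pools: dict[str, HaplotypeMatrix],
    component: str,
    position_bp: int | None,
    p0: float,
    tol: float | None = None,
    max_other_freq: float = 0.15,
) -> int:
    """Site where the favored allele segregates near ``p0`` in the swept pool
    and is rare in every other pool (a recently arisen variant), nearest the
    requested position. The frequency tolerance scales with p0 so that the
    realized starting frequency tracks the configured one."""
    pool = pools[component]
    if tol is None:
        # never tighter than the pool's frequency granularity
        tol = max(p0 / 4.0, 1.0 / pool.n_haplotypes)
    freq = (pool.alleles == 1).mean(axis=0)
    others = [p for lab, p in pools.items() if lab != component]
    other_max = (
        np.max([(p.alleles == 1).mean(axis=0) for p in others], axis=0)
        if others
        else np.zeros(pool.n_sites)
    )
    target_pos = position_bp if position_bp is not None else int(pool.positions[-1] // 2)
    seg = (freq > 0) & (freq < 1)
    ok = np.zeros_like(seg)
    for mult, other_cap in ((1, max_other_freq), (2, 2 * max_other_freq), (4, 0.5), (8, 1.0)):
        ok = seg & (np.abs(freq - p0) <= mult * tol + 1e-12) & (other_max <= other_cap)
        if ok.any():
            break
    if not ok.any():
        raise InvalidConfigError(f"no suitable segregating site near p0={p0}")
    cand = np.flatnonzero(ok)
    # closest starting frequency first, then closest position
    best_df = np.min(np.abs(freq[cand] - p0))
    cand = cand[np.abs(freq[cand] - p0) <= best_df + 1e-12]
    return int(cand[np.argmin(np.abs(pool.positions[cand] - target_pos))])


def simulate_scenario(name: str, cfg: SimulationConfig) -> ScenarioBundle:
    """Simulate one named scenario; all randomness derives from ``cfg.seed``.

    Scenarios: ``neutral`` (no sweep), ``private_sweep`` (sweep in the
    autochthonous pool before admixture), ``shared_sweep`` (sweep in a named
    source pool before admixture; the source matrix is returned post-sweep),
    ``post_admixture_sweep`` (ancestry-linked selection on the assembled
    cohort).
    """
    if name not in SCENARIOS:
        raise ValueError(f"unknown scenario {name!r}; choose from {SCENARIOS}")
    rng = np.random.default_rng(cfg.seed)
    pools = build_founder_pools(cfg, rng)
    sweep = cfg.sweep if cfg.sweep is not None else (None if name == "neutral" else _default_sweep(name, cfg))

    truth: dict = {"scenario": name, "seed": cfg.seed, "sweep_pos": None, "sweep_site": None,
                   "favored_allele": None, "component": None, "config": None}
    locus = None
    if name in ("private_sweep", "shared_sweep"):
        comp = sweep.component
        if name == "private_sweep" and comp == "target_post_admixture":
            comp = cfg.ancestries[0]
        locus = _choose_sweep_site(pools, comp, sweep.position_bp, sweep.p0)
        pools[comp] = apply_sweep(
            pools[comp], locus, sweep.s, sweep.generations,
            cfg.recomb_rate, cfg.chrom_length_bp, rng,
        )
        truth.update(component=comp, favored_allele=1)
    elif name == "post_admixture_sweep":
        freq = (pools[cfg.ancestries[0]].alleles == 1).mean(axis=0)
        target_pos = sweep.position_bp if sweep.position_bp is not None else cfg.chrom_length_bp // 2
        locus = int(np.argmin(np.abs(pools[cfg.ancestries[0]].positions - target_pos)))
        truth.update(component=sweep.favored_ancestry, favored_allele=None)

    if name == "post_admixture_sweep":
        # selection acts in a larger post-admixture population; the cohort is
        # a sample drawn from it afterwards, so sampling noise - not closed-
        # population drift - sets the genome-wide dosage variance. The pulse
        # (g generations of tract chopping, in shorthand) precedes the
        # explicitly simulated selection phase: admixture happened
        # g + generations ago and the selective pressure appeared later.
        n_pop = max(cfg.selection_pop_haplotypes, 2 * cfg.cohort_size)
        big_cfg = dataclasses.replace(cfg, cohort_size=n_pop // 2)
        target, tracts = simulate_admixed_cohort(pools, big_cfg, rng)
        target, tracts = _resample_post_admixture(
            target, tracts, cfg, locus, sweep.favored_ancestry, sweep.s, sweep.generations, rng
        )
        target, tracts = _sample_cohort(target, tracts, 2 * cfg.cohort_size, rng)
    else:
        target, tracts = simulate_admixed_cohort(pools, cfg, rng)
    if locus is not None:
        truth["sweep_site"] = locus
        truth["sweep_pos"] = int(target.positions[locus])
    cfg_snapshot = dataclasses.replace(cfg, sweep=sweep)
    truth["config"] = cfg_snapshot.to_dict()
    variants = new_variant_table(cfg.chrom, target.positions)
    return ScenarioBundle(target, tracts, pools, variants, truth)


# ---------------------------------------------------------------------------
# Bundle I/O
# ---------------------------------------------------------------------------

def write_bundle(bundle: ScenarioBundle, outdir) -> dict[str, Path]:
    """Write a bundle as VCF + tract TSV + truth JSON + population tables.

    The target cohort and all source pools share one phased VCF; group
    membership lives in ``populations.tsv`` / ``groups.yaml``. Reading the
    files back reproduces the in-memory bundle exactly.
    """
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    cfg = SimulationConfig.from_dict(bundle.truth["config"])
    labels = list(bundle.sources)

    mats = [bundle.target] + [bundle.sources[lab] for lab in labels]
    alleles = np.vstack([m.alleles for m in mats])
    hap_ids, smap, offset = [], {}, 0
    for m in mats:
        hap_ids.extend(m.haplotype_ids)
        for s, (a, b) in m.sample_map.items():
            smap[s] = (a + offset, b + offset)
        offset += m.n_haplotypes
    combined = HaplotypeMatrix(alleles, bundle.target.positions, bundle.target.chrom, hap_ids, smap)

    paths = {
        "vcf": outdir / "cohort.vcf",
        "tracts": outdir / "tracts.tsv",
        "truth": outdir / "truth.json",
        "populations": outdir / "populations.tsv",
        "groups": outdir / "groups.yaml",
    }
    genio.write_vcf(combined, _combined_variants(bundle, combined), paths["vcf"],
                    contig_length=cfg.chrom_length_bp)
    genio.write_tracts(bundle.tracts, paths["tracts"])
    with open(paths["truth"], "w") as fh:
        json.dump(bundle.truth, fh, indent=1, sort_keys=True)
    from .core import PopulationSpec

    assignments = {s: "target" for s in bundle.target.samples}
    for lab in labels:
        assignments.update({s: lab for s in bundle.sources[lab].samples})
    groups = {"target": ["target"]}
    groups.update({f"source_{lab}": [lab] for lab in labels})
    spec = PopulationSpec(assignments, groups)
    genio.write_population_spec(spec, paths["populations"], paths["groups"])
    return paths


def _combined_variants(bundle: ScenarioBundle, combined: HaplotypeMatrix):
    vt = bundle.variants.copy()
    vt["pos"] = combined.positions
    return vt


def read_bundle(indir) -> ScenarioBundle:
    """Inverse of :func:`write_bundle`."""
    indir = Path(indir)
    with open(indir / "truth.json") as fh:
        truth = json.load(fh)
    cfg = SimulationConfig.from_dict(truth["config"])
    hm, vt = genio.read_vcf(indir / "cohort.vcf")
    spec = genio.read_population_spec(indir / "populations.tsv", indir / "groups.yaml")
    tracts = genio.read_tracts(indir / "tracts.tsv", cfg.chrom_length_bp)
    target = hm.take_samples(spec.group_samples("target"))
    sources = {
        lab: hm.take_samples(spec.group_samples(lab)) for lab in cfg.ancestries
    }
    return ScenarioBundle(target, tracts, sources, vt, truth)
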