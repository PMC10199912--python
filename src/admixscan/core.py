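"""Shared in-memory containers for phased data, scan scores, and ancestry tracts.

Conventions used throughout the package:

* haplotype alleles are ``int8`` codes: ``0`` (reference/ancestral after
  polarization), ``1`` (alternate/derived), ``-1`` (missing);
* genomic coordinates are 0-based half-open internally and 1-based only in
  VCF files;
* a diploid sample always owns exactly two haplotype rows.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

MISSING = np.int8(-1)


class InvalidConfigError(ValueError):
    """Raised when a simulation or run configuration violates its invariants."""


@dataclass
class HaplotypeMatrix:
    """Phased biallelic alleles for ``2N`` haplotypes at ``L`` ordered sites.

    Parameters
    ----------
    alleles
        ``(2N, L)`` int8 array of codes in ``{0, 1, -1}``.
    positions
        Strictly increasing base-pair positions (0-based).
    chrom
        Chromosome label shared by all sites.
    haplotype_ids
        One identifier per row of ``alleles``.
    sample_map
        Mapping ``sample -> (row_a, row_b)``; every sample owns two rows.
    """

    alleles: np.ndarray
    positions: np.ndarray
    chrom: str
    haplotype_ids: list[str]
    sample_map: dict[str, tuple[int, int]]

    def __post_init__(self) -> None:
        self.alleles = np.ascontiguousarray(self.alleles, dtype=np.int8)
        self.positions = np.asarray(self.positions, dtype=np.int64)
        if self.alleles.ndim != 2:
            raise ValueError("alleles must be 2-D (haplotypes x sites)")
        if self.positions.shape[0] != self.alleles.shape[1]:
            raise ValueError("positions length must match number of sites")
        if self.positions.size > 1 and not np.all(np.diff(self.positions) > 0):
            raise ValueError("positions must be strictly increasing")
        if len(self.haplotype_ids) != self.alleles.shape[0]:
            raise ValueError("haplotype_ids length must match haplotype count")
        for s, (a, b) in self.sample_map.items():
            if not (0 <= a < self.n_haplotypes and 0 <= b < self.n_haplotypes):
                raise ValueError(f"sample {s!r} maps outside the matrix")

    @property
    def n_haplotypes(self) -> int:
        return self.alleles.shape[0]

    @property
    def n_sites(self) -> int:
        return self.alleles.shape[1]

    @property
    def samples(self) -> list[str]:
        return list(self.sample_map)

    def take_sites(self, idx: np.ndarray) -> "HaplotypeMatrix":
        """New matrix restricted to site indices ``idx`` (kept in order)."""
        idx = np.asarray(idx)
        return HaplotypeMatrix(
            self.alleles[:, idx],
            self.positions[idx],
            self.chrom,
            list(self.haplotype_ids),
            dict(self.sample_map),
        )

    def take_samples(self, samples: Sequence[str]) -> "HaplotypeMatrix":
        """New matrix holding only the haplotypes of ``samples``."""
        rows: list[int] = []
        ids: list[str] = []
        smap: dict[str, tuple[int, int]] = {}
        for s in samples:
            a, b = self.sample_map[s]
            smap[s] = (len(rows), len(rows) + 1)
            rows.extend([a, b])
            ids.extend([self.haplotype_ids[a], self.haplotype_ids[b]])
        return HaplotypeMatrix(self.alleles[rows], self.positions, self.chrom, ids, smap)

    def haplotype_rows(self, samples: Iterable[str]) -> np.ndarray:
        """Row indices of the haplotypes belonging to ``samples``."""
        out: list[int] = []
        for s in samples:
            a, b = self.sample_map[s]
            out.extend([a, b])
        return np.asarray(out, dtype=np.intp)

    def __eq__(self, other: object) -> bool:  # pragma: no cover - convenience
        if not isinstance(other, HaplotypeMatrix):
            return NotImplemented
        return (
            self.chrom == other.chrom
            and np.array_equal(self.alleles, other.alleles)
            and np.array_equal(self.positions, other.positions)
            and self.haplotype_ids == other.haplotype_ids
            and self.sample_map == other.sample_map
        )


def new_variant_table(
    chrom: str,
    positions: np.ndarray,
    ids: Sequence[str] | None = None,
    ref: Sequence[str] | None = None,
    alt: Sequence[str] | None = None,
    ancestral: Sequence[str] | None = None,
) -> pd.DataFrame:
    """Per-site metadata table with columns id, chrom, pos, ref, alt, aa.

    ``aa`` is the ancestral allele; ``"N"`` marks an unknown state.
    """
    n = len(positions)
    return pd.DataFrame(
        {
            "id": list(ids) if ids is not None else [f"snp{i}" for i in range(n)],
            "chrom": chrom,
            "pos": np.asarray(positions, dtype=np.int64),
            "ref": list(ref) if ref is not None else ["A"] * n,
            "alt": list(alt) if alt is not None else ["G"] * n,
            "aa": list(ancestral) if ancestral is not None else ["A"] * n,
        }
    )


@dataclass
class PopulationSpec:
    """Sample-to-population assignments plus named unions of populations."""

    assignments: dict[str, str]
    groups: dict[str, list[str]] = field(default_factory=dict)

    def __post_init__(self) -> None:
        pops = set(self.assignments.values())
        for g, members in self.groups.items():
            missing = [p for p in members if p not in pops]
            if missing:
                raise ValueError(f"group {g!r} references unknown populations {missing}")

    def populations(self) -> list[str]:
        seen: dict[str, None] = {}
        for p in self.assignments.values():
            seen.setdefault(p)
        return list(seen)

    def group_samples(self, group: str) -> list[str]:
        """Samples in a named group (falling back to a bare population name)."""
        pops = set(self.groups.get(group, [group]))
        return [s for s, p in self.assignments.items() if p in pops]


@dataclass
class ScanScores:
    """Per-SNP values of one statistic plus its normalization metadata.

    ``table`` always carries ``chrom``, ``pos`` and the statistic columns
    (``raw``/``std`` where applicable); ``meta`` holds bin means/SDs, variance
    components or anything else needed to reproduce the standardization.
    """

    statistic: str
    table: pd.DataFrame
    meta: dict = field(default_factory=dict)

    def to_tsv(self, path) -> None:
        self.table.to_csv(path, sep="\t", index=False, float_format="%.10g")


@dataclass
class EHHCurve:
    """Extended haplotype homozygosity decay on one side of a core site."""

    core_index: int
    core_pos: int
    allele_mode: str  # "derived" | "ancestral" | "pooled"
    direction: str  # "up" (increasing pos) | "down"
    distances: np.ndarray  # bp from core, starting at 0
    ehh: np.ndarray
    reached_end: bool  # curve ran to the chromosome edge / max-gap truncation
    n_carriers: int

    def __post_init__(self) -> None:
        self.distances = np.asarray(self.distances, dtype=np.int64)
        self.ehh = np.asarray(self.ehh, dtype=np.float64)


@dataclass
class AncestryTractSet:
    """Per-haplotype labelled intervals tiling ``[0, chrom_length)``.

    Tracts are stored unmerged: adjacent same-label tracts are legal and all
    consumers are invariant to such splits.
    """

    table: pd.DataFrame  # haplotype_id, chrom, start, end, ancestry
    chrom_length: int

    def __post_init__(self) -> None:
        req = ["haplotype_id", "chrom", "start", "end", "ancestry"]
        if list(self.table.columns[:5]) != req:
            self.table = self.table[req]
        self.table = self.table.sort_values(["haplotype_id", "start"], kind="stable").reset_index(
            drop=True
        )

    def haplotype_ids(self) -> list[str]:
        seen: dict[str, None] = {}
        for h in self.table["haplotype_id"]:
            seen.setdefault(h)
        return list(seen)

    def validate_tiling(self) -> None:
        """Raise if any haplotype's tracts fail to tile the chromosome."""
        for hap, sub in self.table.groupby("haplotype_id", sort=False):
            starts = sub["start"].to_numpy()
            ends = sub["end"].to_numpy()
            if starts[0] != 0 or ends[-1] != self.chrom_length:
                raise ValueError(f"tracts of {hap} do not span the chromosome")
            if not np.array_equal(starts[1:], ends[:-1]):
                raise ValueError(f"tracts of {hap} overlap or leave gaps")

    def labels_at(self, hap: str, positions: np.ndarray) -> np.ndarray:
        sub = self.table[self.table["haplotype_id"] == hap]
        ends = sub["end"].to_numpy()
        idx = np.searchsorted(ends, positions, side="right")
        return sub["ancestry"].to_numpy()[idx]


@dataclass
class LocusAncestryProfile:
    """Per-site ancestry dosage fractions with genome-wide moments."""

    labels: list[str]
    positions: np.ndarray  # (L,)
    alpha: np.ndarray  # (K, L) dosage fractions, rows follow `labels`
    n_haplotypes: int
    chrom: str = "1"

    def __post_init__(self) -> None:
        self.alpha = np.asarray(self.alpha, dtype=np.float64)
        self.positions = np.asarray(self.positions, dtype=np.int64)

    @property
    def genome_mean(self) -> np.ndarray:
        return self.alpha.mean(axis=1)

    @property
    def genome_sd(self) -> np.ndarray:
        return self.alpha.std(axis=1)


@dataclass
class OutlierSet:
    """Top-fraction outliers of one ranking with their rank-based p-values."""

    statistic: str
    key: str  # "signed" or "abs"
    q: float
    table: pd.DataFrame  # site, chrom, pos, score, rank, p (rank 1 = most extreme)
    n_scored: int


@dataclass
class CandidateRegion:
    """A merged run of outlier SNPs attributed to one scan on one group."""

    chrom: str
    start: int
    end: int
    sites: list[int]  # site positions (bp) supporting the region
    tests: list[str]
    group: str
    genes: list[str] = field(default_factory=list)
    labels: list[str] = field(default_factory=list)
    info: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if not self.start < self.end:
            raise ValueError("region start must be < end")

    def overlaps(self, other: "CandidateRegion") -> bool:
        return self.chrom == other.chrom and self.start < other.end and other.start < self.end


@dataclass
class LDResult:
    """Two-locus haplotype-frequency LD summary."""

    site_i: int
    site_j: int
    counts: np.ndarray  # 2x2 haplotype counts, rows = allele at i, cols = at j
    D: float
    Dprime: float
    r2: float
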