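"""Inner loops for extended-haplotype-homozygosity walks (numba-compiled).

The walk maintains the partition of core-allele carriers into identical
extended haplotypes, refining it one site at a time away from the core.
Haplotypes are dropped at the first missing call in the extension; the
denominator stays fixed at the number of carriers present at the core, so
EHH is non-increasing by construction.
"""

from __future__ import annotations

import numpy as np
from numba import njit


@njit(cache=True)
def ehh_walk(
    alleles: np.ndarray,  # int8 (haplotypes x sites)
    positions: np.ndarray,  # int64
    core: int,
    carriers: np.ndarray,  # int64 row indices
    step: int,  # +1 upstream in position, -1 downstream
    maxgap: int,
    stop_below: float,  # record the first point with EHH < stop_below, then stop
    max_dist: int,
):
    """Walk EHH outward from ``core``.

    Returns ``(dists, ehhs, n_points, reached_end)``; ``reached_end`` is True
    when the walk stopped at the chromosome edge, a gap larger than
    ``maxgap``, or ``max_dist`` - i.e. EHH never dropped below
    ``stop_below`` inside the walked range.
    """
    n0 = carriers.shape[0]
    L = alleles.shape[1]
    dists = np.empty(L + 1, np.int64)
    ehhs = np.empty(L + 1, np.float64)
    dists[0] = 0
    ehhs[0] = 1.0
    m = 1
    reached_end = True
    if n0 < 2:
        return dists[:m], ehhs[:m], m, True
    denom = n0 * (n0 - 1) / 2.0
    grp = np.zeros(n0, np.int64)
    alive = np.ones(n0, np.uint8)
    lut_stamp = np.full(2 * n0 + 2, -1, np.int64)
    lut_id = np.empty(2 * n0 + 2, np.int64)
    core_pos = positions[core]
    prev_pos = core_pos
    j = core
    t = 0
    while True:
        j += step
        if j < 0 or j >= L:
            break
        gap = positions[j] - prev_pos
        if step < 0:
            gap = -gap
        if gap > maxgap:
            break
        dist = positions[j] - core_pos
        if step < 0:
            dist = -dist
        if dist > max_dist:
            break
        prev_pos = positions[j]
        t += 1
        ngrp = 0
        for i in range(n0):
            if alive[i] == 0:
                continue
            a = alleles[carriers[i], j]
            if a < 0:
                alive[i] = 0
                continue
            key = grp[i] * 2 + a
            if lut_stamp[key] != t:
                lut_stamp[key] = t
                lut_id[key] = ngrp
                ngrp += 1
            grp[i] = lut_id[key]
        cnt = np.zeros(ngrp, np.int64)
        for i in range(n0):
            if alive[i] == 1:
                cnt[grp[i]] += 1
        hom = 0.0
        for g in range(ngrp):
            hom += cnt[g] * (cnt[g] - 1) / 2.0
        e = hom / denom
        dists[m] = dist
        ehhs[m] = e
        m += 1
        if e < stop_below:
            reached_end = False
            break
        if e <= 0.0:
            reached_end = False
            break
    return dists[:m], ehhs[:m], m, reached_end


@njit(cache=True)
def trapezoid_prefix(dists: np.ndarray, ehhs: np.ndarray, cutoff: float) -> float:
    """Trapezoidal integral over the maximal prefix with EHH >= cutoff."""
    area = 0.0
    for i in range(1, dists.shape[0]):
        if ehhs[i] < cutoff:
            break
        area += (dists[i] - dists[i - 1]) * (ehhs[i] + ehhs[i - 1]) / 2.0
    return area


@njit(cache=True)
def trapezoid_to_extent(dists: np.ndarray, ehhs: np.ndarray, extent: int) -> float:
    """Trapezoidal integral over all points with distance <= extent."""
    area = 0.0
    for i in range(1, dists.shape[0]):
        if dists[i] > extent:
            break
        area += (dists[i] - dists[i - 1]) * (ehhs[i] + ehhs[i - 1]) / 2.0
    return area
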