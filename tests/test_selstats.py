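"""Selection statistics against independent oracles and their invariants."""

import numpy as np
import pytest

from admixscan import selstats as ss
from admixscan.core import PopulationSpec
from conftest import make_hm, two_group_spec


# ---------------------------------------------------------------------------
# Allele frequencies
# ---------------------------------------------------------------------------

def test_allele_frequencies_with_missing():
    hm = make_hm([[1, 1, 1], [1, 1, 0], [1, -1, 0], [1, 0, 0]])
    f = ss.allele_frequencies(hm)
    assert f[0] == 1.0
    assert f[1] == pytest.approx(2 / 3)
    assert f[2] == pytest.approx(0.25)


# ---------------------------------------------------------------------------
# Weir-Cockerham F_ST
# ---------------------------------------------------------------------------

def fst_oracle(geno_a, geno_b):
    """Naive scalar transcription of the 1984 two-population variance
    components from diploid genotypes (rows = individuals, one site)."""
    out = []
    for ga, gb in zip(geno_a.T, geno_b.T):
        ga = ga[ga >= 0]
        gb = gb[gb >= 0]
        n1, n2 = len(ga), len(gb)
        p1 = sum(ga) / (2 * n1)
        p2 = sum(gb) / (2 * n2)
        h1 = sum(1 for g in ga if g == 1) / n1
        h2 = sum(1 for g in gb if g == 1) / n2
        r = 2
        nbar = (n1 + n2) / r
        nc = (r * nbar - (n1**2 + n2**2) / (r * nbar)) / (r - 1)
        pbar = (n1 * p1 + n2 * p2) / (r * nbar)
        s2 = (n1 * (p1 - pbar) ** 2 + n2 * (p2 - pbar) ** 2) / ((r - 1) * nbar)
        hbar = (n1 * h1 + n2 * h2) / (r * nbar)
        a = (nbar / nc) * (
            s2 - (1 / (nbar - 1)) * (pbar * (1 - pbar) - ((r - 1) / r) * s2 - hbar / 4)
        )
        b = (nbar / (nbar - 1)) * (
            pbar * (1 - pbar) - ((r - 1) / r) * s2 - ((2 * nbar - 1) / (4 * nbar)) * hbar
        )
        c = hbar / 2
        out.append((a, b, c))
    return np.array(out)


def _random_fst_instance(rng, n_a, n_b, n_sites):
    n = n_a + n_b
    alleles = (rng.random((2 * n, n_sites)) < rng.uniform(0.1, 0.9, n_sites)).astype(np.int8)
    hm = make_hm(alleles)
    spec = two_group_spec(hm, n_a)
    return hm, spec


def test_fst_fixed_opposite_alleles_is_one():
    a = np.vstack([np.ones((4, 3)), np.zeros((4, 3))]).astype(np.int8)
    hm = make_hm(a)
    spec = two_group_spec(hm, 2)
    t = ss.weir_cockerham_fst(hm, spec, "A", "B").table
    np.testing.assert_allclose(t["fst"], 1.0)


def test_fst_monomorphic_site_flagged_undefined():
    a = np.zeros((8, 2), dtype=np.int8)
    a[0, 1] = 1
    hm = make_hm(a)
    spec = two_group_spec(hm, 2)
    t = ss.weir_cockerham_fst(hm, spec, "A", "B").table
    assert not t["defined"][0] and np.isnan(t["fst"][0])
    assert t["defined"][1]


def test_fst_matches_naive_oracle_on_random_instances(rng):
    for _ in range(200):
        n_a = int(rng.integers(2, 8))
        n_b = int(rng.integers(2, 8))
        hm, spec = _random_fst_instance(rng, n_a, n_b, 4)
        res = ss.weir_cockerham_fst(hm, spec, "A", "B").table
        ga = np.array([hm.alleles[hm.sample_map[s][0]] + hm.alleles[hm.sample_map[s][1]]
                       for s in spec.group_samples("A")])
        gb = np.array([hm.alleles[hm.sample_map[s][0]] + hm.alleles[hm.sample_map[s][1]]
                       for s in spec.group_samples("B")])
        want = fst_oracle(ga, gb)
        for j in range(4):
            a, b, c = want[j]
            if res["defined"][j]:
                assert res["a"][j] == pytest.approx(a, abs=1e-12)
                assert res["b"][j] == pytest.approx(b, abs=1e-12)
                assert res["c"][j] == pytest.approx(c, abs=1e-12)
                assert res["fst"][j] == pytest.approx(a / (a + b + c), abs=1e-12)


def test_fst_symmetric_in_group_order(rng):
    hm, spec = _random_fst_instance(rng, 5, 7, 6)
    t1 = ss.weir_cockerham_fst(hm, spec, "A", "B").table
    t2 = ss.weir_cockerham_fst(hm, spec, "B", "A").table
    np.testing.assert_allclose(t1["fst"], t2["fst"], equal_nan=True)


def test_fst_rejects_overlapping_or_tiny_groups():
    hm = make_hm(np.zeros((8, 2), dtype=np.int8))
    spec = two_group_spec(hm, 2)
    with pytest.raises(ValueError):
        ss.weir_cockerham_fst(hm, spec, "A", "A")
    one = PopulationSpec({s: p for s, p in zip(hm.samples, ["A", "A", "A", "B"])})
    with pytest.raises(ValueError):
        ss.weir_cockerham_fst(hm, one, "A", "B")


# ---------------------------------------------------------------------------
# EHH
# ---------------------------------------------------------------------------

def ehh_oracle(alleles, core, carriers, direction):
    """Direct homozygous-pair count, dropping haplotypes at first missing."""
    idx = range(core + 1, alleles.shape[1]) if direction == "up" else range(core - 1, -1, -1)
    n0 = len(carriers)
    denom = n0 * (n0 - 1) / 2
    alive = list(carriers)
    out = [1.0]
    ext = {h: [] for h in carriers}
    for j in idx:
        alive = [h for h in alive if alleles[h, j] >= 0]
        for h in alive:
            ext[h].append(alleles[h, j])
        pairs = 0
        for x in range(len(alive)):
            for y in range(x + 1, len(alive)):
                if ext[alive[x]] == ext[alive[y]]:
                    pairs += 1
        out.append(pairs / denom)
    return out


def test_ehh_identical_carriers_is_one():
    a = np.vstack([np.tile([1, 0, 1, 0, 1], (4, 1)), np.tile([0, 1, 0, 1, 0], (2, 1))]).astype(np.int8)
    a[:, 2] = [1, 1, 1, 1, 0, 0]
    hm = make_hm(a)
    c = ss.ehh_curve(hm, 2, "derived", "up")
    np.testing.assert_allclose(c.ehh, 1.0)


def test_ehh_two_pair_split_worked_value():
    # 4 carriers split 2+2 one site from the core: EHH = (1+1)/C(4,2) = 1/3
    a = np.array(
        [[1, 0, 0], [1, 0, 0], [1, 1, 0], [1, 1, 0], [0, 0, 0], [0, 1, 0]], dtype=np.int8
    )
    hm = make_hm(a)
    c = ss.ehh_curve(hm, 0, "derived", "up")
    assert c.ehh[1] == pytest.approx(1 / 3, abs=1e-15)


def test_ehh_needs_two_carriers():
    a = np.zeros((4, 3), dtype=np.int8)
    a[0, 1] = 1
    hm = make_hm(a)
    with pytest.raises(ValueError):
        ss.ehh_curve(hm, 1, "derived", "up")


@pytest.mark.parametrize("direction", ["up", "down"])
def test_ehh_matches_pair_enumeration_oracle(direction, rng):
    for trial in range(60):
        a = rng.integers(0, 2, size=(20, 50)).astype(np.int8)
        a[rng.random(a.shape) < 0.05] = -1
        core = int(rng.integers(5, 45))
        hm = make_hm(a, spacing=1000)
        for mode, allele in (("derived", 1), ("ancestral", 0)):
            carriers = np.flatnonzero(a[:, core] == allele)
            if carriers.size < 2:
                continue
            got = ss.ehh_curve(hm, core, mode, direction)
            want = ehh_oracle(a, core, list(carriers), direction)
            np.testing.assert_allclose(got.ehh, want[: len(got.ehh)], atol=1e-12)
            # monotone non-increasing, bounded
            assert np.all(np.diff(got.ehh) <= 1e-12)
            assert got.ehh[0] == 1.0 and np.all((got.ehh >= 0) & (got.ehh <= 1))


def test_ehh_truncates_at_large_gap():
    a = np.tile([1, 1, 1], (4, 1)).astype(np.int8)
    hm = make_hm(a, positions=[0, 10_000, 500_000])
    c = ss.ehh_curve(hm, 0, "derived", "up", maxgap_bp=200_000)
    assert len(c.ehh) == 2 and c.reached_end


# ---------------------------------------------------------------------------
# iHH integration
# ---------------------------------------------------------------------------

def _curve(dists, ehhs, reached_end=False):
    from admixscan.core import EHHCurve

    return EHHCurve(0, 0, "derived", "up", np.array(dists), np.array(ehhs), reached_end, 4)


def test_integrate_step_curve():
    # the first point below the cutoff is excluded from the prefix
    ihh, cens = ss.integrate_ehh(_curve([0, 100_000, 100_001], [1.0, 1.0, 0.0]))
    assert ihh == pytest.approx(100_000, abs=1e-9)


def test_integrate_triangle_with_zero_cutoff():
    ihh, _ = ss.integrate_ehh(_curve([0, 100_000], [1.0, 0.0]), cutoff=0.0)
    assert ihh == pytest.approx(50_000)


def test_integrate_cutoff_one_gives_zero():
    ihh, _ = ss.integrate_ehh(_curve([0, 50_000], [1.0, 0.8]), cutoff=1.0)
    assert ihh == 0.0


def test_integrate_flags_censored_curve():
    ihh, cens = ss.integrate_ehh(_curve([0, 50_000], [1.0, 0.5], reached_end=True))
    assert cens
    _, cens2 = ss.integrate_ehh(_curve([0, 50_000, 60_000], [1.0, 0.5, 0.01], reached_end=False))
    assert not cens2


def test_integrate_rejects_empty_curve():
    with pytest.raises(ValueError):
        ss.integrate_ehh(_curve([], []))


# ---------------------------------------------------------------------------
# iHS
# ---------------------------------------------------------------------------

def test_ihs_symmetric_site_scores_zero():
    # derived and ancestral carriers have mirror-identical extension patterns
    block = np.array(
        [
            [0, 1, 1, 1, 0, 0],
            [1, 1, 1, 0, 1, 0],
            [0, 0, 1, 1, 0, 1],
            [1, 0, 1, 0, 1, 1],
        ],
        dtype=np.int8,
    )
    a = np.vstack([block, block ^ np.array([0, 0, 1, 0, 0, 0], dtype=np.int8)])
    hm = make_hm(a, spacing=5000)
    scores = ss.ihs_scan(hm, maf_min=0.0, n_bins=1)
    raw = scores.table["raw"].to_numpy()
    core = 2
    assert np.isfinite(raw[core]) and raw[core] == pytest.approx(0.0, abs=1e-12)


def test_ihs_bins_standardized(neutral_bundle):
    scores = ss.ihs_scan(neutral_bundle.target, neutral_bundle.variants)
    t = scores.table
    fin = t[np.isfinite(t["std"])]
    for _, grp in fin.groupby("bin"):
        assert abs(grp["std"].mean()) < 1e-9
        if len(grp) > 1:
            assert abs(grp["std"].std(ddof=0) - 1) < 1e-9


# ---------------------------------------------------------------------------
# XP-EHH
# ---------------------------------------------------------------------------

def test_xpehh_same_panel_is_zero(neutral_bundle):
    hm = neutral_bundle.sources["EUR"]
    scores = ss.xpehh_scan(hm, hm)
    raw = scores.table["raw"].to_numpy()
    fin = raw[np.isfinite(raw)]
    assert fin.size > 0
    np.testing.assert_allclose(fin, 0.0, atol=1e-12)


def test_xpehh_panel_swap_negates_raw(neutral_bundle):
    a = neutral_bundle.target
    b = neutral_bundle.sources["WEA"]
    r1 = ss.xpehh_scan(a, b).table["raw"].to_numpy()
    r2 = ss.xpehh_scan(b, a).table["raw"].to_numpy()
    np.testing.assert_allclose(r1, -r2, atol=1e-12, equal_nan=True)


def test_xpehh_standardization(neutral_bundle):
    scores = ss.xpehh_scan(neutral_bundle.target, neutral_bundle.sources["WEA"])
    v = scores.table["std"].to_numpy()
    v = v[np.isfinite(v)]
    assert abs(v.mean()) < 1e-9 and abs(v.std() - 1) < 1e-9


def test_xpehh_requires_shared_site_map(neutral_bundle):
    a = neutral_bundle.target
    b = neutral_bundle.sources["WEA"].take_sites(np.arange(10))
    with pytest.raises(ValueError):
        ss.xpehh_scan(a, b)
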