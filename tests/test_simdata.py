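"""Generator contracts: pools, sweeps, admixture, scenarios, bundle I/O."""

import dataclasses

import numpy as np
import pytest
from scipy import stats as sps

from admixscan import genio, selstats as ss, simdata as sd
from admixscan.core import HaplotypeMatrix, InvalidConfigError, PopulationSpec


# ---------------------------------------------------------------------------
# Founder pools
# ---------------------------------------------------------------------------

def test_two_ancestry_pools_share_sites_and_are_polymorphic():
    cfg = sd.SimulationConfig(
        seed=5, n_sites=100, chrom_length_bp=2_000_000, ancestries=("A", "B"),
        admix_proportions=(0.5, 0.5), pool_sizes=40, cohort_size=10,
    )
    pools = sd.build_founder_pools(cfg)
    a, b = pools["A"], pools["B"]
    assert a.alleles.shape == (40, 100) and b.alleles.shape == (40, 100)
    np.testing.assert_array_equal(a.positions, b.positions)
    for m in (a, b):
        f = m.alleles.mean(axis=0)
        assert ((f > 0) & (f < 1)).mean() > 0.5


def test_pools_deterministic_under_seed():
    cfg = sd.SimulationConfig(seed=9, n_sites=200, chrom_length_bp=4_000_000,
                              pool_sizes=40, cohort_size=10)
    p1 = sd.build_founder_pools(cfg)
    p2 = sd.build_founder_pools(cfg)
    for lab in cfg.ancestries:
        assert np.array_equal(p1[lab].alleles, p2[lab].alleles)
        assert np.array_equal(p1[lab].positions, p2[lab].positions)


def test_invalid_configs_rejected():
    with pytest.raises(InvalidConfigError):
        sd.SimulationConfig(n_sites=1)
    with pytest.raises(InvalidConfigError):
        sd.SimulationConfig(pool_sizes=2)
    with pytest.raises(InvalidConfigError):
        sd.SimulationConfig(admix_proportions=(0.5, 0.5, 0.1, 0.1))
    with pytest.raises(InvalidConfigError):
        sd.SimulationConfig(sweep=sd.SweepConfig(s=-0.1))
    with pytest.raises(InvalidConfigError):
        sd.SimulationConfig(sweep=sd.SweepConfig(p0=1.5))


def test_realized_fst_within_half_of_target():
    vals = []
    for seed in range(10):
        cfg = sd.SimulationConfig(seed=seed, n_sites=500, chrom_length_bp=10_000_000,
                                  pool_sizes=60, cohort_size=10)
        pools = sd.build_founder_pools(cfg)
        labs = list(pools)
        for i in range(len(labs)):
            for j in range(i + 1, len(labs)):
                A, B = pools[labs[i]], pools[labs[j]]
                alle = np.vstack([A.alleles, B.alleles])
                off = A.n_haplotypes
                smap = dict(A.sample_map)
                smap.update({s + "x": (x + off, y + off) for s, (x, y) in B.sample_map.items()})
                ids = A.haplotype_ids + [h + "x" for h in B.haplotype_ids]
                hm = HaplotypeMatrix(alle, A.positions, A.chrom, ids, smap)
                spec = PopulationSpec({s: ("B" if s.endswith("x") else "A") for s in smap})
                t = ss.weir_cockerham_fst(hm, spec, "A", "B").table
                vals.append(t["a"].sum() / (t["a"] + t["b"] + t["c"]).sum())
    mean = float(np.mean(vals))
    assert 0.5 * 0.10 <= mean <= 1.5 * 0.10


# ---------------------------------------------------------------------------
# Sweeps
# ---------------------------------------------------------------------------

def _pool_with_carriers(n_carriers, m=100, n_sites=40, seed=0):
    rng = np.random.default_rng(seed)
    alle = (rng.random((m, n_sites)) < 0.4).astype(np.int8)
    locus = n_sites // 2
    alle[:, locus] = 0
    alle[:n_carriers, locus] = 1
    pos = np.arange(1, n_sites + 1) * 25_000
    ids = [f"P{i//2:03d}_{'AB'[i%2]}" for i in range(m)]
    smap = {f"P{i:03d}": (2 * i, 2 * i + 1) for i in range(m // 2)}
    return HaplotypeMatrix(alle, pos, "1", ids, smap), locus


def test_sweep_neutral_s_keeps_frequency():
    pool, locus = _pool_with_carriers(5)
    rng = np.random.default_rng(1)
    out = sd.apply_sweep(pool, locus, 0.0, 50, 1e-8, 1_100_000, rng)
    assert (out.alleles[:, locus] == 1).mean() == pytest.approx(0.05)


def test_sweep_final_frequency_matches_recursion():
    pool, locus = _pool_with_carriers(5)
    rng = np.random.default_rng(2)
    out = sd.apply_sweep(pool, locus, 0.05, 400, 1e-8, 1_100_000, rng)
    traj = sd.selection_trajectory(0.05, 0.05, 400)
    want = round(traj[-1] * 100) / 100
    assert (out.alleles[:, locus] == 1).mean() == pytest.approx(want)
    assert traj[-1] > 0.99


def test_sweep_requires_segregating_favored_allele():
    pool, locus = _pool_with_carriers(0)
    with pytest.raises(ValueError):
        sd.apply_sweep(pool, locus, 0.05, 100, 1e-8, 1_100_000, np.random.default_rng(0))


def test_sweep_elevates_ehh_at_50kb():
    """Mean pooled EHH 50 kb from the locus, swept vs unswept pool, 10 seeds."""
    diffs = []
    for seed in range(10):
        cfg = sd.SimulationConfig(seed=seed, n_sites=400, chrom_length_bp=10_000_000,
                                  pool_sizes=60, cohort_size=10)
        pools = sd.build_founder_pools(cfg)
        pool = pools["MAG"]
        locus = sd._choose_sweep_site(pools, "MAG", None, 0.05)
        rng = np.random.default_rng(seed + 1000)
        swept = sd.apply_sweep(pool, locus, 0.05, 200, cfg.recomb_rate, cfg.chrom_length_bp, rng)

        def ehh_at_50kb(hm):
            c = ss.ehh_curve(hm, locus, "pooled", "up", stop_below=0.0)
            sel = c.distances >= 50_000
            return c.ehh[np.argmax(sel)] if sel.any() else c.ehh[-1]

        diffs.append(ehh_at_50kb(swept) - ehh_at_50kb(pool))
    assert np.mean(diffs) > 0


# ---------------------------------------------------------------------------
# Admixture
# ---------------------------------------------------------------------------

def test_single_ancestry_cohort_has_unit_dosage():
    cfg = sd.SimulationConfig(
        seed=3, n_sites=50, chrom_length_bp=1_000_000, ancestries=("A", "B"),
        admix_proportions=(1.0, 0.0), pool_sizes=20, cohort_size=10,
    )
    pools = sd.build_founder_pools(cfg)
    hm, tracts = sd.simulate_admixed_cohort(pools, cfg)
    assert set(tracts.table["ancestry"]) == {"A"}
    tracts.validate_tiling()


def test_missing_pool_raises():
    cfg = sd.SimulationConfig(seed=3, n_sites=50, chrom_length_bp=1_000_000,
                              pool_sizes=20, cohort_size=5)
    pools = sd.build_founder_pools(cfg)
    del pools["MEA"]
    with pytest.raises(ValueError):
        sd.simulate_admixed_cohort(pools, cfg)


def test_tract_length_mean_matches_analytic():
    # breakpoints are Poisson(g*r) per bp so interior tract lengths are
    # exponential with mean 1/(g*r); use a chromosome much longer than the
    # mean so boundary truncation is negligible
    cfg = sd.SimulationConfig(seed=4, n_sites=10, chrom_length_bp=2_000_000_000,
                              generations_since_admixture=10)
    tr = sd.simulate_ancestry_tracts(cfg, np.random.default_rng(4), n_haplotypes=60)
    tab = tr.table
    inner = tab[(tab.start > 0) & (tab.end < cfg.chrom_length_bp)]
    lengths = (inner.end - inner.start).to_numpy()
    assert len(lengths) > 1000
    mean = lengths.mean()
    se = lengths.std() / np.sqrt(len(lengths))
    assert abs(mean - 10_000_000) < 2 * se + 1e-5 * 10_000_000


def test_tract_lengths_are_exponential_ks():
    passed = 0
    for seed in range(10):
        cfg = sd.SimulationConfig(seed=seed, n_sites=10, chrom_length_bp=6_000_000_000)
        tr = sd.simulate_ancestry_tracts(cfg, np.random.default_rng(seed), n_haplotypes=10)
        tab = tr.table
        inner = tab[(tab.start > 0) & (tab.end < cfg.chrom_length_bp)]
        lengths = (inner.end - inner.start).to_numpy()[:5000]
        p = sps.kstest(lengths, "expon", args=(0, 1e7)).pvalue
        passed += p > 0.01
    assert passed >= 9


def test_genome_wide_dosage_matches_proportions(neutral_bundle, small_cfg):
    from admixscan import ancestryscan as anc

    prof = anc.tracts_to_locus_dosage(
        neutral_bundle.tracts, neutral_bundle.target.positions, list(small_cfg.ancestries)
    )
    n_hap = 2 * small_cfg.cohort_size
    for k, q in enumerate(small_cfg.admix_proportions):
        se = np.sqrt(q * (1 - q) / n_hap)
        assert abs(prof.genome_mean[k] - q) < 3 * se + 0.02


# ---------------------------------------------------------------------------
# Scenarios
# ---------------------------------------------------------------------------

def test_neutral_truth_has_no_sweep(neutral_bundle):
    assert neutral_bundle.truth["scenario"] == "neutral"
    assert neutral_bundle.truth["sweep_pos"] is None


def test_unknown_scenario_rejected(small_cfg):
    with pytest.raises(ValueError):
        sd.simulate_scenario("bogus", small_cfg)


def test_shared_scenario_returns_swept_source(small_cfg):
    cfg = dataclasses.replace(small_cfg, seed=21)
    b = sd.simulate_scenario("shared_sweep", cfg)
    j = b.truth["sweep_site"]
    assert b.truth["component"] == "EUR"
    assert (b.sources["EUR"].alleles[:, j] == 1).mean() > 0.7


def test_post_admixture_scenario_raises_local_dosage(small_cfg):
    from admixscan import ancestryscan as anc

    hits = 0
    for seed in (31, 32, 33):
        cfg = dataclasses.replace(small_cfg, seed=seed)
        b = sd.simulate_scenario("post_admixture_sweep", cfg)
        prof = anc.tracts_to_locus_dosage(
            b.tracts, b.target.positions, list(cfg.ancestries)
        )
        k = prof.labels.index("EUR")
        hits += prof.alpha[k, b.truth["sweep_site"]] > prof.genome_mean[k]
    assert hits >= 2


def test_scenario_is_pure_function_of_config(small_cfg):
    cfg = dataclasses.replace(small_cfg, seed=77)
    b1 = sd.simulate_scenario("private_sweep", cfg)
    b2 = sd.simulate_scenario("private_sweep", cfg)
    assert np.array_equal(b1.target.alleles, b2.target.alleles)
    assert b1.tracts.table.equals(b2.tracts.table)
    assert b1.truth == b2.truth


# ---------------------------------------------------------------------------
# Bundle I/O
# ---------------------------------------------------------------------------

def test_bundle_round_trip(tmp_path, neutral_bundle):
    paths = sd.write_bundle(neutral_bundle, tmp_path / "b")
    back = sd.read_bundle(tmp_path / "b")
    assert back.target == neutral_bundle.target
    for lab, m in neutral_bundle.sources.items():
        assert back.sources[lab] == m
    assert back.truth["seed"] == neutral_bundle.truth["seed"]
    tr1 = neutral_bundle.tracts.table.reset_index(drop=True)
    tr2 = back.tracts.table.reset_index(drop=True)
    assert tr1.equals(tr2)


def test_bundle_tracts_tile_chromosome(neutral_bundle):
    neutral_bundle.tracts.validate_tiling()


def test_bundle_rerun_writes_identical_files(tmp_path, small_cfg):
    cfg = dataclasses.replace(small_cfg, seed=42)
    for d in ("r1", "r2"):
        sd.write_bundle(sd.simulate_scenario("neutral", cfg), tmp_path / d)
    for name in ("cohort.vcf", "tracts.tsv", "truth.json", "populations.tsv", "groups.yaml"):
        assert (tmp_path / "r1" / name).read_bytes() == (tmp_path / "r2" / name).read_bytes()
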