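import numpy as np
import pytest

from admixscan.core import HaplotypeMatrix, PopulationSpec, new_variant_table


def make_hm(alleles, positions=None, chrom="1", spacing=10_000):
    """HaplotypeMatrix from a 2-D list/array; rows paired into samples."""
    alleles = np.asarray(alleles, dtype=np.int8)
    n_hap, n_sites = alleles.shape
    assert n_hap % 2 == 0
    if positions is None:
        positions = np.arange(1, n_sites + 1) * spacing
    ids = [f"S{i // 2:03d}_{'AB'[i % 2]}" for i in range(n_hap)]
    smap = {f"S{i:03d}": (2 * i, 2 * i + 1) for i in range(n_hap // 2)}
    return HaplotypeMatrix(alleles, np.asarray(positions, dtype=np.int64), chrom, ids, smap)


def single_pop_spec(hm, name="pop"):
    return PopulationSpec({s: name for s in hm.samples})


def two_group_spec(hm, n_a):
    samples = hm.samples
    assignments = {s: ("A" if i < n_a else "B") for i, s in enumerate(samples)}
    return PopulationSpec(assignments)


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture(scope="session")
def small_cfg():
    """Down-scaled simulation used by module-level tests."""
    from admixscan.simdata import SimulationConfig

    return SimulationConfig(
        seed=11, n_sites=600, chrom_length_bp=8_000_000, pool_sizes=60, cohort_size=40
    )


@pytest.fixture(scope="session")
def neutral_bundle(small_cfg):
    from admixscan.simdata import simulate_scenario

    return simulate_scenario("neutral", small_cfg)


def variant_table_for(hm):
    return new_variant_table(hm.chrom, hm.positions)
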