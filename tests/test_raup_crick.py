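"""Raup-Crick null model: exact oracle, Monte-Carlo consistency, classification."""

import numpy as np
import pytest
from hypothesis import given, strategies as st

from islandstr.dataset import ArchipelagoDataset, IslandMetadata
from islandstr.raup_crick import (
    PairSimilarity,
    RaupCrickResult,
    classify_processes,
    exact_src_unweighted,
    raup_crick_island,
    raup_crick_pair,
)

from conftest import ts_from_sets

# 3 sigma on the rescaled statistic at worst-case binomial variance
def mc_tolerance(n_rand: int) -> float:
    return 3.0 * np.sqrt(0.25 / n_rand) * 2.0


def test_exact_oracle_reference_values():
    # pool of 10 equiprobable taxa, two singleton communities
    assert exact_src_unweighted(1, 1, 10, 1) == pytest.approx(0.9)
    assert exact_src_unweighted(1, 1, 10, 0) == pytest.approx(-0.1)
    # full-pool degenerate case: sharing is forced, indistinguishable from chance
    for n in (3, 7):
        assert exact_src_unweighted(n, n, n, n) == pytest.approx(0.0)


def test_exact_oracle_rejects_invalid_combinatorics():
    with pytest.raises(ValueError):
        exact_src_unweighted(3, 2, 10, 3)
    with pytest.raises(ValueError):
        exact_src_unweighted(0, 2, 10, 0)
    with pytest.raises(ValueError):
        exact_src_unweighted(11, 2, 10, 0)


def test_exact_oracle_monotone_in_shared_count():
    for pool, na, nb in [(10, 4, 6), (12, 5, 5), (8, 3, 7)]:
        vals = [exact_src_unweighted(na, nb, pool, s) for s in range(min(na, nb) + 1)]
        assert np.all(np.diff(vals) >= 0)
        # strictly increasing on the support of the null distribution
        lo = max(0, na + nb - pool)
        assert np.all(np.diff(vals[lo:]) > 0)


def test_monte_carlo_matches_hypergeometric_grid():
    """Equiprobable MC estimates track the closed form across small configs."""
    n_rand = 10_000
    rng_seed = 1234
    grid = [
        # (pool, comm_a, comm_b)
        (10, ["t0"], ["t0"]),
        (10, ["t0"], ["t1"]),
        (5, ["t0", "t1"], ["t1", "t2", "t3"]),
        (8, ["t0", "t1", "t2", "t3"], ["t2", "t3", "t4", "t5"]),
        (12, [f"t{i}" for i in range(6)], [f"t{i}" for i in range(3, 9)]),
        (12, [f"t{i}" for i in range(12)], [f"t{i}" for i in range(12)]),
    ]
    for k, (pool_n, a, b) in enumerate(grid):
        pool = [f"t{i}" for i in range(pool_n)]
        obs = len(set(a) & set(b))
        exact = exact_src_unweighted(len(a), len(b), pool_n, obs)
        est = raup_crick_pair(
            set(a), set(b), pool, n_rand=n_rand, seed=rng_seed + k,
            null_weighting="equiprobable",
        )
        assert est == pytest.approx(exact, abs=mc_tolerance(n_rand)), (pool_n, a, b)


def test_full_pool_pair_is_exactly_zero():
    pool = [f"t{i}" for i in range(6)]
    assert raup_crick_pair(set(pool), set(pool), pool, n_rand=500, seed=0) == 0.0


def test_pair_symmetry_under_mc_error():
    pool = [f"t{i}" for i in range(12)]
    a = {"t0", "t1", "t2"}
    b = {"t2", "t3", "t4", "t5", "t6"}
    n_rand = 20_000
    ab = raup_crick_pair(a, b, pool, n_rand=n_rand, seed=5, null_weighting="equiprobable")
    ba = raup_crick_pair(b, a, pool, n_rand=n_rand, seed=5, null_weighting="equiprobable")
    assert ab == pytest.approx(ba, abs=mc_tolerance(n_rand))


def test_pair_input_validation():
    pool = ["a", "b", "c"]
    with pytest.raises(ValueError, match="empty"):
        raup_crick_pair(set(), {"a"}, pool)
    with pytest.raises(ValueError, match="not in pool"):
        raup_crick_pair({"z"}, {"a"}, pool)


def _dataset_from_sets(all_island_sets: dict[str, list[set[str]]]) -> ArchipelagoDataset:
    islands = [ts_from_sets(s, island_id=i) for i, s in all_island_sets.items()]
    meta = {
        i: IslandMetadata(i, area_cm2=10.0, volume_ml=100.0) for i in all_island_sets
    }
    return ArchipelagoDataset.from_islands(islands, meta)


def test_island_pair_count_and_determinism():
    sets = [{"a", "b"}, {"b", "c"}, {"a", "d"}, {"b", "d"}]
    big_pool = [{f"p{i}"} | {"q"} for i in range(3)]
    ds = _dataset_from_sets({"I1": sets, "I2": big_pool})
    ts = ds.island("I1")
    r1 = raup_crick_island(ts, ds, n_rand=200, seed=99)
    r2 = raup_crick_island(ts, ds, n_rand=200, seed=99)
    assert len(r1.pairs) == 6  # 4*3/2
    np.testing.assert_array_equal(r1.values, r2.values)
    assert raup_crick_island(ts, ds, n_rand=200, seed=100).values.shape == (6,)
    with pytest.raises(ValueError, match="not part"):
        raup_crick_island(ts_from_sets(sets, island_id="ghost"), ds, n_rand=10)


def test_identical_censuses_small_richness_flag_dispersal():
    """Identical communities far below pool size rank above ~all null draws."""
    pool_sets = [{f"p{i}", f"p{i+1}"} for i in range(0, 40, 2)]
    ds = _dataset_from_sets(
        {"I1": [{"p0", "p2"}] * 4, "I2": pool_sets}
    )
    exact = exact_src_unweighted(2, 2, ds.pool_size, 2)
    assert exact > 0.95  # oracle confirms the configuration is extreme
    res = raup_crick_island(ds.island("I1"), ds, n_rand=1000, seed=1,
                            null_weighting="equiprobable")
    assert np.all(res.values >= 0.95)
    freqs = classify_processes(res)
    assert freqs.pct_homogenizing_dispersal == 100.0


def _result(values):
    pairs = [
        PairSimilarity(census_i=0, census_j=j + 1, day_i=0, day_j=j + 1,
                       obs_shared=0, s_rc=v)
        for j, v in enumerate(values)
    ]
    return RaupCrickResult("I", pairs, n_randomizations=0, null_weighting="occurrence",
                           seed=None)


def test_classification_bookkeeping():
    freqs = classify_processes(_result([0.99, 0.99, 0.5, -0.99]))
    assert freqs.pct_homogenizing_dispersal == pytest.approx(50.0)
    assert freqs.pct_drift == pytest.approx(25.0)
    assert freqs.pct_dispersal_limitation == pytest.approx(25.0)
    all_drift = classify_processes(_result([0.0, 0.0, 0.0]))
    assert all_drift.pct_drift == 100.0
    # boundary values are inclusive
    boundary = classify_processes(_result([0.95, -0.95]))
    assert boundary.pct_homogenizing_dispersal == pytest.approx(50.0)
    assert boundary.pct_dispersal_limitation == pytest.approx(50.0)
    with pytest.raises(ValueError, match="no pairs"):
        classify_processes(_result([]))


@given(st.lists(st.floats(min_value=-1.0, max_value=1.0), min_size=1, max_size=40))
def test_classification_percentages_sum_to_100(values):
    freqs = classify_processes(_result(values))
    total = (
        freqs.pct_homogenizing_dispersal
        + freqs.pct_dispersal_limitation
        + freqs.pct_drift
    )
    assert total == pytest.approx(100.0)
    for v in (freqs.pct_homogenizing_dispersal, freqs.pct_dispersal_limitation,
              freqs.pct_drift):
        assert 0.0 <= v <= 100.0
    # invariance to pair ordering
    rev = classify_processes(_result(values[::-1]))
    assert rev.pct_drift == freqs.pct_drift
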