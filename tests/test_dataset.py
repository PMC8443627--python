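"""Data-model invariants and TSV round trips."""

import numpy as np
import pandas as pd
import pytest

from islandstr.dataset import (
    ArchipelagoDataset,
    CommunityTimeSeries,
    DatasetError,
    IslandMetadata,
    read_archipelago,
    write_archipelago,
    write_results,
)
from islandstr.simulate import SimulationConfig, generate_archipelago


def _write_tables(tmp_path, counts: pd.DataFrame, meta: pd.DataFrame):
    tmp_path.mkdir(parents=True, exist_ok=True)
    taxa_p = tmp_path / "taxa.tsv"
    meta_p = tmp_path / "meta.tsv"
    counts.to_csv(taxa_p, sep="\t", index=False)
    meta.to_csv(meta_p, sep="\t", index=False)
    return taxa_p, meta_p


@pytest.fixture
def toy_tables(tmp_path):
    counts = pd.DataFrame(
        {
            "taxon_id": ["a", "b", "c"],
            "s1": [3, 1, 0],
            "s2": [0, 3, 0],
            "s3": [5, 0, 0],
            "s4": [0, 4, 0],
        }
    )
    meta = pd.DataFrame(
        {
            "sample_id": ["s1", "s2", "s3", "s4"],
            "island_id": ["I1"] * 4,
            "day": [0, 30, 60, 90],
            "area_cm2": [100.0] * 4,
            "volume_ml": [500.0] * 4,
        }
    )
    return _write_tables(tmp_path, counts, meta)


def test_single_island_load(toy_tables):
    ds = read_archipelago(*toy_tables)
    assert len(ds.islands) == 1
    ts = ds.islands[0]
    assert ts.n_censuses == 4
    # the all-zero taxon row 'c' is dropped
    assert ts.taxon_ids == ["a", "b"]
    assert ds.regional_pool == ["a", "b"]
    np.testing.assert_array_equal(ts.census_days, [0, 30, 60, 90])
    np.testing.assert_array_equal(ts.presence, [[1, 0, 1, 0], [1, 1, 0, 1]])


def test_days_rebased_to_first_census(tmp_path):
    counts = pd.DataFrame({"taxon_id": ["a"], "s1": [1], "s2": [2]})
    meta = pd.DataFrame(
        {
            "sample_id": ["s1", "s2"],
            "island_id": ["I1", "I1"],
            "day": [40, 75],
            "area_cm2": [10.0, 10.0],
            "volume_ml": [50.0, 50.0],
        }
    )
    ds = read_archipelago(*_write_tables(tmp_path, counts, meta))
    np.testing.assert_array_equal(ds.islands[0].census_days, [0, 35])


def test_regional_pool_union_and_occurrence(tmp_path):
    # two islands sharing taxa {a,b} and {b,c}: pool = {a,b,c}
    counts = pd.DataFrame(
        {
            "taxon_id": ["a", "b", "c"],
            "i1s1": [1, 1, 0],
            "i1s2": [1, 1, 0],
            "i2s1": [0, 1, 1],
            "i2s2": [0, 0, 1],
        }
    )
    meta = pd.DataFrame(
        {
            "sample_id": ["i1s1", "i1s2", "i2s1", "i2s2"],
            "island_id": ["I1", "I1", "I2", "I2"],
            "day": [0, 30, 0, 30],
            "area_cm2": [10.0] * 4,
            "volume_ml": [50.0] * 4,
        }
    )
    ds = read_archipelago(*_write_tables(tmp_path, counts, meta))
    assert ds.regional_pool == ["a", "b", "c"]
    assert ds.occurrence_freq == {"a": 2, "b": 3, "c": 2}
    total = sum(ts.presence.sum() for ts in ds.islands)
    assert sum(ds.occurrence_freq.values()) == total


@pytest.mark.parametrize(
    "mutation, message",
    [
        (lambda m: m.assign(sample_id=["s1", "s2", "s3", "sX"]), "unknown sample"),
        (lambda m: m.assign(day=[0, 30, 30, 90]), "duplicate"),
    ],
)
def test_bad_metadata_fatal(toy_tables, tmp_path, mutation, message):
    taxa_p, meta_p = toy_tables
    meta = mutation(pd.read_csv(meta_p, sep="\t"))
    bad = tmp_path / "bad_meta.tsv"
    meta.to_csv(bad, sep="\t", index=False)
    with pytest.raises(DatasetError, match=message):
        read_archipelago(taxa_p, bad)


def test_negative_counts_and_empty_sample_fatal(toy_tables, tmp_path):
    taxa_p, meta_p = toy_tables
    counts = pd.read_csv(taxa_p, sep="\t")
    counts.loc[0, "s1"] = -1
    bad = tmp_path / "neg.tsv"
    counts.to_csv(bad, sep="\t", index=False)
    with pytest.raises(DatasetError, match="negative"):
        read_archipelago(bad, meta_p)
    counts = pd.read_csv(taxa_p, sep="\t")
    counts["s2"] = 0
    empty = tmp_path / "empty.tsv"
    counts.to_csv(empty, sep="\t", index=False)
    with pytest.raises(DatasetError, match="empty sample"):
        read_archipelago(empty, meta_p)


def test_presence_threshold(toy_tables):
    ds = read_archipelago(*toy_tables, presence_threshold=3)
    ts = ds.islands[0]
    assert ts.taxon_ids == ["a", "b"]
    np.testing.assert_array_equal(ts.presence, [[1, 0, 1, 0], [0, 1, 0, 1]])


def test_type_invariants_enforced():
    with pytest.raises(DatasetError, match="strictly increasing"):
        CommunityTimeSeries("I", ["a"], [0, 0], np.ones((1, 2), bool))
    with pytest.raises(DatasetError, match="all-zero"):
        CommunityTimeSeries("I", ["a", "b"], [0, 1], np.array([[1, 1], [0, 0]], bool))
    with pytest.raises(DatasetError, match="empty census"):
        CommunityTimeSeries("I", ["a"], [0, 1], np.array([[1, 0]], bool))
    with pytest.raises(DatasetError, match="positive"):
        IslandMetadata("I", area_cm2=-1.0, volume_ml=10.0)


def test_pool_invariant_under_permutation(tmp_path):
    counts = pd.DataFrame(
        {
            "taxon_id": ["a", "b", "c"],
            "s1": [1, 1, 0],
            "s2": [0, 1, 1],
        }
    )
    meta = pd.DataFrame(
        {
            "sample_id": ["s1", "s2"],
            "island_id": ["I1", "I1"],
            "day": [0, 30],
            "area_cm2": [10.0, 10.0],
            "volume_ml": [50.0, 50.0],
        }
    )
    ds1 = read_archipelago(*_write_tables(tmp_path / "a1", counts, meta))
    shuffled = counts.iloc[[2, 0, 1]][["taxon_id", "s2", "s1"]]
    ds2 = read_archipelago(*_write_tables(tmp_path / "a2", shuffled, meta.iloc[[1, 0]]))
    assert ds1.regional_pool == ds2.regional_pool
    assert ds1.occurrence_freq == ds2.occurrence_freq


def test_round_trip_preserves_presence(tmp_path):
    cfg = SimulationConfig(n_islands=3, pool_size=60, n_censuses=5, c_v=5.0, seed=11)
    ds = generate_archipelago(cfg)
    write_archipelago(ds, tmp_path / "t.tsv", tmp_path / "m.tsv")
    back = read_archipelago(tmp_path / "t.tsv", tmp_path / "m.tsv")
    assert back.regional_pool == ds.regional_pool
    assert back.occurrence_freq == ds.occurrence_freq
    for orig, re_read in zip(ds.islands, back.islands):
        assert orig.island_id == re_read.island_id
        assert orig.taxon_ids == re_read.taxon_ids
        np.testing.assert_array_equal(orig.presence, re_read.presence)
        np.testing.assert_array_equal(orig.census_days, re_read.census_days)


def test_write_results_deterministic(tmp_path):
    tables = {
        "empty": pd.DataFrame(columns=["island_id", "x"]),
        "vals": pd.DataFrame({"island_id": ["I1"], "x": [1 / 3]}),
    }
    p1 = write_results(tables, tmp_path / "r1", run_summary={"seed": 1})
    p2 = write_results(tables, tmp_path / "r2", run_summary={"seed": 1})
    assert p1["empty"].read_text() == "island_id\tx\n"
    for name in tables:
        assert p1[name].read_bytes() == p2[name].read_bytes()


def test_metadata_series_summary():
    md = IslandMetadata(
        "I", area_cm2=10.0, volume_ml=100.0, volume_series=np.array([90.0, 110.0])
    )
    mean, sd = md.mean_volume()
    assert mean == 100.0
    assert sd == pytest.approx(np.std([90.0, 110.0], ddof=1))
    assert IslandMetadata("J", 10.0, 100.0).mean_volume() == (100.0, 0.0)


def test_from_islands_requires_metadata(worked_ts):
    with pytest.raises(DatasetError, match="without metadata"):
        ArchipelagoDataset.from_islands([worked_ts], {})
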