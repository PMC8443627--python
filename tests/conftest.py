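"""Shared fixtures and independent oracles for the test suite."""

from __future__ import annotations

import numpy as np
import pytest
from hypothesis import settings

from islandstr.dataset import CommunityTimeSeries

settings.register_profile("suite", derandomize=True, max_examples=50, deadline=None)
settings.load_profile("suite")


def ts_from_sets(census_sets: list[set[str]], island_id: str = "X",
                 days: list[int] | None = None) -> CommunityTimeSeries:
    """Build a CommunityTimeSeries from a list of per-census taxon sets."""
    taxa = sorted(set().union(*census_sets))
    presence = np.array([[t in c for c in census_sets] for t in taxa], dtype=bool)
    if days is None:
        days = list(range(0, 10 * len(census_sets), 10))
    return CommunityTimeSeries(island_id, taxa, np.array(days), presence)


def oracle_str(census_sets: list[set[str]]) -> dict[str, list[float]]:
    """Straightforward set-based enumeration of all three STR constructions.

    Deliberately naive and independent of the package implementation: MW
    walks pairwise and counts taxa absent from the immediately preceding
    census; CMW is the running union; EPW takes the union richness of every
    contiguous window of each span and averages within span.
    """
    n = len(census_sets)
    mw = [float(len(census_sets[0]))]
    for t in range(1, n):
        mw.append(mw[-1] + len(census_sets[t] - census_sets[t - 1]))
    cmw = [float(len(set().union(*census_sets[: t + 1]))) for t in range(n)]
    epw = []
    for k in range(1, n + 1):
        vals = [len(set().union(*census_sets[a : a + k])) for a in range(n - k + 1)]
        epw.append(sum(vals) / len(vals))
    return {"MW": mw, "CMW": cmw, "EPW": epw}


@pytest.fixture
def worked_sets() -> list[set[str]]:
    """The hand-checked 4-census example {a,b}, {b,c}, {a,d}, {b}."""
    return [{"a", "b"}, {"b", "c"}, {"a", "d"}, {"b"}]


@pytest.fixture
def worked_ts(worked_sets) -> CommunityTimeSeries:
    return ts_from_sets(worked_sets)


def random_census_sets(
    rng: np.random.Generator, n_taxa: int = 6, n_censuses: int = 6, p: float = 0.5
) -> list[set[str]]:
    """Random presence structure with no empty census and no unseen taxon."""
    taxa = [f"t{i}" for i in range(n_taxa)]
    while True:
        mat = rng.random((n_taxa, n_censuses)) < p
        if mat.any(axis=0).all() and mat.any(axis=1).all():
            return [{taxa[i] for i in range(n_taxa) if mat[i, t]} for t in range(n_censuses)]
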