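"""Monte-Carlo Raup-Crick similarity and ecological-process classification.

The Raup-Crick index asks whether two presence/absence communities share
more or fewer taxa than expected by chance, holding each community's
richness fixed and drawing null communities from the regional taxon pool.
With the null shared-count distribution in hand, the index used here is the
similarity-oriented rescaling to [-1, 1]:

    s_rc = 2 * ( P(null < obs) + 0.5 * P(null = obs) ) - 1

so +1 means the pair shares far more taxa than chance (homogenizing
dispersal), -1 far fewer (dispersal limitation / selection), and values in
between are indistinguishable from chance (ecological drift).  Ties get
half weight, which makes the forced-sharing degenerate case (both
communities equal to the whole pool) land exactly at 0.

Null draws sample taxa without replacement, by default with probability
proportional to each taxon's dataset-wide occurrence frequency (occupancy);
an equiprobable option is provided, for which the null distribution is
exactly hypergeometric and serves as a closed-form oracle.

Census pairs within an island are classified with the conventional +/-0.95
thresholds (inclusive): s_rc >= 0.95 homogenizing dispersal, <= -0.95
dispersal limitation, otherwise drift.  Speciation is not modeled.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .dataset import ArchipelagoDataset, CommunityTimeSeries

__all__ = [
    "RaupCrickResult",
    "ProcessFrequencies",
    "exact_src_unweighted",
    "raup_crick_pair",
    "raup_crick_island",
    "classify_processes",
    "PROCESSES",
]

PROCESSES = ("homogenizing_dispersal", "dispersal_limitation", "drift")


@dataclass(frozen=True)
class PairSimilarity:
    census_i: int
    census_j: int
    day_i: int
    day_j: int
    obs_shared: int
    s_rc: float


@dataclass
class RaupCrickResult:
    """All within-island pairwise s_rc values for one island."""

    island_id: str
    pairs: list[PairSimilarity]
    n_randomizations: int
    null_weighting: str
    seed: int | None

    @property
    def values(self) -> np.ndarray:
        return np.array([p.s_rc for p in self.pairs], dtype=float)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "island_id": self.island_id,
                "census_i": [p.census_i for p in self.pairs],
                "census_j": [p.census_j for p in self.pairs],
                "day_i": [p.day_i for p in self.pairs],
                "day_j": [p.day_j for p in self.pairs],
                "obs_shared": [p.obs_shared for p in self.pairs],
                "s_rc": [p.s_rc for p in self.pairs],
                "class": [classify_value(p.s_rc) for p in self.pairs],
            }
        )


@dataclass(frozen=True)
class ProcessFrequencies:
    """Percentages of an island's census pairs assigned to each process."""

    island_id: str
    pct_homogenizing_dispersal: float
    pct_dispersal_limitation: float
    pct_drift: float
    n_pairs: int


def _rescale(p_less: float, p_tie: float) -> float:
    return 2.0 * (p_less + 0.5 * p_tie) - 1.0


def exact_src_unweighted(
    richness_a: int, richness_b: int, pool_size: int, obs_shared: int
) -> float:
    """Closed-form s_rc under the equiprobable null.

    With uniform draws without replacement the null shared count follows
    the hypergeometric distribution
    P(shared = s) = C(n_a, s) C(pool - n_a, n_b - s) / C(pool, n_b),
    so the rescaled statistic is evaluated exactly.  Used as the
    independent oracle for the Monte-Carlo path.
    """
    if not (0 < richness_a <= pool_size and 0 < richness_b <= pool_size):
        raise ValueError("richness must be in 1..pool_size")
    if not 0 <= obs_shared <= min(richness_a, richness_b):
        raise ValueError("observed shared count exceeds the smaller richness")
    dist = stats.hypergeom(pool_size, richness_a, richness_b)
    p_less = float(dist.cdf(obs_shared - 1)) if obs_shared > 0 else 0.0
    p_tie = float(dist.pmf(obs_shared))
    return _rescale(p_less, p_tie)


def _null_presence(
    rng: np.random.Generator,
    weights: np.ndarray,
    richness: int,
    n_rand: int,
) -> np.ndarray:
    """``n_rand`` null communities of fixed richness as a boolean matrix.

    Weighted sampling without replacement via exponential sort keys
    (Efraimidis-Spirakis): taxon i gets key Exp(1)/w_i and the ``richness``
    smallest keys win, which reproduces sequential draws proportional to
    the remaining weights.
    """
    pool = weights.size
    if richness == pool:
        return np.ones((n_rand, pool), dtype=bool)
    keys = rng.exponential(size=(n_rand, pool)) / weights
    chosen = np.argpartition(keys, richness - 1, axis=1)[:, :richness]
    out = np.zeros((n_rand, pool), dtype=bool)
    np.put_along_axis(out, chosen, True, axis=1)
    return out


def _src_from_null(obs: int, null_shared: np.ndarray) -> float:
    n = null_shared.size
    p_less = np.count_nonzero(null_shared < obs) / n
    p_tie = np.count_nonzero(null_shared == obs) / n
    return _rescale(p_less, p_tie)


def raup_crick_pair(
    comm_a: frozenset | set,
    comm_b: frozenset | set,
    pool: list[str],
    weights: np.ndarray | None = None,
    n_rand: int = 1000,
    seed: int | np.random.Generator | None = None,
    null_weighting: str = "occurrence",
) -> float:
    """Monte-Carlo s_rc for one pair of communities.

    Each randomization draws one null community matching the richness of
    ``comm_a`` and one matching ``comm_b`` from the pool (without
    replacement, weighted unless ``null_weighting="equiprobable"``), and the
    observed shared-taxon count is ranked against the null shared counts.
    """
    pool_index = {t: i for i, t in enumerate(pool)}
    if not comm_a or not comm_b:
        raise ValueError("empty community")
    for comm in (comm_a, comm_b):
        unknown = set(comm) - pool_index.keys()
        if unknown:
            raise ValueError(f"community taxa not in pool: {sorted(unknown)[:5]}")
    n_a, n_b = len(comm_a), len(comm_b)
    if n_rand < 1:
        raise ValueError("n_rand must be >= 1")
    if null_weighting == "equiprobable" or weights is None:
        w = np.ones(len(pool), dtype=float)
    elif null_weighting == "occurrence":
        w = np.asarray(weights, dtype=float)
        if w.shape != (len(pool),) or (w <= 0).any():
            raise ValueError("weights must be positive and aligned with the pool")
    else:
        raise ValueError(f"unknown null weighting {null_weighting!r}")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    obs = len(set(comm_a) & set(comm_b))
    null_a = _null_presence(rng, w, n_a, n_rand)
    null_b = _null_presence(rng, w, n_b, n_rand)
    null_shared = np.count_nonzero(null_a & null_b, axis=1)
    return _src_from_null(obs, null_shared)


def raup_crick_island(
    ts: CommunityTimeSeries,
    dataset: ArchipelagoDataset,
    n_rand: int = 1000,
    seed: int | None = None,
    null_weighting: str = "occurrence",
) -> RaupCrickResult:
    """s_rc for every unordered census pair within one island.

    The pool and occupancy weights come from the whole archipelago and are
    applied identically to every island.  One null ensemble of ``n_rand``
    communities is drawn per census (at that census's richness) and pairs
    are ranked against the shared counts between the two censuses'
    ensembles; results are deterministic given the seed and symmetric in
    the pair order by construction.
    """
    if not any(t is ts for t in dataset.islands) and ts.island_id not in {
        t.island_id for t in dataset.islands
    }:
        raise ValueError(f"island {ts.island_id!r} is not part of the dataset")
    pool = dataset.regional_pool
    w = dataset.pool_weights(null_weighting)
    rng = np.random.default_rng(seed)
    n = ts.n_censuses
    rich = ts.richness_per_census()
    # align the island's taxa with pool columns once
    idx = np.array([pool.index(t) for t in ts.taxon_ids])
    pres = np.zeros((len(pool), n), dtype=bool)
    pres[idx, :] = ts.presence
    nulls = [_null_presence(rng, w, int(rich[t]), n_rand) for t in range(n)]
    pairs: list[PairSimilarity] = []
    for i in range(n):
        for j in range(i + 1, n):
            obs = int(np.count_nonzero(pres[:, i] & pres[:, j]))
            null_shared = np.count_nonzero(nulls[i] & nulls[j], axis=1)
            pairs.append(
                PairSimilarity(
                    census_i=i,
                    census_j=j,
                    day_i=int(ts.census_days[i]),
                    day_j=int(ts.census_days[j]),
                    obs_shared=obs,
                    s_rc=_src_from_null(obs, null_shared),
                )
            )
    return RaupCrickResult(
        island_id=ts.island_id,
        pairs=pairs,
        n_randomizations=n_rand,
        null_weighting=null_weighting,
        seed=seed,
    )


def classify_value(s_rc: float, threshold: float = 0.95) -> str:
    """Map one s_rc value to its process; thresholds are inclusive."""
    if s_rc >= threshold:
        return "homogenizing_dispersal"
    if s_rc <= -threshold:
        return "dispersal_limitation"
    return "drift"


def classify_processes(
    result: RaupCrickResult, threshold: float = 0.95
) -> ProcessFrequencies:
    """Percentage of an island's pairs assigned to each ecological process."""
    vals = result.values
    if vals.size == 0:
        raise ValueError("no pairs to classify")
    n = vals.size
    hd = np.count_nonzero(vals >= threshold)
    dl = np.count_nonzero(vals <= -threshold)
    drift = n - hd - dl
    return ProcessFrequencies(
        island_id=result.island_id,
        pct_homogenizing_dispersal=100.0 * hd / n,
        pct_dispersal_limitation=100.0 * dl / n,
        pct_drift=100.0 * drift / n,
        n_pairs=n,
    )
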