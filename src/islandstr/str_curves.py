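"""Species-time relationship (STR) curve construction.

An STR records how observed species richness S grows with the length of
time T over which a fixed community is monitored; empirically it follows
the power law S = c*T^w, the temporal analogue of the species-area
relationship.  Three window algorithms are implemented, differing in how a
"new" taxon is counted as a window moves along the time series:

MW (moving window)
    Adjoining censuses are taken pairwise; the count grows by the taxa
    present at census t but absent at census t-1.  A taxon that disappears
    and later re-appears is counted again at every re-appearance, so MW
    reflects gross immigration events.

CMW (cumulative moving window)
    Only the first appearance of each taxon counts: point t is the richness
    of the union of censuses 1..t, a running species-accumulation curve.

EPW (every possible window)
    For every span k, richness is accumulated within each of the
    n-k+1 contiguous windows of that span (which, on presence/absence,
    equals the union richness of the window) and the mean over windows is
    recorded at span k.

Spans are expressed in census counts (T = 1, 2, ..., n) so that log T is
defined at the first point even for single-census windows; the mean day
extent of the windows behind each point is reported alongside for plotting
against real time.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .dataset import CommunityTimeSeries

__all__ = [
    "STRPoint",
    "STRCurve",
    "enumerate_windows",
    "build_str_mw",
    "build_str_cmw",
    "build_str_epw",
    "build_str",
    "METHODS",
]

METHODS = ("MW", "CMW", "EPW")


@dataclass(frozen=True)
class STRPoint:
    """One (time span, species count) point of an STR curve.

    ``span`` counts censuses (>= 1); ``species`` is the cumulative count for
    MW/CMW and the mean over same-span windows for EPW; ``span_days_mean``
    is the mean day extent (last day - first day) of the contributing
    window(s); ``n_windows`` is how many windows fed the point.
    """

    span: int
    species: float
    span_days_mean: float
    n_windows: int


@dataclass
class STRCurve:
    island_id: str
    method: str
    points: list[STRPoint]
    #: per-window union richness keyed by span, kept for audit (EPW only)
    window_values: dict[int, np.ndarray] = field(default_factory=dict)

    def __post_init__(self) -> None:
        spans = [p.span for p in self.points]
        if spans != sorted(set(spans)):
            raise ValueError("STR points must be ordered by span with no duplicates")

    @property
    def spans(self) -> np.ndarray:
        return np.array([p.span for p in self.points], dtype=float)

    @property
    def species(self) -> np.ndarray:
        return np.array([p.species for p in self.points], dtype=float)

    @property
    def spans_days(self) -> np.ndarray:
        return np.array([p.span_days_mean for p in self.points], dtype=float)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "island_id": self.island_id,
                "method": self.method,
                "span": [p.span for p in self.points],
                "span_days_mean": [p.span_days_mean for p in self.points],
                "S": [p.species for p in self.points],
                "n_windows": [p.n_windows for p in self.points],
            }
        )


def enumerate_windows(n_censuses: int, span_k: int) -> list[tuple[int, int]]:
    """All contiguous census-index windows of span ``span_k``.

    Returns the n - k + 1 inclusive index pairs (a, a+k-1) in order, e.g. a
    20-census series has 20 span-1 windows, 19 span-2 windows, 18 span-3
    windows, and so on.
    """
    if not 1 <= span_k <= n_censuses:
        raise ValueError(f"span {span_k} out of range for {n_censuses} censuses")
    return [(a, a + span_k - 1) for a in range(n_censuses - span_k + 1)]


def build_str_mw(ts: CommunityTimeSeries) -> STRCurve:
    """Moving-window STR: re-counts taxa at every re-appearance.

    Point 1 is the richness of the first census; point t adds the number of
    taxa present at census t but absent at census t-1.
    """
    pres = ts.presence
    new_vs_prev = pres[:, 1:] & ~pres[:, :-1]
    s = np.concatenate([[pres[:, 0].sum()], new_vs_prev.sum(axis=0)]).cumsum()
    points = [
        STRPoint(
            span=t + 1,
            species=float(s[t]),
            span_days_mean=float(ts.census_days[t] - ts.census_days[0]),
            n_windows=1,
        )
        for t in range(ts.n_censuses)
    ]
    return STRCurve(ts.island_id, "MW", points)


def build_str_cmw(ts: CommunityTimeSeries) -> STRCurve:
    """Cumulative-moving-window STR: first appearances only (running union)."""
    first_seen = ts.presence.argmax(axis=1)  # rows all have >= 1 presence
    s = np.zeros(ts.n_censuses)
    np.add.at(s, first_seen, 1)
    s = s.cumsum()
    points = [
        STRPoint(
            span=t + 1,
            species=float(s[t]),
            span_days_mean=float(ts.census_days[t] - ts.census_days[0]),
            n_windows=1,
        )
        for t in range(ts.n_censuses)
    ]
    return STRCurve(ts.island_id, "CMW", points)


def build_str_epw(ts: CommunityTimeSeries) -> STRCurve:
    """Every-possible-window STR: mean accumulated richness per span.

    Windows are grouped by census-count span even when their day extents
    differ under irregular sampling; the mean day extent per span is
    reported alongside.  Within a window, chaining first appearances over
    its censuses reduces, for presence/absence data, to the union richness
    of the window.
    """
    n = ts.n_censuses
    pres = ts.presence
    days = ts.census_days
    points = []
    window_values: dict[int, np.ndarray] = {}
    for k in range(1, n + 1):
        wins = enumerate_windows(n, k)
        vals = np.array(
            [pres[:, a : b + 1].any(axis=1).sum() for a, b in wins], dtype=float
        )
        window_values[k] = vals
        points.append(
            STRPoint(
                span=k,
                species=float(vals.mean()),
                span_days_mean=float(np.mean([days[b] - days[a] for a, b in wins])),
                n_windows=len(wins),
            )
        )
    return STRCurve(ts.island_id, "EPW", points, window_values=window_values)


_BUILDERS = {"MW": build_str_mw, "CMW": build_str_cmw, "EPW": build_str_epw}


def build_str(ts: CommunityTimeSeries, method: str) -> STRCurve:
    """Dispatch to one of the three construction methods by name."""
    try:
        return _BUILDERS[method.upper()](ts)
    except KeyError:
        raise ValueError(f"unknown STR method {method!r}; choose from {METHODS}") from None
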