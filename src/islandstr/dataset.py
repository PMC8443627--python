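"""Core data model and tabular I/O for archipelago community time series.

An *archipelago* is a set of discrete island-like habitats (e.g. water-filled
tree-holes on a single tree) that share one regional taxon pool.  Each island
is censused repeatedly over time; the unit record is a taxon x census
presence/absence matrix plus per-island size metadata (surface area, volume).

All downstream statistics (species-time relationships, Raup-Crick null
models) operate on presence/absence, so counts are optional and are reduced
to presence at load time via ``presence_threshold``.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

__all__ = [
    "CommunityTimeSeries",
    "IslandMetadata",
    "ArchipelagoDataset",
    "read_archipelago",
    "write_archipelago",
    "write_results",
]


class DatasetError(ValueError):
    """Raised when input tables violate the data-model invariants."""


@dataclass
class CommunityTimeSeries:
    """One island's presence/absence taxon matrix over ordered censuses.

    Parameters
    ----------
    island_id
        Opaque island label.
    taxon_ids
        Taxon labels, one per matrix row.  Opaque strings; no taxonomy is
        parsed anywhere.
    census_days
        Integer days since the island's first census (first entry 0),
        strictly increasing, length >= 2.
    presence
        Boolean taxon x census matrix.  Every row must have at least one
        presence; empty censuses (all-zero columns) are rejected because
        log-richness and null-model draws are undefined for them.
    counts
        Optional non-negative integer matrix of the same shape.
    """

    island_id: str
    taxon_ids: list[str]
    census_days: np.ndarray
    presence: np.ndarray
    counts: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.census_days = np.asarray(self.census_days, dtype=int)
        self.presence = np.asarray(self.presence, dtype=bool)
        if self.census_days.ndim != 1 or self.census_days.size < 2:
            raise DatasetError(
                f"{self.island_id}: need >= 2 censuses, got {self.census_days.size}"
            )
        if np.any(np.diff(self.census_days) <= 0):
            raise DatasetError(f"{self.island_id}: census_days must be strictly increasing")
        if self.presence.shape != (len(self.taxon_ids), self.census_days.size):
            raise DatasetError(
                f"{self.island_id}: presence shape {self.presence.shape} does not match "
                f"{len(self.taxon_ids)} taxa x {self.census_days.size} censuses"
            )
        if len(set(self.taxon_ids)) != len(self.taxon_ids):
            raise DatasetError(f"{self.island_id}: duplicate taxon ids")
        if self.presence.shape[0] == 0 or not self.presence.any(axis=1).all():
            raise DatasetError(f"{self.island_id}: all-zero taxon rows are not allowed")
        if not self.presence.any(axis=0).all():
            raise DatasetError(f"{self.island_id}: empty census (no taxa observed)")
        if self.counts is not None:
            self.counts = np.asarray(self.counts, dtype=int)
            if self.counts.shape != self.presence.shape:
                raise DatasetError(f"{self.island_id}: counts shape mismatch")
            if (self.counts < 0).any():
                raise DatasetError(f"{self.island_id}: negative counts")

    @property
    def n_censuses(self) -> int:
        return self.census_days.size

    @property
    def n_taxa(self) -> int:
        return len(self.taxon_ids)

    def richness_per_census(self) -> np.ndarray:
        """Observed richness at each census (column sums of presence)."""
        return self.presence.sum(axis=0)

    def census_taxa(self, t: int) -> frozenset[str]:
        """Set of taxa present at census index ``t``."""
        mask = self.presence[:, t]
        return frozenset(tax for tax, m in zip(self.taxon_ids, mask) if m)

    @property
    def duration_days(self) -> int:
        return int(self.census_days[-1] - self.census_days[0])


@dataclass
class IslandMetadata:
    """Island size metadata: surface area (cm^2) and habitat volume (mL).

    When the island was re-measured at each census (aquatic habitats refill
    and drain), the per-census series is retained and the summary size is
    the mean over censuses with its sample SD.  A single measurement gets
    SD 0.
    """

    island_id: str
    area_cm2: float
    volume_ml: float
    area_series: np.ndarray | None = None
    volume_series: np.ndarray | None = None

    def __post_init__(self) -> None:
        if self.area_cm2 <= 0 or self.volume_ml <= 0:
            raise DatasetError(f"{self.island_id}: area and volume must be positive")
        for name in ("area_series", "volume_series"):
            s = getattr(self, name)
            if s is not None:
                s = np.asarray(s, dtype=float)
                if (s <= 0).any():
                    raise DatasetError(f"{self.island_id}: non-positive {name}")
                setattr(self, name, s)

    def _summary(self, series: np.ndarray | None, single: float) -> tuple[float, float]:
        if series is None or series.size < 2:
            return float(single), 0.0
        return float(series.mean()), float(series.std(ddof=1))

    def mean_area(self) -> tuple[float, float]:
        """(mean, sample SD) of area over censuses; SD 0 for one measurement."""
        return self._summary(self.area_series, self.area_cm2)

    def mean_volume(self) -> tuple[float, float]:
        """(mean, sample SD) of volume over censuses; SD 0 for one measurement."""
        return self._summary(self.volume_series, self.volume_ml)


@dataclass
class ArchipelagoDataset:
    """A set of island time series sharing one regional taxon pool.

    ``regional_pool`` is the exact union of taxa observed anywhere in the
    dataset, and ``occurrence_freq`` maps each pool member to the number of
    samples (island-censuses, dataset-wide) in which it occurs.  These drive
    the occupancy-weighted Raup-Crick null model.
    """

    islands: list[CommunityTimeSeries]
    metadata: dict[str, IslandMetadata]
    regional_pool: list[str] = field(default_factory=list)
    occurrence_freq: dict[str, int] = field(default_factory=dict)

    @classmethod
    def from_islands(
        cls,
        islands: list[CommunityTimeSeries],
        metadata: dict[str, IslandMetadata] | list[IslandMetadata],
    ) -> "ArchipelagoDataset":
        if not isinstance(metadata, dict):
            metadata = {m.island_id: m for m in metadata}
        missing = [ts.island_id for ts in islands if ts.island_id not in metadata]
        if missing:
            raise DatasetError(f"islands without metadata: {missing}")
        freq: dict[str, int] = {}
        for ts in islands:
            occ = ts.presence.sum(axis=1)
            for tax, k in zip(ts.taxon_ids, occ):
                freq[tax] = freq.get(tax, 0) + int(k)
        pool = sorted(freq)
        return cls(islands=islands, metadata=metadata, regional_pool=pool, occurrence_freq=freq)

    def __post_init__(self) -> None:
        if not self.regional_pool and self.islands:
            rebuilt = ArchipelagoDataset.from_islands(self.islands, self.metadata)
            self.regional_pool = rebuilt.regional_pool
            self.occurrence_freq = rebuilt.occurrence_freq

    @property
    def pool_size(self) -> int:
        return len(self.regional_pool)

    def island(self, island_id: str) -> CommunityTimeSeries:
        for ts in self.islands:
            if ts.island_id == island_id:
                return ts
        raise DatasetError(f"unknown island {island_id!r}")

    def pool_weights(self, weighting: str = "occurrence") -> np.ndarray:
        """Null-model draw weights aligned with ``regional_pool``.

        ``"occurrence"`` weights each taxon by its dataset-wide occupancy
        (number of samples in which it occurs); ``"equiprobable"`` gives
        uniform weights.
        """
        if weighting == "occurrence":
            return np.array([self.occurrence_freq[t] for t in self.regional_pool], dtype=float)
        if weighting == "equiprobable":
            return np.ones(self.pool_size, dtype=float)
        raise ValueError(f"unknown null weighting {weighting!r}")


def read_archipelago(
    taxon_table_path: str | Path,
    metadata_path: str | Path,
    presence_threshold: int = 1,
) -> ArchipelagoDataset:
    """Load an archipelago from a taxon table TSV and a sample metadata TSV.

    The taxon table has a first column ``taxon_id`` and one integer column
    per sample.  The metadata table maps every sample column to
    ``island_id``, ``day``, ``area_cm2`` and ``volume_ml``.  Samples are
    grouped by island and sorted by day; days are re-based so each island's
    first census is day 0.  Presence is scored as count >= threshold
    (default 1 read).  Taxa never observed within an island are dropped from
    that island's matrix but stay in the regional pool if seen elsewhere.
    """
    table = pd.read_csv(taxon_table_path, sep="\t", dtype={0: str})
    if table.columns[0] != "taxon_id":
        raise DatasetError("taxon table must start with a 'taxon_id' column")
    table = table.set_index("taxon_id")
    meta = pd.read_csv(metadata_path, sep="\t", dtype={"sample_id": str, "island_id": str})
    required = {"sample_id", "island_id", "day", "area_cm2", "volume_ml"}
    if not required.issubset(meta.columns):
        raise DatasetError(f"metadata must have columns {sorted(required)}")

    unknown = set(meta["sample_id"]) - set(table.columns)
    if unknown:
        raise DatasetError(f"metadata references unknown sample columns: {sorted(unknown)}")
    unmapped = set(table.columns) - set(meta["sample_id"])
    if unmapped:
        raise DatasetError(f"taxon-table samples missing from metadata: {sorted(unmapped)}")
    if meta.duplicated(["island_id", "day"]).any():
        dup = meta[meta.duplicated(["island_id", "day"], keep=False)]
        raise DatasetError(f"duplicate (island, day) pairs:\n{dup}")
    if (table.to_numpy() < 0).any():
        raise DatasetError("negative counts in taxon table")

    islands: list[CommunityTimeSeries] = []
    metadata: dict[str, IslandMetadata] = {}
    for island_id, grp in meta.groupby("island_id", sort=True):
        grp = grp.sort_values("day")
        days = grp["day"].to_numpy(dtype=int)
        days = days - days.min()
        counts = table[grp["sample_id"].tolist()].to_numpy(dtype=int)
        presence = counts >= presence_threshold
        keep = presence.any(axis=1)
        if not presence.any(axis=0).all():
            empty = days[~presence.any(axis=0)]
            raise DatasetError(f"{island_id}: empty sample(s) at day(s) {empty.tolist()}")
        islands.append(
            CommunityTimeSeries(
                island_id=str(island_id),
                taxon_ids=[t for t, k in zip(table.index, keep) if k],
                census_days=days,
                presence=presence[keep],
                counts=counts[keep],
            )
        )
        areas = grp["area_cm2"].to_numpy(dtype=float)
        vols = grp["volume_ml"].to_numpy(dtype=float)
        metadata[str(island_id)] = IslandMetadata(
            island_id=str(island_id),
            area_cm2=float(areas.mean()),
            volume_ml=float(vols.mean()),
            area_series=areas if len(set(areas)) > 1 else None,
            volume_series=vols if len(set(vols)) > 1 else None,
        )
    return ArchipelagoDataset.from_islands(islands, metadata)


def write_archipelago(
    dataset: ArchipelagoDataset,
    taxon_table_path: str | Path,
    metadata_path: str | Path,
) -> None:
    """Write a dataset back to the taxon-table + metadata TSV pair.

    Counts are written when present, otherwise presence as 0/1; reading the
    pair back reproduces every presence matrix exactly.
    """
    cols: dict[str, np.ndarray] = {}
    meta_rows = []
    pool = dataset.regional_pool
    index = {t: i for i, t in enumerate(pool)}
    for ts in dataset.islands:
        md = dataset.metadata[ts.island_id]
        for j, day in enumerate(ts.census_days):
            sample = f"{ts.island_id}_d{int(day)}"
            col = np.zeros(len(pool), dtype=int)
            vals = ts.counts[:, j] if ts.counts is not None else ts.presence[:, j].astype(int)
            for tax, v in zip(ts.taxon_ids, vals):
                col[index[tax]] = v
            cols[sample] = col
            area = md.area_series[j] if md.area_series is not None else md.area_cm2
            vol = md.volume_series[j] if md.volume_series is not None else md.volume_ml
            meta_rows.append(
                {
                    "sample_id": sample,
                    "island_id": ts.island_id,
                    "day": int(day),
                    "area_cm2": float(area),
                    "volume_ml": float(vol),
                }
            )
    table = pd.DataFrame(cols, index=pd.Index(pool, name="taxon_id"))
    table.to_csv(taxon_table_path, sep="\t")
    pd.DataFrame(meta_rows).to_csv(metadata_path, sep="\t", index=False)


def write_results(
    tables: dict[str, pd.DataFrame],
    out_dir: str | Path,
    run_summary: dict | None = None,
    float_format: str = "%.6g",
) -> dict[str, Path]:
    """Write result tables as TSVs plus a JSON run summary.

    Column order is taken from each DataFrame as-is and floats are written
    at fixed precision, so re-running with identical inputs reproduces
    byte-identical files.
    """
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    paths: dict[str, Path] = {}
    for name, df in tables.items():
        p = out / f"{name}.tsv"
        df.to_csv(p, sep="\t", index=False, float_format=float_format)
        paths[name] = p
    if run_summary is not None:
        p = out / "run_summary.json"
        p.write_text(json.dumps(run_summary, indent=2, sort_keys=True) + "\n")
        paths["run_summary"] = p
    return paths
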