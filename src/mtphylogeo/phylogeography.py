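"""Geographic ranges, dispersal centers, frequency tables, native-region rules.

The center-of-dispersal convention is the arithmetic mean of decimal-degree
coordinates (with per-axis sample standard deviations), applied first to the
regions where a haplogroup's basal lineages occur (its geometric center) and
then to the centers of a haplogroup's evolved daughter clades (the dispersal
focus of the ancestor).  A great-circle (spherical centroid) alternative is
available behind a flag.  Native-region assignment follows the 90%/10% rule:
a clade is native to the region holding at least 90% of its occurrences when
no other region exceeds 10%; clades present in every region are widespread.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from .mtdna_io import Haplotype


@dataclass(frozen=True)
class GeoPoint:
    lat: float
    lon: float
    label: str = ""
    lat_sd: float = 0.0
    lon_sd: float = 0.0

    def __post_init__(self) -> None:
        if not (-90 <= self.lat <= 90):
            raise ValueError(f"latitude {self.lat} outside -90..90")
        if not (-180 <= self.lon <= 180):
            raise ValueError(f"longitude {self.lon} outside -180..180")


@dataclass
class RegionPartition:
    """Named regions with member populations and a representative coordinate."""

    regions: list[tuple[str, tuple[str, ...], GeoPoint]]

    def __post_init__(self) -> None:
        pops = [p for _, members, _ in self.regions for p in members]
        if len(pops) != len(set(pops)):
            raise ValueError("population names must be unique across regions")

    @property
    def names(self) -> list[str]:
        return [name for name, _, _ in self.regions]

    def point(self, region: str) -> GeoPoint:
        for name, _, pt in self.regions:
            if name == region:
                return pt
        raise KeyError(f"unknown region {region!r}")

    def region_of(self, population: str) -> str:
        for name, members, _ in self.regions:
            if population in members:
                return name
        raise KeyError(f"population {population!r} not in any region")

    @classmethod
    def from_tsv(cls, path) -> "RegionPartition":
        df = pd.read_csv(path, sep="\t", dtype={"region": str, "populations": str}).fillna("")
        return cls(
            [
                (
                    row.region,
                    tuple(p for p in str(row.populations).split(",") if p),
                    GeoPoint(float(row.lat), float(row.lon), row.region),
                )
                for row in df.itertuples()
            ]
        )


class AntimeridianError(ValueError):
    """Longitudes span >=180 degrees; pass unwrap=True with a cut longitude."""


def haplogroup_range(
    samples: Sequence[Haplotype],
    haplogroup: str,
    assignments: Mapping[str, str],
    basal_only: bool = False,
    exclude_regions: Iterable[str] = (),
    daughters: Iterable[str] = (),
) -> set[str]:
    """Regions where the haplogroup is present.

    ``assignments`` maps sample_id -> assigned haplogroup name.  With
    ``basal_only``, samples assigned to a named daughter clade (any name in
    ``daughters``) do not establish presence.  Regions on the exclusion list
    (known recent colonization) are removed.
    """
    daughters = set(daughters)
    present: set[str] = set()
    for s in samples:
        assigned = assignments.get(s.sample_id)
        if assigned is None:
            continue
        if basal_only:
            if assigned == haplogroup:
                present.add(s.region)
        elif assigned == haplogroup or assigned in daughters:
            present.add(s.region)
    return present - set(exclude_regions)


def geometric_center(
    points: Sequence[GeoPoint],
    unwrap: bool = False,
    spherical: bool = False,
    label: str = "",
) -> GeoPoint:
    """Arithmetic mean of decimal-degree coordinates with per-axis sample SDs.

    Longitude spans of 180 degrees or more raise :class:`AntimeridianError`
    unless ``unwrap`` shifts the western hemisphere by +360 first.  With
    ``spherical`` the mean is taken on unit vectors (great-circle centroid)
    instead; SDs are still reported per axis in degrees.
    """
    if not points:
        raise ValueError("need at least one point")
    lats = np.array([p.lat for p in points], dtype=float)
    lons = np.array([p.lon for p in points], dtype=float)
    if lons.max() - lons.min() >= 180:
        if not unwrap:
            raise AntimeridianError(
                "longitude span >= 180 degrees; pass unwrap=True to shift "
                "negative longitudes by +360"
            )
        lons = np.where(lons < 0, lons + 360, lons)
        if lons.max() - lons.min() >= 180:
            raise AntimeridianError("longitudes still span >= 180 after unwrap")
    if spherical:
        lat_r, lon_r = np.radians(lats), np.radians(lons)
        x = np.mean(np.cos(lat_r) * np.cos(lon_r))
        y = np.mean(np.cos(lat_r) * np.sin(lon_r))
        z = np.mean(np.sin(lat_r))
        mean_lat = math.degrees(math.atan2(z, math.hypot(x, y)))
        mean_lon = math.degrees(math.atan2(y, x))
    else:
        mean_lat = float(lats.mean())
        mean_lon = float(lons.mean())
    lat_sd = float(lats.std(ddof=1)) if len(points) > 1 else 0.0
    lon_sd = float(lons.std(ddof=1)) if len(points) > 1 else 0.0
    if mean_lon > 180:
        mean_lon -= 360
    return GeoPoint(mean_lat, mean_lon, label, lat_sd, lon_sd)


def dispersal_focus(
    centers: Sequence[GeoPoint], unwrap: bool = False, label: str = ""
) -> GeoPoint:
    """Averaged coordinates of evolved daughter-clade centers: the hypothetic
    focus of the ancestor's first dispersal.  Same contract as
    :func:`geometric_center`."""
    return geometric_center(centers, unwrap=unwrap, label=label)


@dataclass
class RegionTable:
    """Haplogroup x region count table with frequency and total views."""

    counts: pd.DataFrame  # index: haplogroup, columns: region, values: int

    def __post_init__(self) -> None:
        if (self.counts.values < 0).any():
            raise ValueError("counts must be non-negative")

    @property
    def totals(self) -> pd.Series:
        return self.counts.sum(axis=0)

    def frequencies(self) -> pd.DataFrame:
        totals = self.totals.replace(0, np.nan)
        return self.counts.div(totals, axis=1).fillna(0.0)

    def haplogroup_share(self) -> pd.DataFrame:
        """Each haplogroup's distribution of occurrences across regions."""
        row_tot = self.counts.sum(axis=1).replace(0, np.nan)
        return self.counts.div(row_tot, axis=0).fillna(0.0)

    def to_tsv(self, path) -> None:
        self.counts.to_csv(path, sep="\t")

    @classmethod
    def from_tsv(cls, path) -> "RegionTable":
        return cls(pd.read_csv(path, sep="\t", index_col=0))


def region_frequency_table(
    samples: Sequence[Haplotype],
    assignments: Mapping[str, str],
    regions: Sequence[str],
    level_names: Sequence[str],
    level_of: Mapping[str, str] | None = None,
) -> RegionTable:
    """Counts of samples per (haplogroup-at-level x region).

    ``level_of`` maps any assigned clade name to its category at the chosen
    depth (e.g. U3a1c -> U3a*); identity when omitted.
    """
    counts = pd.DataFrame(0, index=list(level_names), columns=list(regions), dtype=int)
    for s in samples:
        if s.region not in counts.columns:
            raise ValueError(
                f"sample {s.sample_id!r} region {s.region!r} not in partition {list(regions)}"
            )
        assigned = assignments.get(s.sample_id)
        if assigned is None:
            continue
        cat = level_of.get(assigned, assigned) if level_of else assigned
        if cat in counts.index:
            counts.loc[cat, s.region] += 1
    return RegionTable(counts)


def assign_native_region(
    table: RegionTable, major: float = 0.90, minor: float = 0.10
) -> dict[str, str]:
    """Per-haplogroup label: a region name, ``widespread``, or ``unassigned``.

    Native to region r: share of occurrences in r >= ``major`` and <= ``minor``
    in every other region.  Widespread: present in every region, or native-rule
    candidate in every region (degenerate thresholds).  Else unassigned.
    """
    share = table.haplogroup_share()
    out: dict[str, str] = {}
    nregions = share.shape[1]
    if nregions < 2:
        raise ValueError("native-region rule needs at least two regions")
    for hg, row in share.iterrows():
        total = table.counts.loc[hg].sum()
        if total == 0:
            out[hg] = "unassigned"
            continue
        candidates = [
            r for r in share.columns
            if row[r] >= major and (row.drop(r) <= minor).all()
        ]
        if len(candidates) == 1:
            out[hg] = candidates[0]
        elif len(candidates) == nregions or (table.counts.loc[hg] > 0).all():
            out[hg] = "widespread"
        else:
            out[hg] = "unassigned"
    return out


def haversine_km(a: GeoPoint, b: GeoPoint, radius_km: float = 6371.0) -> float:
    """Great-circle distance in kilometres."""
    la1, lo1, la2, lo2 = map(math.radians, (a.lat, a.lon, b.lat, b.lon))
    h = (
        math.sin((la2 - la1) / 2) ** 2
        + math.cos(la1) * math.cos(la2) * math.sin((lo2 - lo1) / 2) ** 2
    )
    return 2 * radius_km * math.asin(math.sqrt(h))


def geographic_distance_matrix(points: Sequence[GeoPoint]) -> np.ndarray:
    n = len(points)
    d = np.zeros((n, n))
    for i in range(n):
        for j in range(i + 1, n):
            d[i, j] = d[j, i] = haversine_km(points[i], points[j])
    return d
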