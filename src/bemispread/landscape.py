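"""Habitat layers for the stepping-stone simulator.

Land-cover class codes are reclassified into a relative carrying capacity
(fraction of the best whitefly habitat) and a vegetation friction, and an
altitude layer contributes a hard dispersal barrier above a threshold
(whiteflies are weak fliers; ridges above ~600 m a.s.l. block spread).
The two friction sources combine by elementwise maximum: a cell that either
layer declares impassable stays impassable.
"""

from __future__ import annotations

import csv
from dataclasses import dataclass

import numpy as np

from .raster_io import GridSpec, RasterLayer

__all__ = [
    "ReclassEntry",
    "ReclassTable",
    "FrictionParams",
    "Landscape",
    "ReclassificationError",
    "default_reclass_table",
    "reclassify_landcover",
    "altitude_friction",
    "combine_friction",
    "build_landscape",
]

#: side length of a ~72 km^2 deme
DEFAULT_CELL_KM = 72.0 ** 0.5
DEFAULT_K_MAX = 10_000.0


class ReclassificationError(ValueError):
    """Raised when a cover raster contains codes absent from the table."""


@dataclass(frozen=True)
class ReclassEntry:
    code: int
    name: str
    k_rel: float
    friction_veg: float

    def __post_init__(self) -> None:
        if not (0.0 <= self.k_rel <= 1.0):
            raise ValueError(f"k_rel out of [0,1] for class {self.name!r}: {self.k_rel}")
        if not (0.0 <= self.friction_veg <= 1.0):
            raise ValueError(
                f"friction out of [0,1] for class {self.name!r}: {self.friction_veg}"
            )
        if self.k_rel == 0.0 and self.friction_veg != 1.0:
            raise ValueError(
                f"class {self.name!r}: zero carrying capacity requires friction 1"
            )


@dataclass
class ReclassTable:
    """Lookup from land-cover class code to (k_rel, friction_veg)."""

    entries: dict[int, ReclassEntry]

    def __post_init__(self) -> None:
        self._by_name = {e.name: e for e in self.entries.values()}

    def by_name(self, name: str) -> ReclassEntry:
        return self._by_name[name]

    def codes(self) -> set[int]:
        return set(self.entries)

    @classmethod
    def from_rows(cls, rows) -> "ReclassTable":
        entries = {}
        for code, name, k_rel, friction in rows:
            code = int(code)
            entries[code] = ReclassEntry(code, str(name), float(k_rel), float(friction))
        return cls(entries)

    @classmethod
    def read(cls, path) -> "ReclassTable":
        """Read a delimited table with columns code,name,k_rel,friction."""
        with open(path, newline="", encoding="utf-8") as fh:
            sample = fh.read(2048)
            fh.seek(0)
            delim = "\t" if "\t" in sample.splitlines()[0] else ","
            reader = csv.reader(fh, delimiter=delim)
            rows = []
            for row in reader:
                if not row or row[0].lstrip().startswith("#"):
                    continue
                if row[0].strip().lower() in ("code", "class"):
                    continue  # header
                rows.append(row[:4])
        return cls.from_rows(rows)

    def write(self, path) -> None:
        with open(path, "w", newline="", encoding="utf-8") as fh:
            writer = csv.writer(fh)
            writer.writerow(["code", "name", "k_rel", "friction"])
            for code in sorted(self.entries):
                e = self.entries[code]
                writer.writerow([e.code, e.name, e.k_rel, e.friction_veg])


# Shipped GLC2000-style table (22 vegetation classes).  Only the 100% and 0%
# assignments are fixed by the habitat-quality rules above; intermediate
# classes follow the documented default friction = 1 - k_rel, with open
# shrub/grass/savanna habitat at 50% and dense humid forest (where the B
# mitotype is least likely to establish) at 10%.  Users override via a table
# file with the same codes.
_DEFAULT_ROWS = [
    (1, "tropical evergreen forest dense humid", 0.1, 0.9),
    (2, "tropical deciduous forest", 0.1, 0.9),
    (3, "montane forest", 0.1, 0.9),
    (4, "temperate broadleaved forest", 0.1, 0.9),
    (5, "tropical semideciduous forest", 0.5, 0.5),
    (6, "fresh water flooded forests", 0.0, 1.0),
    (7, "mangroves", 0.0, 1.0),
    (8, "forest plantation", 0.3, 0.7),
    (9, "mosaic forest cropland", 0.5, 0.5),
    (10, "closed shrubland", 0.5, 0.5),
    (11, "open shrubland", 0.5, 0.5),
    (12, "closed grassland", 0.5, 0.5),
    (13, "open grassland", 0.5, 0.5),
    (14, "savanna cerrado", 0.5, 0.5),
    (15, "flooded savanna", 0.3, 0.7),
    (16, "barren bare soil", 0.0, 1.0),
    (17, "sparse desertic vegetation", 0.2, 0.8),
    (18, "agriculture intensive", 1.0, 0.0),
    (19, "mosaic agriculture degraded forests", 1.0, 0.0),
    (20, "mosaic agriculture degraded vegetation", 1.0, 0.0),
    (21, "water bodies", 0.0, 1.0),
    (22, "permanent snow ice", 0.0, 1.0),
]


def default_reclass_table() -> ReclassTable:
    """The shipped 22-class reclassification table."""
    return ReclassTable.from_rows(_DEFAULT_ROWS)


@dataclass(frozen=True)
class FrictionParams:
    """Altitude-barrier parameterization.

    Cells above ``altitude_threshold_m`` (meters a.s.l.) receive
    ``blocked_friction``; lowland cells receive ``base_altitude_friction``
    (default 0: unimpeded flight).
    """

    altitude_threshold_m: float = 600.0
    blocked_friction: float = 1.0
    base_altitude_friction: float = 0.0

    def __post_init__(self) -> None:
        if not (0.0 <= self.base_altitude_friction < self.blocked_friction <= 1.0):
            raise ValueError("require 0 <= base < blocked <= 1")


@dataclass
class Landscape:
    """The simulator's arena: absolute carrying capacity and friction grids.

    ``K`` is in individuals per deme (k_rel scaled by ``k_max``); friction is
    in [0, 1], where 1 means immigration into the deme is impossible.
    ``cell_km`` is the deme side length in kilometers.
    """

    K: RasterLayer
    friction: RasterLayer
    cell_km: float = DEFAULT_CELL_KM
    k_max: float = DEFAULT_K_MAX

    def __post_init__(self) -> None:
        if not self.K.spec.approx_equal(self.friction.spec):
            raise ValueError("K and friction must share one GridSpec")
        kv = self.K.values[~self.K.mask]
        fv = self.friction.values[~self.friction.mask]
        if kv.size and kv.min() < 0:
            raise ValueError("carrying capacity must be non-negative")
        if fv.size and (fv.min() < 0 or fv.max() > 1):
            raise ValueError("friction must lie in [0, 1]")

    @property
    def spec(self) -> GridSpec:
        return self.K.spec

    @property
    def shape(self) -> tuple[int, int]:
        return self.K.shape


def reclassify_landcover(
    cover: RasterLayer, table: ReclassTable
) -> tuple[RasterLayer, RasterLayer]:
    """Elementwise lookup of (k_rel, friction_veg) from class codes.

    Masked cover cells stay masked in both outputs; an unmasked code missing
    from the table raises :class:`ReclassificationError` naming all
    offending codes.
    """
    codes = cover.values
    unmasked = ~cover.mask
    present = [int(c) for c in np.unique(codes[unmasked])]
    unknown = sorted(set(present) - table.codes())
    if unknown:
        raise ReclassificationError(f"unknown land-cover class codes: {unknown}")

    k_rel = np.zeros(cover.shape)
    fric = np.ones(cover.shape)
    for code in present:
        sel = unmasked & (codes == code)
        entry = table.entries[int(code)]
        k_rel[sel] = entry.k_rel
        fric[sel] = entry.friction_veg
    mask = cover.mask.copy()
    return (
        RasterLayer(cover.spec, k_rel, mask),
        RasterLayer(cover.spec, fric, mask.copy()),
    )


def altitude_friction(alt: RasterLayer, params: FrictionParams = FrictionParams()) -> RasterLayer:
    """Hard-threshold altitude barrier: above the threshold, blocked."""
    out = np.where(
        alt.values > params.altitude_threshold_m,
        params.blocked_friction,
        params.base_altitude_friction,
    )
    return RasterLayer(alt.spec, out, alt.mask.copy())


def combine_friction(friction_veg: RasterLayer, friction_alt: RasterLayer) -> RasterLayer:
    """Elementwise maximum: a barrier in either layer blocks the cell."""
    if not friction_veg.spec.approx_equal(friction_alt.spec):
        raise ValueError("friction layers must share one GridSpec")
    mask = friction_veg.mask | friction_alt.mask
    out = np.maximum(friction_veg.values, friction_alt.values)
    return RasterLayer(friction_veg.spec, out, mask)


def build_landscape(
    cover: RasterLayer,
    alt: RasterLayer,
    table: ReclassTable | None = None,
    params: FrictionParams = FrictionParams(),
    k_max: float = DEFAULT_K_MAX,
    cell_km: float = DEFAULT_CELL_KM,
) -> Landscape:
    """Compose reclassification and the altitude barrier into a Landscape."""
    if table is None:
        table = default_reclass_table()
    if not cover.spec.approx_equal(alt.spec):
        raise ValueError("cover and altitude must share one GridSpec")
    k_rel, fric_veg = reclassify_landcover(cover, table)
    fric_alt = altitude_friction(alt, params)
    friction = combine_friction(fric_veg, fric_alt)
    K = RasterLayer(cover.spec, k_rel.values * k_max, friction.mask.copy())
    return Landscape(K=K, friction=friction, cell_km=cell_km, k_max=k_max)
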