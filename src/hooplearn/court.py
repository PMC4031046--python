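"""Court geometry: coordinates, shot distance, 2 pt / 3 pt classification, regions.

Coordinates are in feet. The origin sits at the intersection of the baseline
and the court's long axis; ``x`` is the signed lateral offset, ``y`` runs from
the baseline toward half court. The basket center is at ``(0, basket_y)``.

The NBA 3 pt line is an arc of radius ``arc_radius`` (23.75 ft) that meets two
straight segments parallel to the sidelines at ``|x| = corner_offset`` (22 ft).
A shot taken 22–23.75 ft from the basket can therefore be either a 2 pt or a
3 pt attempt depending on its angle — the corner/arc dissociation that several
analyses in this package exploit.

Region maps partition the half court into 16 labeled regions falling into
three groups: the five 3 pt sectors (labels 1, 4, 7, 11, 14), the five
long-distance 2 pt sectors (2, 5, 8, 12, 15) and the six short-distance 2 pt
regions (3, 6, 9, 10, 13, 16; label 16 is the central region around the
basket). The default :class:`SectorRegionMap` is a parameterized angular/radial
reconstruction; any object satisfying the same small interface can be passed
wherever a region map is expected.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from enum import Enum
from typing import Iterable, Mapping, Sequence

import numpy as np
import yaml

#: Sentinel label for points outside every region (excluded downstream).
NO_REGION = 0


class Group(str, Enum):
    """Coarse court partition: 3 pt, long 2 pt, short 2 pt."""

    THREE = "THREE"
    LONG2 = "LONG2"
    SHORT2 = "SHORT2"


GROUP_ORDER: tuple[Group, Group, Group] = (Group.THREE, Group.LONG2, Group.SHORT2)


@dataclass(frozen=True)
class CourtSpec:
    """Geometric constants of the court, NBA values by default."""

    basket_x: float = 0.0
    basket_y: float = 5.25
    arc_radius: float = 23.75
    corner_offset: float = 22.0
    half_court_y: float = 47.0
    court_half_width: float = 25.0

    def __post_init__(self) -> None:
        if not self.corner_offset < self.arc_radius:
            raise ValueError("corner_offset must be smaller than arc_radius")
        if not 0.0 < self.basket_y < self.half_court_y:
            raise ValueError("basket_y must lie strictly between baseline and half court")

    @property
    def corner_break_y(self) -> float:
        """y at which the straight corner 3 pt segments meet the arc."""
        return self.basket_y + math.sqrt(self.arc_radius**2 - self.corner_offset**2)

    def to_dict(self) -> dict:
        return {
            "basket_x": self.basket_x,
            "basket_y": self.basket_y,
            "arc_radius": self.arc_radius,
            "corner_offset": self.corner_offset,
            "half_court_y": self.half_court_y,
            "court_half_width": self.court_half_width,
        }


def shot_distance(x, y, spec: CourtSpec = CourtSpec()):
    """Euclidean distance (ft) from a point to the basket center.

    Accepts scalars or arrays.
    """
    return np.hypot(np.asarray(x, dtype=float) - spec.basket_x,
                    np.asarray(y, dtype=float) - spec.basket_y)


def classify_point_value(x, y, spec: CourtSpec = CourtSpec()):
    """Point value (2 or 3) of a shot at ``(x, y)``.

    A shot is worth 3 points iff it is beyond the 3 pt line: past the straight
    corner segment (``|x| > corner_offset``) below the corner break, or beyond
    the arc above it. Vectorized; returns an int array (or scalar int).
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    d = shot_distance(x, y, spec)
    below_break = y <= spec.corner_break_y
    three = np.where(below_break, np.abs(x) > spec.corner_offset, d > spec.arc_radius)
    out = np.where(three, 3, 2)
    if out.ndim == 0:
        return int(out)
    return out.astype(int)


class RegionMap:
    """Interface for court partitions used by the analyses.

    Concrete maps provide ``labels`` (ordered region labels), ``group_of``
    (label -> :class:`Group`), and ``assign`` (coordinates -> label array with
    :data:`NO_REGION` outside every region).
    """

    labels: tuple[int, ...]

    def group_of(self, label: int) -> Group:  # pragma: no cover - interface
        raise NotImplementedError

    def assign(self, x, y) -> np.ndarray:  # pragma: no cover - interface
        raise NotImplementedError

    @property
    def n_regions(self) -> int:
        return len(self.labels)

    def group_index(self, label: int) -> int:
        return GROUP_ORDER.index(self.group_of(label))

    def labels_in_group(self, group: Group) -> tuple[int, ...]:
        return tuple(l for l in self.labels if self.group_of(l) is group)


def region_group(label: int, region_map: RegionMap) -> Group:
    """Coarse group of a region label; raises ``KeyError`` on unknown labels."""
    if label not in region_map.labels:
        raise KeyError(f"unknown region label: {label!r}")
    return region_map.group_of(label)


# Default label layout of the sector map. Sector 0 is the right corner
# (smallest angle from the right baseline), sector 4 the left corner.
_THREE_LABELS = (14, 11, 7, 4, 1)
_LONG2_LABELS = (15, 12, 8, 5, 2)
_SHORT2_LABELS = (13, 10, 9, 6, 3)
_CENTRAL_LABEL = 16


@dataclass(frozen=True)
class SectorRegionMap(RegionMap):
    """Default 16-region partition: a central disc plus 5 angular sectors × 3 radial bands.

    Band boundaries: the central short-2 pt region is the disc of radius
    ``inner_radius`` around the basket; short vs long 2 pt split at
    ``mid_radius``; the 2 pt / 3 pt boundary is the actual 3 pt line (arc +
    corner segments), so every 3 pt region lies entirely beyond the line.
    Shots farther than ``max_three_radius`` from the basket, or off the half
    court, are assigned :data:`NO_REGION`.

    Angles are measured from the right baseline (positive x axis through the
    basket): 0° is the right corner, 180° the left corner. Points behind the
    basket plane are clamped into the nearest corner sector.
    """

    spec: CourtSpec = field(default_factory=CourtSpec)
    sector_edges_deg: tuple[float, ...] = (0.0, 30.0, 75.0, 105.0, 150.0, 180.0)
    inner_radius: float = 8.0
    mid_radius: float = 16.0
    max_three_radius: float = 30.0

    def __post_init__(self) -> None:
        if len(self.sector_edges_deg) != 6 or list(self.sector_edges_deg) != sorted(
            self.sector_edges_deg
        ):
            raise ValueError("sector_edges_deg must be 6 non-decreasing angles spanning 0..180")
        if not 0 < self.inner_radius < self.mid_radius < self.spec.corner_offset:
            raise ValueError("need 0 < inner_radius < mid_radius < corner_offset")

    @property
    def labels(self) -> tuple[int, ...]:  # type: ignore[override]
        return tuple(range(1, 17))

    def group_of(self, label: int) -> Group:
        if label in _THREE_LABELS:
            return Group.THREE
        if label in _LONG2_LABELS:
            return Group.LONG2
        if label in _SHORT2_LABELS or label == _CENTRAL_LABEL:
            return Group.SHORT2
        raise KeyError(f"unknown region label: {label!r}")

    def _sector(self, x: np.ndarray, y: np.ndarray) -> np.ndarray:
        dy = y - self.spec.basket_y
        phi = np.degrees(np.arctan2(dy, x - self.spec.basket_x))
        # clamp points behind the basket plane into the corner sectors
        phi = np.where(dy < 0, np.where(x >= self.spec.basket_x, 0.0, 180.0), phi)
        edges = np.asarray(self.sector_edges_deg[1:-1])
        return np.searchsorted(edges, phi, side="right")

    def assign(self, x, y) -> np.ndarray:
        x = np.atleast_1d(np.asarray(x, dtype=float))
        y = np.atleast_1d(np.asarray(y, dtype=float))
        spec = self.spec
        r = shot_distance(x, y, spec)
        pv = classify_point_value(x, y, spec)
        sector = self._sector(x, y)

        on_court = (
            (np.abs(x) <= spec.court_half_width)
            & (y >= 0.0)
            & (y <= spec.half_court_y)
        )
        labels = np.full(x.shape, NO_REGION, dtype=int)

        central = on_court & (r < self.inner_radius)
        labels[central] = _CENTRAL_LABEL

        short2 = on_court & ~central & (pv == 2) & (r < self.mid_radius)
        labels[short2] = np.take(_SHORT2_LABELS, sector[short2])

        long2 = on_court & ~central & (pv == 2) & (r >= self.mid_radius)
        labels[long2] = np.take(_LONG2_LABELS, sector[long2])

        three = on_court & (pv == 3) & (r <= self.max_three_radius)
        labels[three] = np.take(_THREE_LABELS, sector[three])
        return labels

    def representative_point(self, label: int) -> tuple[float, float]:
        """An interior point of a region, used e.g. to place synthetic shots.

        Found by scanning a polar grid in the region's sector/band; guaranteed
        to satisfy ``assign(x, y) == label``.
        """
        if label == _CENTRAL_LABEL:
            return (0.0, self.spec.basket_y + 0.6 * self.inner_radius)
        for lab_list, radii in (
            (_SHORT2_LABELS, np.arange(self.inner_radius + 1.0, self.mid_radius, 0.5)),
            (_LONG2_LABELS, np.arange(self.mid_radius + 1.0, self.spec.arc_radius, 0.25)),
            (_THREE_LABELS, np.arange(self.spec.arc_radius - 2.0, self.max_three_radius, 0.25)),
        ):
            if label in lab_list:
                s = lab_list.index(label)
                lo, hi = self.sector_edges_deg[s], self.sector_edges_deg[s + 1]
                for frac in (0.5, 0.35, 0.65, 0.2, 0.8):
                    phi = math.radians(lo + frac * (hi - lo))
                    for r in radii:
                        x = r * math.cos(phi) + self.spec.basket_x
                        y = r * math.sin(phi) + self.spec.basket_y
                        if int(self.assign(x, y)[0]) == label:
                            return (float(x), float(y))
                raise RuntimeError(f"no interior point found for region {label}")
        raise KeyError(f"unknown region label: {label!r}")

    # -- serialization ------------------------------------------------------

    def to_dict(self) -> dict:
        return {
            "type": "sector_map",
            "court": self.spec.to_dict(),
            "sector_edges_deg": list(self.sector_edges_deg),
            "inner_radius": self.inner_radius,
            "mid_radius": self.mid_radius,
            "max_three_radius": self.max_three_radius,
        }

    @classmethod
    def from_dict(cls, d: Mapping) -> "SectorRegionMap":
        spec = CourtSpec(**d.get("court", {}))
        return cls(
            spec=spec,
            sector_edges_deg=tuple(d.get("sector_edges_deg", cls.sector_edges_deg)),
            inner_radius=d.get("inner_radius", cls.inner_radius),
            mid_radius=d.get("mid_radius", cls.mid_radius),
            max_three_radius=d.get("max_three_radius", cls.max_three_radius),
        )

    def to_yaml(self, path) -> None:
        with open(path, "w", encoding="utf-8") as fh:
            yaml.safe_dump(self.to_dict(), fh, sort_keys=False)

    @classmethod
    def from_yaml(cls, path) -> "SectorRegionMap":
        with open(path, encoding="utf-8") as fh:
            return cls.from_dict(yaml.safe_load(fh))


class LabelRegionMap(RegionMap):
    """Abstract region map: labels and groups only, no geometry.

    Used for tables that already carry an explicit ``region`` column (toy
    examples, abstract synthetic cohorts). ``assign`` maps every coordinate to
    :data:`NO_REGION`, so estimation must rely on the stored column.
    """

    def __init__(self, groups: Mapping[int, Group] | Sequence[tuple[int, Group]]):
        items = list(groups.items()) if isinstance(groups, Mapping) else list(groups)
        self._groups = {int(l): Group(g) for l, g in items}
        self.labels = tuple(sorted(self._groups))
        if NO_REGION in self._groups:
            raise ValueError(f"label {NO_REGION} is reserved for 'no region'")

    def group_of(self, label: int) -> Group:
        return self._groups[label]

    def assign(self, x, y) -> np.ndarray:
        return np.full(np.atleast_1d(np.asarray(x)).shape, NO_REGION, dtype=int)


DEFAULT_REGION_MAP = SectorRegionMap()
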