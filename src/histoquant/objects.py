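"""Hierarchical image-object model.

Every analysis stage reads and writes a tree of :class:`PathObject` nodes —
annotations, detections, cells and TMA cores — each carrying a region of
interest (ROI), an optional classification, and a map of named numeric
measurements.  The tree supports filtered queries (by type, classification
and spatial containment) and lossless GeoJSON round trips.

Coordinates are continuous, 0-based pixel units with the origin at the top
left (x to the right, y down).  Areas are converted to square micrometres
only at measurement time, using the ROI's isotropic pixel size.

Spatial containment is decided by ROI centroid so that every detection
contributes to exactly one enclosing region (no double counting at core
borders).
"""

from __future__ import annotations

import csv
import json
import math
from dataclasses import dataclass, field
from typing import Iterable, Iterator, Optional, Sequence

import numpy as np
from shapely.geometry import Point as ShapelyPoint
from shapely.geometry import Polygon as ShapelyPolygon

__all__ = [
    "ROI",
    "PathObject",
    "ObjectHierarchy",
    "export_objects",
    "import_objects",
    "export_measurements_csv",
]

OBJECT_TYPES = ("annotation", "detection", "cell", "tma_core")
ROI_KINDS = ("polygon", "ellipse", "rectangle", "point")


@dataclass(frozen=True)
class ROI:
    """A region of interest in continuous pixel coordinates.

    Parameters
    ----------
    kind
        One of ``polygon``, ``ellipse``, ``rectangle`` or ``point``.
    vertices
        ``(n, 2)`` array of (x, y) pairs for polygons; ignored otherwise.
        The ring must be simple (non self-intersecting) and is stored
        unclosed.
    center, radii
        Center (x, y) and semi-axes (rx, ry) for ellipses, rectangles
        (half-width/half-height) and points (radii ``(0, 0)``).
    pixel_size_um
        Isotropic micrometres per pixel; used for area/length conversion.
    """

    kind: str
    vertices: Optional[np.ndarray] = None
    center: Optional[tuple[float, float]] = None
    radii: Optional[tuple[float, float]] = None
    pixel_size_um: float = 1.0

    def __post_init__(self) -> None:
        if self.kind not in ROI_KINDS:
            raise ValueError(f"unknown ROI kind {self.kind!r}")
        if self.kind == "polygon":
            if self.vertices is None:
                raise ValueError("polygon ROI requires vertices")
            v = np.asarray(self.vertices, dtype=float)
            if v.ndim != 2 or v.shape[1] != 2 or v.shape[0] < 3:
                raise ValueError("polygon vertices must be an (n>=3, 2) array")
            object.__setattr__(self, "vertices", v)
            if not ShapelyPolygon(v).is_valid:
                raise ValueError("polygon ring is not simple")
        elif self.kind == "point":
            if self.center is None:
                raise ValueError("point ROI requires a center")
            object.__setattr__(self, "radii", (0.0, 0.0))
        else:
            if self.center is None or self.radii is None:
                raise ValueError(f"{self.kind} ROI requires center and radii")
        if self.pixel_size_um <= 0:
            raise ValueError("pixel_size_um must be positive")

    # -- geometry ---------------------------------------------------------

    def to_shapely(self):
        if self.kind == "polygon":
            return ShapelyPolygon(self.vertices)
        if self.kind == "point":
            return ShapelyPoint(self.center)
        cx, cy = self.center
        rx, ry = self.radii
        if self.kind == "rectangle":
            return ShapelyPolygon(
                [(cx - rx, cy - ry), (cx + rx, cy - ry), (cx + rx, cy + ry), (cx - rx, cy + ry)]
            )
        # ellipse: 64-gon approximation, used for display/overlap only --
        # exact area/centroid come from the closed forms below
        t = np.linspace(0.0, 2.0 * math.pi, 64, endpoint=False)
        return ShapelyPolygon(np.c_[cx + rx * np.cos(t), cy + ry * np.sin(t)])

    @property
    def centroid(self) -> tuple[float, float]:
        if self.kind == "polygon":
            c = ShapelyPolygon(self.vertices).centroid
            return (c.x, c.y)
        return self.center

    @property
    def area_px(self) -> float:
        if self.kind == "polygon":
            return ShapelyPolygon(self.vertices).area
        if self.kind == "point":
            return 0.0
        rx, ry = self.radii
        if self.kind == "rectangle":
            return 4.0 * rx * ry
        return math.pi * rx * ry

    @property
    def area_um2(self) -> float:
        return self.area_px * self.pixel_size_um**2

    def contains_point(self, x: float, y: float) -> bool:
        """Point-in-ROI test; ellipse and rectangle use closed forms."""
        if self.kind == "rectangle":
            cx, cy = self.center
            rx, ry = self.radii
            return abs(x - cx) <= rx and abs(y - cy) <= ry
        if self.kind == "ellipse":
            cx, cy = self.center
            rx, ry = self.radii
            if rx == 0 or ry == 0:
                return False
            return ((x - cx) / rx) ** 2 + ((y - cy) / ry) ** 2 <= 1.0
        if self.kind == "point":
            return (x, y) == self.center
        poly = ShapelyPolygon(self.vertices)
        return poly.covers(ShapelyPoint(x, y))


@dataclass
class PathObject:
    """One node of the object tree."""

    object_type: str
    roi: ROI
    id: Optional[int] = None
    nucleus_roi: Optional[ROI] = None
    classification: Optional[str] = None
    measurements: dict[str, float] = field(default_factory=dict)
    metadata: dict[str, object] = field(default_factory=dict)
    parent: Optional[int] = None
    children: list[int] = field(default_factory=list)

    def __post_init__(self) -> None:
        if self.object_type not in OBJECT_TYPES:
            raise ValueError(f"unknown object_type {self.object_type!r}")
        if self.nucleus_roi is not None and self.object_type != "cell":
            raise ValueError("nucleus_roi is only valid on cell objects")

    def set_measurement(self, name: str, value: float) -> "PathObject":
        """Store a named measurement; silently overwrites an existing name."""
        value = float(value)
        if not math.isfinite(value):
            raise ValueError(f"measurement {name!r} must be finite, got {value}")
        self.measurements[name] = value
        return self


# kept as a module-level alias because detection/scoring code calls it
# functionally on bare objects
def set_measurement(obj: PathObject, name: str, value: float) -> PathObject:
    return obj.set_measurement(name, value)


class ObjectHierarchy:
    """Tree of :class:`PathObject` with deterministic insertion-order ids.

    The root is an implicit node with id 0; every inserted object receives
    the next sequential id unless it already carries an unused one.
    """

    ROOT_ID = 0

    def __init__(self) -> None:
        self._objects: dict[int, PathObject] = {}
        self._children: dict[int, list[int]] = {self.ROOT_ID: []}
        self._next_id = 1

    # -- basics -----------------------------------------------------------

    def __len__(self) -> int:
        return len(self._objects)

    def __contains__(self, obj_id: int) -> bool:
        return obj_id in self._objects or obj_id == self.ROOT_ID

    def __iter__(self) -> Iterator[PathObject]:
        return iter(self._objects[i] for i in sorted(self._objects))

    def get(self, obj_id: int) -> PathObject:
        return self._objects[obj_id]

    def children_of(self, obj_id: int) -> list[int]:
        return list(self._children.get(obj_id, []))

    # -- mutation ---------------------------------------------------------

    def insert(self, obj: PathObject, parent: Optional[int] = None) -> int:
        """Attach ``obj`` under ``parent`` (root when omitted); returns its id."""
        if parent is None:
            parent = self.ROOT_ID
        if parent != self.ROOT_ID and parent not in self._objects:
            raise KeyError(f"unknown parent id {parent}")
        if obj.id is None:
            obj.id = self._next_id
        elif obj.id in self._objects or obj.id == self.ROOT_ID:
            raise ValueError(f"duplicate object id {obj.id}")
        self._next_id = max(self._next_id, obj.id + 1)
        obj.parent = parent
        self._objects[obj.id] = obj
        self._children.setdefault(obj.id, [])
        self._children.setdefault(parent, []).append(obj.id)
        if parent != self.ROOT_ID:
            self._objects[parent].children.append(obj.id)
        return obj.id

    def insert_all(self, objs: Iterable[PathObject], parent: Optional[int] = None) -> list[int]:
        return [self.insert(o, parent) for o in objs]

    # -- queries ----------------------------------------------------------

    def select(
        self,
        object_type: Optional[str] = None,
        classification: Optional[str] = None,
        within: Optional[ROI] = None,
    ) -> list[PathObject]:
        """All objects matching every given filter, ordered by id.

        ``within`` keeps objects whose ROI centroid lies inside the query
        ROI (centroid rule — each object matches at most one disjoint
        region).
        """
        out = []
        for obj_id in sorted(self._objects):
            obj = self._objects[obj_id]
            if object_type is not None and obj.object_type != object_type:
                continue
            if classification is not None and obj.classification != classification:
                continue
            if within is not None:
                cx, cy = obj.roi.centroid
                if not within.contains_point(cx, cy):
                    continue
            out.append(obj)
        return out


# ---------------------------------------------------------------------------
# GeoJSON serialization


def _roi_to_geojson(roi: ROI) -> tuple[dict, dict]:
    """Return (geometry, extra-properties) for one ROI."""
    props: dict[str, object] = {"roi_kind": roi.kind, "pixel_size_um": roi.pixel_size_um}
    if roi.kind == "polygon":
        ring = [[float(x), float(y)] for x, y in roi.vertices]
        ring.append(ring[0])
        geom = {"type": "Polygon", "coordinates": [ring]}
    elif roi.kind == "point":
        geom = {"type": "Point", "coordinates": [float(roi.center[0]), float(roi.center[1])]}
    else:
        # ellipse / rectangle: polygon approximation for interoperability;
        # exact parameters ride along in properties for lossless import
        geom = {
            "type": "Polygon",
            "coordinates": [
                [[float(x), float(y)] for x, y in
                 np.vstack([np.asarray(roi.to_shapely().exterior.coords)])]
            ],
        }
        props["center"] = [float(roi.center[0]), float(roi.center[1])]
        props["radii"] = [float(roi.radii[0]), float(roi.radii[1])]
    return geom, props


def _roi_from_geojson(geom: dict, props: dict) -> ROI:
    kind = props.get("roi_kind", "polygon")
    psz = float(props.get("pixel_size_um", 1.0))
    if kind == "polygon":
        ring = geom["coordinates"][0]
        return ROI("polygon", vertices=np.asarray(ring[:-1], dtype=float), pixel_size_um=psz)
    if kind == "point":
        x, y = geom["coordinates"]
        return ROI("point", center=(float(x), float(y)), pixel_size_um=psz)
    cx, cy = props["center"]
    rx, ry = props["radii"]
    return ROI(kind, center=(float(cx), float(cy)), radii=(float(rx), float(ry)), pixel_size_um=psz)


def export_objects(h: ObjectHierarchy, path) -> None:
    """Write the hierarchy as a GeoJSON FeatureCollection (RFC 7946 layout)."""
    features = []
    for obj in h:
        geom, props = _roi_to_geojson(obj.roi)
        props.update(
            {
                "object_id": obj.id,
                "object_type": obj.object_type,
                "classification": obj.classification,
                "measurements": {k: float(v) for k, v in obj.measurements.items()},
                "parent": obj.parent,
                "metadata": obj.metadata,
            }
        )
        if obj.nucleus_roi is not None:
            ngeom, nprops = _roi_to_geojson(obj.nucleus_roi)
            props["nucleus"] = {"geometry": ngeom, "properties": nprops}
        features.append({"type": "Feature", "geometry": geom, "properties": props})
    with open(path, "w") as fh:
        json.dump({"type": "FeatureCollection", "features": features}, fh)


def import_objects(path) -> ObjectHierarchy:
    """Read a FeatureCollection written by :func:`export_objects`.

    Objects are re-inserted parents-first; original ids are preserved.
    """
    with open(path) as fh:
        doc = json.load(fh)
    if doc.get("type") != "FeatureCollection":
        raise ValueError("not a GeoJSON FeatureCollection")
    parsed = []
    for i, feat in enumerate(doc.get("features", [])):
        try:
            props = feat["properties"]
            roi = _roi_from_geojson(feat["geometry"], props)
            nucleus = None
            if props.get("nucleus") is not None:
                nucleus = _roi_from_geojson(
                    props["nucleus"]["geometry"], props["nucleus"]["properties"]
                )
            parsed.append(
                (
                    int(props["object_id"]),
                    int(props.get("parent") or 0),
                    PathObject(
                        object_type=props["object_type"],
                        roi=roi,
                        id=int(props["object_id"]),
                        nucleus_roi=nucleus,
                        classification=props.get("classification"),
                        measurements={
                            k: float(v) for k, v in props.get("measurements", {}).items()
                        },
                        metadata=props.get("metadata", {}),
                    ),
                )
            )
        except (KeyError, TypeError, ValueError) as exc:
            raise ValueError(f"malformed feature at index {i}: {exc}") from exc
    h = ObjectHierarchy()
    pending = {obj_id: (parent, obj) for obj_id, parent, obj in parsed}
    placed: set[int] = {ObjectHierarchy.ROOT_ID}
    while pending:
        progress = False
        for obj_id in sorted(pending):
            parent, obj = pending[obj_id]
            if parent in placed:
                h.insert(obj, parent if parent != 0 else None)
                placed.add(obj_id)
                del pending[obj_id]
                progress = True
        if not progress:
            raise ValueError(f"malformed feature: unresolvable parent links {sorted(pending)}")
    return h


def export_measurements_csv(objects: Sequence[PathObject], path) -> None:
    """One row per object, one column per measurement, columns sorted."""
    names = sorted({m for o in objects for m in o.measurements})
    with open(path, "w", newline="") as fh:
        w = csv.writer(fh)
        w.writerow(["id", "object_type", "classification", "centroid_x", "centroid_y"] + names)
        for o in objects:
            cx, cy = o.roi.centroid
            w.writerow(
                [o.id, o.object_type, o.classification or "", f"{cx:.3f}", f"{cy:.3f}"]
                + [repr(o.measurements[n]) if n in o.measurements else "" for n in names]
            )
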