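"""Labeled tissue maps: cell point sets and region polygons in micrometres.

A :class:`TissueMap` is the substrate for all morphometric features. It holds

* ``cells`` — a DataFrame with columns ``x``, ``y`` (µm, origin at the field's
  lower-left corner), ``cell_type`` (``epithelial`` / ``lymphocyte`` /
  ``mitotic`` / ``stromal``) and ``nuclear_area_um2``;
* ``structures`` — region polygons with a role (``epithelium`` or ``lumen``);
  every lumen references the epithelium structure that encloses it;
* ``field_extent_um`` — the (width, height) of the rectangular field.

Maps round-trip through a small GeoJSON dialect: Point features carry
``cell_type`` and ``nuclear_area_um2`` properties, Polygon features carry
``region`` and ``structure_id`` (and ``parent_id`` for lumina).
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from typing import Optional

import numpy as np
import pandas as pd
from shapely.geometry import Polygon, mapping, shape

CELL_TYPES = ("epithelial", "lymphocyte", "mitotic", "stromal")
CELL_COLUMNS = ("x", "y", "cell_type", "nuclear_area_um2")


class TissueMapError(ValueError):
    """Raised when a tissue map violates its structural invariants."""


@dataclass
class Structure:
    """One region polygon: an epithelial structure or a lumen inside one."""

    polygon: Polygon
    region: str  # "epithelium" | "lumen"
    structure_id: int
    parent_id: Optional[int] = None  # for lumina: enclosing epithelium id


@dataclass
class TissueMap:
    cells: pd.DataFrame
    structures: list[Structure] = field(default_factory=list)
    field_extent_um: tuple[float, float] = (2000.0, 2000.0)

    def __post_init__(self) -> None:
        self.validate()

    # -- accessors ---------------------------------------------------------
    def cells_of_type(self, cell_type: str) -> pd.DataFrame:
        return self.cells[self.cells["cell_type"] == cell_type]

    def epithelium(self) -> list[Structure]:
        return [s for s in self.structures if s.region == "epithelium"]

    def lumina(self) -> list[Structure]:
        return [s for s in self.structures if s.region == "lumen"]

    def lumina_of(self, structure_id: int) -> list[Structure]:
        return [s for s in self.lumina() if s.parent_id == structure_id]

    # -- invariants --------------------------------------------------------
    def validate(self) -> None:
        missing = set(CELL_COLUMNS) - set(self.cells.columns)
        if missing:
            raise TissueMapError(f"cells table lacks columns {sorted(missing)}")
        bad = set(self.cells["cell_type"]) - set(CELL_TYPES)
        if bad:
            raise TissueMapError(f"unknown cell types {sorted(bad)}")
        areas = self.cells["nuclear_area_um2"].to_numpy(dtype=float)
        if len(areas) and not (np.isfinite(areas).all() and (areas > 0).all()):
            raise TissueMapError("nuclear_area_um2 must be positive and finite")
        w, h = self.field_extent_um
        if w <= 0 or h <= 0:
            raise TissueMapError(f"degenerate field extent {self.field_extent_um}")
        epi = {s.structure_id: s for s in self.epithelium()}
        for s in self.structures:
            if not s.polygon.is_valid or s.polygon.is_empty:
                raise TissueMapError(f"structure {s.structure_id}: invalid polygon")
            if s.polygon.area <= 0:
                raise TissueMapError(f"structure {s.structure_id}: zero-area polygon")
            if s.region == "lumen":
                parent = epi.get(s.parent_id)
                if parent is None:
                    raise TissueMapError(
                        f"lumen {s.structure_id} references missing epithelium "
                        f"{s.parent_id}"
                    )
                if not s.polygon.within(parent.polygon):
                    raise TissueMapError(
                        f"lumen {s.structure_id} not inside epithelium {s.parent_id}"
                    )
            elif s.region != "epithelium":
                raise TissueMapError(f"unknown region role {s.region!r}")

    # -- GeoJSON dialect ---------------------------------------------------
    def to_geojson(self) -> str:
        features = []
        for s in self.structures:
            props = {"region": s.region, "structure_id": int(s.structure_id)}
            if s.parent_id is not None:
                props["parent_id"] = int(s.parent_id)
            features.append(
                {"type": "Feature", "geometry": mapping(s.polygon), "properties": props}
            )
        for row in self.cells.itertuples(index=False):
            features.append(
                {
                    "type": "Feature",
                    "geometry": {"type": "Point", "coordinates": [row.x, row.y]},
                    "properties": {
                        "cell_type": row.cell_type,
                        "nuclear_area_um2": row.nuclear_area_um2,
                    },
                }
            )
        return json.dumps(
            {
                "type": "FeatureCollection",
                "field_extent_um": list(self.field_extent_um),
                "features": features,
            }
        )

    @classmethod
    def from_geojson(cls, text: str) -> "TissueMap":
        doc = json.loads(text)
        if doc.get("type") != "FeatureCollection":
            raise TissueMapError("expected a GeoJSON FeatureCollection")
        extent = tuple(doc.get("field_extent_um", (2000.0, 2000.0)))
        cells: dict[str, list] = {c: [] for c in CELL_COLUMNS}
        structures: list[Structure] = []
        for feat in doc.get("features", []):
            geom, props = feat.get("geometry", {}), feat.get("properties", {})
            if geom.get("type") == "Point":
                x, y = geom["coordinates"]
                cells["x"].append(float(x))
                cells["y"].append(float(y))
                cells["cell_type"].append(props["cell_type"])
                cells["nuclear_area_um2"].append(float(props["nuclear_area_um2"]))
            elif geom.get("type") == "Polygon":
                structures.append(
                    Structure(
                        polygon=shape(geom),
                        region=props["region"],
                        structure_id=int(props["structure_id"]),
                        parent_id=props.get("parent_id"),
                    )
                )
            else:
                raise TissueMapError(f"unsupported geometry {geom.get('type')!r}")
        return cls(
            cells=pd.DataFrame(cells), structures=structures, field_extent_um=extent
        )


def make_cells(
    xy: np.ndarray, cell_type: str, nuclear_area_um2: np.ndarray | float
) -> pd.DataFrame:
    """Build a cell table fragment from an (n, 2) coordinate array."""
    xy = np.asarray(xy, dtype=float).reshape(-1, 2)
    area = np.broadcast_to(np.asarray(nuclear_area_um2, dtype=float), xy.shape[0])
    return pd.DataFrame(
        {
            "x": xy[:, 0],
            "y": xy[:, 1],
            "cell_type": cell_type,
            "nuclear_area_um2": area.astype(float),
        }
    )


def concat_cells(parts: list[pd.DataFrame]) -> pd.DataFrame:
    parts = [p for p in parts if len(p)]
    if not parts:
        return pd.DataFrame({c: [] for c in CELL_COLUMNS})
    return pd.concat(parts, ignore_index=True)
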