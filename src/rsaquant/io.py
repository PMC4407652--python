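"""Reading and writing root architectures.

Two interchange formats are supported:

* a restricted Root System Markup Language (RSML) dialect — one ``<scene>``,
  2-D polylines, two root orders (top-level roots are seminal, their children
  lateral; deeper nesting is rejected rather than flattened);
* a flat polyline table (CSV) with header exactly
  ``plant_id,root_id,order,parent_id,point_index,x,y``.

Coordinates are image-frame pixels (y down) and round-trip bit-exactly:
the writer emits shortest-exact decimal text (``repr``-grade, >= 17
significant digits).  The seed origin is carried as a plant-level
``<annotation name="seed_origin">`` element; when absent it defaults to the
first vertex of the first seminal root.
"""
from __future__ import annotations

import io as _stdio
import xml.etree.ElementTree as ET

import pandas as pd

from .architecture import Point2D, RootRecord, RootSystem
from .errors import ParseError, SchemaError, ValidationError

POLYLINE_TABLE_COLUMNS = ("plant_id", "root_id", "order", "parent_id",
                          "point_index", "x", "y")


def _fmt(value: float) -> str:
    return repr(float(value))  # shortest text that round-trips float64


# ---------------------------------------------------------------------------
# RSML


def parse_rsml(document: str) -> list[RootSystem]:
    """Parse an RSML document into one :class:`RootSystem` per plant."""
    try:
        tree = ET.fromstring(document)
    except ET.ParseError as exc:
        raise ParseError(f"malformed RSML XML: {exc}") from exc
    if tree.tag != "rsml":
        raise ParseError(f"root element is <{tree.tag}>, expected <rsml>")
    scene = tree.find("scene")
    if scene is None:
        raise ParseError("RSML document lacks a <scene> element")

    systems: list[RootSystem] = []
    for plant in scene.iterfind("plant"):
        plant_id = plant.get("id") or f"plant{len(systems) + 1}"
        roots: list[RootRecord] = []
        for top in plant.iterfind("root"):
            _parse_root(top, order=1, parent_id=None, roots=roots,
                        plant_id=plant_id)
        seed = _parse_seed_annotation(plant)
        if seed is None:
            firsts = [r for r in roots if r.order == 1]
            if not firsts:
                raise ValidationError(
                    f"plant {plant_id!r}: no first-order root",
                    plant_id=plant_id)
            seed = Point2D(float(firsts[0].polyline[0, 0]),
                           float(firsts[0].polyline[0, 1]))
        system = RootSystem(plant_id=plant_id, seed_origin=seed, roots=roots,
                            line_id=plant.get("label"),
                            experiment_id=plant.get("experiment"))
        system.validate()
        systems.append(system)
    return systems


def _parse_seed_annotation(plant: ET.Element) -> Point2D | None:
    for ann in plant.iterfind("annotation"):
        if ann.get("name") == "seed_origin":
            pt = ann.find("point")
            if pt is None:
                raise ParseError("seed_origin annotation lacks a <point>")
            return Point2D(float(pt.get("x")), float(pt.get("y")))
    return None


def _parse_root(el: ET.Element, order: int, parent_id: str | None,
                roots: list[RootRecord], plant_id: str) -> None:
    if order > 2:
        raise ValidationError(
            f"plant {plant_id!r}: root nesting deeper than 2 orders is not "
            "supported by this dialect", plant_id=plant_id,
            root_id=el.get("id"))
    root_id = el.get("id") or f"{plant_id}.r{len(roots) + 1}"
    polyline = el.find("geometry/polyline")
    if polyline is None:
        raise ParseError(f"root {root_id!r}: missing <geometry>/<polyline>")
    points = [(float(p.get("x")), float(p.get("y")))
              for p in polyline.iterfind("point")]
    if len(points) < 2:
        raise ValidationError(
            f"root {root_id!r}: polyline has {len(points)} point(s), need >= 2",
            root_id=root_id, plant_id=plant_id)
    roots.append(RootRecord(root_id=root_id, order=order, parent_id=parent_id,
                            polyline=points))
    for child in el.iterfind("root"):
        _parse_root(child, order + 1, root_id, roots, plant_id)


def write_rsml(systems: list[RootSystem]) -> str:
    """Serialise systems to RSML text; ``parse_rsml`` inverts it exactly."""
    rsml = ET.Element("rsml")
    meta = ET.SubElement(rsml, "metadata")
    ET.SubElement(meta, "version").text = "1"
    ET.SubElement(meta, "unit").text = "pixel"
    scene = ET.SubElement(rsml, "scene")
    for system in systems:
        system.validate()
        plant = ET.SubElement(scene, "plant", id=system.plant_id)
        if system.line_id is not None:
            plant.set("label", system.line_id)
        if system.experiment_id is not None:
            plant.set("experiment", system.experiment_id)
        ann = ET.SubElement(plant, "annotation", name="seed_origin")
        ET.SubElement(ann, "point", x=_fmt(system.seed_origin.x),
                      y=_fmt(system.seed_origin.y))
        elements: dict[str, ET.Element] = {}
        for root in system.roots:
            parent_el = plant if root.parent_id is None else elements[root.parent_id]
            el = ET.SubElement(parent_el, "root", id=root.root_id)
            geom = ET.SubElement(el, "geometry")
            poly = ET.SubElement(geom, "polyline")
            for x, y in root.polyline:
                ET.SubElement(poly, "point", x=_fmt(x), y=_fmt(y))
            elements[root.root_id] = el
    ET.indent(rsml)
    return ET.tostring(rsml, encoding="unicode", xml_declaration=True)


# ---------------------------------------------------------------------------
# polyline table (CSV)


def parse_polyline_table(table: str) -> list[RootSystem]:
    """Parse the flat polyline-table CSV dialect into RootSystems."""
    try:
        df = pd.read_csv(_stdio.StringIO(table),
                         dtype={"plant_id": str, "root_id": str,
                                "parent_id": str},
                         float_precision="round_trip")
    except Exception as exc:  # pandas raises several parser error types
        raise ParseError(f"malformed polyline CSV: {exc}") from exc
    missing = [c for c in POLYLINE_TABLE_COLUMNS if c not in df.columns]
    if missing:
        raise SchemaError(f"polyline table missing column(s): {missing}")

    systems: list[RootSystem] = []
    for plant_id, plant_df in df.groupby("plant_id", sort=False):
        roots: list[RootRecord] = []
        for root_id, root_df in plant_df.groupby("root_id", sort=False):
            root_df = root_df.sort_values("point_index")
            idx = root_df["point_index"].to_numpy()
            if list(idx) != list(range(len(idx))):
                raise ValidationError(
                    f"root {root_id!r}: point_index not contiguous from 0",
                    root_id=str(root_id), plant_id=str(plant_id))
            orders = root_df["order"].unique()
            parents = root_df["parent_id"].where(root_df["parent_id"].notna(),
                                                 None).unique()
            if len(orders) != 1 or len(parents) != 1:
                raise ValidationError(
                    f"root {root_id!r}: inconsistent order/parent_id rows",
                    root_id=str(root_id), plant_id=str(plant_id))
            parent = parents[0] if parents[0] is not None else None
            roots.append(RootRecord(
                root_id=str(root_id), order=int(orders[0]),
                parent_id=None if parent is None else str(parent),
                polyline=root_df[["x", "y"]].to_numpy(dtype=float)))
        firsts = [r for r in roots if r.order == 1]
        if not firsts:
            raise ValidationError(
                f"plant {plant_id!r}: no first-order root",
                plant_id=str(plant_id))
        seed = Point2D(float(firsts[0].polyline[0, 0]),
                       float(firsts[0].polyline[0, 1]))
        system = RootSystem(plant_id=str(plant_id), seed_origin=seed,
                            roots=roots)
        system.validate()
        systems.append(system)
    return systems


def write_polyline_table(systems: list[RootSystem]) -> str:
    """Serialise systems to the flat polyline-table CSV dialect."""
    lines = [",".join(POLYLINE_TABLE_COLUMNS)]
    for system in systems:
        system.validate()
        for root in system.roots:
            parent = "" if root.parent_id is None else root.parent_id
            for i, (x, y) in enumerate(root.polyline):
                lines.append(f"{system.plant_id},{root.root_id},{root.order},"
                             f"{parent},{i},{_fmt(x)},{_fmt(y)}")
    return "\n".join(lines) + "\n"
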