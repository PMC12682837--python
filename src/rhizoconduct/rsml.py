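"""Reading and writing RSML (Root System Markup Language) root traces.

RSML is the XML interchange format emitted by root-tracing tools; the
document hierarchy is scene → plant → root, with laterals nested inside
their parent ``<root>`` element.  Geometry is an ordered polyline of 3D
points in cm; per-node radii travel in a ``diameter`` (or ``radius``)
function, and per-node creation times (days) in a creation-time function
when the tracing carried temporal information.

Conventions: right-handed coordinates with z negative downward, units cm,
so a seed planted 3 cm deep sits at z = -3.  Both per-node radius arrays
and single-radius attributes are accepted on read; per-node radii are
always written.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Optional

import numpy as np
from lxml import etree

__all__ = ["RsmlRoot", "read_rsml", "write_rsml"]

ROOT_TYPES = ("primary", "seminal", "crown", "l-lateral", "s-lateral", "unlabelled")

_TIME_FN_NAMES = {"node_creation_time", "creation_time", "age", "emergence_time"}
_RADIUS_FN_NAMES = {"diameter", "radius"}


@dataclass
class RsmlRoot:
    """One traced root: polyline geometry plus per-node attributes."""

    id: str
    parent_id: Optional[str]
    polyline: np.ndarray  # (n, 3) points, cm
    radii: np.ndarray  # (n,) per-node radius, cm
    creation_times: Optional[np.ndarray] = None  # (n,) days, None if untimed
    type_label: str = "unlabelled"
    branching_order: int = 0
    properties: dict = field(default_factory=dict)

    def __post_init__(self):
        self.polyline = np.asarray(self.polyline, dtype=float)
        self.radii = np.asarray(self.radii, dtype=float)
        if self.polyline.ndim != 2 or self.polyline.shape[1] != 3:
            raise ValueError(f"root {self.id}: polyline must be (n, 3)")
        if self.polyline.shape[0] < 2:
            raise ValueError(f"root {self.id}: polyline needs at least 2 points")
        if self.radii.shape[0] != self.polyline.shape[0]:
            raise ValueError(f"root {self.id}: one radius per polyline node required")
        if np.any(self.radii <= 0):
            raise ValueError(f"root {self.id}: radii must be positive")
        if self.creation_times is not None:
            self.creation_times = np.asarray(self.creation_times, dtype=float)
            if self.creation_times.shape[0] != self.polyline.shape[0]:
                raise ValueError(f"root {self.id}: one creation time per node required")
        if self.type_label not in ROOT_TYPES:
            raise ValueError(f"root {self.id}: unknown type label {self.type_label!r}")

    @property
    def length(self) -> float:
        """Polyline arc length (cm)."""
        return float(np.sum(np.linalg.norm(np.diff(self.polyline, axis=0), axis=1)))


def _parse_function(fn_el) -> np.ndarray:
    return np.array([float(s.get("value")) for s in fn_el.findall("sample")])


def _parse_root(root_el, parent_id: Optional[str], order: int,
                roots: list[RsmlRoot]) -> None:
    rid = root_el.get("ID") or root_el.get("id")
    if rid is None:
        rid = f"auto-{len(roots)}"
    poly_el = root_el.find("geometry/polyline")
    if poly_el is None:
        raise ValueError(f"root {rid}: missing geometry/polyline")
    pts = np.array([[float(p.get("x", 0.0)), float(p.get("y", 0.0)),
                     float(p.get("z", 0.0))] for p in poly_el.findall("point")])
    if pts.ndim != 2 or pts.shape[0] < 2:
        raise ValueError(f"root {rid}: polyline has fewer than 2 nodes")

    n = pts.shape[0]
    radii = None
    times = None
    for fn in root_el.findall("functions/function"):
        name = (fn.get("name") or "").lower()
        if name in _RADIUS_FN_NAMES:
            vals = _parse_function(fn)
            radii = vals / 2.0 if name == "diameter" else vals
        elif name in _TIME_FN_NAMES:
            times = _parse_function(fn)

    props = {}
    props_el = root_el.find("properties")
    if props_el is not None:
        for child in props_el:
            tag = etree.QName(child).localname
            props[tag] = child.get("value", child.text)

    if radii is None:
        # fall back to a single-radius attribute/property (uniform along the root)
        r_attr = root_el.get("radius") or props.get("radius") or props.get("diameter")
        if r_attr is None:
            raise ValueError(f"root {rid}: no radius information")
        r = float(r_attr)
        if "diameter" in props and "radius" not in props and root_el.get("radius") is None:
            r /= 2.0
        radii = np.full(n, r)

    label = root_el.get("label") or props.get("type") or props.get("label")
    if label not in ROOT_TYPES:
        # default typing by branching order, mirroring tracing output where only
        # axial roots carry explicit flags
        label = "primary" if order == 0 else "unlabelled"

    roots.append(RsmlRoot(id=str(rid), parent_id=parent_id, polyline=pts,
                          radii=radii, creation_times=times,
                          type_label=str(label), branching_order=order,
                          properties=props))
    for child in root_el.findall("root"):
        _parse_root(child, str(rid), order + 1, roots)


def read_rsml(path) -> list[RsmlRoot]:
    """Parse an RSML file into a flat list of roots with parent links preserved.

    Creation times absent from the file are left as ``None`` (flagged, never
    invented).  Malformed XML raises with the parser's line information;
    roots with fewer than two nodes are rejected by id.
    """
    try:
        tree = etree.parse(str(path))
    except etree.XMLSyntaxError as exc:
        raise ValueError(f"malformed RSML {path}: {exc}") from exc
    roots: list[RsmlRoot] = []
    for scene in tree.getroot().findall("scene"):
        for plant in scene.findall("plant"):
            for root_el in plant.findall("root"):
                _parse_root(root_el, None, 0, roots)
    return roots


def _write_root(parent_el, root: RsmlRoot, children: dict) -> None:
    el = etree.SubElement(parent_el, "root", ID=root.id, label=root.type_label)
    props = etree.SubElement(el, "properties")
    for key, value in root.properties.items():
        etree.SubElement(props, key, value=str(value))
    geom = etree.SubElement(el, "geometry")
    poly = etree.SubElement(geom, "polyline")
    for x, y, z in root.polyline:
        etree.SubElement(poly, "point", x=repr(float(x)), y=repr(float(y)),
                         z=repr(float(z)))
    fns = etree.SubElement(el, "functions")
    diam = etree.SubElement(fns, "function", name="diameter", domain="polyline")
    for r in root.radii:
        etree.SubElement(diam, "sample", value=repr(float(2.0 * r)))
    if root.creation_times is not None:
        ct = etree.SubElement(fns, "function", name="node_creation_time",
                              domain="polyline")
        for t in root.creation_times:
            etree.SubElement(ct, "sample", value=repr(float(t)))
    for child in children.get(root.id, []):
        _write_root(el, child, children)


def write_rsml(roots: Iterable[RsmlRoot], path) -> None:
    """Write roots as an RSML document; laterals nest inside their parent.

    Round trip with :func:`read_rsml` is lossless on topology and labels and
    exact to float repr (≪ 1e-9 cm) on coordinates.  A child referencing an
    absent parent id is an error.
    """
    roots = list(roots)
    by_id = {r.id: r for r in roots}
    children: dict[str, list[RsmlRoot]] = {}
    top: list[RsmlRoot] = []
    for r in roots:
        if r.parent_id is None:
            top.append(r)
        else:
            if r.parent_id not in by_id:
                raise ValueError(f"root {r.id} references unknown parent {r.parent_id}")
            children.setdefault(r.parent_id, []).append(r)

    rsml = etree.Element("rsml")
    meta = etree.SubElement(rsml, "metadata")
    etree.SubElement(meta, "version").text = "1"
    etree.SubElement(meta, "unit").text = "cm"
    etree.SubElement(meta, "software").text = "rhizoconduct"
    scene = etree.SubElement(rsml, "scene")
    if top:
        plant = etree.SubElement(scene, "plant")
        for r in top:
            _write_root(plant, r, children)
    Path(path).write_bytes(etree.tostring(rsml, pretty_print=True,
                                          xml_declaration=True, encoding="UTF-8"))
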