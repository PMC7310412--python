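"""Image loading, the plate-image filename convention, RSML and CSV I/O.

Root architectures are exchanged as RSML 1.0 (Root System Markup Language):
an XML ``scene/plant/root`` hierarchy where lateral roots nest inside their
parent ``<root>`` element and geometry is a polyline of ``<point x= y=>``
elements.  Coordinates are written in plate millimetres.  Manual corrections
are expressed as an RSML file that overrides the automatic extraction
(axes replaced by id, added, or flagged deleted).
"""
from __future__ import annotations

import re
from dataclasses import dataclass
from datetime import datetime
from pathlib import Path
from typing import Optional, Sequence, Union

import numpy as np
import pandas as pd
from lxml import etree

from .errors import LabelParseError, RSMLError, ValidationError
from .plate_model import (
    TRAIT_FIELDS,
    PlateImageMeta,
    Polyline,
    RootAxis,
    RootSystem,
    TraitRecord,
    View,
)

__all__ = [
    "GrayImage",
    "ColorImage",
    "load_image",
    "parse_image_label",
    "DEFAULT_LABEL_PATTERN",
    "read_rsml",
    "write_rsml",
    "traits_to_dataframe",
    "write_traits_csv",
    "read_trait_matrix",
]


@dataclass
class GrayImage:
    """2-D array of 8-bit intensities plus plate metadata."""

    pixels: np.ndarray
    meta: PlateImageMeta

    def __post_init__(self) -> None:
        if self.pixels.ndim != 2:
            raise ValidationError("GrayImage requires a 2-D array")


@dataclass
class ColorImage:
    """RGB image (H x W x 3, 8-bit) plus plate metadata."""

    pixels: np.ndarray
    meta: PlateImageMeta

    def __post_init__(self) -> None:
        if self.pixels.ndim != 3 or self.pixels.shape[2] != 3:
            raise ValidationError("ColorImage requires an (H, W, 3) array")


# <timestamp>_<plateNo>_<root|shoot>.<ext>; timestamp = YYYYMMDD'T'HHMM[SS]
DEFAULT_LABEL_PATTERN = (
    r"^(?P<timestamp>\d{8}T\d{4}(?:\d{2})?)_(?P<plate>[A-Za-z0-9-]+)_"
    r"(?P<view>root|shoot)\.(?P<ext>bmp|png|tif|tiff)$"
)


def parse_image_label(filename: Union[str, Path], pattern: str = DEFAULT_LABEL_PATTERN) -> PlateImageMeta:
    """Parse ``<timestamp>_<plateNo>_<root|shoot>.<ext>`` into metadata.

    The dialect is configurable: any regex with named groups ``timestamp``,
    ``plate`` and ``view`` may be supplied.
    """
    name = Path(filename).name
    m = re.match(pattern, name, flags=re.IGNORECASE)
    if m is None:
        raise LabelParseError(
            f"filename {name!r} does not match the expected pattern "
            f"<timestamp>_<plateNo>_<root|shoot>.<ext> ({pattern})"
        )
    ts = m.group("timestamp")
    fmt = "%Y%m%dT%H%M%S" if len(ts) == 15 else "%Y%m%dT%H%M"
    try:
        capture_time = datetime.strptime(ts, fmt)
    except ValueError as exc:
        raise LabelParseError(f"bad timestamp {ts!r} in {name!r}") from exc
    return PlateImageMeta(
        plate_id=m.group("plate"),
        view=View(m.group("view").lower()),
        capture_time=capture_time,
    )


def _to_uint8(arr: np.ndarray) -> np.ndarray:
    """Rescale higher-bit-depth integer data to 8 bits by the dtype range."""
    if arr.dtype == np.uint8:
        return arr
    if np.issubdtype(arr.dtype, np.integer):
        maxval = float(np.iinfo(arr.dtype).max)
        return np.round(arr.astype(float) * (255.0 / maxval)).astype(np.uint8)
    if np.issubdtype(arr.dtype, np.floating):
        return np.round(np.clip(arr, 0.0, 1.0) * 255.0).astype(np.uint8)
    raise IOError(f"unsupported pixel dtype {arr.dtype}")


def load_image(
    path: Union[str, Path],
    meta: Optional[PlateImageMeta] = None,
    pattern: str = DEFAULT_LABEL_PATTERN,
) -> Union[GrayImage, ColorImage]:
    """Load a BMP/PNG/TIFF plate image, pixel-exact for 8-bit input.

    Metadata is parsed from the filename unless supplied.  A single-channel
    file yields a :class:`GrayImage`; a 3-channel file yields a
    :class:`ColorImage` unless the metadata says ``view=root``, in which case
    it is converted to grayscale (channel mean).  16-bit input is rescaled to
    8 bits by the dtype range.
    """
    import imageio.v3 as iio

    path = Path(path)
    if not path.exists():
        raise IOError(f"image file not found: {path}")
    if meta is None:
        try:
            meta = parse_image_label(path.name, pattern)
        except LabelParseError:
            meta = PlateImageMeta(plate_id=path.stem, view=View.ROOT)
    try:
        arr = iio.imread(path)
    except Exception as exc:  # pragma: no cover - backend specific
        raise IOError(f"cannot read image {path}: {exc}") from exc
    if arr.ndim == 3 and arr.shape[2] == 4:  # drop alpha
        arr = arr[:, :, :3]
    arr = _to_uint8(arr)
    if arr.ndim == 3 and meta.view is View.ROOT:
        arr = np.round(arr.mean(axis=2)).astype(np.uint8)
    meta.image_height_px, meta.image_width_px = arr.shape[0], arr.shape[1]
    if arr.ndim == 2:
        return GrayImage(arr, meta)
    return ColorImage(arr, meta)


# ---------------------------------------------------------------------------
# RSML
# ---------------------------------------------------------------------------

def _root_element(ax: RootAxis, children_by_parent: dict) -> etree._Element:
    el = etree.Element("root", ID=ax.axis_id, label=f"order-{ax.order}")
    props = etree.SubElement(el, "properties")
    if ax.branch_pos_mm is not None:
        etree.SubElement(props, "branch-position-mm").text = repr(float(ax.branch_pos_mm))
    if ax.mean_diameter_um is not None:
        etree.SubElement(props, "diameter-um").text = repr(float(ax.mean_diameter_um))
    if ax.deleted:
        etree.SubElement(props, "deleted").text = "true"
    geom = etree.SubElement(el, "geometry")
    poly = etree.SubElement(geom, "polyline")
    for x, y in ax.path.vertices:
        etree.SubElement(poly, "point", x=repr(float(x)), y=repr(float(y)))
    for child in children_by_parent.get(ax.axis_id, ()):
        el.append(_root_element(child, children_by_parent))
    return el


def write_rsml(systems: Sequence[RootSystem], path: Union[str, Path]) -> None:
    """Write root systems to an RSML 1.0 file (one ``<plant>`` per system)."""
    rsml = etree.Element("rsml")
    md = etree.SubElement(rsml, "metadata")
    etree.SubElement(md, "version").text = "1"
    etree.SubElement(md, "unit").text = "mm"
    etree.SubElement(md, "resolution").text = "1"
    etree.SubElement(md, "software").text = "rhizotrace"
    scene = etree.SubElement(rsml, "scene")
    for system in systems:
        plant = etree.SubElement(scene, "plant", ID=system.plant_id, label=system.plant_id)
        props = etree.SubElement(plant, "properties")
        etree.SubElement(props, "plate-id").text = system.plate_id
        if system.capture_time is not None:
            etree.SubElement(props, "capture-time").text = system.capture_time.isoformat()
        etree.SubElement(props, "seed-x-mm").text = repr(float(system.seed_point[0]))
        etree.SubElement(props, "seed-y-mm").text = repr(float(system.seed_point[1]))
        if system.empty:
            etree.SubElement(props, "empty").text = "true"
        children: dict[str, list[RootAxis]] = {}
        tops = []
        for ax in system.axes:
            if ax.parent_id is None:
                tops.append(ax)
            else:
                children.setdefault(ax.parent_id, []).append(ax)
        for ax in tops:
            plant.append(_root_element(ax, children))
    tree = etree.ElementTree(rsml)
    tree.write(str(path), pretty_print=True, xml_declaration=True, encoding="UTF-8")


def _prop_text(el: etree._Element, name: str) -> Optional[str]:
    node = el.find(f"properties/{name}")
    return None if node is None else node.text


def _parse_root(el: etree._Element, order: int, parent_id: Optional[str], out: list[RootAxis]) -> None:
    axis_id = el.get("ID")
    if axis_id is None:
        raise RSMLError("<root> element without ID attribute")
    pts = el.findall("geometry/polyline/point")
    if len(pts) < 2:
        raise RSMLError(f"root {axis_id}: missing or degenerate polyline geometry")
    verts = [(float(p.get("x")), float(p.get("y"))) for p in pts]
    branch_txt = _prop_text(el, "branch-position-mm")
    diam_txt = _prop_text(el, "diameter-um")
    deleted = (_prop_text(el, "deleted") or "").strip().lower() == "true"
    out.append(
        RootAxis(
            axis_id=axis_id,
            order=order,
            path=Polyline(verts),
            parent_id=parent_id,
            branch_pos_mm=None if branch_txt is None else float(branch_txt),
            mean_diameter_um=None if diam_txt is None else float(diam_txt),
            deleted=deleted,
        )
    )
    for child in el.findall("root"):
        _parse_root(child, order + 1, axis_id, out)


def read_rsml(path: Union[str, Path]) -> list[RootSystem]:
    """Read root systems from an RSML file (inverse of :func:`write_rsml`)."""
    try:
        tree = etree.parse(str(path))
    except (etree.XMLSyntaxError, OSError) as exc:
        raise RSMLError(f"cannot parse RSML file {path}: {exc}") from exc
    systems = []
    for plant in tree.findall(".//scene/plant"):
        plant_id = plant.get("ID") or plant.get("label") or "plant"
        plate_id = _prop_text(plant, "plate-id") or ""
        t_txt = _prop_text(plant, "capture-time")
        capture_time = None if t_txt is None else datetime.fromisoformat(t_txt)
        sx = _prop_text(plant, "seed-x-mm")
        sy = _prop_text(plant, "seed-y-mm")
        empty = (_prop_text(plant, "empty") or "").strip().lower() == "true"
        axes: list[RootAxis] = []
        for el in plant.findall("root"):
            _parse_root(el, 0, None, axes)
        if sx is not None and sy is not None:
            seed = (float(sx), float(sy))
        elif axes:
            seed = tuple(axes[0].path.first())
        else:
            seed = (0.0, 0.0)
        systems.append(
            RootSystem(
                plant_id=plant_id,
                plate_id=plate_id,
                seed_point=seed,
                axes=axes,
                capture_time=capture_time,
                empty=empty or not axes,
            )
        )
    return systems


# ---------------------------------------------------------------------------
# Trait tables
# ---------------------------------------------------------------------------


def traits_to_dataframe(records: Sequence[TraitRecord]) -> pd.DataFrame:
    """One row per plant x timepoint; columns exactly the trait field names."""
    return pd.DataFrame([r.to_dict() for r in records], columns=["plant_id", "capture_time", *TRAIT_FIELDS])


def write_traits_csv(records: Sequence[TraitRecord], path: Union[str, Path]) -> None:
    traits_to_dataframe(records).to_csv(path, index=False)


def read_trait_matrix(path: Union[str, Path], index_col: str = "genotype") -> pd.DataFrame:
    """Read a genotypes x traits CSV into a DataFrame (NaN = missing)."""
    df = pd.read_csv(path)
    if index_col in df.columns:
        df = df.set_index(index_col)
    return df.apply(pd.to_numeric, errors="coerce")
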