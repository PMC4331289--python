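"""Raster/vector I/O and parcel-to-pixel resolution.

Rasters are four-band (Blue, Green, Red, NIR) GeoTIFFs holding digital
numbers on a north-up regular grid; parcels are GeoJSON polygons with a
unique ID attribute and, for ground-truthed parcels, a land-use label.
Pixel membership follows the standard zonal-statistics convention: a pixel
belongs to a parcel iff its center point lies in the (closed) polygon.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import shapely
import tifffile
from shapely.geometry import shape as shapely_shape
from shapely.geometry import mapping as shapely_mapping

#: Canonical band names, in storage order. "Gree" (not "Green") is the
#: canonical token used in feature-column names such as ``T3Gree``.
BAND_NAMES = ("Blue", "Gree", "Red", "NIR")

BAND_ALIASES = {"Green": "Gree", "B": "Blue", "G": "Gree", "R": "Red"}

# GeoTIFF tag codes for the affine georeferencing of a north-up grid.
_TAG_MODEL_PIXEL_SCALE = 33550
_TAG_MODEL_TIEPOINT = 33922


class GeoFormatError(ValueError):
    """Raised for unreadable or structurally invalid raster/vector files."""


def canonical_band(name: str) -> str:
    name = name.strip()
    resolved = BAND_ALIASES.get(name, name)
    if resolved not in BAND_NAMES:
        raise GeoFormatError(f"unknown band name {name!r}")
    return resolved


@dataclass
class RasterScene:
    """One acquisition: four aligned band grids plus georeferencing.

    Parameters
    ----------
    bands
        Mapping from canonical band name to a 2-D array of non-negative
        digital numbers; all four grids share one shape.
    geotransform
        ``(origin_x, origin_y, pixel_size_x, pixel_size_y)`` with the
        origin at the top-left corner of the top-left pixel and strictly
        positive pixel sizes (north-up, row 0 at the top).
    crs_tag
        Opaque CRS label; scenes and parcels are only combined when their
        tags compare equal (no reprojection is attempted).
    time_tag
        Ordinal acquisition label, ``T1`` ... ``Tn``.
    """

    bands: dict[str, np.ndarray]
    geotransform: tuple[float, float, float, float]
    crs_tag: str = "local"
    time_tag: str = "T1"

    def __post_init__(self) -> None:
        if set(self.bands) != set(BAND_NAMES):
            raise GeoFormatError(
                f"expected bands {BAND_NAMES}, got {tuple(sorted(self.bands))}"
            )
        shapes = {b: np.asarray(g).shape for b, g in self.bands.items()}
        if len(set(shapes.values())) != 1:
            raise GeoFormatError(f"band grids differ in shape: {shapes}")
        for b in BAND_NAMES:
            grid = np.asarray(self.bands[b], dtype=float)
            if grid.ndim != 2:
                raise GeoFormatError(f"band {b} is not a 2-D grid")
            if not np.all(np.isfinite(grid)) or np.any(grid < 0):
                raise GeoFormatError(f"band {b} holds non-finite or negative values")
            self.bands[b] = grid
        ox, oy, px, py = self.geotransform
        if not (px > 0 and py > 0):
            raise GeoFormatError("pixel sizes must be strictly positive")

    @property
    def shape(self) -> tuple[int, int]:
        return self.bands[BAND_NAMES[0]].shape

    def pixel_center(self, row: int, col: int) -> tuple[float, float]:
        """Map coordinates of the center of pixel ``(row, col)``."""
        ox, oy, px, py = self.geotransform
        return ox + (col + 0.5) * px, oy - (row + 0.5) * py


@dataclass
class Parcel:
    parcel_id: str
    polygon: shapely.Geometry
    label: str | None = None


@dataclass
class ParcelSet:
    """Validated collection of parcels with unique IDs."""

    parcels: list[Parcel]
    crs_tag: str = "local"

    def __post_init__(self) -> None:
        seen: set[str] = set()
        dupes: list[str] = []
        bad: list[str] = []
        for p in self.parcels:
            if p.parcel_id in seen:
                dupes.append(p.parcel_id)
            seen.add(p.parcel_id)
            geom = p.polygon
            if (
                geom is None
                or geom.is_empty
                or not math.isfinite(geom.area)
                or geom.area <= 0
                or not geom.is_valid
            ):
                bad.append(p.parcel_id)
        if dupes:
            raise GeoFormatError(f"duplicate parcel IDs: {sorted(set(dupes))}")
        if bad:
            raise GeoFormatError(f"invalid or zero-area polygons: {bad}")

    def __len__(self) -> int:
        return len(self.parcels)

    def __iter__(self):
        return iter(self.parcels)

    @property
    def ids(self) -> list[str]:
        return [p.parcel_id for p in self.parcels]

    def labels(self) -> dict[str, str]:
        return {p.parcel_id: p.label for p in self.parcels if p.label is not None}


# ---------------------------------------------------------------------------
# Label hierarchy: crop -> cropping system -> Veg/NonVeg

#: Default crop-to-cropping-system grouping. ATO = adult tree orchards,
#: SUC = summer crops, WIC = winter crops, YTO = young tree orchards,
#: CiWo = civil works, WTS = water surfaces.
DEFAULT_CROP_TO_SYSTEM = {
    "CIT": "ATO", "MFO": "ATO", "OLV": "ATO", "POP": "ATO",
    "COT": "SUC", "CRN": "SUC", "POT": "SUC", "SUN": "SUC",
    "BNS": "WIC", "CKP": "WIC", "OAT": "WIC", "WHT": "WIC",
    "YTO": "YTO",
    "CIV": "CiWo",
    "WAT": "WTS",
}

DEFAULT_SYSTEM_TO_VEG = {
    "ATO": "Veg", "SUC": "Veg", "WIC": "Veg", "YTO": "Veg",
    "CiWo": "NonVeg", "WTS": "NonVeg",
}

#: Sentinel label for parcels with no ground truth.
UNKNOWN = "UNKNOWN"


@dataclass
class LabelHierarchy:
    """Two-level grouping of crop codes: crop -> system -> Veg/NonVeg."""

    crop_to_system: dict[str, str] = field(
        default_factory=lambda: dict(DEFAULT_CROP_TO_SYSTEM)
    )
    system_to_veg: dict[str, str] = field(
        default_factory=lambda: dict(DEFAULT_SYSTEM_TO_VEG)
    )

    def __post_init__(self) -> None:
        missing = {s for s in self.crop_to_system.values() if s not in self.system_to_veg}
        if missing:
            raise ValueError(f"systems with no Veg/NonVeg assignment: {sorted(missing)}")
        bad = {v for v in self.system_to_veg.values() if v not in ("Veg", "NonVeg")}
        if bad:
            raise ValueError(f"top-level groups must be Veg/NonVeg, got {sorted(bad)}")

    @property
    def crops(self) -> list[str]:
        return sorted(self.crop_to_system)

    def system(self, crop: str) -> str:
        if crop not in self.crop_to_system:
            raise KeyError(f"label {crop!r} is not in the hierarchy")
        return self.crop_to_system[crop]

    def veg(self, crop: str) -> str:
        return self.system_to_veg[self.system(crop)]

    def relabel(self, label: str, level: str) -> str:
        """Map a crop code to the requested level: crop, system, or veg."""
        if label == UNKNOWN:
            return UNKNOWN
        if level == "crop":
            if label not in self.crop_to_system:
                raise KeyError(f"label {label!r} is not in the hierarchy")
            return label
        if level == "system":
            return self.system(label)
        if level == "veg":
            return self.veg(label)
        raise ValueError(f"unknown level {level!r}")

    @classmethod
    def from_file(cls, path: str | Path) -> "LabelHierarchy":
        """Load a hierarchy from a JSON/YAML mapping file."""
        import yaml

        with open(path, "r", encoding="utf-8") as fh:
            data = yaml.safe_load(fh)
        return cls(
            crop_to_system=dict(data["crop_to_system"]),
            system_to_veg=dict(data["system_to_veg"]),
        )


# ---------------------------------------------------------------------------
# Raster I/O


def write_raster(scene: RasterScene, path: str | Path) -> None:
    """Write a four-band GeoTIFF with pixel-scale and tiepoint tags."""
    ox, oy, px, py = scene.geotransform
    data = np.stack([scene.bands[b] for b in BAND_NAMES])
    meta = {"crs_tag": scene.crs_tag, "time_tag": scene.time_tag,
            "band_order": list(BAND_NAMES)}
    extratags = [
        (_TAG_MODEL_PIXEL_SCALE, "d", 3, (float(px), float(py), 0.0)),
        (_TAG_MODEL_TIEPOINT, "d", 6, (0.0, 0.0, 0.0, float(ox), float(oy), 0.0)),
    ]
    tifffile.imwrite(
        path,
        data,
        photometric="minisblack",
        planarconfig="separate",
        description=json.dumps(meta),
        extratags=extratags,
    )


def read_raster(
    path: str | Path,
    time_tag: str | None = None,
    band_order: tuple[str, ...] | None = None,
    crs_tag: str | None = None,
) -> RasterScene:
    """Read a multiband GeoTIFF into a :class:`RasterScene`.

    ``band_order`` maps file bands to roles; the default is
    ``(Blue, Gree, Red, NIR)`` i.e. file bands 1-4 = B, G, R, NIR.
    """
    path = Path(path)
    try:
        with tifffile.TiffFile(path) as tif:
            page = tif.pages[0]
            data = tif.asarray()
            desc = page.description
            scale_tag = page.tags.get(_TAG_MODEL_PIXEL_SCALE)
            tiepoint_tag = page.tags.get(_TAG_MODEL_TIEPOINT)
            scale = scale_tag.value if scale_tag is not None else None
            tiepoint = tiepoint_tag.value if tiepoint_tag is not None else None
    except (OSError, ValueError, tifffile.TiffFileError) as exc:
        raise GeoFormatError(f"cannot read raster {path}: {exc}") from exc

    data = np.atleast_3d(np.asarray(data))
    # normalize to (bands, rows, cols); tifffile may yield (r, c, b)
    if data.ndim != 3:
        raise GeoFormatError(f"{path}: unsupported raster layout {data.shape}")
    if data.shape[0] not in (1, 2, 3, 4, 5) and data.shape[2] <= 8:
        data = np.moveaxis(data, 2, 0)
    elif data.shape[2] <= 8 < data.shape[0]:
        data = np.moveaxis(data, 2, 0)
    if data.shape[0] < 4:
        raise GeoFormatError(f"{path}: expected 4 bands, found {data.shape[0]}")
    if not np.issubdtype(data.dtype, np.number):
        raise GeoFormatError(f"{path}: non-numeric pixel data ({data.dtype})")

    meta: dict = {}
    if desc:
        try:
            meta = json.loads(desc)
        except (json.JSONDecodeError, TypeError):
            meta = {}

    if scale is None or tiepoint is None:
        raise GeoFormatError(f"{path}: unreadable geotransform tags")
    px, py = float(scale[0]), float(scale[1])
    ox, oy = float(tiepoint[3]), float(tiepoint[4])

    order = tuple(band_order or meta.get("band_order") or BAND_NAMES)
    order = tuple(canonical_band(b) for b in order)
    if set(order) != set(BAND_NAMES):
        raise GeoFormatError(f"{path}: band order {order} does not cover {BAND_NAMES}")
    bands = {role: np.asarray(data[i], dtype=float) for i, role in enumerate(order)}
    return RasterScene(
        bands=bands,
        geotransform=(ox, oy, px, py),
        crs_tag=crs_tag or meta.get("crs_tag", "local"),
        time_tag=time_tag or meta.get("time_tag", "T1"),
    )


# ---------------------------------------------------------------------------
# Vector I/O (GeoJSON)


def read_parcels(
    path: str | Path,
    id_attr: str = "parcel_id",
    label_attr: str = "land_use",
) -> ParcelSet:
    """Read a GeoJSON FeatureCollection of parcel polygons."""
    path = Path(path)
    try:
        with open(path, "r", encoding="utf-8") as fh:
            doc = json.load(fh)
    except (OSError, json.JSONDecodeError) as exc:
        raise GeoFormatError(f"cannot read parcels {path}: {exc}") from exc
    feats = doc.get("features")
    if feats is None:
        raise GeoFormatError(f"{path}: not a GeoJSON FeatureCollection")
    parcels = []
    for i, feat in enumerate(feats):
        props = feat.get("properties") or {}
        if id_attr not in props:
            raise GeoFormatError(f"{path}: feature {i} lacks ID attribute {id_attr!r}")
        try:
            geom = shapely_shape(feat["geometry"])
        except (KeyError, ValueError, AttributeError) as exc:
            raise GeoFormatError(f"{path}: feature {props[id_attr]!r}: bad geometry") from exc
        label = props.get(label_attr)
        parcels.append(Parcel(str(props[id_attr]), geom, label))
    crs_tag = doc.get("crs_tag", "local")
    return ParcelSet(parcels, crs_tag=crs_tag)


def write_parcels(
    parcels: ParcelSet,
    path: str | Path,
    id_attr: str = "parcel_id",
    label_attr: str = "land_use",
) -> None:
    feats = []
    for p in parcels:
        props = {id_attr: p.parcel_id}
        if p.label is not None:
            props[label_attr] = p.label
        feats.append(
            {"type": "Feature", "properties": props,
             "geometry": shapely_mapping(p.polygon)}
        )
    doc = {"type": "FeatureCollection", "crs_tag": parcels.crs_tag, "features": feats}
    with open(path, "w", encoding="utf-8") as fh:
        json.dump(doc, fh)


# ---------------------------------------------------------------------------
# Parcel -> pixel resolution


def parcel_pixel_indices(
    scene: RasterScene,
    polygon: shapely.Geometry,
    crs_tag: str | None = None,
    buffer: float = 0.0,
) -> set[tuple[int, int]]:
    """Pixels of ``scene`` whose center lies in the (closed) polygon.

    A center exactly on the boundary counts as inside. ``buffer`` < 0
    shrinks the parcel to avoid mixed edge pixels. Returns an empty set for
    polygons wholly outside the raster.
    """
    if crs_tag is not None and crs_tag != scene.crs_tag:
        raise GeoFormatError(
            f"CRS mismatch: parcels {crs_tag!r} vs scene {scene.crs_tag!r}"
        )
    if buffer != 0.0:
        polygon = polygon.buffer(buffer)
        if polygon.is_empty:
            return set()
    nrows, ncols = scene.shape
    ox, oy, px, py = scene.geotransform
    minx, miny, maxx, maxy = polygon.bounds
    # candidate window of pixel centers overlapping the polygon bounds
    c0 = max(0, int(math.floor((minx - ox) / px - 0.5)))
    c1 = min(ncols - 1, int(math.ceil((maxx - ox) / px - 0.5)))
    r0 = max(0, int(math.floor((oy - maxy) / py - 0.5)))
    r1 = min(nrows - 1, int(math.ceil((oy - miny) / py - 0.5)))
    if c1 < c0 or r1 < r0:
        return set()
    cols = np.arange(c0, c1 + 1)
    rows = np.arange(r0, r1 + 1)
    xs = ox + (cols + 0.5) * px
    ys = oy - (rows + 0.5) * py
    gx, gy = np.meshgrid(xs, ys)
    # intersects == covered-by for points: boundary centers count as inside
    inside = shapely.intersects_xy(polygon, gx.ravel(), gy.ravel())
    rr, cc = np.meshgrid(rows, cols, indexing="ij")
    mask = inside.reshape(gx.shape)
    return set(zip(rr[mask].tolist(), cc[mask].tolist()))
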