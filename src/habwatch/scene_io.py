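"""Scene and raster-field I/O with georeferencing.

A *scene* is a stack of quantized integer bands (blue, green, red, nir,
tir10) plus the per-scene radiometric constants needed to turn counts into
physical units. Derived quantities (reflectance, radiance, brightness
temperature, NDVI, Pv, emissivity, Chl-a, LSAT) travel as
:class:`RasterField` objects: a float grid, a validity mask, and the
georeference inherited from the scene.

Files are GeoTIFFs written through :mod:`tifffile` carrying the standard
``ModelPixelScale``/``ModelTiepoint`` geokeys and a ``GDAL_NODATA`` tag, so
they open in GDAL/QGIS; non-spatial metadata rides in a JSON sidecar (one
flat key-value document per scene). Vendor MTL parsing is out of scope.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np
import shapely
import tifffile
from shapely.geometry import box, shape
from shapely.geometry.base import BaseGeometry

from .geo import GridTransform

__all__ = [
    "BAND_ROLES",
    "RadiometricMetadata",
    "Scene",
    "RasterField",
    "SceneIOError",
    "MetadataError",
    "MissingBandError",
    "read_scene",
    "write_scene",
    "read_field",
    "write_field",
    "apply_aoi_mask",
    "load_aoi",
]

#: Recognized band roles, in canonical storage order.
BAND_ROLES = ("blue", "green", "red", "nir", "tir10")

# GeoTIFF / GDAL tag codes used for round-tripping georeference and nodata.
_TAG_MODEL_PIXEL_SCALE = 33550
_TAG_MODEL_TIEPOINT = 33922
_TAG_GDAL_NODATA = 42113

#: Sentinel written into integer bands when pixels are invalidated (e.g. by
#: an AOI mask) and the scene declares no nodata value of its own.
DEFAULT_NODATA = -9999


class SceneIOError(RuntimeError):
    """Raised for unreadable, inconsistent or unwritable scene files."""


class MetadataError(ValueError):
    """A radiometric-metadata invariant is violated; names the offending key."""


class MissingBandError(KeyError):
    """A retrieval needs a band role the scene does not carry."""


@dataclass(frozen=True)
class RadiometricMetadata:
    """Per-scene radiometric constants.

    Defaults follow the Landsat-8 Collection-2 conventions: band-10 radiance
    rescaling ``ml``/``al``, thermal constants ``k1``/``k2`` (standard
    published band-10 values — always check them against the actual scene
    metadata), Level-2 surface-reflectance scaling, the band-10 effective
    wavelength, and the radiation constant ``rho`` = h·c/σ used by the
    mono-window correction term. All are overridable per scene.
    """

    ml: float = 0.0003342          # radiance per DN
    al: float = 0.1                # W m-2 sr-1 um-1
    k1: float = 774.8853           # W m-2 sr-1 um-1
    k2: float = 1321.0789          # K
    refl_scale: float = 0.0000275  # reflectance per DN
    refl_offset: float = -0.2      # reflectance
    lambda10: float = 10.895e-6    # m
    rho: float = 1.4388e-2         # m K

    def __post_init__(self) -> None:
        for key in ("ml", "k1", "k2", "lambda10", "rho", "refl_scale"):
            value = getattr(self, key)
            if not (math.isfinite(value) and value > 0):
                raise MetadataError(f"{key} must be finite and > 0, got {value!r}")

    def to_dict(self) -> dict:
        return {
            "ml": self.ml, "al": self.al, "k1": self.k1, "k2": self.k2,
            "refl_scale": self.refl_scale, "refl_offset": self.refl_offset,
            "lambda10": self.lambda10, "rho": self.rho,
        }

    @classmethod
    def from_dict(cls, data: dict) -> "RadiometricMetadata":
        known = {k: data[k] for k in cls.__dataclass_fields__ if k in data}
        return cls(**known)


@dataclass
class RasterField:
    """One georeferenced grid of physical values with a validity mask.

    ``mask`` is True where the value is valid; invalid values are never
    consumed downstream (operations propagate and intersect masks).
    """

    values: np.ndarray
    mask: np.ndarray
    role: str
    transform: GridTransform = field(default_factory=GridTransform.identity)
    crs_id: str = ""

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=np.float64)
        self.mask = np.asarray(self.mask, dtype=bool)
        if self.values.ndim != 2:
            raise ValueError("RasterField values must be 2-D")
        if self.values.shape != self.mask.shape:
            raise ValueError("values and mask shapes differ")

    @property
    def shape(self) -> tuple[int, int]:
        return self.values.shape

    def filled(self, fill=np.nan) -> np.ndarray:
        """Values with invalid pixels replaced by ``fill``."""
        return np.where(self.mask, self.values, fill)

    def valid_values(self) -> np.ndarray:
        return self.values[self.mask]


@dataclass
class Scene:
    """Multiband quantized raster + radiometric metadata + georeference."""

    bands: dict[str, np.ndarray]
    meta: RadiometricMetadata
    transform: GridTransform = field(default_factory=GridTransform.identity)
    crs_id: str = ""
    nodata: int | None = None

    def __post_init__(self) -> None:
        if not self.bands:
            raise ValueError("scene has no bands")
        shapes = {role: np.asarray(grid).shape for role, grid in self.bands.items()}
        if len(set(shapes.values())) != 1:
            raise ValueError(f"band grids differ in shape: {shapes}")
        for role in self.bands:
            if role not in BAND_ROLES:
                raise ValueError(f"unknown band role {role!r}")
            self.bands[role] = np.asarray(self.bands[role])
            if not np.issubdtype(self.bands[role].dtype, np.integer):
                raise ValueError(f"band {role!r} is not an integer grid")

    @property
    def shape(self) -> tuple[int, int]:
        return next(iter(self.bands.values())).shape

    def band(self, role: str) -> np.ndarray:
        if role not in self.bands:
            raise MissingBandError(f"scene has no {role!r} band")
        return self.bands[role]

    def band_mask(self, role: str) -> np.ndarray:
        """Validity mask for a band: True where the DN is not nodata."""
        grid = self.band(role)
        if self.nodata is None:
            return np.ones(grid.shape, dtype=bool)
        return grid != self.nodata


# ---------------------------------------------------------------------------
# GeoTIFF helpers


def _geo_tags(transform: GridTransform, nodata_repr: str | None):
    if not transform.is_north_up:
        raise SceneIOError("only north-up transforms are writable")
    scale = (transform.a, -transform.e, 0.0)
    tiepoint = (0.0, 0.0, 0.0, transform.c, transform.f, 0.0)
    tags = [
        (_TAG_MODEL_PIXEL_SCALE, "d", 3, scale, True),
        (_TAG_MODEL_TIEPOINT, "d", 6, tiepoint, True),
    ]
    if nodata_repr is not None:
        tags.append((_TAG_GDAL_NODATA, "s", 0, nodata_repr, True))
    return tags


def _read_geo(page) -> tuple[GridTransform, str | None, dict]:
    tags = page.tags
    transform = GridTransform.identity()
    if _TAG_MODEL_PIXEL_SCALE in tags and _TAG_MODEL_TIEPOINT in tags:
        sx, sy, _ = tags[_TAG_MODEL_PIXEL_SCALE].value[:3]
        tie = tags[_TAG_MODEL_TIEPOINT].value
        # tiepoint anchors raster (i, j) = (0, 0) at map (x, y)
        transform = GridTransform(sx, 0.0, float(tie[3]), 0.0, -sy, float(tie[4]))
    nodata = tags[_TAG_GDAL_NODATA].value if _TAG_GDAL_NODATA in tags else None
    description: dict = {}
    if 270 in tags:
        try:
            description = json.loads(tags[270].value)
        except (TypeError, json.JSONDecodeError):
            description = {}
    return transform, nodata, description


def write_field(field_: RasterField, path) -> Path:
    """Persist a field as a single-band float64 GeoTIFF.

    Invalid pixels are stored as NaN with a matching ``GDAL_NODATA`` tag, so
    the write/read round trip is bit-exact for finite valid values.
    """
    path = Path(path)
    data = field_.filled(np.nan)
    description = {"role": field_.role, "crs_id": field_.crs_id}
    try:
        tifffile.imwrite(
            path, data.astype(np.float64),
            photometric="minisblack",
            description=json.dumps(description),
            extratags=_geo_tags(field_.transform, "nan"),
        )
    except OSError as exc:
        raise SceneIOError(f"cannot write {path}: {exc}") from exc
    return path


def read_field(path) -> RasterField:
    """Read a field written by :func:`write_field`."""
    path = Path(path)
    if not path.exists():
        raise SceneIOError(f"no such file: {path}")
    with tifffile.TiffFile(path) as tif:
        page = tif.pages[0]
        values = page.asarray().astype(np.float64)
        transform, _, description = _read_geo(page)
    mask = np.isfinite(values)
    return RasterField(
        values=np.where(mask, values, 0.0),
        mask=mask,
        role=description.get("role", ""),
        transform=transform,
        crs_id=description.get("crs_id", ""),
    )


def write_scene(scene: Scene, scene_path, meta_path) -> tuple[Path, Path]:
    """Write a scene as a multi-band int32 GeoTIFF plus a JSON sidecar.

    The sidecar declares the band order (role names), the nodata sentinel
    and the radiometric constants; :func:`read_scene` requires it.
    """
    scene_path, meta_path = Path(scene_path), Path(meta_path)
    roles = [r for r in BAND_ROLES if r in scene.bands]
    stack = np.stack([scene.bands[r].astype(np.int32) for r in roles])
    nodata_repr = None if scene.nodata is None else str(scene.nodata)
    description = {"bands": roles, "crs_id": scene.crs_id}
    try:
        tifffile.imwrite(
            scene_path, stack,
            photometric="minisblack",
            description=json.dumps(description),
            extratags=_geo_tags(scene.transform, nodata_repr),
        )
        sidecar = {
            "bands": roles,
            "nodata": scene.nodata,
            "crs_id": scene.crs_id,
            "transform": list(scene.transform.coefficients),
            **scene.meta.to_dict(),
        }
        meta_path.write_text(json.dumps(sidecar, indent=2))
    except OSError as exc:
        raise SceneIOError(f"cannot write scene: {exc}") from exc
    return scene_path, meta_path


def read_scene(scene_path, meta_path) -> Scene:
    """Read a scene raster and its JSON metadata sidecar.

    The sidecar's ``bands`` list maps raster planes to roles; bands absent
    from the list are absent from the scene (never zero-filled). Metadata
    invariants are validated on load and reported with the offending key.
    """
    scene_path, meta_path = Path(scene_path), Path(meta_path)
    for p in (scene_path, meta_path):
        if not p.exists():
            raise SceneIOError(f"no such file: {p}")
    try:
        sidecar = json.loads(meta_path.read_text())
    except json.JSONDecodeError as exc:
        raise SceneIOError(f"metadata sidecar does not parse: {exc}") from exc
    roles = sidecar.get("bands")
    if not roles:
        raise SceneIOError("sidecar declares no bands")
    meta = RadiometricMetadata.from_dict(sidecar)

    with tifffile.TiffFile(scene_path) as tif:
        stack = tif.asarray()
        transform, _, _ = _read_geo(tif.pages[0])
    if stack.ndim == 2:
        stack = stack[None]
    if stack.shape[0] < len(roles):
        raise SceneIOError(
            f"band-count mismatch: raster has {stack.shape[0]} planes, "
            f"sidecar declares {len(roles)} ({roles})"
        )
    if "transform" in sidecar:
        transform = GridTransform(*sidecar["transform"])
    bands = {role: stack[i].astype(np.int32) for i, role in enumerate(roles)}
    return Scene(
        bands=bands,
        meta=meta,
        transform=transform,
        crs_id=sidecar.get("crs_id", ""),
        nodata=sidecar.get("nodata"),
    )


# ---------------------------------------------------------------------------
# AOI masking


def load_aoi(path) -> BaseGeometry:
    """Load the first polygon from a GeoJSON document."""
    doc = json.loads(Path(path).read_text())
    if doc.get("type") == "FeatureCollection":
        geoms = [shape(f["geometry"]) for f in doc["features"]]
        return shapely.union_all(geoms)
    if doc.get("type") == "Feature":
        return shape(doc["geometry"])
    return shape(doc)


def _footprint(scene: Scene) -> BaseGeometry:
    rows, cols = scene.shape
    x0, y0 = scene.transform.xy(0, 0, offset="corner")
    x1, y1 = scene.transform.xy(rows, cols, offset="corner")
    return box(min(x0, x1), min(y0, y1), max(x0, x1), max(y0, y1))


def apply_aoi_mask(scene: Scene, polygon: BaseGeometry) -> Scene:
    """Invalidate every band at pixels whose centers fall outside ``polygon``.

    The polygon is expressed in the scene CRS. Pixels inside are untouched,
    so the operation is idempotent. Raises if the polygon does not overlap
    the scene footprint (including degenerate zero-area polygons).
    """
    inter = polygon.intersection(_footprint(scene))
    if inter.is_empty or inter.area == 0:
        raise ValueError("AOI polygon does not intersect the scene footprint")
    rows, cols = scene.shape
    rr, cc = np.meshgrid(np.arange(rows), np.arange(cols), indexing="ij")
    x, y = scene.transform.xy(rr, cc)
    inside = shapely.contains_xy(polygon, x.ravel(), y.ravel()).reshape(rows, cols)

    nodata = scene.nodata if scene.nodata is not None else DEFAULT_NODATA
    bands = {}
    for role, grid in scene.bands.items():
        out = grid.astype(np.int32, copy=True)
        out[~inside] = nodata
        bands[role] = out
    return replace(scene, bands=bands, nodata=nodata)
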