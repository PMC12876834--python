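"""Annotation reading, physical-scale normalisation and tile extraction.

Histology scanners digitise at different spacings (0.2208-0.2506 um/px
in the cohorts this pipeline targets); all learning happens on 512x512
tiles resampled to a common 0.5 um/px. Regions come in as QuPath-style
GeoJSON polygons; tiles are laid on a grid over each region's bounding
box and kept when their center falls inside the polygon. Coordinates
are 0-based, y-down, with half-open tile windows [x, x+T) x [y, y+T).
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
from shapely.geometry import MultiPolygon, Point, Polygon, box, shape
from shapely.validation import make_valid
from skimage import draw as _draw
from skimage.transform import resize

log = logging.getLogger(__name__)

__all__ = [
    "RegionAnnotation",
    "TilingConfig",
    "Tile",
    "read_annotations",
    "write_annotations",
    "rescale_to_mpp",
    "extract_tiles",
    "label_tiles",
    "make_region_templates",
    "rasterize_region",
]


@dataclass
class RegionAnnotation:
    """One annotated polygon in pixel coordinates (0-based, y-down)."""

    polygon: list[tuple[float, float]]
    class_name: str
    case_id: str = ""
    slide_id: str = ""
    region_id: str = ""

    def shapely(self) -> Polygon:
        p = Polygon(self.polygon)
        if not p.is_valid:
            p = make_valid(p)
            if isinstance(p, MultiPolygon):  # keep the dominant part
                p = max(p.geoms, key=lambda g: g.area)
        return p


@dataclass
class TilingConfig:
    tile_px: int = 512
    target_mpp: float = 0.5
    stride_px: int = 512
    pad_value: tuple[int, int, int] = (255, 255, 255)

    def __post_init__(self) -> None:
        if self.tile_px <= 0 or self.stride_px <= 0:
            raise ValueError("tile_px and stride_px must be positive")
        if self.target_mpp <= 0:
            raise ValueError("target_mpp must be positive")


@dataclass
class Tile:
    pixels: np.ndarray  # uint8, tile_px x tile_px x 3
    origin: tuple[int, int]  # (x, y) in target-mpp pixel space
    region_id: str
    label: str = "unknown"  # "foamy" | "not_foamy" | "unknown"
    case_id: str = ""
    slide_id: str = ""
    masks: dict[str, np.ndarray] = field(default_factory=dict)


# ---------------------------------------------------------------------------
# GeoJSON interchange


def read_annotations(path: str | Path) -> list[RegionAnnotation]:
    """Parse a QuPath-style GeoJSON FeatureCollection.

    Multi-polygons are split into one region per part; a feature without
    a classification gets class_name "unclassified" with a warning.
    """
    path = Path(path)
    try:
        doc = json.loads(path.read_text())
    except json.JSONDecodeError as e:
        raise ValueError(f"malformed GeoJSON in {path}: {e}") from e
    regions: list[RegionAnnotation] = []
    for i, feat in enumerate(doc.get("features", [])):
        geom = feat.get("geometry")
        if geom is None:
            log.warning("%s: feature %d has no geometry, skipped", path, i)
            continue
        props = feat.get("properties", {}) or {}
        cls = props.get("classification") or {}
        name = cls.get("name")
        if not name:
            name = "unclassified"
            log.warning("%s: feature %d has no classification", path, i)
        g = shape(geom)
        parts = list(g.geoms) if isinstance(g, MultiPolygon) else [g]
        for j, part in enumerate(parts):
            if part.is_empty or not isinstance(part, Polygon):
                continue
            rid = props.get("region_id", f"{path.stem}-f{i}")
            if len(parts) > 1:
                rid = f"{rid}-p{j}"
            regions.append(RegionAnnotation(
                polygon=[(float(x), float(y)) for x, y in part.exterior.coords],
                class_name=str(name).lower(),
                case_id=str(props.get("case_id", "")),
                slide_id=str(props.get("slide_id", "")),
                region_id=rid,
            ))
    return regions


def write_annotations(
    regions: list[RegionAnnotation], path: str | Path
) -> Path:
    """Serialize regions as a GeoJSON FeatureCollection (QuPath dialect)."""
    features = []
    for r in regions:
        coords = [[float(x), float(y)] for x, y in r.polygon]
        if coords and coords[0] != coords[-1]:
            coords.append(coords[0])
        features.append({
            "type": "Feature",
            "geometry": {"type": "Polygon", "coordinates": [coords]},
            "properties": {
                "objectType": "annotation",
                "classification": {"name": r.class_name, "color": [200, 0, 0]},
                "case_id": r.case_id,
                "slide_id": r.slide_id,
                "region_id": r.region_id,
            },
        })
    path = Path(path)
    path.write_text(json.dumps(
        {"type": "FeatureCollection", "features": features}
    ))
    return path


# ---------------------------------------------------------------------------
# rescaling


def rescale_to_mpp(
    image: np.ndarray, src_mpp: float, dst_mpp: float
) -> np.ndarray:
    """Resample to a new pixel spacing.

    Output size is round(dim * src/dst); bilinear for intensity images,
    nearest-neighbour for boolean masks (they must stay binary).
    """
    if src_mpp <= 0 or dst_mpp <= 0:
        raise ValueError("pixel spacings must be positive")
    if src_mpp == dst_mpp:
        return image
    scale = src_mpp / dst_mpp
    out_shape = (
        max(1, round(image.shape[0] * scale)),
        max(1, round(image.shape[1] * scale)),
    )
    if image.dtype == bool:
        out = resize(image, out_shape, order=0, anti_aliasing=False,
                     preserve_range=True)
        return out.astype(bool)
    out = resize(image, out_shape, order=1, anti_aliasing=scale < 1,
                 preserve_range=True)
    return out.astype(image.dtype)


def _crop_padded(
    image: np.ndarray, x: int, y: int, size: int, pad_value
) -> np.ndarray:
    """Half-open window [x, x+size) x [y, y+size), padded where it
    extends beyond the image."""
    if image.ndim == 3:
        out = np.empty((size, size, image.shape[2]), dtype=image.dtype)
        out[:] = np.asarray(pad_value, dtype=image.dtype)
    else:
        out = np.zeros((size, size), dtype=image.dtype)
    x0, y0 = max(x, 0), max(y, 0)
    x1, y1 = min(x + size, image.shape[1]), min(y + size, image.shape[0])
    if x1 > x0 and y1 > y0:
        out[y0 - y : y1 - y, x0 - x : x1 - x] = image[y0:y1, x0:x1]
    return out


# ---------------------------------------------------------------------------
# tiling


def extract_tiles(
    image: np.ndarray,
    region: RegionAnnotation,
    cfg: TilingConfig,
    src_mpp: float,
    aligned_masks: dict[str, np.ndarray] | None = None,
) -> list[Tile]:
    """Extract label-ready tiles for one region.

    The image (and any aligned ground-truth masks) is resampled to
    ``cfg.target_mpp``; the region polygon is scaled by the same factor.
    Tiles are gridded over the polygon's bounding box from its top-left
    corner with ``stride_px`` and kept when the tile center lies inside
    the polygon; a region smaller than one tile yields exactly one tile
    centered on its bounding box. Tiles are ordered by (origin_y,
    origin_x) and padded with ``pad_value`` where they leave the image.
    """
    if src_mpp <= 0:
        raise ValueError("src_mpp must be positive")
    scale = src_mpp / cfg.target_mpp
    h, w = image.shape[:2]
    poly = region.shapely()
    img_box = box(0, 0, w, h)
    if not poly.intersects(img_box):
        log.warning("region %s lies outside the image", region.region_id)
        return []

    scaled = rescale_to_mpp(image, src_mpp, cfg.target_mpp)
    masks = {
        k: rescale_to_mpp(m.astype(bool), src_mpp, cfg.target_mpp)
        for k, m in (aligned_masks or {}).items()
    }
    from shapely.affinity import scale as shp_scale

    poly_t = shp_scale(poly, xfact=scale, yfact=scale, origin=(0, 0))
    minx, miny, maxx, maxy = poly_t.bounds
    T, S = cfg.tile_px, cfg.stride_px

    origins: list[tuple[int, int]]
    if (maxx - minx) <= T and (maxy - miny) <= T:
        cx, cy = (minx + maxx) / 2, (miny + maxy) / 2
        origins = [(int(round(cx - T / 2)), int(round(cy - T / 2)))]
    else:
        x0, y0 = int(np.floor(minx)), int(np.floor(miny))
        origins = [
            (x, y)
            for y in range(y0, int(np.ceil(maxy)), S)
            for x in range(x0, int(np.ceil(maxx)), S)
            if poly_t.covers(Point(x + T / 2, y + T / 2))
        ]
    origins.sort(key=lambda o: (o[1], o[0]))

    tiles = []
    for x, y in origins:
        tiles.append(Tile(
            pixels=_crop_padded(scaled, x, y, T, cfg.pad_value),
            origin=(x, y),
            region_id=region.region_id,
            case_id=region.case_id,
            slide_id=region.slide_id,
            masks={k: _crop_padded(m, x, y, T, 0) for k, m in masks.items()},
        ))
    return tiles


def label_tiles(
    tiles: list[Tile],
    podocyte_regions: list[RegionAnnotation],
    tile_px: int = 512,
) -> list[Tile]:
    """Assign foamy/not_foamy by polygon overlap.

    A tile is foamy iff its square window intersects any foamy-podocyte
    polygon with positive area; coordinates must share the tiles'
    target-mpp space. Labels are set in place and the list returned.
    """
    polys = [r.shapely() for r in podocyte_regions]
    for t in tiles:
        x, y = t.origin
        window = box(x, y, x + tile_px, y + tile_px)
        t.label = "foamy" if any(
            window.intersection(p).area > 0 for p in polys
        ) else "not_foamy"
    return tiles


def make_region_templates(
    glomerulus_centers_um: list[tuple[float, float]],
    side_um: float,
    mpp: float,
    class_name: str = "glomerulus",
) -> list[RegionAnnotation]:
    """Square region templates of physical side ``side_um`` centered on
    the given (x, y) positions in microns, emitted in pixel coordinates
    at spacing ``mpp`` (ready to be adjusted around glomeruli)."""
    if side_um <= 0:
        raise ValueError("side_um must be positive")
    half = side_um / 2
    regions = []
    for i, (cx, cy) in enumerate(glomerulus_centers_um):
        verts = [
            ((cx - half) / mpp, (cy - half) / mpp),
            ((cx + half) / mpp, (cy - half) / mpp),
            ((cx + half) / mpp, (cy + half) / mpp),
            ((cx - half) / mpp, (cy + half) / mpp),
        ]
        regions.append(RegionAnnotation(
            polygon=verts, class_name=class_name,
            region_id=f"template-{i}",
        ))
    return regions


def rasterize_region(
    region: RegionAnnotation, shape: tuple[int, int]
) -> np.ndarray:
    """Rasterize a region polygon into a boolean mask of ``shape``."""
    xs = np.array([v[0] for v in region.polygon])
    ys = np.array([v[1] for v in region.polygon])
    rr, cc = _draw.polygon(ys, xs, shape=shape)
    mask = np.zeros(shape, dtype=bool)
    mask[rr, cc] = True
    return mask
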