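"""Annotation interchange and scale-normalised tile extraction.

Writes a case's masks as QuPath-style GeoJSON, reads them back, and
extracts 512x512 tiles at 0.5 um/px from the source-resolution image
(0.2208 um/px here) — the normalisation every scanner's output goes
through before any model sees it.
"""

import tempfile
from pathlib import Path

import zebra
from zebra import tiling

spec = zebra.SyntheticCohortSpec(n_cases_pos=1, n_cases_neg=0,
                                 glomeruli_per_case=(2, 2), seed=1)
cases, _ = zebra.generate_cohort(spec)
case = cases[0]

with tempfile.TemporaryDirectory() as tmp:
    paths = zebra.export_annotations(case, tmp)
    regions = zebra.read_annotations(paths[0])
print(f"round-tripped {len(regions)} annotation features; classes: "
      f"{sorted({r.class_name for r in regions})}")

g = case.glomeruli[0]
h, w = g.image.shape[:2]
region = tiling.RegionAnnotation(
    polygon=[(0, 0), (w, 0), (w, h), (0, h)], class_name="glomerulus",
    case_id=g.case_id, slide_id=g.slide_id, region_id=g.glomerulus_id,
)
tiles = zebra.extract_tiles(g.image, region, zebra.TilingConfig(),
                            src_mpp=g.mpp)
print(f"source image {w}x{h} px at {g.mpp} um/px -> "
      f"{len(tiles)} tile(s) of {tiles[0].pixels.shape[0]} px at 0.5 um/px")
# the tile grid covers the region's bounding box; each kept tile's
# center lies inside the region polygon.
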