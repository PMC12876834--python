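"""Synthetic glomerular histology with ground truth.

Generates toy H&E- or PAS-like images of single glomeruli: a blobby,
darker-stained tuft on a pale background, with optional clusters of
pale, rimmed discs standing in for foamy (vacuolated) podocytes. Each
image comes with exact ground-truth masks and the achieved lesion area
fraction, organised into cases (patients) so that case-level
cross-validation, scoring and statistics can all be tested end to end.

Images are emitted at a *source* spacing (0.2208 / 0.2506 / 0.25 um/px,
the scanner resolutions the real cohort mixes) so the physical-scale
normalisation step downstream is always exercised. Nothing here claims
biological realism: lesions are area-controlled texture cues, not
podocytes.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass
from pathlib import Path

import imageio.v3 as iio
import numpy as np
import pandas as pd
from scipy import ndimage
from skimage import draw, measure

log = logging.getLogger(__name__)

__all__ = [
    "SyntheticCohortSpec",
    "SyntheticGlomerulus",
    "SyntheticCase",
    "generate_glomerulus",
    "generate_cohort",
    "export_annotations",
    "write_cohort",
    "mask_to_polygons",
    "summarize_manifest",
]

VALID_MPP = (0.2208, 0.2506, 0.25)

# 8-bit RGB palettes; lesions are pale with a faint blue-gray cast and a
# darker rim so a trainable segmenter has a colour + context cue.
_PALETTES = {
    "HE": {"background": (244, 233, 238), "tuft": (198, 130, 155),
           "lesion": (228, 225, 236), "rim": (150, 110, 140)},
    "PAS": {"background": (246, 235, 242), "tuft": (185, 95, 150),
            "lesion": (230, 226, 238), "rim": (140, 70, 120)},
}

_FRACTION_TOL = 0.01  # achieved-vs-target area fraction tolerance
_MPVS_SIGMA = 0.15  # noise on the synthetic manual score (ISGFN 0-3)


@dataclass
class SyntheticCohortSpec:
    """Study conditions for one synthetic cohort.

    ``fraction_positive_glomeruli`` defaults to 0.74: in the real FN
    cohort 74% of FN glomeruli carried vacuolized podocytes.
    ``target_fraction_range`` is the per-glomerulus lesion burden range
    for lesioned glomeruli of positive cases (a free parameter of the
    generator, not a biological claim).
    """

    n_cases_pos: int = 10
    n_cases_neg: int = 10
    glomeruli_per_case: tuple[int, int] = (3, 5)
    target_fraction_range: tuple[float, float] = (0.10, 0.30)
    fraction_positive_glomeruli: float = 0.74
    stain: str = "HE"
    source_mpp: float = 0.2208
    noise_level: float = 4.0  # 8-bit gray-level sd of pixel noise
    seed: int = 0
    canvas_um: float = 256.0  # physical side of each glomerulus crop

    def __post_init__(self) -> None:
        lo, hi = self.target_fraction_range
        if not (0 <= lo <= hi):
            raise ValueError("target_fraction_range must satisfy 0 <= lo <= hi")
        if hi > 0.5:
            raise ValueError("target fractions above 0.5 are rejected")
        if self.n_cases_pos < 0 or self.n_cases_neg < 0:
            raise ValueError("case counts must be >= 0")
        if self.glomeruli_per_case[0] < 1:
            raise ValueError("glomeruli_per_case must be >= 1")
        if not 0 <= self.fraction_positive_glomeruli <= 1:
            raise ValueError("fraction_positive_glomeruli must be in [0,1]")
        if self.stain not in _PALETTES:
            raise ValueError(f"stain must be one of {sorted(_PALETTES)}")
        if self.source_mpp <= 0:
            raise ValueError("source_mpp must be positive")
        if self.noise_level < 0:
            raise ValueError("noise_level must be >= 0")


@dataclass
class SyntheticGlomerulus:
    image: np.ndarray  # uint8 RGB, HxWx3, at mpp
    glomerulus_mask: np.ndarray  # bool
    podocyte_mask: np.ndarray  # bool, subset of glomerulus_mask
    true_fraction: float
    label: str  # "foamy" | "not_foamy"
    case_id: str
    slide_id: str
    glomerulus_id: str
    mpp: float


@dataclass
class SyntheticCase:
    case_id: str
    disease: str  # "FN" | "control"
    glomeruli: list[SyntheticGlomerulus]
    synthetic_mpvs: float
    sex: str = "F"
    stain: str = "HE"


# ---------------------------------------------------------------------------
# single glomerulus


def _tuft_mask(px: int, rng: np.random.Generator) -> np.ndarray:
    """Blobby elliptical tuft: radius modulated by low-order harmonics."""
    cy, cx = px / 2 + rng.normal(0, px * 0.02, size=2)
    r0 = px * rng.uniform(0.33, 0.40)
    amps = rng.normal(0, 0.035, size=4)
    phases = rng.uniform(0, 2 * np.pi, size=4)
    yy, xx = np.mgrid[0:px, 0:px]
    theta = np.arctan2(yy - cy, xx - cx)
    rr = np.hypot(yy - cy, xx - cx)
    boundary = r0 * (
        1.0 + sum(a * np.cos((k + 2) * theta + p)
                  for k, (a, p) in enumerate(zip(amps, phases)))
    )
    return rr <= boundary


def _place_lesions(
    glom: np.ndarray,
    target_fraction: float,
    mpp: float,
    rng: np.random.Generator,
) -> np.ndarray:
    """Greedy placement of pale-disc clusters until the podocyte mask
    area fraction is within +-0.01 of ``target_fraction``.

    Each disc is clamped so a single placement can never overshoot past
    target + tol, which makes the loop converge deterministically.
    """
    pod = np.zeros_like(glom)
    if target_fraction <= 0:
        return pod
    tgA = int(glom.sum())
    target_px = target_fraction * tgA
    tol_px = _FRACTION_TOL * tgA
    count = 0
    ys, xs = np.nonzero(glom)
    r_lo, r_hi = 3.5 / mpp, 8.0 / mpp  # lesion disc radii of ~3.5-8 um

    iters = 0
    while count < target_px - tol_px and iters < 2000:
        iters += 1
        j = rng.integers(len(ys))
        c0 = np.array([ys[j], xs[j]], dtype=float)
        n_discs = rng.integers(2, 11)
        for _ in range(n_discs):
            remaining = target_px + tol_px - count
            if remaining <= 0:
                break
            r = rng.uniform(r_lo, r_hi)
            r = min(r, np.sqrt(remaining / np.pi))
            if r < 1.0:
                break
            center = c0 + rng.normal(0, r * 0.9, size=2)
            rr, cc = draw.disk(center, r, shape=glom.shape)
            keep = glom[rr, cc] & ~pod[rr, cc]
            if keep.sum() > remaining:
                continue
            pod[rr[keep], cc[keep]] = True
            count += int(keep.sum())
    return pod


def generate_glomerulus(
    spec: SyntheticCohortSpec,
    target_fraction: float,
    rng: np.random.Generator,
    case_id: str = "case",
    slide_id: str = "slide",
    glomerulus_id: str = "g0",
) -> SyntheticGlomerulus:
    """Render one glomerulus image with ground-truth masks.

    ``target_fraction`` is the desired foamy area / glomerular area; the
    achieved fraction is within +-0.01 (exactly 0 when the target is 0).
    """
    if not 0 <= target_fraction <= 0.5:
        raise ValueError("target_fraction must be in [0, 0.5]")
    px = int(round(spec.canvas_um / spec.source_mpp))
    pal = _PALETTES[spec.stain]

    glom = _tuft_mask(px, rng)
    pod = _place_lesions(glom, target_fraction, spec.source_mpp, rng)

    img = np.empty((px, px, 3), dtype=np.float32)
    img[:] = pal["background"]
    img[glom] = pal["tuft"]
    # fine stain texture inside the tuft
    tex = rng.normal(0, 1, size=(px, px)).astype(np.float32)
    tex = ndimage.gaussian_filter(tex, 3.0 / spec.source_mpp * 0.25)
    img[glom] += (tex[glom, None] * 25.0)
    img[pod] = pal["lesion"]
    rim_px = max(1, int(round(1.0 / spec.source_mpp)))
    rim = pod & ~ndimage.binary_erosion(pod, iterations=rim_px)
    img[rim] = pal["rim"]
    if spec.noise_level > 0:
        img += rng.normal(0, spec.noise_level, size=img.shape)
    img = np.clip(img, 0, 255).astype(np.uint8)

    tgA = int(glom.sum())
    frac = float(pod.sum()) / tgA if tgA else 0.0
    return SyntheticGlomerulus(
        image=img,
        glomerulus_mask=glom,
        podocyte_mask=pod,
        true_fraction=frac,
        label="foamy" if pod.any() else "not_foamy",
        case_id=case_id,
        slide_id=slide_id,
        glomerulus_id=glomerulus_id,
        mpp=spec.source_mpp,
    )


# ---------------------------------------------------------------------------
# cohort


def _case_plan(spec: SyntheticCohortSpec, rng: np.random.Generator):
    """Draw the per-case layout (ids, sexes, per-glomerulus fractions)."""
    plan = []
    lo, hi = spec.glomeruli_per_case
    for i in range(spec.n_cases_pos):
        n_g = int(rng.integers(lo, hi + 1))
        lesioned = rng.random(n_g) < spec.fraction_positive_glomeruli
        if spec.fraction_positive_glomeruli > 0 and not lesioned.any():
            # a sampled FN case always shows at least one affected
            # glomerulus; the per-glomerulus share stays ~the nominal one
            lesioned[rng.integers(n_g)] = True
        fracs = np.where(
            lesioned, rng.uniform(*spec.target_fraction_range, size=n_g), 0.0
        )
        plan.append((f"FN{i + 1:03d}", "FN", fracs,
                     "F" if rng.random() < 0.5 else "M"))
    for i in range(spec.n_cases_neg):
        n_g = int(rng.integers(lo, hi + 1))
        plan.append((f"C{i + 1:03d}", "control", np.zeros(n_g),
                     "F" if rng.random() < 0.5 else "M"))
    return plan


def iter_cases(spec: SyntheticCohortSpec):
    """Yield cases one at a time (memory-friendly route used by the
    pipeline; ``generate_cohort`` materialises the full list)."""
    rng = np.random.default_rng(spec.seed)
    plan = _case_plan(spec, rng)
    max_frac = max(spec.target_fraction_range[1], 1e-9)
    for case_id, disease, fracs, sex in plan:
        slide_id = f"{case_id}-S1"
        gloms = [
            generate_glomerulus(
                spec, float(f), rng, case_id=case_id, slide_id=slide_id,
                glomerulus_id=f"{case_id}-g{j + 1:02d}",
            )
            for j, f in enumerate(fracs)
        ]
        if disease == "FN":
            mean_frac = float(np.mean([g.true_fraction for g in gloms]))
            mpvs = float(np.clip(
                3.0 * mean_frac / max_frac + rng.normal(0, _MPVS_SIGMA), 0, 3
            ))
        else:
            mpvs = 0.0
        yield SyntheticCase(
            case_id=case_id, disease=disease, glomeruli=gloms,
            synthetic_mpvs=mpvs, sex=sex, stain=spec.stain,
        )


def generate_cohort(
    spec: SyntheticCohortSpec,
) -> tuple[list[SyntheticCase], pd.DataFrame]:
    """Generate the full cohort and its manifest table."""
    cases = list(iter_cases(spec))
    return cases, manifest_table(cases)


def manifest_table(cases: list[SyntheticCase]) -> pd.DataFrame:
    rows = []
    for case in cases:
        for g in case.glomeruli:
            rows.append({
                "case_id": g.case_id,
                "slide_id": g.slide_id,
                "glomerulus_id": g.glomerulus_id,
                "disease": case.disease,
                "label": g.label,
                "true_fraction": g.true_fraction,
                "mpp": g.mpp,
                "stain": case.stain,
            })
    return pd.DataFrame(rows)


def summarize_manifest(manifest: pd.DataFrame) -> dict:
    """Cohort bookkeeping: glomerulus counts by disease and label.

    ``positive_share_fn`` is the share of FN-case glomeruli bearing
    lesions; ``n_negative_total`` pools lesion-free FN glomeruli with
    all control glomeruli.
    """
    fn = manifest[manifest["disease"] == "FN"]
    n_fn = len(fn)
    n_fn_pos = int((fn["label"] == "foamy").sum())
    n_control = int((manifest["disease"] == "control").sum())
    return {
        "n_glomeruli_fn": n_fn,
        "n_glomeruli_fn_positive": n_fn_pos,
        "n_glomeruli_control": n_control,
        "positive_share_fn": n_fn_pos / n_fn if n_fn else float("nan"),
        "n_negative_total": (n_fn - n_fn_pos) + n_control,
    }


# ---------------------------------------------------------------------------
# annotation export (QuPath GeoJSON dialect)


def mask_to_polygons(mask: np.ndarray) -> list[np.ndarray]:
    """Polygonize a binary mask into one closed (x, y) vertex ring per
    connected component, traced at the half-level between 0 and 1."""
    if not mask.any():
        return []
    polys = []
    labeled, n = ndimage.label(mask)
    for i in range(1, n + 1):
        comp = labeled == i
        padded = np.pad(comp.astype(np.float32), 1)
        for contour in measure.find_contours(padded, 0.5):
            # (row, col) -> (x, y), undo the 1-px pad
            xy = np.stack([contour[:, 1] - 1, contour[:, 0] - 1], axis=1)
            if len(xy) >= 4:  # closed ring needs >= 3 distinct vertices
                polys.append(xy)
    return polys


def _feature(xy: np.ndarray, name: str, props: dict) -> dict:
    coords = [[float(x), float(y)] for x, y in xy]
    if coords[0] != coords[-1]:
        coords.append(coords[0])
    return {
        "type": "Feature",
        "geometry": {"type": "Polygon", "coordinates": [coords]},
        "properties": {
            "objectType": "annotation",
            "classification": {"name": name, "color": [200, 0, 0]},
            **props,
        },
    }


def export_annotations(case: SyntheticCase, outdir: str | Path) -> list[Path]:
    """Write one GeoJSON FeatureCollection per glomerulus image.

    Each file carries the glomerulus outline plus one feature per foamy
    lesion component, in that image's own pixel frame — the per-image
    convention QuPath uses for annotation interchange.
    """
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    paths = []
    for g in case.glomeruli:
        if not g.glomerulus_mask.any():
            raise ValueError(f"degenerate glomerulus mask in {g.glomerulus_id}")
        props = {"case_id": g.case_id, "slide_id": g.slide_id,
                 "region_id": g.glomerulus_id, "mpp": g.mpp}
        features = [
            _feature(xy, "glomerulus", props)
            for xy in mask_to_polygons(g.glomerulus_mask)
        ]
        features += [
            _feature(xy, "foamy_podocyte", props)
            for xy in mask_to_polygons(g.podocyte_mask)
        ]
        path = outdir / f"{g.glomerulus_id}.geojson"
        path.write_text(json.dumps(
            {"type": "FeatureCollection", "features": features}
        ))
        paths.append(path)
    return paths


def write_cohort(
    cases: list[SyntheticCase], outdir: str | Path
) -> pd.DataFrame:
    """Write images (PNG), masks (PNG 0/255), GeoJSON annotations and
    the CSV manifest; returns the manifest."""
    outdir = Path(outdir)
    (outdir / "images").mkdir(parents=True, exist_ok=True)
    (outdir / "masks").mkdir(exist_ok=True)
    for case in cases:
        export_annotations(case, outdir / "annotations")
        for g in case.glomeruli:
            iio.imwrite(outdir / "images" / f"{g.glomerulus_id}.png", g.image)
            iio.imwrite(
                outdir / "masks" / f"{g.glomerulus_id}_glomerulus.png",
                (g.glomerulus_mask * 255).astype(np.uint8),
            )
            iio.imwrite(
                outdir / "masks" / f"{g.glomerulus_id}_podocyte.png",
                (g.podocyte_mask * 255).astype(np.uint8),
            )
    manifest = manifest_table(cases)
    manifest.to_csv(outdir / "manifest.csv", index=False)
    records = pd.DataFrame([
        {"case_id": c.case_id, "disease": c.disease,
         "mpvs": c.synthetic_mpvs, "sex": c.sex, "stain": c.stain}
        for c in cases
    ])
    records.to_csv(outdir / "cases.csv", index=False)
    return manifest
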