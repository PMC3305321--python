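"""Seeded generator of adjacent-section slide pairs with known ground truth.

Each synthetic case emulates one digitized prostatectomy block: an H&E-like
reference image (pink/purple textured tissue blob on a white background),
one IHC image per stain (hematoxylin-like blue-gray tissue with brown DAB
pixels planted at region-specific positive fractions), pathologist-style
annotation polygons, five landmark pairs on the tissue boundary, and the
exact dihedral+rigid transform each IHC image was moved by.

Brown pixels are planted on a deterministic 16x16 Bayer ordered-dither
pattern rather than i.i.d. sampling, so the realized positive fraction of
any region is known exactly to within one dither quantum (1/256); this
turns positive-pixel-count checks into near-exact assertions.  The native
IHC rasters are produced from the reference-frame stain content by
nearest-neighbour warping, which preserves the pure stain colors (no
interpolated color mixtures), and Gaussian read noise is added last.
Landmarks are emitted in both frames through the exact ground-truth
transform, so downstream landmark errors isolate registration error only.
"""

from __future__ import annotations

import copy
import json
import math
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Sequence

import numpy as np
from scipy import ndimage

from .geometry import (
    DihedralOp,
    Polygon,
    RigidTransform,
    apply_dihedral_to_image,
    dihedral_inverse,
    invert,
    points_in_polygon,
)
from .slide_io import AnnotationSet, SlideImage, write_annotations, write_slide
from .validation import LandmarkPair, write_landmarks

__all__ = [
    "RegionSpec",
    "StainSpec",
    "SyntheticCase",
    "SyntheticSpec",
    "bayer_matrix",
    "default_spec",
    "generate_case",
    "generate_cohort",
    "plant_brown_mask",
    "uniform_stain_image",
    "write_case",
]


class GenerationError(RuntimeError):
    """A synthetic spec that cannot be realized (e.g. region outside tissue)."""


# stain colors by overall DAB intensity class (mimicking a low / medium /
# high intensity antibody panel) and the hematoxylin-like counterstain
_DAB_RGB = {
    "high": (101, 58, 32),
    "medium": (135, 85, 48),
    "low": (168, 118, 76),
}
_COUNTERSTAIN_RGB = (197, 200, 219)
_EOSIN_RGB = (231, 170, 192)
_NUCLEI_HE_RGB = (118, 70, 150)
_NUCLEI_IHC_RGB = (150, 155, 195)


@dataclass
class RegionSpec:
    """One annotated disease region: label, placement, and disease class."""

    label: str
    center: tuple[float, float]  # fraction of image size
    radius: float  # fraction of image size
    aggressive: bool = False
    n_vertices: int = 12


@dataclass
class StainSpec:
    """One IHC stain: sign, intensity class, planted fractions, ground truth move."""

    name: str
    sign: int
    intensity_class: str  # low | medium | high
    fractions: dict[str, float]  # region label -> planted DAB-positive fraction
    background_fraction: float  # planted fraction in tissue outside regions
    pre: DihedralOp = DihedralOp.IDENTITY
    theta: float = 0.0
    translation: tuple[float, float] = (0.0, 0.0)

    def __post_init__(self):
        for label, f in {**self.fractions, "background": self.background_fraction}.items():
            if not (0.0 <= f <= 1.0):
                raise ValueError(f"{self.name}: fraction for {label!r} outside [0, 1]")


@dataclass
class SyntheticSpec:
    """Full description of one synthetic case; the defaults are the study conditions."""

    image_size: tuple[int, int] = (1024, 1024)  # (w, h)
    microns_per_pixel: float = 2.5
    tissue_center: tuple[float, float] = (0.45, 0.52)  # fraction of (w, h)
    tissue_radius: float = 0.34  # fraction of min(w, h)
    boundary_noise: float = 0.06  # harmonic amplitude of the lobe boundary
    lobe2_center: tuple[float, float] = (0.72, 0.30)
    lobe2_radius: float = 0.12
    regions: list[RegionSpec] = field(default_factory=lambda: [
        RegionSpec("3+3", center=(-0.13, 0.06), radius=0.15, aggressive=False),
        RegionSpec("4+3", center=(0.13, -0.07), radius=0.15, aggressive=True),
    ])
    stains: list[StainSpec] = field(default_factory=list)
    noise_sigma: float = 2.0
    seed: int = 0


def default_spec(seed: int = 0) -> SyntheticSpec:
    """Three-stain case: high-intensity down-regulated marker plus medium and
    low intensity up-regulated markers, with a 3x / (1/3)x planted contrast
    between the aggressive and non-aggressive regions."""
    stains = [
        StainSpec("ACPP", sign=-1, intensity_class="high",
                  fractions={"3+3": 0.45, "4+3": 0.15}, background_fraction=0.30),
        StainSpec("CD34", sign=+1, intensity_class="medium",
                  fractions={"3+3": 0.04, "4+3": 0.12}, background_fraction=0.06),
        StainSpec("MKI67", sign=+1, intensity_class="low",
                  fractions={"3+3": 0.015, "4+3": 0.045}, background_fraction=0.02),
    ]
    return SyntheticSpec(stains=stains, seed=seed)


@dataclass
class SyntheticCase:
    reference: SlideImage
    ihc_images: list[SlideImage]
    annotations: AnnotationSet
    transforms: dict[str, RigidTransform]  # ground truth, native -> reference
    landmarks: list[LandmarkPair]
    spec: SyntheticSpec


def bayer_matrix(n: int = 16) -> np.ndarray:
    """Ordered-dither index matrix with values 0..n*n-1 (n a power of two)."""
    m = np.array([[0]])
    while m.shape[0] < n:
        k = m.shape[0]
        m = np.block([[4 * m + 0, 4 * m + 2], [4 * m + 3, 4 * m + 1]])
    return m


_BAYER = bayer_matrix(16)


def plant_brown_mask(shape: tuple[int, int], fraction: float) -> np.ndarray:
    """Deterministic pixel mask with a realized density of ``fraction``
    (exact to one 1/256 dither quantum on any 16x16-aligned area)."""
    h, w = shape
    tiled = np.tile(_BAYER, (h // 16 + 1, w // 16 + 1))[:h, :w]
    return tiled / 256.0 < fraction


def _polygon_mask(poly: Polygon, shape: tuple[int, int]) -> np.ndarray:
    """Rasterize by the package's own pixel-center-in-polygon rule."""
    h, w = shape
    x0, y0, x1, y1 = poly.bounds()
    xs = np.arange(max(0, int(np.floor(x0))), min(w, int(np.ceil(x1)) + 1))
    ys = np.arange(max(0, int(np.floor(y0))), min(h, int(np.ceil(y1)) + 1))
    out = np.zeros(shape, dtype=bool)
    if len(xs) == 0 or len(ys) == 0:
        return out
    gx, gy = np.meshgrid(xs, ys)
    pts = np.column_stack([gx.ravel(), gy.ravel()])
    member = points_in_polygon(pts, poly.vertices)
    out[gy.ravel()[member], gx.ravel()[member]] = True
    return out


def _tissue_geometry(spec: SyntheticSpec, rng: np.random.Generator):
    """Chiral two-lobe tissue mask plus the main-lobe boundary radius function."""
    w, h = spec.image_size
    n = min(w, h)
    cx, cy = spec.tissue_center[0] * w, spec.tissue_center[1] * h
    yy, xx = np.mgrid[0:h, 0:w]
    phi = np.arctan2(yy - cy, xx - cx)
    rr = np.sqrt(((xx - cx) / 1.12) ** 2 + (yy - cy) ** 2)
    amps = spec.boundary_noise * np.array([1.6, 1.1, 0.9])
    phases = rng.uniform(0, 2 * np.pi, 3)

    def radius(angle):
        out = spec.tissue_radius * n * np.ones_like(np.asarray(angle, dtype=float))
        for k, (a, p) in enumerate(zip(amps, phases), start=1):
            out = out * (1 + a * np.cos(k * np.asarray(angle) + p))
        return out

    mask = rr < radius(phi)
    # second, smaller lobe makes the outline chiral so the dihedral search is unambiguous
    l2x, l2y = spec.lobe2_center[0] * w, spec.lobe2_center[1] * h
    mask |= np.sqrt((xx - l2x) ** 2 + (yy - l2y) ** 2) < spec.lobe2_radius * n
    return mask, (cx, cy), radius


def _textures(spec: SyntheticSpec, rng: np.random.Generator):
    w, h = spec.image_size
    macro = ndimage.gaussian_filter(rng.normal(size=(h, w)), min(w, h) / 50.0)
    macro /= max(np.abs(macro).max(), 1e-9)
    fine = ndimage.gaussian_filter(rng.normal(size=(h, w)), 2.5)
    nuclei = fine > np.quantile(fine, 0.88)
    return macro, nuclei


def _region_polygon(region: RegionSpec, spec: SyntheticSpec, rng: np.random.Generator) -> Polygon:
    w, h = spec.image_size
    n = min(w, h)
    cx = (spec.tissue_center[0] + region.center[0]) * w
    cy = (spec.tissue_center[1] + region.center[1]) * h
    ang = np.linspace(0, 2 * np.pi, region.n_vertices, endpoint=False)
    rad = region.radius * n * rng.uniform(0.82, 1.0, region.n_vertices)
    verts = np.column_stack([cx + rad * np.cos(ang), cy + rad * np.sin(ang)])
    return Polygon(verts, label=region.label)


def generate_case(spec: SyntheticSpec | None = None) -> SyntheticCase:
    """Build one reference/IHC bundle with exact ground truth (deterministic per seed)."""
    spec = spec or default_spec()
    rng = np.random.default_rng(spec.seed)
    w, h = spec.image_size
    tissue, (cx, cy), radius_fn = _tissue_geometry(spec, rng)
    macro, nuclei = _textures(spec, rng)
    nuclei &= tissue

    # ---- reference (H&E-like) image
    ref_px = np.full((h, w, 3), 255.0)
    for ch, (base, amp) in enumerate(zip(_EOSIN_RGB, (26.0, 40.0, 24.0))):
        layer = base + amp * macro
        ref_px[..., ch] = np.where(tissue, layer, 255.0)
    for ch, v in enumerate(_NUCLEI_HE_RGB):
        ref_px[..., ch] = np.where(nuclei, v, ref_px[..., ch])
    reference = SlideImage(np.clip(ref_px, 0, 255).astype(np.uint8),
                           spec.microns_per_pixel, name="H&E")

    # ---- annotations
    polys = []
    for region in spec.regions:
        poly = _region_polygon(region, spec, rng)
        m = _polygon_mask(poly, (h, w))
        if not tissue[m].all():
            raise GenerationError(f"region {region.label!r} falls outside the tissue blob")
        polys.append(poly)
    annotations = AnnotationSet(
        layers=[(p.label, [p]) for p in polys], source_slide=reference.name
    )

    # ---- per-stain IHC images
    ihc_images: list[SlideImage] = []
    transforms: dict[str, RigidTransform] = {}
    landmarks: list[LandmarkPair] = []
    lm_angles = (np.arange(5) * 2 * np.pi / 5) + float(rng.uniform(0, 2 * np.pi))
    lm_ref = []
    for ang in lm_angles:
        # near-boundary anatomic feature; shrink inward until on tissue
        for shrink in np.arange(0.9, 0.4, -0.05):
            r = shrink * float(radius_fn(ang))
            p = (cx + 1.12 * r * math.cos(ang), cy + r * math.sin(ang))
            ix, iy = int(round(p[0])), int(round(p[1]))
            if 0 <= ix < w and 0 <= iy < h and tissue[iy, ix]:
                lm_ref.append(p)
                break
        else:  # pragma: no cover - defensive
            raise GenerationError("could not place a landmark on tissue")
    lm_ref = np.asarray(lm_ref)

    for stain in spec.stains:
        content = np.full((h, w, 3), 255.0)
        for ch, v in enumerate(_COUNTERSTAIN_RGB):
            content[..., ch] = np.where(tissue, v + 14.0 * macro, 255.0)
        for ch, v in enumerate(_NUCLEI_IHC_RGB):
            content[..., ch] = np.where(nuclei, v + 10.0 * macro, content[..., ch])
        # DAB planting: background level in tissue, region-specific level inside polygons
        brown = plant_brown_mask((h, w), stain.background_fraction) & tissue
        for region, poly in zip(spec.regions, polys):
            f = stain.fractions.get(region.label, stain.background_fraction)
            rmask = _polygon_mask(poly, (h, w))
            brown = np.where(rmask, plant_brown_mask((h, w), f), brown)
        dab = _DAB_RGB[stain.intensity_class]
        for ch in range(3):
            content[..., ch] = np.where(brown, dab[ch], content[..., ch])

        truth = RigidTransform(
            pre=stain.pre,
            theta=stain.theta,
            tx=stain.translation[0],
            ty=stain.translation[1],
            image_size=dihedral_output_size_inv(stain.pre, (w, h)),
        )
        native = _warp_to_native(content, truth)
        srng = np.random.default_rng([spec.seed, hash_stain(stain.name)])
        noisy = np.clip(native + srng.normal(0.0, spec.noise_sigma, native.shape), 0, 255)
        ihc_images.append(SlideImage(noisy.astype(np.uint8), spec.microns_per_pixel, name=stain.name))
        transforms[stain.name] = truth

        inv = invert(truth)
        for p in lm_ref:
            q = inv.apply_points(p)
            landmarks.append(LandmarkPair(stain.name, (float(p[0]), float(p[1])), (float(q[0]), float(q[1]))))

    return SyntheticCase(
        reference=reference,
        ihc_images=ihc_images,
        annotations=annotations,
        transforms=transforms,
        landmarks=landmarks,
        spec=spec,
    )


def hash_stain(name: str) -> int:
    """Stable small integer from a stain name (process-hash independent)."""
    return sum((i + 1) * ord(c) for i, c in enumerate(name)) % (2**16)


def dihedral_output_size_inv(op: DihedralOp, ref_size: tuple[int, int]) -> tuple[int, int]:
    """Native image size whose dihedral image has the reference size."""
    from .geometry import dihedral_output_size

    return dihedral_output_size(dihedral_inverse(op), ref_size)


def _warp_to_native(content: np.ndarray, truth: RigidTransform) -> np.ndarray:
    """native(p) = content(T(p)) by nearest-neighbour lookup (white outside)."""
    _, center = truth._resolve(None)
    t = math.radians(truth.theta)
    c, s = math.cos(t), math.sin(t)
    a_xy = np.array([[c, -s], [s, c]])
    off_xy = -a_xy @ center + center + np.array([truth.tx, truth.ty])
    a_yx = a_xy[::-1, ::-1]
    off_yx = off_xy[::-1]
    chans = [
        ndimage.affine_transform(content[..., ch], a_yx, offset=off_yx, order=0,
                                 mode="constant", cval=255.0)
        for ch in range(content.shape[2])
    ]
    tmp = np.stack(chans, axis=-1)
    return apply_dihedral_to_image(dihedral_inverse(truth.pre), tmp)


def uniform_stain_image(
    size: tuple[int, int],
    fraction: float,
    intensity_class: str = "high",
    microns_per_pixel: float = 2.5,
    name: str = "uniform",
) -> SlideImage:
    """Whole-frame counterstain with an exactly dithered brown fraction (test fixture)."""
    w, h = size
    px = np.empty((h, w, 3), dtype=np.uint8)
    px[:] = _COUNTERSTAIN_RGB
    brown = plant_brown_mask((h, w), fraction)
    for ch in range(3):
        px[..., ch] = np.where(brown, _DAB_RGB[intensity_class][ch], px[..., ch])
    return SlideImage(px, microns_per_pixel, name=name)


def generate_cohort(
    n_cases: int = 10, base_spec: SyntheticSpec | None = None, seed: int = 0
) -> list[SyntheticCase]:
    """n independent cases with per-case seeds derived from (seed, case index).

    Each case randomizes the ground-truth moves (any dihedral op, rotation
    within +-10 degrees, translation within +-8% of the image) and jitters
    the planted fractions by +-20% while preserving the region contrast.
    """
    if n_cases < 1:
        raise ValueError("n_cases must be >= 1")
    base = base_spec or default_spec()
    ops = list(DihedralOp)
    cases = []
    for i in range(n_cases):
        crng = np.random.default_rng([seed, i])
        case_seed = int(crng.integers(0, 2**31 - 1))
        stains = []
        for stain in base.stains:
            jitter = float(crng.uniform(0.8, 1.2))
            n = min(base.image_size)
            stains.append(
                replace(
                    stain,
                    fractions={k: min(1.0, v * jitter) for k, v in stain.fractions.items()},
                    background_fraction=min(1.0, stain.background_fraction * jitter),
                    pre=ops[int(crng.integers(8))],
                    theta=float(crng.uniform(-10, 10)),
                    translation=(float(crng.uniform(-0.08, 0.08) * n), float(crng.uniform(-0.08, 0.08) * n)),
                )
            )
        spec = replace(copy.deepcopy(base), stains=stains, seed=case_seed)
        cases.append(generate_case(spec))
    return cases


def write_case(case: SyntheticCase, outdir) -> None:
    """Emit the file formats the pipeline consumes (PNG, XML, CSV, JSON)."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    write_slide(case.reference, outdir / "reference.png")
    for img in case.ihc_images:
        write_slide(img, outdir / f"{img.name}.png")
    write_annotations(case.annotations, outdir / "annotations.xml")
    write_landmarks(case.landmarks, outdir / "landmarks.csv")
    truth = {name: t.to_dict() for name, t in case.transforms.items()}
    truth["microns_per_pixel"] = case.spec.microns_per_pixel
    with open(outdir / "truth_transforms.json", "w") as fh:
        json.dump(truth, fh, indent=2)
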