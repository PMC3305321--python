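"""Reference-frame analysis grid with Monte Carlo annotation filtering.

The grid tiles the reference image with axis-aligned, half-open cells of a
physical size (default 250x250 um, i.e. 0.25x0.25 mm^2).  A cell is kept for
analysis only when, by uniform random point sampling (default 500 points,
threshold 50%), it lies on tissue, inside a single annotation layer's
polygons, and outside every negative-pen exclusion region of every slide.
Per-cell RNG substreams are derived from ``(seed, row, col)`` so that the
retained set is independent of evaluation order.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
from skimage.morphology import closing, disk
from skimage.transform import resize

from .geometry import Polygon, RigidTransform, points_in_any_polygon, transform_polygon
from .slide_io import AnnotationSet, SlideImage

__all__ = [
    "CellStatus",
    "GridCell",
    "GridSpec",
    "cell_rng",
    "filter_grid",
    "make_grid",
    "make_tissue_mask",
    "monte_carlo_fraction",
]


class CellStatus:
    RETAINED = "retained"
    OUTSIDE_TISSUE = "outside_tissue"
    OUTSIDE_ANNOTATION = "outside_annotation"
    NEGATIVE_EXCLUDED = "negative_excluded"


@dataclass
class GridSpec:
    """Grid geometry plus Monte Carlo sampling parameters."""

    cell_width_um: float = 250.0
    cell_height_um: float = 250.0
    origin: tuple[float, float] = (0.0, 0.0)
    mc_points: int = 500
    mc_threshold: float = 0.5
    seed: int = 0

    def __post_init__(self):
        if self.cell_width_um <= 0 or self.cell_height_um <= 0:
            raise ValueError("cell dimensions must be positive")
        if self.mc_points < 1:
            raise ValueError("mc_points must be >= 1")
        if not (0.0 < self.mc_threshold <= 1.0):
            raise ValueError("mc_threshold must be in (0, 1]")


@dataclass
class GridCell:
    """Half-open pixel rectangle [x0, x1) x [y0, y1) in the reference frame."""

    row: int
    col: int
    x0: float
    y0: float
    x1: float
    y1: float
    region_label: str | None = None
    status: str = CellStatus.RETAINED

    @property
    def corners(self) -> np.ndarray:
        return np.array(
            [[self.x0, self.y0], [self.x1, self.y0], [self.x1, self.y1], [self.x0, self.y1]]
        )

    def contains(self, pts: np.ndarray) -> np.ndarray:
        pts = np.atleast_2d(pts)
        return (
            (pts[:, 0] >= self.x0)
            & (pts[:, 0] < self.x1)
            & (pts[:, 1] >= self.y0)
            & (pts[:, 1] < self.y1)
        )


def make_grid(ref: SlideImage, spec: GridSpec) -> list[GridCell]:
    """Tile the reference image with half-open cells; edge cells are clipped."""
    cw = spec.cell_width_um / ref.microns_per_pixel
    ch = spec.cell_height_um / ref.microns_per_pixel
    if cw < 1 or ch < 1:
        raise ValueError("grid cell smaller than one pixel at this resolution")
    W, H = ref.size
    ox, oy = spec.origin
    if cw > W or ch > H:
        warnings.warn("grid cell larger than the image; grid degenerates to clipped cell(s)", stacklevel=2)
    cells = []
    n_rows = int(np.ceil((H - oy) / ch))
    n_cols = int(np.ceil((W - ox) / cw))
    for r in range(n_rows):
        for c in range(n_cols):
            x0, y0 = ox + c * cw, oy + r * ch
            cells.append(
                GridCell(row=r, col=c, x0=x0, y0=y0, x1=min(x0 + cw, float(W)), y1=min(y0 + ch, float(H)))
            )
    return cells


def cell_rng(seed: int, row: int, col: int) -> np.random.Generator:
    """Per-cell RNG substream, stable under evaluation order."""
    return np.random.default_rng([seed, row, col])


def _sample_points(cell: GridCell, n: int, rng: np.random.Generator) -> np.ndarray:
    xs = rng.uniform(cell.x0, cell.x1, n)
    ys = rng.uniform(cell.y0, cell.y1, n)
    return np.column_stack([xs, ys])


def monte_carlo_fraction(
    cell: GridCell,
    polygons: Sequence[Polygon],
    n: int,
    rng: np.random.Generator,
    points: np.ndarray | None = None,
) -> float:
    """Fraction of n uniform points in the cell falling inside the polygon union.

    Even-odd rule per polygon; boundary points count as inside.  A
    pre-drawn point set may be passed so multiple membership tests share
    one sample (as :func:`filter_grid` does).
    """
    if n < 1:
        raise ValueError("n must be >= 1")
    if not polygons:
        return 0.0
    pts = points if points is not None else _sample_points(cell, n, rng)
    return float(points_in_any_polygon(pts, polygons).mean())


def make_tissue_mask(
    ref: SlideImage,
    gray_max: float = 235.0,
    saturation_min: float = 0.05,
    closing_radius: int = 5,
    max_side: int = 2048,
) -> np.ndarray:
    """Binary tissue-foreground mask for a (mostly white background) slide.

    A pixel is tissue when its grayscale luminance is below ``gray_max`` or
    its HSV saturation exceeds ``saturation_min``; small gaps are closed
    morphologically (disk radius ``closing_radius`` at a working resolution
    of at most ``max_side`` on the longest side).
    """
    px = ref.pixels.astype(float)
    scale = max(px.shape[0], px.shape[1]) / max_side
    work = px
    if scale > 1:
        work = resize(px, (int(round(px.shape[0] / scale)), int(round(px.shape[1] / scale))),
                      anti_aliasing=True, preserve_range=True)
    gray = work @ np.array([0.299, 0.587, 0.114])
    mx = work.max(axis=2)
    mn = work.min(axis=2)
    sat = np.where(mx > 0, (mx - mn) / np.maximum(mx, 1e-12), 0.0)
    mask = (gray < gray_max) | (sat > saturation_min)
    mask = closing(mask, disk(closing_radius))
    if scale > 1:
        mask = resize(mask.astype(float), px.shape[:2], order=0, preserve_range=True) > 0.5
    return mask


def _mask_fraction(mask: np.ndarray, pts: np.ndarray) -> float:
    ys = np.clip(pts[:, 1].astype(int), 0, mask.shape[0] - 1)
    xs = np.clip(pts[:, 0].astype(int), 0, mask.shape[1] - 1)
    return float(mask[ys, xs].mean())


def filter_grid(
    cells: Sequence[GridCell],
    annotations: AnnotationSet,
    tissue_mask: np.ndarray,
    negatives_by_stain: Sequence[AnnotationSet] = (),
    spec: GridSpec | None = None,
    transforms: Mapping[str, RigidTransform] | None = None,
) -> list[GridCell]:
    """Retain cells on tissue, inside a single annotation layer, off negatives.

    ``negatives_by_stain`` holds annotation sets whose negative-pen polygons
    are honoured on *all* stains; polygons drawn on an IHC slide are mapped
    to the reference frame through that stain's registered transform
    (``transforms[source_slide]``, native -> reference) first.  Decisions use
    one Monte Carlo point sample per cell (substream from (seed, row, col)).
    """
    spec = spec or GridSpec()
    transforms = transforms or {}

    neg_polys: list[Polygon] = list(annotations.negative_polygons())
    for aset in negatives_by_stain:
        t = transforms.get(aset.source_slide)
        for poly in aset.negative_polygons():
            neg_polys.append(transform_polygon(t, poly) if t is not None else poly)

    pos_layers = annotations.positive_layers()
    out: list[GridCell] = []
    tie_warned = False
    for cell in cells:
        rng = cell_rng(spec.seed, cell.row, cell.col)
        pts = _sample_points(cell, spec.mc_points, rng)
        cell = GridCell(cell.row, cell.col, cell.x0, cell.y0, cell.x1, cell.y1)

        if _mask_fraction(tissue_mask, pts) < spec.mc_threshold:
            cell.status = CellStatus.OUTSIDE_TISSUE
            out.append(cell)
            continue

        best_label, best_frac = None, -1.0
        for layer_name, polys in pos_layers:
            frac = monte_carlo_fraction(cell, polys, spec.mc_points, rng, points=pts)
            if frac > best_frac:
                best_label, best_frac = layer_name, frac
            elif frac == best_frac and frac >= spec.mc_threshold and not tie_warned:
                warnings.warn(
                    f"cell ({cell.row},{cell.col}): layers tie at fraction {frac:.3f}; "
                    "assigning the layer listed first",
                    stacklevel=2,
                )
                tie_warned = True
        if best_frac < spec.mc_threshold:
            cell.status = CellStatus.OUTSIDE_ANNOTATION
            out.append(cell)
            continue

        if neg_polys and monte_carlo_fraction(cell, neg_polys, spec.mc_points, rng, points=pts) >= spec.mc_threshold:
            cell.status = CellStatus.NEGATIVE_EXCLUDED
            out.append(cell)
            continue

        cell.status = CellStatus.RETAINED
        cell.region_label = best_label
        out.append(cell)
    return out


def retained(cells: Sequence[GridCell]) -> list[GridCell]:
    return [c for c in cells if c.status == CellStatus.RETAINED]
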