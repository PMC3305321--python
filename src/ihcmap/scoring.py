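"""Brown-chromogen (DAB) positive-pixel-count scoring per grid cell.

Pixels are classified in HSI space: intensity I = (R+G+B)/3, saturation
S = 1 - min(R,G,B)/I, and hue on the standard RGB hexagon (red at 0,
fraction of the color circle).  A pixel is candidate-positive when its
circular hue distance to the configured brown hue is within half the hue
width, S >= saturation_min, and I <= the weak intensity bound; candidates
are binned into weak/moderate/strong by the intensity cut-points.  The
default thresholds (hue 0.1, width 0.5, saturation 0.04, intensity
220/175/100) are the widely published defaults of the commercial Positive
Pixel Count v9 algorithm; all are configurable.

Scores are computed at full resolution in each IHC image's *native* frame:
grid cells are carried there through the inverse registration transform and
a pixel belongs to a cell when its center, mapped forward to the reference
frame, lands inside the half-open cell rectangle.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np

from .geometry import RigidTransform, invert
from .grid import GridCell
from .slide_io import SlideImage

__all__ = [
    "CellScore",
    "IHCMap",
    "PPCConfig",
    "PixelCounts",
    "classify_pixels",
    "score_cell",
    "score_stain",
]


@dataclass
class PPCConfig:
    """Positive-pixel-count thresholds (hue/saturation as fractions, intensity 8-bit)."""

    hue_center: float = 0.10
    hue_width: float = 0.50
    saturation_min: float = 0.04
    weak_upper: float = 220.0
    moderate_upper: float = 175.0
    strong_upper: float = 100.0
    score_mode: str = "positivity"  # or "weighted"

    def __post_init__(self):
        if not (0 <= self.strong_upper < self.moderate_upper < self.weak_upper <= 255):
            raise ValueError("require 0 <= strong < moderate < weak <= 255")
        if self.score_mode not in ("positivity", "weighted"):
            raise ValueError(f"unknown score_mode {self.score_mode!r}")


@dataclass(frozen=True)
class PixelCounts:
    n_total: int
    n_weak: int
    n_moderate: int
    n_strong: int

    @property
    def n_positive(self) -> int:
        return self.n_weak + self.n_moderate + self.n_strong


@dataclass
class CellScore:
    """Per-cell pixel counts and the resulting dimensionless score in [0, 1]."""

    row: int
    col: int
    counts: PixelCounts
    score: float | None
    empty: bool = False


@dataclass
class IHCMap:
    """Per-grid-cell scores for one stain, keyed by reference (row, col)."""

    stain: str
    scores: dict[tuple[int, int], CellScore]
    cells: dict[tuple[int, int], GridCell]
    microns_per_pixel: float
    frame: str = "reference"

    def non_empty_keys(self) -> set[tuple[int, int]]:
        return {k for k, s in self.scores.items() if not s.empty}

    def grid_signature(self) -> tuple:
        """Geometry fingerprint used to refuse mixing maps from different grids."""
        return tuple(sorted((k, c.x0, c.y0, c.x1, c.y1) for k, c in self.cells.items()))


def _hsi(tile: np.ndarray):
    rgb = tile.astype(float)
    r, g, b = rgb[..., 0], rgb[..., 1], rgb[..., 2]
    i = (r + g + b) / 3.0
    mn = np.minimum(np.minimum(r, g), b)
    mx = np.maximum(np.maximum(r, g), b)
    s = np.where(i > 0, 1.0 - mn / np.where(i > 0, i, 1.0), 0.0)
    c = mx - mn
    hp = np.zeros_like(i)  # hue in [0,6); 0 where achromatic
    nz = c > 0
    rm, gm, bm = (mx == r) & nz, (mx == g) & nz & (mx != r), (mx == b) & nz & (mx != r) & (mx != g)
    cs = np.where(nz, c, 1.0)
    hp = np.where(rm, ((g - b) / cs) % 6.0, hp)
    hp = np.where(gm, (b - r) / cs + 2.0, hp)
    hp = np.where(bm, (r - g) / cs + 4.0, hp)
    return i, s, hp / 6.0


def classify_pixels(tile: np.ndarray, cfg: PPCConfig | None = None) -> PixelCounts:
    """Count weak/moderate/strong brown-positive pixels in an RGB tile."""
    cfg = cfg or PPCConfig()
    tile = np.asarray(tile)
    if tile.size == 0:
        raise ValueError("empty tile")
    i, s, h = _hsi(tile.reshape(-1, 3) if tile.ndim == 3 else tile)
    dist = np.abs(h - cfg.hue_center)
    dist = np.minimum(dist, 1.0 - dist)
    cand = (dist <= cfg.hue_width / 2.0) & (s >= cfg.saturation_min) & (i <= cfg.weak_upper)
    strong = cand & (i <= cfg.strong_upper)
    moderate = cand & (i > cfg.strong_upper) & (i <= cfg.moderate_upper)
    weak = cand & ~strong & ~moderate
    return PixelCounts(
        n_total=int(i.size),
        n_weak=int(weak.sum()),
        n_moderate=int(moderate.sum()),
        n_strong=int(strong.sum()),
    )


def score_cell(counts: PixelCounts, cfg: PPCConfig | None = None) -> float:
    """Positive fraction (positivity mode) or intensity-weighted index in [0, 1]."""
    cfg = cfg or PPCConfig()
    if counts.n_total < 1:
        raise ValueError("cell has no pixels (flag it empty instead of scoring)")
    if cfg.score_mode == "positivity":
        return counts.n_positive / counts.n_total
    return (counts.n_weak + 2 * counts.n_moderate + 3 * counts.n_strong) / (3 * counts.n_total)


def score_stain(
    ihc: SlideImage,
    cells: Sequence[GridCell],
    transform: RigidTransform,
    cfg: PPCConfig | None = None,
) -> IHCMap:
    """Score retained grid cells on one IHC image in its native frame.

    ``transform`` maps the IHC native frame to the reference frame (the
    registration result); its inverse carries each cell into the native
    frame, where full-resolution pixels are classified.  Results are keyed
    by the reference (row, col).  Cells mapping entirely off the image are
    flagged empty and excluded downstream.
    """
    cfg = cfg or PPCConfig()
    inv = invert(transform)  # reference -> native
    H, W = ihc.pixels.shape[:2]
    scores: dict[tuple[int, int], CellScore] = {}
    cell_index: dict[tuple[int, int], GridCell] = {}
    for cell in cells:
        native_corners = inv.apply_points(cell.corners)
        x_lo = int(np.floor(native_corners[:, 0].min()))
        x_hi = int(np.ceil(native_corners[:, 0].max()))
        y_lo = int(np.floor(native_corners[:, 1].min()))
        y_hi = int(np.ceil(native_corners[:, 1].max()))
        x_lo, x_hi = max(x_lo, 0), min(x_hi, W - 1)
        y_lo, y_hi = max(y_lo, 0), min(y_hi, H - 1)
        key = (cell.row, cell.col)
        cell_index[key] = cell
        if x_lo > x_hi or y_lo > y_hi:
            scores[key] = CellScore(cell.row, cell.col, PixelCounts(0, 0, 0, 0), None, empty=True)
            continue
        xs = np.arange(x_lo, x_hi + 1)
        ys = np.arange(y_lo, y_hi + 1)
        gx, gy = np.meshgrid(xs, ys)
        pts = np.column_stack([gx.ravel(), gy.ravel()]).astype(float)
        member = cell.contains(transform.apply_points(pts))
        if not member.any():
            scores[key] = CellScore(cell.row, cell.col, PixelCounts(0, 0, 0, 0), None, empty=True)
            continue
        tile = ihc.pixels[y_lo : y_hi + 1, x_lo : x_hi + 1].reshape(-1, 3)[member]
        counts = classify_pixels(tile, cfg)
        scores[key] = CellScore(cell.row, cell.col, counts, score_cell(counts, cfg))
    n_empty = sum(1 for s in scores.values() if s.empty)
    if n_empty:
        warnings.warn(f"{ihc.name or 'stain'}: {n_empty} cell(s) mapped off-image; flagged empty", stacklevel=2)
    return IHCMap(stain=ihc.name, scores=scores, cells=cell_index, microns_per_pixel=ihc.microns_per_pixel)
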