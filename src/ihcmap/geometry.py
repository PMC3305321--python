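"""Coordinate conventions and the rigid transform algebra.

Frame convention used throughout the package: 0-based pixel indices,
``x`` = column (rightward), ``y`` = row (downward), origin at the top-left
corner; continuous coordinates refer to pixel centers.  A rigid slide
transform is a dihedral pre-operation (one of the eight flip/90-degree
symmetries of the image rectangle) followed by a continuous rotation about
the image center and a translation.  Positive ``theta`` is a clockwise
rotation as displayed (y-down frame).
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field, replace
from enum import Enum
from typing import Iterable, Sequence

import numpy as np

__all__ = [
    "DihedralOp",
    "Point2D",
    "Polygon",
    "RigidTransform",
    "apply_dihedral_to_image",
    "apply_transform",
    "compose_dihedral",
    "dihedral_apply_points",
    "dihedral_inverse",
    "dihedral_output_size",
    "invert",
    "points_in_polygon",
    "transform_polygon",
]

Point2D = tuple[float, float]


class DihedralOp(Enum):
    """The eight symmetries of an axis-aligned image rectangle.

    ``ROT90`` is a clockwise quarter turn as displayed (y-down frame);
    ``TRANSPOSE`` is flipH∘rot90 and ``ANTITRANSPOSE`` is flipV∘rot90.
    """

    IDENTITY = "identity"
    ROT90 = "rot90"
    ROT180 = "rot180"
    ROT270 = "rot270"
    FLIP_H = "flip_h"
    FLIP_V = "flip_v"
    TRANSPOSE = "transpose"
    ANTITRANSPOSE = "antitranspose"


# Linear part M and whether the op swaps (width, height).  The affine offset
# depends on the rectangle size and is derived in dihedral_apply_points.
_DIHEDRAL_MATRIX: dict[DihedralOp, np.ndarray] = {
    DihedralOp.IDENTITY: np.array([[1, 0], [0, 1]]),
    DihedralOp.ROT90: np.array([[0, -1], [1, 0]]),
    DihedralOp.ROT180: np.array([[-1, 0], [0, -1]]),
    DihedralOp.ROT270: np.array([[0, 1], [-1, 0]]),
    DihedralOp.FLIP_H: np.array([[-1, 0], [0, 1]]),
    DihedralOp.FLIP_V: np.array([[1, 0], [0, -1]]),
    DihedralOp.TRANSPOSE: np.array([[0, 1], [1, 0]]),
    DihedralOp.ANTITRANSPOSE: np.array([[0, -1], [-1, 0]]),
}

_MATRIX_TO_OP = {m.tobytes(): op for op, m in _DIHEDRAL_MATRIX.items()}

_SWAPS_SIZE = frozenset(
    {DihedralOp.ROT90, DihedralOp.ROT270, DihedralOp.TRANSPOSE, DihedralOp.ANTITRANSPOSE}
)


def dihedral_output_size(op: DihedralOp, image_size: tuple[int, int]) -> tuple[int, int]:
    """Size (w, h) of the rectangle after applying ``op`` to a (w, h) image."""
    w, h = image_size
    return (h, w) if op in _SWAPS_SIZE else (w, h)


def _dihedral_offset(op: DihedralOp, image_size) -> np.ndarray:
    w, h = image_size
    offsets = {
        DihedralOp.IDENTITY: (0.0, 0.0),
        DihedralOp.ROT90: (h - 1.0, 0.0),
        DihedralOp.ROT180: (w - 1.0, h - 1.0),
        DihedralOp.ROT270: (0.0, w - 1.0),
        DihedralOp.FLIP_H: (w - 1.0, 0.0),
        DihedralOp.FLIP_V: (0.0, h - 1.0),
        DihedralOp.TRANSPOSE: (0.0, 0.0),
        DihedralOp.ANTITRANSPOSE: (h - 1.0, w - 1.0),
    }
    return np.array(offsets[op], dtype=float)


def dihedral_apply_points(op: DihedralOp, pts: np.ndarray, image_size: tuple[int, int]) -> np.ndarray:
    """Apply a dihedral op to an (N, 2) array of (x, y) points on a (w, h) rectangle."""
    pts = np.asarray(pts, dtype=float)
    squeeze = pts.ndim == 1
    pts = np.atleast_2d(pts)
    m = _DIHEDRAL_MATRIX[op]
    b = np.asarray(_dihedral_offset(op, image_size), dtype=float)
    out = pts @ m.T + b
    return out[0] if squeeze else out


def compose_dihedral(a: DihedralOp, b: DihedralOp) -> DihedralOp:
    """Op equivalent to applying ``b`` first, then ``a`` (a∘b)."""
    m = _DIHEDRAL_MATRIX[a] @ _DIHEDRAL_MATRIX[b]
    return _MATRIX_TO_OP[m.tobytes()]


def dihedral_inverse(op: DihedralOp) -> DihedralOp:
    # orthogonal linear part: the inverse matrix is the transpose
    return _MATRIX_TO_OP[_DIHEDRAL_MATRIX[op].T.copy().tobytes()]


def dihedral_is_reflection(op: DihedralOp) -> bool:
    return bool(round(np.linalg.det(_DIHEDRAL_MATRIX[op])) == -1)


def apply_dihedral_to_image(op: DihedralOp, image: np.ndarray) -> np.ndarray:
    """Remap a raster so that ``out[op(p)] == image[p]`` (first two axes = rows, cols)."""
    if op is DihedralOp.IDENTITY:
        return image
    if op is DihedralOp.ROT90:  # clockwise on screen
        return np.rot90(image, k=-1, axes=(0, 1))
    if op is DihedralOp.ROT180:
        return np.rot90(image, k=2, axes=(0, 1))
    if op is DihedralOp.ROT270:
        return np.rot90(image, k=1, axes=(0, 1))
    if op is DihedralOp.FLIP_H:
        return np.flip(image, axis=1)
    if op is DihedralOp.FLIP_V:
        return np.flip(image, axis=0)
    if op is DihedralOp.TRANSPOSE:
        return np.swapaxes(image, 0, 1)
    if op is DihedralOp.ANTITRANSPOSE:
        return np.flip(np.swapaxes(image, 0, 1), axis=(0, 1))
    raise ValueError(op)  # pragma: no cover


def _rotation_matrix(theta_deg: float) -> np.ndarray:
    """Clockwise rotation (y-down display convention) by ``theta_deg``."""
    t = math.radians(theta_deg)
    c, s = math.cos(t), math.sin(t)
    return np.array([[c, -s], [s, c]])


@dataclass
class RigidTransform:
    """Dihedral pre-operation followed by rotation about ``center`` and translation.

    Maps points from the input frame (a ``image_size`` = (w, h) rectangle) into
    the output frame.  ``center`` defaults to the center of the post-dihedral
    rectangle, ((w'-1)/2, (h'-1)/2).
    """

    pre: DihedralOp = DihedralOp.IDENTITY
    theta: float = 0.0  # degrees, positive = clockwise on screen
    tx: float = 0.0
    ty: float = 0.0
    image_size: tuple[int, int] | None = None  # (w, h) of the input frame
    center: Point2D | None = None

    def _resolve(self, image_size=None):
        size = image_size if image_size is not None else self.image_size
        if size is None:
            raise ValueError("image_size required (transform carries none)")
        w2, h2 = dihedral_output_size(self.pre, size)
        center = self.center if self.center is not None else ((w2 - 1) / 2.0, (h2 - 1) / 2.0)
        return tuple(size), np.asarray(center, dtype=float)

    def apply_points(self, pts: np.ndarray, image_size: tuple[int, int] | None = None) -> np.ndarray:
        size, center = self._resolve(image_size)
        pts = np.asarray(pts, dtype=float)
        if not np.all(np.isfinite(pts)):
            raise ValueError("non-finite coordinates")
        squeeze = pts.ndim == 1
        pts = np.atleast_2d(pts)
        p = dihedral_apply_points(self.pre, pts, size)
        out = (p - center) @ _rotation_matrix(self.theta).T + center + np.array([self.tx, self.ty])
        return out[0] if squeeze else out

    @property
    def output_size(self) -> tuple[int, int] | None:
        if self.image_size is None:
            return None
        return dihedral_output_size(self.pre, self.image_size)

    # -- serialization ------------------------------------------------------

    def to_dict(self) -> dict:
        return {
            "pre": self.pre.value,
            "theta_deg": self.theta,
            "tx_px": self.tx,
            "ty_px": self.ty,
            "center": None if self.center is None else list(self.center),
            "image_size": None if self.image_size is None else list(self.image_size),
        }

    @classmethod
    def from_dict(cls, d: dict) -> "RigidTransform":
        return cls(
            pre=DihedralOp(d["pre"]),
            theta=float(d["theta_deg"]),
            tx=float(d["tx_px"]),
            ty=float(d["ty_px"]),
            image_size=None if d.get("image_size") is None else tuple(d["image_size"]),
            center=None if d.get("center") is None else tuple(d["center"]),
        )

    def to_json(self, path) -> None:
        with open(path, "w") as fh:
            json.dump(self.to_dict(), fh, indent=2)

    @classmethod
    def from_json(cls, path) -> "RigidTransform":
        with open(path) as fh:
            return cls.from_dict(json.load(fh))


def apply_transform(
    t: RigidTransform, p: np.ndarray | Point2D, image_size: tuple[int, int] | None = None
) -> np.ndarray:
    """Map point(s) ``p`` from the transform's input frame to its output frame."""
    return t.apply_points(p, image_size)


def invert(t: RigidTransform, image_size: tuple[int, int] | None = None) -> RigidTransform:
    """Exact inverse, expressed in the same dihedral-then-rigid parametrization.

    The dihedral part conjugates the rotation: when ``pre`` contains a
    reflection the inverse rotation keeps the same sign of theta, otherwise
    it is negated.  The residual translation is solved numerically.
    """
    size, _ = t._resolve(image_size)
    out_size = dihedral_output_size(t.pre, size)
    inv_pre = dihedral_inverse(t.pre)
    inv_theta = t.theta if dihedral_is_reflection(t.pre) else -t.theta
    cand = RigidTransform(pre=inv_pre, theta=inv_theta, tx=0.0, ty=0.0, image_size=out_size)
    # linear parts cancel by construction; the residual is a pure translation
    probes = np.array([[0.0, 0.0], [7.0, 3.0]])
    resid = cand.apply_points(t.apply_points(probes, size)) - probes
    if not np.allclose(resid[0], resid[1], atol=1e-9):  # pragma: no cover - algebraic guarantee
        raise AssertionError("inverse residual is not a pure translation")
    return replace(cand, tx=-resid[0, 0], ty=-resid[0, 1])


@dataclass
class Polygon:
    """Closed polygon in pixel coordinates (implicitly closed; even-odd fill rule)."""

    vertices: np.ndarray  # (N, 2) float, N >= 3
    label: str = ""
    negative: bool = False

    def __post_init__(self):
        v = np.asarray(self.vertices, dtype=float)
        if v.ndim != 2 or v.shape[1] != 2 or v.shape[0] < 3:
            raise ValueError("polygon needs an (N>=3, 2) vertex array")
        if not np.all(np.isfinite(v)):
            raise ValueError("non-finite polygon vertices")
        self.vertices = v

    def bounds(self) -> tuple[float, float, float, float]:
        v = self.vertices
        return float(v[:, 0].min()), float(v[:, 1].min()), float(v[:, 0].max()), float(v[:, 1].max())


def transform_polygon(
    t: RigidTransform, poly: Polygon, image_size: tuple[int, int] | None = None
) -> Polygon:
    """Vertex-wise transform; label and negative flag are preserved."""
    return Polygon(t.apply_points(poly.vertices, image_size), label=poly.label, negative=poly.negative)


def points_in_polygon(
    pts: np.ndarray, vertices: np.ndarray, boundary_eps: float = 1e-9
) -> np.ndarray:
    """Even-odd (crossing-number) point-in-polygon test; boundary counts inside.

    Handles self-intersecting rings by the even-odd rule.  Vectorized over
    points; the edge loop is over the (small) vertex count.
    """
    pts = np.atleast_2d(np.asarray(pts, dtype=float))
    v = np.asarray(vertices, dtype=float)
    x, y = pts[:, 0], pts[:, 1]
    inside = np.zeros(len(pts), dtype=bool)
    on_edge = np.zeros(len(pts), dtype=bool)
    n = len(v)
    for i in range(n):
        x1, y1 = v[i]
        x2, y2 = v[(i + 1) % n]
        # crossing-number toggle for the horizontal ray towards +x
        crosses = (y1 > y) != (y2 > y)
        if np.any(crosses):
            xint = x1 + (y[crosses] - y1) * (x2 - x1) / (y2 - y1)
            hit = inside[crosses].copy()
            hit ^= x[crosses] < xint
            inside[crosses] = hit
        # boundary test: distance from point to segment
        dx, dy = x2 - x1, y2 - y1
        seg2 = dx * dx + dy * dy
        if seg2 == 0.0:
            d2 = (x - x1) ** 2 + (y - y1) ** 2
        else:
            u = np.clip(((x - x1) * dx + (y - y1) * dy) / seg2, 0.0, 1.0)
            d2 = (x - (x1 + u * dx)) ** 2 + (y - (y1 + u * dy)) ** 2
        on_edge |= d2 <= boundary_eps**2
    return inside | on_edge


def points_in_any_polygon(pts: np.ndarray, polygons: Sequence[Polygon]) -> np.ndarray:
    """Membership in the union of polygons (each by the even-odd rule)."""
    pts = np.atleast_2d(np.asarray(pts, dtype=float))
    out = np.zeros(len(pts), dtype=bool)
    for poly in polygons:
        out |= points_in_polygon(pts, poly.vertices)
    return out
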