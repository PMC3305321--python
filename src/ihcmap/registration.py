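"""Two-step rigid alignment of IHC slides to the H&E reference.

Coarse step: exhaustive search over the eight dihedral (flip / 90-degree
rotation) symmetries on small grayscale thumbnails, or a user-supplied op.
Fine step: minimization of the mean squared grayscale difference over the
overlap region, with rotation + translation only, run coarse-to-fine over a
multiresolution pyramid (factor 2 per level) with bilinear warping and a
deterministic derivative-free (Powell) search at each level.  Cost is
normalized by the overlap pixel count; an overlap below 25% of the
reference flags the result as failed.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
from scipy import ndimage, optimize
from skimage.transform import resize

from .geometry import (
    DihedralOp,
    RigidTransform,
    apply_dihedral_to_image,
    dihedral_output_size,
)
from .slide_io import SlideImage

__all__ = [
    "RegistrationConfig",
    "RegistrationResult",
    "coarse_align",
    "fine_register",
    "register_all",
    "to_grayscale",
]

_LUMA = np.array([0.299, 0.587, 0.114])


def to_grayscale(img: SlideImage | np.ndarray) -> np.ndarray:
    """Rec. 601 luminance in [0, 255] as float."""
    px = img.pixels if isinstance(img, SlideImage) else np.asarray(img)
    return px.astype(float) @ _LUMA


@dataclass
class RegistrationConfig:
    max_side: int = 1024  # working resolution cap for the fine stage
    coarse_side: int = 128  # coarsest pyramid level, longest side
    thumb_side: int = 128  # dihedral-search thumbnails
    theta_bound: float = 20.0  # degrees searched either side of the init
    translation_bound_frac: float = 0.25  # of the working image's longest side
    min_overlap: float = 0.25
    maxiter: int = 30  # Powell iterations per level
    maxiter_finest: int = 4  # the finest level starts very near the optimum
    maxfev: int = 400  # cost-evaluation budget per pyramid level
    maxfev_finest: int = 80
    coarse_theta_starts: tuple[float, ...] = (0.0,)
    coarse_maxiter: int = 8  # per-op refinement budget in the dihedral search


@dataclass
class RegistrationResult:
    """Recovered native->reference transform with diagnostics."""

    transform: RigidTransform
    final_cost: float
    pyramid_levels: int
    overlap_fraction: float
    failed: bool = False
    message: str = ""


def _thumb(gray: np.ndarray, max_side: int) -> np.ndarray:
    s = max(gray.shape) / max_side
    if s <= 1:
        return gray
    shape = (max(1, int(round(gray.shape[0] / s))), max(1, int(round(gray.shape[1] / s))))
    return resize(gray, shape, anti_aliasing=True, preserve_range=True)


def coarse_align(
    ref: SlideImage,
    ihc: SlideImage,
    mode: str = "auto",
    manual_op: DihedralOp | None = None,
    config: RegistrationConfig | None = None,
) -> DihedralOp:
    """Pick the dihedral op best pre-aligning ``ihc`` with ``ref``.

    ``manual`` mode returns the supplied op, preserving the workflow where a
    user eyeballs the flip/rotation; ``auto`` evaluates all eight ops on
    grayscale thumbnails and returns the one with the smallest mean squared
    difference.  Because the sections may additionally differ by a residual
    rotation and shift, each op's cost is taken after a short bounded
    rotation+translation refinement at thumbnail scale (the op ranking is
    otherwise unstable for off-center tissue).
    """
    if mode == "manual":
        if manual_op is None:
            raise ValueError("manual mode requires manual_op")
        return manual_op
    if mode != "auto":
        raise ValueError(f"unknown coarse mode {mode!r}")
    cfg = config or RegistrationConfig()
    g_ref = _thumb(to_grayscale(ref), cfg.thumb_side).astype(np.float32)
    g_ihc = to_grayscale(ihc)
    if g_ref.std() < 1e-6 or g_ihc.std() < 1e-6:
        warnings.warn("constant-intensity image; coarse alignment defaulting to identity", stacklevel=2)
        return DihedralOp.IDENTITY
    tb = cfg.translation_bound_frac * max(g_ref.shape)
    best_op, best_cost = DihedralOp.IDENTITY, np.inf
    for op in DihedralOp:
        cand = apply_dihedral_to_image(op, g_ihc)
        cand = resize(cand, g_ref.shape, anti_aliasing=True, preserve_range=True).astype(np.float32)
        center = np.array([(cand.shape[1] - 1) / 2.0, (cand.shape[0] - 1) / 2.0])

        def cost_fn(x, _cand=cand, _c=center):
            return _warp_cost(g_ref, _cand, x[0], x[1], x[2], _c, cfg.min_overlap)[0]

        cost = np.inf
        for th0 in cfg.coarse_theta_starts:
            res = optimize.minimize(
                cost_fn,
                [th0, 0.0, 0.0],
                method="Powell",
                bounds=[(th0 - cfg.theta_bound, th0 + cfg.theta_bound), (-tb, tb), (-tb, tb)],
                options={"maxiter": cfg.coarse_maxiter, "xtol": 0.1, "ftol": 1e-4},
            )
            cost = min(cost, float(res.fun))
        if cost < best_cost:
            best_op, best_cost = op, cost
    return best_op


def _warp_cost(ref: np.ndarray, mov: np.ndarray, theta: float, tx: float, ty: float,
               center: np.ndarray, min_overlap: float) -> tuple[float, float]:
    """Masked MSE between ref and mov warped by (theta, t) about center.

    Inverse warping: for each ref pixel q, sample mov at R(-theta)(q-c-t)+c
    (bilinear); pixels falling outside mov are excluded from the mean.
    """
    t = math.radians(theta)
    c, s = math.cos(t), math.sin(t)
    # inverse map in (x, y); convert to scipy's (row, col) ordering
    a_xy = np.array([[c, s], [-s, c]])
    off_xy = -a_xy @ (center + np.array([tx, ty])) + center
    a_yx = a_xy[::-1, ::-1]
    off_yx = off_xy[::-1]
    warped = ndimage.affine_transform(mov, a_yx, offset=off_yx, output_shape=ref.shape,
                                      order=1, mode="constant", cval=np.nan)
    valid = ~np.isnan(warped)
    overlap = float(valid.mean())
    if overlap < min_overlap:
        return 1e12 * (1.0 + (min_overlap - overlap)), overlap
    diff = ref[valid] - warped[valid]
    return float(np.mean(diff * diff)), overlap


def fine_register(
    ref: SlideImage,
    ihc: SlideImage,
    init: DihedralOp = DihedralOp.IDENTITY,
    config: RegistrationConfig | None = None,
) -> RegistrationResult:
    """Rigid (rotation + translation) registration refined over a pyramid.

    The optimizer starts from theta=0, t=(0,0) on the dihedral-pre-aligned
    IHC image; each pyramid level's solution initializes the next.  The
    returned transform has ``pre=init`` and maps the IHC native frame to the
    reference frame at base resolution.
    """
    cfg = config or RegistrationConfig()
    g_ref_full = to_grayscale(ref)
    g_ihc_full = apply_dihedral_to_image(init, to_grayscale(ihc))

    # downscale both by one common factor so the recovered transform rescales cleanly
    scale = max(max(g_ref_full.shape), max(g_ihc_full.shape)) / cfg.max_side
    scale = max(scale, 1.0)

    def _downscale(gray: np.ndarray, s: float) -> np.ndarray:
        if s <= 1:
            return gray
        shape = (max(1, int(round(gray.shape[0] / s))), max(1, int(round(gray.shape[1] / s))))
        return resize(gray, shape, anti_aliasing=True, preserve_range=True)

    g_ref = _downscale(g_ref_full, scale).astype(np.float32)
    g_ihc = _downscale(g_ihc_full, scale).astype(np.float32)

    # pyramid factors, coarsest first (factor 2 per level, coarsest <= coarse_side)
    factors = [1]
    while max(g_ref.shape) / (factors[-1] * 2) >= cfg.coarse_side:
        factors.append(factors[-1] * 2)
    factors = factors[::-1]

    center_work = np.array([(g_ihc.shape[1] - 1) / 2.0, (g_ihc.shape[0] - 1) / 2.0])
    theta, tx, ty = 0.0, 0.0, 0.0
    n_levels = len(factors)

    for li, f in enumerate(factors):
        ref_l = _thumb(g_ref, int(math.ceil(max(g_ref.shape) / f))).astype(np.float32)
        mov_l = _thumb(g_ihc, int(math.ceil(max(g_ihc.shape) / f))).astype(np.float32)
        lf = max(g_ihc.shape) / max(mov_l.shape)  # actual level scale
        c_l = center_work / lf
        tb = cfg.translation_bound_frac * max(ref_l.shape)

        def cost_fn(x, _ref=ref_l, _mov=mov_l, _c=c_l):
            return _warp_cost(_ref, _mov, x[0], x[1], x[2], _c, cfg.min_overlap)[0]

        x0s = [[theta, tx / lf, ty / lf]]
        if li == 0:
            x0s += [[th, 0.0, 0.0] for th in cfg.coarse_theta_starts if th != 0.0]
        best = None
        for x0 in x0s:
            res = optimize.minimize(
                cost_fn,
                x0,
                method="Powell",
                bounds=[(x0[0] - cfg.theta_bound, x0[0] + cfg.theta_bound), (-tb, tb), (-tb, tb)],
                options={
                    "maxiter": cfg.maxiter_finest if f == 1 and len(factors) > 1 else cfg.maxiter,
                    "maxfev": cfg.maxfev_finest if f == 1 and len(factors) > 1 else cfg.maxfev,
                    "xtol": 1e-3,
                    "ftol": 1e-7,
                },
            )
            if best is None or res.fun < best.fun:
                best = res
        theta = float(best.x[0])
        tx, ty = float(best.x[1] * lf), float(best.x[2] * lf)

    # guarantee monotonicity at the finest level: never worse than the init
    cost_init, _ = _warp_cost(g_ref, g_ihc, 0.0, 0.0, 0.0, center_work, 0.0)
    final_cost, overlap = _warp_cost(g_ref, g_ihc, theta, tx, ty, center_work, 0.0)
    if final_cost > cost_init:
        theta, tx, ty = 0.0, 0.0, 0.0
        final_cost, overlap = cost_init, _warp_cost(g_ref, g_ihc, 0, 0, 0, center_work, 0.0)[1]
        warnings.warn("fine registration did not improve on its initialization; keeping init", stacklevel=2)

    failed = overlap < cfg.min_overlap
    if failed:
        warnings.warn(f"registration overlap {overlap:.2f} below {cfg.min_overlap}; flagged failed", stacklevel=2)

    transform = RigidTransform(
        pre=init,
        theta=theta,
        tx=tx * scale,
        ty=ty * scale,
        image_size=(ihc.width, ihc.height),
        center=tuple(center_work * scale),
    )
    return RegistrationResult(
        transform=transform,
        final_cost=final_cost,
        pyramid_levels=n_levels,
        overlap_fraction=overlap,
        failed=failed,
    )


def register_all(
    ref: SlideImage,
    ihcs: Sequence[SlideImage],
    config: RegistrationConfig | None = None,
    coarse_mode: str = "auto",
    manual_ops: Sequence[DihedralOp] | None = None,
) -> list[RegistrationResult]:
    """Independently register each IHC image to the reference (order preserved)."""
    results = []
    for i, ihc in enumerate(ihcs):
        try:
            op = coarse_align(ref, ihc, mode=coarse_mode,
                              manual_op=manual_ops[i] if manual_ops else None, config=config)
            results.append(fine_register(ref, ihc, init=op, config=config))
        except Exception as exc:  # per-stain failures are collected, not fatal
            warnings.warn(f"registration of {ihc.name or i} failed: {exc}", stacklevel=2)
            results.append(
                RegistrationResult(
                    transform=RigidTransform(image_size=(ihc.width, ihc.height)),
                    final_cost=float("inf"),
                    pyramid_levels=0,
                    overlap_fraction=0.0,
                    failed=True,
                    message=str(exc),
                )
            )
    return results
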