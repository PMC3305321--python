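"""End-to-end orchestration: register, grid, score, and combine one or more cases.

This is thin glue over the individual modules; it exists so the CLI, the
test-suite, and cohort-level analyses (benchmark-vs-native comparisons)
share one code path.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np

from .geometry import RigidTransform
from .grid import GridCell, GridSpec, filter_grid, make_grid, make_tissue_mask, retained
from .registration import RegistrationConfig, register_all
from .scoring import IHCMap, PPCConfig, score_stain
from .signature import (
    GeneWeight,
    SignatureMap,
    build_signature_map,
    compute_weights,
    region_summaries,
)
from .slide_io import AnnotationSet, SlideImage
from .synthetic import SyntheticCase

__all__ = ["CaseScores", "CohortAnalysis", "register_case", "score_case", "analyze_cohort"]


@dataclass
class CaseScores:
    cells: list[GridCell]
    maps: dict[str, IHCMap]
    transforms: dict[str, RigidTransform]


@dataclass
class CohortAnalysis:
    per_case: list[CaseScores]
    weights: list[GeneWeight]
    signature_maps: list[SignatureMap]


def register_case(
    case: SyntheticCase, config: RegistrationConfig | None = None
) -> dict[str, RigidTransform]:
    """Recover each stain's native->reference transform from the images alone."""
    results = register_all(case.reference, case.ihc_images, config=config)
    return {img.name: res.transform for img, res in zip(case.ihc_images, results)}


def score_case(
    reference: SlideImage,
    ihc_images: Sequence[SlideImage],
    annotations: AnnotationSet,
    transforms: Mapping[str, RigidTransform],
    grid_spec: GridSpec | None = None,
    ppc: PPCConfig | None = None,
    negatives_by_stain: Sequence[AnnotationSet] = (),
) -> CaseScores:
    """Grid the reference, filter to annotated tissue, and score every stain."""
    grid_spec = grid_spec or GridSpec()
    mask = make_tissue_mask(reference)
    cells = make_grid(reference, grid_spec)
    cells = filter_grid(cells, annotations, mask, negatives_by_stain, grid_spec, transforms)
    keep = retained(cells)
    maps = {
        img.name: score_stain(img, keep, transforms[img.name], ppc) for img in ihc_images
    }
    return CaseScores(cells=cells, maps=maps, transforms=dict(transforms))


def analyze_cohort(
    cases: Sequence[SyntheticCase],
    transforms_per_case: Sequence[Mapping[str, RigidTransform]],
    signs: Mapping[str, int],
    grid_spec: GridSpec | None = None,
    ppc: PPCConfig | None = None,
) -> CohortAnalysis:
    """Score all cases, pool weights across them, and build per-case signature maps."""
    per_case = [
        score_case(c.reference, c.ihc_images, c.annotations, t, grid_spec, ppc)
        for c, t in zip(cases, transforms_per_case)
    ]
    all_maps = [m for cs in per_case for m in cs.maps.values()]
    weights = compute_weights(all_maps, signs)
    signature_maps = [
        build_signature_map(list(cs.maps.values()), weights) for cs in per_case
    ]
    return CohortAnalysis(per_case=per_case, weights=weights, signature_maps=signature_maps)
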