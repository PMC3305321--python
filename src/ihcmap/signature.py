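"""Weighted multigene combination of co-located IHC scores.

For n stains scored on the same reference grid, the signature score at a
cell x is the linear "voting" combination

    S(x) = sum_i  w_i * gene_i(x)

where gene_i(x) is stain i's positive-pixel score at the cell and
w_i = sign_i * magnitude_i.  The sign encodes whether the gene is up- or
down-regulated with respect to the outcome of interest; the magnitude
normalizes mean staining intensity across stains: with m_i the mean score
of stain i over retained annotated cells (pooled across all provided
cases), magnitude_i = m_r / m_i relative to a reference stain r (by
default the stain with the largest mean, which therefore gets magnitude
exactly 1).  S is defined only where all n stains are measured; cells
missing any stain are dropped, not imputed.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np

from .scoring import IHCMap

__all__ = [
    "GeneWeight",
    "RegionSummary",
    "SignatureMap",
    "build_signature_map",
    "compute_weights",
    "region_summaries",
    "signature_score",
]

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class GeneWeight:
    stain: str
    sign: int  # +1 or -1
    magnitude: float

    def __post_init__(self):
        if self.sign not in (+1, -1):
            raise ValueError("sign must be +1 or -1")
        if not self.magnitude > 0:
            raise ValueError("magnitude must be positive")

    @property
    def weight(self) -> float:
        return self.sign * self.magnitude


@dataclass
class SignatureMap:
    """Per-cell signature values S in reference orientation (relative units)."""

    scores: dict[tuple[int, int], float]
    weights: tuple[GeneWeight, ...]
    stains: tuple[str, ...]
    cells: dict[tuple[int, int], "object"]  # GridCell by (row, col)
    microns_per_pixel: float

    def region_labels(self) -> dict[tuple[int, int], str | None]:
        return {k: self.cells[k].region_label for k in self.scores}


@dataclass(frozen=True)
class RegionSummary:
    """Five-number summary of signature scores within one annotated region."""

    region: str
    n_cells: int
    minimum: float
    q1: float
    median: float
    q3: float
    maximum: float

    def as_tuple(self) -> tuple[float, float, float, float, float]:
        return (self.minimum, self.q1, self.median, self.q3, self.maximum)


def _stain_means(maps: Sequence[IHCMap], annotated_only: bool = True) -> dict[str, float]:
    pooled: dict[str, list[float]] = {}
    for m in maps:
        vals = pooled.setdefault(m.stain, [])
        for key, rec in m.scores.items():
            if rec.empty:
                continue
            if annotated_only and m.cells[key].region_label is None:
                continue
            vals.append(rec.score)
    return {stain: float(np.mean(v)) if v else float("nan") for stain, v in pooled.items()}


def compute_weights(
    maps: Sequence[IHCMap],
    signs: Mapping[str, int],
    reference: str = "auto",
) -> list[GeneWeight]:
    """Signed, mean-normalized weights, pooled over all provided maps.

    Multiple maps of the same stain (one per case) are pooled before taking
    the mean.  The reference stain — by default the one with the largest
    mean score — gets magnitude 1.0; every other stain gets m_ref / m_i.
    """
    means = _stain_means(maps)
    if not means:
        raise ValueError("no maps provided")
    for stain, m in means.items():
        if not np.isfinite(m):
            raise ValueError(f"stain {stain!r} has no scored annotated cells")
        if m == 0:
            raise ValueError(f"stain {stain!r} has zero mean score; weight undefined")
    if reference == "auto":
        reference = max(means, key=means.get)
    elif reference not in means:
        raise ValueError(f"reference stain {reference!r} not among {sorted(means)}")
    m_ref = means[reference]
    out = []
    for stain, m in means.items():
        if stain not in signs:
            raise ValueError(f"no sign configured for stain {stain!r}")
        out.append(GeneWeight(stain=stain, sign=int(signs[stain]), magnitude=m_ref / m))
    return out


def signature_score(
    cell_scores: Mapping[str, float], weights: Sequence[GeneWeight]
) -> float:
    """S = sum_i w_i * gene_i for one grid cell (all stains must be present)."""
    missing = [w.stain for w in weights if w.stain not in cell_scores]
    if missing:
        raise KeyError(f"missing stain(s) at cell: {missing}")
    return float(sum(w.weight * cell_scores[w.stain] for w in weights))


def build_signature_map(maps: Sequence[IHCMap], weights: Sequence[GeneWeight]) -> SignatureMap:
    """Combine per-stain maps on the cell set where every stain is non-empty."""
    if not maps:
        raise ValueError("need at least one IHC map")
    sig0 = maps[0].grid_signature()
    for m in maps[1:]:
        if m.grid_signature() != sig0:
            raise ValueError(f"map for {m.stain!r} uses a different grid; refusing to combine")
    by_stain = {m.stain: m for m in maps}
    wmap = {w.stain: w for w in weights}
    if set(by_stain) - set(wmap):
        raise ValueError(f"no weight for stain(s) {sorted(set(by_stain) - set(wmap))}")
    common = set.intersection(*(m.non_empty_keys() for m in maps))
    dropped = set.union(*(set(m.scores) for m in maps)) - common
    if dropped:
        logger.info("signature map: %d cell(s) dropped (missing in at least one stain)", len(dropped))
    if not common:
        warnings.warn("no cell is scored in every stain; signature map is empty", stacklevel=2)
    used = tuple(wmap[s] for s in sorted(by_stain))
    scores = {
        key: signature_score({s: by_stain[s].scores[key].score for s in by_stain}, used)
        for key in common
    }
    return SignatureMap(
        scores=scores,
        weights=used,
        stains=tuple(sorted(by_stain)),
        cells=dict(maps[0].cells),
        microns_per_pixel=maps[0].microns_per_pixel,
    )


def region_summaries(sig_map: SignatureMap) -> list[RegionSummary]:
    """Per-region min / Q1 / median / Q3 / max (linear-interpolation quartiles)."""
    if not sig_map.scores:
        raise ValueError("empty signature map")
    by_region: dict[str, list[float]] = {}
    for key, s in sig_map.scores.items():
        label = sig_map.cells[key].region_label
        if label is None:
            continue
        by_region.setdefault(label, []).append(s)
    out = []
    for region in sorted(by_region):
        vals = np.asarray(by_region[region])
        mn, q1, med, q3, mx = np.percentile(vals, [0, 25, 50, 75, 100])
        out.append(
            RegionSummary(
                region=region, n_cells=len(vals),
                minimum=float(mn), q1=float(q1), median=float(med), q3=float(q3), maximum=float(mx),
            )
        )
    return out
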