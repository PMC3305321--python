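"""Landmark-based registration-error assessment and benchmark comparisons.

Registration accuracy is quantified from corresponding landmark pairs: each
IHC-native landmark is carried to the reference frame through that stain's
registered transform, and the Euclidean distance to its reference landmark
(in micrometers) is the registration error.  Errors are summarized per
stain and pooled, binned into a histogram, and expressed as multiples of a
nominal malignant-cell diameter (15 um by default).  A second check
compares per-region signature five-number summaries between a benchmark
(gold-standard transforms) and a native (pipeline-registered) run.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .geometry import Point2D, RigidTransform
from .signature import RegionSummary, SignatureMap, region_summaries

__all__ = [
    "ErrorReport",
    "LandmarkPair",
    "RegionComparison",
    "cell_diameter_equivalent",
    "compare_benchmark_native",
    "landmark_errors",
    "read_landmarks",
    "write_landmarks",
]

DEFAULT_CELL_DIAMETER_UM = 15.0
DEFAULT_HIST_BIN_UM = 25.0


@dataclass(frozen=True)
class LandmarkPair:
    """The same anatomic feature marked in both frames."""

    stain: str
    ref_point: Point2D  # reference frame, pixels
    ihc_point: Point2D  # IHC native frame, pixels


@dataclass
class ErrorReport:
    per_pair: pd.DataFrame  # stain, ref_x, ref_y, ihc_x, ihc_y, error_um
    median_um: dict[str, float]  # per stain
    max_um: dict[str, float]
    pooled_median_um: float
    pooled_max_um: float
    hist_edges_um: np.ndarray
    hist_counts: np.ndarray
    cell_diameter_um: float
    median_cell_diameters: dict[str, int]
    max_cell_diameters: dict[str, int]


def read_landmarks(path) -> list[LandmarkPair]:
    """Landmark CSV: columns stain, ref_x, ref_y, ihc_x, ihc_y (pixels)."""
    # round_trip float parsing: the default C parser can be 1 ulp off on
    # 17-significant-digit decimals, breaking exact write/read identity
    df = pd.read_csv(path, comment="#", float_precision="round_trip")
    return [
        LandmarkPair(str(r.stain), (float(r.ref_x), float(r.ref_y)), (float(r.ihc_x), float(r.ihc_y)))
        for r in df.itertuples()
    ]


def write_landmarks(pairs: Sequence[LandmarkPair], path) -> None:
    pd.DataFrame(
        [
            {"stain": p.stain, "ref_x": p.ref_point[0], "ref_y": p.ref_point[1],
             "ihc_x": p.ihc_point[0], "ihc_y": p.ihc_point[1]}
            for p in pairs
        ]
    ).to_csv(path, index=False, float_format="%.17g")


def cell_diameter_equivalent(error_um: float, cell_diameter_um: float = DEFAULT_CELL_DIAMETER_UM) -> int:
    """Error expressed in whole cell diameters, rounded half away from zero."""
    if not (error_um > 0 and cell_diameter_um > 0):
        raise ValueError("error and cell diameter must be positive")
    return int(math.floor(error_um / cell_diameter_um + 0.5))


def landmark_errors(
    pairs: Sequence[LandmarkPair],
    transforms: Mapping[str, RigidTransform],
    microns_per_pixel: float,
    hist_bin_um: float = DEFAULT_HIST_BIN_UM,
    cell_diameter_um: float = DEFAULT_CELL_DIAMETER_UM,
) -> ErrorReport:
    """Vector-length registration errors for all landmark pairs, in micrometers."""
    rows = []
    for p in pairs:
        if p.stain not in transforms:
            raise KeyError(f"no transform for stain {p.stain!r}")
        mapped = transforms[p.stain].apply_points(np.asarray(p.ihc_point, dtype=float))
        err = float(np.hypot(*(mapped - np.asarray(p.ref_point)))) * microns_per_pixel
        rows.append(
            {"stain": p.stain, "ref_x": p.ref_point[0], "ref_y": p.ref_point[1],
             "ihc_x": p.ihc_point[0], "ihc_y": p.ihc_point[1], "error_um": err}
        )
    df = pd.DataFrame(rows)
    med = df.groupby("stain")["error_um"].median().to_dict()
    mx = df.groupby("stain")["error_um"].max().to_dict()
    top = max(df.error_um.max(), hist_bin_um)
    edges = np.arange(0.0, top + hist_bin_um, hist_bin_um)
    counts, _ = np.histogram(df.error_um.to_numpy(), bins=edges)
    to_cells = lambda v: cell_diameter_equivalent(v, cell_diameter_um) if v > 0 else 0
    return ErrorReport(
        per_pair=df,
        median_um={k: float(v) for k, v in med.items()},
        max_um={k: float(v) for k, v in mx.items()},
        pooled_median_um=float(df.error_um.median()),
        pooled_max_um=float(df.error_um.max()),
        hist_edges_um=edges,
        hist_counts=counts,
        cell_diameter_um=cell_diameter_um,
        median_cell_diameters={k: to_cells(v) for k, v in med.items()},
        max_cell_diameters={k: to_cells(v) for k, v in mx.items()},
    )


_STATS = ("minimum", "q1", "median", "q3", "maximum")


@dataclass(frozen=True)
class RegionComparison:
    region: str
    benchmark: RegionSummary
    native: RegionSummary
    relative_difference: dict[str, float]  # |native-benchmark| / |benchmark| per statistic


def compare_benchmark_native(
    benchmark: SignatureMap, native: SignatureMap
) -> tuple[list[RegionComparison], list[str]]:
    """Paired five-number summaries per region plus relative differences.

    Returns (comparisons, incomparable_region_labels); a region present in
    only one map is reported as incomparable rather than compared.
    """
    bench = {s.region: s for s in region_summaries(benchmark)}
    nat = {s.region: s for s in region_summaries(native)}
    comparisons = []
    for region in sorted(set(bench) & set(nat)):
        b, n = bench[region], nat[region]
        rel = {}
        for stat in _STATS:
            bv, nv = getattr(b, stat), getattr(n, stat)
            rel[stat] = abs(nv - bv) / abs(bv) if bv != 0 else (0.0 if nv == 0 else float("inf"))
        comparisons.append(RegionComparison(region=region, benchmark=b, native=n, relative_difference=rel))
    incomparable = sorted(set(bench) ^ set(nat))
    return comparisons, incomparable
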