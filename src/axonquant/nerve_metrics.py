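"""Optic- and sciatic-nerve regeneration quantification.

Implements the standard whole-mount quantification scheme for regenerating
axons after nerve crush:

* Z-projection of confocal stacks into optical sections (default 4
  consecutive 2-µm slices → 8-µm sections);
* fiber counts at fixed 250-µm intervals distal to the crush site, summed
  over all optical sections, scanned until no signal remains;
* per-axon lengths and the mean length of the top-5 longest axons;
* axonal tip morphometry — the maximal tip width over the terminal window
  relative to the adjacent shaft diameter; tips with ratio > 4 are
  retraction bulbs, the rest growth cones;
* trajectory metrics over the top-20 longest axons (or all axons entering
  the chiasm): U-turn rate (terminal direction > 90° off the longitudinal
  axis, one U-turn counted per axon) and branching index (terminal tips per
  analyzed axon);
* chiasm fate classification of terminal points (pre-chiasmic vs the
  ipsilateral/contralateral tract and contralateral nerve);
* sciatic-nerve length measurements with the ≥ 15-identifiable-axon QC rule.

Note on the interval counts: an axon spanning several optical sections is
counted once per section it appears in — the literal sum-over-projections
rule — so interval counts can exceed the axon number. This is recorded in
the profile metadata.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field
from typing import List, Literal, Optional, Sequence, Tuple

import numpy as np
import pandas as pd
from scipy import ndimage

from .errors import GeometryError, InsufficientLengthError
from .geometry import ChiasmLandmarks, NerveGeometry
from .stack import ImageStack
from .tracing import BinaryMask
from .trees import AxonTree

__all__ = [
    "ZProjectionSet",
    "RegenerationProfile",
    "TipMeasurement",
    "TrajectoryMetrics",
    "ChiasmFateTable",
    "SciaticResult",
    "project_z",
    "count_fibers",
    "axon_lengths",
    "measure_tip",
    "classify_tip_ratio",
    "detect_uturn",
    "trajectory_metrics",
    "classify_chiasm_fates",
    "sciatic_regeneration",
]

TIP_RATIO_THRESHOLD = 4.0
UTURN_ANGLE_DEG = 90.0


# ---------------------------------------------------------------------------
# Z-projections


@dataclass
class ZProjectionSet:
    """Max-intensity projections over groups of consecutive z-slices."""

    projections: List[np.ndarray]
    slice_ranges: List[Tuple[int, int]]     # half-open [start, stop)
    stack: ImageStack
    group: int

    def __len__(self) -> int:
        return len(self.projections)


def project_z(stack: ImageStack, group: int = 4) -> ZProjectionSet:
    """Partition slices into groups of `group` and max-project each.

    ``group`` equal to (or exceeding, with a warning) the slice count gives
    the full maximum-intensity projection.
    """
    if group < 1:
        raise ValueError("group must be >= 1")
    n = stack.n_slices
    if group > n:
        warnings.warn(
            f"group {group} exceeds slice count {n}; producing one full MIP"
        )
        group = n
    projections = []
    ranges = []
    for start in range(0, n, group):
        stop = min(start + group, n)
        projections.append(stack.data[start:stop].max(axis=0))
        ranges.append((start, stop))
    return ZProjectionSet(
        projections=projections, slice_ranges=ranges, stack=stack, group=group
    )


# ---------------------------------------------------------------------------
# interval fiber counts


@dataclass
class RegenerationProfile:
    """Summed fiber counts at each counting distance, plus length stats."""

    distances: np.ndarray               # µm, multiples of the interval
    counts: np.ndarray                  # summed over all projections
    stop_distance: float                # first distance with zero everywhere
    interval: float = 250.0
    top5_mean_length: Optional[float] = None
    per_axon_lengths: Optional[np.ndarray] = None
    meta: dict = field(default_factory=dict)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({"distance_um": self.distances, "count": self.counts})


def _count_runs(line: np.ndarray, threshold: float, min_run: int = 2) -> int:
    """Maximal suprathreshold runs of length >= min_run along a pixel line."""
    above = line > threshold
    if not above.any():
        return 0
    padded = np.concatenate([[False], above, [False]])
    starts = np.flatnonzero(padded[1:] & ~padded[:-1])
    stops = np.flatnonzero(~padded[1:] & padded[:-1])
    return int(np.sum((stops - starts) >= min_run))


def count_fibers(
    projections: ZProjectionSet,
    geometry: NerveGeometry,
    interval: float = 250.0,
    threshold: Optional[float] = None,
    min_run_px: int = 2,
) -> RegenerationProfile:
    """Count fibers crossing lines at k·interval distal to the crush site.

    In every optical-section projection, the counting line perpendicular to
    the nerve axis at each distance is scanned for maximal suprathreshold
    runs of at least ``min_run_px`` pixels; run counts are summed over all
    projections. Scanning stops at the first distance where every projection
    yields zero (the ``stop_distance``); zeros are reported beyond it.

    The default threshold is the stack background estimate (median) plus
    three robust standard deviations.
    """
    stack = projections.stack
    # crush plane in image x-coordinates (axis assumed along image x)
    axis = geometry.axis_vector
    if abs(axis[0]) < 0.99:
        raise GeometryError(
            "count_fibers requires the nerve axis aligned with image x"
        )
    x0_um = geometry.crush[0]
    nx = stack.data.shape[2]
    x_max_um = stack.origin[0] + (nx - 1) * stack.pixel_size_xy
    if not (stack.origin[0] <= x0_um <= x_max_um):
        raise GeometryError("crush plane lies outside the image")
    if threshold is None:
        med = float(np.median(stack.data))
        mad = float(np.median(np.abs(stack.data - med)))
        threshold = med + 3.0 * 1.4826 * mad

    distances = []
    counts = []
    stop_distance = None
    k = 1
    while True:
        d = k * interval
        x_um = x0_um + d
        if x_um > x_max_um:
            break
        col = int(round((x_um - stack.origin[0]) / stack.pixel_size_xy))
        col = min(max(col, 0), nx - 1)
        total = 0
        for proj in projections.projections:
            total += _count_runs(proj[:, col], threshold, min_run_px)
        distances.append(d)
        counts.append(total)
        if total == 0 and stop_distance is None:
            stop_distance = d
        k += 1
    if stop_distance is None:
        stop_distance = k * interval
    distances = np.asarray(distances, dtype=float)
    counts = np.asarray(counts, dtype=int)
    # zeros beyond the stop distance (visibility criterion)
    counts[distances > stop_distance] = 0
    return RegenerationProfile(
        distances=distances,
        counts=counts,
        stop_distance=float(stop_distance),
        interval=interval,
        meta={
            "threshold": threshold,
            "min_run_px": min_run_px,
            "n_projections": len(projections),
            "sum_over_projections": True,   # literal rule: one axon may be
                                            # counted in several sections
        },
    )


# ---------------------------------------------------------------------------
# length statistics


def axon_lengths(
    trees: Sequence[AxonTree], k: int = 5
) -> Tuple[np.ndarray, float]:
    """Per-axon lengths (longest root-to-tip path) and top-k mean.

    With fewer than k axons the mean is over all of them (with a warning).
    Ties are broken by tree order for determinism.
    """
    if len(trees) == 0:
        raise ValueError("no axons: length statistics undefined "
                         "(distinct from zero length)")
    lengths = np.array([t.length() for t in trees])
    if len(lengths) < k:
        warnings.warn(
            f"only {len(lengths)} axons for a top-{k} mean; using all"
        )
        top = lengths
    else:
        order = np.lexsort((np.arange(len(lengths)), -lengths))
        top = lengths[order[:k]]
    return lengths, float(top.mean())


# ---------------------------------------------------------------------------
# tip morphometry


@dataclass
class TipMeasurement:
    """Tip width, adjacent shaft diameter, their ratio, and the class."""

    tip_width: float
    shaft_diameter: float

    @property
    def ratio(self) -> float:
        return self.tip_width / self.shaft_diameter

    @property
    def klass(self) -> str:
        return classify_tip_ratio(self.ratio)


def classify_tip_ratio(ratio: float) -> str:
    """Retraction bulb iff tip/shaft ratio strictly exceeds 4."""
    return "retraction_bulb" if ratio > TIP_RATIO_THRESHOLD else "growth_cone"


def _arc_from_tip(tree: AxonTree, path: List[int]) -> np.ndarray:
    pts = tree.nodes[path]
    seg = np.linalg.norm(np.diff(pts, axis=0), axis=1)
    arc = np.concatenate([[0.0], np.cumsum(seg)])
    return arc[-1] - arc


def measure_tip(
    tree: AxonTree,
    mask: Optional[BinaryMask] = None,
    tip_window: float = 10.0,
    shaft_window: float = 20.0,
    shaft_gap: float = 10.0,
) -> TipMeasurement:
    """Measure the terminal tip width relative to the adjacent shaft.

    Widths are taken on the Z-projection of the mask (the convention for
    whole-mount measurements): local width at a path point = 2 × the
    maximal Euclidean distance transform of the projected mask within 1 µm
    of the point, i.e. the largest inscribed disk there. In image-free mode
    the stored node radii are used instead. The tip width is the maximum
    over the last ``tip_window`` µm of the longest root-to-tip path; the
    shaft diameter is the median width over a ``shaft_window`` starting
    ``shaft_gap`` µm proximal to the tip window.
    """
    path = tree.longest_path()
    rel = _arc_from_tip(tree, path)
    total = rel[0]
    needed = tip_window + shaft_gap + shaft_window
    if total < needed:
        raise InsufficientLengthError(
            f"axon path {total:.1f} µm shorter than the "
            f"{needed:.1f} µm measurement windows"
        )
    tip_sel = rel <= tip_window
    shaft_sel = (rel >= tip_window + shaft_gap) & (
        rel <= tip_window + shaft_gap + shaft_window
    )
    if mask is not None:
        stack = mask.stack
        px = stack.pixel_size_xy
        mask2d = mask.data.max(axis=0)
        edt = ndimage.distance_transform_edt(mask2d, sampling=(px, px))
        pts = tree.nodes[path]
        ry = (pts[:, 1] - stack.origin[1]) / px
        rx = (pts[:, 0] - stack.origin[0]) / px
        h, w = mask2d.shape

        def local_width(k: int, search_um: float) -> float:
            search = max(1, int(math.ceil(search_um / px)))
            y0 = max(int(ry[k]) - search, 0)
            y1 = min(int(ry[k]) + search + 1, h)
            x0 = max(int(rx[k]) - search, 0)
            x1 = min(int(rx[k]) + search + 1, w)
            patch = edt[y0:y1, x0:x1]
            return 2.0 * (float(patch.max()) if patch.size else 0.0)

        # maximal width of the terminal: the largest inscribed disk within
        # tip_window of the terminal point (the tip may bulge off-path)
        tip_width = max(
            local_width(k, tip_window / 2.0)
            for k in np.flatnonzero(tip_sel)
        )
        shaft = float(np.median(
            [local_width(k, 1.0) for k in np.flatnonzero(shaft_sel)]
        ))
    else:
        widths = 2.0 * tree.radius[path]
        tip_width = float(widths[tip_sel].max())
        shaft = float(np.median(widths[shaft_sel]))
    if shaft <= 0:
        raise InsufficientLengthError("degenerate shaft width")
    return TipMeasurement(tip_width=tip_width, shaft_diameter=shaft)


# ---------------------------------------------------------------------------
# U-turns and trajectory metrics


def detect_uturn(
    tree: AxonTree,
    axis=(1.0, 0.0, 0.0),
    direction_window: float = 20.0,
) -> Tuple[float, bool]:
    """Angle between the terminal direction and the longitudinal axis.

    The terminal direction is the chord from the point ``direction_window``
    µm of arc before the terminal to the terminal, on the longest
    root-to-tip path. An angle strictly greater than 90° is a U-turn.
    """
    ax = np.asarray(axis, dtype=float)
    ax = ax / np.linalg.norm(ax)
    tip_dir = tree.terminal_direction(window=direction_window)
    angle = float(np.degrees(np.arccos(np.clip(np.dot(tip_dir, ax), -1.0, 1.0))))
    return angle, angle > UTURN_ANGLE_DEG


@dataclass
class TrajectoryMetrics:
    """Per-nerve U-turn rate and branching index over the selected axons."""

    n_axons_analyzed: int
    uturn_count: int
    tip_count: int
    angles_deg: np.ndarray
    uturn_flags: np.ndarray
    selection: str
    selection_site_um: float = 0.0

    @property
    def uturn_rate(self) -> float:
        return self.uturn_count / self.n_axons_analyzed

    @property
    def branching_index(self) -> float:
        return self.tip_count / self.n_axons_analyzed


def trajectory_metrics(
    trees: Sequence[AxonTree],
    axis=(1.0, 0.0, 0.0),
    selection: Literal["top_20_longest", "all_in_region"] = "top_20_longest",
    n_select: int = 20,
    direction_window: float = 20.0,
    selection_site_um: float = 0.0,
) -> TrajectoryMetrics:
    """U-turn rate and branching index for one nerve.

    ``top_20_longest`` selects the 20 longest axons (all present, with a
    warning, if fewer); ``all_in_region`` analyzes every tree given (the
    chiasm convention). One U-turn is counted per axon, so the rate is
    bounded by 1. The branching index is terminal tips per analyzed axon.
    """
    if len(trees) == 0:
        raise ValueError("no axons to analyze")
    trees = list(trees)
    if selection == "top_20_longest":
        if len(trees) < n_select:
            warnings.warn(
                f"only {len(trees)} axons for top-{n_select} selection; using all"
            )
            chosen = trees
        else:
            lengths = np.array([t.length() for t in trees])
            order = np.lexsort((np.arange(len(trees)), -lengths))
            chosen = [trees[i] for i in order[:n_select]]
    elif selection == "all_in_region":
        chosen = trees
    else:
        raise ValueError(f"unknown selection {selection!r}")
    angles = []
    flags = []
    tips = 0
    for t in chosen:
        angle, is_u = detect_uturn(t, axis=axis, direction_window=direction_window)
        angles.append(angle)
        flags.append(is_u)
        tips += t.n_tips()
    return TrajectoryMetrics(
        n_axons_analyzed=len(chosen),
        uturn_count=int(np.sum(flags)),
        tip_count=tips,
        angles_deg=np.asarray(angles),
        uturn_flags=np.asarray(flags, dtype=bool),
        selection=selection,
        selection_site_um=selection_site_um,
    )


# ---------------------------------------------------------------------------
# chiasm fate classification


@dataclass
class ChiasmFateTable:
    """Counts and fractions of axons per chiasm fate category."""

    counts: dict
    n_axons: int

    @property
    def fractions(self) -> dict:
        if self.n_axons == 0:
            return {k: float("nan") for k in self.counts}
        return {k: v / self.n_axons for k, v in self.counts.items()}

    def to_frame(self) -> pd.DataFrame:
        fr = self.fractions
        return pd.DataFrame(
            {"fate": list(self.counts), "count": list(self.counts.values()),
             "fraction": [fr[k] for k in self.counts]}
        )


def classify_chiasm_fates(
    trees: Sequence[AxonTree],
    geometry: NerveGeometry,
) -> ChiasmFateTable:
    """Assign each axon a fate from the region containing its terminal point.

    A terminal proximal to the OCTZ plane — including axons that turned
    back — is pre-chiasmic. Post-chiasmic terminals are classified by the
    landmark region (ipsi/contra optic tract, contralateral optic nerve)
    containing them; terminals in none go to an explicit ``unassigned``
    bucket, never silently dropped.
    """
    lm = geometry.chiasm
    if lm is None:
        raise GeometryError("geometry has no chiasm landmarks")
    counts = {k: 0 for k in ChiasmLandmarks.FATES}
    counts["unassigned"] = 0
    for tree in trees:
        path = tree.longest_path()
        term = tree.nodes[path[-1]]
        # named post-chiasmic regions take precedence: the contralateral
        # nerve lies anterior of the OCTZ plane but is not pre-chiasmic
        for fate in ("ipsi_tract", "contra_tract", "contra_nerve"):
            if lm.region_for(fate).contains(term):
                counts[fate] += 1
                break
        else:
            if term[0] <= lm.octz_x:
                counts["pre_chiasmic"] += 1
            else:
                counts["unassigned"] += 1
    return ChiasmFateTable(counts=counts, n_axons=len(list(trees)))


# ---------------------------------------------------------------------------
# sciatic nerve


@dataclass
class SciaticResult:
    """Per-axon sciatic lengths with the ≥ min_axons QC flag."""

    lengths: np.ndarray
    qc_pass: bool
    min_axons: int

    @property
    def mean_length(self) -> Optional[float]:
        return float(self.lengths.mean()) if self.qc_pass else None


def sciatic_regeneration(
    trees: Sequence[AxonTree], min_axons: int = 15
) -> SciaticResult:
    """Lengths from the crush site to each distal tip, with QC.

    Nerves with fewer than ``min_axons`` identifiable axons fail QC and are
    excluded from summary statistics (no mean is emitted).
    """
    lengths = np.array([t.length() for t in trees], dtype=float)
    qc = len(lengths) >= min_axons
    if not qc:
        warnings.warn(
            f"QC fail: {len(lengths)} axons < required {min_axons}; "
            "no summary statistics emitted"
        )
    return SciaticResult(lengths=lengths, qc_pass=qc, min_axons=min_axons)
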