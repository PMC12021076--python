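"""High-level quantification pipelines tying the modules together.

These are the entry points the CLI, the analysis scripts and the
acceptance checks share: quantify a nerve from an image stack (binarize →
trace → metrics) or directly from SWC trees (image-free mode), and
quantify a retina pair from rendered fields (detect → count → rates).
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import asdict, is_dataclass
from typing import Optional, Sequence

import numpy as np
import pandas as pd

from . import nerve_metrics as nm
from . import retina_metrics as rm
from .geometry import NerveGeometry
from .simulate import RetinaField
from .stack import ImageStack
from .tracing import binarize, trace_axons
from .trees import AxonTree

__all__ = [
    "config_hash",
    "quantify_nerve_stack",
    "quantify_nerve_trees",
    "quantify_retina_fields",
]


def config_hash(obj) -> str:
    """Stable short hash of a configuration mapping/dataclass."""
    if is_dataclass(obj) and not isinstance(obj, type):
        obj = asdict(obj)

    def default(o):
        if isinstance(o, (np.integer,)):
            return int(o)
        if isinstance(o, (np.floating,)):
            return float(o)
        if isinstance(o, np.ndarray):
            return o.tolist()
        return str(o)

    blob = json.dumps(obj, sort_keys=True, default=default).encode()
    return hashlib.sha256(blob).hexdigest()[:12]


def quantify_nerve_trees(
    trees: Sequence[AxonTree],
    geometry: Optional[NerveGeometry] = None,
    selection: str = "top_20_longest",
    top_k_lengths: int = 5,
    direction_window: float = 20.0,
) -> dict:
    """Image-free quantification from traced/simulated trees.

    Returns per-axon metrics (length, terminal angle, U-turn flag, tips)
    and the nerve-level summary (top-5 mean length, U-turn rate, branching
    index, chiasm fates when landmarks are present).
    """
    geometry = geometry or NerveGeometry()
    lengths, top5 = nm.axon_lengths(trees, k=top_k_lengths)
    traj = nm.trajectory_metrics(
        trees,
        axis=geometry.axis,
        selection=selection,
        direction_window=direction_window,
    )
    per_axon = pd.DataFrame({
        "axon_id": np.arange(len(trees)),
        "length_um": lengths,
        "n_tips": [t.n_tips() for t in trees],
    })
    angles = np.full(len(trees), np.nan)
    flags = np.zeros(len(trees), dtype=bool)
    for i, t in enumerate(trees):
        try:
            a, u = nm.detect_uturn(t, axis=geometry.axis,
                                   direction_window=direction_window)
            angles[i], flags[i] = a, u
        except ValueError:
            pass
    per_axon["angle_deg"] = angles
    per_axon["is_uturn"] = flags
    summary = {
        "n_axons": len(trees),
        "top5_mean_length_um": top5,
        "uturn_rate": traj.uturn_rate,
        "branching_index": traj.branching_index,
        "n_axons_analyzed": traj.n_axons_analyzed,
        "selection": traj.selection,
    }
    out = {"per_axon": per_axon, "summary": summary, "trajectory": traj}
    if geometry.chiasm is not None:
        fates = nm.classify_chiasm_fates(trees, geometry)
        out["fates"] = fates
        summary["fate_fractions"] = fates.fractions
    return out


def quantify_nerve_stack(
    stack: ImageStack,
    geometry: NerveGeometry,
    threshold_method: str = "otsu",
    threshold: Optional[float] = None,
    interval: float = 250.0,
    group: int = 4,
    min_length: float = 50.0,
    selection: str = "top_20_longest",
) -> dict:
    """Full image pipeline: project, count, binarize, trace, measure.

    Combines the interval fiber-count profile (computed on the optical
    sections) with tree-based metrics from the traced mask.
    """
    projections = nm.project_z(stack, group=group)
    mask = binarize(stack, method=threshold_method, threshold=threshold)
    profile = nm.count_fibers(
        projections, geometry, interval=interval, threshold=mask.threshold
    )
    trace = trace_axons(mask, geometry, min_length=min_length)
    out = {"profile": profile, "trace": trace, "mask": mask}
    if trace.trees:
        out.update(
            quantify_nerve_trees(trace.trees, geometry, selection=selection)
        )
        lengths, top5 = nm.axon_lengths(trace.trees)
        profile.per_axon_lengths = lengths
        profile.top5_mean_length = top5
        # tip morphometry against the mask where the axon is long enough
        tips = []
        for i, t in enumerate(trace.trees):
            try:
                m = nm.measure_tip(t, mask)
                tips.append({
                    "axon_id": i, "tip_width_um": m.tip_width,
                    "shaft_diameter_um": m.shaft_diameter,
                    "tip_ratio": m.ratio, "tip_class": m.klass,
                })
            except nm.InsufficientLengthError:
                continue
        out["tips"] = pd.DataFrame(
            tips, columns=["axon_id", "tip_width_um", "shaft_diameter_um",
                           "tip_ratio", "tip_class"]
        )
    return out


def quantify_retina_fields(
    control_fields: Sequence[RetinaField],
    injured_fields: Sequence[RetinaField],
    marker: str = "cre",
    cell_radius: float = 5.0,
    match_radius: float = 6.0,
) -> dict:
    """Detect cells in rendered fields and compute survival and fractions.

    Detection runs on the Tuj1 channel of every field; the marker channel
    (default Cre) is detected per field and matched to Tuj1 centroids to
    form double-positive counts. Returns survival rate (%), marker fraction
    (%) over the control+injured fields, and the per-field count table.
    """
    def field_counts(fields):
        tuj1_counts, double_counts = [], []
        for f in fields:
            tuj1 = rm.detect_cells(
                f.images["tuj1"], cell_radius=cell_radius,
                pixel_size=f.pixel_size,
            )
            tuj1_counts.append(len(tuj1))
            if marker in f.images:
                try:
                    mk = rm.detect_cells(
                        f.images[marker], cell_radius=cell_radius,
                        pixel_size=f.pixel_size,
                    )
                except Exception:
                    mk = pd.DataFrame(columns=["x_um", "y_um"])
                double_counts.append(rm.match_channels(tuj1, mk, radius=match_radius))
            else:
                double_counts.append(0)
        return tuj1_counts, double_counts

    ctrl_tuj1, ctrl_double = field_counts(control_fields)
    inj_tuj1, inj_double = field_counts(injured_fields)
    rate, per_field = rm.survival_rate(inj_tuj1, ctrl_tuj1)
    total_tuj1 = sum(ctrl_tuj1) + sum(inj_tuj1)
    total_double = sum(ctrl_double) + sum(inj_double)
    frac = rm.marker_fraction(total_double, total_tuj1) if total_tuj1 else float("nan")
    return {
        "survival_rate_pct": rate,
        "marker_fraction_pct": frac,
        "per_field": per_field,
        "counts": {
            "control_tuj1": ctrl_tuj1, "injured_tuj1": inj_tuj1,
            "control_double": ctrl_double, "injured_double": inj_double,
        },
    }
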