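"""Synthetic ground-truth generator for nerve and retina quantification.

This module produces the three kinds of synthetic data the quantification
pipeline is validated against:

* regenerating-axon trajectories emanating from a crush plane — correlated
  random walks with a truncated-exponential extension law, optional terminal
  U-turns (a smooth reversal arc through more than 90°), Poisson branch
  events along the arc, and terminal morphologies drawn from a retraction
  bulb / growth cone mixture with controllable tip-to-shaft width ratios;
* fluorescence rasterizations of those trajectories — tubes on a voxel grid
  with Gaussian PSF blur, Poisson shot noise and Gaussian read noise;
* whole-mount retina fields of marker-positive cells with controllable
  densities, co-expression fractions and intensity distributions.

Every simulation is a pure function of its config (including the seed):
identical config + seed give bit-identical output. Per-axon random
substreams are derived from the root seed by counter, so adding axons does
not perturb earlier ones.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np
import pandas as pd
from scipy import ndimage

from .errors import ConfigurationError, ResourceError
from .geometry import ChiasmLandmarks, NerveGeometry
from .stack import ImageStack
from .trees import AxonTree

__all__ = [
    "NerveSimConfig",
    "ImagingConfig",
    "RetinaSimConfig",
    "GroundTruth",
    "RetinaField",
    "simulate_nerve",
    "simulate_chiasm",
    "rasterize_stack",
    "simulate_retina_pair",
    "count_plane_crossings",
]

#: width-ratio threshold separating retraction bulbs from growth cones
TIP_RATIO_THRESHOLD = 4.0

#: arc length (µm) of the terminal region widened to the tip ratio
TIP_WIDEN_LENGTH = 6.0


# ---------------------------------------------------------------------------
# configs


@dataclass(frozen=True)
class NerveSimConfig:
    """Parameters of the regenerating-nerve simulation (lengths in µm)."""

    n_axons: int = 20
    crush_x: float = 0.0
    nerve_length: float = 1500.0
    nerve_radius: float = 100.0
    length_scale: float = 400.0
    step: float = 5.0
    tortuosity_sd: float = 8.0          # degrees per step
    p_uturn: float = 0.0
    branch_rate: float = 0.0            # events per mm of arc length
    p_bulb: float = 0.0
    bulb_ratio_range: Tuple[float, float] = (5.0, 8.0)
    gc_ratio_range: Tuple[float, float] = (1.0, 2.0)
    shaft_diameter: float = 2.0
    seed: int = 0
    #: optional fixed per-axon extension lengths, replacing the length law
    lengths: Optional[Tuple[float, ...]] = None
    #: minimum extension so terminal-direction windows are well defined
    min_length: float = 60.0
    #: per-step fraction of the heading angle relaxed back toward the
    #: longitudinal axis (guidance bias); 0 gives a pure correlated random
    #: walk whose lateral drift grows ballistically, values ~0.05-0.2 give
    #: the bounded meander of guided regeneration
    heading_reversion: float = 0.05
    #: confine trajectories to the plane of their entry point (z constant),
    #: emulating a nerve imaged within a single optical section
    planar: bool = False
    #: minimum µm between axon entry points on the crush plane
    #: (None → 3 × shaft_diameter); keeps tubes resolvable in the image
    min_start_separation: Optional[float] = None

    def __post_init__(self):
        pos = {
            "nerve_length": self.nerve_length,
            "nerve_radius": self.nerve_radius,
            "length_scale": self.length_scale,
            "step": self.step,
            "shaft_diameter": self.shaft_diameter,
        }
        for name, val in pos.items():
            if not np.isfinite(val) or val <= 0:
                raise ConfigurationError(f"{name} must be positive and finite")
        if self.n_axons < 0:
            raise ConfigurationError("n_axons must be non-negative")
        if not np.isfinite(self.tortuosity_sd) or self.tortuosity_sd < 0:
            raise ConfigurationError("tortuosity_sd must be >= 0")
        if not np.isfinite(self.branch_rate) or self.branch_rate < 0:
            raise ConfigurationError("branch_rate must be >= 0")
        for name, p in (("p_uturn", self.p_uturn), ("p_bulb", self.p_bulb),
                        ("heading_reversion", self.heading_reversion)):
            if not (0.0 <= p <= 1.0):
                raise ConfigurationError(f"{name} must lie in [0, 1]")
        lo, hi = self.bulb_ratio_range
        if not (TIP_RATIO_THRESHOLD < lo <= hi):
            raise ConfigurationError(
                "bulb_ratio_range must lie entirely above the ratio threshold 4"
            )
        lo, hi = self.gc_ratio_range
        if not (0 < lo <= hi < TIP_RATIO_THRESHOLD):
            raise ConfigurationError(
                "gc_ratio_range must lie entirely below the ratio threshold 4"
            )
        if self.lengths is not None:
            object.__setattr__(self, "lengths", tuple(float(v) for v in self.lengths))
            if len(self.lengths) != self.n_axons:
                raise ConfigurationError("lengths must have one entry per axon")
            if any(v <= 0 or not np.isfinite(v) for v in self.lengths):
                raise ConfigurationError("fixed lengths must be positive and finite")


@dataclass(frozen=True)
class ImagingConfig:
    """Confocal imaging model: voxel sizes, PSF, and noise."""

    pixel_size_xy: float = 1.0
    z_spacing: float = 2.0
    psf_sigma: float = 0.0              # µm; 0 disables blur
    background: float = 10.0
    photon_scale: float = 50.0          # intensity per µm of axon thickness
    read_noise_sd: float = 0.0
    noise: bool = True                  # Poisson shot + Gaussian read noise
    seed: int = 0

    def __post_init__(self):
        if self.pixel_size_xy <= 0 or self.z_spacing <= 0:
            raise ConfigurationError("voxel sizes must be positive")
        if self.psf_sigma < 0:
            raise ConfigurationError("psf_sigma must be >= 0")
        if self.read_noise_sd < 0:
            raise ConfigurationError("read_noise_sd must be >= 0")


@dataclass(frozen=True)
class RetinaSimConfig:
    """Parameters of the whole-mount retina field simulation."""

    field_size: Tuple[float, float] = (500.0, 500.0)   # µm
    n_fields: int = 15
    cell_density: float = 2000.0        # cells per mm^2
    survival_fraction: float = 1.0      # injured density / control density
    cre_fraction: float = 0.0           # P(Cre+ | Tuj1+)
    ps6_fraction: float = 0.0           # P(p-S6+ | Tuj1+)
    cell_radius: float = 5.0            # µm
    intensity_mean: float = 200.0
    intensity_sd: float = 30.0
    noise_sd: float = 3.0
    background: float = 10.0
    pixel_size: float = 1.0             # µm per pixel for rendered fields
    seed: int = 0

    def __post_init__(self):
        if self.cell_density <= 0:
            raise ConfigurationError("cell_density must be positive")
        for name, p in (
            ("survival_fraction", self.survival_fraction),
            ("cre_fraction", self.cre_fraction),
            ("ps6_fraction", self.ps6_fraction),
        ):
            if not (0.0 <= p <= 1.0):
                raise ConfigurationError(f"{name} must lie in [0, 1]")
        if self.cell_radius <= 0 or self.pixel_size <= 0:
            raise ConfigurationError("cell_radius and pixel_size must be positive")
        if self.n_fields < 1:
            raise ConfigurationError("n_fields must be >= 1")


# ---------------------------------------------------------------------------
# ground truth containers


@dataclass
class GroundTruth:
    """Simulated nerve with exact per-axon labels and crossing counts.

    ``labels`` has one row per axon: uturn_flag, tip_class, true_tip_ratio,
    length_um, n_tips, and (for chiasm simulations) fate. ``crossing_table``
    gives the exact number of axon-plane crossings at each 250-µm distance,
    computed from the polylines themselves.
    """

    geometry: NerveGeometry
    axons: List[AxonTree]
    labels: pd.DataFrame
    crossing_table: pd.DataFrame
    config: Optional[NerveSimConfig] = None


@dataclass
class RetinaField:
    """One rendered retina field: channel images plus true cell records."""

    images: Dict[str, np.ndarray]
    cells: pd.DataFrame             # columns x_um, y_um, cre, ps6, intensity
    field_size: Tuple[float, float]
    pixel_size: float


# ---------------------------------------------------------------------------
# plane crossings


def count_plane_crossings(
    trees: Sequence[AxonTree],
    geometry: NerveGeometry,
    interval: float = 250.0,
    max_distance: Optional[float] = None,
) -> pd.DataFrame:
    """Exact count of tree-edge crossings of planes at k*interval distal.

    A segment (a, b) crosses the plane at distance d iff
    ``min(da, db) < d <= max(da, db)`` where da, db are axial distances, so
    an axon ending exactly on a counting plane is counted there.
    """
    if max_distance is None:
        max_distance = geometry.nerve_length
    distances = np.arange(interval, max_distance + 1e-9, interval)
    counts = np.zeros(len(distances), dtype=int)
    for tree in trees:
        d = np.asarray(geometry.axial_distance(tree.nodes)).reshape(-1)
        for i, p in enumerate(tree.parent):
            if p < 0:
                continue
            lo, hi = sorted((d[p], d[i]))
            counts += (lo < distances) & (distances <= hi)
    return pd.DataFrame({"distance_um": distances, "count": counts})


# ---------------------------------------------------------------------------
# nerve simulation internals


def _axon_rng(seed: int, index: int) -> np.random.Generator:
    # counter-based substream: axon i always sees the same stream
    return np.random.default_rng(np.random.SeedSequence(seed, spawn_key=(index,)))


def _truncated_exponential(rng, scale: float, upper: float) -> float:
    # inverse-CDF sample of Exp(scale) conditioned on (0, upper)
    u = rng.uniform()
    return -scale * math.log1p(-u * (1.0 - math.exp(-upper / scale)))


def _rotate_towards(direction: np.ndarray, target: np.ndarray, angle: float) -> np.ndarray:
    """Rotate `direction` by `angle` radians in the plane spanned with `target`."""
    d = direction / np.linalg.norm(direction)
    t = target / np.linalg.norm(target)
    perp = t - np.dot(t, d) * d
    n = np.linalg.norm(perp)
    if n < 1e-12:
        # pick an arbitrary perpendicular when (anti)parallel
        perp = np.array([-d[1], d[0], 0.0])
        n = np.linalg.norm(perp)
        if n < 1e-12:
            perp = np.array([0.0, -d[2], d[1]])
            n = np.linalg.norm(perp)
    perp /= n
    remaining = math.acos(np.clip(np.dot(d, t), -1.0, 1.0))
    a = min(angle, remaining)
    return d * math.cos(a) + perp * math.sin(a)


def _perturb(rng, direction: np.ndarray, sd_deg: float) -> np.ndarray:
    if sd_deg <= 0:
        return direction
    theta = math.radians(rng.normal(0.0, sd_deg))
    # random axis perpendicular to the current direction
    v = rng.normal(size=3)
    v -= np.dot(v, direction) * direction
    n = np.linalg.norm(v)
    if n < 1e-12:
        return direction
    v /= n
    out = direction * math.cos(theta) + v * math.sin(theta)
    return out / np.linalg.norm(out)


#: maximum heading deviation from the longitudinal axis during forward
#: growth (degrees); keeps the U-turn label unambiguous — only an explicit
#: reversal arc can push the terminal direction past 90°
FORWARD_CONE_DEG = 80.0


def _diverge(rng, direction: np.ndarray, lo_deg: float, hi_deg: float,
             planar: bool = False) -> np.ndarray:
    """Rotate `direction` by an angle in [lo, hi] degrees about a random
    perpendicular axis (sign-symmetric in-plane rotation when planar)."""
    angle = math.radians(rng.uniform(lo_deg, hi_deg))
    if planar:
        sign = 1.0 if rng.uniform() < 0.5 else -1.0
        c, s = math.cos(sign * angle), math.sin(sign * angle)
        out = np.array([
            c * direction[0] - s * direction[1],
            s * direction[0] + c * direction[1],
            0.0,
        ])
        return out / np.linalg.norm(out)
    v = rng.normal(size=3)
    v -= np.dot(v, direction) * direction
    n = np.linalg.norm(v)
    if n < 1e-12:
        v = np.array([0.0, 1.0, 0.0])
        n = 1.0
    v /= n
    out = direction * math.cos(angle) + v * math.sin(angle)
    return out / np.linalg.norm(out)


def _walk(
    rng,
    start: np.ndarray,
    direction: np.ndarray,
    length: float,
    cfg: NerveSimConfig,
    confine: bool = True,
    planar: bool = False,
) -> List[np.ndarray]:
    """Correlated random walk of total arc `length` from `start`.

    The heading is confined to a forward cone about +x so that trajectories
    without an explicit reversal never exceed the 90° U-turn criterion.
    With ``planar`` the walk stays in its starting z-plane. Near the nerve
    wall the heading is steered gently (bounded turn) back toward the core.
    """
    pts = [start.copy()]
    d = direction.astype(float).copy()
    if planar:
        d[2] = 0.0
    d /= np.linalg.norm(d)
    cone_cos = math.cos(math.radians(FORWARD_CONE_DEG))
    n_steps = max(1, int(round(length / cfg.step)))
    for _ in range(n_steps):
        d = _perturb(rng, d, cfg.tortuosity_sd)
        if planar:
            d[2] = 0.0
            n = np.linalg.norm(d)
            if n < 1e-12:
                d = np.array([1.0, 0.0, 0.0])
            else:
                d = d / n
        off_axis = math.acos(np.clip(d[0], -1.0, 1.0))
        if cfg.heading_reversion > 0 and off_axis > 1e-9:
            d = _rotate_towards(d, np.array([1.0, 0.0, 0.0]),
                                cfg.heading_reversion * off_axis)
        if d[0] < cone_cos:
            d = _rotate_towards(
                d, np.array([1.0, 0.0, 0.0]),
                math.acos(np.clip(d[0], -1.0, 1.0)) - math.radians(FORWARD_CONE_DEG),
            )
        nxt = pts[-1] + d * cfg.step
        if confine:
            lateral = nxt[1:]
            r = np.linalg.norm(lateral)
            rmax = 0.92 * cfg.nerve_radius
            if r > rmax:
                nxt[1:] = lateral * (rmax / r)
                # steer gently back toward the nerve core (bounded turn)
                inward = np.array([max(d[0], 0.2), -lateral[0], -lateral[1]])
                d = _rotate_towards(d, inward / np.linalg.norm(inward),
                                    math.radians(20.0))
            nxt[0] = min(nxt[0], cfg.crush_x + cfg.nerve_length)
        pts.append(nxt)
    return pts


def _append_uturn(rng, pts: List[np.ndarray], cfg: NerveSimConfig) -> None:
    """Append a smooth reversal arc so the terminal heading points backward.

    The turn sweeps the heading toward a direction ~160° off +x over several
    steps, then runs straight long enough that any terminal-direction window
    of up to ~40 µm sees an angle well above 90°.
    """
    d = pts[-1] - pts[-2]
    d = d / np.linalg.norm(d)
    back = np.array([-1.0, 0.0, 0.0])
    # small lateral tilt so the reversed segment does not retrace itself
    tilt = rng.uniform(-0.3, 0.3, size=2)
    if cfg.planar:
        tilt[1] = 0.0
    target = back + np.array([0.0, tilt[0], tilt[1]])
    target /= np.linalg.norm(target)
    turn_steps = 6
    for _ in range(turn_steps):
        d = _rotate_towards(d, target, math.radians(170.0) / turn_steps)
        pts.append(pts[-1] + d * cfg.step)
    run = max(45.0, 2.0 * cfg.step)
    for _ in range(int(round(run / cfg.step))):
        d = _perturb(rng, d, min(cfg.tortuosity_sd, 3.0))
        if d[0] > -0.5:   # keep the reversed run clearly backward
            d = _rotate_towards(d, target, math.radians(25.0))
        pts.append(pts[-1] + d * cfg.step)


def _widen_tip(radius: np.ndarray, arc_from_tip: np.ndarray, ratio: float,
               shaft_radius: float) -> None:
    """Set radii over the terminal TIP_WIDEN_LENGTH µm to ratio×shaft."""
    sel = arc_from_tip <= TIP_WIDEN_LENGTH
    radius[sel] = ratio * shaft_radius


def _build_axon(
    rng,
    cfg: NerveSimConfig,
    length: float,
    make_uturn: bool,
    start: np.ndarray,
) -> Tuple[AxonTree, dict]:
    shaft_r = cfg.shaft_diameter / 2.0
    pts = _walk(rng, start, np.array([1.0, 0.0, 0.0]), length, cfg,
                planar=cfg.planar)
    if make_uturn:
        _append_uturn(rng, pts, cfg)
    main = np.asarray(pts)
    if cfg.planar:
        main[:, 2] = start[2]
    n_main = len(main)

    # branch events: Poisson along the main arc, away from root and terminal
    seg = np.linalg.norm(np.diff(main, axis=0), axis=1)
    arc = np.concatenate([[0.0], np.cumsum(seg)])
    total_arc = arc[-1]
    branches: List[np.ndarray] = []
    attach_idx: List[int] = []
    if cfg.branch_rate > 0 and total_arc > 150.0:
        n_branch = rng.poisson(cfg.branch_rate * total_arc / 1000.0)
        for _ in range(n_branch):
            pos = rng.uniform(0.15, 0.6) * total_arc
            j = int(np.searchsorted(arc, pos))
            j = min(max(j, 1), n_main - 2)
            local = main[j + 1] - main[j - 1]
            local /= np.linalg.norm(local)
            # branches diverge by a definite angle off the parent shaft so
            # the daughter separates from the trunk tube
            bdir = _diverge(rng, local, 25.0, 60.0, planar=cfg.planar)
            hi_len = max(35.0, min(100.0, 0.5 * (total_arc - arc[j])))
            blen = rng.uniform(30.0, hi_len)
            bpts = _walk(rng, main[j].copy(), bdir, blen, cfg,
                         planar=cfg.planar)
            barr = np.asarray(bpts[1:])
            if cfg.planar:
                barr[:, 2] = start[2]
            branches.append(barr)
            attach_idx.append(j)

    # assemble node arrays
    nodes = [main]
    parent = list(range(-1, n_main - 1))
    for bp, j in zip(branches, attach_idx):
        base = sum(len(a) for a in nodes)
        nodes.append(bp)
        parent.extend([j] + list(range(base, base + len(bp) - 1)))
    all_nodes = np.vstack(nodes)
    radius = np.full(len(all_nodes), shaft_r)

    # tip morphology: the main terminal carries the drawn class/ratio;
    # branch tips are slim growth-cone-like terminals
    is_bulb = rng.uniform() < cfg.p_bulb
    if is_bulb:
        tip_ratio = rng.uniform(*cfg.bulb_ratio_range)
    else:
        tip_ratio = rng.uniform(*cfg.gc_ratio_range)
    arc_from_tip = total_arc - arc
    _widen_tip(radius[:n_main], arc_from_tip, tip_ratio, shaft_r)
    offset = n_main
    for bp in branches:
        bseg = np.linalg.norm(np.diff(bp, axis=0), axis=1)
        barc = np.concatenate([[0.0], np.cumsum(bseg)])
        b_ratio = rng.uniform(*cfg.gc_ratio_range)
        _widen_tip(radius[offset:offset + len(bp)], barc[-1] - barc, b_ratio, shaft_r)
        offset += len(bp)

    tree = AxonTree(nodes=all_nodes, radius=radius, parent=np.array(parent))
    info = {
        "uturn_flag": bool(make_uturn),
        "tip_class": "bulb" if is_bulb else "growth_cone",
        "true_tip_ratio": float(tip_ratio),
        "length_um": float(tree.length()),
        "n_tips": int(tree.n_tips()),
    }
    tree.labels.update(info)
    return tree, info


# ---------------------------------------------------------------------------
# public simulators


def simulate_nerve(config: NerveSimConfig) -> GroundTruth:
    """Simulate regenerating axons from a crush plane with exact labels.

    Deterministic for a fixed seed. Each axon is a correlated random walk
    starting on the crush plane heading distal (+x); extension lengths follow
    a truncated-exponential law (or the fixed list in ``config.lengths``);
    with probability ``p_uturn`` a smooth reversal arc is appended so the
    terminal direction exceeds 90° to the axis; branch events form a Poisson
    process along arc length; terminal tip classes and true width ratios are
    drawn from the configured bulb/growth-cone mixture. The crossing table is
    computed exactly from the polylines.
    """
    geometry = NerveGeometry(
        crush_position=(config.crush_x, 0.0, 0.0),
        axis=(1.0, 0.0, 0.0),
        nerve_length=config.nerve_length,
        nerve_radius=config.nerve_radius,
    )
    axons: List[AxonTree] = []
    rows = []
    min_sep = (
        config.min_start_separation
        if config.min_start_separation is not None
        else 3.0 * config.shaft_diameter
    )
    accepted_starts: List[np.ndarray] = []
    for i in range(config.n_axons):
        rng = _axon_rng(config.seed, i)
        if config.lengths is not None:
            length = config.lengths[i]
        else:
            length = _truncated_exponential(
                rng, config.length_scale, 0.95 * config.nerve_length
            )
            length = max(length, config.min_length)
        make_uturn = bool(rng.uniform() < config.p_uturn)
        if make_uturn:
            # leave room for the reversal arc without re-entering the crush plane
            length = max(length, 150.0)
        # entry-point placement uses its own per-axon substream so adding
        # axons never perturbs earlier trajectories; rejection against the
        # already-placed entries enforces the minimum separation
        place_rng = np.random.default_rng(
            np.random.SeedSequence(config.seed, spawn_key=(1, i))
        )
        start = None
        for _attempt in range(200):
            if config.planar:
                cand = np.array([
                    config.crush_x,
                    place_rng.uniform(-0.8, 0.8) * config.nerve_radius,
                    0.0,
                ])
            else:
                r0 = 0.8 * config.nerve_radius * math.sqrt(place_rng.uniform())
                phi = place_rng.uniform(0.0, 2.0 * math.pi)
                cand = np.array(
                    [config.crush_x, r0 * math.cos(phi), r0 * math.sin(phi)]
                )
            if all(
                np.linalg.norm(cand[1:] - q[1:]) >= min_sep
                for q in accepted_starts
            ):
                start = cand
                break
        if start is None:
            start = cand    # saturated crush plane: accept the last draw
        accepted_starts.append(start)
        tree, info = _build_axon(rng, config, length, make_uturn, start)
        info["axon_id"] = i
        axons.append(tree)
        rows.append(info)
    labels = pd.DataFrame(
        rows,
        columns=["axon_id", "uturn_flag", "tip_class", "true_tip_ratio",
                 "length_um", "n_tips"],
    )
    crossings = count_plane_crossings(axons, geometry)
    return GroundTruth(
        geometry=geometry, axons=axons, labels=labels,
        crossing_table=crossings, config=config,
    )


def simulate_chiasm(
    config: NerveSimConfig,
    chiasm_landmarks: Optional[ChiasmLandmarks] = None,
    fate_probs: Sequence[float] = (0.6, 0.3, 0.05, 0.05),
) -> GroundTruth:
    """Simulate axons approaching the optic chiasm with ground-truth fates.

    ``fate_probs`` gives the probabilities of (pre_chiasmic, ipsi_tract,
    contra_tract, contra_nerve) in that order; terminal points are placed in
    the corresponding landmark region. Turned-back (U-turn) axons arise only
    among the pre-chiasmic fraction, consistent with the fate definition that
    a terminal proximal to the OCTZ is pre-chiasmic.
    """
    lm = chiasm_landmarks or ChiasmLandmarks()
    fate_probs = np.asarray(fate_probs, dtype=float)
    if fate_probs.shape != (4,) or np.any(fate_probs < 0):
        raise ConfigurationError("fate_probs must be 4 non-negative numbers")
    if abs(fate_probs.sum() - 1.0) > 1e-9:
        raise ConfigurationError("fate probabilities must sum to 1")

    nerve_len = max(config.nerve_length, lm.ipsi_tract.xmax + 50.0)
    geometry = NerveGeometry(
        crush_position=(config.crush_x, lm.nerve_y, 0.0),
        axis=(1.0, 0.0, 0.0),
        nerve_length=nerve_len,
        nerve_radius=config.nerve_radius,
        chiasm=lm,
    )
    shaft_r = config.shaft_diameter / 2.0
    fates = list(ChiasmLandmarks.FATES)
    axons: List[AxonTree] = []
    rows = []
    for i in range(config.n_axons):
        rng = _axon_rng(config.seed, i)
        fate = fates[rng.choice(4, p=fate_probs)]
        start = np.array([
            config.crush_x,
            lm.nerve_y + rng.uniform(-0.4, 0.4) * config.nerve_radius,
            rng.uniform(-0.3, 0.3) * config.nerve_radius,
        ])
        if fate == "pre_chiasmic":
            term = np.array([
                config.crush_x + rng.uniform(0.3, 0.92) * (lm.octz_x - config.crush_x),
                lm.nerve_y + rng.uniform(-0.5, 0.5) * config.nerve_radius,
                rng.uniform(-0.3, 0.3) * config.nerve_radius,
            ])
            waypoints = [start, term]
        else:
            region = lm.region_for(fate)
            term = region.sample(rng, margin=8.0)
            entry = np.array([
                lm.octz_x,
                0.6 * lm.nerve_y + rng.uniform(-15.0, 15.0),
                rng.uniform(-10.0, 10.0),
            ])
            waypoints = [start, entry, term]
        pts = _polyline_with_jitter(rng, waypoints, config.step,
                                    min(config.tortuosity_sd, 4.0))
        make_uturn = fate == "pre_chiasmic" and rng.uniform() < config.p_uturn
        if make_uturn:
            _append_uturn(rng, pts, config)
            # a reversal must stay proximal to the OCTZ to remain pre-chiasmic
            for p in pts:
                p[0] = min(p[0], lm.octz_x - 10.0)
        main = np.asarray(pts)
        radius = np.full(len(main), shaft_r)
        is_bulb = rng.uniform() < config.p_bulb
        ratio = rng.uniform(*(config.bulb_ratio_range if is_bulb
                              else config.gc_ratio_range))
        seg = np.linalg.norm(np.diff(main, axis=0), axis=1)
        arc = np.concatenate([[0.0], np.cumsum(seg)])
        _widen_tip(radius, arc[-1] - arc, ratio, shaft_r)
        tree = AxonTree(
            nodes=main, radius=radius,
            parent=np.arange(-1, len(main) - 1),
        )
        info = {
            "axon_id": i,
            "uturn_flag": bool(make_uturn),
            "tip_class": "bulb" if is_bulb else "growth_cone",
            "true_tip_ratio": float(ratio),
            "length_um": float(tree.length()),
            "n_tips": int(tree.n_tips()),
            "fate": fate,
        }
        tree.labels.update(info)
        axons.append(tree)
        rows.append(info)
    labels = pd.DataFrame(
        rows,
        columns=["axon_id", "uturn_flag", "tip_class", "true_tip_ratio",
                 "length_um", "n_tips", "fate"],
    )
    crossings = count_plane_crossings(axons, geometry, max_distance=nerve_len)
    return GroundTruth(
        geometry=geometry, axons=axons, labels=labels,
        crossing_table=crossings, config=config,
    )


def _polyline_with_jitter(rng, waypoints, step, sd_deg) -> List[np.ndarray]:
    """Piecewise walk through waypoints with angular jitter, exact endpoints."""
    pts = [np.asarray(waypoints[0], dtype=float)]
    for target in waypoints[1:]:
        target = np.asarray(target, dtype=float)
        while True:
            vec = target - pts[-1]
            dist = np.linalg.norm(vec)
            if dist <= step:
                pts.append(target.copy())
                break
            d = _perturb(rng, vec / dist, sd_deg)
            pts.append(pts[-1] + d * step)
    return pts


# ---------------------------------------------------------------------------
# rasterization


#: default cap on rasterized voxel count (~0.5 GiB float32)
MAX_VOXELS = 2 ** 27


def rasterize_stack(
    truth: GroundTruth,
    imaging: ImagingConfig,
    pad: float = 12.0,
    max_voxels: int = MAX_VOXELS,
    allow_large: bool = False,
) -> ImageStack:
    """Render ground-truth axons as fluorescent tubes on a voxel grid.

    Axons are drawn as tubes of their per-node radius (the terminal region
    already widened to the true tip ratio by the simulator); voxel intensity
    inside a tube is ``photon_scale × local thickness``. The expected image
    is blurred by a Gaussian PSF; with ``imaging.noise`` on, Poisson shot
    noise and Gaussian read noise are applied on top of the constant
    background. With ``psf_sigma = 0`` and noise off, thresholding just above
    background recovers the exact tube rasterization.
    """
    all_nodes = (
        np.vstack([t.nodes for t in truth.axons if t.n_nodes])
        if any(t.n_nodes for t in truth.axons)
        else np.zeros((1, 3))
    )
    max_r = max(
        (float(t.radius.max()) for t in truth.axons if t.n_nodes), default=1.0
    )
    margin = pad + max_r + 4.0 * imaging.psf_sigma
    lo = all_nodes.min(axis=0) - margin
    hi = all_nodes.max(axis=0) + margin
    # include the crush plane so distances are measurable on the image
    lo[0] = min(lo[0], truth.geometry.crush[0] - pad)
    # snap the origin to the voxel grid: voxel centres then sit on integer
    # multiples of the voxel size, so translation of the scene by whole
    # voxels reproduces the same rasterization and the z = 0 midplane of a
    # planar nerve coincides with a slice centre
    steps = np.array(
        [imaging.pixel_size_xy, imaging.pixel_size_xy, imaging.z_spacing]
    )
    origin = np.floor(lo / steps) * steps
    nx = int(math.ceil((hi[0] - lo[0]) / imaging.pixel_size_xy)) + 1
    ny = int(math.ceil((hi[1] - lo[1]) / imaging.pixel_size_xy)) + 1
    nz = int(math.ceil((hi[2] - lo[2]) / imaging.z_spacing)) + 1
    if nx * ny * nz > max_voxels and not allow_large:
        raise ResourceError(
            f"voxel grid {nz}x{ny}x{nx} exceeds cap {max_voxels}; "
            "pass allow_large=True to override"
        )
    img = np.zeros((nz, ny, nx), dtype=np.float32)
    vs = np.array([imaging.z_spacing, imaging.pixel_size_xy, imaging.pixel_size_xy])

    for tree in truth.axons:
        for i, p in enumerate(tree.parent):
            if p < 0:
                _stamp_ball(img, origin, vs, tree.nodes[i], tree.radius[i],
                            imaging.photon_scale)
                continue
            a, b = tree.nodes[p], tree.nodes[i]
            ra, rb = tree.radius[p], tree.radius[i]
            seg_len = np.linalg.norm(b - a)
            n_samp = max(2, int(math.ceil(seg_len / (vs.min() / 2.0))) + 1)
            for t in np.linspace(0.0, 1.0, n_samp):
                _stamp_ball(img, origin, vs, a + t * (b - a),
                            ra + t * (rb - ra), imaging.photon_scale)

    if imaging.psf_sigma > 0:
        sigma_vox = imaging.psf_sigma / vs
        img = ndimage.gaussian_filter(img, sigma=sigma_vox)
    expected = img + imaging.background
    if imaging.noise:
        rng = np.random.default_rng(imaging.seed)
        out = rng.poisson(expected).astype(np.float32)
        if imaging.read_noise_sd > 0:
            out += rng.normal(0.0, imaging.read_noise_sd, out.shape).astype(
                np.float32
            )
    else:
        out = expected.astype(np.float32)
    return ImageStack(
        data=out,
        pixel_size_xy=imaging.pixel_size_xy,
        z_spacing=imaging.z_spacing,
        origin=tuple(origin),
    )


def _stamp_ball(img, origin, vs, center_um, radius, photon_scale) -> None:
    """Set voxels within `radius` of the centre to the tube intensity."""
    # centre in (z, y, x) voxel coordinates
    cz = (center_um[2] - origin[2]) / vs[0]
    cy = (center_um[1] - origin[1]) / vs[1]
    cx = (center_um[0] - origin[0]) / vs[2]
    rz, ry, rx = radius / vs[0], radius / vs[1], radius / vs[2]
    z0, z1 = int(math.floor(cz - rz)), int(math.ceil(cz + rz))
    y0, y1 = int(math.floor(cy - ry)), int(math.ceil(cy + ry))
    x0, x1 = int(math.floor(cx - rx)), int(math.ceil(cx + rx))
    z0, y0, x0 = max(z0, 0), max(y0, 0), max(x0, 0)
    z1 = min(z1, img.shape[0] - 1)
    y1 = min(y1, img.shape[1] - 1)
    x1 = min(x1, img.shape[2] - 1)
    if z1 < z0 or y1 < y0 or x1 < x0:
        return
    zz, yy, xx = np.ogrid[z0:z1 + 1, y0:y1 + 1, x0:x1 + 1]
    dist2 = (
        ((zz - cz) * vs[0]) ** 2
        + ((yy - cy) * vs[1]) ** 2
        + ((xx - cx) * vs[2]) ** 2
    )
    inside = dist2 <= radius * radius
    amp = photon_scale * 2.0 * radius
    region = img[z0:z1 + 1, y0:y1 + 1, x0:x1 + 1]
    np.maximum(region, np.where(inside, amp, 0.0), out=region)


# ---------------------------------------------------------------------------
# retina simulation


def _place_cells(rng, n: int, size, min_sep: float) -> np.ndarray:
    """Uniform non-overlapping placement; raises if the field saturates."""
    placed: List[np.ndarray] = []
    attempts = 0
    cap = max(2000, 80 * max(n, 1))
    while len(placed) < n:
        attempts += 1
        if attempts > cap:
            raise ConfigurationError(
                "cell density too high for non-overlapping placement"
            )
        cand = rng.uniform([min_sep, min_sep],
                           [size[0] - min_sep, size[1] - min_sep])
        if all(np.linalg.norm(cand - q) >= min_sep for q in placed):
            placed.append(cand)
    return np.asarray(placed) if placed else np.zeros((0, 2))


def _render_field(rng, cells: pd.DataFrame, cfg: RetinaSimConfig) -> Dict[str, np.ndarray]:
    w = int(round(cfg.field_size[0] / cfg.pixel_size))
    h = int(round(cfg.field_size[1] / cfg.pixel_size))
    yy, xx = np.mgrid[0:h, 0:w]
    images = {}
    for channel, flag_col in (("tuj1", None), ("cre", "cre"), ("ps6", "ps6")):
        img = np.full((h, w), cfg.background, dtype=np.float32)
        for _, cell in cells.iterrows():
            if flag_col is not None and not cell[flag_col]:
                continue
            cx = cell["x_um"] / cfg.pixel_size
            cy = cell["y_um"] / cfg.pixel_size
            r = cfg.cell_radius / cfg.pixel_size
            x0, x1 = max(int(cx - r) - 1, 0), min(int(cx + r) + 2, w)
            y0, y1 = max(int(cy - r) - 1, 0), min(int(cy + r) + 2, h)
            sub_y, sub_x = yy[y0:y1, x0:x1], xx[y0:y1, x0:x1]
            inside = (sub_x - cx) ** 2 + (sub_y - cy) ** 2 <= r * r
            patch = img[y0:y1, x0:x1]
            patch[inside] = np.maximum(
                patch[inside], cfg.background + cell[f"i_{channel}"]
            )
        if cfg.noise_sd > 0:
            img = img + rng.normal(0.0, cfg.noise_sd, img.shape).astype(np.float32)
        images[channel] = img
    return images


def simulate_retina_pair(
    config: RetinaSimConfig, render: bool = True
) -> Tuple[List[RetinaField], List[RetinaField], pd.DataFrame]:
    """Simulate paired control / injured whole-mount retina field sets.

    Control fields draw cell counts from Poisson(cell_density × area);
    injured fields use ``cell_density × survival_fraction``. Every Tuj1+
    cell is Cre+ with probability ``cre_fraction`` and p-S6+ with
    probability ``ps6_fraction``, independently. Returns (control fields,
    injured fields, truth table) where truth has one row per field with the
    exact counts. ``render=False`` skips image rendering (cell records
    only), for count-level studies.
    """
    rng = np.random.default_rng(config.seed)
    area_mm2 = config.field_size[0] * config.field_size[1] / 1e6
    truth_rows = []
    arms: Dict[str, List[RetinaField]] = {"control": [], "injured": []}
    for arm, dens in (
        ("control", config.cell_density),
        ("injured", config.cell_density * config.survival_fraction),
    ):
        for f in range(config.n_fields):
            n = rng.poisson(dens * area_mm2)
            pos = _place_cells(rng, n, config.field_size, 2.2 * config.cell_radius)
            cre = rng.uniform(size=n) < config.cre_fraction
            ps6 = rng.uniform(size=n) < config.ps6_fraction
            inten = {
                ch: np.clip(
                    rng.normal(config.intensity_mean, config.intensity_sd, n),
                    0.2 * config.intensity_mean, None,
                )
                for ch in ("tuj1", "cre", "ps6")
            }
            cells = pd.DataFrame({
                "x_um": pos[:, 0] if n else np.zeros(0),
                "y_um": pos[:, 1] if n else np.zeros(0),
                "cre": cre, "ps6": ps6,
                "i_tuj1": inten["tuj1"],
                "i_cre": inten["cre"],
                "i_ps6": inten["ps6"],
            })
            images = _render_field(rng, cells, config) if render else {}
            arms[arm].append(RetinaField(
                images=images, cells=cells,
                field_size=config.field_size, pixel_size=config.pixel_size,
            ))
            truth_rows.append({
                "arm": arm, "field": f, "n_cells": int(n),
                "n_cre": int(cre.sum()), "n_ps6": int(ps6.sum()),
            })
    truth = pd.DataFrame(truth_rows)
    return arms["control"], arms["injured"], truth
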