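"""Synthetic-data generators with known ground truth for every pipeline stage.

Each generator emulates one input class of the study — confocal volumes with
puncta/fibril/cell channels, foraging-arena event logs, behavioral-battery
feature vectors, and solubility-fractionated protein intensity tables — and
returns the exact planted structure alongside the data, so every downstream
quantification can be checked against truth.  All generators are
deterministic given their seed.

What the image generator emulates (and what it does not): puncta are
isotropic 3-D Gaussians (in-plane sigma 1 px, axial 0.5 slices) over additive
background with Poisson noise, which reproduces the blob statistics that make
thresholding nontrivial but is not an optical PSF model; fibrils are
random-walk polylines dilated to a small radius, giving connected-component
and box-counting statistics comparable to interstitial-matrix images.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import tifffile
from scipy import ndimage

from .behavior import FEEDER_ZONES, ForagingSession, ZoneEvent
from .classify import FEATURES, MIDDLE_AGED, YOUNG, CohortFeatures
from .containers import DEFAULT_VOXEL_SIZE, ImageStack
from .proteomics import FRACTION_ORDER, IntensityTable

# ---------------------------------------------------------------------------
# images
# ---------------------------------------------------------------------------


@dataclass
class ImageParams:
    """Knobs for :func:`gen_image_stack`.

    Defaults follow the imaging conditions of the analysis: 512x512x20
    voxels at 0.125 µm/px in-plane and 0.3 µm z-step, so that the 4-px
    proximity shell spans 0.5 µm.
    """

    shape: tuple[int, int, int] = (20, 512, 512)  # (z, y, x)
    voxel_size: tuple[float, float, float] = DEFAULT_VOXEL_SIZE
    puncta_counts: dict[str, int] = field(default_factory=dict)  # channel -> n puncta
    fibril_counts: dict[str, int] = field(default_factory=dict)  # channel -> n fibrils
    cell_counts: dict[str, int] = field(default_factory=dict)  # channel -> n cells
    enrichment_factor: float = 1.0  # puncta density in fibril shell vs outside
    shell_px: int = 4
    fibril_steps: int = 60
    fibril_step_px: float = 3.0
    fibril_radius_px: int = 1
    soma_radius_um: float = 4.0
    n_rays: int = 4
    ray_length_um: float = 25.0
    ray_angles: tuple[float, ...] | None = None  # fixed angles override n_rays
    puncta_sigma: tuple[float, float, float] = (0.5, 1.0, 1.0)  # (z slices, y px, x px)
    amplitude: float = 200.0
    background: float = 8.0
    poisson_noise: bool = True


@dataclass
class ImageGroundTruth:
    """Exact planted object placements for one synthetic field of view."""

    puncta_centroids: dict[str, np.ndarray]  # channel -> (n, 3) float voxel coords
    fibril_skeletons: dict[str, np.ndarray]  # channel -> (m, 3) int voxel coords
    fibril_radius_px: int
    cell_somata: dict[str, list[dict]]  # channel -> [{center_vox, radius_um, rays}]
    enrichment_factor: float
    shell_px: int
    voxel_size: tuple[float, float, float]
    seed: int


def _fibril_skeleton(rng: np.random.Generator, shape, steps: int, step_px: float) -> np.ndarray:
    """Random-walk polyline voxels, mostly in-plane, clipped to the volume."""
    nz, ny, nx = shape
    pos = np.array([rng.uniform(0, nz), rng.uniform(0, ny), rng.uniform(0, nx)])
    theta = rng.uniform(0, 2 * np.pi)
    voxels = []
    for _ in range(steps):
        theta += rng.normal(0, 0.4)
        dz = rng.normal(0, 0.15)
        step = np.array([dz, np.sin(theta), np.cos(theta)]) * step_px
        new = pos + step
        for t in np.linspace(0, 1, int(step_px) * 2 + 1):
            p = np.round(pos + t * step).astype(int)
            if (p >= 0).all() and (p < np.array(shape)).all():
                voxels.append(tuple(p))
        pos = np.clip(new, 0, np.array(shape) - 1)
    return np.array(sorted(set(voxels)), dtype=int) if voxels else np.empty((0, 3), int)


def _disk(radius: int) -> np.ndarray:
    yy, xx = np.mgrid[-radius : radius + 1, -radius : radius + 1]
    return yy * yy + xx * xx <= radius * radius


def _render_mask_volume(shape, voxels: np.ndarray, radius_px: int) -> np.ndarray:
    vol = np.zeros(shape, dtype=bool)
    if len(voxels):
        vol[voxels[:, 0], voxels[:, 1], voxels[:, 2]] = True
        if radius_px >= 1:
            disk = _disk(radius_px)
            for z in range(shape[0]):
                vol[z] = ndimage.binary_dilation(vol[z], structure=disk)
    return vol


def _inplane_shell_map(fibril_mask: np.ndarray, shell_px: int) -> np.ndarray:
    """Voxels within ``shell_px`` (in-plane Euclidean) of the fibril mask."""
    inside = np.zeros_like(fibril_mask)
    for z in range(fibril_mask.shape[0]):
        if fibril_mask[z].any():
            dist = ndimage.distance_transform_edt(~fibril_mask[z])
            inside[z] = dist <= shell_px
    return inside


def gen_image_stack(
    params: ImageParams | None = None, seed: int = 0
) -> tuple[ImageStack, ImageGroundTruth]:
    """Generate one multi-channel confocal-like field of view.

    Fibril channels are rendered first; puncta channels are placed by
    rejection sampling against the in-plane distance map of the first
    fibril channel so that the planted density ratio inside vs outside the
    ``shell_px`` fibril shell equals ``enrichment_factor`` exactly (in
    expectation).  Cell channels hold spherical somata with straight radial
    processes.  All channels get additive background and Poisson noise.
    """
    params = params or ImageParams()
    shape = params.shape
    if any(s <= 0 for s in shape):
        raise ValueError("volume dimensions must be positive")
    if params.enrichment_factor < 0:
        raise ValueError("enrichment_factor must be >= 0")
    n_vox = int(np.prod(shape))
    for ch, n in params.puncta_counts.items():
        if n < 0:
            raise ValueError(f"negative puncta count for {ch!r}")
        if n > n_vox:
            raise ValueError(f"{n} puncta exceed volume capacity ({n_vox} voxels)")
    rng = np.random.default_rng(seed)
    dz, dy, dx = params.voxel_size

    channels: dict[str, np.ndarray] = {}
    skeletons: dict[str, np.ndarray] = {}
    fibril_mask = None
    for ch, n_fib in params.fibril_counts.items():
        vox_all: list[np.ndarray] = []
        for _ in range(n_fib):
            vox_all.append(
                _fibril_skeleton(rng, shape, params.fibril_steps, params.fibril_step_px)
            )
        skel = np.vstack(vox_all) if vox_all else np.empty((0, 3), int)
        skeletons[ch] = skel
        mask = _render_mask_volume(shape, skel, params.fibril_radius_px)
        channels[ch] = mask.astype(float) * params.amplitude
        if fibril_mask is None:
            fibril_mask = mask

    inside_map = None
    if fibril_mask is not None and fibril_mask.any() and params.enrichment_factor != 1.0:
        inside_map = _inplane_shell_map(fibril_mask, params.shell_px)

    puncta: dict[str, np.ndarray] = {}
    e = params.enrichment_factor
    for ch, n_p in params.puncta_counts.items():
        pts = np.empty((n_p, 3))
        accepted = 0
        guard = 0
        while accepted < n_p:
            guard += 1
            if guard > 1000 * max(n_p, 1):
                raise RuntimeError("rejection sampling failed to place puncta")
            p = rng.uniform(0, 1, 3) * (np.array(shape) - 1)
            if inside_map is not None:
                is_in = bool(inside_map[tuple(np.round(p).astype(int))])
                accept = (e / max(e, 1.0)) if is_in else (1.0 / max(e, 1.0))
                if rng.uniform() > accept:
                    continue
            pts[accepted] = p
            accepted += 1
        puncta[ch] = pts
        vol = np.zeros(shape, dtype=float)
        for p in np.round(pts).astype(int):
            vol[tuple(p)] += params.amplitude
        channels[ch] = ndimage.gaussian_filter(vol, sigma=params.puncta_sigma)

    somata: dict[str, list[dict]] = {}
    for ch, n_cells in params.cell_counts.items():
        vol = np.zeros(shape, dtype=bool)
        cells = []
        margin_px = int((params.soma_radius_um + params.ray_length_um) / dx) + 2
        for _ in range(n_cells):
            cz = shape[0] // 2
            cy = int(rng.integers(min(margin_px, shape[1] // 2), max(shape[1] - margin_px, shape[1] // 2) + 1))
            cx = int(rng.integers(min(margin_px, shape[2] // 2), max(shape[2] - margin_px, shape[2] // 2) + 1))
            zz, yy, xx = np.mgrid[0 : shape[0], 0 : shape[1], 0 : shape[2]]
            r2 = ((zz - cz) * dz) ** 2 + ((yy - cy) * dy) ** 2 + ((xx - cx) * dx) ** 2
            vol |= r2 <= params.soma_radius_um**2
            if params.ray_angles is not None:
                angles = np.asarray(params.ray_angles, float)
            else:
                angles = rng.uniform(0, 2 * np.pi, params.n_rays)
            rays = []
            for a in angles:
                length = params.ray_length_um
                # ~2 px wide so a 1°-sampled Sholl circle cannot step over it
                for t in np.arange(0, length + dx / 2, dx / 4):
                    fy = cy + t * np.sin(a) / dy
                    fx = cx + t * np.cos(a) / dx
                    for py in (int(np.floor(fy)), int(np.ceil(fy))):
                        for px in (int(np.floor(fx)), int(np.ceil(fx))):
                            if 0 <= py < shape[1] and 0 <= px < shape[2]:
                                for zoff in (-1, 0, 1):
                                    if 0 <= cz + zoff < shape[0]:
                                        vol[cz + zoff, py, px] = True
                rays.append({"angle_rad": float(a), "length_um": float(length)})
            cells.append(
                {"center_vox": (cz, cy, cx), "radius_um": params.soma_radius_um, "rays": rays}
            )
        somata[ch] = cells
        channels[ch] = vol.astype(float) * params.amplitude

    for ch in list(channels):
        img = channels[ch] + params.background
        if params.poisson_noise:
            img = rng.poisson(img).astype(float)
        channels[ch] = img
    if not channels:  # all densities zero: background-only single channel
        img = np.full(shape, params.background, dtype=float)
        if params.poisson_noise:
            img = rng.poisson(img).astype(float)
        channels["background"] = img

    stack = ImageStack(channels, params.voxel_size)
    truth = ImageGroundTruth(
        puncta_centroids=puncta,
        fibril_skeletons=skeletons,
        fibril_radius_px=params.fibril_radius_px,
        cell_somata=somata,
        enrichment_factor=params.enrichment_factor,
        shell_px=params.shell_px,
        voxel_size=params.voxel_size,
        seed=seed,
    )
    return stack, truth


# ---------------------------------------------------------------------------
# foraging sessions
# ---------------------------------------------------------------------------


@dataclass
class ForagingParams:
    """Cohort layout and planted learning structure for the foraging task.

    Defaults mirror the study design: 18 mice per age group, 25 encode
    sessions (5 weeks at 5 days/week), interleaved 2 h and 24 h probes, and
    a win-stay rule (the first feeder visited at the encoded location is
    correct).
    """

    group_sizes: dict[str, int] = field(default_factory=lambda: {YOUNG: 18, MIDDLE_AGED: 18})
    n_encode: int = 25
    n_probes_each: int = 4  # per probe type
    probe_p_correct: dict[str, dict[str, float]] = field(
        default_factory=lambda: {
            YOUNG: {"probe2h": 0.7, "probe24h": 0.7},
            MIDDLE_AGED: {"probe2h": 0.65, "probe24h": 0.45},
        }
    )
    learning_trial: dict[str, int] = field(
        default_factory=lambda: {YOUNG: 8, MIDDLE_AGED: 10}
    )
    p_pre: float = 0.15
    p_post: float = 0.9
    probe_duration_s: int = 120
    perimeter_proportion: float = 0.3
    speed_cm_s: float = 8.0


@dataclass
class BehaviorGroundTruth:
    """Planted behavioral structure (foraging and/or battery)."""

    learning_trial: dict[str, int] = field(default_factory=dict)  # mouse -> trial index
    probe_p_correct: dict[str, dict[str, float]] = field(default_factory=dict)
    cluster_membership: dict[str, int] = field(default_factory=dict)  # mouse -> cluster
    age_group: dict[str, str] = field(default_factory=dict)
    seed: int = 0


def _probe_session(
    rng: np.random.Generator,
    mouse: str,
    session_idx: int,
    trial_type: str,
    p_correct: float,
    params: ForagingParams,
) -> ForagingSession:
    correct = FEEDER_ZONES[int(rng.integers(0, 4))]
    events: list[ZoneEvent] = []
    t = 0
    latency = int(rng.integers(2, 9))
    events.append(ZoneEvent("start_box", 0, latency, 0.0))
    t = latency
    # first feeder choice: correct with probability p_correct
    if rng.uniform() < p_correct:
        order = [correct]
    else:
        order = [rng.choice([f for f in FEEDER_ZONES if f != correct])]
    remaining = [f for f in FEEDER_ZONES if f not in order]
    rng.shuffle(remaining)
    for f in remaining:
        if order[-1] == correct:
            break
        order.append(f)
    # mice keep searching until they hit the encoded feeder
    if correct not in order:
        order.append(correct)
        order = order[: order.index(correct) + 1]
    for f in order:
        travel = int(rng.integers(3, 8))
        zone = "perimeter" if rng.uniform() < params.perimeter_proportion else "center"
        events.append(ZoneEvent(zone, t, t + travel, params.speed_cm_s * travel))
        t += travel
        dwell = int(rng.integers(3, 7))
        events.append(ZoneEvent(f, t, t + dwell, 0.0))
        t += dwell
    # fill the rest of the session alternating perimeter / center
    while t < params.probe_duration_s:
        dur = min(int(rng.integers(5, 15)), params.probe_duration_s - t)
        zone = "perimeter" if rng.uniform() < params.perimeter_proportion else "center"
        events.append(ZoneEvent(zone, t, t + dur, params.speed_cm_s * dur * 0.5))
        t += dur
    return ForagingSession(mouse, session_idx, trial_type, events, correct_feeder=correct)


def gen_foraging_cohort(
    params: ForagingParams | None = None, seed: int = 0
) -> tuple[list[ForagingSession], BehaviorGroundTruth]:
    """Simulate a foraging cohort with a planted per-mouse learning trial.

    Encode-session outcomes are Bernoulli with success probability stepping
    from ``p_pre`` to ``p_post`` at the planted learning trial; probe
    sessions carry full zone-event logs whose first feeder choice is
    correct with the planted probe probability and whose subsequent visits
    sample the remaining feeders without replacement until the correct one.
    """
    params = params or ForagingParams()
    for grp, n in params.group_sizes.items():
        if n < 1:
            raise ValueError(f"group {grp!r} must have >= 1 mouse")
    for grp, probes in params.probe_p_correct.items():
        for name, p in probes.items():
            if not 0.0 <= p <= 1.0:
                raise ValueError(f"probe probability {name} for {grp!r} outside [0, 1]")
    if not 0.0 <= params.p_pre <= 1.0 or not 0.0 <= params.p_post <= 1.0:
        raise ValueError("encode probabilities outside [0, 1]")
    rng = np.random.default_rng(seed)
    sessions: list[ForagingSession] = []
    truth = BehaviorGroundTruth(probe_p_correct=dict(params.probe_p_correct), seed=seed)
    for grp, n in params.group_sizes.items():
        for i in range(n):
            mouse = f"{grp}_{i:02d}"
            truth.age_group[mouse] = grp
            lt = params.learning_trial[grp]
            truth.learning_trial[mouse] = lt
            for s in range(1, params.n_encode + 1):
                p = params.p_post if s >= lt else params.p_pre
                outcome = int(rng.uniform() < p)
                events = [
                    ZoneEvent("start_box", 0, int(rng.integers(2, 9)), 0.0),
                    ZoneEvent("center", 10, 290, params.speed_cm_s * 120),
                ]
                sessions.append(
                    ForagingSession(mouse, s, "encode", events, outcome=outcome)
                )
            idx = params.n_encode
            for probe_type in ("probe2h", "probe24h"):
                for _ in range(params.n_probes_each):
                    idx += 1
                    sessions.append(
                        _probe_session(
                            rng, mouse, idx, probe_type,
                            params.probe_p_correct[grp][probe_type], params,
                        )
                    )
    return sessions, truth


# ---------------------------------------------------------------------------
# behavioral battery
# ---------------------------------------------------------------------------


@dataclass
class BatteryParams:
    """Two planted behavioral clusters in the three battery features.

    ``separation_sd`` is the per-feature distance between cluster means in
    units of the feature SD (each feature shifts by that many SDs, toward
    the impaired direction: more perimeter time, lower discrimination,
    lower alternation).  Cohort layout defaults to the study: 12 young and
    24 middle-aged mice, with 75% of young and ~46% of middle-aged in the
    unimpaired cluster.
    """

    n_young: int = 12
    n_middle: int = 24
    separation_sd: float = 3.0
    feature_sd: tuple[float, float, float] = (0.06, 0.12, 0.08)
    cluster1_mean: tuple[float, float, float] = (0.50, 0.35, 0.65)
    young_majority: float = 0.75
    middle_in_cluster1: float = 0.46


def gen_behavior_battery(
    params: BatteryParams | None = None, seed: int = 0
) -> tuple[CohortFeatures, BehaviorGroundTruth]:
    """Generate battery feature vectors with two planted clusters."""
    params = params or BatteryParams()
    if any(s < 0 for s in params.feature_sd):
        raise ValueError("negative feature SD")
    rng = np.random.default_rng(seed)
    sd = np.array(params.feature_sd)
    mean1 = np.array(params.cluster1_mean)
    direction = np.array([1.0, -1.0, -1.0])  # impaired: anxious, poor DI, poor AI
    mean2 = mean1 + direction * params.separation_sd * sd

    n_young_c1 = int(round(params.young_majority * params.n_young))
    n_mid_c1 = int(round(params.middle_in_cluster1 * params.n_middle))
    rows = []
    truth = BehaviorGroundTruth(seed=seed)
    mice = [(f"Y{i:02d}", YOUNG, 1 if i < n_young_c1 else 2) for i in range(params.n_young)]
    mice += [
        (f"M{i:02d}", MIDDLE_AGED, 1 if i < n_mid_c1 else 2) for i in range(params.n_middle)
    ]
    for mouse, age, cluster in mice:
        mean = mean1 if cluster == 1 else mean2
        feat = rng.normal(mean, sd)
        feat[0] = float(np.clip(feat[0], 0.0, 1.0))  # perimeter proportion
        feat[1] = float(np.clip(feat[1], -1.0, 1.0))  # discrimination index
        feat[2] = float(np.clip(feat[2], 0.0, 1.0))  # alternation index
        rows.append({"mouse_id": mouse, "age_group": age, **dict(zip(FEATURES, feat))})
        truth.cluster_membership[mouse] = cluster
        truth.age_group[mouse] = age
    return CohortFeatures(pd.DataFrame(rows)), truth


# ---------------------------------------------------------------------------
# proteome
# ---------------------------------------------------------------------------

PROTEIN_CLASSES = ("matrisome", "synapse", "innate-immune", "microglia-enriched", "other")


@dataclass
class ProteomeParams:
    """Fraction-structured log-normal intensity model with planted age effects.

    Defaults follow the proteomic design: 4 mice per age group, five
    solubility fractions per mouse, log2-normal noise of 0.25 SD, and a
    +1 log2 aged/young effect planted on the matrisome class.  ``dropout``
    is the missing-at-random rate.
    """

    n_proteins: int = 400
    mice_per_group: int = 4
    fractions: tuple[str, ...] = FRACTION_ORDER
    class_proportions: dict[str, float] = field(
        default_factory=lambda: {
            "matrisome": 0.12,
            "synapse": 0.12,
            "innate-immune": 0.08,
            "microglia-enriched": 0.05,
            "other": 0.63,
        }
    )
    planted_log2fc: float = 1.0  # aged/young effect on matrisome proteins
    solubility_shift_log2: float = 0.0  # extra aged effect in the most soluble fraction
    noise_sd: float = 0.25
    dropout: float = 0.1
    region: str = "midbrain"


@dataclass
class ProteomeGroundTruth:
    protein_class: pd.Series  # protein -> class
    effects: pd.DataFrame  # protein x fraction planted log2 aged effects
    fraction_offsets: pd.DataFrame  # class x fraction mean log2 offsets
    noise_sd: float
    seed: int


def gen_proteome(
    params: ProteomeParams | None = None, seed: int = 0
) -> tuple[IntensityTable, ProteomeGroundTruth]:
    """Generate a raw (linear-scale) intensity table with planted effects."""
    params = params or ProteomeParams()
    if params.mice_per_group < 2:
        raise ValueError("need >= 2 mice per age group")
    if params.solubility_shift_log2 != 0.0 and len(params.fractions) < 2:
        raise ValueError("solubility shifts need >= 2 fractions")
    if not 0.0 <= params.dropout < 1.0:
        raise ValueError("dropout must lie in [0, 1)")
    rng = np.random.default_rng(seed)

    proteins = [f"P{i:04d}" for i in range(params.n_proteins)]
    classes = list(params.class_proportions)
    probs = np.array([params.class_proportions[c] for c in classes], float)
    probs /= probs.sum()
    cls = pd.Series(rng.choice(classes, size=params.n_proteins, p=probs), index=proteins)

    # solubility profile: matrisome skews insoluble, everything else soluble
    n_f = len(params.fractions)
    offsets = pd.DataFrame(index=classes, columns=list(params.fractions), dtype=float)
    grad = np.linspace(1.0, -1.0, n_f)
    for c in classes:
        offsets.loc[c] = -grad if c == "matrisome" else grad

    effects = pd.DataFrame(0.0, index=proteins, columns=list(params.fractions))
    matrisome = cls.index[cls == "matrisome"]
    effects.loc[matrisome, :] = params.planted_log2fc
    if params.solubility_shift_log2 != 0.0:
        effects.loc[matrisome, params.fractions[0]] += params.solubility_shift_log2

    base = rng.normal(20.0, 1.5, params.n_proteins)
    cols: dict[str, np.ndarray] = {}
    meta_rows = []
    for age in (YOUNG, "aged"):
        for m in range(params.mice_per_group):
            mouse = f"{age}_{m}"
            sex = "M" if m % 2 == 0 else "F"
            for f in params.fractions:
                log2_mean = (
                    base
                    + offsets.loc[cls.to_numpy(), f].to_numpy(float)
                    + (effects[f].to_numpy() if age == "aged" else 0.0)
                )
                vals = 2.0 ** (log2_mean + rng.normal(0.0, params.noise_sd, params.n_proteins))
                drop = rng.uniform(size=params.n_proteins) < params.dropout
                vals = np.where(drop, np.nan, vals)
                sid = f"{mouse}__{f}"
                cols[sid] = vals
                meta_rows.append(
                    pd.Series(
                        {
                            "mouse": mouse,
                            "age_group": age,
                            "sex": sex,
                            "region": params.region,
                            "fraction": f,
                            "cognitive_status": None,
                        },
                        name=sid,
                    )
                )
    table = IntensityTable(
        values=pd.DataFrame(cols, index=proteins),
        samples=pd.DataFrame(meta_rows),
        proteins=pd.DataFrame({"protein_class": cls}),
        log2=False,
    )
    truth = ProteomeGroundTruth(cls, effects, offsets, params.noise_sd, seed)
    return table, truth


# ---------------------------------------------------------------------------
# file round-trips (TIFF stacks, CSV event logs, CSV intensity tables)
# ---------------------------------------------------------------------------


def write_image_stack(stack: ImageStack, path: str, truth: ImageGroundTruth | None = None) -> None:
    """Write a multi-channel TIFF (axes ZCYX) plus an optional JSON sidecar."""
    names = stack.channel_names
    arr = np.stack([stack[c] for c in names], axis=1).astype(np.float32)
    tifffile.imwrite(
        path,
        arr,
        metadata={"axes": "ZCYX", "channels": names, "voxel_size_um": list(stack.voxel_size)},
    )
    if truth is not None:
        side = {
            "puncta_centroids": {c: v.tolist() for c, v in truth.puncta_centroids.items()},
            "fibril_skeletons": {c: v.tolist() for c, v in truth.fibril_skeletons.items()},
            "fibril_radius_px": truth.fibril_radius_px,
            "cell_somata": truth.cell_somata,
            "enrichment_factor": truth.enrichment_factor,
            "shell_px": truth.shell_px,
            "voxel_size": list(truth.voxel_size),
            "seed": truth.seed,
        }
        with open(str(path) + ".json", "w") as fh:
            json.dump(side, fh)


def read_image_stack(path: str) -> ImageStack:
    with tifffile.TiffFile(path) as tf:
        arr = tf.asarray()
        meta = tf.shaped_metadata[0] if tf.shaped_metadata else {}
    names = meta.get("channels", [f"ch{i}" for i in range(arr.shape[1])])
    voxel = tuple(meta.get("voxel_size_um", DEFAULT_VOXEL_SIZE))
    return ImageStack({c: arr[:, i].astype(float) for i, c in enumerate(names)}, voxel)


_LOG_COLUMNS = [
    "mouse_id", "session", "trial_type", "zone",
    "t_start_s", "t_end_s", "distance_cm", "correct_feeder", "outcome",
]


def write_event_log(sessions: list[ForagingSession], path: str) -> None:
    """Write sessions as a long CSV of 1-s-resolution zone events."""
    rows = []
    for s in sessions:
        for e in s.sorted_events():
            rows.append(
                (s.mouse_id, s.session, s.trial_type, e.zone, e.t_start_s, e.t_end_s,
                 e.distance_cm, s.correct_feeder or "", "" if s.outcome is None else s.outcome)
            )
    pd.DataFrame(rows, columns=_LOG_COLUMNS).to_csv(path, index=False)


def read_event_log(path: str) -> list[ForagingSession]:
    df = pd.read_csv(path, keep_default_na=False)
    sessions = []
    for (mouse, idx, ttype), sub in df.groupby(
        ["mouse_id", "session", "trial_type"], sort=False
    ):
        events = [
            ZoneEvent(r.zone, float(r.t_start_s), float(r.t_end_s), float(r.distance_cm))
            for r in sub.itertuples()
        ]
        correct = sub["correct_feeder"].iloc[0] or None
        raw_outcome = str(sub["outcome"].iloc[0])
        outcome = int(float(raw_outcome)) if raw_outcome not in ("", "nan") else None
        sessions.append(ForagingSession(str(mouse), int(idx), str(ttype), events, correct, outcome))
    return sessions


def write_intensity_table(table: IntensityTable, path: str) -> None:
    """Long-format CSV: protein, sample, fraction + metadata, intensity."""
    long = table.values.stack(future_stack=True).rename("intensity").reset_index()
    long.columns = ["protein", "sample", "intensity"]
    long = long.merge(table.samples, left_on="sample", right_index=True)
    long = long.merge(
        table.proteins, left_on="protein", right_index=True, how="left"
    )
    long["log2"] = table.log2
    long.to_csv(path, index=False)


def read_intensity_table(path: str) -> IntensityTable:
    long = pd.read_csv(path)
    values = long.pivot(index="protein", columns="sample", values="intensity")
    from .proteomics import SAMPLE_COLUMNS

    samples = long.drop_duplicates("sample").set_index("sample")[list(SAMPLE_COLUMNS)]
    values = values[samples.index]
    proteins = (
        long.drop_duplicates("protein").set_index("protein")[["protein_class"]]
    )
    return IntensityTable(values, samples, proteins.loc[values.index], bool(long["log2"].iloc[0]))


def write_cohort_features(features: CohortFeatures, path: str) -> None:
    features.frame.to_csv(path, index=False)


def read_cohort_features(path: str) -> CohortFeatures:
    return CohortFeatures(pd.read_csv(path))
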