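"""Ground-truth-labelled synthetic inputs for every pipeline stage.

Three generators emulate the raw material the analysis stages consume, each
with a known latent state so recovery can be checked exactly:

- :func:`simulate_localizations` — a PALM-style localization map inside a
  7 x 7 µm ROI: receptor complexes of configured sizes, localization noise,
  and Poisson photoblinking duplicates, with true complex membership
  recorded per emitted point.
- :func:`simulate_poses` — rigid docking poses with sampled tilt and
  z-offset, so the membrane-topology filter can be validated against a
  ground-truth accept set.
- :func:`simulate_bret` — noisy saturation / one-phase-association /
  dose-response BRET curves from known parameters.

All randomness flows from one ``numpy.random.default_rng(seed)`` per call;
identical config + seed gives bit-identical output.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, asdict
from typing import Callable, Mapping

import numpy as np
import pandas as pd

from .palm import LocalizationMap
from .poses import DockPose
from .structures import StructureModel

__all__ = [
    "PalmSimConfig",
    "PoseSimConfig",
    "BretSimConfig",
    "PalmGroundTruth",
    "PoseGroundTruth",
    "SimulationError",
    "simulate_localizations",
    "simulate_poses",
    "simulate_bret",
    "synthetic_protomer",
]


class SimulationError(RuntimeError):
    """Raised when a requested simulation is infeasible (e.g. packing)."""


# ---------------------------------------------------------------------------
# configs
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class PalmSimConfig:
    """Configuration of the localization-map simulator.

    counts_per_size maps oligomer size -> number of complexes, e.g.
    ``{1: 50, 2: 30}`` places 50 monomers and 30 dimers.  Each complex of
    size s puts s true receptors uniformly in a disc of
    ``cluster_radius_nm`` around a center drawn uniformly in the ROI
    (optionally with a minimum center separation).  Each receptor emits one
    localization displaced by N(0, loc_error_sd_nm) plus
    Poisson(blink_rate) duplicates displaced by N(0, blink_sd_nm).
    """

    counts_per_size: Mapping[int, int]
    seed: int
    roi_width_nm: float = 7000.0
    roi_height_nm: float = 7000.0
    cluster_radius_nm: float = 10.0
    loc_error_sd_nm: float = 10.0
    blink_rate: float = 0.0
    blink_sd_nm: float = 5.0
    min_center_sep_nm: float | None = None

    def __post_init__(self):
        if self.roi_width_nm <= 0 or self.roi_height_nm <= 0:
            raise ValueError("ROI dimensions must be positive")
        if self.cluster_radius_nm < 0 or self.loc_error_sd_nm < 0:
            raise ValueError("lengths must be non-negative")
        if self.blink_rate < 0 or self.blink_sd_nm < 0:
            raise ValueError("blink parameters must be non-negative")
        for size, count in self.counts_per_size.items():
            if size < 1 or count < 0:
                raise ValueError("oligomer sizes must be >= 1 and counts >= 0")
        if self.min_center_sep_nm is not None and self.min_center_sep_nm <= 0:
            raise ValueError("min_center_sep_nm must be positive when set")


@dataclass(frozen=True)
class PoseSimConfig:
    """Configuration of the docking-pose simulator.

    Tilt is sampled uniformly from ``tilt_range`` (radians, within [0, pi])
    about a random in-plane axis, composed with a random spin about z;
    z-offset is sampled uniformly from ``zoffset_range`` (Å).  The accept
    flag in the ground truth is evaluated at (``tilt_max_rad``,
    ``z_offset_max_A``) — the thresholds the downstream filter will use.
    ``score_model`` maps pose index to score (monotone decreasing default).
    """

    n_poses: int
    seed: int
    tilt_range: tuple[float, float] = (0.0, 0.8)
    zoffset_range: tuple[float, float] = (-12.0, 12.0)
    tilt_max_rad: float = 0.4
    z_offset_max_A: float = 6.0
    xy_range_A: float = 30.0
    score_model: Callable[[int], float] | None = None

    def __post_init__(self):
        if self.n_poses <= 0:
            raise ValueError("n_poses must be positive")
        lo, hi = self.tilt_range
        if not (0 <= lo <= hi <= np.pi):
            raise ValueError("tilt_range must satisfy 0 <= lo <= hi <= pi")
        if self.zoffset_range[0] > self.zoffset_range[1]:
            raise ValueError("zoffset_range must be increasing")


@dataclass(frozen=True)
class BretSimConfig:
    """Configuration of the BRET-curve simulator.

    mode selects the model:

    - ``saturation``:    y = BRETmax * x / (BRET50 + x)
    - ``kinetics``:      y = plateau * (1 - exp(-k * t))
    - ``dose_response``: y = baseline + (Emax - baseline) / (1 + EC50/conc)

    ``grid`` holds the x values (acceptor/donor ratio, time in s, or molar
    concentration); Gaussian noise of sd ``noise_sd`` is added
    independently per point and replicate.
    """

    mode: str
    grid: tuple[float, ...]
    seed: int
    noise_sd: float = 0.0
    replicates: int = 1
    bretmax: float = 0.3
    bret50: float = 0.05
    k_per_s: float = 0.02
    plateau: float = 0.05
    ec50_m: float = 4.34e-6
    emax: float = 1.0
    baseline: float = 0.0

    def __post_init__(self):
        if self.mode not in ("saturation", "kinetics", "dose_response"):
            raise ValueError(f"unknown mode {self.mode!r}")
        grid = np.asarray(self.grid, dtype=float)
        if len(grid) == 0 or np.any(np.diff(grid) <= 0):
            raise ValueError("grid must be non-empty and strictly increasing")
        for name in ("bretmax", "bret50", "k_per_s", "plateau", "ec50_m", "emax"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be non-negative")
        if self.noise_sd < 0 or self.replicates < 1:
            raise ValueError("noise_sd must be >= 0 and replicates >= 1")


# ---------------------------------------------------------------------------
# ground truth records
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class PalmGroundTruth:
    """Latent state of a simulated localization map.

    ``complex_id``/``receptor_id`` label each emitted localization with the
    complex and the true receptor it came from; ``is_duplicate`` marks
    blink duplicates.  ``complex_sizes`` gives the true size per complex
    and ``composition`` the configured size -> count table.
    """

    complex_id: np.ndarray
    receptor_id: np.ndarray
    is_duplicate: np.ndarray
    complex_sizes: np.ndarray
    composition: dict[int, int]
    true_receptor_positions: np.ndarray

    @property
    def n_true_receptors(self) -> int:
        return int(self.complex_sizes.sum())


@dataclass(frozen=True)
class PoseGroundTruth:
    """True tilt/z-offset per pose plus the accept flag at the configured
    filter thresholds."""

    tilt_rad: np.ndarray
    z_offset_A: np.ndarray
    accept: np.ndarray
    tilt_max_rad: float
    z_offset_max_A: float


# ---------------------------------------------------------------------------
# localization maps
# ---------------------------------------------------------------------------

_MAX_TRIES = 10_000


def _draw_centers(config: PalmSimConfig, n: int, rng: np.random.Generator) -> np.ndarray:
    lo = np.zeros(2)
    hi = np.array([config.roi_width_nm, config.roi_height_nm])
    if config.min_center_sep_nm is None:
        return rng.uniform(lo, hi, size=(n, 2))
    centers: list[np.ndarray] = []
    sep2 = config.min_center_sep_nm**2
    for _ in range(n):
        for _try in range(_MAX_TRIES):
            c = rng.uniform(lo, hi)
            if all(((c - p) ** 2).sum() >= sep2 for p in centers):
                centers.append(c)
                break
        else:
            raise SimulationError(
                f"could not place {n} complex centers at min separation "
                f"{config.min_center_sep_nm} nm in the ROI"
            )
    return np.array(centers) if centers else np.empty((0, 2))


def _emit_inside(
    origin: np.ndarray, sd: float, config: PalmSimConfig, rng: np.random.Generator
) -> np.ndarray:
    """One localization at origin + N(0, sd), redrawn until inside the ROI."""
    for _try in range(_MAX_TRIES):
        p = origin + rng.normal(0.0, sd, size=2) if sd > 0 else origin.copy()
        if 0 <= p[0] < config.roi_width_nm and 0 <= p[1] < config.roi_height_nm:
            return p
        if sd == 0:
            raise SimulationError("true receptor position lies outside the ROI")
    raise SimulationError("could not draw a localization inside the ROI")


def simulate_localizations(
    config: PalmSimConfig,
) -> tuple[LocalizationMap, PalmGroundTruth]:
    """Simulate a PALM localization map with known complex membership."""
    rng = np.random.default_rng(config.seed)
    sizes = [
        s for s in sorted(config.counts_per_size) for _ in range(config.counts_per_size[s])
    ]
    centers = _draw_centers(config, len(sizes), rng)

    points, frames = [], []
    complex_id, receptor_id, is_dup = [], [], []
    true_pos = []
    frame = 0
    rec_idx = 0
    for ci, (size, center) in enumerate(zip(sizes, centers)):
        for _ in range(size):
            # uniform in a disc of cluster_radius_nm around the center
            for _try in range(_MAX_TRIES):
                r = config.cluster_radius_nm * np.sqrt(rng.uniform())
                theta = rng.uniform(0, 2 * np.pi)
                pos = center + r * np.array([np.cos(theta), np.sin(theta)])
                if (
                    0 <= pos[0] < config.roi_width_nm
                    and 0 <= pos[1] < config.roi_height_nm
                ):
                    break
            else:
                raise SimulationError("could not place a receptor inside the ROI")
            true_pos.append(pos)
            n_blinks = int(rng.poisson(config.blink_rate)) if config.blink_rate > 0 else 0
            for k in range(1 + n_blinks):
                sd = config.loc_error_sd_nm if k == 0 else config.blink_sd_nm
                points.append(_emit_inside(pos, sd, config, rng))
                frames.append(frame)
                frame += 1
                complex_id.append(ci)
                receptor_id.append(rec_idx)
                is_dup.append(k > 0)
            rec_idx += 1

    loc_map = LocalizationMap(
        np.array(points) if points else np.empty((0, 2)),
        config.roi_width_nm,
        config.roi_height_nm,
        np.array(frames, dtype=int),
    )
    truth = PalmGroundTruth(
        complex_id=np.array(complex_id, dtype=int),
        receptor_id=np.array(receptor_id, dtype=int),
        is_duplicate=np.array(is_dup, dtype=bool),
        complex_sizes=np.array(sizes, dtype=int),
        composition={s: c for s, c in sorted(config.counts_per_size.items()) if c > 0},
        true_receptor_positions=np.array(true_pos) if true_pos else np.empty((0, 2)),
    )
    return loc_map, truth


# ---------------------------------------------------------------------------
# docking poses
# ---------------------------------------------------------------------------


def _rot_about(axis: np.ndarray, angle: float) -> np.ndarray:
    """Rodrigues rotation matrix about a unit axis."""
    axis = np.asarray(axis, dtype=float)
    k = axis / np.linalg.norm(axis)
    K = np.array([[0, -k[2], k[1]], [k[2], 0, -k[0]], [-k[1], k[0], 0]])
    return np.eye(3) + np.sin(angle) * K + (1 - np.cos(angle)) * (K @ K)


def simulate_poses(
    config: PoseSimConfig, probe: StructureModel | None = None
) -> tuple[list[DockPose], PoseGroundTruth]:
    """Simulate scored docking poses with known tilt and z-offset.

    Each rotation is a spin about z followed by a tilt about a random
    in-plane axis, so the recomputed tilt equals the sampled one exactly.
    The translation's z-component is chosen so the probe's Cα-center
    displacement along z equals the sampled z-offset (for a probe centered
    at the origin this is just the z-component itself).
    """
    rng = np.random.default_rng(config.seed)
    c = probe.ca_center if probe is not None else np.zeros(3)
    lo_t, hi_t = config.tilt_range
    lo_z, hi_z = config.zoffset_range
    score_of = config.score_model or (lambda i: float(config.n_poses - i))

    poses = []
    tilts = np.empty(config.n_poses)
    zoffs = np.empty(config.n_poses)
    for i in range(config.n_poses):
        tilt = lo_t if hi_t == lo_t else rng.uniform(lo_t, hi_t)
        zoff = lo_z if hi_z == lo_z else rng.uniform(lo_z, hi_z)
        phi = rng.uniform(0, 2 * np.pi)  # in-plane tilt axis direction
        psi = rng.uniform(0, 2 * np.pi)  # spin about z
        R = _rot_about([np.cos(phi), np.sin(phi), 0.0], tilt) @ _rot_about(
            [0.0, 0.0, 1.0], psi
        )
        t_xy = rng.uniform(-config.xy_range_A, config.xy_range_A, size=2)
        tz = zoff - (R @ c - c)[2]
        poses.append(DockPose(i, R, np.array([t_xy[0], t_xy[1], tz]), score_of(i)))
        tilts[i] = tilt
        zoffs[i] = zoff
    accept = (tilts <= config.tilt_max_rad) & (np.abs(zoffs) <= config.z_offset_max_A)
    return poses, PoseGroundTruth(
        tilts, zoffs, accept, config.tilt_max_rad, config.z_offset_max_A
    )


def synthetic_protomer(
    n_residues: int = 40, rise_A: float = 1.5, radius_A: float = 2.3, turn_rad: float = 1.745
) -> StructureModel:
    """A synthetic Cα-only helical trace used as a docking probe stand-in.

    An idealized α-helical spiral along z, centered on the origin.  It is a
    geometric test body for RMSD/clustering and topology operations, not a
    model of any real protein.
    """
    i = np.arange(n_residues)
    coords = np.column_stack(
        [
            radius_A * np.cos(turn_rad * i),
            radius_A * np.sin(turn_rad * i),
            rise_A * i,
        ]
    )
    coords -= coords.mean(axis=0)
    return StructureModel.from_arrays(coords)


# ---------------------------------------------------------------------------
# BRET curves
# ---------------------------------------------------------------------------


def saturation_model(x, bretmax, bret50):
    x = np.asarray(x, dtype=float)
    return bretmax * x / (bret50 + x)


def kinetics_model(t, k, plateau):
    t = np.asarray(t, dtype=float)
    return plateau * (1.0 - np.exp(-k * t))


def dose_response_model(conc, baseline, emax, ec50):
    conc = np.asarray(conc, dtype=float)
    return baseline + (emax - baseline) / (1.0 + ec50 / conc)


def simulate_bret(config: BretSimConfig) -> pd.DataFrame:
    """Simulate replicate BRET readouts on the configured grid.

    Returns a long-format table with columns ``series`` (the mode), ``x``
    (ratio, seconds, or molar), ``y``, and ``replicate``.
    """
    rng = np.random.default_rng(config.seed)
    x = np.asarray(config.grid, dtype=float)
    if config.mode == "saturation":
        mean = saturation_model(x, config.bretmax, config.bret50)
    elif config.mode == "kinetics":
        mean = kinetics_model(x, config.k_per_s, config.plateau)
    else:
        mean = dose_response_model(x, config.baseline, config.emax, config.ec50_m)
    frames = []
    for rep in range(config.replicates):
        noise = (
            rng.normal(0.0, config.noise_sd, size=len(x))
            if config.noise_sd > 0
            else np.zeros(len(x))
        )
        frames.append(
            pd.DataFrame(
                {"series": config.mode, "x": x, "y": mean + noise, "replicate": rep}
            )
        )
    return pd.concat(frames, ignore_index=True)


def config_to_json(config) -> str:
    """Serialize any simulator config to JSON (callables are dropped)."""
    d = asdict(config)
    d.pop("score_model", None)
    if "counts_per_size" in d:
        d["counts_per_size"] = {str(k): v for k, v in d["counts_per_size"].items()}
    return json.dumps(d, indent=2)
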