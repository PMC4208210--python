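"""Synthetic trial generator with known ground truth.

Emulates one foot of a manual-material-handling (MMH) trial as seen by the
three instruments: marker trajectories of a shoe-mounted triad (HEEL, MT1,
MT5), a force platform, and a 99-sensor pressure insole, all mutually
consistent under a known, configurable insole-to-shoe rigid transform.

Construction per frame (60 Hz):

1. A smooth task-dependent insole COP path and vertical-load profile; the
   load ramps from zero at both trial ends so the 20 N contact gate is
   always exercised.
2. Pressures: an isotropic squared-exponential bump centered on the COP
   path, truncated at a device floor and scaled so the summed sensor force
   equals the platform's vertical force.  The *measured* insole COP is the
   force-weighted centroid of these (noiseless) pressures — the quantity
   every downstream consumer can actually observe.
3. Shoe-frame COP: the true rigid transform applied to the measured insole
   COP, plus an optional load-dependent deformation displacement (below).
4. A planar shoe pose (yaw about the heel plus in-plane translation — sway
   for lifts, fore-aft sweep for push/pull, large yaw excursions for the
   asymmetric lift) maps the shoe-frame COP to the global frame; platform
   moments are synthesized from that point by moment balance.
5. Noise: additive Gaussian marker noise, plate-COP noise (applied to the
   point entering the moment balance) and pressure noise with a
   noise-floor threshold, each independently configurable.

Deformation model ("bending", the default): a pliant insole shifts the
apparent COP when load concentrates away from a flat stance, so the shoe
deforms both in flexion (AP) and — during turning/rolling of the foot — in
eversion (ML).  The displacement is

    AP: delta * (anterior load share - posterior load share)
    ML: 0.5 * delta * (medial load share - lateral load share)

computed from the eight-region partition; it vanishes when the shares
balance and scales linearly in the amplitude ``delta``.  The "ap_only" tag
drops the ML term.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict

import numpy as np
import yaml

from .errors import DataError
from . import features as _features
from .signal_io import (ForcePlateRecording, InsoleRecording, MarkerTrajectory,
                        SensorGeometry, N_SENSORS, write_geometry, write_trial)

GRAVITY_MS2 = 9.81

#: marker triad in the shoe frame (mm); symmetric metatarsal markers make
#: the reconstructed frame coincide exactly with the generating pose
_MARKER_LOCAL = {
    "heel": np.array([0.0, 0.0, 25.0]),
    "mt1": np.array([-30.0, 155.0, 25.0]),
    "mt5": np.array([30.0, 155.0, 25.0]),
}

TASKS = ("LL_GROUND", "LL_KNUCKLE", "LL_ASYM", "PushPull")

#: per-task motion profile: insole COP excursion (x amp mm, y mid/amp as
#: fractions of insole length, rates Hz) and pose excursions (yaw deg,
#: heel translation mm)
_TASK_PROFILES = {
    "LL_GROUND": dict(x_amp=10.0, f_x=0.40, y_mid=0.50, y_amp=0.22, f_y=0.25,
                      yaw_deg=4.0, f_yaw=0.20, heel_amp=(15.0, 15.0), f_heel=0.15),
    "LL_KNUCKLE": dict(x_amp=6.0, f_x=0.35, y_mid=0.52, y_amp=0.10, f_y=0.30,
                       yaw_deg=2.0, f_yaw=0.25, heel_amp=(8.0, 8.0), f_heel=0.20),
    "LL_ASYM": dict(x_amp=14.0, f_x=0.30, y_mid=0.50, y_amp=0.16, f_y=0.22,
                    yaw_deg=15.0, f_yaw=0.18, heel_amp=(35.0, 12.0), f_heel=0.18),
    "PushPull": dict(x_amp=5.0, f_x=0.30, y_mid=0.55, y_amp=0.25, f_y=0.25,
                     yaw_deg=3.0, f_yaw=0.20, heel_amp=(8.0, 45.0), f_heel=0.25),
}

_DEFAULT_ROWS = (5, 6, 7, 7, 7, 7, 7, 7, 7, 7, 7, 7, 7, 6, 5)


@dataclass
class SyntheticConfig:
    """Ground truth and study conditions for one generated trial."""

    task: str = "LL_GROUND"
    duration_s: float = 8.0
    theta_deg: float = 8.0                  # true insole->shoe rotation
    d_mm: tuple = (12.0, -7.0)              # true insole->shoe translation
    deformation_mm: float = 0.0             # delta
    deformation_model: str = "bending"      # bending | ap_only
    rate_hz: float = 60.0
    plate_rate_hz: float = 60.0             # 960 to exercise conditioning
    marker_noise_mm: float = 0.3
    cop_noise_mm: float = 1.0
    pressure_noise_kpa: float = 2.0
    body_mass_kg: float = 76.1
    bump_width_mm: float = 25.0
    pressure_floor_kpa: float = 0.5
    participant: str = "P01"
    foot: str = "left"
    replication: int = 1
    seed: int = 0

    def __post_init__(self):
        if self.task not in TASKS:
            raise DataError(f"unknown task {self.task!r}; expected one of {TASKS}")
        if self.deformation_mm < 0 or self.duration_s <= 0:
            raise DataError("deformation must be >= 0 and duration > 0")
        if min(self.marker_noise_mm, self.cop_noise_mm, self.pressure_noise_kpa) < 0:
            raise DataError("noise levels must be >= 0")

    @property
    def trial_id(self) -> str:
        return f"{self.participant}_{self.foot}_{self.task}_r{self.replication}"


@dataclass
class SyntheticTrial:
    markers: MarkerTrajectory
    plate: ForcePlateRecording
    insole: InsoleRecording
    truth: dict = field(default_factory=dict)


def make_sensor_geometry(row_counts=_DEFAULT_ROWS,
                         insole_length_mm: float = 250.0) -> SensorGeometry:
    """Canonical 99-sensor grid: 15 rows, narrower at heel and toes.

    Deterministic (no randomness); sensor pitch 10.5 mm across rows spaced
    length/15 apart, each sensor covering pitch x spacing.
    """
    row_counts = tuple(int(c) for c in row_counts)
    if sum(row_counts) != N_SENSORS:
        raise DataError(f"row counts sum to {sum(row_counts)}, need {N_SENSORS}")
    pitch = 10.5
    spacing = insole_length_mm / len(row_counts)
    centers = []
    for j, count in enumerate(row_counts):
        cy = (j + 0.5) * spacing
        for i in range(count):
            cx = (i - (count - 1) / 2.0) * pitch
            centers.append((cx, cy))
    centers = np.asarray(centers)
    areas = np.full(N_SENSORS, pitch * spacing)
    return SensorGeometry(centers_mm=centers, areas_mm2=areas,
                          length_mm=insole_length_mm)


def _smooth_ramp(t: np.ndarray, duration: float, edge_s: float = 0.6) -> np.ndarray:
    """Raised-cosine 0->1->0 envelope so the load crosses the contact gate."""
    up = np.clip(t / edge_s, 0.0, 1.0)
    down = np.clip((duration - t) / edge_s, 0.0, 1.0)
    return 0.5 * (1 - np.cos(np.pi * up)) * 0.5 * (1 - np.cos(np.pi * down))


def deformation_shift(pressures_kpa: np.ndarray, geom: SensorGeometry,
                      partition: _features.RegionPartition, delta_mm: float,
                      model: str = "bending") -> np.ndarray:
    """Per-frame (ML, AP) COP displacement of the load-share deformation model."""
    if model not in ("bending", "ap_only"):
        raise DataError(f"unknown deformation model {model!r}")
    loads = pressures_kpa * geom.areas_mm2
    total = loads.sum(axis=1)
    tot = np.where(total > 0, total, 1.0)

    def share(*regions):
        idx = np.concatenate([partition.indices(r) for r in regions])
        return loads[:, idx].sum(axis=1) / tot

    anterior = share("forefoot_1", "forefoot_2", "forefoot_3", "toes")
    posterior = share("heel_lateral", "heel_medial")
    ap = delta_mm * (anterior - posterior)
    if model == "bending":
        medial = share("heel_medial", "midfoot_2", "forefoot_1")
        lateral = share("heel_lateral", "midfoot_1", "forefoot_3")
        ml = 0.5 * delta_mm * (medial - lateral)
    else:
        ml = np.zeros_like(ap)
    shift = np.column_stack([ml, ap])
    shift[total <= 0] = 0.0
    return shift


def generate_trial(config: SyntheticConfig,
                   geom: SensorGeometry | None = None) -> SyntheticTrial:
    """Generate one internally consistent trial plus its ground-truth record."""
    if geom is None:
        geom = make_sensor_geometry()
    rng = np.random.default_rng(config.seed)
    prof = _TASK_PROFILES[config.task]
    n = int(round(config.duration_s * config.rate_hz))
    t = np.arange(n) / config.rate_hz
    length = geom.length_mm

    # --- insole COP path and vertical load profile -------------------------
    phases = rng.uniform(0, 2 * np.pi, size=4)
    cop_x = prof["x_amp"] * np.sin(2 * np.pi * prof["f_x"] * t + phases[0])
    cop_y = length * (prof["y_mid"]
                      + prof["y_amp"] * np.sin(2 * np.pi * prof["f_y"] * t + phases[1]))
    half_bw = 0.5 * config.body_mass_kg * GRAVITY_MS2
    fz = half_bw * (0.85 + 0.25 * np.sin(2 * np.pi * 0.45 * t + phases[2]))
    fz = fz * _smooth_ramp(t, config.duration_s)
    fz[fz < 0.5] = 0.0

    # --- pressures: truncated bump scaled to the vertical load -------------
    d2 = ((geom.centers_mm[None, :, 0] - cop_x[:, None]) ** 2
          + (geom.centers_mm[None, :, 1] - cop_y[:, None]) ** 2)
    bump = np.exp(-d2 / (2 * config.bump_width_mm ** 2))
    denom = (bump * geom.areas_mm2).sum(axis=1)
    amp = np.where(denom > 0, fz * 1000.0 / np.where(denom > 0, denom, 1.0), 0.0)
    p0 = amp[:, None] * bump
    p0[p0 < config.pressure_floor_kpa] = 0.0
    # rescale the truncated bump so the summed sensor force equals the
    # platform's vertical force exactly (the centroid is scale-invariant);
    # frames whose whole bump fell below the device floor count as off-ground
    kept = (p0 * geom.areas_mm2).sum(axis=1) / 1000.0
    fz[kept <= 0] = 0.0
    scale = np.where(kept > 0, fz / np.where(kept > 0, kept, 1.0), 0.0)
    p0 *= scale[:, None]

    # measured insole COP: what insole_cop() recovers from these pressures
    w = p0 * geom.areas_mm2
    wtot = w.sum(axis=1)
    loaded = wtot > 0
    cop_meas = np.full((n, 2), np.nan)
    cop_meas[loaded] = (w[loaded] @ geom.centers_mm) / wtot[loaded, None]

    # --- shoe-frame COP through the true transform + deformation -----------
    partition = _features.default_partition(geom)
    shift = deformation_shift(p0, geom, partition, config.deformation_mm,
                              config.deformation_model)
    theta = np.radians(config.theta_deg)
    rot = np.array([[np.cos(theta), -np.sin(theta)],
                    [np.sin(theta), np.cos(theta)]])
    shoe_cop = np.full((n, 2), np.nan)
    shoe_cop[loaded] = (cop_meas[loaded] @ rot.T + np.asarray(config.d_mm)
                        + shift[loaded])

    # --- planar shoe pose: yaw about the heel plus in-plane translation ----
    yaw = np.radians(prof["yaw_deg"]) * np.sin(2 * np.pi * prof["f_yaw"] * t + phases[3])
    heel_xy = np.column_stack([
        prof["heel_amp"][0] * np.sin(2 * np.pi * prof["f_heel"] * t + phases[3] / 2),
        prof["heel_amp"][1] * np.sin(2 * np.pi * prof["f_heel"] * t + 1.0)])
    cos_y, sin_y = np.cos(yaw), np.sin(yaw)

    def pose_apply(local_xy):
        x = cos_y * local_xy[0] - sin_y * local_xy[1] + heel_xy[:, 0]
        y = sin_y * local_xy[0] + cos_y * local_xy[1] + heel_xy[:, 1]
        return x, y

    marker_arrays = {}
    for name, local in _MARKER_LOCAL.items():
        mx, my = pose_apply(local[:2])
        arr = np.column_stack([mx, my, np.full(n, local[2])])
        arr = arr + rng.normal(0.0, config.marker_noise_mm, size=arr.shape) \
            if config.marker_noise_mm > 0 else arr
        marker_arrays[name] = arr

    # --- platform record from the globally expressed COP -------------------
    g = np.zeros((n, 2))
    gx = cos_y * shoe_cop[:, 0] - sin_y * shoe_cop[:, 1] + heel_xy[:, 0]
    gy = sin_y * shoe_cop[:, 0] + cos_y * shoe_cop[:, 1] + heel_xy[:, 1]
    g[:, 0] = np.where(loaded, gx, 0.0)
    g[:, 1] = np.where(loaded, gy, 0.0)
    if config.cop_noise_mm > 0:
        g[loaded] += rng.normal(0.0, config.cop_noise_mm, size=(int(loaded.sum()), 2))
    shear = 0.03 * fz
    force = np.column_stack([shear * np.sin(2 * np.pi * 0.7 * t),
                             shear * np.cos(2 * np.pi * 0.7 * t), fz])
    r3 = np.column_stack([g, np.zeros(n)])
    moment = np.cross(r3, force)

    time60 = t
    if config.plate_rate_hz == config.rate_hz:
        plate = ForcePlateRecording(time_s=time60, force_n=force,
                                    moment_nmm=moment, rate_hz=config.rate_hz,
                                    trial_id=config.trial_id)
    else:
        ratio = config.plate_rate_hz / config.rate_hz
        if abs(ratio - round(ratio)) > 1e-9:
            raise DataError("plate rate must be an integer multiple of 60 Hz")
        tp = np.arange(int(round(config.duration_s * config.plate_rate_hz))) \
            / config.plate_rate_hz
        force_p = np.column_stack([np.interp(tp, time60, force[:, j]) for j in range(3)])
        moment_p = np.column_stack([np.interp(tp, time60, moment[:, j]) for j in range(3)])
        plate = ForcePlateRecording(time_s=tp, force_n=force_p, moment_nmm=moment_p,
                                    rate_hz=config.plate_rate_hz,
                                    trial_id=config.trial_id)

    p_emit = p0
    if config.pressure_noise_kpa > 0:
        p_emit = p0 + rng.normal(0.0, config.pressure_noise_kpa, size=p0.shape)
        floor = max(config.pressure_floor_kpa, 2.0 * config.pressure_noise_kpa)
        p_emit[p_emit < floor] = 0.0

    markers = MarkerTrajectory(time_s=time60, heel=marker_arrays["heel"],
                               mt1=marker_arrays["mt1"], mt5=marker_arrays["mt5"],
                               rate_hz=config.rate_hz, trial_id=config.trial_id)
    insole = InsoleRecording(time_s=time60, pressure_kpa=p_emit,
                             rate_hz=config.rate_hz, side=config.foot,
                             body_mass_kg=config.body_mass_kg,
                             trial_id=config.trial_id)
    truth = {
        "theta_deg": config.theta_deg,
        "d_mm": list(config.d_mm),
        "deformation_mm": config.deformation_mm,
        "deformation_model": config.deformation_model,
        "seed": config.seed,
        "task": config.task,
        "insole_cop": cop_meas,
        "shoe_cop": shoe_cop,
        "deformation_shift": shift,
        "loaded": loaded,
        "config": asdict(config),
    }
    return SyntheticTrial(markers=markers, plate=plate, insole=insole, truth=truth)


def write_truth(path, truth: dict) -> None:
    """Ground-truth record as structured text (scalars + per-frame shifts)."""
    doc = {k: truth[k] for k in ("theta_deg", "d_mm", "deformation_mm",
                                 "deformation_model", "seed", "task", "config")}
    doc["deformation_shift_mm"] = np.asarray(truth["deformation_shift"]).round(6).tolist()
    with open(path, "w") as fh:
        yaml.safe_dump(doc, fh, sort_keys=False)


def write_trial_files(trial: SyntheticTrial, outdir, geom: SensorGeometry) -> dict:
    """Write the signal_io file dialects for one trial; returns the paths."""
    from pathlib import Path
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    tid = trial.markers.trial_id
    paths = {
        "markers": outdir / f"{tid}_markers.csv",
        "plate": outdir / f"{tid}_plate.csv",
        "insole": outdir / f"{tid}_insole.csv",
        "geometry": outdir / "geometry.csv",
        "truth": outdir / f"{tid}_truth.yaml",
    }
    write_trial(paths["markers"], paths["plate"], paths["insole"],
                trial.markers, trial.plate, trial.insole)
    write_geometry(paths["geometry"], geom)
    write_truth(paths["truth"], trial.truth)
    return paths
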