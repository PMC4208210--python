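"""Readers, writers and conditioning for the three synchronized data streams.

A trial consists of marker trajectories (HEEL, MT1, MT5 at 60 Hz, mm, global
frame), a force-platform record (force N, moment N·mm about the plate origin),
and an in-shoe pressure record (99 capacitive sensors, kPa, 60 Hz). All files
are delimited text with ``# key = value`` metadata lines before the header
row; streams of one trial share a trial identifier and a trigger sample
(emulating hardware TTL synchronization), and are aligned by sample index
from the trigger onward.

Force-plate conditioning follows the usual protocol for this kind of data:
2nd-order zero-lag (forward-backward) Butterworth low-pass at 15 Hz, then
decimation from 960 Hz to the 60 Hz rate of the other streams.  Frames where
the vertical ground-reaction force falls below 20 N are treated as
off-ground and excluded from every downstream fit and metric.
"""

from __future__ import annotations

import io
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
import yaml
from scipy import signal as _sig

from .errors import DataError, FormatError

N_SENSORS = 99

#: default conditioning parameters
FILTER_CUTOFF_HZ = 15.0
FILTER_ORDER = 2
TARGET_RATE_HZ = 60.0
CONTACT_THRESHOLD_N = 20.0


# ---------------------------------------------------------------------------
# domain types
# ---------------------------------------------------------------------------

@dataclass
class MarkerTrajectory:
    """HEEL / MT1 / MT5 positions (mm, global frame) at a uniform rate."""

    time_s: np.ndarray          # (n,)
    heel: np.ndarray            # (n, 3) mm
    mt1: np.ndarray             # (n, 3) mm
    mt5: np.ndarray             # (n, 3) mm
    rate_hz: float = 60.0
    valid: np.ndarray = None    # (n,) bool; False marks occluded frames
    trial_id: str = "trial"
    trigger_sample: int = 0

    def __post_init__(self):
        self.time_s = np.asarray(self.time_s, dtype=float)
        for name in ("heel", "mt1", "mt5"):
            arr = np.asarray(getattr(self, name), dtype=float)
            if arr.ndim != 2 or arr.shape[1] != 3:
                raise FormatError(f"{name} must be (n, 3), got {arr.shape}")
            setattr(self, name, arr)
        if self.valid is None:
            self.valid = np.ones(len(self.time_s), dtype=bool)
        self.valid = np.asarray(self.valid, dtype=bool)
        n = len(self.time_s)
        if not (len(self.heel) == len(self.mt1) == len(self.mt5) == len(self.valid) == n):
            raise FormatError("marker stream lengths disagree")

    def __len__(self):
        return len(self.time_s)


@dataclass
class ForcePlateRecording:
    """Force (N) and moment (N·mm) about the plate origin, global axes.

    ``origin_mm`` locates the plate origin in the global frame;
    ``surface_z_mm`` is the height of the walking surface (global Z=0 by
    convention).  COP is resolved on that surface by moment balance.
    """

    time_s: np.ndarray          # (n,)
    force_n: np.ndarray         # (n, 3)
    moment_nmm: np.ndarray      # (n, 3)
    rate_hz: float = 960.0
    origin_mm: np.ndarray = field(default_factory=lambda: np.zeros(3))
    surface_z_mm: float = 0.0
    trial_id: str = "trial"
    trigger_sample: int = 0

    def __post_init__(self):
        self.time_s = np.asarray(self.time_s, dtype=float)
        self.force_n = np.asarray(self.force_n, dtype=float)
        self.moment_nmm = np.asarray(self.moment_nmm, dtype=float)
        self.origin_mm = np.asarray(self.origin_mm, dtype=float)
        if self.rate_hz <= 0:
            raise FormatError("sampling rate must be positive")
        if self.force_n.shape != self.moment_nmm.shape or self.force_n.shape[1:] != (3,):
            raise FormatError("force and moment must both be (n, 3)")

    def __len__(self):
        return len(self.time_s)

    @property
    def fz(self) -> np.ndarray:
        return self.force_n[:, 2]


@dataclass
class InsoleRecording:
    """n x 99 plantar pressure frames (kPa) for one foot."""

    time_s: np.ndarray          # (n,)
    pressure_kpa: np.ndarray    # (n, 99)
    rate_hz: float = 60.0
    side: str = "left"
    body_mass_kg: float = 76.1
    trial_id: str = "trial"
    trigger_sample: int = 0

    def __post_init__(self):
        self.time_s = np.asarray(self.time_s, dtype=float)
        self.pressure_kpa = np.asarray(self.pressure_kpa, dtype=float)
        if self.pressure_kpa.ndim != 2 or self.pressure_kpa.shape[1] != N_SENSORS:
            raise FormatError(
                f"expected {N_SENSORS} sensors, got "
                f"{self.pressure_kpa.shape[1] if self.pressure_kpa.ndim == 2 else '?'}"
            )
        if np.any(self.pressure_kpa < 0):
            raise FormatError("pressures must be non-negative")

    def __len__(self):
        return len(self.time_s)


@dataclass
class SensorGeometry:
    """Sensor centers (mm, insole frame), areas (mm^2) and insole length."""

    centers_mm: np.ndarray      # (99, 2)
    areas_mm2: np.ndarray       # (99,)
    length_mm: float

    def __post_init__(self):
        self.centers_mm = np.asarray(self.centers_mm, dtype=float)
        self.areas_mm2 = np.asarray(self.areas_mm2, dtype=float)
        if self.centers_mm.shape != (N_SENSORS, 2) or self.areas_mm2.shape != (N_SENSORS,):
            raise FormatError(f"geometry must describe exactly {N_SENSORS} sensors")
        if np.any(self.areas_mm2 <= 0):
            raise FormatError("sensor areas must be positive")


# ---------------------------------------------------------------------------
# file dialects
# ---------------------------------------------------------------------------

def _write_table(path, meta: dict, frame: pd.DataFrame) -> None:
    with open(path, "w") as fh:
        for key, val in meta.items():
            fh.write(f"# {key} = {val}\n")
        frame.to_csv(fh, index=False, float_format="%.6f")


def _read_table(path) -> tuple[dict, pd.DataFrame]:
    meta = {}
    lines = []
    with open(path) as fh:
        for line in fh:
            if line.startswith("#"):
                key, _, val = line[1:].partition("=")
                meta[key.strip()] = val.strip()
            else:
                lines.append(line)
    if not lines:
        raise FormatError(f"{path}: no table found")
    frame = pd.read_csv(io.StringIO("".join(lines)))
    return meta, frame


def _common_meta(stream) -> dict:
    return {"trial_id": stream.trial_id, "trigger_sample": stream.trigger_sample,
            "rate_hz": stream.rate_hz}


def write_markers(path, markers: MarkerTrajectory) -> None:
    cols = {"frame": np.arange(len(markers)), "time": markers.time_s}
    for name in ("heel", "mt1", "mt5"):
        arr = getattr(markers, name)
        for j, ax in enumerate("xyz"):
            cols[f"{name}_{ax}"] = arr[:, j]
    cols["valid"] = markers.valid.astype(int)
    _write_table(path, _common_meta(markers), pd.DataFrame(cols))


def read_markers(path) -> MarkerTrajectory:
    meta, tab = _read_table(path)
    expected = [f"{m}_{ax}" for m in ("heel", "mt1", "mt5") for ax in "xyz"]
    missing = [c for c in ["frame", "time", *expected] if c not in tab.columns]
    if missing:
        raise FormatError(f"{path}: missing columns {missing}")
    def block(name):
        return tab[[f"{name}_x", f"{name}_y", f"{name}_z"]].to_numpy()
    valid = tab["valid"].to_numpy().astype(bool) if "valid" in tab.columns else None
    return MarkerTrajectory(
        time_s=tab["time"].to_numpy(), heel=block("heel"), mt1=block("mt1"),
        mt5=block("mt5"), rate_hz=float(meta.get("rate_hz", 60)), valid=valid,
        trial_id=meta.get("trial_id", "trial"),
        trigger_sample=int(meta.get("trigger_sample", 0)))


def write_plate(path, plate: ForcePlateRecording) -> None:
    meta = _common_meta(plate)
    meta["origin_mm"] = " ".join(f"{v:.6f}" for v in plate.origin_mm)
    meta["surface_z_mm"] = f"{plate.surface_z_mm:.6f}"
    tab = pd.DataFrame({
        "frame": np.arange(len(plate)), "time": plate.time_s,
        "fx": plate.force_n[:, 0], "fy": plate.force_n[:, 1], "fz": plate.force_n[:, 2],
        "mx": plate.moment_nmm[:, 0], "my": plate.moment_nmm[:, 1],
        "mz": plate.moment_nmm[:, 2]})
    _write_table(path, meta, tab)


def read_plate(path) -> ForcePlateRecording:
    meta, tab = _read_table(path)
    needed = ["time", "fx", "fy", "fz", "mx", "my", "mz"]
    missing = [c for c in needed if c not in tab.columns]
    if missing:
        raise FormatError(f"{path}: missing columns {missing}")
    origin = np.fromstring(meta.get("origin_mm", "0 0 0"), sep=" ")
    return ForcePlateRecording(
        time_s=tab["time"].to_numpy(),
        force_n=tab[["fx", "fy", "fz"]].to_numpy(),
        moment_nmm=tab[["mx", "my", "mz"]].to_numpy(),
        rate_hz=float(meta.get("rate_hz", 960)), origin_mm=origin,
        surface_z_mm=float(meta.get("surface_z_mm", 0)),
        trial_id=meta.get("trial_id", "trial"),
        trigger_sample=int(meta.get("trigger_sample", 0)))


def write_insole(path, rec: InsoleRecording) -> None:
    meta = _common_meta(rec)
    meta.update(side=rec.side, body_mass_kg=rec.body_mass_kg)
    cols = {"frame": np.arange(len(rec)), "time": rec.time_s}
    for j in range(N_SENSORS):
        cols[f"p{j + 1:03d}"] = rec.pressure_kpa[:, j]
    _write_table(path, meta, pd.DataFrame(cols))


def read_insole(path) -> InsoleRecording:
    meta, tab = _read_table(path)
    pcols = [c for c in tab.columns if c.startswith("p") and c[1:].isdigit()]
    if len(pcols) != N_SENSORS:
        raise FormatError(f"{path}: expected {N_SENSORS} sensors, found {len(pcols)}")
    pcols = sorted(pcols)
    return InsoleRecording(
        time_s=tab["time"].to_numpy(), pressure_kpa=tab[pcols].to_numpy(),
        rate_hz=float(meta.get("rate_hz", 60)), side=meta.get("side", "left"),
        body_mass_kg=float(meta.get("body_mass_kg", 76.1)),
        trial_id=meta.get("trial_id", "trial"),
        trigger_sample=int(meta.get("trigger_sample", 0)))


def write_geometry(path, geom: SensorGeometry) -> None:
    tab = pd.DataFrame({
        "sensor": np.arange(1, N_SENSORS + 1),
        "cx": geom.centers_mm[:, 0], "cy": geom.centers_mm[:, 1],
        "area": geom.areas_mm2})
    _write_table(path, {"length_mm": f"{geom.length_mm:.6f}"}, tab)


def read_geometry(path) -> SensorGeometry:
    meta, tab = _read_table(path)
    if len(tab) != N_SENSORS:
        raise FormatError(f"{path}: expected {N_SENSORS} rows, found {len(tab)}")
    return SensorGeometry(
        centers_mm=tab[["cx", "cy"]].to_numpy(),
        areas_mm2=tab["area"].to_numpy(), length_mm=float(meta["length_mm"]))


def read_config(path) -> dict:
    with open(path) as fh:
        cfg = yaml.safe_load(fh)
    if not isinstance(cfg, dict):
        raise FormatError(f"{path}: config must be a mapping")
    return cfg


def read_trial(marker_path, plate_path, insole_path) -> tuple[
        MarkerTrajectory, ForcePlateRecording, InsoleRecording]:
    """Read one synchronized trial and validate cross-stream consistency."""
    markers = read_markers(marker_path)
    plate = read_plate(plate_path)
    insole = read_insole(insole_path)
    ids = {markers.trial_id, plate.trial_id, insole.trial_id}
    if len(ids) != 1:
        raise DataError(f"streams belong to different trials: {sorted(ids)}")
    trig = {markers.trigger_sample, plate.trigger_sample, insole.trigger_sample}
    if len(trig) != 1:
        raise DataError(f"trigger samples disagree: {sorted(trig)}")
    return markers, plate, insole


def write_trial(marker_path, plate_path, insole_path, markers, plate, insole) -> None:
    write_markers(marker_path, markers)
    write_plate(plate_path, plate)
    write_insole(insole_path, insole)


# ---------------------------------------------------------------------------
# conditioning
# ---------------------------------------------------------------------------

def lowpass_downsample(plate: ForcePlateRecording,
                       cutoff_hz: float = FILTER_CUTOFF_HZ,
                       order: int = FILTER_ORDER,
                       target_hz: float = TARGET_RATE_HZ) -> ForcePlateRecording:
    """Zero-lag Butterworth low-pass, then decimate to ``target_hz``.

    Forward-backward application cancels phase delay and squares the
    magnitude response; the 15 Hz filter also serves as the anti-alias
    filter for the decimation, so plain sample-picking follows.
    """
    ratio = plate.rate_hz / target_hz
    if abs(ratio - round(ratio)) > 1e-9:
        raise DataError(
            f"input rate {plate.rate_hz} Hz is not an integer multiple of {target_hz} Hz")
    factor = int(round(ratio))
    sos = _sig.butter(order, cutoff_hz, btype="low", fs=plate.rate_hz, output="sos")
    force = _sig.sosfiltfilt(sos, plate.force_n, axis=0)
    moment = _sig.sosfiltfilt(sos, plate.moment_nmm, axis=0)
    sl = slice(None, None, factor)
    return replace(plate, time_s=plate.time_s[sl], force_n=force[sl],
                   moment_nmm=moment[sl], rate_hz=target_hz)


def condition_plate(plate: ForcePlateRecording,
                    target_hz: float = TARGET_RATE_HZ) -> ForcePlateRecording:
    """Conditioning entry point for the pipeline.

    Streams already at the target rate are taken as conditioned (the
    synthetic generator emits them this way); anything faster is filtered
    and decimated.
    """
    if plate.rate_hz == target_hz:
        return plate
    return lowpass_downsample(plate, target_hz=target_hz)


def gate_ground_contact(plate: ForcePlateRecording,
                        threshold_n: float = CONTACT_THRESHOLD_N) -> np.ndarray:
    """Contact mask: True where vertical GRF >= threshold.

    Frames with Fz below the threshold count as off-ground (strict
    less-than on the off-ground side, so exactly 20 N is contact).
    """
    return plate.fz >= threshold_n
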