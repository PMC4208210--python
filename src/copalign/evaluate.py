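"""Comparative measures and the two-fold cross-validation protocol.

Per test trial and axis (AP = shoe Y, ML = shoe X) three measures compare an
estimated shoe-frame COP series with the reference derived from the force
platform: root-mean-square error (RMSE, mm), peak absolute error (PAE, mm),
and the coefficient of determination r^2 (squared Pearson correlation by
default; 1 - SS_res/SS_tot available as an option).

Cross-validation is two-fold at the participant level: each fold trains the
mapping (RIGID or one MFNN variant) on one replication of the two simple
lifting tasks (LL_GROUND, LL_KNUCKLE) and tests on the other replication of
all four MMH tasks; the folds then swap replications.  Metrics are computed
on contact-gated frames only, and every fold records the exact
(trial, frame) sets used for training and testing so train/test
disjointness can be audited.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats as _stats

from .errors import DataError, InsufficientDataError
from .features import (PCAModel, RegionPartition, build_features,
                       default_partition, fit_pca,
                       pressures_to_normalized_forces)
from .frames import (PlanarCOPSeries, forceplate_cop, insole_cop,
                     shoe_frame_series, to_shoe_frame)
from .mfnn import HIDDEN_GRID, predict, select_hidden_size
from .rigid_fit import apply_rigid, fit_rigid
from .signal_io import (ForcePlateRecording, InsoleRecording, MarkerTrajectory,
                        SensorGeometry, condition_plate, gate_ground_contact)

TRAIN_TASKS = ("LL_GROUND", "LL_KNUCKLE")
ALL_TASKS = ("LL_GROUND", "LL_KNUCKLE", "LL_ASYM", "PushPull")
METHODS = ("RIGID", "MFNN1", "MFNN2", "MFNN3", "MFNN4")
AXES = ("AP", "ML")
_AXIS_COL = {"AP": 1, "ML": 0}


# ---------------------------------------------------------------------------
# comparative measures
# ---------------------------------------------------------------------------

def _axis_errors(est: PlanarCOPSeries, ref: PlanarCOPSeries, axis: str):
    if axis not in _AXIS_COL:
        raise DataError(f"axis must be one of {AXES}, got {axis!r}")
    if len(est) != len(ref):
        raise DataError("series lengths disagree")
    both = est.valid & ref.valid
    if not np.any(both):
        raise InsufficientDataError("no jointly valid frames")
    col = _AXIS_COL[axis]
    return est.xy[both, col], ref.xy[both, col]


def rmse(est: PlanarCOPSeries, ref: PlanarCOPSeries, axis: str) -> float:
    """Root-mean-square per-frame error along one axis (mm)."""
    e, r = _axis_errors(est, ref, axis)
    return float(np.sqrt(np.mean((e - r) ** 2)))


def pae(est: PlanarCOPSeries, ref: PlanarCOPSeries, axis: str) -> float:
    """Peak absolute per-frame error along one axis (mm)."""
    e, r = _axis_errors(est, ref, axis)
    return float(np.max(np.abs(e - r)))


def r2(est: PlanarCOPSeries, ref: PlanarCOPSeries, axis: str,
       kind: str = "pearson") -> float:
    """Coefficient of determination along one axis.

    ``pearson`` (default): squared Pearson correlation, in [0, 1]; the sign
    of the association is lost.  ``ss``: 1 - SS_res/SS_tot, which can be
    negative for estimates worse than the mean.  Returns NaN when either
    series has zero variance.
    """
    e, r = _axis_errors(est, ref, axis)
    if len(e) < 2 or np.std(e) < 1e-12 or np.std(r) < 1e-12:
        return float("nan")
    if kind == "pearson":
        return float(np.corrcoef(e, r)[0, 1] ** 2)
    if kind == "ss":
        ss_res = np.sum((r - e) ** 2)
        ss_tot = np.sum((r - r.mean()) ** 2)
        return float(1.0 - ss_res / ss_tot)
    raise DataError(f"unknown r2 kind {kind!r}")


# ---------------------------------------------------------------------------
# trial containers and per-trial preparation
# ---------------------------------------------------------------------------

@dataclass
class Trial:
    participant: str
    foot: str
    task: str
    replication: int
    markers: MarkerTrajectory
    plate: ForcePlateRecording
    insole: InsoleRecording

    @property
    def key(self):
        return (self.participant, self.foot, self.task, self.replication)

    @property
    def trial_id(self) -> str:
        return f"{self.participant}_{self.foot}_{self.task}_r{self.replication}"


@dataclass
class TrialSet:
    trials: list
    geometry: SensorGeometry


@dataclass
class PreparedTrial:
    """Frame-aligned, gated insole COP and shoe-frame reference COP."""

    trial: Trial
    insole_cop: PlanarCOPSeries
    shoe_cop: PlanarCOPSeries
    valid: np.ndarray

    def __len__(self):
        return len(self.valid)


def prepare_trial(trial: Trial, geom: SensorGeometry,
                  gate_threshold_n: float = 20.0) -> PreparedTrial:
    """Condition, gate and express the reference COP in the shoe frame."""
    plate = condition_plate(trial.plate)
    contact = gate_ground_contact(plate, gate_threshold_n)
    n = len(trial.markers)
    if len(plate) != n or len(trial.insole) != n:
        raise DataError(
            f"{trial.trial_id}: stream lengths disagree "
            f"(markers {n}, plate {len(plate)}, insole {len(trial.insole)})")
    poses = shoe_frame_series(trial.markers)
    ref_global = forceplate_cop(plate, contact)
    ref_shoe = to_shoe_frame(poses, ref_global)
    ins = insole_cop(trial.insole, geom)
    valid = ref_shoe.valid & ins.valid
    return PreparedTrial(trial=trial, insole_cop=ins, shoe_cop=ref_shoe, valid=valid)


def _masked(series: PlanarCOPSeries, valid: np.ndarray) -> PlanarCOPSeries:
    return PlanarCOPSeries(xy=series.xy, valid=valid, frame=series.frame)


def _concat(series_list, valid_list, frame):
    xy = np.concatenate([s.xy for s in series_list])
    valid = np.concatenate(list(valid_list))
    return PlanarCOPSeries(xy=xy, valid=valid, frame=frame)


# ---------------------------------------------------------------------------
# cross-validation
# ---------------------------------------------------------------------------

@dataclass
class CrossValidationResult:
    report: pd.DataFrame
    audits: list = field(default_factory=list)
    models: dict = field(default_factory=dict)

    def train_test_disjoint(self) -> bool:
        """Audit: no (trial, frame) pair used for training appears in a test."""
        return all(not (a["train_keys"] & a["test_keys"]) for a in self.audits)


def _frame_keys(prepared: PreparedTrial, valid: np.ndarray) -> set:
    return {(prepared.trial.trial_id, int(i)) for i in np.flatnonzero(valid)}


def crossvalidate(dataset: TrialSet, method: str, seed: int = 0, *,
                  h_grid=HIDDEN_GRID, partition: RegionPartition | None = None,
                  gate_threshold_n: float = 20.0,
                  train_tasks=TRAIN_TASKS, test_tasks=ALL_TASKS,
                  **train_kwargs) -> CrossValidationResult:
    """Two-fold cross-validation of one method over a trial set.

    Raises :class:`DataError` naming the participant and task when a
    required replication is missing.
    """
    method = method.upper()
    if method not in METHODS:
        raise DataError(f"unknown method {method!r}; expected one of {METHODS}")
    variant = None if method == "RIGID" else int(method[-1])
    if partition is None:
        partition = default_partition(dataset.geometry)

    prepared = {t.key: prepare_trial(t, dataset.geometry, gate_threshold_n)
                for t in dataset.trials}
    groups = sorted({(t.participant, t.foot) for t in dataset.trials})
    rows, audits, models = [], [], {}

    for participant, foot in groups:
        def get(task, rep):
            key = (participant, foot, task, rep)
            if key not in prepared:
                raise DataError(
                    f"missing replication {rep} of {task} for participant "
                    f"{participant}, {foot} foot")
            return prepared[key]

        for fold, (train_rep, test_rep) in enumerate([(1, 2), (2, 1)], start=1):
            train_prep = [get(task, train_rep) for task in train_tasks]
            test_prep = [get(task, test_rep) for task in test_tasks]
            fold_seed = seed * 2 + (fold - 1)

            if method == "RIGID":
                source = _concat([p.insole_cop for p in train_prep],
                                 [p.valid for p in train_prep], "insole")
                target = _concat([p.shoe_cop for p in train_prep],
                                 [p.valid for p in train_prep], "shoe")
                model = fit_rigid(source, target)
                predict_one = (lambda m: lambda p: apply_rigid(
                    m, _masked(p.insole_cop, p.valid)))(model)
            else:
                pca_model = None
                if variant == 1:
                    forces = np.concatenate([
                        pressures_to_normalized_forces(p.trial.insole,
                                                       dataset.geometry)[p.valid]
                        for p in train_prep])
                    pca_model = fit_pca(forces)
                feats = {p.trial.trial_id: build_features(
                    p.trial.insole, dataset.geometry, partition, variant,
                    pca_model) for p in list(prepared.values())}
                x_train = np.concatenate([feats[p.trial.trial_id].values[p.valid]
                                          for p in train_prep])
                y_train = np.concatenate([p.shoe_cop.xy[p.valid]
                                          for p in train_prep])
                model = select_hidden_size(x_train, y_train, h_grid=h_grid,
                                           seed=fold_seed, **train_kwargs)
                predict_one = lambda p: predict(
                    model, feats[p.trial.trial_id].values, valid=p.valid)

            models[(participant, foot, fold)] = model
            train_keys = set().union(*[_frame_keys(p, p.valid) for p in train_prep])
            test_keys = set()
            for p in test_prep:
                est = predict_one(p)
                ref = _masked(p.shoe_cop, p.valid)
                test_keys |= _frame_keys(p, p.valid & est.valid)
                for axis in AXES:
                    rows.append({
                        "participant": participant, "foot": foot,
                        "task": p.trial.task, "method": method, "fold": fold,
                        "axis": axis,
                        "rmse_mm": rmse(est, ref, axis),
                        "pae_mm": pae(est, ref, axis),
                        "r2": r2(est, ref, axis),
                        "n_frames": int(np.sum(p.valid & est.valid)),
                    })
            audits.append({"participant": participant, "foot": foot, "fold": fold,
                           "train_keys": train_keys, "test_keys": test_keys})

    report = pd.DataFrame(rows).sort_values(
        ["participant", "foot", "fold", "task", "axis"]).reset_index(drop=True)
    return CrossValidationResult(report=report, audits=audits, models=models)


def summarize(report: pd.DataFrame) -> pd.DataFrame:
    """Mean and 95% CI of each measure per (task, method, axis)."""
    def agg(group):
        out = {}
        for col in ("rmse_mm", "pae_mm", "r2"):
            vals = group[col].dropna().to_numpy()
            mean = vals.mean() if len(vals) else np.nan
            if len(vals) > 1:
                half = (_stats.t.ppf(0.975, len(vals) - 1)
                        * vals.std(ddof=1) / np.sqrt(len(vals)))
            else:
                half = np.nan
            out[f"{col}_mean"] = mean
            out[f"{col}_ci95"] = half
        out["n"] = len(group)
        return pd.Series(out)
    return (report.groupby(["task", "method", "axis"])
            .apply(agg, include_groups=False).reset_index())
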