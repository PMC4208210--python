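"""Input-variable sets extracted from insole recordings for the MFNN mapping.

Four variants are defined, each ending with the insole-frame COP (XY, mm):

* ``MFNN1`` — principal-component scores of the 99 normalized sensor forces
  (smallest number of components whose cumulative explained variance
  exceeds 90%), plus COP.  Width k + 2.
* ``MFNN2`` — total normalized force and the global active-sensor ratio,
  plus COP.  Width 4.
* ``MFNN3`` — total normalized force and the active-sensor ratio in each of
  eight insole regions, plus COP.  Width 11.
* ``MFNN4`` — normalized force and active-sensor ratio in each of the eight
  regions, plus COP.  Width 18.

Sensor pressures are converted to forces (pressure x area) and normalized by
half the participant's body weight (0.5 m g), making the force features
dimensionless.  A sensor counts as active when its pressure is strictly
positive.  The eight regions split the insole into lateral/medial heel, two
midfoot areas, three forefoot areas and one toe area, with longitudinal cuts
at 30/60/85% of insole length; the boundaries live in an editable partition
table so labs can substitute their own region definitions.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from sklearn.decomposition import PCA

from .errors import DataError
from .frames import insole_cop
from .signal_io import N_SENSORS, InsoleRecording, SensorGeometry

GRAVITY_MS2 = 9.81
PCA_VARIANCE_THRESHOLD = 0.90

REGIONS = ("heel_lateral", "heel_medial", "midfoot_1", "midfoot_2",
           "forefoot_1", "forefoot_2", "forefoot_3", "toes")

#: longitudinal band edges as fractions of insole length (heel at 0)
BAND_FRACTIONS = {"heel": (0.0, 0.30), "midfoot": (0.30, 0.60),
                  "forefoot": (0.60, 0.85), "toes": (0.85, 1.0 + 1e-9)}


@dataclass
class RegionPartition:
    """Assignment of each of the 99 sensors to one of eight regions."""

    labels: np.ndarray          # (99,) of str, values in REGIONS

    def __post_init__(self):
        self.labels = np.asarray(self.labels, dtype=object)
        if self.labels.shape != (N_SENSORS,):
            raise DataError(f"partition must label exactly {N_SENSORS} sensors")
        unknown = set(self.labels) - set(REGIONS)
        if unknown:
            raise DataError(f"unknown region labels: {sorted(unknown)}")
        for region in REGIONS:
            if not np.any(self.labels == region):
                raise DataError(f"region {region!r} is empty")

    def indices(self, region: str) -> np.ndarray:
        return np.flatnonzero(self.labels == region)


def default_partition(geom: SensorGeometry) -> RegionPartition:
    """Partition a sensor layout by the default boundary rules.

    Heel and midfoot are split medial/lateral at the insole midline (medial
    = positive X by convention); the forefoot is split into medial, central
    and lateral thirds by sensor X position.
    """
    frac = geom.centers_mm[:, 1] / geom.length_mm
    midline = geom.centers_mm[:, 0].mean()
    labels = np.empty(N_SENSORS, dtype=object)

    heel = (frac >= BAND_FRACTIONS["heel"][0]) & (frac < BAND_FRACTIONS["heel"][1])
    mid = (frac >= BAND_FRACTIONS["midfoot"][0]) & (frac < BAND_FRACTIONS["midfoot"][1])
    fore = (frac >= BAND_FRACTIONS["forefoot"][0]) & (frac < BAND_FRACTIONS["forefoot"][1])
    toes = frac >= BAND_FRACTIONS["toes"][0]

    medial = geom.centers_mm[:, 0] >= midline
    labels[heel & medial] = "heel_medial"
    labels[heel & ~medial] = "heel_lateral"
    labels[mid & medial] = "midfoot_2"
    labels[mid & ~medial] = "midfoot_1"

    fi = np.flatnonzero(fore)
    order = fi[np.argsort(-geom.centers_mm[fi, 0])]   # medial first
    thirds = np.array_split(order, 3)
    for name, idx in zip(("forefoot_1", "forefoot_2", "forefoot_3"), thirds):
        labels[idx] = name
    labels[toes] = "toes"
    return RegionPartition(labels=labels)


def write_partition(path, partition: RegionPartition) -> None:
    pd.DataFrame({"sensor": np.arange(1, N_SENSORS + 1),
                  "region": partition.labels}).to_csv(path, index=False)


def read_partition(path) -> RegionPartition:
    tab = pd.read_csv(path)
    if list(tab.columns[:2]) != ["sensor", "region"] or len(tab) != N_SENSORS:
        raise DataError(f"{path}: expected columns sensor,region with {N_SENSORS} rows")
    labels = np.empty(N_SENSORS, dtype=object)
    labels[tab["sensor"].to_numpy() - 1] = tab["region"].to_numpy()
    return RegionPartition(labels=labels)


# ---------------------------------------------------------------------------
# primitive feature operations
# ---------------------------------------------------------------------------

def pressures_to_normalized_forces(rec: InsoleRecording,
                                   geom: SensorGeometry) -> np.ndarray:
    """Per-sensor forces normalized by half body weight (dimensionless).

    kPa x mm^2 = mN, hence the /1000 to Newtons before normalization.
    """
    if rec.body_mass_kg <= 0:
        raise DataError("body mass must be positive")
    forces_n = rec.pressure_kpa * geom.areas_mm2 / 1000.0
    half_bw = 0.5 * rec.body_mass_kg * GRAVITY_MS2
    return forces_n / half_bw


def active_ratio(pressures: np.ndarray, subset: np.ndarray | None = None) -> np.ndarray:
    """Fraction of sensors in ``subset`` with strictly positive pressure.

    ``pressures`` may be one frame (99,) or a stack (n, 99); the denominator
    is the subset size (99 for the global ratio, the region size for
    regional ratios).
    """
    pressures = np.atleast_2d(np.asarray(pressures, dtype=float))
    if subset is None:
        subset = np.arange(pressures.shape[1])
    subset = np.asarray(subset)
    if subset.size == 0:
        raise DataError("sensor subset must be non-empty")
    ratio = (pressures[:, subset] > 0).mean(axis=1)
    return ratio if ratio.size > 1 else ratio.reshape(-1)


# ---------------------------------------------------------------------------
# PCA
# ---------------------------------------------------------------------------

@dataclass
class PCAModel:
    """Frozen training-fold PCA: mean, loadings and retained-component count."""

    mean: np.ndarray                    # (99,)
    components: np.ndarray              # (k, 99)
    explained_variance_ratio: np.ndarray
    k: int


def fit_pca(train_forces: np.ndarray,
            threshold: float = PCA_VARIANCE_THRESHOLD) -> PCAModel:
    """Mean-centered PCA on training-fold normalized forces.

    Retains the smallest k whose cumulative explained variance exceeds the
    threshold (>90% by default).  No variance scaling: inputs share units.
    """
    x = np.asarray(train_forces, dtype=float)
    if x.ndim != 2 or len(x) < 2:
        raise DataError("PCA needs at least two training frames")
    if np.allclose(x.var(axis=0), 0):
        raise DataError("zero-variance training data")
    pca = PCA()
    pca.fit(x)
    ratios = pca.explained_variance_ratio_
    k = int(np.searchsorted(np.cumsum(ratios), threshold) + 1)
    k = min(k, len(ratios))
    return PCAModel(mean=pca.mean_, components=pca.components_[:k],
                    explained_variance_ratio=ratios, k=k)


def project_pca(model: PCAModel, forces: np.ndarray) -> np.ndarray:
    return (np.asarray(forces, dtype=float) - model.mean) @ model.components.T


def write_pca(path, model: PCAModel) -> None:
    import json
    doc = {"mean": model.mean.tolist(), "components": model.components.tolist(),
           "explained_variance_ratio": model.explained_variance_ratio.tolist(),
           "k": model.k}
    with open(path, "w") as fh:
        json.dump(doc, fh, indent=1)


def read_pca(path) -> PCAModel:
    import json
    with open(path) as fh:
        doc = json.load(fh)
    return PCAModel(mean=np.asarray(doc["mean"]),
                    components=np.asarray(doc["components"]),
                    explained_variance_ratio=np.asarray(doc["explained_variance_ratio"]),
                    k=int(doc["k"]))


# ---------------------------------------------------------------------------
# feature-matrix assembly
# ---------------------------------------------------------------------------

@dataclass
class FeatureMatrix:
    values: np.ndarray          # (n, m)
    names: list[str]
    variant: int
    valid: np.ndarray           # (n,) rows usable downstream (nonzero load)

    @property
    def width(self) -> int:
        return self.values.shape[1]

    def __len__(self):
        return len(self.values)


def build_features(rec: InsoleRecording, geom: SensorGeometry,
                   partition: RegionPartition, variant: int,
                   pca_model: PCAModel | None = None) -> FeatureMatrix:
    """Assemble the input-variable set for one MFNN variant.

    Rows align one-to-one with recording frames; the ``valid`` mask flags
    frames with nonzero total load (insole COP defined).  ``pca_model`` is
    required for variant 1 and ignored otherwise.
    """
    if variant not in (1, 2, 3, 4):
        raise DataError(f"unknown variant {variant!r}; expected 1-4")
    forces = pressures_to_normalized_forces(rec, geom)
    cop = insole_cop(rec, geom)
    cols: list[np.ndarray] = []
    names: list[str] = []

    if variant == 1:
        if pca_model is None:
            raise DataError("variant 1 requires a fitted PCA model")
        scores = project_pca(pca_model, forces)
        cols.extend(scores.T)
        names.extend(f"pc{j + 1}" for j in range(pca_model.k))
    elif variant == 2:
        cols.append(forces.sum(axis=1))
        names.append("total_force")
        cols.append(active_ratio(rec.pressure_kpa))
        names.append("active_ratio")
    elif variant == 3:
        cols.append(forces.sum(axis=1))
        names.append("total_force")
        for region in REGIONS:
            cols.append(active_ratio(rec.pressure_kpa, partition.indices(region)))
            names.append(f"ratio_{region}")
    else:   # variant 4
        for region in REGIONS:
            cols.append(forces[:, partition.indices(region)].sum(axis=1))
            names.append(f"force_{region}")
        for region in REGIONS:
            cols.append(active_ratio(rec.pressure_kpa, partition.indices(region)))
            names.append(f"ratio_{region}")

    cols.append(cop.xy[:, 0])
    cols.append(cop.xy[:, 1])
    names.extend(["cop_x", "cop_y"])
    values = np.column_stack(cols)
    return FeatureMatrix(values=values, names=names, variant=variant,
                         valid=cop.valid.copy())


def write_features(path, fm: FeatureMatrix) -> None:
    tab = pd.DataFrame(fm.values, columns=fm.names)
    tab.insert(0, "frame", np.arange(len(fm)))
    tab["valid"] = fm.valid.astype(int)
    with open(path, "w") as fh:
        fh.write(f"# variant = MFNN{fm.variant}\n")
        tab.to_csv(fh, index=False, float_format="%.6f")
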