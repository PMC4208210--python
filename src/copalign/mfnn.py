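"""One-hidden-layer feed-forward network mapping features to shoe-frame COP.

Architecture: sigmoid (logistic) hidden layer, linear output layer of width
two (AP and ML coordinates in mm).  Inputs and targets are standardized with
training-fold statistics; predictions are destandardized on the way out.
Hidden sizes from 3 to 20 are considered, and the final size minimizes the
RMS error on a held-out 20% slice of the training fold (ties broken toward
the smallest network).

Training delegates to scikit-learn's MLPRegressor (L-BFGS by default, which
is deterministic given the initialization seed, with an L2 penalty for
capacity control); the fitted weights are copied into a plain
:class:`TrainedMapper` so prediction and serialization are self-contained.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass

import numpy as np
from scipy.special import expit
from sklearn.exceptions import ConvergenceWarning
from sklearn.neural_network import MLPRegressor

from .errors import DataError, InsufficientDataError
from .features import FeatureMatrix
from .frames import PlanarCOPSeries

HIDDEN_GRID = tuple(range(3, 21))
MIN_ROWS = 50
VALIDATION_FRACTION = 0.2


def _as_xy(features) -> tuple[np.ndarray, np.ndarray | None, int | None]:
    if isinstance(features, FeatureMatrix):
        return features.values, features.valid, features.variant
    x = np.asarray(features, dtype=float)
    return x, None, None


@dataclass
class TrainedMapper:
    """A trained network plus the standardization constants to use it."""

    variant: int | None
    hidden: int
    x_mean: np.ndarray
    x_scale: np.ndarray
    y_mean: np.ndarray
    y_scale: np.ndarray
    w1: np.ndarray              # (m, h)
    b1: np.ndarray              # (h,)
    w2: np.ndarray              # (h, 2)
    b2: np.ndarray              # (2,)
    seed: int = 0
    train_rmse_mm: float = float("nan")
    val_rmse_mm: float = float("nan")

    @property
    def n_inputs(self) -> int:
        return self.w1.shape[0]

    def forward(self, x: np.ndarray) -> np.ndarray:
        xs = (x - self.x_mean) / self.x_scale
        hidden = expit(xs @ self.w1 + self.b1)
        ys = hidden @ self.w2 + self.b2
        return ys * self.y_scale + self.y_mean


def _standardize_params(a: np.ndarray):
    mean = a.mean(axis=0)
    scale = a.std(axis=0)
    scale = np.where(scale > 1e-12, scale, 1.0)   # constant columns pass through
    return mean, scale


def _param_count(m: int, h: int) -> int:
    return (m + 1) * h + (h + 1) * 2


def train(features, targets, hidden: int, seed: int = 0, *,
          max_iter: int = 300, alpha: float = 1e-4,
          solver: str = "lbfgs") -> TrainedMapper:
    """Train one network of the given hidden size.

    ``features`` may be a FeatureMatrix (its validity mask selects rows) or a
    plain array.  Deterministic given ``seed``.  Raises
    :class:`InsufficientDataError` when there are fewer rows than the larger
    of 50 and the network's parameter count.
    """
    x, valid, variant = _as_xy(features)
    y = np.asarray(targets, dtype=float)
    if y.ndim != 2 or y.shape[1] != 2:
        raise DataError(f"targets must be (n, 2) COP coordinates, got {y.shape}")
    if valid is not None:
        x, y = x[valid], y[valid]
    if not np.all(np.isfinite(x)) or not np.all(np.isfinite(y)):
        raise DataError("features/targets contain non-finite values")
    n, m = x.shape
    need = max(MIN_ROWS, _param_count(m, hidden))
    if n < need:
        raise InsufficientDataError(
            f"{n} rows < {need} required for {m} inputs and {hidden} hidden units "
            f"({_param_count(m, hidden)} parameters)")

    x_mean, x_scale = _standardize_params(x)
    y_mean, y_scale = _standardize_params(y)
    xs = (x - x_mean) / x_scale
    ys = (y - y_mean) / y_scale

    net = MLPRegressor(hidden_layer_sizes=(hidden,), activation="logistic",
                       solver=solver, alpha=alpha, max_iter=max_iter,
                       random_state=int(seed), tol=1e-7)
    with warnings.catch_warnings():
        # max_iter is a deliberate budget; stopping there is not a failure
        warnings.simplefilter("ignore", ConvergenceWarning)
        net.fit(xs, ys)
    mapper = TrainedMapper(
        variant=variant, hidden=hidden,
        x_mean=x_mean, x_scale=x_scale, y_mean=y_mean, y_scale=y_scale,
        w1=net.coefs_[0], b1=net.intercepts_[0],
        w2=net.coefs_[1], b2=net.intercepts_[1], seed=int(seed))
    resid = mapper.forward(x) - y
    mapper.train_rmse_mm = float(np.sqrt(np.mean(resid**2)))
    return mapper


def select_hidden_size(features, targets, h_grid=HIDDEN_GRID, seed: int = 0,
                       **train_kwargs) -> TrainedMapper:
    """Hidden-size model selection on an 80/20 split of the training fold.

    One network is trained per candidate size on the 80% slice; the mapper
    with the smallest validation RMS error on the 20% slice is returned
    (ties toward the smallest size).  Sizes whose parameter count exceeds
    the available rows are skipped; if every size is skipped the error from
    the smallest size propagates.
    """
    h_grid = list(h_grid)
    if not h_grid:
        raise DataError("hidden-size grid is empty")
    x, valid, variant = _as_xy(features)
    y = np.asarray(targets, dtype=float)
    if valid is not None:
        x, y = x[valid], y[valid]
    rng = np.random.default_rng(seed)
    n = len(x)
    perm = rng.permutation(n)
    n_val = max(1, int(round(VALIDATION_FRACTION * n)))
    val_idx, fit_idx = perm[:n_val], perm[n_val:]

    best: TrainedMapper | None = None
    first_error: Exception | None = None
    for h in h_grid:
        try:
            mapper = train(x[fit_idx], y[fit_idx], h, seed=seed, **train_kwargs)
        except InsufficientDataError as exc:
            if first_error is None:
                first_error = exc
            continue
        resid = mapper.forward(x[val_idx]) - y[val_idx]
        val_rmse = float(np.sqrt(np.mean(resid**2)))
        mapper.val_rmse_mm = val_rmse
        mapper.variant = variant
        if best is None or val_rmse < best.val_rmse_mm:   # strict: ties keep smaller h
            best = mapper
    if best is None:
        raise first_error if first_error else InsufficientDataError("no usable hidden size")
    if not (min(HIDDEN_GRID) <= best.hidden <= max(HIDDEN_GRID)) and set(h_grid) <= set(HIDDEN_GRID):
        raise AssertionError("selected hidden size escaped the 3..20 grid")
    return best


def predict(mapper: TrainedMapper, features,
            valid: np.ndarray | None = None) -> PlanarCOPSeries:
    """Map features to a shoe-frame COP estimate; masks pass through."""
    x, fm_valid, _ = _as_xy(features)
    if x.shape[1] != mapper.n_inputs:
        raise DataError(
            f"feature width {x.shape[1]} does not match mapper input width "
            f"{mapper.n_inputs}")
    if valid is None:
        valid = fm_valid if fm_valid is not None else np.ones(len(x), dtype=bool)
    xy = np.full((len(x), 2), np.nan)
    idx = np.flatnonzero(valid)
    if idx.size:
        xy[idx] = mapper.forward(x[idx])
    return PlanarCOPSeries(xy=xy, valid=np.asarray(valid, dtype=bool), frame="shoe")


# --- serialization ----------------------------------------------------------

def mapper_to_text(mapper: TrainedMapper) -> str:
    doc = {"variant": mapper.variant, "hidden": mapper.hidden,
           "seed": mapper.seed, "train_rmse_mm": mapper.train_rmse_mm,
           "val_rmse_mm": mapper.val_rmse_mm}
    for name in ("x_mean", "x_scale", "y_mean", "y_scale", "b1", "b2"):
        doc[name] = getattr(mapper, name).tolist()
    for name in ("w1", "w2"):
        doc[name] = getattr(mapper, name).tolist()
    return json.dumps(doc, indent=1)


def mapper_from_text(text: str) -> TrainedMapper:
    doc = json.loads(text)
    arrays = {k: np.asarray(doc[k], dtype=float)
              for k in ("x_mean", "x_scale", "y_mean", "y_scale", "w1", "b1", "w2", "b2")}
    return TrainedMapper(variant=doc["variant"], hidden=int(doc["hidden"]),
                         seed=int(doc["seed"]),
                         train_rmse_mm=float(doc["train_rmse_mm"]),
                         val_rmse_mm=float(doc["val_rmse_mm"]), **arrays)


def write_mapper(path, mapper: TrainedMapper) -> None:
    with open(path, "w") as fh:
        fh.write(mapper_to_text(mapper))


def read_mapper(path) -> TrainedMapper:
    with open(path) as fh:
        return mapper_from_text(fh.read())
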