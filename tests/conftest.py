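import numpy as np
import pytest

import copalign as ca
from copalign.synthetic import TASKS

NOISELESS = dict(marker_noise_mm=0.0, cop_noise_mm=0.0, pressure_noise_kpa=0.0)


@pytest.fixture(scope="session")
def geometry():
    return ca.make_sensor_geometry()


@pytest.fixture(scope="session")
def partition(geometry):
    return ca.default_partition(geometry)


@pytest.fixture(scope="session")
def noiseless_trial(geometry):
    """One zero-noise, zero-deformation trial with an asymmetric true transform."""
    cfg = ca.SyntheticConfig(theta_deg=17.3, d_mm=(22.0, -31.0), seed=7,
                             **NOISELESS)
    return cfg, ca.generate_trial(cfg, geometry)


@pytest.fixture(scope="session")
def noisy_trial(geometry):
    cfg = ca.SyntheticConfig(task="LL_ASYM", deformation_mm=5.0, seed=11)
    return cfg, ca.generate_trial(cfg, geometry)


def make_trialset(seed, deformation_mm, geometry, participant="P01", foot="left",
                  **overrides):
    """One participant-foot: two replications of all four MMH tasks."""
    trials = []
    for i, task in enumerate(TASKS):
        for rep in (1, 2):
            cfg = ca.SyntheticConfig(task=task, replication=rep,
                                     deformation_mm=deformation_mm,
                                     participant=participant, foot=foot,
                                     seed=seed * 16 + i * 2 + rep, **overrides)
            trial = ca.generate_trial(cfg, geometry)
            trials.append(ca.Trial(participant, foot, task, rep,
                                   trial.markers, trial.plate, trial.insole))
    return ca.TrialSet(trials=trials, geometry=geometry)


@pytest.fixture(scope="session")
def noiseless_trialset(geometry):
    return make_trialset(5, 0.0, geometry, **NOISELESS)


def prepared_series(trial, geometry):
    """Jointly valid insole and shoe-frame COP series from one trial."""
    t = ca.Trial(trial.markers.trial_id, "left", "LL_GROUND", 1,
                 trial.markers, trial.plate, trial.insole)
    prep = ca.prepare_trial(t, geometry)
    src = ca.PlanarCOPSeries(prep.insole_cop.xy, prep.valid, "insole")
    tgt = ca.PlanarCOPSeries(prep.shoe_cop.xy, prep.valid, "shoe")
    return src, tgt
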