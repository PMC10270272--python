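"""Shared fixtures: synthetic subjects and the (expensive) dispersion sweep."""

import numpy as np
import pytest

from cdgram.model import CardiodynamicsModel
from cdgram.synth import BeatTemplate, DispersionSpec, simulate_ecg

#: stt_jitter levels of the dispersion sweep, spanning the estimator's
#: responsive regime above the additive-noise floor.
SWEEP_LEVELS = (0.0, 0.2, 0.4, 0.8, 1.2)
SWEEP_SEEDS = tuple(range(10))
SWEEP_NOISE_MV = 0.01


def make_subject(stt_jitter=0.0, noise_mv=SWEEP_NOISE_MV, seed=0,
                 duration_s=20.0, heart_rate=60.0, **disp_kwargs):
    """One synthetic 12-lead record + ground truth."""
    tmpl = BeatTemplate(heart_rate=heart_rate)
    disp = DispersionSpec(stt_jitter=stt_jitter, noise_mv=noise_mv, seed=seed,
                          **disp_kwargs)
    return simulate_ecg(tmpl, disp, duration_s=duration_s)


@pytest.fixture(scope="session")
def clean_subject():
    """Noiseless, zero-dispersion 20 s record with ground truth."""
    return make_subject(noise_mv=0.0, seed=1)


@pytest.fixture(scope="session")
def clean_fit():
    """Fitted cardiodynamics model of a zero-dispersion subject."""
    rec, truth = make_subject(noise_mv=0.0, seed=1)
    model = CardiodynamicsModel.from_ecg(rec)
    return model, model.fit()


@pytest.fixture(scope="session")
def dispersion_sweep():
    """SHI / CDG value / trajectory dispersion over the full jitter sweep.

    Computed once per session (50 pipeline fits) and shared by the
    monotonicity tests.  Returns {level: list of dicts per seed}.
    """
    out = {}
    for level in SWEEP_LEVELS:
        rows = []
        for seed in SWEEP_SEEDS:
            rec, _ = make_subject(stt_jitter=level, seed=seed)
            model = CardiodynamicsModel.from_ecg(rec)
            res = model.fit()
            traj = res.trajectory
            segs = traj.points.reshape(model.loops.n_beats, model.loops.L, 3)
            # mean pairwise inter-beat segment distance
            nb = segs.shape[0]
            dists = [np.mean(np.linalg.norm(segs[i] - segs[j], axis=1))
                     for i in range(nb) for j in range(i + 1, nb)]
            rows.append({
                "shi": res.shi,
                "cdg_value": res.cdg_value,
                "traj_dispersion": float(np.mean(dists)),
            })
        out[level] = rows
    return out
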