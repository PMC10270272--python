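"""RBF lattice construction, deterministic learning and CDG generation."""

import numpy as np
import pytest

from cdgram.errors import LatticeSizeError
from cdgram.fiducials import STTLoopSet
from cdgram.model import (CardiodynamicsModel, LearningParams, RBFNetwork,
                          build_rbf_lattice, generate_cdg, learn_dynamics)

from conftest import make_subject


def _unit_cube_loops(n_beats=2, L=20):
    """Loops whose bounding box is exactly the unit cube."""
    rng = np.random.default_rng(0)
    loops = rng.uniform(0.05, 0.95, size=(n_beats, L, 3))
    loops[0, 0] = [0, 0, 0]
    loops[0, 1] = [1, 1, 1]
    return STTLoopSet(loops, fs=1000.0)


def _limit_cycle_loops(n_beats=8, L=100, noise=0.0, seed=0):
    """A closed, noiseless (or noisy) 3-D limit cycle repeated n_beats times."""
    rng = np.random.default_rng(seed)
    th = np.linspace(0, 2 * np.pi, L, endpoint=False)
    loop = np.column_stack([np.cos(th), np.sin(th), 0.3 * np.sin(2 * th)])
    loops = np.tile(loop, (n_beats, 1, 1))
    if noise:
        loops += noise * rng.standard_normal(loops.shape)
    return STTLoopSet(loops, fs=1000.0)


class TestLattice:
    def test_unit_cube_spacing_half_gives_125_centers(self):
        net = build_rbf_lattice(_unit_cube_loops(), spacing=0.5)
        assert net.n_centers == 125
        for axis in range(3):
            vals = np.unique(net.centers[:, axis])
            assert np.allclose(vals, [-0.5, 0.0, 0.5, 1.0, 1.5])

    def test_spacing_larger_than_box_still_covers(self):
        net = build_rbf_lattice(_unit_cube_loops(), spacing=5.0)
        assert net.n_centers >= 8
        assert len(np.unique(net.centers[:, 0])) >= 2

    def test_weights_start_at_zero(self):
        net = build_rbf_lattice(_unit_cube_loops(), spacing=0.5)
        assert not net.weights.any()

    def test_center_cap_enforced(self):
        with pytest.raises(LatticeSizeError):
            build_rbf_lattice(_unit_cube_loops(), spacing=0.01)


class TestLearning:
    def test_one_step_prediction_on_limit_cycle(self):
        """Learned dynamics predicts the per-step change to < 5% RMS."""
        loops = _limit_cycle_loops()
        net = build_rbf_lattice(loops)
        trained = learn_dynamics(loops, net)
        orbit = loops.concatenated()
        pred = trained.dynamics(orbit[:-1])
        obs = np.diff(orbit, axis=0)
        rmse = np.sqrt(np.mean((pred - obs) ** 2))
        assert rmse < 0.05 * np.mean(np.linalg.norm(obs, axis=1))

    def test_zero_adaptation_leaves_weights_zero(self):
        loops = _limit_cycle_loops(n_beats=2)
        net = build_rbf_lattice(loops)
        trained = learn_dynamics(loops, net, LearningParams(gamma=0.0, epochs=2))
        assert not trained.weights.any()

    def test_training_deterministic(self):
        loops = _limit_cycle_loops(noise=0.01, seed=3)
        net = build_rbf_lattice(loops)
        w1 = learn_dynamics(loops, net, LearningParams(epochs=5)).weights
        w2 = learn_dynamics(loops, net, LearningParams(epochs=5)).weights
        assert np.array_equal(w1, w2)

    def test_rbf_representable_dynamics_recovered(self):
        """When the true step map is an RBF field on the lattice, the learned
        field matches it along the orbit to <= 10% relative error."""
        loops0 = _limit_cycle_loops(n_beats=1)
        net = build_rbf_lattice(loops0)
        orbit0 = loops0.concatenated()
        # project the cycle's step field onto the lattice -> true weights
        s = net.regressor(orbit0)
        delta = np.vstack([np.diff(orbit0, axis=0),
                           (orbit0[0] - orbit0[-1])[None, :]])
        w_true, *_ = np.linalg.lstsq(s, delta, rcond=None)
        truth = RBFNetwork(net.centers, net.width, w_true)
        # rebuild an orbit that follows the RBF field exactly
        x = orbit0[0].copy()
        pts = []
        for _ in range(8 * len(orbit0)):
            pts.append(x.copy())
            x = x + truth.dynamics(x)[0]
        L = len(orbit0)
        loops = STTLoopSet(np.array(pts).reshape(8, L, 3), fs=1000.0)
        trained = learn_dynamics(loops, build_rbf_lattice(loops))
        on_orbit = loops.concatenated()
        f_true = truth.dynamics(on_orbit)
        f_hat = trained.dynamics(on_orbit)
        rel = (np.linalg.norm(f_hat - f_true)
               / np.linalg.norm(f_true))
        assert rel <= 0.10

    def test_kernel_localization(self):
        """Points several widths outside the lattice produce ~zero output."""
        loops = _limit_cycle_loops(n_beats=2)
        trained = learn_dynamics(loops, build_rbf_lattice(loops))
        on = np.max(np.abs(trained.dynamics(loops.concatenated())))
        span = trained.centers.max(axis=0)
        far = span + 5.0 * trained.width
        off = np.max(np.abs(trained.dynamics(far[None, :])))
        assert off < 1e-6 * on


class TestCDG:
    def test_zero_weight_net_warns_and_zero_trajectory(self):
        loops = _limit_cycle_loops(n_beats=2)
        net = build_rbf_lattice(loops)
        with pytest.warns(UserWarning):
            traj = generate_cdg(net, loops)
        assert traj.n_points == loops.n_beats * loops.L
        assert not traj.points.any()

    def test_identical_loops_give_identical_segments(self):
        loops = _limit_cycle_loops(n_beats=6)
        trained = learn_dynamics(loops, build_rbf_lattice(loops))
        traj = generate_cdg(trained, loops)
        segs = traj.points.reshape(6, loops.L, 3)
        assert np.abs(segs - segs[0]).max() < 1e-6

    def test_dispersion_monotone_in_generator_jitter(self, dispersion_sweep):
        """Mean inter-beat CDG segment distance tracks the ST-T dispersion
        parameter (Spearman rho >= 0.9 across the sweep)."""
        from scipy.stats import spearmanr

        levels = sorted(dispersion_sweep)
        med = [np.median([r["traj_dispersion"] for r in dispersion_sweep[lv]])
               for lv in levels]
        rho, _ = spearmanr(levels, med)
        assert rho >= 0.9

    def test_model_results_interface(self, clean_fit):
        model, res = clean_fit
        assert res.trajectory.n_points == model.loops.n_beats * model.loops.L
        assert np.isfinite(res.shi) and np.isfinite(res.thi)
        assert res.call in ("positive", "negative")
        text = res.summary()
        assert "SHI" in text and "CDG value" in text

    def test_fit_deterministic(self):
        rec, _ = make_subject(noise_mv=0.01, seed=9, duration_s=12.0)
        r1 = CardiodynamicsModel.from_ecg(rec).fit()
        r2 = CardiodynamicsModel.from_ecg(rec).fit()
        assert r1.cdg_value == r2.cdg_value
        assert np.array_equal(r1.trajectory.points, r2.trajectory.points)
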