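"""SHI/THI: brute-force oracle equivalence, invariances, determinism."""

import math

import numpy as np
import pytest

from cdgram.errors import DegenerateTrajectoryError, TrajectorySizeError
from cdgram.heterogeneity import compute_indices, compute_shi, compute_thi
from cdgram.model import CDGTrajectory


# -- independent brute-force oracles (kept deliberately naive) ---------------

def shi_oracle(points, step_k=10, theiler_w=10):
    """Direct formula: exhaustive nearest-neighbor search, no vectorization."""
    n = len(points)
    logs = []
    for i in range(n - step_k):
        best_j, best_d = None, math.inf
        for j in range(n - step_k):
            if abs(i - j) <= theiler_w:
                continue
            d = math.dist(points[i], points[j])
            if 0.0 < d < best_d:
                best_d, best_j = d, j
        if best_j is None:
            continue
        d2 = math.dist(points[i + step_k], points[best_j + step_k])
        if d2 == 0.0:
            continue
        logs.append(math.log(d2 / best_d))
    if not logs:
        raise ValueError("degenerate")
    return sum(logs) / len(logs)


def thi_oracle(points, grid=None):
    """Exhaustive grid scan of |F(lam)| * exp(-0.1 lam), smallest-lam ties."""
    norms = [math.dist(p, (0, 0, 0)) for p in points]
    mean = sum(norms) / len(norms)
    spec = np.abs(np.fft.rfft([v - mean for v in norms]))
    if grid is None:
        grid = range(1, len(points) // 2 + 1)
    best_lam, best_obj = None, math.inf
    for lam in grid:
        obj = spec[lam] * math.exp(-0.1 * lam)
        if obj < best_obj:  # strict: keeps the smallest lam on ties
            best_obj, best_lam = obj, lam
    return float(best_lam)


def _two_cycle_fixture(seed=7, n=40):
    """Two slowly diverging noisy cycles, 40 points."""
    rng = np.random.default_rng(seed)
    th = np.linspace(0, 4 * np.pi, n)
    growth = np.exp(0.02 * np.arange(n))
    pts = np.column_stack([growth * np.cos(th), growth * np.sin(th),
                           0.1 * th]) + 0.01 * rng.standard_normal((n, 3))
    return pts


class TestSHI:
    @pytest.mark.parametrize("seed", range(50))
    def test_matches_brute_force_on_random_trajectories(self, seed):
        rng = np.random.default_rng(seed)
        n = int(rng.integers(30, 201))
        pts = rng.standard_normal((n, 3))
        w = int(rng.integers(0, 12))
        assert compute_shi(pts, step_k=10, theiler_w=w) == pytest.approx(
            shi_oracle(pts, 10, w), abs=1e-12)

    def test_seed7_fixture_matches_oracle(self):
        pts = _two_cycle_fixture()
        assert compute_shi(pts, step_k=10, theiler_w=5) == pytest.approx(
            shi_oracle(pts, 10, 5), abs=1e-12)

    def test_exactly_periodic_trajectory_gives_zero(self):
        """Period dividing step_k: every pair recurs, so all log ratios are 0."""
        cycle = np.column_stack([np.cos(np.linspace(0, 2 * np.pi, 10,
                                                    endpoint=False)),
                                 np.sin(np.linspace(0, 2 * np.pi, 10,
                                                    endpoint=False)),
                                 np.zeros(10)])
        pts = np.tile(cycle, (4, 1))
        assert compute_shi(pts, step_k=10, theiler_w=0) == pytest.approx(0.0,
                                                                         abs=1e-12)

    def test_scale_and_translation_invariance(self):
        pts = _two_cycle_fixture(seed=11)
        base = compute_shi(pts, theiler_w=5)
        assert compute_shi(4.2 * pts, theiler_w=5) == pytest.approx(base,
                                                                    rel=1e-12)
        assert compute_shi(pts + np.array([5.0, -3.0, 2.0]),
                           theiler_w=5) == pytest.approx(base, rel=1e-9)

    def test_shi_monotone_in_dispersion(self, dispersion_sweep):
        """Median SHI strictly increases over the 5-level jitter sweep."""
        levels = sorted(dispersion_sweep)
        med = [np.median([r["shi"] for r in dispersion_sweep[lv]])
               for lv in levels]
        assert all(a < b for a, b in zip(med, med[1:]))

    def test_degenerate_inputs_raise(self):
        with pytest.raises(TrajectorySizeError):
            compute_shi(np.zeros((5, 3)), step_k=10)
        with pytest.raises(DegenerateTrajectoryError):
            compute_shi(np.zeros((50, 3)), step_k=10, theiler_w=0)

    def test_trajectory_object_uses_loop_length_theiler(self):
        pts = _two_cycle_fixture(seed=13, n=60)
        traj = CDGTrajectory(pts, loop_length=20)
        assert compute_shi(traj) == pytest.approx(shi_oracle(pts, 10, 20),
                                                  abs=1e-12)


class TestTHI:
    def test_single_zero_bin_is_the_argmin(self):
        """A tone at bin 3 leaves every other bin ~zero; the damped objective
        then bottoms out wherever the spectrum is zero — but a *zeroed* bin in
        an otherwise flat spectrum is the unique minimizer."""
        n = 64
        k = np.arange(n)
        # construct a norm series whose spectrum is flat except a null at 3
        rng = np.random.default_rng(2)
        series = rng.standard_normal(n)
        f = np.fft.rfft(series - series.mean())
        f[3] = 0.0
        # a damped objective can still prefer large bins; restrict the grid
        pts = np.column_stack([np.abs(np.fft.irfft(f, n)) + 2.0,
                               np.zeros(n), np.zeros(n)])
        grid = np.arange(1, 9)
        got = compute_thi(pts, lambda_grid=grid)
        assert got == thi_oracle(pts, range(1, 9))

    def test_tie_breaks_to_smallest_lambda(self, monkeypatch):
        import cdgram.heterogeneity as het

        monkeypatch.setattr(het, "_magnitude_spectrum",
                            lambda points, mode: np.array(
                                [9.0, 5.0, 2.0 * np.exp(0.2), 7.0, 9.0,
                                 2.0 * np.exp(0.5), 9.0]))
        # objective equal (2.0 * exp(0.1*lam) damped back to 2.0) at 2 and 5
        pts = np.zeros((12, 3))
        assert compute_thi(pts, lambda_grid=np.array([2, 5])) == 2.0

    def test_seed7_fixture_matches_grid_scan(self):
        pts = _two_cycle_fixture()
        assert compute_thi(pts) == thi_oracle(pts)

    def test_repeated_calls_bit_identical(self):
        pts = _two_cycle_fixture(seed=21, n=120)
        vals = {compute_thi(pts) for _ in range(5)}
        assert len(vals) == 1

    def test_bad_grid_rejected(self):
        pts = _two_cycle_fixture()
        with pytest.raises(ValueError):
            compute_thi(pts, lambda_grid=np.array([]))
        with pytest.raises(ValueError):
            compute_thi(pts, lambda_grid=np.array([5, 3]))


def test_compute_indices_bundles_both():
    pts = _two_cycle_fixture(seed=5, n=80)
    idx = compute_indices(pts, step_k=10, theiler_w=8)
    assert idx.n_points == 80 and idx.step_k == 10
    assert idx.shi == pytest.approx(shi_oracle(pts, 10, 8), abs=1e-12)
    assert idx.thi == thi_oracle(pts)
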