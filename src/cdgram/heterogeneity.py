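"""Spatial and temporal heterogeneity indices of a CDG trajectory.

SHI — spatial heterogeneity index
    A Lyapunov-style divergence rate.  For each trajectory point n, let
    ``d_n1`` be the distance to its nearest neighbor j (temporal neighbors
    within a Theiler window excluded, exact duplicates skipped) and ``d_n2``
    the distance between the two points ``step_k`` steps later:

        SHI = (1/N') * sum_n ln(d_n2 / d_n1)

    over the N' points whose indices stay in range.  A trajectory whose
    beats repeat exactly has d_n2 = d_n1 and SHI = 0; diverging neighboring
    segments give SHI > 0.  SHI is invariant to uniform scaling and
    translation of the trajectory.

THI — temporal heterogeneity index
    The frequency-bin index minimizing an exponentially damped Fourier
    objective:

        THI = argmin_{lambda_i} |F(lambda_i)| * exp(-0.1 * lambda_i)

    where F is the magnitude spectrum of the trajectory.  By default F is the
    real-FFT of the Euclidean norm series ||p_n|| after mean removal,
    evaluated at integer bins lambda_i in {1, ..., floor(N/2)}; ties break to
    the smallest lambda.  This bin-index reading of the objective is a
    documented package convention (``spectrum_mode="axes"`` averages per-axis
    spectra instead).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.spatial.distance import cdist

from .errors import DegenerateTrajectoryError, TrajectorySizeError
from .model import CDGTrajectory


@dataclass
class HeterogeneityIndices:
    """SHI/THI pair with the bookkeeping needed to reproduce them."""

    shi: float
    thi: float
    n_points: int
    step_k: int

    def __post_init__(self):
        if self.n_points <= self.step_k:
            raise TrajectorySizeError("n_points must exceed step_k")


def _as_points(traj) -> tuple:
    if isinstance(traj, CDGTrajectory):
        return traj.points, traj.loop_length
    return np.asarray(traj, dtype=float), None


def compute_shi(traj, step_k: int = 10, theiler_w: int | None = None) -> float:
    """Mean log divergence ratio over a ``step_k``-step horizon.

    ``theiler_w`` excludes neighbors with |n - j| <= theiler_w from the
    nearest-neighbor search; the default is one loop length when the
    trajectory carries it, else ``step_k``.  Zero-distance (duplicate)
    neighbors are skipped in favor of the nearest distinct one.
    """
    points, loop_len = _as_points(traj)
    n = points.shape[0]
    if theiler_w is None:
        theiler_w = loop_len if loop_len else step_k
    if n < step_k + 2:
        raise TrajectorySizeError(
            f"trajectory of {n} points too short for step_k={step_k}"
        )
    d = cdist(points, points)
    idx = np.arange(n)
    band = np.abs(idx[:, None] - idx[None, :]) <= theiler_w
    invalid = band | (d == 0.0)
    # neighbor must itself have a point step_k later
    invalid[:, n - step_k:] = True
    dm = np.where(invalid, np.inf, d)
    logs = []
    for i in range(n - step_k):
        j = int(np.argmin(dm[i]))
        d1 = dm[i, j]
        if not np.isfinite(d1):
            continue
        d2 = np.linalg.norm(points[i + step_k] - points[j + step_k])
        if d2 == 0.0:
            continue
        logs.append(np.log(d2 / d1))
    if not logs:
        raise DegenerateTrajectoryError(
            "no usable neighbor pairs (all points duplicated or too few points)"
        )
    return float(np.mean(logs))


def compute_thi(traj, lambda_grid=None, spectrum_mode: str = "norm") -> float:
    """Damped-spectrum argmin; deterministic, ties to the smallest bin."""
    points, _ = _as_points(traj)
    n = points.shape[0]
    if n == 0:
        raise ValueError("empty trajectory")
    spectrum = _magnitude_spectrum(points, spectrum_mode)
    if lambda_grid is None:
        lambda_grid = np.arange(1, n // 2 + 1)
    grid = np.asarray(lambda_grid)
    if grid.size == 0:
        raise ValueError("lambda_grid must be nonempty")
    if np.any(np.diff(grid) <= 0):
        raise ValueError("lambda_grid must be sorted ascending")
    if grid[0] < 0 or grid[-1] >= spectrum.size:
        raise ValueError("lambda_grid indexes outside the spectrum")
    objective = spectrum[grid] * np.exp(-0.1 * grid)
    return float(grid[int(np.argmin(objective))])  # argmin takes the first tie


def _magnitude_spectrum(points: np.ndarray, mode: str) -> np.ndarray:
    if mode == "norm":
        series = np.linalg.norm(points, axis=1)
        return np.abs(np.fft.rfft(series - series.mean()))
    if mode == "axes":
        centered = points - points.mean(axis=0)
        return np.abs(np.fft.rfft(centered, axis=0)).mean(axis=1)
    raise ValueError(f"unknown spectrum_mode {mode!r}")


def compute_indices(traj, step_k: int = 10, theiler_w: int | None = None,
                    lambda_grid=None, spectrum_mode: str = "norm") -> HeterogeneityIndices:
    """Convenience wrapper returning both indices for one trajectory."""
    points, _ = _as_points(traj)
    return HeterogeneityIndices(
        shi=compute_shi(traj, step_k=step_k, theiler_w=theiler_w),
        thi=compute_thi(traj, lambda_grid=lambda_grid, spectrum_mode=spectrum_mode),
        n_points=points.shape[0],
        step_k=step_k,
    )
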