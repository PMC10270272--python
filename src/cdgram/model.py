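"""Deterministic learning of ST-T loop dynamics and the CDG trajectory.

The concatenated ST-T loops form a recurrent orbit ``x(k)`` in 3-D loop
space.  A radial-basis-function (RBF) network with Gaussian kernels on a
regular lattice is trained by the deterministic-learning scheme

    x_hat(k+1) = x_hat(k) - a * (x_hat(k) - x(k)) + W(k)^T S(x(k))
    W(k+1)     = W(k) - g(k) * S(x(k)) e(k)^T - g(k) * sigma * W(k)

with observer error ``e = x_hat - x``, Gaussian regressor
``S_i(x) = exp(-||x - c_i||^2 / eta^2)``, normalized adaptation step
``g(k) = gamma / (1 + ||S(x(k))||^2)`` and sigma-modification leakage
``sigma``.  The normalization (NLMS-style) keeps the discrete-time update
stable regardless of how many overlapping kernels a dense lattice activates
at once; without it the stable range of ``gamma`` would shrink with lattice
density.  Along a recurrent orbit the locally
excited weights converge so that ``W^T S(x(k))`` approximates the one-step
state change ``x(k+1) - x(k)``: the dynamics of the repolarization loop.

The cardiodynamicsgram (CDG) is the sequence ``W_bar^T S(x(k))`` over the
orbit, with ``W_bar`` the time-average of ``W`` over the final training
epoch.  For healthy, repeatable repolarization the per-beat segments of this
trajectory nearly coincide (an annular 3-D figure); beat-to-beat ST-T
dispersion spreads them apart.

:class:`CardiodynamicsModel` / :class:`CardiodynamicsResults` wrap the
procedure in a fit/results interface: build the model from an
:class:`~cdgram.fiducials.STTLoopSet` (or straight from an ECG record via
:meth:`CardiodynamicsModel.from_ecg`), call :meth:`~CardiodynamicsModel.fit`,
and read SHI, THI, the CDG value and the binary call off the results.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass

import numpy as np

from .errors import InstabilityError, LatticeSizeError
from .fiducials import STTLoopSet

_WEIGHT_NORM_CAP = 1e6


@dataclass
class RBFNetwork:
    """Gaussian RBF network: M centers in 3-D, one width, (M, 3) output weights."""

    centers: np.ndarray
    width: float
    weights: np.ndarray = None

    def __post_init__(self):
        self.centers = np.asarray(self.centers, dtype=float)
        if self.centers.ndim != 2 or self.centers.shape[1] != 3:
            raise ValueError("centers must have shape (M, 3)")
        if self.width <= 0:
            raise ValueError("kernel width must be positive")
        if self.weights is None:
            self.weights = np.zeros_like(self.centers)
        self.weights = np.asarray(self.weights, dtype=float)
        if self.weights.shape != self.centers.shape:
            raise ValueError("weights must have shape (M, 3)")

    @property
    def n_centers(self) -> int:
        return self.centers.shape[0]

    def regressor(self, points: np.ndarray) -> np.ndarray:
        """Kernel activations S(x), shape (n_points, M)."""
        pts = np.atleast_2d(np.asarray(points, dtype=float))
        d2 = ((pts[:, None, :] - self.centers[None, :, :]) ** 2).sum(axis=2)
        return np.exp(-d2 / self.width**2)

    def dynamics(self, points: np.ndarray) -> np.ndarray:
        """Learned dynamics W^T S(x) at each point, shape (n_points, 3)."""
        return self.regressor(points) @ self.weights

    def to_json(self, path: str) -> None:
        with open(path, "w") as fh:
            json.dump(
                {
                    "centers": self.centers.tolist(),
                    "width": self.width,
                    "weights": self.weights.tolist(),
                },
                fh,
            )

    @classmethod
    def from_json(cls, path: str) -> "RBFNetwork":
        with open(path) as fh:
            d = json.load(fh)
        return cls(np.array(d["centers"]), d["width"], np.array(d["weights"]))


@dataclass
class LearningParams:
    """Deterministic-learning hyperparameters.

    ``gain_a`` is the observer gain per step, ``gamma`` the adaptation rate,
    ``sigma`` the weight-leakage rate and ``epochs`` the number of passes over
    the concatenated loop orbit.  Training is deterministic; ``seed`` is
    reserved for optional center jitter and does not affect the default path.
    """

    gain_a: float = 0.5
    gamma: float = 0.5
    sigma: float = 1e-4
    epochs: int = 20
    seed: int | None = None

    def __post_init__(self):
        if self.gain_a <= 0 or self.gamma < 0 or self.sigma < 0 or self.epochs < 1:
            raise ValueError("invalid learning parameters")


@dataclass
class CDGTrajectory:
    """The cardiodynamicsgram: N ordered 3-D dynamics values along the orbit."""

    points: np.ndarray
    subject_id: str = ""
    loop_length: int | None = None  # L of the source loop set, if known

    def __post_init__(self):
        self.points = np.asarray(self.points, dtype=float)
        if self.points.ndim != 2 or self.points.shape[1] != 3:
            raise ValueError("trajectory points must have shape (N, 3)")
        if not np.all(np.isfinite(self.points)):
            raise ValueError("non-finite trajectory values")

    @property
    def n_points(self) -> int:
        return self.points.shape[0]

    def to_frame(self):
        import pandas as pd

        return pd.DataFrame(self.points, columns=["x", "y", "z"]).rename_axis("n")


def build_rbf_lattice(loops: STTLoopSet, spacing: float | None = None,
                      width_factor: float = 1.5, max_centers: int = 20000) -> RBFNetwork:
    """Regular 3-D center lattice covering the loops' bounding box.

    The box is expanded by one spacing on every side.  With the default
    ``spacing=None`` the spacing is chosen as (largest box extent)/5, giving
    roughly 8 centers along the longest axis.  Width is 1.5x spacing so
    neighboring kernels overlap.  Weights start at zero.
    """
    orbit = loops.concatenated()
    lo, hi = orbit.min(axis=0), orbit.max(axis=0)
    if spacing is None:
        extent = float(np.max(hi - lo))
        spacing = extent / 5.0 if extent > 0 else 1.0
    if spacing <= 0:
        raise ValueError("spacing must be positive")
    axes = [np.arange(l - spacing, h + spacing + 0.5 * spacing, spacing)
            for l, h in zip(lo, hi)]
    m = int(np.prod([len(a) for a in axes]))
    if m > max_centers:
        raise LatticeSizeError(
            f"lattice of {m} centers exceeds cap {max_centers}; increase spacing"
        )
    gx, gy, gz = np.meshgrid(*axes, indexing="ij")
    centers = np.column_stack([gx.ravel(), gy.ravel(), gz.ravel()])
    return RBFNetwork(centers, width_factor * spacing)


def learn_dynamics(loops: STTLoopSet, net: RBFNetwork,
                   params: LearningParams | None = None) -> RBFNetwork:
    """Train the network along the concatenated loop orbit.

    Returns a new network whose weights are the time-average of W over the
    final epoch.  Loops are concatenated in beat order; the observer restarts
    at each loop's first point so the artificial jump between one beat's T
    end and the next beat's J point is never treated as dynamics to learn
    (no inter-beat blending).
    """
    if params is None:
        params = LearningParams()
    orbit = loops.concatenated()
    n = orbit.shape[0]
    if n < 2:
        raise ValueError("orbit needs at least 2 points")
    s = net.regressor(orbit)  # (n, M) — orbit repeats across epochs
    a, gamma, sigma = params.gain_a, params.gamma, params.sigma
    gain = gamma / (1.0 + (s**2).sum(axis=1))  # normalized adaptation steps
    loop_len = loops.L
    w = net.weights.copy()
    w_sum = np.zeros_like(w)
    n_updates = 0
    for epoch in range(params.epochs):
        final = epoch == params.epochs - 1
        for start in range(0, n, loop_len):
            # each loop is one pass: the observer restarts at the loop's
            # first point, so the T-end -> next-J seam never enters the
            # learned dynamics (no inter-beat blending)
            xhat = orbit[start].copy()
            for k in range(start, min(start + loop_len, n)):
                e = xhat - orbit[k]
                sk = s[k]
                xhat = xhat - a * e + w.T @ sk
                w -= gain[k] * (np.outer(sk, e) + sigma * w)
                if final:
                    w_sum += w
                    n_updates += 1
        if not np.isfinite(w).all() or np.linalg.norm(w) > _WEIGHT_NORM_CAP:
            raise InstabilityError(
                "weight norm diverged; reduce gamma or the observer gain"
            )
    return RBFNetwork(net.centers.copy(), net.width, w_sum / max(n_updates, 1))


def generate_cdg(net: RBFNetwork, loops: STTLoopSet) -> CDGTrajectory:
    """Evaluate the learned dynamics along the orbit: the CDG itself.

    N = n_beats * L points in beat order.  An untrained (all-zero-weight)
    network yields an all-zero trajectory and a warning.
    """
    if not net.weights.any():
        warnings.warn("network weights are all zero; CDG trajectory will be zero",
                      stacklevel=2)
    values = net.dynamics(loops.concatenated())
    return CDGTrajectory(values, loops.subject_id, loop_length=loops.L)


class CardiodynamicsModel:
    """Deterministic-learning model of ST-T loop dynamics.

    Parameters
    ----------
    loops : STTLoopSet
        Per-beat resampled ST-T trajectories.
    spacing : float, optional
        RBF lattice spacing in mV (default: bounding-box extent / 5).
    params : LearningParams, optional
        Training hyperparameters.
    classifier : CDGClassifier, optional
        Decision function applied to (SHI, THI); defaults to the frozen
        ``paper-2023`` coefficients.

    Examples
    --------
    >>> model = CardiodynamicsModel.from_ecg(record)      # doctest: +SKIP
    >>> res = model.fit()                                 # doctest: +SKIP
    >>> res.shi, res.thi, res.cdg_value, res.call         # doctest: +SKIP
    """

    def __init__(self, loops: STTLoopSet, spacing: float | None = None,
                 width_factor: float = 1.5, params: LearningParams | None = None,
                 classifier=None, subject_id: str | None = None):
        self.loops = loops
        self.spacing = spacing
        self.width_factor = width_factor
        self.params = params or LearningParams()
        if classifier is None:
            from .classifier import CDGClassifier

            classifier = CDGClassifier.paper_2023()
        self.classifier = classifier
        self.subject_id = subject_id if subject_id is not None else loops.subject_id

    @classmethod
    def from_ecg(cls, rec, filter_spec=None, kors_matrix=None, L: int = 100,
                 min_beats: int = 8, detector_lead: str = "magnitude", **kwargs):
        """Full preprocessing chain: denoise → Kors VCG → fiducials → loops."""
        from .fiducials import detect_r_peaks, extract_stt_loops, locate_beat_fiducials
        from .io import denoise
        from .vcg import kors_transform

        clean = denoise(rec, filter_spec)
        v = kors_transform(clean, kors_matrix)
        peaks = detect_r_peaks(v, use_lead=detector_lead)
        fids = locate_beat_fiducials(v, peaks)
        loops = extract_stt_loops(v, fids, L=L)
        if loops.n_beats < min_beats:
            raise InstabilityError(
                f"only {loops.n_beats} usable beats; need at least {min_beats}"
            )
        return cls(loops, subject_id=rec.subject_id, **kwargs)

    def fit(self) -> "CardiodynamicsResults":
        """Build the lattice, run deterministic learning, emit the CDG."""
        net = build_rbf_lattice(self.loops, self.spacing, self.width_factor)
        net = learn_dynamics(self.loops, net, self.params)
        traj = generate_cdg(net, self.loops)
        return CardiodynamicsResults(self, net, traj)


class CardiodynamicsResults:
    """Fitted cardiodynamics: trained network, CDG trajectory and indices.

    SHI/THI and the CDG value are computed lazily with the package defaults
    (divergence horizon 10 steps, Theiler window of one loop length, THI grid
    1..N/2 on the norm spectrum) and cached.
    """

    def __init__(self, model: CardiodynamicsModel, network: RBFNetwork,
                 trajectory: CDGTrajectory):
        self.model = model
        self.network = network
        self.trajectory = trajectory
        self._indices = None

    @property
    def indices(self):
        if self._indices is None:
            from .heterogeneity import compute_indices

            self._indices = compute_indices(self.trajectory)
        return self._indices

    @property
    def shi(self) -> float:
        return self.indices.shi

    @property
    def thi(self) -> float:
        return self.indices.thi

    @property
    def cdg_value(self) -> float:
        return self.model.classifier.cdg_value(self.indices)

    @property
    def call(self) -> str:
        return self.model.classifier.classify(self.cdg_value)

    def plot(self, ax=None):
        """3-D rendering of the CDG trajectory."""
        from .plotting import plot_cdg

        return plot_cdg(self.trajectory, ax=ax)

    def summary(self) -> str:
        clf = self.model.classifier
        lines = [
            "Cardiodynamicsgram fit",
            "=" * 54,
            f"subject:            {self.model.subject_id or '-'}",
            f"beats x loop points: {self.model.loops.n_beats} x {self.model.loops.L}"
            f"  (N = {self.trajectory.n_points})",
            f"RBF centers:        {self.network.n_centers}"
            f"  (width {self.network.width:.4g} mV)",
            f"epochs:             {self.model.params.epochs}",
            "-" * 54,
            f"SHI (spatial heterogeneity):   {self.shi: .6f}",
            f"THI (temporal heterogeneity):  {self.thi: .6f}",
            f"CDG value:                     {self.cdg_value: .4f}",
            f"call (>= {clf.threshold:g} positive):        {self.call}",
            f"classifier:                    {clf.version}",
            "=" * 54,
        ]
        return "\n".join(lines)
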