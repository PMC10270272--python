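"""3-D rendering of CDG trajectories."""

from __future__ import annotations

import matplotlib

matplotlib.use("Agg", force=False)

import matplotlib.pyplot as plt  # noqa: E402


def plot_cdg(traj, ax=None, color_by_beat: bool = True):
    """Plot the CDG as a 3-D curve; per-beat segments get distinct colors.

    Healthy, repeatable repolarization shows near-coincident annular
    segments; dispersed repolarization spreads them apart.
    """
    if ax is None:
        fig = plt.figure(figsize=(6, 5))
        ax = fig.add_subplot(111, projection="3d")
    pts = traj.points
    L = traj.loop_length
    if color_by_beat and L and pts.shape[0] % L == 0:
        n_beats = pts.shape[0] // L
        cmap = plt.get_cmap("viridis")
        for b in range(n_beats):
            seg = pts[b * L:(b + 1) * L]
            ax.plot(seg[:, 0], seg[:, 1], seg[:, 2],
                    color=cmap(b / max(1, n_beats - 1)), lw=0.8)
    else:
        ax.plot(pts[:, 0], pts[:, 1], pts[:, 2], lw=0.8)
    ax.set_xlabel("X")
    ax.set_ylabel("Y")
    ax.set_zlabel("Z")
    ax.set_title(f"CDG ({traj.subject_id or 'trajectory'})")
    return ax
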