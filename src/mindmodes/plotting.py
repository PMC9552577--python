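"""Optional matplotlib views of trajectories in (γ_A, γ_D, γ_C) space.

These plots show the space of modes of thought — how a thinker traverses
abstractness, divergence and context-specificity — not conceptual space.
Requires matplotlib (install the ``plot`` extra).
"""

from __future__ import annotations

from .trajectory import Trajectory


def plot_trajectories(named_trajectories: dict[str, Trajectory], path=None):
    """Scatter each trajectory through the 3-D mode-of-thought space.

    Returns the matplotlib figure; saves to ``path`` when given.
    """
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    fig = plt.figure(figsize=(6, 5))
    ax = fig.add_subplot(111, projection="3d")
    for name, traj in named_trajectories.items():
        xs = [p.gamma_A for p in traj.profiles]
        ys = [p.gamma_D for p in traj.profiles]
        zs = [p.gamma_C for p in traj.profiles]
        ax.plot(xs, ys, zs, marker="o", label=name)
        for k, (x, y, z) in enumerate(zip(xs, ys, zs)):
            ax.text(x, y, z, str(k), fontsize=7)
    ax.set_xlabel(r"abstractness $\gamma_A$")
    ax.set_ylabel(r"divergence $\gamma_D$")
    ax.set_zlabel(r"context-specificity $\gamma_C$")
    ax.legend()
    fig.tight_layout()
    if path is not None:
        fig.savefig(path, dpi=150)
    return fig
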