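"""Optional matplotlib views of trajectories and branch diagrams."""

from __future__ import annotations


def _mpl():
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    return plt


def plot_trajectory(traj, path) -> None:
    """Time courses of A, C, S, V plus the path in the (E, C) plane."""
    plt = _mpl()
    fig, axes = plt.subplots(2, 2, figsize=(10, 7))
    (ax_drv, ax_ac), (ax_sv, ax_ec) = axes
    ax_drv.plot(traj.t, traj.E, label="E")
    ax_drv.plot(traj.t, traj.lam, label="lambda")
    ax_drv.set_xlabel("week"); ax_drv.legend(); ax_drv.set_title("drivers")
    ax_ac.plot(traj.t, traj.A, lw=0.6, label="A")
    ax_ac.plot(traj.t, traj.C, label="C")
    ax_ac.set_xlabel("week"); ax_ac.legend(); ax_ac.set_title("consumption & craving")
    ax_sv.plot(traj.t, traj.S, "--", label="S")
    ax_sv.plot(traj.t, traj.V, label="V")
    ax_sv.set_xlabel("week"); ax_sv.legend(); ax_sv.set_title("self-control & vulnerability")
    ax_ec.plot(traj.E, traj.C, lw=0.7)
    ax_ec.set_xlabel("E"); ax_ec.set_ylabel("C"); ax_ec.set_title("path in the E,C-plane")
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)


def plot_branches(diagram, path) -> None:
    """Equilibrium branches projected in the (E, C) and (E, S) planes."""
    plt = _mpl()
    df = diagram.to_frame()
    fig, (ax_c, ax_s) = plt.subplots(1, 2, figsize=(10, 4))
    for stable, style in ((True, "."), (False, "x")):
        sub = df[df.stable == stable]
        label = "stable" if stable else "unstable"
        ax_c.plot(sub.E, sub.C_star, style, ms=2, label=label)
        ax_s.plot(sub.E, sub.S_star, style, ms=2, label=label)
    for ax, y in ((ax_c, "C*"), (ax_s, "S*")):
        ax.set_xlabel("E"); ax.set_ylabel(y); ax.legend()
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)
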