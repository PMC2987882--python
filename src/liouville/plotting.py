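"""Optional plotting helpers (matplotlib imported lazily).

Convenience only: nothing in the package's numerical results depends on a
figure.  All helpers write an image file and return the path.
"""

from __future__ import annotations

from pathlib import Path


def _pyplot():
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    return plt


def plot_trajectories(trajectories, path, state_index: int = 0):
    """State (and density as line shading) of each trajectory over time."""
    plt = _pyplot()
    fig, ax = plt.subplots(figsize=(6, 4))
    for traj in trajectories:
        ax.plot(traj.times, traj.states[:, state_index], lw=0.6, color="steelblue")
    ax.set_xlabel("time")
    ax.set_ylabel(f"x{state_index}")
    fig.tight_layout()
    fig.savefig(path, dpi=150)
    plt.close(fig)
    return Path(path)


def plot_density_field_1d(field, path):
    """Density values of a one-dimensional field against the coordinate."""
    if field.dim != 1:
        raise ValueError("this helper plots one-dimensional fields only")
    plt = _pyplot()
    fig, ax = plt.subplots(figsize=(6, 4))
    ax.plot(field.points[:, 0], field.values, lw=1.2)
    ax.set_xlabel("x")
    ax.set_ylabel(f"u(t={field.time:g}, x)")
    fig.tight_layout()
    fig.savefig(path, dpi=150)
    plt.close(fig)
    return Path(path)


def plot_profile(profile, path):
    """Likelihood profile over a single profiled parameter."""
    plt = _pyplot()
    fig, ax = plt.subplots(figsize=(6, 4))
    ax.plot(profile.parameter_values[:, 0], profile.log_likelihoods, marker=".")
    ax.axvline(profile.maximizer_scalar, ls="--", color="gray")
    ax.set_xlabel(profile.param_names[0])
    ax.set_ylabel("log-likelihood")
    fig.tight_layout()
    fig.savefig(path, dpi=150)
    plt.close(fig)
    return Path(path)
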