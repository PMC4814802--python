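"""Optional matplotlib views of trajectories and sweeps.

Imported lazily so the core simulator has no hard plotting dependency.
"""

from __future__ import annotations

from .experiments import PROBE_COLUMNS, Trajectory


def _plt():
    try:
        import matplotlib.pyplot as plt
    except ImportError as err:  # pragma: no cover
        raise ImportError("plotting requires matplotlib (pip install paingate[plot])") from err
    return plt


def plot_parameters(trajectory: Trajectory, ax=None):
    """Weights and shifts of one run along iterations."""
    plt = _plt()
    if ax is None:
        _, ax = plt.subplots(figsize=(7, 4))
    it = trajectory.data["iteration"]
    for col in ("w1", "w2", "w3", "w4"):
        ax.plot(it, trajectory.data[col], label=col)
    for col in ("s1", "s2"):
        ax.plot(it, trajectory.data[col], "--", label=col)
    ax.set_xlabel("iteration")
    ax.set_ylabel("parameter value")
    ax.set_ylim(-0.05, 1.05)
    ax.legend(ncol=3, fontsize=8)
    ax.set_title(f"{trajectory.metadata.get('scenario', '')} (seed {trajectory.metadata.get('seed')})")
    return ax


def plot_responses(trajectory: Trajectory, ax=None):
    """CT-neuron response to each probe pair along iterations (ribbon view)."""
    plt = _plt()
    if ax is None:
        _, ax = plt.subplots(figsize=(7, 4))
    it = trajectory.data["iteration"]
    for col in PROBE_COLUMNS:
        if col in trajectory.data:
            ax.plot(it, trajectory.data[col], label=col.replace("o2_", ""))
    ax.set_xlabel("iteration")
    ax.set_ylabel("CT output rate")
    ax.set_ylim(-0.05, 1.05)
    ax.legend(fontsize=8)
    return ax


def plot_sweep(labels, ax=None):
    """Heatmap of condition labels over the input-intensity plane."""
    plt = _plt()
    import numpy as np

    if ax is None:
        _, ax = plt.subplots(figsize=(6, 5))
    names = sorted({v for v in labels.to_numpy().ravel()})
    code = {n: i for i, n in enumerate(names)}
    mat = labels.applymap(code.get).to_numpy()  # type: ignore[operator]
    im = ax.imshow(mat, origin="lower", aspect="auto", cmap="tab10",
                   extent=(labels.columns.min(), labels.columns.max(),
                           labels.index.min(), labels.index.max()))
    ax.set_xlabel("sensory intensity")
    ax.set_ylabel("nociceptive intensity")
    cbar = plt.colorbar(im, ax=ax, ticks=np.arange(len(names)))
    cbar.ax.set_yticklabels(names)
    return ax
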