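"""Minimal, unstyled plotting helpers for trajectories and fits."""

from __future__ import annotations

from .simulate import TimeSeriesSet


def plot_trajectories(data: TimeSeriesSet, ax=None, gene_names=None,
                      **plot_kw):
    """Line plot of every gene of every trajectory in a set.

    Returns the matplotlib Axes.  Styling is left to the caller.
    """
    import matplotlib.pyplot as plt

    if ax is None:
        _, ax = plt.subplots()
    names = (list(gene_names) if gene_names is not None
             else [f"X{i}" for i in range(1, data.n_genes + 1)])
    for tr in data.trajectories:
        for i, name in enumerate(names):
            label = name if tr is data.trajectories[0] else None
            ax.plot(tr.t, tr.x[:, i], label=label, **plot_kw)
    ax.set_xlabel("time")
    ax.set_ylabel("concentration")
    ax.legend()
    return ax


def plot_fit(observed: TimeSeriesSet, predicted: TimeSeriesSet, ax=None):
    """Observed (solid) vs predicted (dashed) trajectories."""
    import matplotlib.pyplot as plt

    if ax is None:
        _, ax = plt.subplots()
    plot_trajectories(observed, ax=ax, linestyle="-")
    plot_trajectories(predicted, ax=ax, linestyle="--")
    return ax
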