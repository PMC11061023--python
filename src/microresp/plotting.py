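"""Figure helpers: gain structure, rank histograms, sweeps, profiles."""

from __future__ import annotations

import numpy as np

from .profiles import ConditionalProfile
from .reduction import GainRanking
from .validation import RankHistogram, SweepResult


def plot_gains(ranking: GainRanking, ax=None):
    """Bar chart of gains |w*_m| sorted by rank."""
    import matplotlib.pyplot as plt

    ax = ax or plt.gca()
    order_gains = np.sort(ranking.gains)[::-1]
    ax.bar(np.arange(1, ranking.M + 1), order_gains, width=0.9)
    ax.set_xlabel("influence rank")
    ax.set_ylabel(r"gain $|w^\star_m|$")
    return ax


def plot_rank_histograms(hist: RankHistogram, ax=None):
    """Heatmap of per-taxon rank histograms (columns ordered by final rank)."""
    import matplotlib.pyplot as plt

    ax = ax or plt.gca()
    im = ax.imshow(
        hist.counts.T / hist.n_phases, origin="lower", aspect="auto",
        extent=(0.5, hist.taxa.size + 0.5, 0.5, hist.counts.shape[1] + 0.5),
    )
    ax.set_xlabel("taxon (by final rank)")
    ax.set_ylabel("rank received in a training phase")
    plt.colorbar(im, ax=ax, label="fraction of phases")
    return ax


def plot_sweep(sweep: SweepResult, ax=None):
    """Mean accuracy with +/- sd band along a sweep axis."""
    import matplotlib.pyplot as plt

    ax = ax or plt.gca()
    t = sweep.table
    x = t[sweep.axis_name]
    ax.plot(x, t["mean"], marker="o", ms=3)
    ax.fill_between(x, t["mean"] - t["sd"], t["mean"] + t["sd"], alpha=0.25)
    ax.set_xlabel(sweep.axis_name)
    ax.set_ylabel("mean accuracy")
    ax.set_ylim(0, 1)
    return ax


def plot_profile_pair(pair: tuple[ConditionalProfile, ConditionalProfile], ax=None):
    """Overlaid class-conditional sqrt-abundance densities for one taxon."""
    import matplotlib.pyplot as plt

    ax = ax or plt.gca()
    pos, neg = pair
    hi = max(pos.values.max(), neg.values.max(), 1e-6)
    grid = np.linspace(0, 1.05 * hi, 256)
    for prof, name in ((pos, "responder"), (neg, "non-responder")):
        dens = prof.evaluate_density(grid)
        if dens is not None:
            ax.plot(grid, dens, label=name)
        ax.axvline(prof.median, ls="--", lw=0.8)
    ax.set_xlabel(r"$\sqrt{\mathrm{abundance}}$")
    ax.set_ylabel("density")
    ax.legend()
    return ax
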