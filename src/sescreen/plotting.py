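"""Diagnostic plots (matplotlib, Agg backend, optional dependency at runtime)."""
from __future__ import annotations

from typing import Optional, Sequence

import numpy as np

from .enhancers import EnhancerRanking
from .metagene import MetageneProfile


def _axes(ax):
    if ax is not None:
        return ax, None
    import matplotlib

    matplotlib.use("Agg", force=False)
    import matplotlib.pyplot as plt

    fig, ax = plt.subplots(figsize=(5, 4))
    return ax, fig


def plot_ranking(ranking: EnhancerRanking, ax=None, out_path=None):
    """Hockey-stick plot: ascending rank vs H3K27Ac signal with the cutoff."""
    ax, fig = _axes(ax)
    signals = ranking.signals
    ranks = np.arange(1, len(signals) + 1)
    ax.plot(ranks, signals, color="0.3", lw=1)
    supers = [i for i, e in enumerate(ranking.enhancers) if e.klass is not None and e.klass.value == "SUPER"]
    if supers:
        ax.scatter(ranks[supers], signals[supers], s=8, color="crimson", zorder=3,
                   label=f"super ({len(supers)})")
        ax.legend(frameon=False)
    if ranking.cutoff_signal is not None:
        ax.axhline(ranking.cutoff_signal, color="crimson", lw=0.8, ls="--")
    ax.set_xlabel("enhancer rank (ascending signal)")
    ax.set_ylabel("H3K27Ac signal (RPM)")
    if fig is not None and out_path is not None:
        fig.tight_layout()
        fig.savefig(out_path, dpi=150)
        import matplotlib.pyplot as plt

        plt.close(fig)
    return ax


def plot_metagene(
    profiles: Sequence[MetageneProfile],
    labels: Optional[Sequence[str]] = None,
    ax=None,
    out_path=None,
):
    """Overlay metagene profiles; vertical lines mark the body boundaries."""
    ax, fig = _axes(ax)
    labels = list(labels) if labels is not None else [f"set {i}" for i in range(len(profiles))]
    for profile, label in zip(profiles, labels):
        ax.plot(np.arange(len(profile.mean_signal)), profile.mean_signal, label=label)
    if profiles:
        fb = profiles[0].flank_bins
        bb = profiles[0].body_bins
        for xpos in (fb - 0.5, fb + bb - 0.5):
            ax.axvline(xpos, color="0.7", lw=0.8, ls=":")
    ax.set_xlabel("bin (flank | scaled body | flank)")
    ax.set_ylabel("mean signal density (RPM/bp)")
    ax.legend(frameon=False)
    if fig is not None and out_path is not None:
        fig.tight_layout()
        fig.savefig(out_path, dpi=150)
        import matplotlib.pyplot as plt

        plt.close(fig)
    return ax
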