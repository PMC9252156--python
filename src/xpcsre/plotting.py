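"""Optional matplotlib renderings of the analysis artefacts."""

from __future__ import annotations

import numpy as np

from .correlation import ContrastProfile, TwoTimeCorrelation


def _mpl():
    import matplotlib

    matplotlib.use("Agg", force=False)
    import matplotlib.pyplot as plt

    return plt


def plot_ttc(ttc: TwoTimeCorrelation, path=None, vmin=0.0, vmax=1.0):
    """Heatmap of G(t1, t2)."""
    plt = _mpl()
    fig, ax = plt.subplots(figsize=(5, 4.2))
    extent = [ttc.times[0], ttc.times[-1], ttc.times[0], ttc.times[-1]]
    im = ax.imshow(ttc.G, origin="lower", extent=extent, vmin=vmin, vmax=vmax, cmap="viridis")
    ax.set_xlabel("$t_1$")
    ax.set_ylabel("$t_2$")
    ax.set_title(f"G(q = {ttc.q_center:.3g}, t$_1$, t$_2$), ring = {ttc.ring_size} px")
    fig.colorbar(im, ax=ax, label="G")
    if path is not None:
        fig.savefig(path, dpi=150, bbox_inches="tight")
        plt.close(fig)
    return fig


def plot_contrast(profile: ContrastProfile, tail_times=None, path=None):
    """Near-diagonal contrast vs age time, with detected tails marked."""
    plt = _mpl()
    fig, ax = plt.subplots(figsize=(5.5, 3.2))
    ax.plot(profile.t_age, profile.values, lw=1.2)
    if tail_times is not None and len(tail_times):
        ax.plot(tail_times, np.interp(tail_times, profile.t_age, profile.values), "v", ms=7)
    ax.set_xlabel("$t_{age}$")
    ax.set_ylabel(f"contrast (offset {profile.offset})")
    if path is not None:
        fig.savefig(path, dpi=150, bbox_inches="tight")
        plt.close(fig)
    return fig


def plot_xi(t, xi, exponent=None, prefactor=None, path=None):
    """Characteristic length vs time on log-log axes, with an optional power-law fit."""
    plt = _mpl()
    fig, ax = plt.subplots(figsize=(4.5, 3.5))
    ax.loglog(t, xi, "o", ms=4, label=r"$\xi(t)$")
    if exponent is not None and prefactor is not None:
        tt = np.linspace(min(t), max(t), 50)
        ax.loglog(tt, prefactor * tt**exponent, "-", label=f"$t^{{{exponent:.2f}}}$")
    ax.set_xlabel("t")
    ax.set_ylabel(r"$\xi$")
    ax.legend()
    if path is not None:
        fig.savefig(path, dpi=150, bbox_inches="tight")
        plt.close(fig)
    return fig
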