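"""Plotting helpers for predicted and observed spectra."""

from __future__ import annotations

import numpy as np

from .spectral import CSDDataset, coherence

__all__ = ["plot_fit", "plot_population_spectra"]


def plot_fit(observed: CSDDataset, predicted: CSDDataset, ax=None):
    """Overlay predicted on observed auto-spectra and coherence per condition."""
    import matplotlib.pyplot as plt

    nc = len(observed.channels)
    ncols = nc + (1 if nc > 1 else 0)
    if ax is None:
        fig, axes = plt.subplots(
            len(observed.conditions), ncols, figsize=(3.2 * ncols, 2.6 * len(observed.conditions)),
            squeeze=False,
        )
    else:
        axes = np.atleast_2d(ax)
        fig = axes[0, 0].figure
    coh_obs, coh_pred = coherence(observed), coherence(predicted)
    for r, cond in enumerate(observed.conditions):
        for c, ch in enumerate(observed.channels):
            a = axes[r, c]
            a.semilogy(observed.freq, observed.auto_spectra(cond)[:, c], "k.", ms=3, label="observed")
            a.semilogy(predicted.freq, predicted.auto_spectra(cond)[:, c], "r-", label="predicted")
            a.set_title(f"{ch} ({cond})", fontsize=9)
            a.set_xlabel("frequency (Hz)")
            if c == 0:
                a.set_ylabel("PSD (a.u.)")
        if nc > 1:
            a = axes[r, nc]
            a.plot(observed.freq, coh_obs[cond][:, 0, 1], "k.", ms=3)
            a.plot(predicted.freq, coh_pred[cond][:, 0, 1], "r-")
            a.set_ylim(0, 1)
            a.set_title(f"coherence ({cond})", fontsize=9)
            a.set_xlabel("frequency (Hz)")
    axes[0, 0].legend(fontsize=7)
    fig.tight_layout()
    return fig


def plot_population_spectra(freq: np.ndarray, spectra: dict[str, np.ndarray], ax=None):
    """Per-population MAP auto-spectra (virtual-electrode view)."""
    import matplotlib.pyplot as plt

    if ax is None:
        fig, ax = plt.subplots(figsize=(4.5, 3.2))
    else:
        fig = ax.figure
    for label, s in spectra.items():
        ax.plot(freq, s, label=label)
    ax.set_xlabel("frequency (Hz)")
    ax.set_ylabel("PSD (a.u.)")
    ax.legend(fontsize=8)
    fig.tight_layout()
    return fig
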