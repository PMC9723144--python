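"""Display helpers. Smoothing here is for figures only and is never applied
before quantification."""

from __future__ import annotations

import numpy as np
from scipy.ndimage import gaussian_filter1d


def smooth_psd_for_display(psd, sigma_hz: float = 2.0):
    """Gaussian-smoothed copy of a PSD (display only)."""
    sigma_bins = sigma_hz / psd.df()
    from dataclasses import replace

    return replace(psd, power=gaussian_filter1d(psd.power, sigma_bins))


def plot_comodulogram(matrix, ax=None):
    import matplotlib.pyplot as plt

    ax = ax or plt.gca()
    im = ax.pcolormesh(matrix.phase_freqs, matrix.amp_freqs, matrix.values,
                       shading="nearest", vmin=0)
    ax.set_xlabel("phase frequency (Hz)")
    ax.set_ylabel("amplitude frequency (Hz)")
    plt.colorbar(im, ax=ax, label="coherence")
    return ax


def plot_peth(peth, ax=None):
    import matplotlib.pyplot as plt

    ax = ax or plt.gca()
    centers = 0.5 * (peth.edges[:-1] + peth.edges[1:])
    ax.bar(centers, peth.rate, width=np.diff(peth.edges), align="center")
    ax.set_xlabel("time from trigger (s)")
    ax.set_ylabel("rate (events/s)")
    return ax
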