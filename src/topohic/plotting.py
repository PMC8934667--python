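"""Heatmap and track rendering plus BEDGRAPH export.

Ratio matrices and scalograms use the conventional diverging blue-white-red
scale (decrease / no change / increase in the mutant); normalized contact
maps use a white-to-red scale.
"""

from __future__ import annotations

from typing import Optional

import numpy as np

from .compare import Profile, RatioMap, Scalogram
from .contact_map import ContactMap


def _ax(ax):
    if ax is None:
        import matplotlib.pyplot as plt
        _, ax = plt.subplots()
    return ax


def plot_contact_map(cmap: ContactMap, ax=None, vmax_quantile: float = 0.99):
    ax = _ax(ax)
    v = cmap.values
    vmax = np.quantile(v[v > 0], vmax_quantile) if (v > 0).any() else 1.0
    extent = (0, cmap.genome.length / 1e6, cmap.genome.length / 1e6, 0)
    im = ax.imshow(v, cmap="Reds", vmin=0, vmax=vmax, extent=extent,
                   interpolation="none")
    ax.set_xlabel("position (Mb)")
    ax.set_ylabel("position (Mb)")
    ax.figure.colorbar(im, ax=ax, label="contact frequency")
    return ax


def plot_ratio_map(ratio: RatioMap, ax=None, vlim: float = 2.0):
    ax = _ax(ax)
    length_mb = ratio.n_bins * ratio.bin_size / 1e6
    extent = (0, length_mb, length_mb, 0)
    im = ax.imshow(ratio.values, cmap="bwr", vmin=-vlim, vmax=vlim,
                   extent=extent, interpolation="none")
    ax.set_xlabel("position (Mb)")
    ax.set_ylabel("position (Mb)")
    ax.figure.colorbar(im, ax=ax, label="log2 ratio")
    return ax


def plot_scalogram(scal: Scalogram, ax=None, vlim: float = 1.0):
    ax = _ax(ax)
    length_mb = scal.values.shape[0] * scal.bin_size / 1e6
    extent = (0, length_mb, scal.distances[-1] / 1e3, scal.distances[0] / 1e3)
    im = ax.imshow(scal.values.T, cmap="bwr", vmin=-vlim, vmax=vlim,
                   extent=extent, aspect="auto", interpolation="none")
    ax.set_xlabel("position (Mb)")
    ax.set_ylabel("separation (kb)")
    ax.figure.colorbar(im, ax=ax, label="log2 AC ratio")
    return ax


def plot_profile(profile: Profile, ax=None, label: Optional[str] = None):
    ax = _ax(ax)
    ax.plot(profile.positions_bp() / 1e6, profile.values, lw=0.8, label=label)
    ax.set_xlabel("position (Mb)")
    ax.set_ylabel("z-score" if profile.kind == "zscore" else "contact frequency")
    if label:
        ax.legend()
    return ax


def profile_to_bedgraph(profile: Profile, path: str, chrom: str,
                        genome_length: Optional[int] = None) -> None:
    """Write a 1-D track as BEDGRAPH (0-based half-open intervals)."""
    bs = profile.bin_size
    with open(path, "w") as fh:
        for b, v in zip(profile.bins, profile.values):
            if not np.isfinite(v):
                continue
            start = int(b) * bs
            end = start + bs
            if genome_length is not None:
                end = min(end, genome_length)
            fh.write(f"{chrom}\t{start}\t{end}\t{v:.6g}\n")
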