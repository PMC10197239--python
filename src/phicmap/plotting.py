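"""Minimal matrix and track rendering (optional; requires matplotlib)."""

from __future__ import annotations

import numpy as np

from .contact import ContactMatrix


def plot_matrix(m: ContactMatrix, path: str, log: bool = True, cmap: str = "Reds") -> None:
    """Render a contact map to PNG/SVG with a log color scale."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    data = m.matrix
    if log:
        data = np.log10(data + 1e-9)
    fig, ax = plt.subplots(figsize=(6, 6))
    extent_mb = (m.replicon_length or m.n_bins * m.bin_size) / 1e6
    im = ax.imshow(data, cmap=cmap, origin="upper", extent=(0, extent_mb, extent_mb, 0))
    ax.set_xlabel("Genomic position (Mb)")
    ax.set_ylabel("Genomic position (Mb)")
    ax.set_title(m.replicon)
    fig.colorbar(im, ax=ax, shrink=0.8, label="log10 contacts" if log else "contacts")
    fig.savefig(path, dpi=150, bbox_inches="tight")
    plt.close(fig)


def plot_track(starts: np.ndarray, values: np.ndarray, path: str, label: str = "") -> None:
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    fig, ax = plt.subplots(figsize=(8, 2))
    ax.plot(np.asarray(starts) / 1e6, values, lw=0.8)
    ax.set_xlabel("Genomic position (Mb)")
    ax.set_ylabel(label)
    fig.savefig(path, dpi=150, bbox_inches="tight")
    plt.close(fig)
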