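"""Minimal profile plots: correlation-density contrasts and TSS metaprofiles."""

from __future__ import annotations

import numpy as np

import matplotlib

matplotlib.use("Agg")
import matplotlib.pyplot as plt  # noqa: E402


def plot_density_contrast(contrast, path) -> None:
    """Observed vs control correlation densities with the subsample band."""
    fig, (ax1, ax2) = plt.subplots(1, 2, figsize=(9, 3.5))
    g = contrast.grid
    ax1.plot(g, contrast.observed_density, "r-", label="overlapping pairs")
    ax1.plot(g, contrast.control_density, "k-", label="control pairs")
    ax1.set(xlabel="Pearson r", ylabel="density", title=contrast.geometry)
    ax1.legend(frameon=False, fontsize=8)
    for curve in contrast.control_curves:
        ax2.plot(g, curve - contrast.control_density, color="0.8", lw=0.5)
    ax2.plot(g, contrast.difference, "r-")
    ax2.set(xlabel="Pearson r", ylabel="density difference")
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)


def plot_metaprofile(track, promoters, path, half_width: int = 1000, bin_size: int = 50):
    """Mean signal around promoter centers, per promoter class, TSS-oriented."""
    classes: dict[str, list[np.ndarray]] = {}
    for p in promoters:
        mid = (p.window.start + p.window.end) // 2
        vals = track.per_base(p.chrom, mid - half_width, mid + half_width)
        if np.isfinite(vals).mean() < 0.8:
            continue
        vals = np.nan_to_num(vals, nan=0.0)
        if p.strand == "-":
            vals = vals[::-1]
        klass = "KBiP" if p.klass in ("pcKBiP", "lncKBiP") else p.klass
        classes.setdefault(klass, []).append(vals)
    fig, ax = plt.subplots(figsize=(5, 3.5))
    x = np.arange(-half_width, half_width)
    for klass in sorted(classes):
        mean = np.mean(classes[klass], axis=0)
        # bin for readability
        nb = len(mean) // bin_size
        ax.plot(x[: nb * bin_size : bin_size],
                mean[: nb * bin_size].reshape(nb, bin_size).mean(axis=1),
                label=f"{klass} (n={len(classes[klass])})")
    ax.set(xlabel="position relative to promoter center (nt)",
           ylabel=f"mean {track.kind}")
    ax.legend(frameon=False, fontsize=8)
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)
    return {k: len(v) for k, v in classes.items()}
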