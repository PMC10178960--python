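"""Per-chromosome SNP-index / delta(SNP-index) plots.

Each chromosome gets a three-panel figure: per-SNP points (green), the
sliding-window average curve (red), and — in the delta panel — the 95%
(blue) and 99% (purple) Monte-Carlo null confidence bands.
"""

from __future__ import annotations

from pathlib import Path

import matplotlib

matplotlib.use("Agg")
import matplotlib.pyplot as plt
import pandas as pd


def plot_chromosome(
    records: pd.DataFrame,
    windows: pd.DataFrame,
    band: pd.DataFrame | None,
    chrom: str,
    path: str | Path,
) -> None:
    """Render one chromosome's SNP-index and delta panels to an image file."""
    rec = records[records["chrom"] == chrom]
    win = windows[windows["chrom"] == chrom]
    mid = (win["start"] + win["end"]) / 2e6
    fig, axes = plt.subplots(3, 1, figsize=(9, 7), sharex=True)
    panels = [
        ("index_O", "mean_index_O", "SNP-index (O-bulk)", (0, 1)),
        ("index_N", "mean_index_N", "SNP-index (N-bulk)", (0, 1)),
        ("delta", "mean_delta", "Δ(SNP-index)", (-1, 1)),
    ]
    for ax, (col, wcol, label, ylim) in zip(axes, panels):
        ax.scatter(rec["pos"] / 1e6, rec[col], s=4, color="green", alpha=0.5)
        ax.plot(mid, win[wcol], color="red", lw=1.5)
        ax.set_ylabel(label)
        ax.set_ylim(*ylim)
    if band is not None:
        b = band[band["chrom"] == chrom]
        bmid = mid.iloc[: len(b)]
        ax = axes[2]
        ax.plot(bmid, b["upper95"], color="blue", lw=0.8)
        ax.plot(bmid, b["lower95"], color="blue", lw=0.8)
        ax.plot(bmid, b["upper99"], color="purple", lw=0.8)
        ax.plot(bmid, b["lower99"], color="purple", lw=0.8)
    axes[2].axhline(0, color="grey", lw=0.5)
    axes[2].set_xlabel(f"{chrom} position (Mb)")
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)
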