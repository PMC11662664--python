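"""Minimal plots for differential results and peak-centered profiles."""

from __future__ import annotations

import numpy as np
import pandas as pd

import matplotlib

matplotlib.use("Agg")
import matplotlib.pyplot as plt  # noqa: E402


def volcano(diff: pd.DataFrame, adjp_max: float = 0.1, lfc_min: float = 0.5,
            path: str | None = None):
    """Volcano plot of per-RNA differential interaction results."""
    fig, ax = plt.subplots(figsize=(5, 4))
    hit = (diff["adj_p"] <= adjp_max) & (diff["log2fc"].abs() >= lfc_min)
    ax.scatter(diff.loc[~hit, "log2fc"], -np.log10(diff.loc[~hit, "p"]),
               s=6, c="grey", alpha=0.6)
    ax.scatter(diff.loc[hit, "log2fc"], -np.log10(diff.loc[hit, "p"]),
               s=8, c="firebrick")
    ax.axvline(lfc_min, ls="--", lw=0.5, c="k")
    ax.axvline(-lfc_min, ls="--", lw=0.5, c="k")
    ax.set_xlabel("log2 fold change (IP / Input)")
    ax.set_ylabel("-log10 p")
    fig.tight_layout()
    if path:
        fig.savefig(path, dpi=150)
        plt.close(fig)
    return fig


def metaprofile_plot(profiles: dict[str, pd.DataFrame], path: str | None = None):
    """Overlay peak-centered tag density profiles (one line per sample)."""
    fig, ax = plt.subplots(figsize=(5, 4))
    for label, prof in profiles.items():
        ax.plot(prof["offset"], prof["density"], label=label)
    ax.axvline(0, ls="--", lw=0.5, c="k")
    ax.set_xlabel("offset from peak center (bp)")
    ax.set_ylabel("mean tag density per peak")
    ax.legend()
    fig.tight_layout()
    if path:
        fig.savefig(path, dpi=150)
        plt.close(fig)
    return fig
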