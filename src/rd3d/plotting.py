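"""Plotting conveniences for metaplots, TAD profiles and embeddings.

These are presentation helpers over the result tables, not part of the
analysis contract.
"""

from __future__ import annotations

import matplotlib

matplotlib.use("Agg", force=False)

import matplotlib.pyplot as plt
import pandas as pd


def plot_anchor_metaplot(profile: pd.DataFrame, ax=None, title: str | None = None):
    """Observed vs background mean contact counts around loop anchors."""
    if ax is None:
        _, ax = plt.subplots(figsize=(5, 3.5))
    kb = profile["offset"] / 1000
    ax.plot(kb, profile["observed"], label="observed", lw=1.5)
    ax.plot(kb, profile["background"], label="shifted background", lw=1.5, ls="--")
    ax.axvline(0, color="grey", lw=0.5)
    ax.set_xlabel("offset from anchor (kb)")
    ax.set_ylabel("mean contacts / anchor")
    ax.legend(frameon=False)
    if title:
        ax.set_title(title)
    return ax


def plot_tad_metaplot(profile: pd.DataFrame, ax=None, title: str | None = None):
    """Rescaled contact profile around parental TADs (TAD spans [0, 1])."""
    if ax is None:
        _, ax = plt.subplots(figsize=(5, 3.5))
    ax.plot(profile["rel_coord"], profile["mean_profile"], lw=1.5)
    for x in (0.0, 1.0):
        ax.axvline(x, color="grey", lw=0.8, ls=":")
    ax.set_xlabel("position relative to parental TAD")
    ax.set_ylabel("mean normalised contact density")
    if title:
        ax.set_title(title)
    return ax


def plot_embedding(coords: pd.DataFrame, labels=None, ax=None, title: str | None = None):
    """Scatter of the 2-D profile embedding, optionally coloured by label."""
    if ax is None:
        _, ax = plt.subplots(figsize=(4.5, 4.5))
    if labels is None:
        ax.scatter(coords["tsne1"], coords["tsne2"], s=12)
    else:
        for lab in pd.unique(labels):
            m = labels == lab
            ax.scatter(coords.loc[m, "tsne1"], coords.loc[m, "tsne2"], s=12, label=str(lab))
        ax.legend(frameon=False, fontsize=8)
    ax.set_xlabel("t-SNE 1")
    ax.set_ylabel("t-SNE 2")
    if title:
        ax.set_title(title)
    return ax
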