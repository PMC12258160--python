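"""Top-pathway tables and per-pathway enrichment-plot data.

"Top" means: among pathways significant at alpha, the k largest positive
NES (mortality-associated when the ranking is by log hazard ratio) and the
k most negative NES (survival-associated), each ordered by |NES|
descending. Ordering by adjusted p-value is available behind a flag.
"""

from __future__ import annotations

import json
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .cox_rank import RankedList
from .gsea_core import enrichment_score


@dataclass
class EnrichmentPlotData:
    """Everything needed to draw one pathway's enrichment plot."""

    pathway: str
    running_sum: np.ndarray
    hit_indices: np.ndarray
    es: float
    peak_index: int
    stats: np.ndarray

    def to_dict(self) -> dict:
        return {
            "pathway": self.pathway,
            "running_sum": self.running_sum.tolist(),
            "hit_indices": self.hit_indices.tolist(),
            "es": self.es,
            "peak_index": self.peak_index,
            "stats": self.stats.tolist(),
        }

    def to_json(self, path) -> None:
        with open(path, "w") as fh:
            json.dump(self.to_dict(), fh)


def top_tables(
    results: pd.DataFrame,
    k: int = 10,
    alpha: float = 0.15,
    by: str = "nes",
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Top-k significant pathways with positive and with negative NES.

    Returns (positive table, negative table); fewer than k rows when fewer
    pathways qualify, and empty tables (not an error) when none do.
    ``by`` is ``"nes"`` (|NES| descending) or ``"padj"`` (ascending).
    """
    sig = results[results["padj"] < alpha]
    pos = sig[sig["NES"] > 0].copy()
    neg = sig[sig["NES"] < 0].copy()
    if by == "nes":
        pos = pos.sort_values(["NES", "pathway"], ascending=[False, True])
        neg = neg.sort_values(["NES", "pathway"], ascending=[True, True])
    elif by == "padj":
        pos = pos.sort_values(["padj", "pathway"])
        neg = neg.sort_values(["padj", "pathway"])
    else:
        raise ValueError(f"unknown ordering {by!r}; use 'nes' or 'padj'")
    return pos.head(k).reset_index(drop=True), neg.head(k).reset_index(drop=True)


def enrichment_plot_data(ranked: RankedList, gene_set, exponent: float = 1.0) -> EnrichmentPlotData:
    """Full running-sum walk, hit ticks and statistic series for one set."""
    esr = enrichment_score(ranked, gene_set, exponent=exponent)
    name = gene_set.name if hasattr(gene_set, "name") else "gene set"
    return EnrichmentPlotData(
        pathway=name,
        running_sum=esr.running_sum,
        hit_indices=esr.hit_indices,
        es=esr.es,
        peak_index=esr.peak_index,
        stats=np.asarray(ranked.stats, dtype=float),
    )


def plot_enrichment(data: EnrichmentPlotData, path=None, title: str | None = None):
    """Render the classic three-panel enrichment plot (line, rug, statistic)."""
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    n = len(data.running_sum)
    fig, axes = plt.subplots(
        3, 1, figsize=(7, 6), sharex=True,
        gridspec_kw={"height_ratios": [3, 0.6, 1.6], "hspace": 0.08},
    )
    axes[0].plot(np.arange(n), data.running_sum, color="seagreen", lw=1.5)
    axes[0].axhline(0.0, color="grey", lw=0.8)
    axes[0].axvline(data.peak_index, color="firebrick", ls="--", lw=0.8)
    axes[0].set_ylabel("running enrichment score")
    axes[0].set_title(title or f"{data.pathway} (ES = {data.es:.3f})")
    axes[1].vlines(data.hit_indices, 0, 1, color="black", lw=0.4)
    axes[1].set_yticks([])
    axes[1].set_ylabel("hits", rotation=0, ha="right", va="center")
    axes[2].fill_between(np.arange(n), data.stats, step="mid", color="steelblue")
    axes[2].set_ylabel("ranking statistic")
    axes[2].set_xlabel("rank in gene list")
    if path is not None:
        fig.savefig(path, dpi=150, bbox_inches="tight")
        plt.close(fig)
    return fig
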