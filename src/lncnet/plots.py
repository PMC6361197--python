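"""Optional figure output: volcano plot and enrichment bar chart."""

from __future__ import annotations

from pathlib import Path

import matplotlib

matplotlib.use("Agg")
import matplotlib.pyplot as plt
import numpy as np

from .diffexp import DiffExprResult
from .enrichment import EnrichmentRecord
from .io import Regulation

__all__ = ["volcano_plot", "enrichment_barplot"]


def volcano_plot(result: DiffExprResult, path: str | Path) -> None:
    """log2 fold change vs -log10 P, threshold lines at the screen's cuts."""
    x = np.array([r.log2_fold_change for r in result.records])
    y = -np.log10([r.p_value for r in result.records])
    reg = [r.regulation for r in result.records]
    colors = {"UP": "tab:red", "DOWN": "tab:blue", "UNCHANGED": "0.6"}
    fig, ax = plt.subplots(figsize=(5, 4))
    for key in ("UNCHANGED", "UP", "DOWN"):
        mask = [r.value == key for r in reg]
        ax.scatter(x[mask], y[mask], s=8, c=colors[key], label=key.lower())
    lfc = np.log2(result.fc_min)
    for v in (-lfc, lfc):
        ax.axvline(v, color="green", lw=0.8)
    ax.axhline(-np.log10(result.alpha), color="green", lw=0.8)
    ax.set_xlabel("log2 fold change (tumor / normal)")
    ax.set_ylabel("-log10 P")
    ax.legend(frameon=False, fontsize=8)
    fig.tight_layout()
    fig.savefig(path, dpi=150)
    plt.close(fig)


def enrichment_barplot(records: list[EnrichmentRecord], path: str | Path) -> None:
    """Horizontal -log10 P bars, most enriched set on top."""
    names = [r.set_name for r in records][::-1]
    vals = [r.neg_log10_p for r in records][::-1]
    fig, ax = plt.subplots(figsize=(6, max(2, 0.3 * len(names))))
    ax.barh(names, vals, color="tab:purple")
    ax.set_xlabel("-log10 P")
    fig.tight_layout()
    fig.savefig(path, dpi=150)
    plt.close(fig)
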