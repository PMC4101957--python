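"""Diagnostic plots: the GSA P-value plot and the GST ranked-statistic plot.

The plotted arrays are computed by standalone helpers (``ordered_pvalues``,
``gst_curve``, ``significance_bounds``) so their content can be tested
without touching rendered pixels; the ``*_plot`` functions only draw them.

* GSA plot: ordered P-values of every set against rank/k, one line per test,
  with the uniform-null diagonal for reference.  Under the global null the
  curve should hug the diagonal; true signal pulls the small-rank end below.
* GST plot: for one gene set, the ECDF of the set's per-gene statistics over
  the ranked all-gene statistic axis (a SAFE-style plot), tick marks naming
  each member gene's position, and shading over the statistics whose
  parametric per-gene P-value falls below ``alpha`` (two tails for t, upper
  tail for F; default alpha = 0.01).
"""

from __future__ import annotations

import numpy as np

from .gsa import GeneLevelStats, GSAResultTable

__all__ = ["ordered_pvalues", "gst_curve", "significance_bounds", "gsa_plot", "gst_plot"]

_P_COLUMNS = {"ols_p": "OLS", "t2_p": "Hotelling T2", "manova_p": "MANOVA"}


def ordered_pvalues(results: GSAResultTable) -> dict[str, np.ndarray]:
    """Sorted P-value array per test present in the result table."""
    out = {}
    for col, label in _P_COLUMNS.items():
        if col in results.table.columns:
            out[label] = np.sort(results.table[col].to_numpy())
    if not out:
        raise ValueError("result table contains no P-value columns")
    return out


def gst_curve(gene_stats: GeneLevelStats, set_members):
    """ECDF of the set's statistics along the ranked all-gene statistic axis.

    Returns ``(sorted_stats, ecdf, member_ranks)``: the all-gene statistics
    in ascending order, the fraction of set members with statistic at most
    each of them, and the 1-based rank of every member gene.
    """
    members = np.asarray(set_members, dtype=int)
    if members.size == 0:
        raise ValueError("gene set is empty")
    stats = np.asarray(gene_stats.statistic, dtype=float)
    if members.max() >= len(stats) or members.min() < 0:
        raise ValueError("unknown gene index in set_members")
    order = np.argsort(stats, kind="stable")
    sorted_stats = stats[order]
    member_stats = np.sort(stats[members])
    ecdf = np.searchsorted(member_stats, sorted_stats, side="right") / len(member_stats)
    member_ranks = np.asarray(gene_stats.rank)[members]
    return sorted_stats, ecdf, member_ranks


def significance_bounds(gene_stats: GeneLevelStats, alpha: float = 0.01):
    """Statistic regions whose parametric per-gene P is below ``alpha``.

    Returns a list of (lo, hi) statistic intervals: two tails for t
    statistics, one upper tail for F.
    """
    stats = np.asarray(gene_stats.statistic, dtype=float)
    pvals = np.asarray(gene_stats.pvalue, dtype=float)
    sig = pvals < alpha
    if not sig.any():
        return []
    if gene_stats.kind == "t":
        regions = []
        lower = stats[sig & (stats < 0)]
        upper = stats[sig & (stats > 0)]
        if lower.size:
            regions.append((float(stats.min()), float(lower.max())))
        if upper.size:
            regions.append((float(upper.min()), float(stats.max())))
        return regions
    return [(float(stats[sig].min()), float(stats.max()))]


def _pyplot():
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    return plt


def gsa_plot(results: GSAResultTable, out, dump_txt=None) -> None:
    """Render the ordered-P-value-versus-rank plot to ``out`` (PNG/SVG)."""
    plt = _pyplot()
    curves = ordered_pvalues(results)
    fig, ax = plt.subplots(figsize=(5, 5))
    for label, pv in curves.items():
        k = len(pv)
        ax.plot(np.arange(1, k + 1) / k, pv, marker="o", ms=3, lw=1, label=label)
    ax.plot([0, 1], [0, 1], ls="--", color="grey", label="uniform null")
    ax.set_xlabel("rank / k")
    ax.set_ylabel("ordered P-value")
    ax.legend(frameon=False)
    fig.tight_layout()
    fig.savefig(out)
    plt.close(fig)
    if dump_txt is not None:
        import pandas as pd

        pd.DataFrame(curves).to_csv(dump_txt, sep="\t", index=False)


def gst_plot(
    gene_stats: GeneLevelStats,
    set_members,
    gene_names=None,
    alpha: float = 0.01,
    out=None,
    dump_txt=None,
) -> None:
    """Render the GST (SAFE-style) plot for one gene set to ``out``."""
    plt = _pyplot()
    sorted_stats, ecdf, member_ranks = gst_curve(gene_stats, set_members)
    members = np.asarray(set_members, dtype=int)
    if gene_names is None:
        gene_names = [gene_stats.gene_ids[i] if gene_stats.gene_ids else str(i) for i in members]
    fig, ax = plt.subplots(figsize=(6, 4.5))
    for lo, hi in significance_bounds(gene_stats, alpha):
        ax.axvspan(lo, hi, color="lightgrey", alpha=0.6)
    ax.plot(sorted_stats, ecdf, color="black", lw=1.2, label="set ECDF")
    ax.plot(
        sorted_stats,
        np.linspace(1 / len(sorted_stats), 1, len(sorted_stats)),
        color="red",
        lw=0.8,
        label="all genes",
    )
    member_stats = np.asarray(gene_stats.statistic)[members]
    for x, name in zip(member_stats, gene_names):
        ax.axvline(x, ymin=0.97, ymax=1.0, color="black", lw=0.8)
        ax.text(x, 1.02, str(name), rotation=90, fontsize=5, ha="center", va="bottom")
    ax.set_xlabel(f"ranked {gene_stats.kind}-statistic")
    ax.set_ylabel("empirical CDF")
    ax.set_ylim(0, 1.12)
    ax.legend(frameon=False, loc="lower right")
    fig.tight_layout()
    if out is not None:
        fig.savefig(out)
    plt.close(fig)
    if dump_txt is not None:
        import pandas as pd

        pd.DataFrame({"statistic": sorted_stats, "ecdf": ecdf}).to_csv(dump_txt, sep="\t", index=False)
    return None
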