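"""Standard diagnostic figures for scan and architecture results.

All functions draw onto a fresh figure and, when ``path`` is given, save
and close it, returning the path; otherwise the figure is returned for
further styling.
"""

from __future__ import annotations

from pathlib import Path

import matplotlib

matplotlib.use("Agg")
import matplotlib.pyplot as plt
import numpy as np

from gremlite.assoc import GENOME_WIDE_P, SUGGESTIVE_P, AssocTable
from gremlite.enrichment import EnrichmentResult

__all__ = ["manhattan", "qq_plot", "enrichment_histogram", "h2_length_plot"]


def _finish(fig, path):
    if path is None:
        return fig
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    fig.savefig(path, dpi=120, bbox_inches="tight")
    plt.close(fig)
    return path


def manhattan(result: AssocTable, path=None, title: str | None = None):
    """-log10(p) by genomic position with the 5e-8 and 1e-5 reference lines."""
    t = result.table.dropna(subset=["p"]).copy()
    t["chrom_order"] = t["chrom"].astype(str)
    fig, ax = plt.subplots(figsize=(9, 3.2))
    offset = 0
    ticks, labels = [], []
    for i, (chrom, sub) in enumerate(t.groupby("chrom_order", sort=False)):
        x = sub["pos"].to_numpy() + offset
        ax.scatter(x, -np.log10(sub["p"]), s=4, color="C0" if i % 2 else "C7")
        ticks.append(offset + sub["pos"].mean())
        labels.append(chrom)
        offset += sub["pos"].max() + 1
    ax.axhline(-np.log10(GENOME_WIDE_P), color="red", lw=0.8)
    ax.axhline(-np.log10(SUGGESTIVE_P), color="blue", lw=0.8)
    ax.set_xticks(ticks, labels)
    ax.set_xlabel("chromosome")
    ax.set_ylabel(r"$-\log_{10} p$")
    if title:
        ax.set_title(title)
    return _finish(fig, path)


def qq_plot(result: AssocTable, path=None):
    """Observed vs expected -log10(p) quantiles with the inflation factor."""
    p = np.sort(result.table["p"].dropna().to_numpy())
    n = len(p)
    expected = (np.arange(1, n + 1) - 0.5) / n
    fig, ax = plt.subplots(figsize=(3.6, 3.6))
    ax.scatter(-np.log10(expected), -np.log10(p), s=5)
    lim = max(-np.log10(expected[0]), -np.log10(p[0])) * 1.05
    ax.plot([0, lim], [0, lim], color="red", lw=0.8)
    ax.set_xlabel(r"expected $-\log_{10} p$")
    ax.set_ylabel(r"observed $-\log_{10} p$")
    ax.set_title(f"$\\lambda$ = {result.lambda_gc:.3f}")
    return _finish(fig, path)


def enrichment_histogram(result: EnrichmentResult, path=None):
    """Permuted annotated-count distribution with the observed count marked."""
    fig, ax = plt.subplots(figsize=(4.5, 3.2))
    ax.hist(result.permuted_counts, bins="auto", color="C7", edgecolor="white")
    ax.axvline(result.observed_count, color="black", lw=1.5)
    ax.plot([result.observed_count], [0], "ko", clip_on=False)
    ax.set_xlabel(f"annotated SNPs among top {result.top_k}")
    ax.set_ylabel("permutations")
    ax.set_title(f"empirical p = {result.p_value:.3g} (B = {result.effective_B})")
    return _finish(fig, path)


def h2_length_plot(summary, path=None):
    """Per-chromosome h2 against length with the fitted line and its band."""
    t = summary.table.sort_values("length")
    fig, ax = plt.subplots(figsize=(4.5, 3.4))
    ax.scatter(t["length"], t["h2"], s=18)
    ax.plot(t["length"], t["fitted"], color="C0")
    ax.plot(t["length"], t["lo"], "--", color="C0", lw=0.8)
    ax.plot(t["length"], t["hi"], "--", color="C0", lw=0.8)
    for _, row in t[t["outside"]].iterrows():
        ax.annotate(row["label"], (row["length"], row["h2"]),
                    textcoords="offset points", xytext=(4, 4))
    ax.set_xlabel("chromosome length (bp)")
    ax.set_ylabel(r"$h^2$")
    ax.set_title(f"r = {summary.r:.2f}, p = {summary.p_value:.2g}")
    return _finish(fig, path)
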