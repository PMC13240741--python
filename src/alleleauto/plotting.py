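"""Visual outputs: colinearity dot plots and ASE summary figures.

All figures are written in vector format (SVG by default).  The dot
plot is the pipeline's quality-control view: one panel per chromosome
combination, points at gene midpoints colored by terminal filter
status, so retained alleles trace the diagonal and every rejection
class stays visible.
"""

from __future__ import annotations

from pathlib import Path

import matplotlib

matplotlib.use("Agg")
import matplotlib.pyplot as plt
import numpy as np
import pandas as pd

from .ase import CATEGORIES, DIFF_CATEGORIES
from .models import ChromosomeMap, SampleDesign

STATUS_COLORS = {
    "allele": "#1f77b4",
    "rejected_cross_chrom": "#7f7f7f",
    "rejected_non_colinear": "#ff7f0e",
    "rejected_ks_outlier": "#d62728",
    "rejected_slope": "#9467bd",
    "rejected_saturated": "#8c564b",
}


def plot_dotplot(
    pairs: pd.DataFrame, chromosome_map: ChromosomeMap, out_path: str | Path
) -> None:
    """Genome colinearity dot plot of all RBH pairs.

    ``pairs`` is the identification table (needs chrom_a, chrom_b,
    mid_a, mid_b, status).  Panels form a haplotype-A x haplotype-B
    chromosome grid so cross-chromosome pairs are visible off the
    corresponding-panel diagonal.
    """
    chroms_a = [ca for ca, _ in chromosome_map.pairs]
    chroms_b = [cb for _, cb in chromosome_map.pairs]
    extra_a = sorted(set(pairs["chrom_a"]) - set(chroms_a))
    extra_b = sorted(set(pairs["chrom_b"]) - set(chroms_b))
    chroms_a += extra_a
    chroms_b += extra_b
    n_a, n_b = len(chroms_a), len(chroms_b)
    fig, axes = plt.subplots(
        n_b, n_a, figsize=(2.6 * n_a + 1, 2.6 * n_b + 1),
        squeeze=False, sharex="col", sharey="row",
    )
    seen_statuses = []
    for ib, cb in enumerate(chroms_b):
        for ia, ca in enumerate(chroms_a):
            ax = axes[ib][ia]
            sub = pairs[(pairs["chrom_a"] == ca) & (pairs["chrom_b"] == cb)]
            for status, grp in sub.groupby("status"):
                ax.scatter(
                    grp["mid_a"] / 1e6, grp["mid_b"] / 1e6, s=4,
                    c=STATUS_COLORS.get(status, "black"), label=status,
                )
                if status not in seen_statuses:
                    seen_statuses.append(status)
            if ib == n_b - 1:
                ax.set_xlabel(f"{ca} (Mb)")
            if ia == 0:
                ax.set_ylabel(f"{cb} (Mb)")
    handles = [
        plt.Line2D([0], [0], marker="o", linestyle="", color=STATUS_COLORS[s],
                   label=s, markersize=5)
        for s in STATUS_COLORS if s in seen_statuses
    ]
    fig.legend(handles=handles, loc="upper center", ncol=min(len(handles), 6),
               frameon=False)
    fig.tight_layout(rect=(0, 0, 1, 0.94))
    fig.savefig(out_path)
    plt.close(fig)


def plot_ase_summaries(
    ase_results: pd.DataFrame,
    allele_pairs: pd.DataFrame,
    tpm: pd.DataFrame,
    design: SampleDesign,
    out_dir: str | Path,
    fmt: str = "svg",
) -> list[Path]:
    """Write the ASE summary figures; returns the paths written.

    Figures: stacked category bars per condition; Ka/Ks/Ka-Ks
    boxplots by differential category; |TPM_A - TPM_B| boxplots; and
    a haplotype-bias bar chart (per-replicate counts of the more
    highly expressed haplotype, mean +/- s.d. across replicates).
    """
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    written: list[Path] = []

    # 1. stacked category bars
    fig, ax = plt.subplots(figsize=(1.5 + 1.2 * ase_results["condition"].nunique(), 4))
    conditions = sorted(ase_results["condition"].unique())
    bottoms = np.zeros(len(conditions))
    cmap = plt.get_cmap("viridis")
    for k, cat in enumerate(CATEGORIES):
        heights = [
            ((ase_results["condition"] == c) & (ase_results["category"] == cat)).sum()
            for c in conditions
        ]
        ax.bar(conditions, heights, bottom=bottoms, label=cat,
               color=cmap(k / max(len(CATEGORIES) - 1, 1)))
        bottoms += np.array(heights, dtype=float)
    ax.set_ylabel("allele pairs")
    ax.legend(fontsize=8)
    path = out_dir / f"ase_categories.{fmt}"
    fig.tight_layout()
    fig.savefig(path)
    plt.close(fig)
    written.append(path)

    # 2. divergence by category
    merged = ase_results.merge(
        allele_pairs[["gene_a", "gene_b", "ka", "ks", "ka_ks"]],
        on=["gene_a", "gene_b"], how="left",
    )
    fig, axes = plt.subplots(1, 3, figsize=(9, 3.5))
    for ax, metric in zip(axes, ("ka", "ks", "ka_ks")):
        data = [
            merged.loc[merged["category"] == cat, metric].dropna().values
            for cat in DIFF_CATEGORIES
        ]
        ax.boxplot(data, tick_labels=DIFF_CATEGORIES)
        ax.set_title(metric)
    path = out_dir / f"divergence_by_category.{fmt}"
    fig.tight_layout()
    fig.savefig(path)
    plt.close(fig)
    written.append(path)

    # 3. |TPM_A - TPM_B| by category
    gaps: dict[str, list[float]] = {cat: [] for cat in DIFF_CATEGORIES}
    for condition in design.conditions:
        samples = [s for s in design.samples_for(condition) if s in tpm.columns]
        if not samples:
            continue
        means = tpm[samples].mean(axis=1)
        sub = ase_results[ase_results["condition"] == condition]
        for _, r in sub.iterrows():
            if r["category"] in gaps and r["gene_a"] in means.index \
                    and r["gene_b"] in means.index:
                gaps[r["category"]].append(abs(means[r["gene_a"]] - means[r["gene_b"]]))
    fig, ax = plt.subplots(figsize=(4, 3.5))
    ax.boxplot([gaps[c] or [np.nan] for c in DIFF_CATEGORIES],
               tick_labels=DIFF_CATEGORIES)
    ax.set_ylabel("|TPM A - TPM B|")
    path = out_dir / f"expression_gap.{fmt}"
    fig.tight_layout()
    fig.savefig(path)
    plt.close(fig)
    written.append(path)

    # 4. haplotype bias: per-replicate higher-expressed counts, mean +/- sd
    pair_index = ase_results[["gene_a", "gene_b"]].drop_duplicates()
    labels, mean_a, sd_a, mean_b, sd_b = [], [], [], [], []
    for condition in design.conditions:
        samples = [s for s in design.samples_for(condition) if s in tpm.columns]
        if not samples:
            continue
        counts_a, counts_b = [], []
        for s in samples:
            col = tpm[s]
            va = col.reindex(pair_index["gene_a"]).values
            vb = col.reindex(pair_index["gene_b"]).values
            ok = np.isfinite(va) & np.isfinite(vb) & (va != vb)
            counts_a.append(int((va[ok] > vb[ok]).sum()))
            counts_b.append(int((va[ok] < vb[ok]).sum()))
        labels.append(condition)
        mean_a.append(np.mean(counts_a)); sd_a.append(np.std(counts_a))
        mean_b.append(np.mean(counts_b)); sd_b.append(np.std(counts_b))
    fig, ax = plt.subplots(figsize=(1.5 + 1.4 * max(len(labels), 1), 3.5))
    x = np.arange(len(labels))
    ax.bar(x - 0.2, mean_a, 0.4, yerr=sd_a, label="haplotype A higher", capsize=3)
    ax.bar(x + 0.2, mean_b, 0.4, yerr=sd_b, label="haplotype B higher", capsize=3)
    ax.set_xticks(x)
    ax.set_xticklabels(labels)
    ax.set_ylabel("genes")
    ax.legend(fontsize=8)
    path = out_dir / f"haplotype_bias.{fmt}"
    fig.tight_layout()
    fig.savefig(path)
    plt.close(fig)
    written.append(path)
    return written
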