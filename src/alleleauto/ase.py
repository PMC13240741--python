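"""Allele-specific expression: normalization, per-pair differential
tests and five-category classification.

Each allele pair is tested per condition by comparing the two alleles'
size-factor-normalized counts across replicates under a negative
binomial model with a Wald statistic on the (pseudocount-stabilized)
log2 fold change.  Dispersion is estimated per pair by method of
moments and, by default, moderated by flooring at the across-pair mean
— a small-sample guard in the spirit of DESeq2's dispersion sharing;
the plain per-pair estimate is selectable but anti-conservative at
three replicates.  P values are Benjamini-Hochberg adjusted within
each condition and pairs fall into five categories:

* ``No_expression`` — both alleles zero in every replicate;
* ``Diff00`` — adjusted p > alpha (or pair untestable);
* ``Diff0`` — adjusted p <= alpha and |FC| <= 2;
* ``Diff2`` — adjusted p <= alpha and 2 < |FC| < 8;
* ``Diff8`` — adjusted p <= alpha and |FC| >= 8;

where |FC| = max(FC, 1/FC) = 2^|log2FC| is the linear fold-change
magnitude.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .models import ChromosomeMap, CountMatrix, SampleDesign

log = logging.getLogger("alleleauto")

CATEGORIES = ("No_expression", "Diff00", "Diff0", "Diff2", "Diff8")
DIFF_CATEGORIES = ("Diff0", "Diff2", "Diff8")


@dataclass
class DispersionConfig:
    """How the NB dispersion entering the Wald variance is obtained.

    ``moderated`` (default): per-pair method-of-moments floored at the
    across-pair mean; ``per_pair``: raw method-of-moments with only
    the numerical floor; ``fixed``: use ``fixed_alpha`` everywhere.
    """

    method: str = "moderated"
    floor: float = 1e-8
    fixed_alpha: float = 0.1

    def __post_init__(self) -> None:
        if self.method not in ("moderated", "per_pair", "fixed"):
            raise ValueError(f"unknown dispersion method {self.method!r}")


def size_factors(counts: np.ndarray, allow_pseudo_reference: bool = False) -> np.ndarray:
    """Median-of-ratios normalization factors, one per sample (column).

    The reference is the per-gene geometric mean over samples; each
    sample's factor is the median ratio to the reference over genes
    with an all-positive row.  If no gene is positive in every sample,
    an error advises the ``allow_pseudo_reference`` fallback, which
    takes geometric means over positive entries only.
    """
    counts = np.asarray(counts, dtype=float)
    if counts.ndim != 2:
        raise ValueError("counts must be a genes x samples matrix")
    positive = (counts > 0).all(axis=1)
    if not positive.any():
        if not allow_pseudo_reference:
            raise ValueError(
                "no gene has positive counts in all samples; re-run with "
                "allow_pseudo_reference=True to use a positive-part reference"
            )
        with np.errstate(divide="ignore"):
            logc = np.where(counts > 0, np.log(counts), np.nan)
        ref = np.exp(np.nanmean(logc, axis=1))
        use = np.isfinite(ref) & (ref > 0)
    else:
        ref = np.exp(np.log(counts[positive]).mean(axis=1))
        counts = counts  # ratios computed on the positive subset below
        factors = np.median(counts[positive] / ref[:, None], axis=0)
        return factors
    ratios = counts[use] / ref[use, None]
    factors = np.array([
        np.median(col[col > 0]) if (col > 0).any() else 1.0 for col in ratios.T
    ])
    return factors


def compute_tpm(counts: np.ndarray, gene_lengths: Sequence[float]) -> np.ndarray:
    """Transcripts-per-million matrix; each nonzero column sums to 1e6."""
    counts = np.asarray(counts, dtype=float)
    lengths = np.asarray(gene_lengths, dtype=float)
    if (lengths <= 0).any():
        raise ValueError("gene lengths must be > 0")
    rate = counts / (lengths[:, None] / 1000.0)
    colsum = rate.sum(axis=0)
    with np.errstate(invalid="ignore", divide="ignore"):
        tpm = np.where(colsum > 0, rate / colsum * 1e6, 0.0)
    return tpm


def bh_adjust(p_values: Sequence[float]) -> np.ndarray:
    """Benjamini-Hochberg step-up adjustment; NaNs pass through."""
    p = np.asarray(p_values, dtype=float)
    out = np.full(p.shape, np.nan)
    ok = np.isfinite(p)
    if ok.any():
        out[ok] = multipletests(p[ok], method="fdr_bh")[1]
    return out


def nb_wald_test(
    norm_a: np.ndarray,
    norm_b: np.ndarray,
    dispersion: float,
    pseudocount: float = 0.5,
) -> tuple[float, float, float, float]:
    """Wald test of equal means for two NB count groups.

    Returns (mean_a, mean_b, log2fc, p).  The fold change is
    stabilized with ``pseudocount`` on both means; the variance of the
    log mean difference uses the plug-in NB variance
    (1/mu + dispersion)/n per group.
    """
    a = np.asarray(norm_a, dtype=float)
    b = np.asarray(norm_b, dtype=float)
    ma, mb = a.mean(), b.mean()
    lfc_ln = np.log(ma + pseudocount) - np.log(mb + pseudocount)
    var = ((1.0 / (ma + pseudocount) + dispersion) / len(a)
           + (1.0 / (mb + pseudocount) + dispersion) / len(b))
    z = lfc_ln / np.sqrt(var)
    p = 2.0 * stats.norm.sf(abs(z))
    return ma, mb, lfc_ln / np.log(2.0), min(p, 1.0)


def moment_dispersion(norm_a: np.ndarray, norm_b: np.ndarray) -> float:
    """Method-of-moments NB dispersion pooled over the two groups
    (may be negative for under-dispersed samples; caller floors it)."""
    a = np.asarray(norm_a, dtype=float)
    b = np.asarray(norm_b, dtype=float)
    mu = (a.mean() + b.mean()) / 2.0
    if mu <= 0:
        return 0.0
    s2 = (a.var(ddof=1) + b.var(ddof=1)) / 2.0
    return float((s2 - mu) / mu ** 2)


def classify_ase(
    padj: float, fc_magnitude: float, no_expression: bool, alpha: float = 0.05
) -> str:
    """Assign one of the five ASE categories (boundaries: |FC| = 2 ->
    Diff0, |FC| = 8 -> Diff8)."""
    if no_expression:
        return "No_expression"
    if not np.isfinite(padj) or padj > alpha:
        return "Diff00"
    if fc_magnitude <= 2.0:
        return "Diff0"
    if fc_magnitude < 8.0:
        return "Diff2"
    return "Diff8"


def analyze(
    counts: CountMatrix,
    design: SampleDesign,
    allele_pairs: pd.DataFrame,
    min_replicates: int = 3,
    alpha: float = 0.05,
    dispersion: Optional[DispersionConfig] = None,
    allow_pseudo_reference: bool = False,
) -> pd.DataFrame:
    """Test and classify every allele pair in every condition.

    ``allele_pairs`` needs columns gene_a and gene_b (typically the
    ``status == "allele"`` rows of the identification table).  Returns
    one row per pair per condition with means, log2fc, p, padj,
    fc_magnitude and category.  Pairs whose genes are missing from
    the count matrix are skipped with a warning; conditions with fewer
    than ``min_replicates`` replicates leave their pairs untestable
    (classified Diff00 unless No_expression).
    """
    dispersion = dispersion or DispersionConfig()
    gene_pos = {g: i for i, g in enumerate(counts.gene_ids)}
    sample_pos = {s: j for j, s in enumerate(counts.sample_ids)}
    missing_samples = [s for s in design.assignments if s not in sample_pos]
    if missing_samples:
        raise ValueError(f"design samples absent from counts: {missing_samples}")

    factors = size_factors(counts.counts, allow_pseudo_reference)
    norm = counts.counts / factors[None, :]

    usable = []
    skipped = 0
    for _, row in allele_pairs.iterrows():
        if row["gene_a"] in gene_pos and row["gene_b"] in gene_pos:
            usable.append((row["gene_a"], row["gene_b"]))
        else:
            skipped += 1
    if skipped:
        log.warning("%d allele pairs missing from the count matrix", skipped)

    records = []
    for condition in design.conditions:
        cols = [sample_pos[s] for s in design.samples_for(condition)]
        testable = len(cols) >= min_replicates
        if not testable:
            log.warning(
                "condition %s has %d replicates (< %d): pairs untestable",
                condition, len(cols), min_replicates,
            )
        raws, disps = [], []
        for ga, gb in usable:
            na = norm[gene_pos[ga]][:, ][cols]
            nb = norm[gene_pos[gb]][:, ][cols]
            raws.append((na, nb))
            disps.append(moment_dispersion(na, nb) if testable and len(cols) > 1
                         else np.nan)
        disps = np.asarray(disps, dtype=float)
        if dispersion.method == "fixed":
            alphas = np.full(len(usable), dispersion.fixed_alpha)
        else:
            floored = np.maximum(disps, dispersion.floor)
            if dispersion.method == "moderated" and np.isfinite(disps).any():
                pooled = np.nanmean(np.maximum(disps, 0.0))
                alphas = np.maximum(floored, pooled)
            else:
                alphas = floored
        for (ga, gb), (na, nb), alpha_i in zip(usable, raws, alphas):
            ra = counts.counts[gene_pos[ga]][cols]
            rb = counts.counts[gene_pos[gb]][cols]
            no_expr = (ra == 0).all() and (rb == 0).all()
            if testable and not no_expr:
                ma, mb, lfc, p = nb_wald_test(na, nb, float(alpha_i))
            else:
                ma, mb, lfc, p = na.mean(), nb.mean(), np.nan, np.nan
            records.append({
                "gene_a": ga, "gene_b": gb, "condition": condition,
                "mean_a": ma, "mean_b": mb, "log2fc": lfc, "p": p,
            })
    df = pd.DataFrame(records)
    if df.empty:
        return pd.DataFrame(columns=[
            "gene_a", "gene_b", "condition", "mean_a", "mean_b",
            "log2fc", "p", "padj", "fc_magnitude", "category",
        ])
    df["padj"] = np.nan
    for condition in design.conditions:
        sel = df["condition"] == condition
        df.loc[sel, "padj"] = bh_adjust(df.loc[sel, "p"].values)
    df["fc_magnitude"] = 2.0 ** np.abs(df["log2fc"])
    df["category"] = [
        classify_ase(
            row["padj"], row["fc_magnitude"],
            no_expression=not np.isfinite(row["log2fc"]) and _all_zero(row, df),
            alpha=alpha,
        )
        for _, row in df.iterrows()
    ]
    return df


def _all_zero(row: pd.Series, df: pd.DataFrame) -> bool:
    # log2fc is NaN either because the pair was untestable (-> Diff00)
    # or because both alleles were all-zero (-> No_expression); the two
    # are told apart by the recorded raw means.
    return row["mean_a"] == 0 and row["mean_b"] == 0


def category_counts(ase_results: pd.DataFrame) -> pd.DataFrame:
    """Pairs per category per condition (all five categories listed)."""
    rows = []
    for condition, sub in ase_results.groupby("condition"):
        counts = sub["category"].value_counts()
        for cat in CATEGORIES:
            rows.append({
                "condition": condition, "category": cat,
                "n": int(counts.get(cat, 0)),
            })
    return pd.DataFrame(rows, columns=["condition", "category", "n"])


def divergence_by_category(
    allele_pairs: pd.DataFrame, ase_results: pd.DataFrame
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Ka/Ks/Ka-Ks summaries per differential category, plus pairwise
    rank-sum tests between categories.

    Returns (summary, tests).  Categories with no members get n = 0
    and NA statistics.
    """
    merged = ase_results.merge(
        allele_pairs[["gene_a", "gene_b", "ka", "ks", "ka_ks"]],
        on=["gene_a", "gene_b"], how="left",
    )
    summary_rows, test_rows = [], []
    metrics = ("ka", "ks", "ka_ks")
    for cat in DIFF_CATEGORIES:
        sub = merged[merged["category"] == cat]
        row: dict = {"category": cat, "n": len(sub)}
        for m in metrics:
            vals = sub[m].dropna()
            if len(vals):
                row[f"{m}_median"] = vals.median()
                row[f"{m}_q1"] = vals.quantile(0.25)
                row[f"{m}_q3"] = vals.quantile(0.75)
            else:
                row[f"{m}_median"] = row[f"{m}_q1"] = row[f"{m}_q3"] = np.nan
        summary_rows.append(row)
    for i, c1 in enumerate(DIFF_CATEGORIES):
        for c2 in DIFF_CATEGORIES[i + 1:]:
            for m in metrics:
                v1 = merged.loc[merged["category"] == c1, m].dropna()
                v2 = merged.loc[merged["category"] == c2, m].dropna()
                if len(v1) and len(v2):
                    p = stats.mannwhitneyu(v1, v2, alternative="two-sided").pvalue
                else:
                    p = np.nan
                test_rows.append({
                    "metric": m, "category_1": c1, "category_2": c2, "p": p,
                })
    return pd.DataFrame(summary_rows), pd.DataFrame(test_rows)


def haplotype_bias_counts(
    ase_results: pd.DataFrame,
    tpm: pd.DataFrame,
    pair_chromosomes: pd.DataFrame,
    design: SampleDesign,
) -> pd.DataFrame:
    """Per chromosome pair and condition: how many allele pairs are
    more highly expressed from haplotype A vs B (mean TPM over the
    condition's replicates; ties excluded), with a two-sided sign-test
    p value.

    ``tpm`` is a gene x sample DataFrame; ``pair_chromosomes`` needs
    columns gene_a, gene_b, chrom_a, chrom_b.
    """
    chrom_of = pair_chromosomes.set_index(["gene_a", "gene_b"])
    rows = []
    for condition in design.conditions:
        samples = [s for s in design.samples_for(condition) if s in tpm.columns]
        if not samples:
            continue
        means = tpm[samples].mean(axis=1)
        sub = ase_results[ase_results["condition"] == condition]
        tallies: dict[tuple[str, str], list[int]] = {}
        for _, r in sub.iterrows():
            key = (r["gene_a"], r["gene_b"])
            if key not in chrom_of.index:
                continue
            if r["gene_a"] not in means.index or r["gene_b"] not in means.index:
                continue
            ta, tb = means[r["gene_a"]], means[r["gene_b"]]
            if ta == tb:
                continue
            ck = (chrom_of.loc[key, "chrom_a"], chrom_of.loc[key, "chrom_b"])
            tallies.setdefault(ck, [0, 0])[0 if ta > tb else 1] += 1
        for (ca, cb), (n_a, n_b) in sorted(tallies.items()):
            p = stats.binomtest(n_a, n_a + n_b, 0.5).pvalue if n_a + n_b else np.nan
            rows.append({
                "condition": condition, "chrom_a": ca, "chrom_b": cb,
                "n_a_higher": n_a, "n_b_higher": n_b, "sign_test_p": p,
            })
    return pd.DataFrame(rows, columns=[
        "condition", "chrom_a", "chrom_b", "n_a_higher", "n_b_higher",
        "sign_test_p",
    ])


def expression_gap_by_category(
    ase_results: pd.DataFrame, tpm: pd.DataFrame, design: SampleDesign
) -> pd.DataFrame:
    """Distribution of |TPM_A - TPM_B| (condition means) per
    differential category."""
    rows = []
    for condition in design.conditions:
        samples = [s for s in design.samples_for(condition) if s in tpm.columns]
        if not samples:
            continue
        means = tpm[samples].mean(axis=1)
        sub = ase_results[ase_results["condition"] == condition]
        for cat in DIFF_CATEGORIES:
            gaps = []
            for _, r in sub[sub["category"] == cat].iterrows():
                if r["gene_a"] in means.index and r["gene_b"] in means.index:
                    gaps.append(abs(means[r["gene_a"]] - means[r["gene_b"]]))
            gaps_arr = np.asarray(gaps, dtype=float)
            rows.append({
                "condition": condition, "category": cat, "n": len(gaps_arr),
                "gap_median": np.median(gaps_arr) if len(gaps_arr) else np.nan,
                "gap_q1": np.quantile(gaps_arr, 0.25) if len(gaps_arr) else np.nan,
                "gap_q3": np.quantile(gaps_arr, 0.75) if len(gaps_arr) else np.nan,
                "gap_mean": gaps_arr.mean() if len(gaps_arr) else np.nan,
            })
    return pd.DataFrame(rows, columns=[
        "condition", "category", "n", "gap_median", "gap_q1", "gap_q3",
        "gap_mean",
    ])
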