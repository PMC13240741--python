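"""Dual-layer statistical filtering separating allele pairs from paralogs.

Candidate pairs (reciprocal best hits) are whittled down in stages:
cross-chromosome pairs are dropped, non-colinear pairs are dropped,
pairs with saturated divergence are set aside, then two statistical
layers run over what is left — an outlier mask on the Ks distribution
(parametric 3-sigma rule or non-parametric Tukey fences with tunable
multiplier i) and the same mask applied to the per-block slopes of
gene order.  Survivors are called alleles.  Every RBH pair receives
exactly one terminal status and the stage counts telescope.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Iterable, Optional, Sequence

import numpy as np
import pandas as pd

from .divergence import estimate_pair
from .homology import find_rbh, score_all_vs_all
from .models import Anchor, ChromosomeMap, GeneModel, HitRecord, RBHPair, SyntenyBlock
from .synteny import (
    DEFAULT_MAX_GAP,
    DEFAULT_MIN_BLOCK_SIZE,
    chain_by_chromosome,
    make_anchors,
)

log = logging.getLogger("alleleauto")

STATUSES = (
    "allele",
    "rejected_cross_chrom",
    "rejected_non_colinear",
    "rejected_ks_outlier",
    "rejected_slope",
    "rejected_saturated",
)


@dataclass
class FilterConfig:
    """Parameters of the dual-layer filter.

    ``method`` selects the outlier rule applied to both layers:
    "sigma" flags values beyond mean +/- sigma_k standard deviations
    (suits near-normal Ks distributions); "tukey" flags values outside
    [Q1 - m*IQR, Q3 + m*IQR] with m = tukey_i for the inner fence or
    2*tukey_i for the outer (distribution-free; smaller i is
    stricter).  ``ks_before_slope`` orders the two statistical layers.
    """

    method: str = "sigma"
    sigma_k: float = 3.0
    tukey_i: float = 1.5
    fence: str = "inner"
    apply_slope_filter: bool = True
    ks_before_slope: bool = True
    min_block_size: int = DEFAULT_MIN_BLOCK_SIZE
    max_gap: int = DEFAULT_MAX_GAP

    def __post_init__(self) -> None:
        if self.method not in ("sigma", "tukey"):
            raise ValueError(f"unknown method {self.method!r}")
        if self.fence not in ("inner", "outer"):
            raise ValueError(f"unknown fence {self.fence!r}")
        if self.sigma_k <= 0 or self.tukey_i <= 0:
            raise ValueError("sigma_k and tukey_i must be > 0")

    def mask(self, values: Sequence[float]) -> np.ndarray:
        if self.method == "sigma":
            return sigma_mask(values, self.sigma_k)
        return tukey_mask(values, self.tukey_i, self.fence)

    @property
    def min_mask_n(self) -> int:
        return 2 if self.method == "sigma" else 4


@dataclass
class FilterReport:
    """Stage-by-stage retention counts; successive stages telescope."""

    n_rbh: int = 0
    n_same_chrom: int = 0
    n_colinear: int = 0
    n_saturated_removed: int = 0
    n_ks_removed: int = 0
    n_after_ks: int = 0
    n_slope_removed: int = 0
    n_alleles: int = 0
    method: str = ""
    parameters: dict = field(default_factory=dict)

    def to_frame(self) -> pd.DataFrame:
        rows = [
            ("rbh", self.n_rbh, 0),
            ("same_chromosome", self.n_same_chrom, self.n_rbh - self.n_same_chrom),
            ("colinear", self.n_colinear, self.n_same_chrom - self.n_colinear),
            ("unsaturated", self.n_colinear - self.n_saturated_removed,
             self.n_saturated_removed),
            ("ks_filter", self.n_after_ks, self.n_ks_removed),
            ("slope_filter", self.n_alleles, self.n_slope_removed),
        ]
        return pd.DataFrame(rows, columns=["stage", "retained", "removed"])


@dataclass
class FilterResult:
    """Full output of :func:`identify_alleles`."""

    table: pd.DataFrame           # one row per RBH pair with terminal status
    report: FilterReport
    blocks: list[SyntenyBlock]
    anchors: pd.DataFrame         # per-anchor ranks/midpoints and block id

    @property
    def alleles(self) -> pd.DataFrame:
        return self.table[self.table["status"] == "allele"]


def sigma_mask(values: Sequence[float], k: float = 3.0) -> np.ndarray:
    """Flag values beyond ``k`` sample standard deviations from the mean.

    Non-finite entries are never flagged.  A zero standard deviation
    (all-identical values) flags nothing.
    """
    x = np.asarray(values, dtype=float)
    finite = np.isfinite(x)
    if finite.sum() < 2:
        raise ValueError("sigma_mask needs at least 2 finite values")
    mu = x[finite].mean()
    sd = x[finite].std(ddof=1)
    mask = np.zeros(x.shape, dtype=bool)
    if sd == 0:
        return mask
    mask[finite] = (x[finite] < mu - k * sd) | (x[finite] > mu + k * sd)
    return mask


def tukey_mask(
    values: Sequence[float], i: float = 1.5, fence: str = "inner"
) -> np.ndarray:
    """Flag values strictly outside Tukey's fences.

    Q1/Q3 are the 25th/75th percentiles by linear interpolation at
    rank 1 + (n-1)p; the fence multiplier is ``i`` (inner) or ``2i``
    (outer).  When IQR = 0 the window degenerates to the single point
    Q1, and only values different from it are flagged.
    """
    if fence not in ("inner", "outer"):
        raise ValueError(f"unknown fence {fence!r}")
    x = np.asarray(values, dtype=float)
    finite = np.isfinite(x)
    if finite.sum() < 4:
        raise ValueError("tukey_mask needs at least 4 finite values")
    q1, q3 = np.quantile(x[finite], [0.25, 0.75])
    iqr = q3 - q1
    m = i if fence == "inner" else 2.0 * i
    mask = np.zeros(x.shape, dtype=bool)
    if iqr == 0:
        mask[finite] = x[finite] != q1
        return mask
    mask[finite] = (x[finite] < q1 - m * iqr) | (x[finite] > q3 + m * iqr)
    return mask


def slope_filter(
    blocks: Sequence[SyntenyBlock], config: FilterConfig
) -> tuple[list[SyntenyBlock], list[SyntenyBlock]]:
    """Remove blocks whose gene-order slope is a statistical outlier.

    Uses the same mask and parameters as the Ks layer.  With fewer
    blocks than the mask needs (2 for sigma, 4 for tukey) nothing is
    removed and a warning is logged.
    """
    blocks = list(blocks)
    if len(blocks) < config.min_mask_n:
        if blocks:
            log.warning(
                "only %d blocks: slope filter needs >= %d, skipping",
                len(blocks), config.min_mask_n,
            )
        return blocks, []
    slopes = [b.slope for b in blocks]
    outlier = config.mask(slopes)
    retained = [b for b, o in zip(blocks, outlier) if not o]
    removed = [b for b, o in zip(blocks, outlier) if o]
    return retained, removed


def identify_alleles(
    genes_a: Sequence[GeneModel],
    genes_b: Sequence[GeneModel],
    chromosome_map: ChromosomeMap,
    hits: Optional[Iterable[HitRecord]] = None,
    config: Optional[FilterConfig] = None,
) -> FilterResult:
    """Run the full allele-identification pipeline.

    Stages: (1) reciprocal best hits; (2) drop cross-chromosome pairs;
    (3) synteny chaining, drop non-colinear pairs; (4) Ka/Ks, set
    saturated pairs aside; (5) outlier mask on Ks; (6) block-slope
    filter (stages 5 and 6 swap when ``config.ks_before_slope`` is
    False).  Survivors get status "allele".  An empty survivor set is
    a valid result, not an error.
    """
    config = config or FilterConfig()
    gene_index = {g.gene_id: g for g in list(genes_a) + list(genes_b)}
    if len(gene_index) < len(genes_a) + len(genes_b):
        raise ValueError("duplicate gene ids across haplotypes")
    if hits is None:
        hits = score_all_vs_all(
            {g.gene_id: g.protein for g in genes_a},
            {g.gene_id: g.protein for g in genes_b},
        )
    pairs = find_rbh(hits, chromosome_map, gene_index)

    status: dict[tuple[str, str], str] = {}
    report = FilterReport(method=config.method, parameters={
        "sigma_k": config.sigma_k, "tukey_i": config.tukey_i,
        "fence": config.fence, "ks_before_slope": config.ks_before_slope,
        "min_block_size": config.min_block_size, "max_gap": config.max_gap,
    })
    report.n_rbh = len(pairs)

    same = [p for p in pairs if p.same_chrom_pair]
    for p in pairs:
        if not p.same_chrom_pair:
            status[(p.gene_a, p.gene_b)] = "rejected_cross_chrom"
    report.n_same_chrom = len(same)

    anchors = make_anchors(same, gene_index)
    blocks, leftovers = chain_by_chromosome(
        anchors, gene_index, chromosome_map,
        config.min_block_size, config.max_gap,
    )
    for a in leftovers:
        status[(a.gene_a, a.gene_b)] = "rejected_non_colinear"
    colinear = [a for b in blocks for a in b.anchors]
    report.n_colinear = len(colinear)

    # stage 4: divergence; saturated pairs cannot pass a Ks filter
    divergence: dict[tuple[str, str], object] = {}
    for p in pairs:
        key = (p.gene_a, p.gene_b)
        ga, gb = gene_index[p.gene_a], gene_index[p.gene_b]
        if ga.cds and gb.cds:
            divergence[key] = estimate_pair(ga.cds, gb.cds, ga.protein or None,
                                            gb.protein or None)
    alive: list[Anchor] = []
    for a in colinear:
        est = divergence.get((a.gene_a, a.gene_b))
        if est is not None and (est.saturated or "too_short" in est.flags):
            status[(a.gene_a, a.gene_b)] = "rejected_saturated"
            report.n_saturated_removed += 1
        else:
            alive.append(a)

    def ks_layer(candidates: list[Anchor]) -> list[Anchor]:
        ks_vals = np.array([
            divergence[(a.gene_a, a.gene_b)].ks
            if (a.gene_a, a.gene_b) in divergence else np.nan
            for a in candidates
        ], dtype=float)
        if np.isfinite(ks_vals).sum() < config.min_mask_n:
            log.warning("too few Ks values for the %s mask; skipping", config.method)
            return candidates
        outlier = config.mask(ks_vals)
        survivors = []
        for a, o in zip(candidates, outlier):
            if o:
                status[(a.gene_a, a.gene_b)] = "rejected_ks_outlier"
                report.n_ks_removed += 1
            else:
                survivors.append(a)
        return survivors

    def slope_layer(candidates: list[Anchor]) -> list[Anchor]:
        if not config.apply_slope_filter:
            return candidates
        _, removed = slope_filter(blocks, config)
        removed_keys = {
            (a.gene_a, a.gene_b) for b in removed for a in b.anchors
        }
        survivors = []
        for a in candidates:
            if (a.gene_a, a.gene_b) in removed_keys:
                status[(a.gene_a, a.gene_b)] = "rejected_slope"
                report.n_slope_removed += 1
            else:
                survivors.append(a)
        return survivors

    if config.ks_before_slope:
        alive = slope_layer(ks_layer(alive))
        report.n_after_ks = (report.n_colinear - report.n_saturated_removed
                             - report.n_ks_removed)
    else:
        alive = ks_layer(slope_layer(alive))
        report.n_after_ks = (report.n_colinear - report.n_saturated_removed
                             - report.n_slope_removed - report.n_ks_removed)

    for a in alive:
        status[(a.gene_a, a.gene_b)] = "allele"
    report.n_alleles = len(alive)

    block_of: dict[tuple[str, str], int] = {}
    for b in blocks:
        for a in b.anchors:
            block_of[(a.gene_a, a.gene_b)] = b.block_id

    rows = []
    for p in sorted(pairs, key=lambda p: (p.gene_a, p.gene_b)):
        key = (p.gene_a, p.gene_b)
        est = divergence.get(key)
        rows.append({
            "gene_a": p.gene_a,
            "gene_b": p.gene_b,
            "chrom_a": gene_index[p.gene_a].chromosome,
            "chrom_b": gene_index[p.gene_b].chromosome,
            "mid_a": gene_index[p.gene_a].midpoint,
            "mid_b": gene_index[p.gene_b].midpoint,
            "block_id": block_of.get(key, "none"),
            "ks": est.ks if est else np.nan,
            "ka": est.ka if est else np.nan,
            "ka_ks": est.ka_ks if est else np.nan,
            "status": status[key],
        })
    table = pd.DataFrame(rows, columns=[
        "gene_a", "gene_b", "chrom_a", "chrom_b", "mid_a", "mid_b",
        "block_id", "ks", "ka", "ka_ks", "status",
    ])

    anchor_rows = []
    for a in sorted(anchors, key=lambda a: (a.gene_a, a.gene_b)):
        key = (a.gene_a, a.gene_b)
        anchor_rows.append({
            "gene_a": a.gene_a, "gene_b": a.gene_b,
            "block_id": block_of.get(key, "none"),
            "rank_a": a.rank_a, "rank_b": a.rank_b,
            "mid_a": a.mid_a, "mid_b": a.mid_b,
        })
    anchor_df = pd.DataFrame(anchor_rows, columns=[
        "gene_a", "gene_b", "block_id", "rank_a", "rank_b", "mid_a", "mid_b",
    ])
    return FilterResult(table=table, report=report, blocks=blocks, anchors=anchor_df)
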