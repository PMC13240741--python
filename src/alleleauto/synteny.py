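"""Colinear block detection: chain RBH anchors per chromosome pair.

Anchors live in gene-order (rank) space rather than base pairs: for
true one-to-one allelic colinearity the regression slope of rank_b on
rank_a is then close to +1 (or -1 across an inversion) regardless of
gene density, which the downstream slope filter exploits.  Base-pair
midpoints are carried along for dot plots.

Blocks are maximal chains under a longest increasing/decreasing
subsequence dynamic program with a rank-gap constraint; the highest
scoring chain is extracted first, its anchors removed, and the scan
repeated (alleles are 1:1, so blocks never share anchors).  Inverted
blocks are kept — inversions between haplotypes are real; the slope
filter, not orientation, decides removal.
"""

from __future__ import annotations

import logging
from typing import Iterable, Sequence

import numpy as np

from .models import Anchor, ChromosomeMap, GeneModel, RBHPair, SyntenyBlock

log = logging.getLogger("alleleauto")

DEFAULT_MIN_BLOCK_SIZE = 5
DEFAULT_MAX_GAP = 25


def gene_ranks(genes: Iterable[GeneModel]) -> dict[str, int]:
    """Ordinal rank (1-based) of each gene's start on its chromosome."""
    by_chrom: dict[str, list[GeneModel]] = {}
    for g in genes:
        by_chrom.setdefault(g.chromosome, []).append(g)
    ranks: dict[str, int] = {}
    for chrom_genes in by_chrom.values():
        ordered = sorted(chrom_genes, key=lambda g: (g.start, g.gene_id))
        for i, g in enumerate(ordered, start=1):
            ranks[g.gene_id] = i
    return ranks


def make_anchors(
    pairs: Iterable[RBHPair],
    gene_index: dict[str, GeneModel],
) -> list[Anchor]:
    """Project same-chromosome-pair RBH pairs into rank space."""
    genes = list(gene_index.values())
    ranks = gene_ranks(genes)
    anchors = []
    for p in pairs:
        if not p.same_chrom_pair:
            continue
        ga, gb = gene_index[p.gene_a], gene_index[p.gene_b]
        anchors.append(
            Anchor(
                gene_a=p.gene_a, gene_b=p.gene_b,
                rank_a=ranks[p.gene_a], rank_b=ranks[p.gene_b],
                mid_a=ga.midpoint, mid_b=gb.midpoint,
            )
        )
    return anchors


def block_slope(anchors: Sequence[Anchor]) -> float:
    """OLS slope of rank_b regressed on rank_a over a block's anchors."""
    if len(anchors) < 2:
        raise ValueError("slope needs at least 2 anchors")
    x = np.array([a.rank_a for a in anchors], dtype=float)
    y = np.array([a.rank_b for a in anchors], dtype=float)
    xc = x - x.mean()
    denom = (xc ** 2).sum()
    if denom == 0:  # cannot happen: ranks are unique per chromosome
        raise ValueError("degenerate block: all rank_a equal")
    return float((xc * (y - y.mean())).sum() / denom)


def _best_chain(anchors: list[Anchor], direction: int, max_gap: int) -> list[int]:
    """Longest chain (anchor indices into the rank_a-sorted list) with
    steps 0 < d_a <= max_gap and 0 < direction*d_b <= max_gap."""
    n = len(anchors)
    best_len = [1] * n
    prev = [-1] * n
    for j in range(1, n):
        aj = anchors[j]
        for i in range(j - 1, -1, -1):
            ai = anchors[i]
            da = aj.rank_a - ai.rank_a
            if da > max_gap:
                break  # sorted by rank_a: gaps only grow
            if da <= 0:
                continue
            db = direction * (aj.rank_b - ai.rank_b)
            if 0 < db <= max_gap and best_len[i] + 1 > best_len[j]:
                best_len[j] = best_len[i] + 1
                prev[j] = i
    end = int(np.argmax(best_len))
    chain = []
    while end != -1:
        chain.append(end)
        end = prev[end]
    return chain[::-1]


def chain_anchors(
    anchors: Sequence[Anchor],
    chrom_a: str = "",
    chrom_b: str = "",
    min_block_size: int = DEFAULT_MIN_BLOCK_SIZE,
    max_gap: int = DEFAULT_MAX_GAP,
    _start_block_id: int = 1,
) -> tuple[list[SyntenyBlock], list[Anchor]]:
    """Partition one chromosome pair's anchors into colinear blocks.

    Returns (blocks, leftover anchors not in any block).  Input order
    does not matter; anchors are processed in rank_a order and the
    best forward or inverted chain is peeled off repeatedly until no
    chain reaches ``min_block_size``.
    """
    remaining = sorted(anchors, key=lambda a: (a.rank_a, a.rank_b))
    blocks: list[SyntenyBlock] = []
    block_id = _start_block_id
    while len(remaining) >= min_block_size:
        fwd = _best_chain(remaining, +1, max_gap)
        rev = _best_chain(remaining, -1, max_gap)
        chain, direction = (fwd, "forward") if len(fwd) >= len(rev) else (rev, "inverted")
        if len(chain) < min_block_size:
            break
        members = [remaining[i] for i in chain]
        blocks.append(
            SyntenyBlock(
                block_id=block_id, chrom_a=chrom_a, chrom_b=chrom_b,
                anchors=members, orientation=direction,
                slope=block_slope(members),
            )
        )
        block_id += 1
        chosen = set(chain)
        remaining = [a for i, a in enumerate(remaining) if i not in chosen]
    return blocks, remaining


def chain_by_chromosome(
    anchors: Sequence[Anchor],
    gene_index: dict[str, GeneModel],
    chromosome_map: ChromosomeMap,
    min_block_size: int = DEFAULT_MIN_BLOCK_SIZE,
    max_gap: int = DEFAULT_MAX_GAP,
) -> tuple[list[SyntenyBlock], list[Anchor]]:
    """Chain anchors grouped by corresponding chromosome pair."""
    grouped: dict[tuple[str, str], list[Anchor]] = {}
    for a in anchors:
        key = (gene_index[a.gene_a].chromosome, gene_index[a.gene_b].chromosome)
        grouped.setdefault(key, []).append(a)
    blocks: list[SyntenyBlock] = []
    leftovers: list[Anchor] = []
    next_id = 1
    for ca, cb in chromosome_map.pairs:
        group = grouped.get((ca, cb), [])
        if not group:
            continue
        got, rest = chain_anchors(
            group, ca, cb, min_block_size, max_gap, _start_block_id=next_id
        )
        next_id += len(got)
        blocks.extend(got)
        leftovers.extend(rest)
    return blocks, leftovers
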