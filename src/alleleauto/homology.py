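"""All-vs-all protein similarity survey and reciprocal-best-hit selection.

The builtin scorer makes the pipeline self-contained: candidate pairs
are prefiltered by shared k-mers and scored by pairwise protein
alignment (BLOSUM62, affine gaps, one best score per ordered pair).
Production users typically import a precomputed BLAST outfmt-6 table
instead.  RBH selection is genome-wide; chromosome correspondence only
flags cross-chromosome pairs, which downstream filtering rejects, so
they stay visible in reports.
"""

from __future__ import annotations

import logging
from typing import Iterable, Optional

from Bio import Align
from Bio.Align import substitution_matrices

from .models import ChromosomeMap, GeneModel, HitRecord, RBHPair

log = logging.getLogger("alleleauto")


def _local_aligner() -> Align.PairwiseAligner:
    aligner = Align.PairwiseAligner()
    aligner.substitution_matrix = substitution_matrices.load("BLOSUM62")
    aligner.mode = "local"
    aligner.open_gap_score = -11.0
    aligner.extend_gap_score = -1.0
    return aligner


def _kmer_set(seq: str, k: int) -> set[str]:
    return {seq[i : i + k] for i in range(len(seq) - k + 1)}


def score_all_vs_all(
    proteins_a: dict[str, str],
    proteins_b: dict[str, str],
    k: int = 6,
    min_shared_kmers: int = 1,
    prefilter: bool = True,
) -> list[HitRecord]:
    """Score cross-haplotype protein pairs sharing at least
    ``min_shared_kmers`` k-mers (or all pairs when ``prefilter`` is
    False) by local alignment.

    Every scored (a, b) is also emitted as (b, a) with the same score
    (the scoring scheme is symmetric).  Output order is deterministic.
    """
    if not proteins_a or not proteins_b:
        raise ValueError("empty protein set")
    aligner = _local_aligner()
    # invert the k-mer index over B for candidate lookup
    index: dict[str, set[str]] = {}
    if prefilter:
        for gid, seq in proteins_b.items():
            for kmer in _kmer_set(seq, k):
                index.setdefault(kmer, set()).add(gid)
    hits: list[HitRecord] = []
    for gid_a in sorted(proteins_a):
        seq_a = proteins_a[gid_a]
        if prefilter:
            counts: dict[str, int] = {}
            for kmer in _kmer_set(seq_a, k):
                for gid_b in index.get(kmer, ()):
                    counts[gid_b] = counts.get(gid_b, 0) + 1
            candidates = sorted(
                g for g, c in counts.items() if c >= min_shared_kmers
            )
        else:
            candidates = sorted(proteins_b)
        for gid_b in candidates:
            seq_b = proteins_b[gid_b]
            score = aligner.score(seq_a, seq_b)
            if score <= 0:
                continue
            length = min(len(seq_a), len(seq_b))
            ident = _identity_estimate(seq_a, seq_b)
            rec = HitRecord(
                query_id=gid_a, subject_id=gid_b, bit_score=float(score),
                identity_pct=ident, alignment_length=length, evalue=0.0,
            )
            hits.append(rec)
            hits.append(
                HitRecord(
                    query_id=gid_b, subject_id=gid_a, bit_score=float(score),
                    identity_pct=ident, alignment_length=length, evalue=0.0,
                )
            )
    return hits


def _identity_estimate(a: str, b: str) -> float:
    """Cheap ungapped identity over the shorter sequence (reporting only)."""
    n = min(len(a), len(b))
    if n == 0:
        return 0.0
    same = sum(1 for x, y in zip(a, b) if x == y)
    return 100.0 * same / n


def _best_hit(records: list[HitRecord]) -> Optional[HitRecord]:
    """Unique best hit by bit score; ties broken by longer alignment,
    then lower e-value, then lexicographically smaller subject id.
    A tie surviving all breakers means no best hit."""
    if not records:
        return None
    # one entry per subject (imported tables may repeat a pair)
    per_subject: dict[str, HitRecord] = {}
    for h in records:
        cur = per_subject.get(h.subject_id)
        if cur is None or (-h.bit_score, -h.alignment_length, h.evalue) < (
            -cur.bit_score, -cur.alignment_length, cur.evalue
        ):
            per_subject[h.subject_id] = h
    ranked = sorted(
        per_subject.values(),
        key=lambda h: (-h.bit_score, -h.alignment_length, h.evalue, h.subject_id),
    )
    top = ranked[0]
    if len(ranked) > 1:
        nxt = ranked[1]
        if (
            nxt.bit_score == top.bit_score
            and nxt.alignment_length == top.alignment_length
            and nxt.evalue == top.evalue
            and nxt.subject_id == top.subject_id
        ):
            return None
    return top


def find_rbh(
    hits: Iterable[HitRecord],
    chromosome_map: ChromosomeMap,
    gene_index: dict[str, GeneModel],
) -> list[RBHPair]:
    """Select reciprocal best hits between the two haplotypes.

    (a, b) is returned iff b is a's unique best hit by bit score and a
    is b's; pairs whose chromosomes are not a corresponding pair are
    flagged ``same_chrom_pair=False`` (rejected downstream, not here).
    Unknown gene ids in the hit table are an error.
    """
    by_query: dict[str, list[HitRecord]] = {}
    unknown: set[str] = set()
    for h in hits:
        for gid in (h.query_id, h.subject_id):
            if gid not in gene_index:
                unknown.add(gid)
        if unknown:
            continue
        qhap = gene_index[h.query_id].haplotype
        shap = gene_index[h.subject_id].haplotype
        if qhap == shap:
            continue  # within-haplotype hits are irrelevant for RBH
        by_query.setdefault(h.query_id, []).append(h)
    if unknown:
        raise ValueError(
            "hit table references unknown gene ids: " + ", ".join(sorted(unknown))
        )
    best: dict[str, str] = {}
    for gid, records in by_query.items():
        top = _best_hit(records)
        if top is not None:
            best[gid] = top.subject_id
    pairs: list[RBHPair] = []
    for gid_a in sorted(best):
        if gene_index[gid_a].haplotype != "A":
            continue
        gid_b = best[gid_a]
        if best.get(gid_b) != gid_a:
            continue
        score_ab = max(h.bit_score for h in by_query[gid_a] if h.subject_id == gid_b)
        score_ba = max(h.bit_score for h in by_query[gid_b] if h.subject_id == gid_a)
        same = chromosome_map.is_pair(
            gene_index[gid_a].chromosome, gene_index[gid_b].chromosome
        )
        pairs.append(RBHPair(gid_a, gid_b, score_ab, score_ba, same))
    return pairs
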