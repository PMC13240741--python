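"""Shared data model for the allele-identification pipeline.

Coordinates follow the GFF3 convention externally: 1-based, inclusive
on both ends.  Any half-open arithmetic is internal and never
serialized.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional

COMPLEMENT = str.maketrans("ACGTRYSWKMBDHVN", "TGCAYRSWMKVHDBN")


def revcomp(seq: str) -> str:
    return seq.translate(COMPLEMENT)[::-1]


@dataclass
class GeneModel:
    """One annotated protein-coding gene on one haplotype.

    ``cds`` is the spliced, strand-corrected coding sequence (length a
    multiple of 3 once an incomplete terminal codon is trimmed);
    ``protein`` its translation with any terminal stop dropped.
    """

    gene_id: str
    haplotype: str  # "A" or "B"
    chromosome: str
    start: int  # 1-based inclusive
    end: int    # 1-based inclusive
    strand: str  # "+" or "-"
    cds: str = ""
    protein: str = ""

    def __post_init__(self) -> None:
        if self.start > self.end:
            raise ValueError(
                f"gene {self.gene_id}: start {self.start} > end {self.end}"
            )
        if self.strand not in ("+", "-"):
            raise ValueError(f"gene {self.gene_id}: bad strand {self.strand!r}")

    @property
    def midpoint(self) -> float:
        return (self.start + self.end) / 2.0


@dataclass
class ChromosomeMap:
    """Ordered correspondence between haplotype-A and haplotype-B chromosomes."""

    pairs: list[tuple[str, str]]

    def __post_init__(self) -> None:
        seen_a: set[str] = set()
        seen_b: set[str] = set()
        for ca, cb in self.pairs:
            if not ca or not cb:
                raise ValueError("chromosome map entries must be non-empty")
            if ca in seen_a or cb in seen_b:
                raise ValueError(f"chromosome {ca!r}/{cb!r} listed more than once")
            seen_a.add(ca)
            seen_b.add(cb)

    def partner_of_a(self, chrom_a: str) -> Optional[str]:
        for ca, cb in self.pairs:
            if ca == chrom_a:
                return cb
        return None

    def is_pair(self, chrom_a: str, chrom_b: str) -> bool:
        return (chrom_a, chrom_b) in set(self.pairs)


@dataclass
class HitRecord:
    """One row of an all-vs-all similarity survey (BLAST outfmt-6 shape)."""

    query_id: str
    subject_id: str
    bit_score: float
    identity_pct: float = 100.0
    alignment_length: int = 1
    evalue: float = 0.0

    def __post_init__(self) -> None:
        if self.bit_score < 0:
            raise ValueError("bit_score must be >= 0")
        if not 0 <= self.identity_pct <= 100:
            raise ValueError("identity_pct must be in [0, 100]")
        if self.alignment_length <= 0:
            raise ValueError("alignment_length must be > 0")
        if self.evalue < 0:
            raise ValueError("evalue must be >= 0")


@dataclass
class RBHPair:
    """A reciprocal-best-hit gene pair across the two haplotypes."""

    gene_a: str
    gene_b: str
    score_ab: float
    score_ba: float
    same_chrom_pair: bool


@dataclass
class Anchor:
    """An RBH pair projected to gene-order space on its chromosomes."""

    gene_a: str
    gene_b: str
    rank_a: int
    rank_b: int
    mid_a: float
    mid_b: float


@dataclass
class SyntenyBlock:
    """A chained colinear run of anchors with an orientation and a slope."""

    block_id: int
    chrom_a: str
    chrom_b: str
    anchors: list[Anchor]
    orientation: str  # "forward" or "inverted"
    slope: float

    @property
    def n_anchors(self) -> int:
        return len(self.anchors)


@dataclass
class CodonAlignment:
    """Gap-free codon columns retained from an aligned CDS pair."""

    codons_a: list[str]
    codons_b: list[str]
    n_dropped: int = 0

    @property
    def n_codons(self) -> int:
        return len(self.codons_a)


@dataclass
class DivergenceEstimate:
    """NG86 Ka/Ks estimate with site counts and validity flags.

    ``ka``/``ks`` are ``None`` when the Jukes-Cantor correction is
    undefined (p-distance >= 3/4, flagged saturated) or the alignment
    is empty (``too_short``); ``ka_ks`` is defined only when both are
    defined and ks > 0.
    """

    ka: Optional[float]
    ks: Optional[float]
    ka_ks: Optional[float]
    s_sites: float
    n_sites: float
    sd: float
    nd: float
    flags: set[str] = field(default_factory=set)

    @property
    def saturated(self) -> bool:
        return "saturated_ks" in self.flags or "saturated_ka" in self.flags


@dataclass
class CountMatrix:
    """Raw gene x sample count matrix with gene lengths for TPM."""

    gene_ids: list[str]
    sample_ids: list[str]
    counts: "object"  # numpy (genes x samples) int array
    gene_lengths: "object"  # numpy (genes,) array, bp

    def __post_init__(self) -> None:
        import numpy as np

        self.counts = np.asarray(self.counts)
        self.gene_lengths = np.asarray(self.gene_lengths, dtype=float)
        if self.counts.shape != (len(self.gene_ids), len(self.sample_ids)):
            raise ValueError("count matrix dimensions inconsistent with labels")
        if (self.counts < 0).any():
            raise ValueError("negative counts")
        if len(self.gene_lengths) != len(self.gene_ids):
            raise ValueError("gene_lengths length mismatch")
        if (self.gene_lengths <= 0).any():
            raise ValueError("gene lengths must be > 0")


@dataclass
class SampleDesign:
    """sample -> condition assignment with a replicate floor per condition."""

    assignments: dict[str, str]

    def samples_for(self, condition: str) -> list[str]:
        return [s for s, c in self.assignments.items() if c == condition]

    @property
    def conditions(self) -> list[str]:
        out: list[str] = []
        for c in self.assignments.values():
            if c not in out:
                out.append(c)
        return out

    def replicate_counts(self) -> dict[str, int]:
        return {c: len(self.samples_for(c)) for c in self.conditions}
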