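"""Codon alignment and Nei-Gojobori (NG86) Ka/Ks estimation.

The estimator counts synonymous (S) and non-synonymous (N) sites per
codon as the fraction of possible single-base changes that preserve
the amino acid, with changes to stop codons excluded from the
denominator; observed synonymous/non-synonymous differences (Sd, Nd)
are averaged with equal weight over all minimal substitution pathways
between differing codons, excluding pathways that pass through a stop
codon.  Proportions are corrected for multiple hits with the
Jukes-Cantor formula d = -(3/4) ln(1 - 4p/3); p >= 3/4 is flagged as
saturated and left undefined rather than extrapolated.
"""

from __future__ import annotations

import math
from functools import lru_cache
from itertools import permutations
from typing import Optional

from Bio import Align
from Bio.Align import substitution_matrices
from Bio.Data import CodonTable

from .models import CodonAlignment, DivergenceEstimate

BASES = "ACGT"


@lru_cache(maxsize=None)
def genetic_code(table_id: int = 1) -> dict[str, str]:
    """Codon -> amino acid mapping with stops encoded as '*'."""
    table = CodonTable.unambiguous_dna_by_id[table_id]
    code = dict(table.forward_table)
    for stop in table.stop_codons:
        code[stop] = "*"
    return code


def translate(cds: str, table_id: int = 1) -> str:
    code = genetic_code(table_id)
    return "".join(code.get(cds[i : i + 3], "X") for i in range(0, len(cds) - 2, 3))


@lru_cache(maxsize=None)
def _syn_site_fractions(codon: str, table_id: int = 1) -> tuple[float, float]:
    """(synonymous, non-synonymous) site counts for one sense codon.

    Per position: among the three single-base changes, those creating
    stop codons are removed from the denominator; the synonymous
    fraction of the remainder is that position's synonymous site
    weight.
    """
    code = genetic_code(table_id)
    aa = code[codon]
    s_total = 0.0
    for pos in range(3):
        syn = 0
        valid = 0
        for base in BASES:
            if base == codon[pos]:
                continue
            mutant = codon[:pos] + base + codon[pos + 1 :]
            if code[mutant] == "*":
                continue
            valid += 1
            if code[mutant] == aa:
                syn += 1
        s_total += syn / valid if valid else 0.0
    return s_total, 3.0 - s_total


def _classify_step(c_from: str, c_to: str, table_id: int) -> bool:
    """True if the single-base step c_from -> c_to is synonymous."""
    code = genetic_code(table_id)
    return code[c_from] == code[c_to]


@lru_cache(maxsize=None)
def _pathway_counts(codon_a: str, codon_b: str, table_id: int = 1) -> tuple[float, float]:
    """Average (synonymous, non-synonymous) difference counts between two
    sense codons over all minimal substitution pathways.

    Pathways passing through a stop codon are excluded.  If every
    pathway is blocked, each differing position is scored from the
    single-base change in both codon contexts (stop-producing variants
    skipped; positions with no valid variant contribute nothing) — a
    symmetric fallback for a vanishingly rare case.
    """
    code = genetic_code(table_id)
    diff = [i for i in range(3) if codon_a[i] != codon_b[i]]
    if not diff:
        return 0.0, 0.0
    syn_sum = nsyn_sum = 0.0
    n_valid = 0
    for order in permutations(diff):
        current = codon_a
        syn = nsyn = 0
        blocked = False
        for pos in order:
            nxt = current[:pos] + codon_b[pos] + current[pos + 1 :]
            if code[nxt] == "*":
                blocked = True
                break
            if _classify_step(current, nxt, table_id):
                syn += 1
            else:
                nsyn += 1
            current = nxt
        if not blocked:
            syn_sum += syn
            nsyn_sum += nsyn
            n_valid += 1
    if n_valid:
        return syn_sum / n_valid, nsyn_sum / n_valid
    # all pathways blocked: score positions independently and symmetrically
    syn_sum = nsyn_sum = 0.0
    for pos in diff:
        entries = []
        for ctx, other in ((codon_a, codon_b), (codon_b, codon_a)):
            variant = ctx[:pos] + other[pos] + ctx[pos + 1 :]
            if code[variant] != "*":
                entries.append(1.0 if code[variant] == code[ctx] else 0.0)
        if entries:
            frac_syn = sum(entries) / len(entries)
            syn_sum += frac_syn
            nsyn_sum += 1.0 - frac_syn
    return syn_sum, nsyn_sum


def jukes_cantor(p: float) -> Optional[float]:
    """JC69 multiple-hit correction; None when undefined (p >= 3/4)."""
    if p >= 0.75:
        return None
    return -0.75 * math.log(1.0 - 4.0 * p / 3.0) + 0.0


def ng86(alignment: CodonAlignment, table_id: int = 1) -> DivergenceEstimate:
    """Estimate Ka, Ks and Ka/Ks for a codon alignment by NG86."""
    if alignment.n_codons == 0:
        return DivergenceEstimate(
            ka=None, ks=None, ka_ks=None, s_sites=0.0, n_sites=0.0,
            sd=0.0, nd=0.0, flags={"too_short"},
        )
    s_a = s_b = 0.0
    sd = nd = 0.0
    for ca, cb in zip(alignment.codons_a, alignment.codons_b):
        sa, _ = _syn_site_fractions(ca, table_id)
        sb, _ = _syn_site_fractions(cb, table_id)
        s_a += sa
        s_b += sb
        dsyn, dnsyn = _pathway_counts(ca, cb, table_id)
        sd += dsyn
        nd += dnsyn
    s_sites = (s_a + s_b) / 2.0
    n_sites = 3.0 * alignment.n_codons - s_sites
    flags: set[str] = set()
    ps = sd / s_sites if s_sites > 0 else 0.0
    pn = nd / n_sites if n_sites > 0 else 0.0
    ks = jukes_cantor(ps)
    ka = jukes_cantor(pn)
    if ks is None:
        flags.add("saturated_ks")
    if ka is None:
        flags.add("saturated_ka")
    ka_ks = None
    if ka is not None and ks is not None and ks > 0:
        ka_ks = ka / ks
    return DivergenceEstimate(
        ka=ka, ks=ks, ka_ks=ka_ks, s_sites=s_sites, n_sites=n_sites,
        sd=sd, nd=nd, flags=flags,
    )


def _protein_aligner() -> Align.PairwiseAligner:
    aligner = Align.PairwiseAligner()
    aligner.substitution_matrix = substitution_matrices.load("BLOSUM62")
    aligner.mode = "global"
    aligner.open_gap_score = -10.0
    aligner.extend_gap_score = -0.5
    return aligner


def align_codons(
    cds_a: str,
    cds_b: str,
    protein_a: Optional[str] = None,
    protein_b: Optional[str] = None,
    table_id: int = 1,
) -> CodonAlignment:
    """Codon-align two coding sequences via a global protein alignment.

    The proteins (supplied, or translated from the CDS) are aligned
    with BLOSUM62 and affine gaps, and the alignment is back-translated
    to codons.  Columns containing a gap, an ambiguous base, or a stop
    codon in either sequence are dropped and counted.
    """
    for cds, prot, name in ((cds_a, protein_a, "a"), (cds_b, protein_b, "b")):
        if len(cds) % 3:
            raise ValueError(f"cds_{name} length {len(cds)} is not a multiple of 3")
        if prot is not None:
            trans = translate(cds, table_id).rstrip("*")
            if trans != prot.rstrip("*"):
                raise ValueError(f"cds_{name} does not translate to protein_{name}")
    prot_a = (protein_a or translate(cds_a, table_id)).rstrip("*")
    prot_b = (protein_b or translate(cds_b, table_id)).rstrip("*")
    codons_of = lambda cds: [cds[i : i + 3] for i in range(0, len(cds), 3)]
    cod_a, cod_b = codons_of(cds_a), codons_of(cds_b)

    aligner = _protein_aligner()
    aln = aligner.align(prot_a, prot_b)[0]
    code = genetic_code(table_id)
    keep_a: list[str] = []
    keep_b: list[str] = []
    dropped = 0
    ia = ib = 0
    for col_a, col_b in zip(str(aln[0]), str(aln[1])):
        if col_a == "-" and col_b == "-":  # pragma: no cover - aligner never emits
            continue
        if col_a == "-":
            ib += 1
            dropped += 1
            continue
        if col_b == "-":
            ia += 1
            dropped += 1
            continue
        ca, cb = cod_a[ia], cod_b[ib]
        ia += 1
        ib += 1
        ok = (
            all(b in BASES for b in ca + cb)
            and code.get(ca, "*") != "*"
            and code.get(cb, "*") != "*"
        )
        if ok:
            keep_a.append(ca)
            keep_b.append(cb)
        else:
            dropped += 1
    # trailing stop codons (dropped from the protein) are not columns at all
    return CodonAlignment(codons_a=keep_a, codons_b=keep_b, n_dropped=dropped)


def estimate_pair(
    cds_a: str, cds_b: str,
    protein_a: Optional[str] = None, protein_b: Optional[str] = None,
    table_id: int = 1,
) -> DivergenceEstimate:
    """Convenience wrapper: codon-align then NG86."""
    return ng86(align_codons(cds_a, cds_b, protein_a, protein_b, table_id), table_id)
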