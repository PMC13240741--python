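"""Independent brute-force oracles used to check the package's core
numerics.  Deliberately written from first principles, sharing no code
with the implementation under test."""

from __future__ import annotations

import numpy as np

# standard genetic code, written out by hand (independent of the
# package's Bio.Data-derived table)
_AA = (
    "FFLLSSSSYY**CC*WLLLLPPPPHHQQRRRRIIIMTTTTNNKKSSRRVVVVAAAADDEEGGGG"
)
_BASES = "TCAG"
CODE = {
    a + b + c: _AA[16 * i + 4 * j + k]
    for i, a in enumerate(_BASES)
    for j, b in enumerate(_BASES)
    for k, c in enumerate(_BASES)
}
SENSE = sorted(c for c, aa in CODE.items() if aa != "*")


def oracle_sites(codon: str) -> float:
    """Synonymous site count of one codon by explicit enumeration."""
    total = 0.0
    for pos in range(3):
        syn = 0
        non_stop = 0
        for base in "ACGT":
            if base == codon[pos]:
                continue
            mut = codon[:pos] + base + codon[pos + 1 :]
            if CODE[mut] == "*":
                continue
            non_stop += 1
            if CODE[mut] == CODE[codon]:
                syn += 1
        if non_stop:
            total += syn / non_stop
    return total


def _enumerate_paths(cur: str, target: str):
    """Yield (syn_steps, nonsyn_steps) for every stop-free minimal
    pathway from cur to target, by depth-first recursion."""
    diff = [i for i in range(3) if cur[i] != target[i]]
    if not diff:
        yield (0, 0)
        return
    for pos in diff:
        nxt = cur[:pos] + target[pos] + cur[pos + 1 :]
        if CODE[nxt] == "*":
            continue
        step_syn = 1 if CODE[nxt] == CODE[cur] else 0
        for syn, nonsyn in _enumerate_paths(nxt, target):
            yield (step_syn + syn, (1 - step_syn) + nonsyn)


def oracle_differences(codon_a: str, codon_b: str) -> tuple[float, float]:
    """Mean (synonymous, non-synonymous) difference counts over all
    stop-free minimal pathways; symmetric positional fallback when
    every pathway is blocked."""
    paths = list(_enumerate_paths(codon_a, codon_b))
    if paths:
        syn = sum(p[0] for p in paths) / len(paths)
        nonsyn = sum(p[1] for p in paths) / len(paths)
        return syn, nonsyn
    syn = nonsyn = 0.0
    for pos in range(3):
        if codon_a[pos] == codon_b[pos]:
            continue
        entries = []
        for src, dst in ((codon_a, codon_b), (codon_b, codon_a)):
            var = src[:pos] + dst[pos] + src[pos + 1 :]
            if CODE[var] != "*":
                entries.append(1.0 if CODE[var] == CODE[src] else 0.0)
        if entries:
            f = sum(entries) / len(entries)
            syn += f
            nonsyn += 1.0 - f
    return syn, nonsyn


def oracle_ng86(codons_a: list[str], codons_b: list[str]):
    """(ka, ks) for a codon alignment; None where the Jukes-Cantor
    correction is undefined (p >= 3/4)."""
    s = sum(oracle_sites(a) + oracle_sites(b) for a, b in zip(codons_a, codons_b)) / 2.0
    n = 3.0 * len(codons_a) - s
    sd = nd = 0.0
    for a, b in zip(codons_a, codons_b):
        ds, dn = oracle_differences(a, b)
        sd += ds
        nd += dn
    def jc(p):
        if p >= 0.75:
            return None
        return -0.75 * np.log(1.0 - 4.0 * p / 3.0)
    ks = jc(sd / s) if s > 0 else jc(0.0)
    ka = jc(nd / n) if n > 0 else jc(0.0)
    return ka, ks


def oracle_rbh(scores: dict[tuple[str, str], tuple[float, int, float]]):
    """Exhaustive mutual-argmax RBH with the documented tie-breaks.

    ``scores[(q, s)] = (bit_score, alignment_length, evalue)`` over
    ordered cross-haplotype pairs.  Returns the set of (a, b) pairs.
    """
    def best(query, direction):
        cands = [
            (s if direction == "ab" else q, v)
            for (q, s), v in scores.items()
            if (q if direction == "ab" else s) == query
        ]
        if not cands:
            return None
        ranked = sorted(
            cands, key=lambda t: (-t[1][0], -t[1][1], t[1][2], t[0])
        )
        if len(ranked) > 1 and ranked[0][1] == ranked[1][1] \
                and ranked[0][0] == ranked[1][0]:
            return None
        # an exact tie on every criterion incl. id cannot happen for
        # distinct subjects; a tie on score/len/evalue resolves by id
        return ranked[0][0]

    a_ids = sorted({q for q, _ in scores})
    out = set()
    for a in a_ids:
        b = best(a, "ab")
        if b is not None and best(b, "ba") == a:
            out.add((a, b))
    return out


def oracle_chains(
    ranks: list[tuple[int, int]], min_block_size: int, max_gap: int
) -> int:
    """Length of the best single chain by exhaustive subset search
    (exponential; keep inputs tiny)."""
    n = len(ranks)
    best = 0
    order = sorted(range(n), key=lambda i: ranks[i][0])
    for mask in range(1 << n):
        subset = [i for i in order if mask >> i & 1]
        if len(subset) <= best:
            continue
        for sign in (+1, -1):
            ok = True
            for u, v in zip(subset, subset[1:]):
                da = ranks[v][0] - ranks[u][0]
                db = sign * (ranks[v][1] - ranks[u][1])
                if not (0 < da <= max_gap and 0 < db <= max_gap):
                    ok = False
                    break
            if ok:
                best = len(subset)
                break
    return best if best >= min_block_size else 0
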