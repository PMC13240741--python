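"""Truth-labelled synthetic diploid generator.

Emulates the statistical structure the allele filters assume: each
haplotype-A gene has a haplotype-B allele whose synonymous divergence
is drawn from a tight, near-normal distribution (heterozygosity-scale
Ks), while paralog decoys — heavily mutated duplicates of haplotype-A
donors inserted at random positions on haplotype B in place of the
donor's true allele — carry whole-genome-duplication-scale Ks and sit
off the diagonal.  Because the true allele is *replaced*, the
reciprocal-best-hit step genuinely mis-pairs the donor with its decoy,
reproducing the failure mode the statistical filters exist to remove.

The mutation process is codon-aware: synonymous and non-synonymous
single-base changes are placed at distinct codon positions at rates
inverted from the Jukes-Cantor-corrected targets, so realized NG86
estimates track the requested Ka and Ks and proteins stay alignable
even at paralog-level divergence.  Genes are single-exon and
transcript-unique; the pipeline consumes spliced CDS, so introns add
nothing here.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Optional

import numpy as np
import pandas as pd

from . import io as aio
from .divergence import genetic_code, translate, _syn_site_fractions
from .models import ChromosomeMap, CountMatrix, GeneModel, SampleDesign

SENSE_CODONS = tuple(sorted(
    c for c, aa in genetic_code(1).items() if aa != "*"
))


@dataclass
class ExpressionConfig:
    """Negative-binomial expression layer of the simulator.

    ``fraction_ase`` of allelic pairs get their haplotype-A mean
    multiplied by 2**l2fc with |l2fc| = ``ase_log2fc`` and random
    sign; ``fraction_silent`` pairs are silenced on both alleles.
    """

    n_conditions: int = 1
    reps_per_condition: int = 3
    base_mean: float = 100.0
    base_mean_log_sd: float = 0.0
    dispersion: float = 0.1
    fraction_ase: float = 0.2
    ase_log2fc: float = 4.0
    fraction_silent: float = 0.0


@dataclass
class SimConfig:
    """Genome layer of the simulator.

    Defaults describe a compact diploid with heterozygosity-scale
    allelic divergence (Ks ~ N(0.03, 0.01^2)), one hundred
    WGD-scale paralog decoys (Ks uniform in [0.3, 1.0]) and a single
    50-gene inversion between the haplotypes.
    """

    n_chrom_pairs: int = 2
    genes_per_chrom: int = 1000
    allelic_ks_mean: float = 0.03
    allelic_ks_sd: float = 0.01
    allelic_ka_ks: float = 0.3
    n_paralogs: int = 100
    paralog_ks_range: tuple[float, float] = (0.3, 1.0)
    paralog_ka_ks: float = 0.3
    n_inversions: int = 1
    inversion_length: int = 50
    min_codons: int = 250
    max_codons: int = 550
    intergenic_mean: int = 1000
    rng_seed: int = 0
    expression: ExpressionConfig = field(default_factory=ExpressionConfig)

    def __post_init__(self) -> None:
        if self.n_paralogs > self.n_chrom_pairs * self.genes_per_chrom:
            raise ValueError("more paralogs than genes")
        if self.rng_seed is None:
            raise ValueError("a seed is mandatory for reproducibility")


@dataclass
class SimulatedDiploid:
    genes_a: list[GeneModel]
    genes_b: list[GeneModel]
    chromosome_map: ChromosomeMap
    truth: pd.DataFrame  # gene_a, gene_b, label in {allelic, paralog}

    def write(self, outdir: str | Path) -> None:
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        for hap, genes in (("A", self.genes_a), ("B", self.genes_b)):
            aio.write_fasta({g.gene_id: g.cds for g in genes}, outdir / f"hap{hap}.cds.fasta")
            aio.write_fasta({g.gene_id: g.protein for g in genes}, outdir / f"hap{hap}.prot.fasta")
            aio.write_gff3(genes, outdir / f"hap{hap}.gff3")
        aio.write_chromosome_map(self.chromosome_map, outdir / "chrom_map.tsv")
        aio.write_tsv(self.truth, outdir / "truth.tsv")

    def gene_lengths(self) -> pd.Series:
        return pd.Series({
            g.gene_id: float(len(g.cds))
            for g in self.genes_a + self.genes_b
        })


def _p_from_d(d: float) -> float:
    """Invert the Jukes-Cantor correction: expected proportion of
    differing sites for divergence d (capped below saturation)."""
    return min(0.74, 0.75 * (1.0 - math.exp(-4.0 * d / 3.0)))


def _random_cds(rng: np.random.Generator, n_codons: int) -> str:
    idx = rng.integers(0, len(SENSE_CODONS), size=n_codons)
    return "".join(SENSE_CODONS[i] for i in idx)


def _mutation_options(codon: str) -> tuple[list[tuple[int, str]], list[tuple[int, str]]]:
    """(synonymous, non-synonymous) single-base options as
    (position, mutant codon) lists, stops excluded."""
    code = genetic_code(1)
    aa = code[codon]
    syn, nsyn = [], []
    for pos in range(3):
        for base in "ACGT":
            if base == codon[pos]:
                continue
            mut = codon[:pos] + base + codon[pos + 1:]
            if code[mut] == "*":
                continue
            (syn if code[mut] == aa else nsyn).append((pos, mut))
    return syn, nsyn


def mutate_cds(
    cds: str, target_ks: float, target_ka: float, rng: np.random.Generator
) -> str:
    """Derive a diverged copy of ``cds`` with NG86 divergence close to
    the targets.

    Synonymous (non-synonymous) substitutions are placed independently
    at codon positions offering such a change, at per-position rates
    chosen so the expected NG86 proportions match the Jukes-Cantor
    inversion of the targets; at most one substitution per codon
    position.
    """
    codons = [cds[i:i + 3] for i in range(0, len(cds), 3)]
    s_sites = sum(_syn_site_fractions(c)[0] for c in codons)
    n_sites = 3 * len(codons) - s_sites
    options = [_mutation_options(c) for c in codons]
    n_syn_pos = sum(len({p for p, _ in syn}) for syn, _ in options)
    n_nsyn_pos = sum(len({p for p, _ in nsyn}) for _, nsyn in options)
    q_syn = min(1.0, _p_from_d(target_ks) * s_sites / max(n_syn_pos, 1))
    q_nsyn = min(1.0, _p_from_d(target_ka) * n_sites / max(n_nsyn_pos, 1))
    out = []
    for codon, (syn, nsyn) in zip(codons, options):
        mutated_positions: set[int] = set()
        current = codon
        for opts, q in ((syn, q_syn), (nsyn, q_nsyn)):
            positions = sorted({p for p, _ in opts})
            for pos in positions:
                if pos in mutated_positions or rng.random() >= q:
                    continue
                choices = [m for p, m in opts if p == pos]
                mut = choices[rng.integers(0, len(choices))]
                # re-apply in the current context, skipping clashes that
                # would create a stop after earlier edits to this codon
                cand = current[:pos] + mut[pos] + current[pos + 1:]
                if genetic_code(1)[cand] == "*":
                    continue
                current = cand
                mutated_positions.add(pos)
        out.append(current)
    return "".join(out)


def simulate_diploid(config: Optional[SimConfig] = None, **overrides) -> SimulatedDiploid:
    """Generate a truth-labelled diploid gene complement.

    Haplotype B derives from A codon-wise; ``n_paralogs`` decoys
    replace their donors' true alleles and land at random positions;
    ``n_inversions`` contiguous runs of B genes are reversed.  Output
    is bit-reproducible for a given ``rng_seed``.
    """
    if config is None:
        config = SimConfig(**overrides)
    elif overrides:
        config = replace(config, **overrides)
    rng = np.random.default_rng(config.rng_seed)
    cmap = ChromosomeMap([
        (f"chrA{c + 1:02d}", f"chrB{c + 1:02d}") for c in range(config.n_chrom_pairs)
    ])

    genes_a: list[GeneModel] = []
    per_chrom_b: dict[str, list[tuple[str, str, str]]] = {}  # id, cds, strand
    allelic_pairs: list[tuple[str, str]] = []
    donors: list[tuple[int, str, str]] = []  # flat index, a_id, ancestor cds

    flat = 0
    for c, (chrom_a, chrom_b) in enumerate(cmap.pairs):
        per_chrom_b[chrom_b] = []
        for i in range(config.genes_per_chrom):
            n_codons = int(rng.integers(config.min_codons, config.max_codons + 1))
            ancestor = _random_cds(rng, n_codons)
            a_id = f"gA{c + 1:02d}_{i + 1:05d}"
            b_id = f"gB{c + 1:02d}_{i + 1:05d}"
            ks = max(1e-4, rng.normal(config.allelic_ks_mean, config.allelic_ks_sd))
            ka = ks * config.allelic_ka_ks
            cds_b = mutate_cds(ancestor, ks, ka, rng)
            genes_a.append(GeneModel(a_id, "A", chrom_a, 1, 3, "+", cds=ancestor))
            per_chrom_b[chrom_b].append((b_id, cds_b, "+"))
            allelic_pairs.append((a_id, b_id))
            donors.append((flat, a_id, ancestor))
            flat += 1

    # paralog decoys: mutate a donor heavily, delete its true allele,
    # insert the copy at a random spot on a random B chromosome
    truth_rows = []
    donor_idx = rng.choice(flat, size=config.n_paralogs, replace=False)
    deleted: set[str] = set()
    paralogs: list[tuple[str, str, str]] = []
    for j, di in enumerate(sorted(int(x) for x in donor_idx)):
        _, a_id, ancestor = donors[di]
        ks = rng.uniform(*config.paralog_ks_range)
        cds_p = mutate_cds(ancestor, ks, ks * config.paralog_ka_ks, rng)
        p_id = f"pB_{j + 1:04d}"
        b_id = allelic_pairs[di][1]
        deleted.add(b_id)
        paralogs.append((a_id, p_id, cds_p))
        truth_rows.append({"gene_a": a_id, "gene_b": p_id, "label": "paralog"})
    for a_id, b_id in allelic_pairs:
        if b_id not in deleted:
            truth_rows.append({"gene_a": a_id, "gene_b": b_id, "label": "allelic"})

    for chrom_b in per_chrom_b:
        per_chrom_b[chrom_b] = [
            entry for entry in per_chrom_b[chrom_b] if entry[0] not in deleted
        ]
    chroms_b = list(per_chrom_b)
    for a_id, p_id, cds_p in paralogs:
        target = chroms_b[rng.integers(0, len(chroms_b))]
        pos = int(rng.integers(0, len(per_chrom_b[target]) + 1))
        per_chrom_b[target].insert(pos, (p_id, cds_p, "+"))

    # inversions: reverse contiguous runs of B genes (strands flip)
    for _ in range(config.n_inversions):
        chrom = chroms_b[rng.integers(0, len(chroms_b))]
        entries = per_chrom_b[chrom]
        length = min(config.inversion_length, len(entries))
        if length < 2:
            continue
        start = int(rng.integers(0, len(entries) - length + 1))
        run = entries[start:start + length]
        flipped = [(gid, cds, "-" if strand == "+" else "+")
                   for gid, cds, strand in reversed(run)]
        per_chrom_b[chrom][start:start + length] = flipped

    # lay out coordinates and build gene models
    def layout_a(genes: list[GeneModel]) -> list[GeneModel]:
        out = []
        pos: dict[str, int] = {}
        for g in genes:
            start = pos.get(g.chromosome, 1)
            end = start + len(g.cds) - 1
            gap = int(rng.integers(200, 2 * config.intergenic_mean))
            pos[g.chromosome] = end + gap
            out.append(GeneModel(
                g.gene_id, "A", g.chromosome, start, end, g.strand,
                cds=g.cds, protein=translate(g.cds).rstrip("*"),
            ))
        return out

    genes_a = layout_a(genes_a)
    genes_b: list[GeneModel] = []
    for chrom_b, entries in per_chrom_b.items():
        start = 1
        for gid, cds, strand in entries:
            end = start + len(cds) - 1
            genes_b.append(GeneModel(
                gid, "B", chrom_b, start, end, strand,
                cds=cds, protein=translate(cds).rstrip("*"),
            ))
            start = end + int(rng.integers(200, 2 * config.intergenic_mean))

    truth = pd.DataFrame(truth_rows, columns=["gene_a", "gene_b", "label"])
    truth = truth.sort_values(["gene_a", "gene_b"]).reset_index(drop=True)
    return SimulatedDiploid(genes_a, genes_b, cmap, truth)


def simulate_counts(
    sim: SimulatedDiploid,
    config: Optional[ExpressionConfig] = None,
    seed: int = 0,
) -> tuple[CountMatrix, SampleDesign, pd.DataFrame]:
    """Negative-binomial count matrix over all simulated genes.

    Allelic pairs share a base mean; a ``fraction_ase`` of them get
    the A allele scaled by 2**(+/- ase_log2fc) (effect shared across
    conditions).  Returns (counts, design, per-pair expression truth).
    """
    config = config or sim_expression_default()
    rng = np.random.default_rng(seed)
    pairs = sim.truth[sim.truth["label"] == "allelic"].reset_index(drop=True)
    lengths = sim.gene_lengths()
    gene_ids = list(lengths.index)
    mean_of = {g: 0.0 for g in gene_ids}

    expr_rows = []
    for _, row in pairs.iterrows():
        base = config.base_mean
        if config.base_mean_log_sd > 0:
            base *= math.exp(rng.normal(0.0, config.base_mean_log_sd))
        silent = rng.random() < config.fraction_silent
        is_ase = (not silent) and rng.random() < config.fraction_ase
        l2fc = 0.0
        if is_ase:
            l2fc = config.ase_log2fc * (1 if rng.random() < 0.5 else -1)
        mean_a = 0.0 if silent else base * 2.0 ** l2fc
        mean_b = 0.0 if silent else base
        mean_of[row["gene_a"]] = mean_a
        mean_of[row["gene_b"]] = mean_b
        expr_rows.append({
            "gene_a": row["gene_a"], "gene_b": row["gene_b"],
            "true_log2fc": l2fc, "is_ase": is_ase, "silent": silent,
        })

    samples, assignments = [], {}
    for c in range(config.n_conditions):
        cond = f"cond{c + 1}"
        for r in range(config.reps_per_condition):
            s = f"{cond}_rep{r + 1}"
            samples.append(s)
            assignments[s] = cond

    means = np.array([mean_of[g] for g in gene_ids], dtype=float)
    counts = np.zeros((len(gene_ids), len(samples)), dtype=int)
    r_param = 1.0 / config.dispersion
    for j in range(len(samples)):
        mu = means
        lam = np.where(mu > 0, mu, 0.0)
        with np.errstate(divide="ignore", invalid="ignore"):
            p = np.where(lam > 0, r_param / (r_param + lam), 1.0)
        counts[:, j] = rng.negative_binomial(r_param, p)
    cm = CountMatrix(
        gene_ids=gene_ids, sample_ids=samples,
        counts=counts, gene_lengths=lengths.values,
    )
    design = SampleDesign(assignments)
    return cm, design, pd.DataFrame(expr_rows)


def sim_expression_default() -> ExpressionConfig:
    return ExpressionConfig()


def write_counts(
    cm: CountMatrix, design: SampleDesign, outdir: str | Path
) -> None:
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    df = pd.DataFrame(cm.counts, index=cm.gene_ids, columns=cm.sample_ids)
    df.index.name = "gene_id"
    df.to_csv(outdir / "counts.tsv", sep="\t")
    pd.DataFrame({
        "gene_id": cm.gene_ids, "length": cm.gene_lengths,
    }).to_csv(outdir / "gene_lengths.tsv", sep="\t", index=False)
    pd.DataFrame({
        "sample": list(design.assignments),
        "condition": [design.assignments[s] for s in design.assignments],
    }).to_csv(outdir / "design.tsv", sep="\t", index=False)
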