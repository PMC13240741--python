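"""Readers and writers for the formats the pipeline touches.

GFF3, FASTA, BLAST outfmt-6 TSV, a two-column chromosome-correspondence
TSV, count-matrix TSV and a sample design TSV.  All output tables are
TSV with a header line, and all genomic coordinates are reported
1-based inclusive.
"""

from __future__ import annotations

import logging
from pathlib import Path
from typing import Iterable, Optional

import pandas as pd
from Bio import SeqIO

from .models import (
    ChromosomeMap,
    CountMatrix,
    GeneModel,
    HitRecord,
    SampleDesign,
    revcomp,
)

log = logging.getLogger("alleleauto")

GFF3_COLUMNS = 9


def _parse_attributes(field: str) -> dict[str, str]:
    attrs = {}
    for item in field.strip().split(";"):
        item = item.strip()
        if not item:
            continue
        if "=" not in item:
            continue
        key, _, value = item.partition("=")
        attrs[key] = value
    return attrs


def read_gff3(
    path: str | Path,
    feature_type: str = "gene",
    id_attribute: str = "ID",
    haplotype: str = "A",
) -> list[GeneModel]:
    """Read gene skeletons (no sequences) from a GFF3 file.

    One :class:`GeneModel` per ``feature_type`` feature, identified by
    ``id_attribute``.  Coordinates stay 1-based inclusive.  Malformed
    lines raise with their line number; duplicate IDs raise listing
    the duplicates.
    """
    genes: list[GeneModel] = []
    seen: dict[str, int] = {}
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            fields = line.split("\t")
            if len(fields) != GFF3_COLUMNS:
                raise ValueError(
                    f"{path}: line {lineno}: expected {GFF3_COLUMNS} tab-separated "
                    f"columns, got {len(fields)}"
                )
            chrom, _source, ftype, start_s, end_s, _score, strand, _phase, attr_s = fields
            if ftype != feature_type:
                continue
            try:
                start, end = int(start_s), int(end_s)
            except ValueError as exc:
                raise ValueError(f"{path}: line {lineno}: non-integer coordinate") from exc
            attrs = _parse_attributes(attr_s)
            if id_attribute not in attrs:
                raise ValueError(
                    f"{path}: line {lineno}: missing attribute {id_attribute!r}"
                )
            gene_id = attrs[id_attribute]
            if strand not in ("+", "-"):
                raise ValueError(f"{path}: line {lineno}: bad strand {strand!r}")
            try:
                gene = GeneModel(gene_id, haplotype, chrom, start, end, strand)
            except ValueError as exc:
                raise ValueError(f"{path}: line {lineno}: {exc}") from exc
            seen.setdefault(gene_id, 0)
            seen[gene_id] += 1
            genes.append(gene)
    dups = sorted(g for g, n in seen.items() if n > 1)
    if dups:
        raise ValueError(f"{path}: duplicate gene IDs: {', '.join(dups)}")
    return genes


def read_cds_segments(
    path: str | Path, id_attribute: str = "Parent"
) -> dict[str, list[tuple[str, int, int, str]]]:
    """Collect CDS feature segments grouped by their parent gene/mRNA id.

    Returns gene id -> list of (chrom, start, end, strand) in file order.
    """
    segments: dict[str, list[tuple[str, int, int, str]]] = {}
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            fields = line.split("\t")
            if len(fields) != GFF3_COLUMNS:
                raise ValueError(
                    f"{path}: line {lineno}: expected {GFF3_COLUMNS} columns"
                )
            if fields[2] != "CDS":
                continue
            attrs = _parse_attributes(fields[8])
            if id_attribute not in attrs:
                raise ValueError(
                    f"{path}: line {lineno}: CDS missing attribute {id_attribute!r}"
                )
            parent = attrs[id_attribute]
            segments.setdefault(parent, []).append(
                (fields[0], int(fields[3]), int(fields[4]), fields[6])
            )
    return segments


def splice_cds(
    segments: list[tuple[str, int, int, str]], chrom_seqs: dict[str, str]
) -> str:
    """Assemble a spliced, strand-corrected CDS from its exon segments.

    Exons are sorted by start coordinate, concatenated, and
    reverse-complemented for minus-strand genes.  A trailing incomplete
    codon is trimmed with a warning.
    """
    if not segments:
        raise ValueError("no CDS segments")
    strand = segments[0][3]
    ordered = sorted(segments, key=lambda seg: seg[1])
    parts = []
    for chrom, start, end, seg_strand in ordered:
        if seg_strand != strand:
            raise ValueError("mixed strands within one CDS")
        if chrom not in chrom_seqs:
            raise ValueError(f"chromosome {chrom!r} absent from sequence set")
        parts.append(chrom_seqs[chrom][start - 1 : end])
    cds = "".join(parts).upper()
    if strand == "-":
        cds = revcomp(cds)
    if len(cds) % 3:
        log.warning("trimming incomplete terminal codon (%d nt CDS)", len(cds))
        cds = cds[: len(cds) - len(cds) % 3]
    return cds


def read_fasta(path: str | Path) -> dict[str, str]:
    """Read a FASTA file to an id -> sequence mapping.

    Sequences are uppercased with whitespace removed; duplicate
    headers and empty files are errors.
    """
    seqs: dict[str, str] = {}
    for record in SeqIO.parse(str(path), "fasta"):
        if record.id in seqs:
            raise ValueError(f"{path}: duplicate FASTA id {record.id!r}")
        seqs[record.id] = str(record.seq).upper().replace(" ", "")
    if not seqs:
        raise ValueError(f"{path}: empty FASTA file")
    return seqs


def write_fasta(seqs: dict[str, str], path: str | Path, width: int = 60) -> None:
    with open(path, "w") as fh:
        for name, seq in seqs.items():
            fh.write(f">{name}\n")
            for i in range(0, len(seq), width):
                fh.write(seq[i : i + width] + "\n")


def read_hits(path: str | Path) -> list[HitRecord]:
    """Read an all-vs-all hit table in the 12-column BLAST outfmt-6 dialect.

    Column 3 is percent identity, column 4 alignment length, column 11
    the e-value and column 12 the bit score.
    """
    hits: list[HitRecord] = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            fields = line.split("\t")
            if len(fields) != 12:
                raise ValueError(
                    f"{path}: line {lineno}: expected 12 columns, got {len(fields)}"
                )
            try:
                hits.append(
                    HitRecord(
                        query_id=fields[0],
                        subject_id=fields[1],
                        identity_pct=float(fields[2]),
                        alignment_length=int(fields[3]),
                        evalue=float(fields[10]),
                        bit_score=float(fields[11]),
                    )
                )
            except ValueError as exc:
                raise ValueError(f"{path}: line {lineno}: {exc}") from exc
    return hits


def write_hits(hits: Iterable[HitRecord], path: str | Path) -> None:
    with open(path, "w") as fh:
        for h in hits:
            fh.write(
                "\t".join(
                    [
                        h.query_id,
                        h.subject_id,
                        f"{h.identity_pct:.2f}",
                        str(h.alignment_length),
                        "0", "0", "0", "0", "0", "0",
                        f"{h.evalue:.2g}",
                        f"{h.bit_score:.1f}",
                    ]
                )
                + "\n"
            )


def read_chromosome_map(path: str | Path) -> ChromosomeMap:
    """Read the two-column hapA <-> hapB chromosome correspondence TSV."""
    pairs: list[tuple[str, str]] = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            fields = line.split("\t")
            if len(fields) != 2:
                raise ValueError(f"{path}: line {lineno}: expected 2 columns")
            pairs.append((fields[0], fields[1]))
    return ChromosomeMap(pairs)


def write_chromosome_map(cmap: ChromosomeMap, path: str | Path) -> None:
    with open(path, "w") as fh:
        fh.write("#chrom_a\tchrom_b\n")
        for ca, cb in cmap.pairs:
            fh.write(f"{ca}\t{cb}\n")


def read_counts(
    counts_path: str | Path,
    lengths_path: Optional[str | Path] = None,
    default_length: float = 1000.0,
) -> CountMatrix:
    """Read a gene x sample raw count TSV (first column = gene id).

    ``lengths_path`` is a two-column TSV (gene id, length in bp) used
    for TPM; absent genes fall back to ``default_length`` with a
    warning.
    """
    df = pd.read_csv(counts_path, sep="\t", index_col=0)
    if (df.values < 0).any():
        raise ValueError(f"{counts_path}: negative counts")
    lengths = pd.Series(default_length, index=df.index)
    if lengths_path is not None:
        ldf = pd.read_csv(
            lengths_path, sep="\t", index_col=0, header=0
        ).iloc[:, 0]
        missing = df.index.difference(ldf.index)
        if len(missing):
            log.warning(
                "%d genes missing from length table; using %.0f bp",
                len(missing), default_length,
            )
        lengths.update(ldf)
    return CountMatrix(
        gene_ids=list(df.index),
        sample_ids=list(df.columns),
        counts=df.values,
        gene_lengths=lengths.values,
    )


def read_design(path: str | Path) -> SampleDesign:
    """Read the sample design TSV (columns: sample, condition)."""
    df = pd.read_csv(path, sep="\t", header=0)
    if df.shape[1] < 2:
        raise ValueError(f"{path}: design table needs sample and condition columns")
    return SampleDesign(dict(zip(df.iloc[:, 0].astype(str), df.iloc[:, 1].astype(str))))


def write_gff3(genes: Iterable[GeneModel], path: str | Path, source: str = "alleleauto") -> None:
    """Write gene and CDS features (one intron-less CDS per gene)."""
    with open(path, "w") as fh:
        fh.write("##gff-version 3\n")
        for g in genes:
            attrs = f"ID={g.gene_id}"
            fh.write(
                f"{g.chromosome}\t{source}\tgene\t{g.start}\t{g.end}\t.\t{g.strand}\t.\t{attrs}\n"
            )
            if g.cds:
                fh.write(
                    f"{g.chromosome}\t{source}\tCDS\t{g.start}\t{g.end}\t.\t{g.strand}\t0\t"
                    f"ID={g.gene_id}.cds;Parent={g.gene_id}\n"
                )


def write_tsv(df: pd.DataFrame, path: str | Path) -> None:
    """Write a result table as TSV with a header, NA for missing values."""
    df.to_csv(path, sep="\t", index=False, na_rep="NA", float_format="%.6g")
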