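"""Readers and writers for the on-disk formats the toolkit exchanges.

Genomes are FASTA; gene models are BED-like TSV (0-based half-open, columns
chrom, cds_start, cds_end, gene_id, essential, strand) or GFF3; TSS tables
are TSV (gene_id, chrom, position, count; 0-based positions); tracks are
bedGraph with a ``track`` header line declaring the kind; reads are FASTQ
(Phred+33). Emitted result TSVs use 1-based inclusive coordinates.
"""

from __future__ import annotations

import re
from pathlib import Path
from typing import Iterable, Iterator, Optional, Sequence

import pandas as pd
from Bio import SeqIO
from Bio.SeqIO.QualityIO import FastqGeneralIterator

from .genome import AccessibilityTrack, GeneModel, Genome


def load_genome(path) -> Genome:
    """Read a (possibly multi-record) FASTA file into a :class:`Genome`."""
    sequences: dict[str, str] = {}
    for record in SeqIO.parse(str(path), "fasta"):
        if record.id in sequences:
            raise ValueError(f"duplicate chromosome name: {record.id}")
        sequences[record.id] = str(record.seq)
    if not sequences:
        raise ValueError(f"no FASTA records found in {path}")
    return Genome(sequences)


def write_genome(path, genome: Genome, width: int = 70) -> None:
    with open(path, "w") as fh:
        for name, seq in genome.sequences.items():
            fh.write(f">{name}\n")
            for i in range(0, len(seq), width):
                fh.write(seq[i : i + width] + "\n")


_TRUE = {"1", "true", "yes", "y", "t"}
_NA = {"", ".", "na", "nan", "none"}


def _parse_essential(token: str) -> Optional[bool]:
    token = str(token).strip().lower()
    if token in _NA:
        return None
    return token in _TRUE


def load_genes_bed(path) -> list[GeneModel]:
    """BED-like gene models: chrom, cds_start, cds_end, gene_id, essential, strand."""
    genes = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.rstrip("\n")
            if not line or line.startswith(("#", "track", "browser")):
                continue
            fields = line.split("\t")
            if len(fields) < 6:
                raise ValueError(f"{path}:{lineno}: expected 6 columns, got {len(fields)}")
            chrom, start, end, gene_id, essential, strand = fields[:6]
            genes.append(
                GeneModel(
                    gene_id=gene_id,
                    chrom=chrom,
                    strand=strand,
                    cds_start=int(start),
                    cds_end=int(end),
                    essential=_parse_essential(essential),
                )
            )
    return genes


def write_genes_bed(path, genes: Iterable[GeneModel]) -> None:
    with open(path, "w") as fh:
        for g in genes:
            essential = "." if g.essential is None else str(int(g.essential))
            fh.write(
                f"{g.chrom}\t{g.cds_start}\t{g.cds_end}\t{g.gene_id}\t"
                f"{essential}\t{g.strand}\n"
            )


_GFF_ID = re.compile(r"(?:^|;)(?:ID|Name|gene_id)=([^;]+)")


def load_genes_gff3(path) -> list[GeneModel]:
    """Gene models from GFF3 ``gene`` (or ``CDS``) features.

    GFF3 is 1-based inclusive; spans are converted to 0-based half-open.
    """
    genes = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            if not line.strip() or line.startswith("#"):
                continue
            fields = line.rstrip("\n").split("\t")
            if len(fields) < 9:
                raise ValueError(f"{path}:{lineno}: expected 9 GFF3 columns")
            chrom, _src, ftype, start, end, _score, strand, _frame, attrs = fields[:9]
            if ftype not in {"gene", "CDS"}:
                continue
            m = _GFF_ID.search(attrs)
            if not m:
                raise ValueError(f"{path}:{lineno}: feature lacks ID/Name attribute")
            genes.append(
                GeneModel(
                    gene_id=m.group(1),
                    chrom=chrom,
                    strand=strand,
                    cds_start=int(start) - 1,
                    cds_end=int(end),
                )
            )
    return genes


def load_tss_table(path) -> pd.DataFrame:
    """TSS table TSV with columns gene_id, chrom, position, count."""
    table = pd.read_csv(path, sep="\t", comment="#")
    required = {"gene_id", "chrom", "position", "count"}
    missing = required - set(table.columns)
    if missing:
        raise ValueError(f"{path}: TSS table missing columns {sorted(missing)}")
    if (table["count"] < 0).any():
        raise ValueError(f"{path}: negative TSS read counts")
    return table


def write_tss_table(path, table: pd.DataFrame) -> None:
    table.to_csv(path, sep="\t", index=False)


_TRACK_KIND = re.compile(r"(?:kind|name)=\"?(accessibility|occupancy)\"?")


def load_bedgraph(path, genome: Genome, kind: Optional[str] = None) -> AccessibilityTrack:
    """Read a bedGraph into a track sized to ``genome``.

    The track kind is taken from the header line (``track ... kind=...`` or
    ``name=...``) unless given explicitly.
    """
    lines = Path(path).read_text().splitlines()
    if kind is None:
        for line in lines:
            if line.startswith("track"):
                m = _TRACK_KIND.search(line)
                if m:
                    kind = m.group(1)
                break
    if kind is None:
        raise ValueError(f"{path}: track kind not declared and not given")
    track = AccessibilityTrack(kind, {c: genome.length(c) for c in genome.chroms})
    for lineno, line in enumerate(lines, 1):
        if not line.strip() or line.startswith(("track", "#", "browser")):
            continue
        fields = line.split("\t")
        if len(fields) < 4:
            raise ValueError(f"{path}:{lineno}: expected 4 bedGraph columns")
        chrom, start, end, value = fields[:4]
        if chrom not in track.lengths:
            raise ValueError(f"{path}:{lineno}: unknown chromosome {chrom}")
        track.set_values(chrom, int(start), int(end), float(value))
    return track


def write_bedgraph(path, track: AccessibilityTrack, decimals: int = 4) -> None:
    """Write a track as run-length-encoded bedGraph with a kind header."""
    import numpy as np

    with open(path, "w") as fh:
        fh.write(f'track type=bedGraph kind={track.kind}\n')
        for chrom, vals in track.values.items():
            rounded = np.round(vals, decimals)
            start = 0
            for i in range(1, len(rounded) + 1):
                last = rounded[start]
                if i == len(rounded) or not (
                    rounded[i] == last or (np.isnan(rounded[i]) and np.isnan(last))
                ):
                    if not np.isnan(last):
                        fh.write(f"{chrom}\t{start}\t{i}\t{last:.{decimals}f}\n")
                    start = i


def iter_fastq(path) -> Iterator[tuple[str, str, str]]:
    """Yield (title, sequence, quality-string) from a FASTQ file."""
    with open(path) as fh:
        yield from FastqGeneralIterator(fh)


def write_fastq(path, records: Iterable[tuple[str, str, str]]) -> None:
    with open(path, "w") as fh:
        for title, seq, qual in records:
            fh.write(f"@{title}\n{seq}\n+\n{qual}\n")


def phred_scores(quality: str) -> list[int]:
    """Decode a Phred+33 quality string."""
    return [ord(c) - 33 for c in quality]
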