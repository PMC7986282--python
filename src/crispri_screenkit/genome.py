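"""Genomes, gene models, TSS tables, and accessibility tracks.

This module holds the coordinate layer shared by guide design and the
efficacy model: an in-memory reference genome with a both-strand target-site
index, gene models anchored either at a representative transcription start
site (TSS) or at the start of the coding sequence (CDS), per-isoform TSS
tables from transcript-isoform sequencing, and [0, 1]-valued per-base tracks
for chromatin accessibility (ATAC-style) or nucleosome occupancy
(ODM-style).

Coordinates are 0-based, half-open everywhere inside the library; emitted
TSV files use 1-based inclusive coordinates (see :mod:`.io`).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Optional

import numpy as np
import pandas as pd

_COMPLEMENT = str.maketrans("ACGTN", "TGCAN")

VALID_BASES = frozenset("ACGTN")


def revcomp(seq: str) -> str:
    """Reverse complement of an upper-case DNA string over {A,C,G,T,N}."""
    return seq.translate(_COMPLEMENT)[::-1]


class Genome:
    """A reference genome with both-strand k-mer and PAM-site lookups.

    Parameters
    ----------
    sequences
        Mapping of chromosome name to DNA sequence. Sequences are upper-cased
        and must be non-empty and restricted to {A, C, G, T, N}.

    Notes
    -----
    N bases never match any query base, so target sites containing N are
    conservatively treated as absent when counting occurrences.
    """

    def __init__(self, sequences: Mapping[str, str]):
        if not sequences:
            raise ValueError("genome contains no sequences")
        self.sequences: dict[str, str] = {}
        for name, seq in sequences.items():
            if name in self.sequences:
                raise ValueError(f"duplicate chromosome name: {name}")
            seq = seq.upper()
            if not seq:
                raise ValueError(f"empty sequence for chromosome {name}")
            bad = set(seq) - VALID_BASES
            if bad:
                raise ValueError(f"invalid bases {sorted(bad)} in {name}")
            self.sequences[name] = seq
        self._site_index: Optional[dict[str, int]] = None

    @property
    def chroms(self) -> list[str]:
        return list(self.sequences)

    def length(self, chrom: str) -> int:
        return len(self.sequences[chrom])

    def fetch(self, chrom: str, start: int, end: int) -> str:
        """Sequence of the 0-based half-open window [start, end) on ``chrom``."""
        seq = self.sequences[chrom]
        if start < 0 or end > len(seq):
            raise IndexError(f"window [{start}, {end}) outside {chrom}")
        return seq[start:end]

    def count_occurrences(self, pattern: str) -> int:
        """Exact occurrences of ``pattern`` on both strands of the genome.

        An occurrence is a (chromosome, position, strand) triple; a
        palindromic pattern at one locus therefore counts twice. Patterns
        containing N match nothing.
        """
        pattern = pattern.upper()
        if "N" in pattern or not pattern:
            return 0
        total = 0
        for queries in (pattern, revcomp(pattern)):
            for seq in self.sequences.values():
                start = seq.find(queries)
                while start != -1:
                    total += 1
                    start = seq.find(queries, start + 1)
        return total

    # -- NGG target-site uniqueness -------------------------------------

    def _build_site_index(self) -> dict[str, int]:
        """Count every 23-nt NGG site keyed by protospacer, both strands.

        Key is the 20-nt protospacer followed by ``NGG`` with the variable
        PAM base masked, so one lookup counts a protospacer followed by any
        of the four NGG PAMs. Windows containing N are skipped.
        """
        index: dict[str, int] = {}
        for seq in self.sequences.values():
            for s in (seq, revcomp(seq)):
                for i in range(len(s) - 22):
                    if s[i + 21 : i + 23] != "GG":
                        continue
                    window = s[i : i + 21]
                    if "N" in window:
                        continue
                    key = window[:20] + "NGG"
                    index[key] = index.get(key, 0) + 1
        return index

    def count_target_sites(self, protospacer: str) -> int:
        """Genomic sites matching ``protospacer`` + NGG on either strand."""
        if self._site_index is None:
            self._site_index = self._build_site_index()
        return self._site_index.get(protospacer.upper() + "NGG", 0)


@dataclass
class GeneModel:
    """A gene with strand, CDS span, and an optional representative TSS.

    ``annotation_mode`` is ``"TSS"`` when a representative TSS is known and
    ``"CDS"`` otherwise; the guide-design anchor is the TSS in the first case
    and the first base of the CDS (in transcription direction) in the second.
    """

    gene_id: str
    chrom: str
    strand: str
    cds_start: int
    cds_end: int
    tss: Optional[int] = None
    essential: Optional[bool] = None

    def __post_init__(self) -> None:
        if self.strand not in {"+", "-"}:
            raise ValueError(f"{self.gene_id}: strand must be + or -")
        if not self.cds_start < self.cds_end:
            raise ValueError(f"{self.gene_id}: cds_start must be < cds_end")

    @property
    def annotation_mode(self) -> str:
        return "TSS" if self.tss is not None else "CDS"

    @property
    def cds_anchor(self) -> int:
        """First base of the CDS in transcription direction."""
        return self.cds_start if self.strand == "+" else self.cds_end - 1

    @property
    def anchor(self) -> int:
        """Design anchor: the TSS when known, else the CDS start."""
        return self.tss if self.tss is not None else self.cds_anchor

    def offset_of(self, position: int) -> int:
        """Signed offset of a genomic position in transcription direction.

        The anchor is 0 and positive offsets point downstream (into the
        gene).
        """
        if self.strand == "+":
            return position - self.anchor
        return self.anchor - position


def select_representative_tss(
    tss_table: pd.DataFrame, gene: GeneModel
) -> Optional[int]:
    """Modal (highest read count) TSS for a gene, or None when unannotated.

    Ties on read count are broken toward the TSS closest to the CDS start
    (in transcription direction), then toward the smaller genomic
    coordinate, so the choice is deterministic under row permutation.
    """
    rows = tss_table[tss_table["gene_id"] == gene.gene_id]
    if len(rows) == 0:
        return None
    cds_anchor = gene.cds_anchor
    best = min(
        rows.itertuples(index=False),
        key=lambda r: (-r.count, abs(int(r.position) - cds_anchor), int(r.position)),
    )
    return int(best.position)


class AccessibilityTrack:
    """A per-base [0, 1] signal: ATAC-style accessibility or ODM occupancy.

    Missing positions are NaN internally and are filled on read-out with 0.0
    for accessibility tracks (no evidence of openness) and 1.0 for occupancy
    tracks (assume fully occupied) — pessimistic in both directions.
    """

    KINDS = ("accessibility", "occupancy")

    def __init__(self, kind: str, lengths: Mapping[str, int]):
        if kind not in self.KINDS:
            raise ValueError(f"kind must be one of {self.KINDS}")
        self.kind = kind
        self.lengths = dict(lengths)
        self.values: dict[str, np.ndarray] = {
            chrom: np.full(n, np.nan) for chrom, n in self.lengths.items()
        }

    @property
    def fill_value(self) -> float:
        return 0.0 if self.kind == "accessibility" else 1.0

    def set_values(self, chrom: str, start: int, end: int, value) -> None:
        arr = self.values[chrom]
        start = max(start, 0)
        end = min(end, len(arr))
        if start < end:
            arr[start:end] = np.clip(value, 0.0, 1.0)

    def window_values(self, chrom: str, start: int, end: int) -> np.ndarray:
        """Per-position values over [start, end), missing data filled.

        Windows reaching past the chromosome ends are truncated with a
        warning.
        """
        if chrom not in self.lengths:
            raise KeyError(f"chromosome {chrom} not in track")
        n = self.lengths[chrom]
        if start < 0 or end > n:
            warnings.warn(
                f"window [{start}, {end}) truncated to chromosome {chrom} "
                f"bounds [0, {n})",
                stacklevel=2,
            )
            start, end = max(start, 0), min(end, n)
        vals = self.values[chrom][start:end].copy()
        vals[np.isnan(vals)] = self.fill_value
        return vals


def window_values(
    track: AccessibilityTrack, chrom: str, start: int, end: int
) -> np.ndarray:
    """Functional alias for :meth:`AccessibilityTrack.window_values`."""
    return track.window_values(chrom, start, end)
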