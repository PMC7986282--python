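"""Barcode counting, mismatch collapsing, and barcode-to-guide assignment.

Two read-processing workflows share this module:

* **Counting** (single-end): reads are trimmed at the 3' linker adapter,
  barcodes shorter than 10 nt are discarded, barcodes one substitution
  apart are collapsed, and the collated per-library count table is filtered
  (present in >= 2 libraries, >= 33 reads total, no XhoI site).

* **Assignment** (paired-end): R1 yields the barcode (>= 12 nt after a
  longer adapter trim), R2 yields the variable guide (>= 20 nt between
  fixed adapters). Guide reads with any base below Q30 are discarded;
  the rest are aligned against the designed guide library (plus a
  scaffold-only "empty" entry). Each collapsed barcode is then assigned a
  fate: fewer than 3 high-quality reads -> insufficient; majority guide
  below 90% of usable reads -> heterogeneous; majority alignment carrying
  edits -> defective; otherwise assigned (or empty).
"""

from __future__ import annotations

from collections import Counter, defaultdict
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Optional, Sequence

import edlib
import numpy as np
import pandas as pd

from .io import iter_fastq, phred_scores

# adapter downstream of the barcode in counting libraries
COUNT_ADAPTER = "GCATGCGTGAAGTGGCGCGCCTGATA"
# longer adapter used when sequencing barcodes for guide assignment
ASSIGN_ADAPTER = "GCATGCGTGAAGTGGCGCGCCTGATAGCTCGTTTAAACTG"
GUIDE_5_ADAPTER = "CGAAAC"
GUIDE_3_ADAPTER = "AAGTTAAAAT"
XHOI_SITE = "CTCGAG"

MIN_BARCODE_LEN_COUNT = 10
MIN_BARCODE_LEN_ASSIGN = 12
MIN_GUIDE_LEN = 20
MIN_QUALITY = 30
MIN_HQ_READS = 3
MAJORITY_FRACTION = 0.9
MAX_EDITS = 3

EMPTY_GUIDE_ID = "__empty__"

FATES = ("assigned", "empty", "heterogeneous", "defective", "insufficient")


def trim_barcode_read(
    seq: str, adapter: str = COUNT_ADAPTER, min_len: int = MIN_BARCODE_LEN_COUNT
) -> tuple[Optional[str], Optional[str]]:
    """Barcode 5' of the first adapter occurrence, or (None, reason)."""
    pos = seq.find(adapter)
    if pos == -1:
        return None, "no_adapter"
    if pos < min_len:
        return None, "too_short"
    return seq[:pos], None


def trim_guide_read(
    seq: str,
    five_adapter: str = GUIDE_5_ADAPTER,
    three_adapter: str = GUIDE_3_ADAPTER,
    min_len: int = MIN_GUIDE_LEN,
) -> tuple[Optional[tuple[int, int]], Optional[str]]:
    """(start, end) of the residual guide between the two adapters.

    Indices are returned (rather than the substring) so the caller can
    slice the matching quality string; (None, reason) on rejection.
    """
    p5 = seq.find(five_adapter)
    if p5 == -1:
        return None, "no_5_adapter"
    start = p5 + len(five_adapter)
    p3 = seq.find(three_adapter, start)
    if p3 == -1:
        return None, "no_3_adapter"
    if p3 - start < min_len:
        return None, "too_short"
    return (start, p3), None


@dataclass
class BarcodeRecord:
    """A collapsed barcode: representative sequence, counts, members."""

    barcode: str
    count: int
    members: dict[str, int] = field(default_factory=dict)


def _hamming1_masks(barcode: str):
    for pos in range(len(barcode)):
        yield len(barcode), pos, barcode[:pos] + "\0" + barcode[pos + 1 :]


def collapse_barcodes(raw_counts: Mapping[str, int]) -> list[BarcodeRecord]:
    """Greedy single-substitution collapsing of a barcode count table.

    Barcodes are processed by descending count (ties lexicographic); each
    either founds a record or is absorbed into an existing record of the
    same length at Hamming distance 1 (the highest-count founder when
    several qualify). Total counts are conserved and the output is a fixed
    point of re-collapsing (founders are pairwise at distance >= 2).
    """
    order = sorted(raw_counts, key=lambda bc: (-raw_counts[bc], bc))
    records: dict[str, BarcodeRecord] = {}
    mask_index: dict[tuple, list[str]] = defaultdict(list)
    for bc in order:
        count = raw_counts[bc]
        founders = {
            rep
            for mask in _hamming1_masks(bc)
            for rep in mask_index.get(mask, ())
        }
        if founders:
            rep = max(founders, key=lambda r: (records[r].count, [-ord(c) for c in r]))
            rec = records[rep]
            rec.count += count
            rec.members[bc] = count
        else:
            records[bc] = BarcodeRecord(barcode=bc, count=count, members={bc: count})
            for mask in _hamming1_masks(bc):
                mask_index[mask].append(bc)
    return list(records.values())


def collapse_count_table(counts: pd.DataFrame) -> tuple[pd.DataFrame, dict[str, str]]:
    """Collapse a barcode x sample count table by total count.

    Returns the collapsed table (indexed by representative barcode) and the
    member -> representative map.
    """
    totals = counts.sum(axis=1)
    records = collapse_barcodes(totals.to_dict())
    member_map = {m: rec.barcode for rec in records for m in rec.members}
    grouped = counts.groupby(counts.index.map(member_map)).sum()
    reps = [rec.barcode for rec in records]
    return grouped.loc[reps], member_map


def filter_count_table(
    counts: pd.DataFrame,
    min_libraries: int = 2,
    min_total: int = 33,
    forbidden_motif: str = XHOI_SITE,
) -> pd.DataFrame:
    """Keep barcodes seen in >= 2 libraries, >= ``min_total`` reads, no motif."""
    present = (counts > 0).sum(axis=1) >= min_libraries
    deep = counts.sum(axis=1) >= min_total
    clean = ~counts.index.str.contains(forbidden_motif)
    return counts[present & deep & clean]


def count_barcodes(
    fastq_by_sample: Mapping[str, str],
    adapter: str = COUNT_ADAPTER,
    min_len: int = MIN_BARCODE_LEN_COUNT,
    min_libraries: int = 2,
    min_total: int = 33,
) -> pd.DataFrame:
    """Counting workflow: trim, tabulate per sample, collapse, filter."""
    tallies = {}
    for sample, path in fastq_by_sample.items():
        tally: Counter = Counter()
        for _title, seq, _qual in iter_fastq(path):
            bc, _reason = trim_barcode_read(seq, adapter, min_len)
            if bc is not None:
                tally[bc] += 1
        tallies[sample] = tally
    counts = pd.DataFrame(tallies).fillna(0).astype(int)
    counts.index.name = "barcode"
    if counts.empty:
        return counts
    collapsed, _ = collapse_count_table(counts)
    return filter_count_table(collapsed, min_libraries, min_total)


@dataclass
class MatchOutcome:
    """Result of aligning one trimmed guide read against the library."""

    status: str  # perfect | imperfect | low_quality | unmatched | ambiguous
    guide_id: Optional[str] = None
    edits: int = 0


def match_guide(
    guide_seq: str,
    quality: str | Sequence[int],
    library: Mapping[str, str],
    max_edits: int = MAX_EDITS,
) -> MatchOutcome:
    """Align a guide read against the library of guide sequences.

    Reads with any base below Q30 are discarded (``low_quality``). The
    best global-alignment edit distance wins; distances above ``max_edits``
    are ``unmatched`` and ties between two library guides are ``ambiguous``
    (both excluded from majority computations downstream).
    """
    scores = phred_scores(quality) if isinstance(quality, str) else quality
    if any(q < MIN_QUALITY for q in scores):
        return MatchOutcome(status="low_quality")
    best_id, best_dist, tied = None, max_edits + 1, False
    for guide_id, seq in library.items():
        if guide_seq == seq:
            best_id, best_dist, tied = guide_id, 0, False
            break
        dist = edlib.align(guide_seq, seq, mode="NW", task="distance", k=max_edits)[
            "editDistance"
        ]
        if dist == -1:
            continue
        if dist < best_dist:
            best_id, best_dist, tied = guide_id, dist, False
        elif dist == best_dist:
            tied = True
    if best_id is None:
        return MatchOutcome(status="unmatched")
    if tied:
        return MatchOutcome(status="ambiguous")
    status = "perfect" if best_dist == 0 else "imperfect"
    return MatchOutcome(status=status, guide_id=best_id, edits=best_dist)


@dataclass
class AssignmentRecord:
    barcode: str
    fate: str
    guide_id: Optional[str] = None
    n_hq_reads: int = 0
    majority_fraction: float = 0.0


def assign_barcode(
    outcomes: Sequence[MatchOutcome],
    barcode: str = "",
    empty_guide_id: str = EMPTY_GUIDE_ID,
    min_reads: int = MIN_HQ_READS,
    majority_fraction: float = MAJORITY_FRACTION,
) -> AssignmentRecord:
    """Fate of one collapsed barcode from its guide-read outcomes.

    High-quality (HQ) reads are those passing the Q30 filter; reads that
    are unmatched or tie between library guides are additionally excluded
    from the majority computation. The majority guide must reach 90% of
    usable reads, and its modal alignment must be edit-free (ties between
    an edit-free and an edited modal outcome are conservatively called
    defective).
    """
    hq = [o for o in outcomes if o.status != "low_quality"]
    if len(hq) < min_reads:
        return AssignmentRecord(barcode, "insufficient", n_hq_reads=len(hq))
    usable = [o for o in hq if o.status in ("perfect", "imperfect")]
    if not usable:
        return AssignmentRecord(barcode, "heterogeneous", n_hq_reads=len(hq))
    by_guide = Counter(o.guide_id for o in usable)
    majority_guide, n_major = max(by_guide.items(), key=lambda kv: (kv[1], kv[0]))
    frac = n_major / len(usable)
    if frac < majority_fraction:
        return AssignmentRecord(
            barcode, "heterogeneous", n_hq_reads=len(hq), majority_fraction=frac
        )
    edit_counts = Counter(o.edits for o in usable if o.guide_id == majority_guide)
    modal_edits = max(edit_counts.items(), key=lambda kv: (kv[1], kv[0]))[0]
    if modal_edits > 0:
        return AssignmentRecord(
            barcode, "defective", n_hq_reads=len(hq), majority_fraction=frac
        )
    fate = "empty" if majority_guide == empty_guide_id else "assigned"
    return AssignmentRecord(
        barcode, fate, guide_id=majority_guide, n_hq_reads=len(hq),
        majority_fraction=frac,
    )


def assign_barcodes(
    reads_by_barcode: Mapping[str, Sequence[MatchOutcome]],
    empty_guide_id: str = EMPTY_GUIDE_ID,
    min_reads: int = MIN_HQ_READS,
    majority_fraction: float = MAJORITY_FRACTION,
) -> tuple[pd.DataFrame, pd.Series]:
    """Assign every barcode and tally fates.

    Returns the per-barcode assignment table and a fates tally covering all
    fate categories (the tally sums to the number of barcodes).
    """
    records = [
        assign_barcode(outcomes, bc, empty_guide_id, min_reads, majority_fraction)
        for bc, outcomes in reads_by_barcode.items()
    ]
    table = pd.DataFrame(
        {
            "barcode": [r.barcode for r in records],
            "fate": [r.fate for r in records],
            "guide_id": [r.guide_id for r in records],
            "n_hq_reads": [r.n_hq_reads for r in records],
            "majority_fraction": [r.majority_fraction for r in records],
        }
    )
    tally = table["fate"].value_counts().reindex(FATES, fill_value=0)
    tally.name = "n"
    return table, tally


def assign_from_fastq(
    r1_path,
    r2_path,
    library: Mapping[str, str],
    empty_guide_id: str = EMPTY_GUIDE_ID,
    barcode_adapter: str = ASSIGN_ADAPTER,
    min_barcode_len: int = MIN_BARCODE_LEN_ASSIGN,
    max_edits: int = MAX_EDITS,
) -> tuple[pd.DataFrame, pd.Series]:
    """Assignment workflow over paired FASTQ files.

    R1 barcodes are trimmed and collapsed; R2 guides are trimmed, quality
    filtered, and aligned; fates are assigned per collapsed barcode. The
    library mapping should include a scaffold-only sequence under
    ``empty_guide_id`` so guide-free constructs are recognized.
    """
    raw_reads: dict[str, list[tuple[str, str]]] = defaultdict(list)
    for (t1, s1, q1), (t2, s2, q2) in zip(iter_fastq(r1_path), iter_fastq(r2_path)):
        bc, _reason = trim_barcode_read(s1, barcode_adapter, min_barcode_len)
        if bc is None:
            continue
        span, _reason = trim_guide_read(s2)
        if span is None:
            continue
        start, end = span
        raw_reads[bc].append((s2[start:end], q2[start:end]))
    records = collapse_barcodes({bc: len(reads) for bc, reads in raw_reads.items()})
    grouped: dict[str, list[MatchOutcome]] = {}
    for rec in records:
        outcomes = []
        for member in rec.members:
            for seq, qual in raw_reads[member]:
                outcomes.append(match_guide(seq, qual, library, max_edits))
        grouped[rec.barcode] = outcomes
    return assign_barcodes(grouped, empty_guide_id)
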