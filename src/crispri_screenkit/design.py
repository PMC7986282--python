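"""Zone-based CRISPRi guide design.

Candidate guides are all 23-nt protospacer+PAM windows (NGG on either
strand) whose target-sequence center falls in the promoter association
window of a gene: [-220, +20] around the representative TSS when one is
known, [-350, 0] around the CDS start otherwise (offsets are signed in the
gene's transcription direction, anchor = 0).

Candidates are classified for genome-wide uniqueness (perfect-match
protospacer+NGG occurring once, both strands counted) and promoter
specificity (associated with exactly one gene's window), scored by mean
ATAC-style accessibility over the 23 target bases, and then selected:
first the best candidate in each positional zone, then the remaining best
candidates until ten guides per gene or exhaustion. Guides in the shared
window of a divergent promoter pair can later be re-assigned to one likely
target using a fitted position-activity curve.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Mapping, Optional, Sequence

import numpy as np
import pandas as pd

from .genome import AccessibilityTrack, GeneModel, Genome, revcomp

TSS_WINDOW = (-220, 20)
CDS_WINDOW = (-350, 0)
TSS_ZONES = ((-220, -141), (-140, -61), (-60, 20))
CDS_ZONES = ((-350, -271), (-270, -191), (-190, -111), (-110, -30))

#: empirically most active target-center position relative to the TSS
PREFERRED_OFFSET = -50

MAX_GUIDES_PER_GENE = 10

TARGET_LEN = 23  # 20-nt protospacer + 3-nt NGG PAM
#: index (0-based, in genomic order) of the central base of the 23-nt target
CENTER_INDEX = 11


@dataclass
class CandidateGuide:
    """A protospacer+PAM site associated with one gene."""

    gene_id: str
    chrom: str
    strand: str  # strand the protospacer+PAM reads on
    start: int  # 0-based half-open genomic span of the 23-nt target
    end: int
    protospacer: str
    pam: str
    center_offset: int  # target-center offset from the gene anchor
    unique: Optional[bool] = None
    specific: Optional[bool] = None
    accessibility: float = 0.0
    zone: Optional[int] = None
    rank: Optional[int] = None
    alternative_targets: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        if self.end - self.start != TARGET_LEN:
            raise ValueError("target span must be 23 nt")
        if self.pam[1:3] != "GG":
            raise ValueError("PAM must match NGG")

    @property
    def center(self) -> int:
        """Genomic coordinate of the central (12th) base of the target."""
        return self.start + CENTER_INDEX


@dataclass
class DesignedLibrary:
    """Ranked per-gene guide selections plus ambiguity records."""

    guides: dict[str, list[CandidateGuide]]

    @property
    def gene_ids(self) -> list[str]:
        return list(self.guides)

    def all_guides(self) -> list[CandidateGuide]:
        return [g for sel in self.guides.values() for g in sel]

    def to_dataframe(self) -> pd.DataFrame:
        """Flat table with 1-based inclusive genomic coordinates."""
        rows = []
        for gene_id, selection in self.guides.items():
            for g in selection:
                rows.append(
                    {
                        "gene_id": gene_id,
                        "guide_id": f"{gene_id}_g{g.rank}",
                        "chrom": g.chrom,
                        "strand": g.strand,
                        "protospacer": g.protospacer,
                        "pam": g.pam,
                        "target_start": g.start + 1,
                        "target_end": g.end,
                        "center_offset": g.center_offset,
                        "unique": g.unique,
                        "specific": g.specific,
                        "accessibility": g.accessibility,
                        "zone": -1 if g.zone is None else g.zone,
                        "rank": g.rank,
                        "alternative_targets": ",".join(g.alternative_targets),
                    }
                )
        return pd.DataFrame(rows)


def association_window(gene: GeneModel) -> tuple[int, int]:
    """Offset window (inclusive) of target centers associated with a gene."""
    return TSS_WINDOW if gene.annotation_mode == "TSS" else CDS_WINDOW


def genomic_center_interval(gene: GeneModel) -> tuple[int, int]:
    """Genomic interval (inclusive) of target centers in the gene's window."""
    lo, hi = association_window(gene)
    anchor = gene.anchor
    if gene.strand == "+":
        return anchor + lo, anchor + hi
    return anchor - hi, anchor - lo


def zones_for_mode(mode: str) -> tuple[tuple[int, int], ...]:
    return TSS_ZONES if mode == "TSS" else CDS_ZONES


def zone_of(offset: int, mode: str) -> Optional[int]:
    for i, (lo, hi) in enumerate(zones_for_mode(mode)):
        if lo <= offset <= hi:
            return i
    return None


def enumerate_candidates(genome: Genome, gene: GeneModel) -> list[CandidateGuide]:
    """All NGG target sites whose center lies in the gene's window.

    A site on the + strand is a 23-mer ending in GG; a site on the - strand
    is a 23-mer starting with CC read on the forward strand (its reverse
    complement ends in GG). The full 23-nt span must lie inside the
    chromosome and contain no N.
    """
    seq = genome.sequences[gene.chrom]
    lo, hi = genomic_center_interval(gene)
    mode = gene.annotation_mode
    out: list[CandidateGuide] = []
    for center in range(max(lo, 0), min(hi, len(seq) - 1) + 1):
        start = center - CENTER_INDEX
        end = start + TARGET_LEN
        if start < 0 or end > len(seq):
            continue
        window = seq[start:end]
        if "N" in window:
            continue
        offset = gene.offset_of(center)
        if window[21:23] == "GG":
            out.append(
                CandidateGuide(
                    gene_id=gene.gene_id,
                    chrom=gene.chrom,
                    strand="+",
                    start=start,
                    end=end,
                    protospacer=window[:20],
                    pam=window[20:23],
                    center_offset=offset,
                    zone=zone_of(offset, mode),
                )
            )
        if window[0:2] == "CC":
            rc = revcomp(window)
            out.append(
                CandidateGuide(
                    gene_id=gene.gene_id,
                    chrom=gene.chrom,
                    strand="-",
                    start=start,
                    end=end,
                    protospacer=rc[:20],
                    pam=rc[20:23],
                    center_offset=offset,
                    zone=zone_of(offset, mode),
                )
            )
    return out


def classify_uniqueness(genome: Genome, cand: CandidateGuide) -> bool:
    """True iff protospacer+NGG has exactly one genomic site (both strands)."""
    return genome.count_target_sites(cand.protospacer) == 1


def classify_specificity(
    cand: CandidateGuide, genes: Sequence[GeneModel]
) -> tuple[bool, list[str]]:
    """Is the candidate associated with exactly one gene's window?

    Returns the specificity flag and the list of alternative target genes
    (the divergent-promoter ambiguity record).
    """
    associated = []
    for gene in genes:
        if gene.chrom != cand.chrom:
            continue
        lo, hi = genomic_center_interval(gene)
        if lo <= cand.center <= hi:
            associated.append(gene.gene_id)
    alternatives = [g for g in associated if g != cand.gene_id]
    return len(associated) == 1, alternatives


def score_accessibility(
    tracks: Sequence[AccessibilityTrack] | AccessibilityTrack,
    cand: CandidateGuide,
) -> float:
    """Mean accessibility over the 23 target bases, averaged over replicates.

    Missing data reads as 0.0 (inaccessible); replicate tracks are averaged
    by taking the mean of the per-replicate means.
    """
    if isinstance(tracks, AccessibilityTrack):
        tracks = [tracks]
    if not tracks:
        return 0.0
    means = []
    for track in tracks:
        if track.kind != "accessibility":
            raise ValueError("accessibility scoring requires accessibility tracks")
        means.append(float(np.mean(track.window_values(cand.chrom, cand.start, cand.end))))
    return float(np.mean(means))


def priority_key(cand: CandidateGuide):
    """Sort key implementing the selection priority (best first).

    Unique first, then specific, then higher accessibility; ties broken by
    proximity to the empirically best position (-50), then smaller genomic
    coordinate, then + strand.
    """
    return (
        not cand.unique,
        not cand.specific,
        -cand.accessibility,
        abs(cand.center_offset - PREFERRED_OFFSET),
        cand.start,
        cand.strand != "+",
    )


def select_guides(
    cands: Sequence[CandidateGuide],
    mode: str,
    max_guides: int = MAX_GUIDES_PER_GENE,
) -> list[CandidateGuide]:
    """Rank-ordered selection: one best guide per zone, then best remaining.

    Zones without candidates are skipped; selection stops at ``max_guides``
    or when candidates are exhausted. The returned guides carry 1-based
    ranks.
    """
    ranked = sorted(cands, key=priority_key)
    selected: list[CandidateGuide] = []
    chosen = set()
    for zone_idx in range(len(zones_for_mode(mode))):
        for cand in ranked:
            if cand.zone == zone_idx and id(cand) not in chosen:
                selected.append(cand)
                chosen.add(id(cand))
                break
        if len(selected) >= max_guides:
            break
    for cand in ranked:
        if len(selected) >= max_guides:
            break
        if id(cand) not in chosen:
            selected.append(cand)
            chosen.add(id(cand))
    for rank, cand in enumerate(selected, 1):
        cand.rank = rank
    return selected


def design_library(
    genome: Genome,
    genes: Sequence[GeneModel],
    tss_table: Optional[pd.DataFrame] = None,
    atac_tracks: Sequence[AccessibilityTrack] = (),
    max_guides: int = MAX_GUIDES_PER_GENE,
) -> DesignedLibrary:
    """Run the full design: anchors, enumeration, scoring, selection.

    Genes with TSS-table rows are anchored at the modal TSS; others fall
    back to CDS mode. Returns one ranked selection per gene (possibly
    empty, reported as uncovered).
    """
    from .genome import select_representative_tss

    if tss_table is not None:
        for gene in genes:
            gene.tss = select_representative_tss(tss_table, gene)
    per_gene: dict[str, list[CandidateGuide]] = {}
    all_cands: list[CandidateGuide] = []
    for gene in genes:
        cands = enumerate_candidates(genome, gene)
        for cand in cands:
            cand.unique = classify_uniqueness(genome, cand)
            cand.accessibility = score_accessibility(list(atac_tracks), cand)
        per_gene[gene.gene_id] = cands
        all_cands.extend(cands)
    for cand in all_cands:
        cand.specific, cand.alternative_targets = classify_specificity(cand, genes)
    library: dict[str, list[CandidateGuide]] = {}
    for gene in genes:
        library[gene.gene_id] = select_guides(
            per_gene[gene.gene_id], gene.annotation_mode, max_guides
        )
    return DesignedLibrary(guides=library)


def resolve_divergent_targets(
    cand: CandidateGuide,
    genes_by_id: Mapping[str, GeneModel],
    activity_curve,
    margin: float = 2.0,
) -> Optional[str]:
    """Assign an ambiguous guide to its likely target using position bias.

    The fitted position curve (fitness vs TSS offset; more negative = more
    active) is evaluated at the guide's offset from each associated gene's
    anchor. Predicted activity is the depletion magnitude max(0, -curve);
    offsets outside the curve's support count as inactive. The guide is
    assigned to the most active gene when its activity exceeds the runner-up
    by at least ``margin``-fold (default 2:1 odds); otherwise None
    (unresolved).
    """
    targets = [cand.gene_id, *cand.alternative_targets]
    activities = []
    for gene_id in targets:
        gene = genes_by_id[gene_id]
        offset = gene.offset_of(cand.center)
        lo, hi = association_window(gene)
        if offset < lo or offset > hi:
            activities.append(0.0)
        else:
            activities.append(max(0.0, -float(activity_curve.predict([offset])[0])))
    order = sorted(range(len(targets)), key=lambda i: -activities[i])
    best, second = order[0], (order[1] if len(order) > 1 else None)
    if activities[best] <= 0.0:
        return None
    if second is not None and activities[best] < margin * activities[second]:
        return None
    return targets[best]
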