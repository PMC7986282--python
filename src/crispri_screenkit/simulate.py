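"""Synthetic genomes, libraries, reads, and growth trajectories.

Everything the pipeline consumes can be generated here with the
statistical structure it assumes: compact genomes with divergent promoter
pairs a few hundred bases apart, accessibility/occupancy tracks with a
nucleosome-free region upstream of each TSS, barcode/guide assignment
reads carrying synthesis errors and chimeras at the rates observed in real
barcoded libraries (~10% defective, ~5% heterogeneous, ~1% guide-free),
and exponential competitive-growth dynamics sampled multinomially at a
chosen sequencing depth. All generators are deterministic under their
seed.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Optional, Sequence

import numpy as np
import pandas as pd

from .barcodes import ASSIGN_ADAPTER, EMPTY_GUIDE_ID, GUIDE_3_ADAPTER, GUIDE_5_ADAPTER
from .genome import AccessibilityTrack, GeneModel, Genome

#: 5' end of the invariant sgRNA scaffold, used as the reference sequence
#: for guide-free ("empty") expression constructs
EMPTY_GUIDE_SEQ = "GTTTTAGAGCTAGAAATAGC"

DEFAULT_GENS = (0.0, 3.75, 7.5, 11.25)

BASES = np.array(list("ACGT"))


def _random_dna(rng: np.random.Generator, n: int, gc: float = 0.40) -> str:
    p = np.array([(1 - gc) / 2, gc / 2, gc / 2, (1 - gc) / 2])
    return "".join(rng.choice(BASES, size=n, p=p))


# ---------------------------------------------------------------------------
# genome simulation


@dataclass
class SimGenomeSpec:
    """Layout parameters for a synthetic genome with planted promoters."""

    n_chroms: int = 2
    chrom_length: int = 60_000
    n_genes: int = 50
    fraction_divergent_pairs: float = 0.3  # fraction of genes in divergent pairs
    fraction_cds_only: float = 0.2  # genes with no TSS annotation
    fraction_essential: float = 0.4
    tss_offset_range: tuple[int, int] = (30, 120)  # TSS-to-ATG distance
    divergent_separation: tuple[int, int] = (200, 600)  # TSS-to-TSS spacing
    cds_length_range: tuple[int, int] = (500, 1500)
    gc_content: float = 0.40
    seed: int = 0


@dataclass
class SimulatedGenome:
    genome: Genome
    genes: list[GeneModel]
    tss_table: pd.DataFrame
    atac_tracks: list[AccessibilityTrack]
    occupancy_track: AccessibilityTrack
    divergent_pairs: list[tuple[str, str]]
    true_tss: dict[str, int]  # includes genes annotated in CDS mode


def _add_nfr(acc: np.ndarray, gene_like, tss: int, strand: str) -> None:
    """Open-chromatin bump over roughly [-150, +10] around a TSS."""
    offsets = np.arange(-170, 31)
    # smooth plateau: high accessibility through the NFR, shoulders outside
    level = 0.9 / (1.0 + np.exp((np.abs(offsets + 70) - 90) / 12.0))
    positions = tss + offsets if strand == "+" else tss - offsets
    ok = (positions >= 0) & (positions < len(acc))
    np.maximum.at(acc, positions[ok], level[ok])


def simulate_genome(spec: SimGenomeSpec) -> SimulatedGenome:
    """Generate a genome, gene models, TSS table, and chromatin tracks.

    Genes are placed left to right with ~700 bp spacing between units so
    association windows of unrelated genes never overlap; a configurable
    fraction of genes is laid out as divergent pairs whose TSSs face away
    from each other across a shared intergenic region, producing the
    ambiguous-guide geometry of compact genomes.
    """
    rng = np.random.default_rng(spec.seed)
    n_pairs = int(round(spec.n_genes * spec.fraction_divergent_pairs / 2))
    n_single = spec.n_genes - 2 * n_pairs
    units = ["pair"] * n_pairs + ["single"] * n_single
    rng.shuffle(units)

    cursors = {f"chr{i + 1}": 0 for i in range(spec.n_chroms)}
    chrom_names = list(cursors)
    genes: list[GeneModel] = []
    true_tss: dict[str, int] = {}
    divergent_pairs: list[tuple[str, str]] = []
    gene_no = 0

    def new_gene(chrom, strand, cds_start, cds_end, tss):
        nonlocal gene_no
        gene_no += 1
        gid = f"gene{gene_no:04d}"
        essential = bool(rng.random() < spec.fraction_essential)
        genes.append(
            GeneModel(gid, chrom, strand, int(cds_start), int(cds_end),
                      essential=essential)
        )
        true_tss[gid] = int(tss)
        return gid

    for i, unit in enumerate(units):
        chrom = chrom_names[i % spec.n_chroms]
        cursor = cursors[chrom] + 700  # inter-unit gap
        cds_len = lambda: int(rng.integers(*spec.cds_length_range))
        d = lambda: int(rng.integers(*spec.tss_offset_range))
        if unit == "single":
            if rng.random() < 0.5:
                tss = cursor + 260
                cds_start = tss + d()
                end = cds_start + cds_len()
                gid = new_gene(chrom, "+", cds_start, end, tss)
            else:
                cds_start = cursor
                cds_end = cds_start + cds_len()
                tss = cds_end - 1 + d()
                gid = new_gene(chrom, "-", cds_start, cds_end, tss)
                end = tss + 260
        else:
            cds_start_l = cursor
            cds_end_l = cds_start_l + cds_len()
            tss_l = cds_end_l - 1 + d()
            gid_l = new_gene(chrom, "-", cds_start_l, cds_end_l, tss_l)
            sep = int(rng.integers(*spec.divergent_separation))
            tss_r = tss_l + sep
            cds_start_r = tss_r + d()
            end = cds_start_r + cds_len()
            gid_r = new_gene(chrom, "+", cds_start_r, end, tss_r)
            divergent_pairs.append((gid_l, gid_r))
        if end + 700 > spec.chrom_length:
            raise ValueError(
                f"infeasible packing: {spec.n_genes} genes do not fit in "
                f"{spec.n_chroms} x {spec.chrom_length} bp"
            )
        cursors[chrom] = end

    sequences = {c: _random_dna(rng, spec.chrom_length, spec.gc_content)
                 for c in chrom_names}
    genome = Genome(sequences)
    lengths = {c: spec.chrom_length for c in chrom_names}

    base_acc = {c: np.full(spec.chrom_length, 0.05) for c in chrom_names}
    for gene in genes:
        _add_nfr(base_acc[gene.chrom], gene, true_tss[gene.gene_id], gene.strand)
    atac_tracks = []
    for _rep in range(2):
        track = AccessibilityTrack("accessibility", lengths)
        for chrom in chrom_names:
            jitter = rng.normal(0.0, 0.02, spec.chrom_length)
            track.values[chrom][:] = np.clip(base_acc[chrom] + jitter, 0.0, 1.0)
        atac_tracks.append(track)
    occupancy = AccessibilityTrack("occupancy", lengths)
    for chrom in chrom_names:
        jitter = rng.normal(0.0, 0.02, spec.chrom_length)
        occupancy.values[chrom][:] = np.clip(1.0 - base_acc[chrom] + jitter, 0.0, 1.0)

    rows = []
    for gene in genes:
        if rng.random() < spec.fraction_cds_only:
            continue  # CDS-mode gene: no isoform rows
        tss = true_tss[gene.gene_id]
        modal_count = int(rng.integers(50, 200))
        rows.append((gene.gene_id, gene.chrom, tss, modal_count))
        for _ in range(int(rng.integers(0, 3))):
            sign = -1 if gene.strand == "+" else 1  # minor starts upstream
            shift = sign * int(rng.integers(5, 25))
            minor = int(rng.integers(1, max(2, modal_count // 2)))
            rows.append((gene.gene_id, gene.chrom, tss + shift, minor))
    tss_table = pd.DataFrame(rows, columns=["gene_id", "chrom", "position", "count"])

    return SimulatedGenome(
        genome=genome,
        genes=genes,
        tss_table=tss_table,
        atac_tracks=atac_tracks,
        occupancy_track=occupancy,
        divergent_pairs=divergent_pairs,
        true_tss=true_tss,
    )


# ---------------------------------------------------------------------------
# screen simulation


@dataclass
class SimScreenSpec:
    """Rates and sizes for the pooled-screen emulation.

    Defaults follow the characterized regime of barcoded yeast CRISPRi
    libraries: an average of 4 barcodes per guide, ~10% of barcodes linked
    to guides with synthesis errors, ~5% chimeric (linked to two guides),
    and ~1% guide-free scaffold-only constructs with true fitness 0.
    """

    n_guides: int = 100
    true_fitness: Optional[np.ndarray] = None  # drawn from the default mixture
    active_guide_fraction: float = 0.4  # guides with a real knock-down phenotype
    barcodes_per_guide_mean: float = 4.0
    abundance_sigma: float = 1.0  # log-normal initial-abundance spread
    depth: int = 1_000_000
    gens: tuple[float, ...] = DEFAULT_GENS
    n_cultures: int = 2
    synthesis_error_rate: float = 0.10
    chimera_rate: float = 0.05
    empty_fraction: float = 0.01
    sequencing_error_rate: float = 0.001
    low_quality_rate: float = 0.003
    reads_per_barcode_mean: float = 10.0
    low_read_fraction: float = 0.02
    barcode_length: int = 18
    seed: int = 0


@dataclass
class SimulatedScreen:
    counts: pd.DataFrame  # barcodes x samples
    meta: pd.DataFrame  # sample_id index; gens, culture columns
    truth: pd.DataFrame  # barcode-level: guide_id, true_fitness
    guide_truth: pd.DataFrame  # guide-level: true_fitness


def _draw_barcodes(rng: np.random.Generator, n: int, length: int) -> list[str]:
    seen: set[str] = set()
    out = []
    while len(out) < n:
        bc = "".join(rng.choice(BASES, size=length))
        if bc not in seen:
            seen.add(bc)
            out.append(bc)
    return out


def _screen_lineages(spec: SimScreenSpec, rng: np.random.Generator):
    """Barcoded lineages: guide assignment, true fitness, initial abundance."""
    if spec.true_fitness is None:
        # bimodal fitness in [-1, 0]: most guides are ineffective and
        # phenotypically silent (fitness exactly 0), the active minority
        # spreads down to -1; the neutral majority also anchors
        # median-of-ratios normalization, as in real screens
        active = rng.random(spec.n_guides) < spec.active_guide_fraction
        fitness = np.where(active, rng.uniform(-1.0, -0.1, spec.n_guides), 0.0)
    else:
        fitness = np.asarray(spec.true_fitness, dtype=float)
        if len(fitness) != spec.n_guides:
            raise ValueError("true_fitness length must equal n_guides")
    guide_ids = [f"guide{i + 1:04d}" for i in range(spec.n_guides)]
    n_bc = np.maximum(1, rng.poisson(spec.barcodes_per_guide_mean - 1.0,
                                     spec.n_guides) + 1)
    lineage_guides = np.repeat(np.arange(spec.n_guides), n_bc)
    n_targeting = len(lineage_guides)
    n_empty = int(round(spec.empty_fraction * n_targeting / max(1e-9, 1 - spec.empty_fraction)))
    barcode_guide = [guide_ids[i] for i in lineage_guides] + [EMPTY_GUIDE_ID] * n_empty
    barcode_fitness = np.concatenate([fitness[lineage_guides], np.zeros(n_empty)])
    barcodes = _draw_barcodes(rng, len(barcode_guide), spec.barcode_length)
    abundance = rng.lognormal(0.0, spec.abundance_sigma, len(barcode_guide))
    truth = pd.DataFrame(
        {"guide_id": barcode_guide, "true_fitness": barcode_fitness},
        index=pd.Index(barcodes, name="barcode"),
    )
    guide_truth = pd.DataFrame(
        {"true_fitness": fitness}, index=pd.Index(guide_ids, name="guide_id")
    )
    return truth, guide_truth, abundance


def lineage_frequencies(
    initial: np.ndarray, fitness: np.ndarray, gens: float
) -> np.ndarray:
    """Renormalized lineage frequencies after ``gens`` population doublings.

    Each lineage's weight scales as ``s**gens`` with ``s = 2**fitness``, so
    frequencies follow exponential competitive dynamics and sum to one.
    """
    w = np.asarray(initial, dtype=float) * np.exp2(
        np.asarray(fitness, dtype=float) * gens
    )
    return w / w.sum()


def simulate_growth_counts(spec: SimScreenSpec) -> SimulatedScreen:
    """Exponential pooled-growth trajectories with multinomial sampling.

    Initial lineage abundances are shared across replicate cultures (the
    cultures are inoculated from one transformant pool); counts are drawn
    independently per sample at the specified depth.
    """
    rng = np.random.default_rng(spec.seed)
    truth, guide_truth, abundance = _screen_lineages(spec, rng)
    fitness = truth["true_fitness"].to_numpy()
    samples, meta_rows = {}, []
    for c in range(spec.n_cultures):
        culture = f"c{c + 1}"
        for g in spec.gens:
            sample_id = f"{culture}_g{g:g}"
            freqs = lineage_frequencies(abundance, fitness, g)
            samples[sample_id] = rng.multinomial(spec.depth, freqs)
            meta_rows.append({"sample_id": sample_id, "gens": g, "culture": culture})
    counts = pd.DataFrame(samples, index=truth.index)
    meta = pd.DataFrame(meta_rows).set_index("sample_id")
    return SimulatedScreen(counts=counts, meta=meta, truth=truth,
                           guide_truth=guide_truth)


def noise_free_counts(
    fitness: Sequence[float],
    gens: Sequence[float] = DEFAULT_GENS,
    n_cultures: int = 1,
    base_count: float = 5000.0,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Deterministic count trajectories: count = base * 2**(fitness * gens).

    Relative frequencies are *not* renormalized, so a fitness of -1 halves
    a barcode's relative abundance per doubling exactly and a fitness of 0
    keeps it constant. Counts are rounded to integers.
    """
    fitness = np.asarray(fitness, dtype=float)
    samples, meta_rows = {}, []
    for c in range(n_cultures):
        culture = f"c{c + 1}"
        for g in gens:
            sample_id = f"{culture}_g{g:g}"
            samples[sample_id] = np.round(base_count * np.exp2(fitness * g)).astype(int)
            meta_rows.append({"sample_id": sample_id, "gens": g, "culture": culture})
    index = pd.Index([f"bc{i + 1:04d}" for i in range(len(fitness))], name="barcode")
    counts = pd.DataFrame(samples, index=index)
    meta = pd.DataFrame(meta_rows).set_index("sample_id")
    return counts, meta


# ---------------------------------------------------------------------------
# assignment-read simulation


def _mutate_guide(rng: np.random.Generator, seq: str) -> str:
    """One planted synthesis error: substitution or single-base insertion.

    A clean single deletion would shorten the variable region below the
    20-nt trim filter and surface as low coverage rather than a defective
    call, so deletions are not planted here (they are still exercised
    directly in the assignment rules).
    """
    pos = int(rng.integers(0, len(seq)))
    if rng.random() < 0.7:
        alt = rng.choice([b for b in "ACGT" if b != seq[pos]])
        return seq[:pos] + alt + seq[pos + 1 :]
    return seq[:pos] + str(rng.choice(BASES)) + seq[pos:]


def _sequence_read(rng, seq, error_rate, low_q_rate):
    """Apply per-base sequencing errors; return (read, quality-string)."""
    bases = list(seq)
    quals = [38] * len(bases)  # Q38 baseline
    for i in range(len(bases)):
        r = rng.random()
        if r < error_rate:
            bases[i] = str(rng.choice([b for b in "ACGT" if b != bases[i]]))
            quals[i] = 20
        elif r < error_rate + low_q_rate:
            quals[i] = 20
    return "".join(bases), "".join(chr(q + 33) for q in quals)


@dataclass
class SimulatedReads:
    r1: list[tuple[str, str, str]]  # (title, seq, qual)
    r2: list[tuple[str, str, str]]
    truth: pd.DataFrame  # barcode-indexed: guide_id, intended fate
    library: dict[str, str]  # guide_id -> sequence, incl. the empty entry


def simulate_assignment_reads(
    guides: Mapping[str, str],
    spec: SimScreenSpec,
) -> SimulatedReads:
    """Paired barcode/guide reads with planted assignment fates.

    Each barcode is linked to one guide and dealt a fate: guide-free
    (scaffold-only reads), synthesis-error (every read carries the same
    mutated guide), chimeric (reads split between two guides), low
    coverage (< 3 reads), or clean. Reads carry the real adapter
    structure and Phred+33 qualities with planted sequencing errors at Q20.
    """
    rng = np.random.default_rng(spec.seed)
    guide_ids = list(guides)
    if not guide_ids:
        raise ValueError("guide library is empty")
    library = dict(guides)
    library[EMPTY_GUIDE_ID] = EMPTY_GUIDE_SEQ
    n_bc = int(round(spec.n_guides * spec.barcodes_per_guide_mean))
    barcodes = _draw_barcodes(rng, n_bc, spec.barcode_length)
    r1, r2, rows = [], [], []
    for bc in barcodes:
        guide_id = guide_ids[int(rng.integers(0, len(guide_ids)))]
        u = rng.random()
        n_reads = int(rng.poisson(spec.reads_per_barcode_mean))
        fate = "assigned"
        read_seqs: list[str]
        if rng.random() < spec.low_read_fraction:
            n_reads = int(rng.integers(0, 3))
            fate = "insufficient"
        if u < spec.empty_fraction:
            guide_id, fate = EMPTY_GUIDE_ID, ("insufficient" if fate == "insufficient" else "empty")
            read_seqs = [EMPTY_GUIDE_SEQ] * n_reads
        elif u < spec.empty_fraction + spec.synthesis_error_rate:
            if fate != "insufficient":
                fate = "defective"
            broken = _mutate_guide(rng, library[guide_id])
            read_seqs = [broken] * n_reads
        elif u < spec.empty_fraction + spec.synthesis_error_rate + spec.chimera_rate:
            if fate != "insufficient":
                fate = "heterogeneous"
            other = guide_ids[int(rng.integers(0, len(guide_ids)))]
            while other == guide_id and len(guide_ids) > 1:
                other = guide_ids[int(rng.integers(0, len(guide_ids)))]
            read_seqs = [
                library[guide_id if rng.random() < 0.5 else other]
                for _ in range(n_reads)
            ]
        else:
            read_seqs = [library[guide_id]] * n_reads
        rows.append({"barcode": bc, "guide_id": guide_id, "fate": fate,
                     "n_reads": n_reads})
        for k, gseq in enumerate(read_seqs):
            title = f"{bc}:{k}"
            r1_seq = bc + ASSIGN_ADAPTER + _random_dna(rng, 20)
            r1_read, r1_qual = _sequence_read(
                rng, r1_seq, spec.sequencing_error_rate, spec.low_quality_rate
            )
            r2_seq = GUIDE_5_ADAPTER + gseq + GUIDE_3_ADAPTER + _random_dna(rng, 10)
            r2_read, r2_qual = _sequence_read(
                rng, r2_seq, spec.sequencing_error_rate, spec.low_quality_rate
            )
            r1.append((title, r1_read, r1_qual))
            r2.append((title, r2_read, r2_qual))
    truth = pd.DataFrame(rows).set_index("barcode")
    return SimulatedReads(r1=r1, r2=r2, truth=truth, library=library)


# ---------------------------------------------------------------------------
# efficacy-model simulation


def position_activity(offsets) -> np.ndarray:
    """Planted position-activity profile: Gaussian bump peaked at -50."""
    x = np.asarray(offsets, dtype=float)
    return np.exp(-(((x + 50.0) / 45.0) ** 2))


@dataclass
class SimulatedEfficacy:
    features: pd.DataFrame  # offset, odm, protospacer, fitness, active
    eta: np.ndarray  # true logits of the generating law
    threshold: float


def simulate_efficacy_dataset(
    n_guides: int = 2000,
    seed: int = 0,
    beta0: float = -1.5,
    beta_pos: float = 4.5,
    beta_odm: float = -3.0,
    odm_noise: float = 0.20,
    threshold: float = -0.38,
) -> SimulatedEfficacy:
    """Guides whose activity follows a planted position+occupancy logistic law.

    Offsets are uniform over the design window; occupancy tracks the
    position profile (nucleosome-free near the TSS) plus independent noise;
    activity is Bernoulli with logit ``beta0 + beta_pos * a(offset) +
    beta_odm * odm``. Fitness is drawn from a strongly negative component
    for active guides and a near-neutral one for inactive guides, on either
    side of ``threshold``, so the activity label the pipeline derives from
    fitness matches the planted one. Protospacer sequences are random and
    carry no signal.
    """
    rng = np.random.default_rng(seed)
    offsets = rng.integers(-220, 21, n_guides)
    a = position_activity(offsets)
    odm = np.clip(1.0 - 0.8 * a + rng.normal(0.0, odm_noise, n_guides), 0.0, 1.0)
    eta = beta0 + beta_pos * a + beta_odm * odm
    p = 1.0 / (1.0 + np.exp(-eta))
    active = rng.random(n_guides) < p
    fitness = np.where(
        active,
        np.clip(rng.normal(-0.75, 0.12, n_guides), -1.0, -0.45),
        np.clip(rng.normal(-0.05, 0.08, n_guides), -0.30, 0.15),
    )
    protospacers = ["".join(rng.choice(BASES, size=20)) for _ in range(n_guides)]
    features = pd.DataFrame(
        {
            "offset": offsets,
            "odm": odm,
            "protospacer": protospacers,
            "fitness": fitness,
            "active": fitness < threshold,
        },
        index=pd.Index([f"guide{i + 1:04d}" for i in range(n_guides)], name="guide_id"),
    )
    return SimulatedEfficacy(features=features, eta=eta, threshold=threshold)
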