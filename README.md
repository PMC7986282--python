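# crispri-screenkit

A toolkit for genome-scale CRISPRi screening in budding yeast, covering the
full computational stack of a barcoded pooled growth screen:

* **Guide design** — enumerate all NGG target sites in promoter windows
  around each gene's representative TSS (or CDS start when no TSS is
  annotated), classify genome-wide uniqueness and promoter specificity,
  score chromatin accessibility, and select up to ten guides per gene with
  a zone guarantee that spreads guides across the promoter.
* **Read processing** — trim and tabulate guide-linked random nucleotide
  barcodes, collapse single-substitution sequencing errors, and assign
  barcodes to guides with fate calls (assigned / empty / heterogeneous /
  defective / insufficient) that distinguish synthesis errors and chimeric
  constructs from sequencing noise.
* **Fitness inference** — per-barcode negative-binomial regression of
  counts against population doublings (`counts ~ gens + culture`, log link,
  median-of-ratios size factors), reported as the fitness score
  log<sub>2</sub> *s*: the log2 change in a lineage's relative abundance per
  population doubling. 0 is neutral; a non-replicating lineage whose
  persistent plasmid halves in frequency each generation scores −1.
  Guide-level fitness is the inverse-variance weighted mean over barcodes,
  and the active-guide threshold is the 5th percentile of scaffold-only
  negative controls.
* **Activity modeling** — a loess curve of fitness against target-center
  offset from the TSS (α = 0.25 over [−220, +20]) feeds a logistic
  regression `active ~ OffsetPred + ODM + nt01 + … + nt20` together with
  the minimum nucleosome occupancy in a 33-nt window and one-hot
  protospacer bases; evaluated by 10-fold cross-validated AUC and scored
  as logits, where logit 0 means even odds of activity.
* **Simulation** — synthetic genomes with divergent promoter pairs and
  nucleosome-free regions, assignment reads with planted error rates, and
  exponential competitive-growth count trajectories with multinomial
  sampling, so every stage is testable without external data.

## Worked example

```python
from crispri_screenkit.simulate import (SimGenomeSpec, SimScreenSpec,
                                        simulate_genome, simulate_growth_counts)
from crispri_screenkit.design import design_library
from crispri_screenkit.fitness import (filter_preinduction, fit_all_barcodes,
                                       aggregate_guides)

sim = simulate_genome(SimGenomeSpec(n_genes=12, seed=7))
library = design_library(sim.genome, sim.genes, sim.tss_table, sim.atac_tracks)
print(library.to_dataframe().head(4))
```

```
   guide_id strand          protospacer  center_offset  unique  specific  accessibility  zone  rank
gene0001_g1      + GACGACGGATATAAATAGTT           -149    True      True       0.630528     0     1
gene0001_g2      + ATCCGACATGTTCATGAATG            -70    True      True       0.899327     1     2
gene0001_g3      - AAACTCTTGGCATACGATAT            -15    True      True       0.845516     2     3
gene0001_g4      - AGCCTCATTCATGAACATGT            -68    True      True       0.898114     1     4
```

120 guides cover all 12 genes (3 ambiguous at divergent promoters). Each
gene's first three picks are the best guide in each promoter zone —
here at offsets −149, −70, and −15 — ranked by uniqueness, specificity,
then accessibility.

```python
screen = simulate_growth_counts(SimScreenSpec(n_guides=30, depth=500_000, seed=7))
kept = filter_preinduction(screen.counts, screen.meta)     # >= 64 pre-induction reads
fits = fit_all_barcodes(kept, screen.meta)                 # NB GLM per barcode
guides = aggregate_guides(fits, screen.truth["guide_id"].to_dict())
print(guides.join(screen.guide_truth).sort_values("fitness").head(4).round(3))
```

```
           fitness     se  n_barcodes  true_fitness
guide_id
guide0004   -0.830  0.003           5        -0.827
guide0011   -0.757  0.006           4        -0.759
guide0025   -0.709  0.004           5        -0.709
guide0021   -0.671  0.004           5        -0.675
```

The strongest knock-down guides are recovered within a few thousandths of
their simulated fitness (guide-level mean absolute error 0.003 at this
depth).

The same workflow is available from the shell:

```sh
crispri-screenkit sim genome --n-genes 50 --seed 1 --out-prefix toy
crispri-screenkit design --genome toy.fa --genes toy.genes.tsv \
    --tss toy.tss.tsv --atac toy.atac1.bedgraph --atac toy.atac2.bedgraph \
    --out guides.tsv
crispri-screenkit sim screen --n-guides 100 --seed 1 --out-prefix screen
crispri-screenkit fitness --counts screen.counts.tsv --meta screen.meta.tsv \
    --map screen.map.tsv --out-prefix fit
```

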