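# mapanchor

Order and orient genome assembly scaffolds into pseudomolecules by
maximizing weighted colinearity against one or more genomic maps
(genetic, optical, comparative).

Colinearity of a scaffold configuration with a map is measured as the
longest monotonic subsequence (LMS) of map positions taken in physical
order; the objective `L` is the weight-summed LMS over all maps.
Optimization runs in two phases per chromosome:

1. **Phase 1** — pairwise orientation scores assembled into a symmetric
   matrix whose leading-eigenvector signs orient the scaffolds, plus a
   travelling-salesman path over minimum pairwise marker distances
   (nearest-neighbour + 2-opt/Or-opt; an exact external solver can be
   plugged in) to order them.
2. **Phase 2** — an elitist genetic algorithm over signed permutations
   (inversion and insertion mutations, partially-mapped crossover)
   alternated with greedy single-scaffold flip passes until `L` stops
   improving.

Preprocessing partitions the problem by chromosome: the highest-weight
"pivot" map seeds one cluster per linkage group, other linkage groups
join by shared-scaffold counts, scaffolds are assigned by weighted marker
counts (exact ties are flagged chimeric and skipped), and markers with
erratic positions are dropped by a modified z-score (median/MAD) test.

Outputs are pseudomolecule FASTA, AGP v2.0, UCSC CHAIN (for liftOver), a
summary table, a consensus marker map, optional spline-based gap size
estimates, and diagnostic plots. A simulation module generates synthetic
assemblies and maps with controlled inversion/translocation errors and
scores reconstructions against the truth.

## Input formats

Markers are 4-column BED-dialect rows, one observation per line, with
column 4 encoding `<map>-<linkage_group>:<map_position>`:

```
scaffold_1   100    101    JMMale-1:31.6
```

Weights are a whitespace-separated `name weight` file (absent maps
default to weight 1):

```
OpticalMap 3
GeneticMap 2
Chickpea 1
```

## CLI

```sh
# full pipeline: preprocess -> order/orient -> genome release
mapanchor path markers.bed scaffolds.fasta -w weights.txt -o run/ \
    --seed 0 --ngen 1000 --npop 100 [--estimate-gaps] [--gap-size 100]

# convert per-map CSVs (scaffold,pos,lg,map_pos) into the marker BED
mapanchor merge MapA.csv MapB.csv -o markers.bed

# rebuild a genome release from a saved ordering
mapanchor build run/scaffold_order.tsv scaffolds.fasta --bed markers.bed -o rebuild/

# per-junction gap estimates for a saved ordering
mapanchor estimate-gaps run/scaffold_order.tsv markers.bed scaffolds.fasta -o gaps.tsv

# synthetic data with planted errors
mapanchor simulate --genome-size 366000000 --chromosomes 8 \
    --n-scaffolds 2000 --n-markers 8000 --n-maps 3 --p-inv 0.2 --p-trans 0.2 \
    --seed 0 -o simulated/

# diagnostic plots (parallel-coordinates or scatter with Pearson rho)
mapanchor plot run/scaffold_order.tsv markers.bed scaffolds.fasta chr1 \
    --style scatter -o chr1.png
```

`path` writes `genome.fasta`, `genome.agp`, `genome.chain`,
`genome.summary.tsv`, `scaffold_order.tsv`, `consensus_map.tsv` and
`preprocess_report.txt` into the output directory. Runs are fully
deterministic under `--seed`.

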