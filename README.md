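# wgdating

Detection and molecular-clock dating of whole-genome duplications (WGD) from
gene collinearity, plus tandem-duplicate detection and NBS resistance-gene
classification — the genome-evolution analyses used to resolve recursive
polyploidizations in chromosome-scale plant genomes such as tea
(*Camellia sinensis*), where a recent lineage-specific tetraploidization
(CRT, ~59 Mya) followed the core-eudicot hexaploidization (ECH, ~147 Mya).

## What it computes

Given gene models (GFF3) and coding sequences (FASTA), the pipeline:

1. finds homologous protein pairs (built-in Smith–Waterman search with a
   k-mer seed prefilter, or ingested BLAST `-outfmt 6` tables) and removes
   large gene families (>30 matches per gene);
2. chains anchors into collinear blocks by sparse dynamic programming in
   gene-order space (min 4 anchors, ≤50-gene gaps, 5-gene overlap window);
3. estimates Ks and Ka for every anchor pair with the Nei–Gojobori (1986)
   counting method on protein-guided codon alignments, with Jukes–Cantor
   correction

   `d = −(3/4)·ln(1 − (4/3)·p)`;

4. classifies blocks by median Ks (ECH if median Ks > 0.7, else CRT), fits
   the per-event Ks distribution with a Gaussian kernel, and converts the
   density peak to an age through the neutral clock

   `T = Ks / (2r)`,  `r = 3.39 × 10⁻⁹` substitutions/synonymous site/year;

5. detects tandem duplicate arrays (homologs with ≤5 intervening genes,
   merged transitively), classifies NBS genes (N/NL/CN/CNL/TN/RN) from
   supplied domain tables, and runs hypergeometric enrichment with
   Benjamini–Hochberg correction.

A bundled simulator (`wgdating.synthetic_data`) evolves a diploid ancestor
through configurable WGDs, fractionation, tandem bursts and rearrangements
under a calibrated synonymous clock, and emits FASTA + GFF3 + truth tables,
so every stage can be tested without any external data.

## Worked example

```python
from wgdating import (SimulationConfig, RunConfig, run)

sim = SimulationConfig(n_ancestral_genes=400, n_chromosomes=4,
                       wgd_times_mya=[60.0], retention_prob=0.7,
                       tandem_events=10, seed=11)
report = run(RunConfig(outdir="demo_run", simulation=sim, seed=11))
print(report["block_summary"]["n_blocks"], report["block_summary"]["n_pairs"])
print(report["dates"]["CRT"])
```

prints

```
10 282
{'ks_peak': 0.394, 'time_mya': 58.1, 'n_pairs': 282}
```

i.e. the 697-gene simulated genome yields 10 self-collinear blocks holding
282 anchor pairs, whose Ks density peaks at 0.394; at the neutral rate that
dates the duplication to 58.1 Mya — within 4% of the simulated 60 Mya, the
expected accuracy given the Ks spread of a few hundred pairs.  The same
stages run from the shell:

```bash
wgdating simulate --seed 11 --out sim/           # FASTA + GFF3 + truth tables
wgdating run --config run.yaml                   # full pipeline from YAML
wgdating concordance --markers placements.tsv    # genetic-map QC
```

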