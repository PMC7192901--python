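# Methods

## Scope and model

The package infers and dates whole-genome duplications (WGD) from a single
annotated genome: self-homology is chained into collinear blocks in
gene-order space, each anchor pair receives an NG86 synonymous distance
(Ks), blocks are assigned to polyploidization events by their median Ks,
and the per-event Ks distribution's Gaussian-kernel density peak is
converted to an age with a strict molecular clock, T = Ks/(2r).  The
underlying assumptions are the usual ones for Ks-based dating: synonymous
sites evolve neutrally and clock-like at a constant rate r, duplicates from
one polyploidization share a common age, and the Jukes–Cantor correction
adequately handles multiple hits for Ks ≲ 1.5.  Saturated pairs
(p ≥ 3/4) carry no usable signal and are excluded with an explicit status
rather than mapped to infinities.

## Parameters that matter

| parameter | default | unit | why |
|---|---|---|---|
| homology e-value | 1e-5 | — | anchor candidate threshold; acts as a rank filter |
| family filter | 30 | partners/gene | removes promiscuous families whose hits are not positional signal; applied symmetrically per gene |
| min block | 4 | anchors | smallest chain reported (MCScanX `-s`) |
| max gaps | 50 | genes | largest gap between consecutive anchors on either axis (`-m`) |
| overlap window | 5 | genes | max shared genes between two reported blocks before the lower-scoring one is dropped (`-w`) |
| chain scoring | 50/anchor, −1/gap | — | MCScanX defaults; only relative ordering matters |
| Ks threshold | 0.7 | Ks | block-median split between the recent (CRT) and ancient (ECH) event |
| clock rate r | 3.39e-9 | subs/syn site/yr | neutral rate used for all dates |
| tandem e-value | 1e-20 | — | stricter threshold for tandem homolog pairs |
| max intervening | 5 | genes | tandem proximity (order-index distance ≤ 6) |
| min codons | 30 | codons | floor for an ok Ks estimate; guards fragment alignments |

## Numerical choices

- **NG86 conventions.** Synonymous site fractions exclude mutations to stop
  codons from the denominator; multi-step codon differences average over
  all orderings of the single changes, discarding orderings that pass
  through a stop (if every ordering does, all are used).  The full 61×61
  site and pathway tables are checked exactly against an independently
  written enumeration oracle in the test suite.
- **Codon alignment.** Global protein alignment (BLOSUM62, gap open 10,
  extend 0.5) back-translated to codons; columns with gaps, stops or
  ambiguous bases are dropped.  Block medians use ok-status anchors only;
  an even count averages the two central values; blocks with <50% ok
  anchors are flagged low-support.
- **Alignment statistics.** The built-in Smith–Waterman search converts raw
  scores with fixed Karlin–Altschul constants (λ=0.267, K=0.041) and
  E = m·n·2^(−S′).  These are nominal gapped-BLOSUM62 values without
  finite-size correction; every downstream use is a threshold or rank
  filter, so only ordering matters.  An optional k-mer seed prefilter
  (5-mers, ≥2 shared) keeps all-vs-all cost proportional to the number of
  true homolog pairs.
- **Chain extraction.** Per chromosome pair, the optimal chain under the
  gap bound is found by O(n²) dynamic programming for both orientations;
  chains are extracted greedily (best first, anchors removed, repeat), so
  each anchor joins at most one block; ties break on (chromosomes,
  orientation, starting index).  Self-comparison uses each unordered pair
  once and excludes pairs within tandem proximity so arrays do not
  masquerade as blocks.
- **Peak calling.** Gaussian KDE with Silverman's bandwidth (floored at
  1e-3; overridable), evaluated on 2048 points over [0, 3]; peaks are
  interior local maxima with prominence ≥5% of the density maximum — the
  prominence floor suppresses sampling ripple while retaining genuinely
  bimodal structure.  Degenerate (constant) samples return a single
  narrow peak rather than an error.  Dates are computed from the top peak
  of each event's own anchor Ks subset; a bootstrap percentile interval
  over Ks values is available and is this package's construction, not a
  literature convention.
- **Boundary rules.** Median Ks exactly 0.7 classifies as CRT (strictly
  greater is ECH).  Cross-genome blocks attribute to a post-divergence WGD
  only when strictly more than half their anchors are best-hit pairs.
  Tandem homologs at order distance exactly 6 (five intervening genes)
  count; 7 does not.  Marker concordance removes markers with more than
  one placement by default; a `max_placements=2` switch matches the looser
  literal reading of "more than two places".

## The simulator and what it does (not) emulate

`synthetic_data` evolves a diploid ancestor of random sense-codon CDS
(uniform codon usage, ATG start, terminal stop) through a fixed-order
history: WGDs oldest-first (whole-genome copy, then instant loss of each
new duplicate with probability 1 − retention_prob), tandem bursts at times
drawn uniformly since the most recent WGD (matching the observation that
tandem expansion concentrates after the recent event), and
inversions/translocations applied to gene order.  Mutations arrive as a
Poisson process at `neutral_rate` expected substitutions per site per
year; proposals are uniform over non-stop alternatives, synonymous changes
are always accepted and nonsynonymous ones with probability omega — which
makes synonymous-site divergence match 2rt under exactly the site
definition NG86 uses.  The calibration suite verifies the measured mean Ks
is within 5% of 2rt.

Defaults (1500 ancestral genes on 5 chromosomes, 300-codon CDS, one WGD at
60 Mya, retention 0.35, omega 0.15, 40 tandem bursts of ≤3 copies, 5
inversions, 2 translocations) produce a ~2000-gene genome in seconds and
are the standing study conditions for the parameter-recovery tests; the
recovery tests themselves run at 200–400 ancestral genes, which keeps the
whole suite desk-scale while leaving hundreds of anchor pairs per event.

What the simulator does **not** model: intergenic/TE sequence and length
divergence, block-wise fractionation runs (loss is i.i.d. per duplicate),
codon-usage bias, rate variation across sites or lineages, gene
conversion, and alternative transcripts.  Passing recovery tests therefore
show the inference machinery is correct under clock-like divergence and
order-preserving rearrangement — not that real genomes satisfy those
assumptions.

## Design decisions

- One representative transcript per gene is assumed upstream (longest CDS
  if a choice must be made); internal coordinates are 1-based inclusive
  (GFF convention).
- The family filter counts distinct partners per gene after self-hit
  removal and removes pairs symmetrically — the conservative reading of a
  per-family cap.
- Self-synteny counts unordered pairs once (upper-triangle dotplot), so
  block counts are per homeologous region pair, not per copy.
- NG86 (the method behind the standard MCScanX Ks script) is used rather
  than ML codon models; saturation and short alignments are explicit
  statuses, and saturated pairs are excluded before block medians, with
  counts reported.
- Event dating uses the event-specific anchor Ks subset (CRT anchors for
  the CRT date, ECH anchors for ECH) before KDE.
- Domain scanning and coiled-coil prediction are inputs (tabular), never
  computed; KEGG-style annotation is a user-supplied mapping, so results
  do not depend on a remote database version.
- The pipeline report is Markdown plus TSVs; every reported number is
  recomputable from the stage files, and the manifest (verbatim config,
  input checksums, seed) fully determines all outputs.

## Known limitations

- Dates inherit the full uncertainty of the clock rate r; the package
  propagates only the Ks-peak sampling uncertainty (bootstrap), not rate
  uncertainty.
- The KDE peak is biased toward the mode of the *mixture*, so two events
  closer than roughly two bandwidths merge into one reported peak.
- E-values from the built-in aligner are nominal; for cross-database
  comparisons feed real BLAST tabular output instead.
- At Ks ≳ 1.5 the Jukes–Cantor correction under-corrects and saturation
  removes pairs non-randomly, so ancient-event dates are lower bounds in
  practice.
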