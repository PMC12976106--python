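# Methods

## The grouping model

Ribo-Seq contaminants are nuclease fragments of highly abundant non-coding
RNAs. A given fragmentation hotspot yields a *family* of reads sharing a
common core with ragged 5′/3′ ends, so family members are related by
substring containment: each member contains the core, and the shortest
observed member *is* (to a good approximation) the core. The grouping
algorithm exploits exactly this structure:

1. Collapse identical read sequences into unique sequences with per-sample
   counts.
2. Rank by total abundance and take the top `n_patterns` (default 10,000)
   as matching patterns.
3. Process patterns shortest-first; each pattern sweeps up every sequence
   still in the search set that contains it as an exact contiguous
   substring, the matches are eliminated, and the next shortest pattern is
   queued. Elimination makes the groups a disjoint cover of the collapsed
   reads and keeps the sweep fast.
4. Re-rank groups by total count for reporting. The group pattern (its
   shortest member, the shortest common sequence) is the recommended LNA
   target: every family member contains it, so one blocker suppresses the
   whole family.

Assumptions worth stating: matching is exact and sense-strand only (the
library chemistry is stranded; reverse-complement matching would conflate
antisense loci), `N` never matches anything, and no mismatch tolerance is
offered — a fragment family is defined by literal containment, not
homology. The search set is the *entire* collapsed pool, not just the
top-`n_patterns` slice, so low-abundance ragged variants still join their
family's group.

Determinism: all orderings are fully specified — patterns ascending by
(length, −total, sequence), selection descending by (total, sequence) —
so identical inputs give identical outputs regardless of input order. The
sweep is observationally identical to a naive grep-every-pattern reference
(the test suite checks literal equality against an independent brute-force
implementation on randomized inputs).

## Read handling and classification

Only mapped, primary, non-supplementary alignments are used, one record
per query name, with read length in [20, 30] nt inclusive (the gel
excision window; both bounds retained). Sequences are normalized to read
orientation — reverse-strand alignments are reverse-complemented back —
because grouping and probe design operate on the sequenced fragment.
Coordinates are 0-based half-open internally; GFF/GTF 1-based inclusive
coordinates are converted on load.

A read is classified by interval overlap (≥1 shared base, gene-level
features, unstranded by default since rRNA loci dominate regardless of
annotated strand): any overlap with a non-coding biotype makes the read
non-coding; mRNA requires all overlapped features to be coding; no overlap
is unassigned. Biotypes missing from both configured sets default to
non-coding with a warning — contaminant identification favors sensitivity
— and an `unknown_fallback="ambiguous"` mode reserves an explicit
ambiguous category instead. Both biotype sets are configurable.

## Probe design

Blockers alternate DNA and LNA nucleotides beginning with DNA (LNA at
every even 1-based position; odd probe lengths simply end on DNA), carry a
3′-phosphate so they cannot prime extension, and default to the antisense
orientation (reverse complement of the contaminant read); blocking either
strand of the PCR product works, so a sense option exists. Length bounds
default to [14, 20] nt — 14 is the specificity floor for a genome of
Arabidopsis scale; larger genomes may need more. For targets longer than
`max_len` the probe is the window whose GC fraction is closest to 0.5
(ties: leftmost) — a standard primer-design heuristic standing in for
melting-temperature optimization, which for LNA chemistry depends on
proprietary nearest-neighbor parameters and is deliberately out of scope.
QC flags (GC outside [0.4, 0.7], homopolymer > 4, optional exact-match
counts against a reference FASTA) are warnings, not errors.

## Reporting and evaluation conventions

- Percentages are relative to the per-sample total of reads passing the
  alignment and length filters — the denominator the analysis can actually
  see.
- The figure of merit ranks groups by cross-sample total and reports, per
  set size k, the mean over samples of the cumulative percentage of the
  top-k groups; per-sample curves are exported alongside so the mean hides
  nothing.
- "Identified contaminants" in the depletion report means the summed
  percentage of noncoding-dominant groups (matching what the heatmap's
  cumulative row shows); an `all_noncoding` definition covering every
  noncoding-classified read is available. With `shared_patterns` (default)
  the depleted arm is requantified against the undepleted arm's target
  patterns via the same shortest-first sweep, so both arms count the same
  targets even when a target is nearly absent after depletion.
- Both relative reduction (fraction of the undepleted load removed) and
  absolute reduction (percentage points of the library) are reported,
  since either reading of "reduced by X%" can be wanted.
- Gene-level preservation uses Pearson r on log2(x+1)-transformed mean
  mRNA counts per gene (mRNA-classified reads strictly over 20 nt). The
  shifted log is a deliberate, simple variance-stabilizing choice: the
  comparison is a sanity check of level/rank preservation, not a
  differential reanalysis, so a shrinkage-based regularized transform
  would add a dependency without changing the verdict.
- The qPCR helper assumes perfect doubling (efficiency 2.0) by default
  because cycle differences, not standard curves, are the input; the
  efficiency is a parameter in (1, 2].

## The simulator

The simulator generates what the pipeline consumes, with ground truth
attached: a random genome (2 chromosomes by default) carrying rRNA-like
loci and 50 protein-coding genes placed round-robin with fixed spacers (no
overlaps by construction); contaminant cores cut from the rRNA loci; and
reads emitted directly as coordinate-exact SAM plus FASTQ — no aligner in
the loop, so alignment is never a confounder in tests.

Default study conditions, chosen once as a realistic
contaminant-dominated pilot library: five cores at 30/15/8/4/2% of the
library (59% contaminant load total — heavy but unexceptional for
footprint preps), core lengths 20–26 nt, raggedness up to 2 nt per side
(so every family read stays within the 20–30 nt filter window), read
lengths 20–32 nt (the gel range is wider than the analysis filter; the
31–32 nt mRNA tail is deliberately retained and filtered downstream, which
slightly inflates contaminant *percentages* relative to planted library
*fractions* — parameter-recovery checks therefore compare against the
generated read total), 20,000 reads per sample, two replicates per arm.
Gene expression weights are lognormal(1, 1), fixed per genome so both arms
share the same expression landscape. Family sizes are multinomial in the
planted fractions; the un-extended core is always emitted at least once
per family so the recovered pattern can equal the core exactly.

In-silico depletion retains each probe-matching read (read sequence
contains the probe's binding site) with probability 1/factor (default
1000, the blocking strength a good LNA reaches in PCR), then resamples
survivors with replacement back to the original library size — the
fixed-sequencing-budget renormalization that makes mRNA yield *rise* when
contaminants are blocked. Closed-form expectation used by the tests: with
total targeted fraction f and factor F, the post-depletion contaminant
fraction is (f/F)/(1 − f + f/F).

What the simulator does not model — and therefore what passing tests do
not establish about real data: sequencing errors and quality variation,
PCR duplicates, multimapping ambiguity between paralogous rRNA loci,
soft-clipping, partial probe hybridization (depletion is all-or-nothing on
exact containment), and real secondary-structure or Tm effects on blocker
efficiency. Tests demonstrate that the algorithms recover planted structure
faithfully, not that any particular wet-lab depletion factor will be
achieved.

## Problem sizes and numerical notes

Tests and the acceptance script run the full loop at 2 × 20,000 reads per
arm with ~5,000 unique sequences surviving collapse, plus 50 randomized
grouping instances of ≤500 collapsed reads checked against the brute-force
reference — sizes at which exhaustive oracles are still practical while
exercising every code path. Percentage identities are asserted to 1e-9;
parameter recovery to ±2 percentage points (multinomial noise at n=40,000
is ~0.3 points, so this margin is dominated by model effects, not
sampling); depletion reduction to ±3 points of the closed form. Ties are
broken lexicographically everywhere a total or length ties, making every
output byte-reproducible under a fixed seed.

## Known limitations

- Grouping is O(patterns × search set) exact scanning; fine for pilot
  libraries (10–20 M reads collapse to far fewer unique sequences), not
  tuned for full-depth production runs.
- Gene assignment is genomic-interval overlap, not splice-aware; adequate
  for ≤32 nt footprints counted at gene level, wrong for junction-heavy
  use cases.
- A read overlapping coding and non-coding features counts as non-coding;
  mRNA yield is therefore conservative near snoRNA-hosting genes.
- Probe specificity checking is exact-match counting, not thermodynamic
  off-target prediction.
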