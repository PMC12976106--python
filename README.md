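# riboblock

Experiment-specific contaminant profiling and LNA blocker design for
Ribo-Seq libraries.

## The problem

Ribosome profiling sequences the ~20–32 nt mRNA fragments protected by
translating ribosomes (ribosome-protected fragments, RPFs). The nuclease
digestion that generates footprints also fragments abundant non-coding RNAs
— rRNA, tRNA, sno/snRNA — into pieces that co-purify in the same size
range and can dominate the library. Which fragments appear depends on the
organism, the growth conditions and the nuclease, so fixed commercial
depletion panels underperform; the effective strategy is to sequence a
small pilot library, identify *that experiment's* contaminants, and block
them during library amplification with locked-nucleic-acid (LNA)
oligonucleotides, which suppress amplification of their targets in a
single pipetting step with no cleanup.

`riboblock` is the analysis side of that workflow, for anyone preparing
Ribo-Seq libraries: it takes pre-aligned pilot reads (BAM/SAM, one reported
alignment per read) plus a GFF3/GTF annotation, reports the experiment's
contaminant profile, designs blocker oligos against the top targets, and —
after a depleted re-run — quantifies what the blockers achieved. A
ground-truth simulator makes the whole loop testable without sequencing
anything.

## The method

1. **Filter and classify.** Keep mapped reads of 20–30 nt (inclusive;
   matching the gel excision range) and assign each to overlapping
   annotation features, classifying it as mRNA or non-coding by feature
   biotype (any non-coding overlap wins).
2. **Collapse and group.** Collapse identical sequences into counted unique
   reads; take the 10,000 most abundant as matching patterns; then,
   shortest pattern first, sweep up every remaining sequence containing the
   pattern as an exact substring and eliminate the matches before queuing
   the next pattern. Ragged nuclease ends extend a shared core in both
   directions, so each group's pattern — its shortest member, the shortest
   common sequence — is the core, and the recommended LNA target.
3. **Report.** A per-sample percentage table of the top-10 groups with
   per-column cumulative coverage, and a figure of merit: cumulative
   percentage of reads targeted as a function of LNA set size
   (the expected payoff of each additional probe).
4. **Design.** Blockers follow the alternating architecture — DNA and LNA
   nucleotides alternating, *beginning with a DNA nucleotide* (LNA at every
   even position), minimum 14 nt, 3′-phosphorylated so the oligo cannot
   prime extension itself. Rendered in vendor notation
   (`G+CC+TG+GG+TG+TC+AC+A/3Phos/`).
5. **Evaluate.** Between undepleted and depleted arms: contaminant
   reduction (relative and in percentage points), mRNA yield change
   (fraction of mRNA-classified reads over 20 nt — at fixed sequencing
   depth, blocked contaminants free reads for mRNA), and Pearson r of
   log2(x+1)-transformed mean gene counts to confirm quantification is
   unaffected. A helper converts qPCR cycle differences into relative
   target abundance (100 · E^(Ct_control − Ct_treated)).

## Worked example

Simulate a two-arm pilot experiment (five planted contaminant cores at
30/15/8/4/2% of the library, 2 × 20,000 reads per arm, in-silico depletion
at factor 1000), then identify, design and evaluate:

```sh
riboblock simulate -o pilot --seed 1                  # undepleted pilot arm
riboblock identify pilot/manifest.tsv pilot/annotation.gff3 -o out
riboblock design out/groups.tsv -o out
riboblock simulate -o sim --seed 1 --two-arm          # adds an in-silico depleted arm
riboblock evaluate sim/manifest.tsv sim/annotation.gff3 -o out
```

which prints (numbers from this exact run):

```
simulated one arm: 2 replicate(s) x 20000 reads, 5 planted cores -> pilot
identified 5017 groups across 2 samples; top-10 cover 63.58% of reads (mean over samples)
designed 5 probes (0 groups skipped)
  LNA_Top_1: C+TA+GC+AG+TT+AT+TC+AT+TC+AA+C/3Phos/
  LNA_Top_2: G+GC+AC+CG+TT+TA+TC+TG+GA+AT+C/3Phos/
  ...
contaminants 63.21% -> 0.22% (relative reduction 99.66%); mRNA yield x2.72; gene-count r=0.9915 over 50 genes
```

Reading this: the five planted contaminant families jointly cover ~63% of
the filtered reads (59% planted, inflated slightly because some long mRNA
footprints fall outside the 20–30 nt filter window); blocking the five
recovered cores removes >99% of that load; mRNA yield nearly triples at
fixed depth; and gene-level counts remain tightly correlated between arms
(r = 0.99 over the simulator's 50 genes) — depletion does not distort
quantification.

On real data, point `identify` at a manifest of your pilot BAMs
(`sample_id  path  condition  depleted` TSV) and your organism's GFF3/GTF,
order the probes from `out/order_sheet.tsv`, and run `evaluate` on the
combined manifest after the depleted re-sequencing.

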