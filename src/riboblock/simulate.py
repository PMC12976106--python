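"""Synthetic ground-truth universe for testing the contaminant workflow.

Generates a toy genome with rRNA-like non-coding loci and protein-coding
genes, plants contaminant "cores" inside the non-coding loci, and emits
aligned reads as coordinate-exact SAM (no external aligner needed) plus
matching FASTQ.  Contaminant reads are ragged-end fragment families: each
read is its core extended by 0..raggedness nt of flanking genomic sequence
on either side, so every family member contains the core as a substring —
the structure the greedy grouping is built to recover.  The un-extended
core itself is always emitted at least once per family, so the recovered
group pattern equals the planted core exactly.

An in-silico depletion arm retains probe-matching reads with probability
1/factor and resamples survivors back to the original library size,
mimicking a fixed sequencing budget — which is what makes the mRNA yield
rise when contaminants are blocked.

Everything is driven by numpy Generators derived deterministically from the
config seed: a fixed seed reproduces byte-identical outputs.

No sequencing-error, quality or PCR-duplicate model is included.
"""

from __future__ import annotations

import json
import os
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pysam

from riboblock._seq import revcomp

_BASES = np.array(list("ACGT"))


@dataclass(frozen=True)
class SimConfig:
    """Study conditions for the synthetic universe.

    ``contaminant_cores`` entries are (core, fraction): core is either an
    explicit DNA sequence or an integer length to cut from an rRNA locus;
    fraction is the planted share of the library.  Defaults emulate a
    contaminant-dominated footprint library: five cores covering 59% of
    reads, ragged ends up to 2 nt per side, read lengths matching the gel
    excision range.
    """

    seed: int = 0
    n_chroms: int = 2
    noncoding_loci: tuple[tuple[str, int], ...] = (("rRNA", 2000), ("rRNA", 1200), ("rRNA", 600))
    n_coding_genes: int = 50
    gene_length: int = 900
    spacer: int = 150
    contaminant_cores: tuple[tuple[object, float], ...] = (
        (24, 0.30),
        (22, 0.15),
        (26, 0.08),
        (20, 0.04),
        (25, 0.02),
    )
    raggedness: int = 2
    read_len_range: tuple[int, int] = (20, 32)
    n_reads: int = 20000
    n_replicates: int = 2
    depletion_factor: float = 1000.0

    def __post_init__(self) -> None:
        total = sum(f for _, f in self.contaminant_cores)
        if total > 0.95:
            raise ValueError(f"planted fractions sum to {total:.3f} > 0.95")
        if self.raggedness < 0:
            raise ValueError("raggedness must be >= 0")
        if self.read_len_range[0] > self.read_len_range[1]:
            raise ValueError("read_len_range must be (lo, hi) with lo <= hi")


@dataclass(frozen=True)
class SimFeature:
    feature_id: str
    chrom: str
    start: int  # 0-based inclusive
    end: int  # 0-based exclusive
    strand: str
    biotype: str


@dataclass
class SimGenome:
    seqs: dict[str, str]
    features: list[SimFeature]
    gene_weights: dict[str, float]  # expression weights for coding genes

    def coding_genes(self) -> list[SimFeature]:
        return [f for f in self.features if f.biotype == "protein_coding"]

    def noncoding(self) -> list[SimFeature]:
        return [f for f in self.features if f.biotype != "protein_coding"]


@dataclass(frozen=True)
class CoreTruth:
    core_id: str
    sequence: str  # read orientation (locus strand)
    fraction: float
    chrom: str
    start: int
    end: int
    strand: str


@dataclass
class GroundTruth:
    cores: list[CoreTruth]
    provenance: dict[str, dict[str, str]] = field(default_factory=dict)  # sample -> read -> label

    def to_json(self, path: str | os.PathLike) -> None:
        payload = {
            "cores": [asdict(c) for c in self.cores],
            "provenance": self.provenance,
        }
        with open(path, "w") as fh:
            json.dump(payload, fh, indent=2, sort_keys=True)
            fh.write("\n")


@dataclass(frozen=True)
class SimRead:
    name: str
    chrom: str
    start: int
    end: int
    strand: str
    sequence: str  # read orientation
    origin: str  # "core:<id>" or "gene:<gene_id>"


def _random_seq(rng: np.random.Generator, length: int) -> str:
    return "".join(_BASES[rng.integers(0, 4, size=length)])


def simulate_genome(config: SimConfig) -> tuple[SimGenome, GroundTruth]:
    """Build the toy genome, its features, and the planted contaminant cores.

    Non-coding loci and coding genes are placed round-robin across
    chromosomes with fixed spacers, so placements never overlap.  Cores are
    cut from (or spliced into) the rRNA-like loci with enough margin for
    ragged extensions.  Fully determined by ``config.seed``.
    """
    rng = np.random.default_rng([config.seed, 0])

    # round-robin placement of features onto chromosomes
    placements: list[list[tuple[str, int]]] = [[] for _ in range(config.n_chroms)]
    items: list[tuple[str, int]] = [
        (f"rRNA{i + 1}", length) for i, (bt, length) in enumerate(config.noncoding_loci)
    ]
    items += [(f"gene{i + 1}", config.gene_length) for i in range(config.n_coding_genes)]
    for i, item in enumerate(items):
        placements[i % config.n_chroms].append(item)

    biotype_of = {f"rRNA{i + 1}": bt for i, (bt, _) in enumerate(config.noncoding_loci)}

    seqs: dict[str, str] = {}
    features: list[SimFeature] = []
    for ci, placed in enumerate(placements):
        chrom = f"chr{ci + 1}"
        cursor = config.spacer
        length = config.spacer + sum(l + config.spacer for _, l in placed)
        seq = _random_seq(rng, length)
        for fid, flen in placed:
            strand = "+" if rng.random() < 0.7 else "-"
            features.append(
                SimFeature(
                    feature_id=fid,
                    chrom=chrom,
                    start=cursor,
                    end=cursor + flen,
                    strand=strand,
                    biotype=biotype_of.get(fid, "protein_coding"),
                )
            )
            cursor += flen + config.spacer
        seqs[chrom] = seq

    # expression weights for coding genes (lognormal, fixed across samples)
    genes = [f for f in features if f.biotype == "protein_coding"]
    weights = rng.lognormal(mean=1.0, sigma=1.0, size=len(genes))
    gene_weights = {g.feature_id: float(w) for g, w in zip(genes, weights)}

    # plant cores inside non-coding loci, round-robin, with raggedness margin
    noncoding = [f for f in features if f.biotype != "protein_coding"]
    if not noncoding and config.contaminant_cores:
        raise ValueError("cannot plant contaminant cores without non-coding loci")
    margin = config.raggedness + 5
    next_free = {f.feature_id: f.start + margin for f in noncoding}
    cores: list[CoreTruth] = []
    for i, (core_spec, fraction) in enumerate(config.contaminant_cores):
        locus = noncoding[i % len(noncoding)]
        core_len = len(core_spec) if isinstance(core_spec, str) else int(core_spec)
        start = next_free[locus.feature_id]
        end = start + core_len
        if end + margin > locus.end:
            raise ValueError(
                f"locus {locus.feature_id} too short to host core {i + 1} "
                f"(need {end + margin - locus.start} nt, have {locus.end - locus.start})"
            )
        next_free[locus.feature_id] = end + margin
        if isinstance(core_spec, str):
            genomic = core_spec if locus.strand == "+" else revcomp(core_spec)
            s = seqs[locus.chrom]
            seqs[locus.chrom] = s[:start] + genomic.upper() + s[end:]
        window = seqs[locus.chrom][start:end]
        core_seq = window if locus.strand == "+" else revcomp(window)
        cores.append(
            CoreTruth(
                core_id=f"core{i + 1}",
                sequence=core_seq,
                fraction=fraction,
                chrom=locus.chrom,
                start=start,
                end=end,
                strand=locus.strand,
            )
        )
    return SimGenome(seqs=seqs, features=features, gene_weights=gene_weights), GroundTruth(
        cores=cores
    )


def simulate_reads(
    config: SimConfig,
    genome: SimGenome,
    truth: GroundTruth,
    sample_id: str,
    rng: np.random.Generator,
) -> list[SimRead]:
    """Draw one sample's reads: ragged contaminant families plus mRNA footprints.

    Family sizes follow a multinomial over the planted fractions (remainder
    = mRNA); each contaminant read extends its core by uniform 0..raggedness
    nt of flanking genomic sequence per side; mRNA footprints fall uniformly
    within a gene chosen by the genome's fixed expression weights, with
    lengths uniform in ``read_len_range``.
    """
    fractions = [c.fraction for c in truth.cores]
    probs = fractions + [1.0 - sum(fractions)]
    counts = rng.multinomial(config.n_reads, probs)

    genes = genome.coding_genes()
    gene_w = np.array([genome.gene_weights[g.feature_id] for g in genes])
    gene_p = gene_w / gene_w.sum()
    lo, hi = config.read_len_range

    reads: list[SimRead] = []
    serial = 0

    def fragment(chrom: str, start: int, end: int, strand: str, origin: str) -> SimRead:
        nonlocal serial
        serial += 1
        seq = genome.seqs[chrom][start:end]
        if strand == "-":
            seq = revcomp(seq)
        return SimRead(
            name=f"{sample_id}:r{serial:06d}",
            chrom=chrom,
            start=start,
            end=end,
            strand=strand,
            sequence=seq,
            origin=origin,
        )

    for core, n in zip(truth.cores, counts[:-1]):
        for j in range(int(n)):
            if j == 0:
                left = right = 0  # guarantee the bare core is present
            else:
                left = int(rng.integers(0, config.raggedness + 1))
                right = int(rng.integers(0, config.raggedness + 1))
            start = max(core.start - left, 0)
            end = min(core.end + right, len(genome.seqs[core.chrom]))
            reads.append(fragment(core.chrom, start, end, core.strand, f"core:{core.core_id}"))

    n_mrna = int(counts[-1])
    if n_mrna and not genes:
        raise ValueError("mRNA reads requested but the genome has no coding genes")
    if n_mrna:
        gene_idx = rng.choice(len(genes), size=n_mrna, p=gene_p)
        lengths = rng.integers(lo, hi + 1, size=n_mrna)
        offsets = rng.random(size=n_mrna)
        for gi, length, off in zip(gene_idx, lengths, offsets):
            g = genes[int(gi)]
            span = (g.end - g.start) - int(length)
            start = g.start + int(off * (span + 1))
            reads.append(
                fragment(g.chrom, start, start + int(length), g.strand, f"gene:{g.feature_id}")
            )

    truth.provenance[sample_id] = {r.name: r.origin for r in reads}
    return reads


def simulate_depletion(
    reads: list[SimRead],
    probes,
    factor: float,
    rng: np.random.Generator,
    sample_id: str | None = None,
) -> list[SimRead]:
    """Apply in-silico LNA blocking and resample to the original depth.

    A read whose sequence contains any probe's binding site (the read-sense
    sequence the probe hybridizes against) survives with probability
    1/factor; untargeted reads always survive.  Survivors are resampled
    with replacement back to the input library size, mimicking a fixed
    sequencing budget.  Resampled reads get fresh unique names.
    """
    if factor <= 1:
        raise ValueError(f"depletion factor must be > 1, got {factor}")
    sites = [p.binding_site for p in probes]
    p_keep = 1.0 / factor
    survivors = []
    for r in reads:
        if any(site in r.sequence for site in sites):
            if rng.random() < p_keep:
                survivors.append(r)
        else:
            survivors.append(r)
    if not survivors:
        return []
    idx = rng.integers(0, len(survivors), size=len(reads))
    prefix = sample_id or "depleted"
    out = []
    for i, k in enumerate(idx, start=1):
        src = survivors[int(k)]
        out.append(
            SimRead(
                name=f"{prefix}:d{i:06d}",
                chrom=src.chrom,
                start=src.start,
                end=src.end,
                strand=src.strand,
                sequence=src.sequence,
                origin=src.origin,
            )
        )
    return out


# ---------------------------------------------------------------- writers


def write_fasta(genome: SimGenome, path: str | os.PathLike, width: int = 60) -> None:
    with open(path, "w") as fh:
        for chrom in sorted(genome.seqs):
            fh.write(f">{chrom}\n")
            seq = genome.seqs[chrom]
            for i in range(0, len(seq), width):
                fh.write(seq[i : i + width] + "\n")


def write_gff3(genome: SimGenome, path: str | os.PathLike) -> None:
    with open(path, "w") as fh:
        fh.write("##gff-version 3\n")
        for chrom in sorted(genome.seqs):
            fh.write(f"##sequence-region {chrom} 1 {len(genome.seqs[chrom])}\n")
        for f in sorted(genome.features, key=lambda f: (f.chrom, f.start)):
            attrs = f"ID={f.feature_id};gene_id={f.feature_id};gene_biotype={f.biotype}"
            fh.write(
                f"{f.chrom}\triboblock_sim\tgene\t{f.start + 1}\t{f.end}\t.\t{f.strand}\t.\t{attrs}\n"
            )


def write_sam(reads: list[SimRead], genome: SimGenome, path: str | os.PathLike) -> None:
    header = {
        "HD": {"VN": "1.6", "SO": "unsorted"},
        "SQ": [{"SN": c, "LN": len(genome.seqs[c])} for c in sorted(genome.seqs)],
    }
    with pysam.AlignmentFile(str(path), "wh", header=header) as out:
        for r in reads:
            a = pysam.AlignedSegment(out.header)
            a.query_name = r.name
            a.flag = 16 if r.strand == "-" else 0
            a.reference_id = out.header.get_tid(r.chrom)
            a.reference_start = r.start
            a.mapping_quality = 255
            a.cigartuples = [(0, r.end - r.start)]
            # SAM stores reverse-strand reads in reference orientation
            a.query_sequence = r.sequence if r.strand == "+" else revcomp(r.sequence)
            out.write(a)


def write_fastq(reads: list[SimRead], path: str | os.PathLike) -> None:
    with open(path, "w") as fh:
        for r in reads:
            fh.write(f"@{r.name}\n{r.sequence}\n+\n{'I' * len(r.sequence)}\n")


@dataclass
class SimOutput:
    outdir: Path
    genome: SimGenome
    truth: GroundTruth
    fasta: Path
    gff3: Path
    manifest: Path
    sams: dict[str, Path]


def _write_manifest(path: Path, rows: list[tuple[str, str, str, bool]]) -> None:
    with open(path, "w") as fh:
        fh.write("sample_id\tpath\tcondition\tdepleted\n")
        for sid, fname, condition, depleted in rows:
            fh.write(f"{sid}\t{fname}\t{condition}\t{str(depleted).lower()}\n")


def simulate_experiment(
    config: SimConfig,
    outdir: str | os.PathLike,
    probes=None,
) -> SimOutput:
    """Write a complete synthetic experiment to ``outdir``.

    Always produces genome.fa, annotation.gff3, an undepleted arm
    (``n_replicates`` samples, SAM+FASTQ each), manifest.tsv and
    ground_truth.json.  When ``probes`` is given, an in-silico depleted arm
    (same replicate count, depletion at ``config.depletion_factor``) is
    generated too and included in the manifest.  Deterministic in
    ``config.seed``: rerunning yields byte-identical files.
    """
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    genome, truth = simulate_genome(config)
    fasta = outdir / "genome.fa"
    gff3 = outdir / "annotation.gff3"
    write_fasta(genome, fasta)
    write_gff3(genome, gff3)

    sams: dict[str, Path] = {}
    manifest_rows: list[tuple[str, str, str, bool]] = []
    for rep in range(1, config.n_replicates + 1):
        sid = f"undepleted_{rep}"
        rng = np.random.default_rng([config.seed, 1, rep])
        reads = simulate_reads(config, genome, truth, sid, rng)
        sam = outdir / f"{sid}.sam"
        write_sam(reads, genome, sam)
        write_fastq(reads, outdir / f"{sid}.fastq")
        sams[sid] = sam
        manifest_rows.append((sid, sam.name, "undepleted", False))

    if probes is not None:
        for rep in range(1, config.n_replicates + 1):
            sid = f"depleted_{rep}"
            rng = np.random.default_rng([config.seed, 2, rep])
            base = simulate_reads(config, genome, truth, sid, rng)
            depleted = simulate_depletion(
                base, probes, config.depletion_factor, rng, sample_id=sid
            )
            truth.provenance[sid] = {r.name: r.origin for r in depleted}
            sam = outdir / f"{sid}.sam"
            write_sam(depleted, genome, sam)
            write_fastq(depleted, outdir / f"{sid}.fastq")
            sams[sid] = sam
            manifest_rows.append((sid, sam.name, "depleted", True))

    manifest = outdir / "manifest.tsv"
    _write_manifest(manifest, manifest_rows)
    truth.to_json(outdir / "ground_truth.json")
    return SimOutput(
        outdir=outdir,
        genome=genome,
        truth=truth,
        fasta=fasta,
        gff3=gff3,
        manifest=manifest,
        sams=sams,
    )
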