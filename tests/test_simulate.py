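"""Synthetic universe: determinism, placement, SAM self-consistency, depletion."""

import filecmp

import numpy as np
import pysam
import pytest
from scipy import stats

from riboblock._seq import revcomp
from riboblock.design import design_probe
from riboblock.simulate import (
    SimConfig,
    simulate_depletion,
    simulate_experiment,
    simulate_genome,
    simulate_reads,
)

SMALL = SimConfig(seed=42, n_reads=2000, n_replicates=1)


@pytest.fixture(scope="module")
def small_sim(tmp_path_factory):
    return simulate_experiment(SMALL, tmp_path_factory.mktemp("sim"))


class TestGenome:
    def test_fixed_seed_reproduces_byte_identical_outputs(self, small_sim, tmp_path):
        again = simulate_experiment(SMALL, tmp_path / "again")
        for name in ["genome.fa", "annotation.gff3", "undepleted_1.sam", "undepleted_1.fastq"]:
            assert filecmp.cmp(small_sim.outdir / name, again.outdir / name, shallow=False), name

    def test_feature_counts_in_gff(self, tmp_path):
        cfg = SimConfig(
            seed=1,
            noncoding_loci=(("rRNA", 800), ("rRNA", 800)),
            n_coding_genes=50,
            contaminant_cores=((20, 0.3),),
            n_reads=10,
        )
        out = simulate_experiment(cfg, tmp_path)
        lines = [
            l for l in out.gff3.read_text().splitlines() if l and not l.startswith("#")
        ]
        assert len(lines) == 52
        assert sum("gene_biotype=rRNA" in l for l in lines) == 2

    def test_no_overlapping_placements(self, tmp_path):
        cfg = SimConfig(seed=3, n_chroms=1, n_reads=10)
        genome, truth = simulate_genome(cfg)
        # interval-overlap oracle over features and planted cores
        intervals = [(f.chrom, f.start, f.end) for f in genome.features]
        for chrom in genome.seqs:
            spans = sorted(iv[1:] for iv in intervals if iv[0] == chrom)
            for (s1, e1), (s2, e2) in zip(spans, spans[1:]):
                assert e1 <= s2
        for core in truth.cores:
            host = [
                f
                for f in genome.noncoding()
                if f.chrom == core.chrom and f.start <= core.start and core.end <= f.end
            ]
            assert len(host) == 1  # every core sits inside exactly one locus

    def test_explicit_core_sequence_is_embedded(self, tmp_path):
        core = "ACGTTGCAACGGTTAACCGGTTAA"
        cfg = SimConfig(seed=5, contaminant_cores=((core, 0.4),), n_reads=100)
        genome, truth = simulate_genome(cfg)
        assert truth.cores[0].sequence == core
        window = genome.seqs[truth.cores[0].chrom][truth.cores[0].start : truth.cores[0].end]
        assert window in (core, revcomp(core))

    def test_fraction_budget_enforced(self):
        with pytest.raises(ValueError, match="0.95"):
            SimConfig(contaminant_cores=((20, 0.5), (20, 0.5)))


class TestReads:
    def test_raggedness_zero_reads_equal_core(self, tmp_path):
        cfg = SimConfig(seed=6, raggedness=0, n_reads=500)
        genome, truth = simulate_genome(cfg)
        reads = simulate_reads(cfg, genome, truth, "s1", np.random.default_rng(0))
        cores = {c.core_id: c.sequence for c in truth.cores}
        for r in reads:
            if r.origin.startswith("core:"):
                assert r.sequence == cores[r.origin.split(":")[1]]

    def test_every_family_member_contains_its_core(self, small_sim):
        truth = small_sim.truth
        cores = {c.core_id: c.sequence for c in truth.cores}
        genome = small_sim.genome
        reads = simulate_reads(SMALL, genome, truth, "probe", np.random.default_rng(1))
        family = [r for r in reads if r.origin.startswith("core:")]
        assert family
        assert all(cores[r.origin.split(":")[1]] in r.sequence for r in family)
        bare = {r.origin for r in family if r.sequence == cores[r.origin.split(":")[1]]}
        assert bare == {f"core:{c}" for c in cores}  # un-extended core emitted per family

    def test_sam_records_match_reference(self, small_sim):
        ref = small_sim.genome.seqs
        with pysam.AlignmentFile(str(small_sim.sams["undepleted_1"]), "r") as sam:
            n = 0
            for aln in sam.fetch(until_eof=True):
                n += 1
                stored = aln.query_sequence
                slice_ = ref[aln.reference_name][aln.reference_start : aln.reference_end]
                assert stored == slice_  # stored in reference orientation
            assert n == SMALL.n_reads

    def test_planted_fraction_within_binomial_ci(self, tmp_path):
        cfg = SimConfig(seed=8, contaminant_cores=((24, 0.5),), n_reads=10000)
        genome, truth = simulate_genome(cfg)
        reads = simulate_reads(cfg, genome, truth, "s1", np.random.default_rng(2))
        observed = sum(r.origin == "core:core1" for r in reads)
        lo, hi = stats.binom.interval(0.99, cfg.n_reads, 0.5)
        assert lo <= observed <= hi

    def test_provenance_partitions_reads(self, small_sim):
        prov = small_sim.truth.provenance["undepleted_1"]
        assert len(prov) == SMALL.n_reads
        assert all(v.startswith(("core:", "gene:")) for v in prov.values())


@pytest.fixture(scope="module")
def family():
    cfg = SimConfig(seed=9, contaminant_cores=((24, 0.3),), n_reads=20000)
    genome, truth = simulate_genome(cfg)
    reads = simulate_reads(cfg, genome, truth, "s1", np.random.default_rng(3))
    probe = design_probe(truth.cores[0].sequence)
    return cfg, reads, probe


class TestDepletion:
    def test_factor_1000_drives_family_below_point1_percent(self, family):
        _, reads, probe = family
        depleted = simulate_depletion(reads, [probe], 1000.0, np.random.default_rng(4))
        frac = sum(r.origin == "core:core1" for r in depleted) / len(depleted)
        assert frac < 0.001

    def test_huge_factor_eliminates_family(self, family):
        _, reads, probe = family
        depleted = simulate_depletion(reads, [probe], 1e12, np.random.default_rng(5))
        assert len(depleted) == len(reads)  # resampled to original depth
        assert not any(r.origin == "core:core1" for r in depleted)

    def test_untargeted_gene_proportions_preserved(self, family):
        _, reads, probe = family
        depleted = simulate_depletion(reads, [probe], 1000.0, np.random.default_rng(6))

        def gene_counts(rs):
            counts = {}
            for r in rs:
                if r.origin.startswith("gene:"):
                    counts[r.origin] = counts.get(r.origin, 0) + 1
            return counts

        before = gene_counts(reads)
        after = gene_counts(depleted)
        genes = [g for g, n in before.items() if n >= 20]
        obs = np.array([after.get(g, 0) for g in genes], dtype=float)
        exp = np.array([before[g] for g in genes], dtype=float)
        exp = exp / exp.sum() * obs.sum()
        chi2 = ((obs - exp) ** 2 / exp).sum()
        p = stats.chi2.sf(chi2, df=len(genes) - 1)
        assert p > 1e-3

    def test_factor_validated(self, family):
        _, reads, probe = family
        with pytest.raises(ValueError):
            simulate_depletion(reads, [probe], 1.0, np.random.default_rng(7))
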