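"""Shared fixtures: hand-written SAM/GFF builders and helper constructors."""

from __future__ import annotations

import pytest

from riboblock.annotate import ReadClass
from riboblock.io_align import AlignedRead

SAM_HEADER = "@HD\tVN:1.6\tSO:unsorted\n@SQ\tSN:chr1\tLN:100000\n@SQ\tSN:chr2\tLN:100000\n"


def make_read(
    seq: str,
    sample: str = "s1",
    name: str | None = None,
    chrom: str = "chr1",
    start: int = 0,
    strand: str = "+",
) -> AlignedRead:
    return AlignedRead(
        query_name=name or f"r_{sample}_{chrom}_{start}_{strand}_{seq[:6]}",
        sequence=seq,
        chrom=chrom,
        start=start,
        end=start + len(seq),
        strand=strand,
        sample_id=sample,
    )


def make_class(
    seq: str,
    sample: str = "s1",
    category: str = "unassigned",
    biotypes: tuple[str, ...] = (),
    gene_ids: tuple[str, ...] = (),
    **read_kwargs,
) -> ReadClass:
    return ReadClass(
        read=make_read(seq, sample=sample, **read_kwargs),
        assigned_features=gene_ids,
        category=category,
        biotypes=biotypes,
        gene_ids=gene_ids,
    )


@pytest.fixture
def sam_factory(tmp_path):
    """Write a SAM file from (name, flag, chrom, pos1, seq) tuples."""

    def _write(records, filename="reads.sam"):
        path = tmp_path / filename
        lines = [SAM_HEADER.rstrip("\n")]
        for name, flag, chrom, pos1, seq in records:
            lines.append(
                f"{name}\t{flag}\t{chrom}\t{pos1}\t255\t{len(seq)}M\t*\t0\t0\t{seq}\t*"
            )
        path.write_text("\n".join(lines) + "\n")
        return path

    return _write


@pytest.fixture
def gff3_factory(tmp_path):
    """Write a GFF3 from (chrom, type, start1, end1, strand, attrs) tuples."""

    def _write(records, filename="annot.gff3"):
        path = tmp_path / filename
        lines = ["##gff-version 3"]
        for chrom, ftype, start1, end1, strand, attrs in records:
            lines.append(f"{chrom}\ttest\t{ftype}\t{start1}\t{end1}\t.\t{strand}\t.\t{attrs}")
        path.write_text("\n".join(lines) + "\n")
        return path

    return _write
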