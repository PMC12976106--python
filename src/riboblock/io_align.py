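"""Load aligned footprint reads from BAM/SAM with the 20-30 nt length filter.

Alignments are expected one-reported-alignment-per-read (as produced by a
STAR run with ``--outSAMmultNmax 1``), but the loader is defensive: it skips
secondary and supplementary records and keeps only the first primary
alignment per query name, so BAMs produced with other settings remain safe
inputs.

Sequences are normalized to *read orientation* (as sequenced): reverse-strand
alignments are reverse-complemented back, because substring grouping and
probe design operate on the sequenced fragment, not the reference strand.
Coordinates are 0-based half-open throughout (BAM convention).
"""

from __future__ import annotations

import csv
import logging
import os
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable

import pysam

from riboblock._seq import VALID_BASES, revcomp

logger = logging.getLogger(__name__)

MANIFEST_COLUMNS = ("sample_id", "path", "condition", "depleted")

_TRUE_STRINGS = {"true", "1", "yes", "t", "y"}
_FALSE_STRINGS = {"false", "0", "no", "f", "n"}


@dataclass(frozen=True)
class ManifestEntry:
    sample_id: str
    path: Path
    condition: str
    depleted: bool


@dataclass
class SampleManifest:
    """Ordered list of samples: id, alignment file, condition, depleted flag."""

    entries: list[ManifestEntry] = field(default_factory=list)

    def __len__(self) -> int:
        return len(self.entries)

    def __iter__(self):
        return iter(self.entries)

    @property
    def sample_ids(self) -> list[str]:
        return [e.sample_id for e in self.entries]

    def arm(self, depleted: bool) -> list[ManifestEntry]:
        return [e for e in self.entries if e.depleted == depleted]


@dataclass(frozen=True)
class AlignedRead:
    """One aligned footprint, sequence in read orientation (as sequenced)."""

    query_name: str
    sequence: str
    chrom: str
    start: int  # 0-based inclusive
    end: int  # 0-based exclusive
    strand: str  # '+' or '-'
    sample_id: str

    def __post_init__(self) -> None:
        if self.end <= self.start:
            raise ValueError(
                f"read {self.query_name}: end ({self.end}) must exceed start ({self.start})"
            )
        if not set(self.sequence) <= VALID_BASES:
            bad = set(self.sequence) - VALID_BASES
            raise ValueError(f"read {self.query_name}: invalid bases {sorted(bad)}")

    def __len__(self) -> int:
        return len(self.sequence)


def _parse_bool(value: str, row_num: int) -> bool:
    v = value.strip().lower()
    if v in _TRUE_STRINGS:
        return True
    if v in _FALSE_STRINGS:
        return False
    raise ValueError(f"manifest row {row_num}: cannot interpret depleted={value!r} as boolean")


def load_manifest(path: str | os.PathLike) -> SampleManifest:
    """Read a TSV/CSV sample manifest with columns sample_id, path, condition, depleted.

    Relative alignment paths are resolved against the manifest's directory.
    Raises ``ValueError`` on duplicate sample ids and ``FileNotFoundError``
    (naming the offending row) when an alignment file is missing.
    """
    path = Path(path)
    with open(path, newline="") as handle:
        sniff = handle.readline()
        delimiter = "\t" if "\t" in sniff else ","
        handle.seek(0)
        reader = csv.DictReader(handle, delimiter=delimiter)
        if reader.fieldnames is None:
            raise ValueError(f"{path}: empty manifest (no header)")
        missing = set(MANIFEST_COLUMNS) - set(reader.fieldnames)
        if missing:
            raise ValueError(f"{path}: manifest missing columns {sorted(missing)}")
        entries: list[ManifestEntry] = []
        seen: set[str] = set()
        for row_num, row in enumerate(reader, start=2):
            sid = row["sample_id"].strip()
            if sid in seen:
                raise ValueError(f"{path}: duplicate sample_id {sid!r} at row {row_num}")
            seen.add(sid)
            align_path = Path(row["path"].strip())
            if not align_path.is_absolute():
                align_path = path.parent / align_path
            if not align_path.is_file():
                raise FileNotFoundError(
                    f"{path} row {row_num} (sample {sid!r}): alignment file not found: {align_path}"
                )
            entries.append(
                ManifestEntry(
                    sample_id=sid,
                    path=align_path,
                    condition=row["condition"].strip(),
                    depleted=_parse_bool(row["depleted"], row_num),
                )
            )
    if not entries:
        logger.warning("%s: manifest contains a header but no samples", path)
    return SampleManifest(entries=entries)


def load_reads(
    path: str | os.PathLike,
    sample_id: str,
    min_len: int = 20,
    max_len: int = 30,
) -> list[AlignedRead]:
    """Load mapped primary alignments whose read length is within [min_len, max_len].

    Both bounds are inclusive (a 20 nt and a 30 nt read are both retained
    under the defaults).  One record is kept per query name (first primary
    alignment wins); secondary and supplementary alignments are skipped.
    Reverse-strand alignments are reverse-complemented back to read
    orientation.  Reads containing N are retained — they simply cannot
    substring-match across the N downstream.
    """
    if min_len > max_len:
        raise ValueError(f"min_len ({min_len}) must not exceed max_len ({max_len})")
    path = str(path)
    mode = "rb" if path.endswith(".bam") else "r"
    reads: list[AlignedRead] = []
    seen_names: set[str] = set()
    n_records = 0
    with pysam.AlignmentFile(path, mode, check_sq=False) as bam:
        for aln in bam.fetch(until_eof=True):
            n_records += 1
            if aln.is_unmapped or aln.is_secondary or aln.is_supplementary:
                continue
            if aln.query_name in seen_names:
                continue
            seq = aln.query_sequence
            if seq is None:
                raise ValueError(
                    f"{path}: alignment {aln.query_name} has no sequence (SEQ '*'); "
                    "sequences are required for substring grouping"
                )
            if not (min_len <= len(seq) <= max_len):
                seen_names.add(aln.query_name)
                continue
            seq = seq.upper()
            if aln.is_reverse:
                # SAM stores reverse-strand reads in reference orientation
                seq = revcomp(seq)
            if "N" in seq:
                logger.debug("read %s contains N; retained", aln.query_name)
            seen_names.add(aln.query_name)
            reads.append(
                AlignedRead(
                    query_name=aln.query_name,
                    sequence=seq,
                    chrom=aln.reference_name,
                    start=aln.reference_start,
                    end=aln.reference_end,
                    strand="-" if aln.is_reverse else "+",
                    sample_id=sample_id,
                )
            )
    if n_records and not reads:
        logger.warning("%s: no mapped reads passed the %d-%d nt filter", path, min_len, max_len)
    return reads


def load_all_reads(
    manifest: SampleManifest, min_len: int = 20, max_len: int = 30
) -> dict[str, list[AlignedRead]]:
    """Load reads for every manifest sample, keyed by sample_id."""
    return {
        e.sample_id: load_reads(e.path, e.sample_id, min_len=min_len, max_len=max_len)
        for e in manifest
    }
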