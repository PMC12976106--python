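"""GFF3/GTF parsing, interval indexing, and read biotype classification.

Reads are assigned to overlapping annotation features (>=1 shared base) and
classified as mRNA or non-coding.  Because the contaminants of interest are
non-coding fragments, classification is deliberately conservative about
calling a read mRNA: any overlap with a non-coding feature makes the read
non-coding, and biotypes absent from both configured sets default to
non-coding (with a warning) so that contaminant identification favors
sensitivity.
"""

from __future__ import annotations

import logging
import os
from dataclasses import dataclass, field
from collections import defaultdict

from gffutils.feature import feature_from_line
from intervaltree import IntervalTree

from riboblock.io_align import AlignedRead

logger = logging.getLogger(__name__)

#: feature types indexed at gene level
GENE_FEATURE_TYPES = {"gene", "ncRNA_gene", "pseudogene", "transposable_element_gene"}
EXON_FEATURE_TYPES = {"exon"}

DEFAULT_NONCODING_BIOTYPES = frozenset(
    {
        "rRNA",
        "tRNA",
        "snoRNA",
        "snRNA",
        "miRNA",
        "ncRNA",
        "lncRNA",
        "antisense_long_noncoding_rna",
        "novel_transcribed_region",
    }
)
DEFAULT_CODING_BIOTYPES = frozenset({"protein_coding", "mRNA", "CDS"})

_BIOTYPE_ATTR_KEYS = ("gene_biotype", "biotype", "gene_type", "transcript_biotype")
_GENE_ID_ATTR_KEYS = ("gene_id", "ID", "Name")

CATEGORY_MRNA = "mRNA"
CATEGORY_NONCODING = "noncoding"
CATEGORY_UNASSIGNED = "unassigned"
CATEGORY_AMBIGUOUS = "ambiguous"
CATEGORIES = (CATEGORY_MRNA, CATEGORY_NONCODING, CATEGORY_UNASSIGNED, CATEGORY_AMBIGUOUS)


@dataclass(frozen=True)
class BiotypeConfig:
    """Which biotypes count as coding vs non-coding, and the unknown fallback.

    ``unknown_fallback`` is either ``"noncoding"`` (default: unknown biotypes
    are treated as contaminant-origin, logged once) or ``"ambiguous"``
    (reads overlapping only unknown-biotype features get the ambiguous
    category).
    """

    coding_biotypes: frozenset[str] = DEFAULT_CODING_BIOTYPES
    noncoding_biotypes: frozenset[str] = DEFAULT_NONCODING_BIOTYPES
    unknown_fallback: str = "noncoding"

    def __post_init__(self) -> None:
        overlap = set(self.coding_biotypes) & set(self.noncoding_biotypes)
        if overlap:
            raise ValueError(f"biotypes in both coding and noncoding sets: {sorted(overlap)}")
        if self.unknown_fallback not in ("noncoding", "ambiguous"):
            raise ValueError(f"unknown_fallback must be 'noncoding' or 'ambiguous', got {self.unknown_fallback!r}")

    def is_noncoding(self, biotype: str) -> bool:
        if biotype in self.noncoding_biotypes:
            return True
        if biotype in self.coding_biotypes:
            return False
        return self.unknown_fallback == "noncoding"

    def is_known(self, biotype: str) -> bool:
        return biotype in self.noncoding_biotypes or biotype in self.coding_biotypes


@dataclass(frozen=True)
class FeatureRecord:
    """One annotation feature in 0-based half-open coordinates."""

    feature_id: str
    chrom: str
    start: int  # 0-based inclusive
    end: int  # 0-based exclusive
    strand: str  # '+', '-' or '.'
    biotype: str
    gene_id: str
    level: str = "gene"  # 'gene' or 'exon'

    def __post_init__(self) -> None:
        if self.end <= self.start:
            raise ValueError(f"feature {self.feature_id}: end must exceed start")
        if not self.biotype:
            raise ValueError(f"feature {self.feature_id}: empty biotype")


@dataclass
class AnnotationIndex:
    """Per-chromosome interval trees over features, plus the biotype config."""

    features: list[FeatureRecord]
    config: BiotypeConfig = field(default_factory=BiotypeConfig)
    _trees: dict[tuple[str, str], IntervalTree] = field(default_factory=dict, repr=False)

    def __post_init__(self) -> None:
        if not self._trees:
            trees: dict[tuple[str, str], IntervalTree] = defaultdict(IntervalTree)
            for feat in self.features:
                trees[(feat.chrom, feat.level)].addi(feat.start, feat.end, feat)
            self._trees = dict(trees)

    @property
    def chroms(self) -> set[str]:
        return {f.chrom for f in self.features}

    def query(
        self, chrom: str, start: int, end: int, level: str = "gene", strand: str | None = None
    ) -> list[FeatureRecord]:
        """Features overlapping [start, end) by >=1 base, optionally strand-matched."""
        tree = self._trees.get((chrom, level))
        if tree is None:
            return []
        hits = [iv.data for iv in tree.overlap(start, end)]
        if strand is not None:
            hits = [f for f in hits if f.strand == strand or f.strand == "."]
        return sorted(hits, key=lambda f: (f.start, f.end, f.feature_id))


@dataclass(frozen=True)
class ReadClass:
    """A read with its overlapping features and mRNA/non-coding category."""

    read: AlignedRead
    assigned_features: tuple[str, ...]
    category: str
    biotypes: tuple[str, ...] = ()
    gene_ids: tuple[str, ...] = ()


def _extract_attr(attributes, keys) -> str | None:
    for key in keys:
        if key in attributes:
            values = attributes[key]
            if values:
                return values[0]
    return None


def load_annotation(
    path: str | os.PathLike, config: BiotypeConfig | None = None
) -> AnnotationIndex:
    """Parse a GFF3 or GTF file into an interval-indexed annotation.

    The dialect is auto-detected from the attribute column.  GFF/GTF 1-based
    inclusive coordinates are converted to 0-based half-open.  Biotype comes
    from gene_biotype/biotype/gene_type attributes, falling back to the
    feature type column.  Raises ``ValueError`` (with line number) on an
    unparseable line and on an annotation with no indexable features.
    """
    config = config or BiotypeConfig()
    features: list[FeatureRecord] = []
    unknown_biotypes: set[str] = set()
    with open(path) as handle:
        for line_num, line in enumerate(handle, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            if len(line.split("\t")) < 9:
                raise ValueError(
                    f"{path}:{line_num}: cannot parse annotation line: expected 9 "
                    f"tab-separated columns, got {len(line.split(chr(9)))}"
                )
            try:
                feat = feature_from_line(line)
            except Exception as exc:
                raise ValueError(f"{path}:{line_num}: cannot parse annotation line: {exc}") from exc
            if feat.featuretype in GENE_FEATURE_TYPES:
                level = "gene"
            elif feat.featuretype in EXON_FEATURE_TYPES:
                level = "exon"
            else:
                continue
            biotype = _extract_attr(feat.attributes, _BIOTYPE_ATTR_KEYS) or feat.featuretype
            gene_id = _extract_attr(feat.attributes, _GENE_ID_ATTR_KEYS) or f"line{line_num}"
            feature_id = _extract_attr(feat.attributes, ("ID", "gene_id")) or gene_id
            if not config.is_known(biotype):
                unknown_biotypes.add(biotype)
            features.append(
                FeatureRecord(
                    feature_id=feature_id,
                    chrom=feat.seqid,
                    start=feat.start - 1,  # GFF is 1-based inclusive
                    end=feat.end,
                    strand=feat.strand or ".",
                    biotype=biotype,
                    gene_id=gene_id,
                    level=level,
                )
            )
    if not features:
        raise ValueError(f"{path}: no gene- or exon-level features found")
    if unknown_biotypes:
        logger.warning(
            "%s: biotypes not in configured coding/noncoding sets (classified as %s): %s",
            path,
            config.unknown_fallback,
            sorted(unknown_biotypes),
        )
    return AnnotationIndex(features=features, config=config)


def _categorize(biotypes: list[str], config: BiotypeConfig) -> str:
    if not biotypes:
        return CATEGORY_UNASSIGNED
    if any(b in config.noncoding_biotypes for b in biotypes):
        return CATEGORY_NONCODING
    if all(b in config.coding_biotypes for b in biotypes):
        return CATEGORY_MRNA
    # some unknown biotype present; mRNA stays reserved for all-coding reads
    if config.unknown_fallback == "noncoding":
        return CATEGORY_NONCODING
    return CATEGORY_AMBIGUOUS


def classify_reads(
    reads: list[AlignedRead],
    index: AnnotationIndex,
    stranded: bool = False,
    level: str = "gene",
) -> list[ReadClass]:
    """Assign each read to overlapping features and categorize it.

    A read overlapping any non-coding feature is classified non-coding
    (precedence rule); mRNA requires that every overlapped feature is coding.
    Reads on chromosomes absent from the annotation become unassigned, with
    one summary warning.
    """
    config = index.config
    known_chroms = index.chroms
    missing_chroms: set[str] = set()
    out: list[ReadClass] = []
    for read in reads:
        if read.chrom not in known_chroms:
            missing_chroms.add(read.chrom)
            out.append(ReadClass(read=read, assigned_features=(), category=CATEGORY_UNASSIGNED))
            continue
        hits = index.query(
            read.chrom, read.start, read.end, level=level, strand=read.strand if stranded else None
        )
        biotypes = [f.biotype for f in hits]
        out.append(
            ReadClass(
                read=read,
                assigned_features=tuple(f.feature_id for f in hits),
                category=_categorize(biotypes, config),
                biotypes=tuple(biotypes),
                gene_ids=tuple(dict.fromkeys(f.gene_id for f in hits)),
            )
        )
    if missing_chroms:
        logger.warning(
            "%d reads on chromosomes absent from the annotation (unassigned): %s",
            sum(1 for rc in out if rc.read.chrom in missing_chroms),
            sorted(missing_chroms),
        )
    return out


def classification_summary(classes: list[ReadClass], sample_id: str | None = None):
    """Per-category read counts and fractions as a pandas DataFrame."""
    import pandas as pd

    total = len(classes)
    rows = []
    counts = defaultdict(int)
    for rc in classes:
        counts[rc.category] += 1
    for cat in CATEGORIES:
        rows.append(
            {
                "sample_id": sample_id if sample_id is not None else "all",
                "category": cat,
                "read_count": counts[cat],
                "fraction": counts[cat] / total if total else 0.0,
            }
        )
    return pd.DataFrame(rows)
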