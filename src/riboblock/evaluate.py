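"""Depletion performance evaluation between undepleted and depleted arms.

Quantifies what an LNA blocker set achieved: how much the identified
contaminant load dropped, how much the yield of coding-origin footprints
rose (at fixed sequencing depth, blocking contaminants frees reads for
mRNA), and whether gene-level quantification was preserved (Pearson r of
log-transformed mean gene counts between arms).  A small qPCR helper
converts cycle-threshold differences into relative target abundance.
"""

from __future__ import annotations

import json
import math
import os
from collections import defaultdict
from dataclasses import dataclass, asdict

import numpy as np
import pandas as pd
from scipy import stats

from riboblock.aggregate import AggregationResult, CollapsedRead
from riboblock.annotate import CATEGORY_MRNA, CATEGORY_NONCODING, ReadClass


@dataclass
class DepletionReport:
    """Paired undepleted/depleted metrics."""

    contaminant_pct_undepleted: float
    contaminant_pct_depleted: float
    relative_reduction_pct: float
    absolute_reduction_points: float
    mrna_pct_undepleted: float | None = None
    mrna_pct_depleted: float | None = None
    mrna_yield_ratio: float | None = None
    gene_correlation: float | None = None
    n_genes: int | None = None
    contaminant_definition: str = "grouped"

    def to_json(self, path: str | os.PathLike, extra: dict | None = None) -> None:
        payload = asdict(self)
        if extra:
            payload.update(extra)
        with open(path, "w") as fh:
            json.dump(payload, fh, indent=2, sort_keys=True)
            fh.write("\n")


def requantify_patterns(
    patterns: list[str], collapsed: list[CollapsedRead]
) -> dict[str, dict[str, int]]:
    """Count reads matching a fixed pattern set, greedy shortest-first with elimination.

    Mirrors the grouping sweep but against externally supplied patterns
    (which need not occur in this library), so the same targets can be
    quantified in a depleted arm.  Returns pattern -> per-sample counts.
    """
    order = sorted(set(patterns), key=lambda p: (len(p), p))
    remaining = sorted(collapsed, key=lambda r: (-r.total, r.sequence))
    out: dict[str, dict[str, int]] = {}
    for pat in order:
        counts: dict[str, int] = defaultdict(int)
        kept = []
        for r in remaining:
            if pat in r.sequence:
                for sid, n in r.counts.items():
                    counts[sid] += n
            else:
                kept.append(r)
        remaining = kept
        out[pat] = dict(counts)
    return out


def _noncoding_groups(result: AggregationResult):
    return [g for g in result.groups if g.dominant_category == CATEGORY_NONCODING]


def _mean_pct(per_sample_counts: dict[str, int], totals: dict[str, int]) -> float:
    return float(
        np.mean([100.0 * per_sample_counts.get(s, 0) / t for s, t in sorted(totals.items())])
    )


def _arm_contaminant_pct(
    result: AggregationResult, totals: dict[str, int], definition: str
) -> float:
    if definition == "all_noncoding":
        counts: dict[str, int] = defaultdict(int)
        for r in result.all_collapsed():
            if r.category == CATEGORY_NONCODING:
                for sid, n in r.counts.items():
                    counts[sid] += n
        return _mean_pct(counts, totals)
    counts = defaultdict(int)
    for g in _noncoding_groups(result):
        for sid, n in g.counts.items():
            counts[sid] += n
    return _mean_pct(counts, totals)


def depletion_metrics(
    undepleted: tuple[AggregationResult, dict[str, int]],
    depleted: tuple[AggregationResult, dict[str, int]],
    shared_patterns: bool = True,
    definition: str = "grouped",
) -> DepletionReport:
    """Contaminant percentage per arm and the reduction achieved by depletion.

    The contaminant percentage is the summed percentage of
    noncoding-dominant groups, averaged over the samples of each arm
    (``definition="all_noncoding"`` broadens this to every
    noncoding-classified read).  With ``shared_patterns`` (default) the
    depleted arm is requantified against the undepleted arm's noncoding
    patterns so both arms count the same targets.  Reports both relative
    reduction (percent of the undepleted load removed) and absolute
    reduction (percentage points of the library).
    """
    if definition not in ("grouped", "all_noncoding"):
        raise ValueError(f"definition must be 'grouped' or 'all_noncoding', got {definition!r}")
    undep_result, undep_totals = undepleted
    dep_result, dep_totals = depleted

    undep_pct = _arm_contaminant_pct(undep_result, undep_totals, definition)

    if shared_patterns and definition == "grouped":
        patterns = [g.pattern for g in _noncoding_groups(undep_result)]
        requant = requantify_patterns(patterns, dep_result.all_collapsed())
        counts: dict[str, int] = defaultdict(int)
        for per_sample in requant.values():
            for sid, n in per_sample.items():
                counts[sid] += n
        dep_pct = _mean_pct(counts, dep_totals)
    else:
        dep_pct = _arm_contaminant_pct(dep_result, dep_totals, definition)

    if undep_pct > 0:
        relative = 100.0 * (1.0 - dep_pct / undep_pct)
    else:
        relative = 0.0
    return DepletionReport(
        contaminant_pct_undepleted=undep_pct,
        contaminant_pct_depleted=dep_pct,
        relative_reduction_pct=relative,
        absolute_reduction_points=undep_pct - dep_pct,
        contaminant_definition=definition,
    )


def _arm_mrna_pct(classes_by_sample: dict[str, list[ReadClass]], min_len_exclusive: int) -> float:
    pcts = []
    for sid in sorted(classes_by_sample):
        classes = classes_by_sample[sid]
        total = len(classes)
        n_mrna = sum(
            1
            for rc in classes
            if rc.category == CATEGORY_MRNA and len(rc.read.sequence) > min_len_exclusive
        )
        pcts.append(100.0 * n_mrna / total if total else 0.0)
    return float(np.mean(pcts))


def mrna_yield(
    undepleted: dict[str, list[ReadClass]],
    depleted: dict[str, list[ReadClass]],
    min_len_exclusive: int = 20,
) -> tuple[float, float, float]:
    """mRNA-footprint yield per arm and the depleted/undepleted ratio.

    An mRNA footprint here is an mRNA-classified read strictly longer than
    ``min_len_exclusive`` nt (a 20 nt read is excluded under the default).
    Percentages are relative to per-sample filtered totals, averaged within
    each arm.  Raises ``ValueError`` if the undepleted arm has no mRNA reads.
    """
    undep_pct = _arm_mrna_pct(undepleted, min_len_exclusive)
    dep_pct = _arm_mrna_pct(depleted, min_len_exclusive)
    if undep_pct == 0:
        raise ValueError(
            "undepleted arm contains no mRNA reads above the length cutoff; "
            "cannot form a yield ratio"
        )
    return undep_pct, dep_pct, dep_pct / undep_pct


def gene_counts(
    classes_by_sample: dict[str, list[ReadClass]], min_len_exclusive: int = 20
) -> pd.Series:
    """Mean mRNA-read count per gene, averaged across the arm's replicates.

    Only mRNA-classified reads strictly longer than ``min_len_exclusive``
    contribute; a read overlapping several coding genes counts once toward
    each (rare for short footprints).
    """
    per_sample: dict[str, dict[str, int]] = {}
    for sid, classes in classes_by_sample.items():
        counts: dict[str, int] = defaultdict(int)
        for rc in classes:
            if rc.category != CATEGORY_MRNA or len(rc.read.sequence) <= min_len_exclusive:
                continue
            for gid in rc.gene_ids:
                counts[gid] += 1
        per_sample[sid] = counts
    frame = pd.DataFrame(per_sample).fillna(0.0)
    return frame.mean(axis=1).sort_index()


def gene_correlation(
    undepleted_counts: pd.Series | dict[str, float],
    depleted_counts: pd.Series | dict[str, float],
) -> tuple[float, int]:
    """Pearson r of log2(count+1) mean gene counts between arms.

    A shifted-log transform stabilizes the count scale before correlating;
    genes with zero counts in both arms are dropped.  Requires at least 3
    genes.  Returns (r, n_genes).
    """
    undep = pd.Series(undepleted_counts, dtype=float)
    dep = pd.Series(depleted_counts, dtype=float)
    genes = undep.index.union(dep.index)
    u = undep.reindex(genes, fill_value=0.0)
    d = dep.reindex(genes, fill_value=0.0)
    keep = (u > 0) | (d > 0)
    u, d = u[keep], d[keep]
    if len(u) < 3:
        raise ValueError(f"need >= 3 genes with nonzero counts, got {len(u)}")
    r, _ = stats.pearsonr(np.log2(u + 1.0), np.log2(d + 1.0))
    return float(r), int(len(u))


def qpcr_abundance(ct_treated: float, ct_control: float, efficiency: float = 2.0) -> float:
    """Relative target abundance (%) from a qPCR cycle-threshold difference.

    100 * efficiency**(ct_control - ct_treated): one extra cycle in the
    treated sample halves the apparent abundance at perfect efficiency.
    """
    if not (1.0 < efficiency <= 2.0):
        raise ValueError(f"amplification efficiency must be in (1, 2], got {efficiency}")
    return 100.0 * efficiency ** (ct_control - ct_treated)


def evaluate_arms(
    undep_classes: dict[str, list[ReadClass]],
    dep_classes: dict[str, list[ReadClass]],
    n_patterns: int = 10000,
    scope: str = "all",
    shared_patterns: bool = True,
    min_len_exclusive: int = 20,
) -> DepletionReport:
    """Full two-arm evaluation: aggregation per arm, then all report fields."""
    from riboblock.aggregate import run_aggregation

    undep_result, undep_totals = run_aggregation(undep_classes, n_patterns=n_patterns, scope=scope)
    dep_result, dep_totals = run_aggregation(dep_classes, n_patterns=n_patterns, scope=scope)
    report = depletion_metrics(
        (undep_result, undep_totals), (dep_result, dep_totals), shared_patterns=shared_patterns
    )
    u_pct, d_pct, ratio = mrna_yield(undep_classes, dep_classes, min_len_exclusive)
    report.mrna_pct_undepleted = u_pct
    report.mrna_pct_depleted = d_pct
    report.mrna_yield_ratio = ratio
    try:
        r, n = gene_correlation(
            gene_counts(undep_classes, min_len_exclusive),
            gene_counts(dep_classes, min_len_exclusive),
        )
        report.gene_correlation = r
        report.n_genes = n
    except ValueError:
        report.gene_correlation = math.nan
        report.n_genes = 0
    return report
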