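"""Collapse reads and group them by greedy substring containment.

This is the heart of the contaminant-identification workflow.  Identical
read sequences are collapsed into counted unique sequences; the most
abundant are selected as matching patterns; and the patterns are consumed
shortest-first: each pattern sweeps up every remaining sequence that
contains it as an exact contiguous substring, the matched sequences are
eliminated from the search set, and the next shortest pattern is queued.
Because ragged nuclease ends extend a common core in both directions, the
shortest member of each group is the shared core — the recommended LNA
target sequence.

Matching is exact, sense-strand only (the library is stranded), and N never
matches anything.  All tie-breaks are fixed so the output is deterministic
and independent of input order.
"""

from __future__ import annotations

from collections import Counter, defaultdict
from dataclasses import dataclass, field

from riboblock.annotate import CATEGORY_NONCODING, ReadClass

_CATEGORY_TIEBREAK = (CATEGORY_NONCODING,)  # ties in majority vote go to noncoding


@dataclass
class CollapsedRead:
    """A unique read sequence with per-sample occurrence counts."""

    sequence: str
    counts: dict[str, int]
    category: str = "unassigned"
    biotypes: Counter = field(default_factory=Counter)

    @property
    def total(self) -> int:
        return sum(self.counts.values())

    def __len__(self) -> int:
        return len(self.sequence)


@dataclass
class ContaminantGroup:
    """A pattern (shortest common sequence) with its member reads and counts."""

    pattern: str
    members: list[CollapsedRead]
    counts: dict[str, int]
    rank: int = 0
    dominant_biotype: str = "unassigned"
    dominant_category: str = "unassigned"

    @property
    def total(self) -> int:
        return sum(self.counts.values())

    @property
    def n_members(self) -> int:
        return len(self.members)


@dataclass
class AggregationResult:
    """Disjoint cover of the collapsed reads: groups plus ungrouped remainder."""

    groups: list[ContaminantGroup]
    ungrouped: list[CollapsedRead]
    params: dict = field(default_factory=dict)

    @property
    def sample_ids(self) -> list[str]:
        ids: set[str] = set()
        for g in self.groups:
            ids.update(g.counts)
        for r in self.ungrouped:
            ids.update(r.counts)
        return sorted(ids)

    def all_collapsed(self) -> list[CollapsedRead]:
        out: list[CollapsedRead] = []
        for g in self.groups:
            out.extend(g.members)
        out.extend(self.ungrouped)
        return out


def collapse(classes: list[ReadClass]) -> list[CollapsedRead]:
    """Collapse identical read sequences into counted unique sequences.

    Counts are kept per sample.  The collapsed read's category is the
    majority vote over its constituent reads (identical sequences from one
    locus share a class anyway); ties go to noncoding.  Output is sorted by
    descending total then sequence, independent of input order.
    """
    counts: dict[str, dict[str, int]] = defaultdict(lambda: defaultdict(int))
    categories: dict[str, Counter] = defaultdict(Counter)
    biotypes: dict[str, Counter] = defaultdict(Counter)
    for rc in classes:
        seq = rc.read.sequence
        counts[seq][rc.read.sample_id] += 1
        categories[seq][rc.category] += 1
        for bt in rc.biotypes:
            biotypes[seq][bt] += 1
    out = []
    for seq in counts:
        votes = categories[seq]
        top = max(votes.values())
        winners = sorted(c for c, n in votes.items() if n == top)
        category = CATEGORY_NONCODING if CATEGORY_NONCODING in winners else winners[0]
        out.append(
            CollapsedRead(
                sequence=seq,
                counts=dict(sorted(counts[seq].items())),
                category=category,
                biotypes=biotypes[seq],
            )
        )
    out.sort(key=lambda r: (-r.total, r.sequence))
    return out


def select_patterns(
    collapsed: list[CollapsedRead],
    n_patterns: int = 10000,
    scope: str = "all",
) -> list[CollapsedRead]:
    """Select the highest-abundance collapsed reads as matching patterns.

    ``scope`` is ``"all"`` (default) or ``"noncoding"`` (restrict pattern
    selection to noncoding-classified reads).  Returns up to ``n_patterns``
    reads in descending total order, ties broken lexicographically by
    sequence.
    """
    if n_patterns < 1:
        raise ValueError(f"n_patterns must be >= 1, got {n_patterns}")
    if scope not in ("all", "noncoding"):
        raise ValueError(f"scope must be 'all' or 'noncoding', got {scope!r}")
    pool = collapsed if scope == "all" else [r for r in collapsed if r.category == CATEGORY_NONCODING]
    ranked = sorted(pool, key=lambda r: (-r.total, r.sequence))
    return ranked[:n_patterns]


def _dominant(counter: Counter, fallback: str) -> str:
    if not counter:
        return fallback
    top = max(counter.values())
    return sorted(k for k, v in counter.items() if v == top)[0]


def _finalize_group(pattern: CollapsedRead, members: list[CollapsedRead]) -> ContaminantGroup:
    counts: dict[str, int] = defaultdict(int)
    bt = Counter()
    cat = Counter()
    for m in members:
        for sid, n in m.counts.items():
            counts[sid] += n
        for b, n in m.biotypes.items():
            bt[b] += n
        cat[m.category] += m.total
    return ContaminantGroup(
        pattern=pattern.sequence,
        members=members,
        counts=dict(sorted(counts.items())),
        dominant_biotype=_dominant(bt, fallback=_dominant(cat, "unassigned")),
        dominant_category=_dominant(cat, "unassigned"),
    )


def aggregate_groups(
    patterns: list[CollapsedRead],
    search_set: list[CollapsedRead],
) -> AggregationResult:
    """Greedy shortest-pattern-first grouping with elimination.

    Patterns are processed in ascending length order (ties: descending
    total, then lexicographic).  Each pattern collects every sequence still
    in the search set that contains it as an exact contiguous substring;
    matched sequences (including the pattern itself) are eliminated before
    the next pattern is queued, so the groups form a disjoint cover.  Groups
    are re-ranked by descending total for reporting; whatever the patterns
    never matched is returned as ungrouped.
    """
    pattern_seqs = {p.sequence for p in patterns}
    search_seqs = {r.sequence for r in search_set}
    missing = pattern_seqs - search_seqs
    if missing:
        raise ValueError(
            f"{len(missing)} pattern(s) absent from the search set (patterns must be "
            f"drawn from it), e.g. {sorted(missing)[:3]}"
        )

    order = sorted(patterns, key=lambda p: (len(p.sequence), -p.total, p.sequence))
    # stable deterministic ordering of the search set
    remaining = sorted(search_set, key=lambda r: (-r.total, r.sequence))
    consumed: set[str] = set()
    groups: list[ContaminantGroup] = []
    for pat in order:
        if pat.sequence in consumed:
            continue
        needle = pat.sequence
        members = [r for r in remaining if needle in r.sequence]
        remaining = [r for r in remaining if needle not in r.sequence]
        for m in members:
            consumed.add(m.sequence)
        groups.append(_finalize_group(pat, members))

    groups.sort(key=lambda g: (-g.total, g.pattern))
    for rank, g in enumerate(groups, start=1):
        g.rank = rank
    return AggregationResult(
        groups=groups,
        ungrouped=remaining,
        params={"n_patterns": len(patterns), "scope": "explicit", "tie_break": "len,-total,lex"},
    )


def run_aggregation(
    classes_by_sample: dict[str, list[ReadClass]],
    n_patterns: int = 10000,
    scope: str = "all",
) -> tuple[AggregationResult, dict[str, int]]:
    """Convenience pipeline: collapse all samples, select patterns, group.

    Returns the aggregation result plus per-sample totals of filtered reads
    (the denominator used for all percentage reporting).
    """
    all_classes = [rc for classes in classes_by_sample.values() for rc in classes]
    collapsed = collapse(all_classes)
    patterns = select_patterns(collapsed, n_patterns=n_patterns, scope=scope)
    result = aggregate_groups(patterns, collapsed)
    result.params.update({"n_patterns": n_patterns, "scope": scope})
    totals = {sid: len(classes) for sid, classes in classes_by_sample.items()}
    return result, totals


def groups_table(result: AggregationResult, totals: dict[str, int]):
    """Groups as a DataFrame: rank, pattern, counts and percentages per sample."""
    import pandas as pd

    samples = sorted(totals)
    rows = []
    for g in result.groups:
        row = {
            "rank": g.rank,
            "pattern": g.pattern,
            "length": len(g.pattern),
            "dominant_biotype": g.dominant_biotype,
            "dominant_category": g.dominant_category,
            "n_members": g.n_members,
            "total": g.total,
        }
        for sid in samples:
            n = g.counts.get(sid, 0)
            row[f"count_{sid}"] = n
            row[f"pct_{sid}"] = 100.0 * n / totals[sid] if totals[sid] else 0.0
        rows.append(row)
    return pd.DataFrame(rows)
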