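"""Read collapsing, pattern selection and greedy substring-containment grouping."""

import random
from collections import Counter

import pytest

from riboblock.aggregate import (
    CollapsedRead,
    aggregate_groups,
    collapse,
    select_patterns,
)
from tests.conftest import make_class
from tests.oracles import naive_grouping, random_collapsed_input


def cr(seq, **counts):
    return CollapsedRead(sequence=seq, counts=counts)


class TestCollapse:
    def test_counts_per_sample(self):
        classes = [make_class("ACGTACGTACGTACGTACGT", sample=s) for s in ["A"] * 3 + ["B"] * 2]
        (collapsed,) = collapse(classes)
        assert collapsed.counts == {"A": 3, "B": 2}
        assert collapsed.total == 5

    def test_distinct_sequences_stay_distinct(self):
        classes = [make_class("A" * 20), make_class("C" * 20)]
        assert len(collapse(classes)) == 2

    def test_majority_category_with_noncoding_tiebreak(self):
        classes = [
            make_class("A" * 20, category="mRNA"),
            make_class("A" * 20, category="noncoding"),
        ]
        (collapsed,) = collapse(classes)
        assert collapsed.category == "noncoding"
        classes += [make_class("A" * 20, category="mRNA")]
        (collapsed,) = collapse(classes)
        assert collapsed.category == "mRNA"

    def test_against_naive_hash_count_oracle(self):
        rng = random.Random(7)
        pool = ["".join(rng.choice("ACGT") for _ in range(22)) for _ in range(40)]
        classes = [
            make_class(rng.choice(pool), sample=rng.choice(["a", "b", "c"]))
            for _ in range(10000)
        ]
        oracle = Counter((rc.read.sequence, rc.read.sample_id) for rc in classes)
        collapsed = collapse(classes)
        assert sum(r.total for r in collapsed) == len(classes)
        for r in collapsed:
            for sid, n in r.counts.items():
                assert n == oracle[(r.sequence, sid)]

    def test_empty_input(self):
        assert collapse([]) == []


class TestSelectPatterns:
    def test_top_by_total(self):
        pool = [cr("A" * 20, s=5), cr("C" * 20, s=9), cr("G" * 20, s=1), cr("T" * 20, s=7)]
        top = select_patterns(pool, n_patterns=3)
        assert [r.sequence for r in top] == ["C" * 20, "T" * 20, "A" * 20]

    def test_tie_broken_lexicographically(self):
        pool = [cr("TTTT", s=5), cr("AAAA", s=5)]
        assert [r.sequence for r in select_patterns(pool, 1)] == ["AAAA"]

    def test_saturation_returns_all(self):
        pool = [cr("".join(random.Random(i).choices("ACGT", k=20)), s=1) for i in range(200)]
        assert len(select_patterns(pool, n_patterns=10000)) == 200

    def test_noncoding_scope(self):
        nc = CollapsedRead("A" * 20, {"s": 1}, category="noncoding")
        co = CollapsedRead("C" * 20, {"s": 9}, category="mRNA")
        assert select_patterns([nc, co], 10, scope="noncoding") == [nc]

    def test_invalid_params(self):
        with pytest.raises(ValueError):
            select_patterns([], n_patterns=0)
        with pytest.raises(ValueError):
            select_patterns([], scope="bogus")


class TestAggregateGroups:
    def test_containment_by_inspection(self):
        search = [cr("ACGT", a=5), cr("TACGTG", a=3), cr("GGGG", a=2)]
        result = aggregate_groups([search[0]], search)
        (group,) = result.groups
        assert group.pattern == "ACGT"
        assert group.total == 8
        assert [r.sequence for r in result.ungrouped] == ["GGGG"]

    def test_matched_pattern_never_forms_own_group(self):
        # TACGTG is itself a pattern but is consumed by ACGT's group first
        search = [cr("ACGT", a=5), cr("TACGTG", a=3), cr("GGGG", a=2)]
        result = aggregate_groups([search[0], search[1]], search)
        assert [g.pattern for g in result.groups] == ["ACGT"]

    def test_pattern_must_come_from_search_set(self):
        with pytest.raises(ValueError, match="absent"):
            aggregate_groups([cr("AAAA", a=1)], [cr("CCCC", a=1)])

    def test_empty_patterns_leaves_all_ungrouped(self):
        search = [cr("ACGT", a=1)]
        result = aggregate_groups([], search)
        assert result.groups == [] and len(result.ungrouped) == 1

    def test_n_never_matches(self):
        search = [cr("ACNT", a=5), cr("TACGTG", a=3)]
        result = aggregate_groups([search[0]], search)
        (group,) = result.groups
        assert [r.sequence for r in group.members] == ["ACNT"]

    @pytest.mark.parametrize("seed", [0, 1, 2])
    def test_matches_brute_force_oracle(self, seed):
        rng = random.Random(seed)
        pool = random_collapsed_input(rng, 300)
        collapsed = [cr(seq, **counts) for seq, counts in pool]
        patterns = select_patterns(collapsed, n_patterns=50)
        result = aggregate_groups(patterns, collapsed)
        ref_groups, ref_ungrouped = naive_grouping(
            [(p.sequence, p.counts) for p in patterns], pool
        )
        assert [g.pattern for g in result.groups] == [g["pattern"] for g in ref_groups]
        for got, ref in zip(result.groups, ref_groups):
            assert sorted(m.sequence for m in got.members) == ref["members"]
            assert got.counts == ref["counts"]
        assert {r.sequence for r in result.ungrouped} == set(ref_ungrouped)

    def test_disjoint_cover_and_conservation(self):
        rng = random.Random(3)
        pool = random_collapsed_input(rng, 200)
        collapsed = [cr(seq, **counts) for seq, counts in pool]
        patterns = select_patterns(collapsed, n_patterns=40)
        result = aggregate_groups(patterns, collapsed)
        seqs = [m.sequence for g in result.groups for m in g.members]
        seqs += [r.sequence for r in result.ungrouped]
        assert sorted(seqs) == sorted(s for s, _ in pool)  # each read exactly once
        total_in = sum(sum(c.values()) for _, c in pool)
        total_out = sum(g.total for g in result.groups) + sum(r.total for r in result.ungrouped)
        assert total_in == total_out

    def test_pattern_is_shortest_member_and_substring_of_all(self):
        rng = random.Random(4)
        pool = random_collapsed_input(rng, 150)
        collapsed = [cr(seq, **counts) for seq, counts in pool]
        result = aggregate_groups(select_patterns(collapsed, 30), collapsed)
        for g in result.groups:
            assert all(g.pattern in m.sequence for m in g.members)
            assert min(len(m.sequence) for m in g.members) == len(g.pattern)
            assert any(m.sequence == g.pattern for m in g.members)

    def test_deterministic_under_input_shuffling(self):
        rng = random.Random(5)
        pool = random_collapsed_input(rng, 120)
        collapsed = [cr(seq, **counts) for seq, counts in pool]
        patterns = select_patterns(collapsed, 25)
        base = aggregate_groups(patterns, collapsed)
        for _ in range(3):
            rng.shuffle(collapsed)
            rng.shuffle(patterns)
            again = aggregate_groups(patterns, collapsed)
            assert [g.pattern for g in again.groups] == [g.pattern for g in base.groups]
            assert [g.counts for g in again.groups] == [g.counts for g in base.groups]

    def test_ranks_are_descending_total(self):
        rng = random.Random(6)
        pool = random_collapsed_input(rng, 100)
        collapsed = [cr(seq, **counts) for seq, counts in pool]
        result = aggregate_groups(select_patterns(collapsed, 20), collapsed)
        totals = [g.total for g in result.groups]
        assert totals == sorted(totals, reverse=True)
        assert [g.rank for g in result.groups] == list(range(1, len(totals) + 1))
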