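"""Independent brute-force references used to check the implementation.

These deliberately avoid the library's own code paths: substring matching
is a hand-rolled character scan (not ``in``/regex), and grouping is a
direct transcription of the shortest-pattern-first sweep over dictionaries.
"""

from __future__ import annotations

import math


def contains_scan(haystack: str, needle: str) -> bool:
    """Naive O(n*m) substring test by explicit character comparison."""
    n, m = len(haystack), len(needle)
    for i in range(n - m + 1):
        for j in range(m):
            if haystack[i + j] != needle[j]:
                break
        else:
            return True
    return False


def naive_grouping(patterns: list[tuple[str, dict]], search: list[tuple[str, dict]]):
    """Reference greedy grouping over (sequence, per-sample counts) pairs.

    Same contract as the implementation: patterns ascending by (length,
    -total, sequence); each pattern sweeps remaining sequences containing
    it; matches eliminated; groups re-ranked by descending total.
    Returns (groups, ungrouped) with groups as dicts.
    """
    remaining = {seq: counts for seq, counts in search}
    order = sorted(
        patterns, key=lambda p: (len(p[0]), -sum(p[1].values()), p[0])
    )
    groups = []
    done = set()
    for pseq, _ in order:
        if pseq in done:
            continue
        members = sorted(s for s in remaining if contains_scan(s, pseq))
        for s in members:
            done.add(s)
        counts: dict[str, int] = {}
        for s in members:
            for sid, n in remaining[s].items():
                counts[sid] = counts.get(sid, 0) + n
        for s in members:
            del remaining[s]
        groups.append({"pattern": pseq, "members": members, "counts": counts})
    groups.sort(key=lambda g: (-sum(g["counts"].values()), g["pattern"]))
    return groups, dict(remaining)


def pearson(xs, ys) -> float:
    """Hand-rolled Pearson correlation coefficient."""
    n = len(xs)
    mx = sum(xs) / n
    my = sum(ys) / n
    sxy = sum((x - mx) * (y - my) for x, y in zip(xs, ys))
    sxx = sum((x - mx) ** 2 for x in xs)
    syy = sum((y - my) ** 2 for y in ys)
    return sxy / math.sqrt(sxx * syy)


def random_collapsed_input(rng, n_seqs: int, n_samples: int = 2):
    """Random (sequence, counts) pool with deliberate containment structure.

    About a third of sequences are extensions of earlier ones, so substring
    relations actually occur.
    """
    bases = "ACGT"
    seqs: list[str] = []
    while len(seqs) < n_seqs:
        if seqs and rng.random() < 0.35:
            core = rng.choice(seqs)
            left = "".join(rng.choice(bases) for _ in range(rng.randint(0, 4)))
            right = "".join(rng.choice(bases) for _ in range(rng.randint(0, 4)))
            cand = left + core + right
        else:
            cand = "".join(rng.choice(bases) for _ in range(rng.randint(8, 30)))
        if cand not in seqs:
            seqs.append(cand)
    out = []
    for seq in seqs:
        counts = {
            f"s{k + 1}": rng.randint(0, 50) for k in range(n_samples)
        }
        if sum(counts.values()) == 0:
            counts["s1"] = 1
        out.append((seq, counts))
    return out
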