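"""Small sequence helpers shared across modules."""

from __future__ import annotations

_COMPLEMENT = str.maketrans("ACGTNacgtn", "TGCANtgcan")

VALID_BASES = frozenset("ACGTN")


def revcomp(seq: str) -> str:
    """Reverse complement of a DNA string (N maps to N)."""
    return seq.translate(_COMPLEMENT)[::-1]


def gc_fraction(seq: str) -> float:
    """Fraction of G/C bases; 0.0 for the empty string."""
    if not seq:
        return 0.0
    s = seq.upper()
    return (s.count("G") + s.count("C")) / len(s)


def max_homopolymer(seq: str) -> int:
    """Length of the longest single-base run."""
    best = 0
    run = 0
    prev = ""
    for base in seq:
        run = run + 1 if base == prev else 1
        prev = base
        if run > best:
            best = run
    return best
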