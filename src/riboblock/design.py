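"""LNA blocker oligonucleotide design against contaminant target sequences.

A blocker consists of alternating DNA and LNA nucleotides, beginning with a
DNA nucleotide, carries a 3'-phosphate so it cannot prime extension itself,
and should be at least 14 nt long for sequence specificity.  Probes default
to the antisense orientation (reverse complement of the sequenced
contaminant fragment), hybridizing to the read-sense amplicon strand;
blocking either strand of the PCR product suppresses amplification, so a
sense-orientation option is provided too.

Melting-temperature prediction for LNA-containing oligos depends on
proprietary parameter sets and is out of scope; GC fraction, homopolymer
and optional reference-occurrence checks stand in as primer-style sanity
checks.
"""

from __future__ import annotations

import os
from dataclasses import dataclass, field

from Bio import SeqIO

from riboblock._seq import gc_fraction, max_homopolymer, revcomp

GC_FLAG_RANGE = (0.4, 0.7)
HOMOPOLYMER_FLAG = 4


@dataclass
class ProbeQC:
    gc_fraction: float
    max_homopolymer: int
    specificity_hits: int | None = None
    flags: list[str] = field(default_factory=list)


@dataclass
class LNAProbe:
    """A designed blocker: sequence, LNA mask (1-based even positions), 3'-phosphate."""

    name: str
    target_pattern: str
    probe_sequence: str
    lna_positions: frozenset[int]
    phos_3prime: bool = True
    orientation: str = "antisense"
    qc: ProbeQC | None = None

    def __post_init__(self) -> None:
        n = len(self.probe_sequence)
        expected = frozenset(range(2, n + 1, 2))
        if self.lna_positions != expected:
            raise ValueError(
                f"probe {self.name}: LNA positions must be exactly the even 1-based "
                f"indices (DNA first, strictly alternating); got {sorted(self.lna_positions)}"
            )

    def __len__(self) -> int:
        return len(self.probe_sequence)

    @property
    def binding_site(self) -> str:
        """The read-sense sequence this probe hybridizes against."""
        if self.orientation == "antisense":
            return revcomp(self.probe_sequence)
        return self.probe_sequence


def _select_window(seq: str, max_len: int) -> str:
    """max_len-length window with GC fraction closest to 0.5; ties leftmost."""
    if len(seq) <= max_len:
        return seq
    best_start = 0
    best_dist = None
    for start in range(len(seq) - max_len + 1):
        dist = abs(gc_fraction(seq[start : start + max_len]) - 0.5)
        if best_dist is None or dist < best_dist - 1e-12:
            best_dist = dist
            best_start = start
    return seq[best_start : best_start + max_len]


def design_probe(
    target: str,
    min_len: int = 14,
    max_len: int = 20,
    orientation: str = "antisense",
    name: str | None = None,
) -> LNAProbe:
    """Design an LNA blocker against a contaminant target sequence.

    The probe is the target (sense) or its reverse complement (antisense,
    default), trimmed for long targets to the ``max_len`` window whose GC
    fraction is closest to 0.5 (ties: leftmost).  LNA nucleotides occupy
    every even 1-based position so the probe starts and, for even lengths,
    ends the alternation on DNA-first; the 3' end is phosphorylated.

    Raises ``ValueError`` for targets shorter than ``min_len`` (pick a
    longer group pattern) or containing N.
    """
    target = target.upper()
    if orientation not in ("antisense", "sense"):
        raise ValueError(f"orientation must be 'antisense' or 'sense', got {orientation!r}")
    if min_len < 1 or max_len < min_len:
        raise ValueError(f"require 1 <= min_len <= max_len, got {min_len}, {max_len}")
    if "N" in target:
        raise ValueError("target contains N; choose an unambiguous target sequence")
    if not set(target) <= set("ACGT"):
        raise ValueError(f"target contains non-DNA characters: {sorted(set(target) - set('ACGT'))}")
    if len(target) < min_len:
        raise ValueError(
            f"target is {len(target)} nt but blockers need >= {min_len} nt for "
            "specificity; choose a longer contaminant group pattern"
        )
    base = revcomp(target) if orientation == "antisense" else target
    probe_seq = _select_window(base, max_len)
    probe = LNAProbe(
        name=name or f"LNA_{target[:8]}",
        target_pattern=target,
        probe_sequence=probe_seq,
        lna_positions=frozenset(range(2, len(probe_seq) + 1, 2)),
        phos_3prime=True,
        orientation=orientation,
    )
    probe.qc = qc_probe(probe)
    return probe


def render_probe(probe: LNAProbe, notation: str = "plus_prefix") -> str:
    """Render a probe in vendor text notation: '+' before each LNA base, '/3Phos/' suffix."""
    if notation != "plus_prefix":
        raise ValueError(f"unknown notation {notation!r}")
    parts = []
    for i, base in enumerate(probe.probe_sequence, start=1):
        if i in probe.lna_positions:
            parts.append("+")
        parts.append(base)
    if probe.phos_3prime:
        parts.append("/3Phos/")
    return "".join(parts)


def _count_occurrences(haystack: str, needle: str) -> int:
    count = start = 0
    while True:
        idx = haystack.find(needle, start)
        if idx < 0:
            return count
        count += 1
        start = idx + 1


def qc_probe(probe: LNAProbe, reference: str | os.PathLike | None = None) -> ProbeQC:
    """Primer-style sanity checks: GC fraction, homopolymer run, optional specificity.

    When a reference FASTA is supplied, counts exact occurrences of the
    probe's binding site on both strands as ``specificity_hits``.  GC
    outside [0.4, 0.7] or a homopolymer run over 4 raise warning flags, not
    errors.
    """
    gc = gc_fraction(probe.probe_sequence)
    homo = max_homopolymer(probe.probe_sequence)
    flags = []
    if not GC_FLAG_RANGE[0] <= gc <= GC_FLAG_RANGE[1]:
        flags.append(f"gc_fraction {gc:.3f} outside {GC_FLAG_RANGE}")
    if homo > HOMOPOLYMER_FLAG:
        flags.append(f"homopolymer run {homo} > {HOMOPOLYMER_FLAG}")
    hits = None
    if reference is not None:
        site = probe.binding_site
        hits = 0
        for record in SeqIO.parse(str(reference), "fasta"):
            seq = str(record.seq).upper()
            hits += _count_occurrences(seq, site)
            hits += _count_occurrences(revcomp(seq), site)
    return ProbeQC(gc_fraction=gc, max_homopolymer=homo, specificity_hits=hits, flags=flags)


def design_for_groups(
    groups,
    n_probes: int = 5,
    min_len: int = 14,
    max_len: int = 20,
    orientation: str = "antisense",
) -> tuple[list[LNAProbe], list[tuple[str, str]]]:
    """Design probes for the top-ranked groups whose patterns are long enough.

    Groups with too-short patterns are skipped (reported with a reason) and
    the next group is promoted, until ``n_probes`` probes exist or the
    groups run out.  Returns (probes, skipped) where skipped is a list of
    (pattern, reason).
    """
    probes: list[LNAProbe] = []
    skipped: list[tuple[str, str]] = []
    for g in groups:
        if len(probes) >= n_probes:
            break
        try:
            probe = design_probe(
                g.pattern,
                min_len=min_len,
                max_len=max_len,
                orientation=orientation,
                name=f"LNA_Top_{len(probes) + 1}",
            )
        except ValueError as exc:
            skipped.append((g.pattern, str(exc)))
            continue
        probes.append(probe)
    return probes, skipped


def order_sheet(probes: list[LNAProbe], groups_by_pattern: dict[str, int] | None = None):
    """Order sheet as a DataFrame: name, rendered sequence, length, GC%, target."""
    import pandas as pd

    rows = []
    for p in probes:
        rows.append(
            {
                "name": p.name,
                "sequence": render_probe(p),
                "length": len(p),
                "gc_pct": 100.0 * (p.qc.gc_fraction if p.qc else gc_fraction(p.probe_sequence)),
                "orientation": p.orientation,
                "target_group_rank": (groups_by_pattern or {}).get(p.target_pattern, ""),
                "target_pattern": p.target_pattern,
            }
        )
    return pd.DataFrame(rows)
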