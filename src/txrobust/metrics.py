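"""Fragile-codon and fragile-amino-acid usage metrics.

Four per-sequence metrics with explicit defined/undefined semantics:

* ``fcu``  -- fraction of sense codons that are fragile.
* ``nfcu`` -- mean fragile fraction within GC-matched synonymous groups.
* ``fau``  -- fraction of residues that are fragile amino acids.
* ``nfau`` -- mean fragile fraction within GC-matched amino-acid groups.

The normalized metrics average the per-group fractions that are defined
(denominator > 0); a metric whose every group is empty is UNDEFINED, which
is represented as ``value is None`` rather than an exception so that
downstream tabulations can count dropped records.
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass, field
from typing import Iterable, Sequence

from . import genetic_code as gcode

_VALID_NT = frozenset("ACGT")


@dataclass(frozen=True)
class CodonSequence:
    """An ordered list of codons with optional CDS-relative coordinates.

    The terminal stop codon is expected to have been removed upstream.
    ``offsets`` holds the nucleotide offset of each codon's first base in
    the coordinate frame of its parent CDS (defaults to ``3*i``).
    """

    codons: tuple[str, ...]
    source_label: str = ""
    offsets: tuple[int, ...] | None = None

    def __post_init__(self) -> None:
        for c in self.codons:
            if len(c) != 3:
                raise ValueError(f"codon of length != 3: {c!r}")
        if self.offsets is not None and len(self.offsets) != len(self.codons):
            raise ValueError("offsets/codons length mismatch")

    def __len__(self) -> int:
        return len(self.codons)

    @property
    def positions(self) -> tuple[int, ...]:
        if self.offsets is not None:
            return self.offsets
        return tuple(3 * i for i in range(len(self.codons)))

    @property
    def internal_stop_positions(self) -> tuple[int, ...]:
        return tuple(
            i for i, c in enumerate(self.codons) if c in gcode.STOP_CODONS
        )

    @classmethod
    def from_nt(cls, seq: str, source_label: str = "", strip_stop: bool = True
                ) -> "CodonSequence":
        """Split a nucleotide string into codons, optionally stripping a
        terminal stop.  Length must be a multiple of 3."""
        seq = seq.upper()
        if len(seq) % 3:
            raise ValueError("nucleotide length not a multiple of 3")
        codons = tuple(seq[i : i + 3] for i in range(0, len(seq), 3))
        if strip_stop and codons and codons[-1] in gcode.STOP_CODONS:
            codons = codons[:-1]
        return cls(codons=codons, source_label=source_label)


@dataclass(frozen=True)
class MetricValue:
    """One metric evaluation with per-group numerator/denominator bookkeeping."""

    metric: str
    value: float | None
    per_group: tuple[tuple[str, int, int], ...]
    n_used: int
    n_skipped: int

    @property
    def defined(self) -> bool:
        return self.value is not None


def _countable_codon(codon: str) -> bool:
    return set(codon) <= _VALID_NT and codon not in gcode.STOP_CODONS


def fcu(seq: CodonSequence) -> MetricValue:
    """Fraction of countable sense codons that are fragile.

    Codons containing non-ACGT characters and (mis-annotated) stop codons
    are excluded from numerator and denominator and tallied as skipped.
    """
    n_fragile = n_sense = n_skipped = 0
    for codon in seq.codons:
        if not _countable_codon(codon):
            n_skipped += 1
            continue
        n_sense += 1
        if gcode.is_fragile(codon):
            n_fragile += 1
    value = n_fragile / n_sense if n_sense else None
    return MetricValue(
        metric="FCU",
        value=value,
        per_group=(("all", n_fragile, n_sense),),
        n_used=n_sense,
        n_skipped=n_skipped,
    )


def nfcu(
    seq: CodonSequence,
    groups: Sequence[gcode.SynonymousGroup] | None = None,
) -> MetricValue:
    """Unweighted mean, over GC-matched synonymous groups with at least one
    occurrence, of the fraction of occurrences that are fragile codons."""
    if groups is None:
        groups = gcode.nfcu_groups("canonical")
    counts = Counter(seq.codons)
    n_skipped = sum(
        n for codon, n in counts.items() if not _countable_codon(codon)
    )
    per_group = []
    fractions = []
    n_used = 0
    for group in groups:
        den = sum(counts[c] for c in group.members)
        num = sum(counts[c] for c in group.fragile_members)
        per_group.append((group.group_id, num, den))
        n_used += den
        if den:
            fractions.append(num / den)
    value = sum(fractions) / len(fractions) if fractions else None
    return MetricValue(
        metric="NFCU",
        value=value,
        per_group=tuple(per_group),
        n_used=n_used,
        n_skipped=n_skipped,
    )


def fau(peptide: str) -> MetricValue:
    """Fraction of standard residues that are fragile amino acids."""
    fragile = gcode.fragile_amino_acids()
    standard = set(gcode.AMINO_ACIDS)
    n_fragile = n_res = n_skipped = 0
    for aa in peptide.upper():
        if aa not in standard:
            n_skipped += 1
            continue
        n_res += 1
        if aa in fragile:
            n_fragile += 1
    value = n_fragile / n_res if n_res else None
    return MetricValue(
        metric="FAU",
        value=value,
        per_group=(("all", n_fragile, n_res),),
        n_used=n_res,
        n_skipped=n_skipped,
    )


def nfau(
    peptide: str,
    groups: Sequence[gcode.AAGroup] | None = None,
) -> MetricValue:
    """Unweighted mean of defined per-group fragile amino-acid fractions."""
    if groups is None:
        groups = gcode.nfau_groups()
    counts = Counter(peptide.upper())
    n_skipped = sum(
        n for aa, n in counts.items() if aa not in gcode.AMINO_ACIDS
    )
    per_group = []
    fractions = []
    n_used = 0
    for group in groups:
        den = sum(counts[aa] for aa in group.members)
        num = sum(counts[aa] for aa in group.fragile_members)
        per_group.append((group.group_id, num, den))
        n_used += den
        if den:
            fractions.append(num / den)
    value = sum(fractions) / len(fractions) if fractions else None
    return MetricValue(
        metric="NFAU",
        value=value,
        per_group=tuple(per_group),
        n_used=n_used,
        n_skipped=n_skipped,
    )


def metric_table(records: Iterable[tuple[str, MetricValue]]):
    """Tabulate labeled MetricValues as a DataFrame (empty value = UNDEFINED)."""
    import pandas as pd

    rows = []
    for label, mv in records:
        rows.append(
            {
                "label": label,
                "metric": mv.metric,
                "value": mv.value if mv.defined else None,
                "n_used": mv.n_used,
                "n_skipped": mv.n_skipped,
                "per_group": ";".join(
                    f"{gid}:{num}/{den}" for gid, num, den in mv.per_group
                ),
            }
        )
    return pd.DataFrame(rows)
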