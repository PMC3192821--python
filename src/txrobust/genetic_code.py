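"""Fragility classification of codons and amino acids under the standard genetic code.

A sense codon is *fragile* if a single nucleotide substitution can turn it
into a stop codon (TAA, TAG or TGA), and *robust* otherwise.  Amino acids
inherit a three-way classification from their codon families: *fragile*
(all codons fragile), *robust* (all codons robust) or *facultative* (mixed).

The module also derives the GC-matched normalization groups used by the
NFCU and NFAU metrics: synonymous codons of equal GC content that differ in
fragility, and amino-acid families of equal family-wide GC fraction that
differ in fragility.

Everything here is derived by enumeration from the standard nuclear code
(DNA alphabet, uppercase); no fragile/robust table is hard-coded.
"""

from __future__ import annotations

from dataclasses import dataclass
from fractions import Fraction
from functools import lru_cache

from Bio.Data import CodonTable

NUCLEOTIDES: tuple[str, ...] = ("A", "C", "G", "T")

#: Marker used for stop codons in :data:`GENETIC_CODE`.
STOP = "*"

FRAGILE = "fragile"
ROBUST = "robust"
FACULTATIVE = "facultative"


def _standard_code() -> dict[str, str]:
    table = CodonTable.unambiguous_dna_by_id[1]
    code = dict(table.forward_table)
    for stop in table.stop_codons:
        code[stop] = STOP
    return code


#: Codon (uppercase DNA) -> one-letter amino acid, or ``"*"`` for stops.
GENETIC_CODE: dict[str, str] = _standard_code()

STOP_CODONS: frozenset[str] = frozenset(
    c for c, aa in GENETIC_CODE.items() if aa == STOP
)
SENSE_CODONS: tuple[str, ...] = tuple(
    sorted(c for c in GENETIC_CODE if c not in STOP_CODONS)
)
AMINO_ACIDS: tuple[str, ...] = tuple(
    sorted({aa for aa in GENETIC_CODE.values() if aa != STOP})
)


def gc_count(codon: str) -> int:
    """Number of G or C nucleotides in a codon (0-3)."""
    return sum(nt in "GC" for nt in codon)


def synonymous_codons(amino_acid: str) -> tuple[str, ...]:
    """All codons encoding ``amino_acid``, lexicographically sorted."""
    _check_amino_acid(amino_acid)
    return tuple(sorted(c for c, aa in GENETIC_CODE.items() if aa == amino_acid))


def _check_sense_codon(codon: str) -> None:
    if not isinstance(codon, str) or codon not in GENETIC_CODE:
        raise ValueError(f"not a valid uppercase DNA codon: {codon!r}")
    if codon in STOP_CODONS:
        raise ValueError(f"stop codon has no fragility classification: {codon}")


def _check_amino_acid(aa: str) -> None:
    if aa not in AMINO_ACIDS:
        raise ValueError(f"not a standard one-letter amino acid: {aa!r}")


@lru_cache(maxsize=None)
def stop_neighbors(codon: str) -> tuple[str, ...]:
    """Stop codons reachable from a sense codon by one substitution.

    Returns a lexicographically sorted tuple; empty for robust codons.
    Raises ``ValueError`` for stop codons or malformed input.
    """
    _check_sense_codon(codon)
    hits = set()
    for pos in range(3):
        for nt in NUCLEOTIDES:
            if nt == codon[pos]:
                continue
            mutant = codon[:pos] + nt + codon[pos + 1 :]
            if mutant in STOP_CODONS:
                hits.add(mutant)
    return tuple(sorted(hits))


def is_fragile(codon: str) -> bool:
    return bool(stop_neighbors(codon))


@dataclass(frozen=True)
class CodonClassification:
    codon: str
    status: str  # FRAGILE or ROBUST
    stop_neighbors: tuple[str, ...]


@dataclass(frozen=True)
class AminoAcidClassification:
    amino_acid: str
    status: str  # FRAGILE, ROBUST or FACULTATIVE


def classify_codon(codon: str) -> CodonClassification:
    """Classify a sense codon as fragile or robust."""
    neighbors = stop_neighbors(codon)
    status = FRAGILE if neighbors else ROBUST
    return CodonClassification(codon=codon, status=status, stop_neighbors=neighbors)


def classify_amino_acid(amino_acid: str) -> AminoAcidClassification:
    """Classify an amino acid by the fragility of its full codon family."""
    _check_amino_acid(amino_acid)
    statuses = {classify_codon(c).status for c in synonymous_codons(amino_acid)}
    if statuses == {FRAGILE}:
        status = FRAGILE
    elif statuses == {ROBUST}:
        status = ROBUST
    else:
        status = FACULTATIVE
    return AminoAcidClassification(amino_acid=amino_acid, status=status)


def fragile_codons() -> tuple[str, ...]:
    return tuple(c for c in SENSE_CODONS if is_fragile(c))


def robust_codons() -> tuple[str, ...]:
    return tuple(c for c in SENSE_CODONS if not is_fragile(c))


def amino_acids_by_status(status: str) -> tuple[str, ...]:
    return tuple(
        aa for aa in AMINO_ACIDS if classify_amino_acid(aa).status == status
    )


#: The six amino acids encoded exclusively by fragile codons.
def fragile_amino_acids() -> frozenset[str]:
    return frozenset(amino_acids_by_status(FRAGILE))


@dataclass(frozen=True)
class SynonymousGroup:
    """Synonymous codons of equal GC content mixing fragile and robust members."""

    group_id: str
    amino_acid: str
    members: tuple[str, ...]
    fragile_members: tuple[str, ...]
    gc_count: int

    def __post_init__(self) -> None:
        aas = {GENETIC_CODE[c] for c in self.members}
        if aas != {self.amino_acid}:
            raise ValueError(f"group {self.group_id}: members not synonymous")
        if {gc_count(c) for c in self.members} != {self.gc_count}:
            raise ValueError(f"group {self.group_id}: GC content not homogeneous")
        if not self.fragile_members or set(self.fragile_members) - set(self.members):
            raise ValueError(f"group {self.group_id}: bad fragile member set")
        if not set(self.members) - set(self.fragile_members):
            raise ValueError(f"group {self.group_id}: no robust member")


def _make_group(amino_acid: str, members: tuple[str, ...]) -> SynonymousGroup:
    gc = gc_count(members[0])
    return SynonymousGroup(
        group_id=f"{amino_acid}-GC{gc}",
        amino_acid=amino_acid,
        members=members,
        fragile_members=tuple(c for c in members if is_fragile(c)),
        gc_count=gc,
    )


# The canonical group members.  NOTE: the third group below encodes Leucine
# even though the source describing these groups labels it "Lysine" -- both
# Lysine codons (AAA, AAG) are fragile, so no GC-matched mixed Lysine group
# can exist.  The canonical lists also omit AGT/AGC (Ser) and AGG (Arg),
# which would qualify under the stated GC-matching rule; use
# ``nfcu_groups("derived")`` for the complete rule-based partition.
_CANONICAL_NFCU_MEMBERS: tuple[tuple[str, tuple[str, ...]], ...] = (
    ("S", ("TCA", "TCT")),
    ("S", ("TCG", "TCC")),
    ("R", ("CGA", "CGT")),
    ("G", ("GGA", "GGT")),
    ("L", ("TTG", "CTT", "CTA")),
)


def nfcu_groups(mode: str = "canonical") -> tuple[SynonymousGroup, ...]:
    """GC-matched synonymous groups used by the NFCU metric.

    ``canonical`` reproduces the five published groups verbatim; ``derived``
    partitions the codons of every facultative amino acid by GC content and
    keeps the partitions that mix fragile and robust codons (a superset of
    the canonical memberships).
    """
    if mode == "canonical":
        return tuple(_make_group(aa, members) for aa, members in _CANONICAL_NFCU_MEMBERS)
    if mode == "derived":
        groups = []
        for aa in amino_acids_by_status(FACULTATIVE):
            by_gc: dict[int, list[str]] = {}
            for codon in synonymous_codons(aa):
                by_gc.setdefault(gc_count(codon), []).append(codon)
            for members in by_gc.values():
                statuses = {is_fragile(c) for c in members}
                if statuses == {True, False}:
                    groups.append(_make_group(aa, tuple(sorted(members))))
        return tuple(sorted(groups, key=lambda g: g.group_id))
    raise ValueError(f"unknown NFCU group mode: {mode!r}")


@dataclass(frozen=True)
class AAGroup:
    """Amino acids whose codon families share the same overall GC fraction."""

    group_id: str
    members: tuple[str, ...]
    fragile_members: tuple[str, ...]
    family_gc_fraction: Fraction

    def __post_init__(self) -> None:
        for aa in self.members:
            if family_gc_fraction(aa) != self.family_gc_fraction:
                raise ValueError(
                    f"group {self.group_id}: {aa} breaks GC homogeneity"
                )
        if not self.fragile_members:
            raise ValueError(f"group {self.group_id}: no fragile member")
        if not set(self.members) - set(self.fragile_members):
            raise ValueError(f"group {self.group_id}: no non-fragile member")


def family_gc_fraction(amino_acid: str) -> Fraction:
    """G+C nucleotides over total nucleotides across the full codon family."""
    codons = synonymous_codons(amino_acid)
    return Fraction(sum(gc_count(c) for c in codons), 3 * len(codons))


def nfau_groups() -> tuple[AAGroup, ...]:
    """The two GC-matched amino-acid groups used by the NFAU metric.

    Derived by enumeration: the amino acids whose codon families have a GC
    fraction of 1/6 form one group, those at 1/2 the other.  Only amino
    acids classified *fragile* count as fragile members (the facultative
    Ser, present in the 1/2 group, does not).
    """
    fragile = fragile_amino_acids()
    groups = []
    for target in (Fraction(1, 6), Fraction(1, 2)):
        members = tuple(
            aa for aa in AMINO_ACIDS if family_gc_fraction(aa) == target
        )
        groups.append(
            AAGroup(
                group_id=f"AA-GC{target.numerator}/{target.denominator}",
                members=members,
                fragile_members=tuple(aa for aa in members if aa in fragile),
                family_gc_fraction=target,
            )
        )
    return tuple(groups)


def classification_table():
    """Per-sense-codon classification as a pandas DataFrame (TSV-exportable)."""
    import pandas as pd

    rows = []
    for codon in SENSE_CODONS:
        cls = classify_codon(codon)
        rows.append(
            {
                "codon": codon,
                "amino_acid": GENETIC_CODE[codon],
                "status": cls.status,
                "stop_neighbors": ",".join(cls.stop_neighbors),
            }
        )
    return pd.DataFrame(rows)


def write_classification_tsv(path) -> None:
    classification_table().to_csv(path, sep="\t", index=False)
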