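"""Strand-resolved transcript models from FASTA + GFF3.

Builds :class:`TranscriptModel` objects (spliced, transcript-oriented CDS
with codon-to-exon assignment), selects representative transcripts, applies
the structural reliability filters, and extracts per-exon codon sets and
the 5'/3' windows flanking the last exon-exon junction.

Coordinates are 1-based inclusive on disk (GFF3) and 0-based half-open
internally; all reported positions are transcript-oriented.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Iterable, Sequence

import gffutils
import numpy as np
from Bio import SeqIO
from Bio.Seq import Seq

from . import genetic_code as gcode
from .metrics import CodonSequence, MetricValue

logger = logging.getLogger(__name__)

# Validation flag codes
FLAG_MISSING_SEQUENCE = "missing_sequence"
FLAG_BAD_LENGTH = "cds_length_not_multiple_of_3"
FLAG_NO_TERMINAL_STOP = "no_terminal_stop"
FLAG_INTERNAL_STOP = "internal_stop"

# Window ineligibility reason codes
REASON_SINGLE_EXON = "single_exon"
REASON_UNRELIABLE = "unreliable_last_exon"
REASON_SHORT_LAST_EXON = "last_exon_too_short"
REASON_INSUFFICIENT_UPSTREAM = "insufficient_upstream"


@dataclass
class TranscriptModel:
    """One transcript's exon/CDS structure in transcript orientation.

    ``exons`` and ``cds_segments`` are genomic 0-based half-open intervals
    ordered 5'->3' along the transcript; ``codons`` is the spliced CDS with
    the terminal stop removed; ``codon_exon[i]`` is the exon ordinal fully
    containing codon ``i`` (``None`` for junction-spanning codons) and
    ``nt_exon[j]`` the exon ordinal of CDS nucleotide ``j``.
    """

    gene_id: str
    transcript_id: str
    chrom: str
    strand: str
    exons: tuple[tuple[int, int], ...]
    cds_segments: tuple[tuple[int, int, int], ...]  # (start, end, phase)
    codons: CodonSequence
    codon_exon: tuple[int | None, ...]
    nt_exon: tuple[int, ...]
    cds_nt: str  # spliced CDS incl. terminal stop if annotated
    utr3_length: int
    flags: tuple[str, ...]

    @property
    def exon_count(self) -> int:
        return len(self.exons)

    @property
    def peptide_length(self) -> int:
        return len(self.codons)

    @property
    def cds_length_nt(self) -> int:
        return len(self.cds_nt)

    @property
    def peptide(self) -> str:
        return "".join(
            gcode.GENETIC_CODE.get(c, "X") for c in self.codons.codons
        )

    @property
    def has_terminal_stop(self) -> bool:
        return FLAG_NO_TERMINAL_STOP not in self.flags

    @property
    def is_clean(self) -> bool:
        """True when the CDS translated without any validation flag."""
        return not self.flags

    def coding_exon_indices(self) -> tuple[int, ...]:
        return tuple(sorted(set(self.nt_exon)))


@dataclass(frozen=True)
class ExonCodons:
    exon_index: int
    codons: CodonSequence
    is_last: bool


@dataclass(frozen=True)
class BoundaryWindows:
    """50-codon windows flanking the last exon-exon junction.

    ``five_prime_window`` lies upstream (NMD-competent side) ending at least
    ``buffer_nt`` nucleotides before the junction; ``three_prime_window``
    holds the first codons fully contained in the last exon
    (NMD-compromised side).
    """

    five_prime_window: CodonSequence
    three_prime_window: CodonSequence
    buffer_nt: int


def _revcomp(seq: str) -> str:
    return str(Seq(seq).reverse_complement())


def load_annotation(fasta_path, gff3_path) -> list[TranscriptModel]:
    """Parse FASTA + GFF3 into TranscriptModels (all transcripts, all genes).

    Transcripts with structural problems are flagged, never silently
    dropped; genes without any mRNA/CDS are skipped with a log entry.
    """
    sequences = {
        rec.id: str(rec.seq).upper() for rec in SeqIO.parse(str(fasta_path), "fasta")
    }
    db = gffutils.create_db(
        str(gff3_path),
        dbfn=":memory:",
        keep_order=True,
        merge_strategy="create_unique",
    )
    models: list[TranscriptModel] = []
    for gene in db.features_of_type("gene"):
        mrnas = list(db.children(gene, featuretype="mRNA"))
        if not mrnas:
            logger.info("gene %s has no mRNA; skipped", gene.id)
            continue
        for mrna in mrnas:
            model = _build_transcript(db, sequences, gene.id, mrna)
            if model is not None:
                models.append(model)
    return models


def _build_transcript(db, sequences, gene_id, mrna) -> TranscriptModel | None:
    strand = mrna.strand
    chrom = mrna.seqid
    exons = sorted(
        (f.start - 1, f.end) for f in db.children(mrna, featuretype="exon")
    )
    cds = sorted(
        (f.start - 1, f.end, 0 if f.frame in (None, ".") else int(f.frame))
        for f in db.children(mrna, featuretype="CDS")
    )
    if not cds:
        logger.info("transcript %s has no CDS; skipped", mrna.id)
        return None
    if not exons:
        exons = [(s, e) for s, e, _ in cds]
    if strand == "-":
        exons = exons[::-1]
        cds = cds[::-1]

    flags: list[str] = []
    if chrom not in sequences:
        return TranscriptModel(
            gene_id=gene_id, transcript_id=mrna.id, chrom=chrom, strand=strand,
            exons=tuple(exons), cds_segments=tuple(cds),
            codons=CodonSequence(codons=(), source_label=mrna.id),
            codon_exon=(), nt_exon=(), cds_nt="", utr3_length=0,
            flags=(FLAG_MISSING_SEQUENCE,),
        )
    chromseq = sequences[chrom]

    # exon ordinal containing each CDS segment
    seg_exon: list[int] = []
    for s, e, _ in cds:
        hit = None
        for i, (xs, xe) in enumerate(exons):
            if xs <= s and e <= xe:
                hit = i
                break
        if hit is None:
            # CDS segment outside any exon: treat the segment itself as the
            # containing exon to stay robust to sparse annotations.
            hit = min(
                range(len(exons)),
                key=lambda i: abs(exons[i][0] - s),
            )
        seg_exon.append(hit)

    parts: list[str] = []
    nt_exon: list[int] = []
    for (s, e, _), xi in zip(cds, seg_exon):
        sub = chromseq[s:e]
        if strand == "-":
            sub = _revcomp(sub)
        parts.append(sub)
        nt_exon.extend([xi] * (e - s))
    cds_nt = "".join(parts)

    # honor the phase of the first transcript-order segment
    first_phase = cds[0][2]
    if first_phase:
        cds_nt = cds_nt[first_phase:]
        nt_exon = nt_exon[first_phase:]

    if len(cds_nt) % 3:
        flags.append(FLAG_BAD_LENGTH)
        trim = len(cds_nt) - len(cds_nt) % 3
        cds_nt_eff = cds_nt[:trim]
        nt_exon_eff = nt_exon[:trim]
    else:
        cds_nt_eff = cds_nt
        nt_exon_eff = nt_exon

    all_codons = [cds_nt_eff[i : i + 3] for i in range(0, len(cds_nt_eff), 3)]
    if all_codons and all_codons[-1] in gcode.STOP_CODONS:
        codon_list = all_codons[:-1]
        coding_nt_exon = nt_exon_eff[: 3 * len(codon_list)]
    else:
        flags.append(FLAG_NO_TERMINAL_STOP)
        codon_list = all_codons
        coding_nt_exon = nt_exon_eff
    if any(c in gcode.STOP_CODONS for c in codon_list):
        flags.append(FLAG_INTERNAL_STOP)

    codon_exon: list[int | None] = []
    for i in range(len(codon_list)):
        touched = set(coding_nt_exon[3 * i : 3 * i + 3])
        codon_exon.append(touched.pop() if len(touched) == 1 else None)

    utr3 = _spliced_utr3_length(exons, cds, strand)

    return TranscriptModel(
        gene_id=gene_id,
        transcript_id=mrna.id,
        chrom=chrom,
        strand=strand,
        exons=tuple(exons),
        cds_segments=tuple(cds),
        codons=CodonSequence(codons=tuple(codon_list), source_label=mrna.id),
        codon_exon=tuple(codon_exon),
        nt_exon=tuple(coding_nt_exon),
        cds_nt=cds_nt,
        utr3_length=utr3,
        flags=tuple(flags),
    )


def _spliced_utr3_length(exons, cds, strand) -> int:
    """Spliced nucleotide count downstream (transcript orientation) of the CDS."""
    last_s, last_e, _ = cds[-1]
    total = 0
    for xs, xe in exons:
        if strand == "+":
            total += max(0, xe - max(xs, last_e))
        else:
            total += max(0, min(xe, last_s) - xs)
    return total


def validation_report(models: Sequence[TranscriptModel]):
    import pandas as pd

    return pd.DataFrame(
        {
            "gene_id": [m.gene_id for m in models],
            "transcript_id": [m.transcript_id for m in models],
            "exon_count": [m.exon_count for m in models],
            "cds_len_nt": [m.cds_length_nt for m in models],
            "flags": [",".join(m.flags) for m in models],
        }
    )


def select_representative_transcript(
    transcripts: Sequence[TranscriptModel],
) -> TranscriptModel:
    """Transcript encoding the longest peptide; ties broken by smallest id."""
    if not transcripts:
        raise ValueError("gene has no coding transcript")
    return min(transcripts, key=lambda t: (-t.peptide_length, t.transcript_id))


def representative_transcripts(
    models: Iterable[TranscriptModel],
) -> list[TranscriptModel]:
    """One representative transcript per gene, in gene_id order."""
    by_gene: dict[str, list[TranscriptModel]] = {}
    for m in models:
        by_gene.setdefault(m.gene_id, []).append(m)
    return [
        select_representative_transcript(ts)
        for _, ts in sorted(by_gene.items())
    ]


def exon_count(transcript: TranscriptModel) -> int:
    """Total annotated exons, coding and non-coding alike."""
    return transcript.exon_count


def is_reliable_last_exon(transcript: TranscriptModel) -> bool:
    """All three reliability criteria: terminal stop, no exon downstream of
    the stop-bearing exon, and spliced 3' UTR of at least 100 nt."""
    if transcript.exon_count < 2:
        return False
    if not transcript.has_terminal_stop or FLAG_BAD_LENGTH in transcript.flags:
        return False
    stop_exon = transcript.nt_exon[-1] if transcript.nt_exon else None
    if stop_exon is None or stop_exon != transcript.exon_count - 1:
        return False
    return transcript.utr3_length >= 100


def assign_codons_to_exons(transcript: TranscriptModel) -> list[ExonCodons]:
    """Per-exon codon lists, in transcript order, covering every coding exon.

    Junction-spanning codons appear in no record.  Codon offsets are
    CDS-relative nucleotide positions.
    """
    last = transcript.exon_count - 1
    by_exon: dict[int, list[int]] = {
        xi: [] for xi in transcript.coding_exon_indices()
    }
    for i, xi in enumerate(transcript.codon_exon):
        if xi is not None:
            by_exon[xi].append(i)
    out = []
    for xi in sorted(by_exon):
        idxs = by_exon[xi]
        out.append(
            ExonCodons(
                exon_index=xi,
                codons=CodonSequence(
                    codons=tuple(transcript.codons.codons[i] for i in idxs),
                    source_label=f"{transcript.transcript_id}:exon{xi}",
                    offsets=tuple(3 * i for i in idxs),
                ),
                is_last=(xi == last),
            )
        )
    return out


def last_junction_cds_position(transcript: TranscriptModel) -> int | None:
    """CDS-relative nucleotide position of the last exon-exon junction,
    i.e. the count of coding nucleotides upstream of the last exon.
    ``None`` if no coding nucleotide lies in the last exon."""
    last = transcript.exon_count - 1
    for j, xi in enumerate(transcript.nt_exon):
        if xi == last:
            return j
    return None


def extract_boundary_windows(
    transcript: TranscriptModel,
    window_size: int = 50,
    buffer_nt: int = 50,
) -> tuple[BoundaryWindows | None, str | None]:
    """Windows flanking the last junction, or ``(None, reason)``.

    Eligibility: reliable last exon; more than 100 codons fully inside the
    last exon; at least ``window_size`` complete codons ending at least
    ``buffer_nt`` nucleotides upstream of the junction.
    """
    if transcript.exon_count < 2:
        return None, REASON_SINGLE_EXON
    if not is_reliable_last_exon(transcript):
        return None, REASON_UNRELIABLE
    last = transcript.exon_count - 1
    last_codon_idx = [
        i for i, xi in enumerate(transcript.codon_exon) if xi == last
    ]
    if len(last_codon_idx) <= 100:
        return None, REASON_SHORT_LAST_EXON
    junction = last_junction_cds_position(transcript)
    assert junction is not None
    # complete codons whose final nucleotide lies >= buffer_nt before the junction
    n_avail = (junction - buffer_nt) // 3
    if n_avail < window_size:
        return None, REASON_INSUFFICIENT_UPSTREAM
    five_idx = list(range(n_avail - window_size, n_avail))
    three_idx = last_codon_idx[:window_size]
    codons = transcript.codons.codons
    five = CodonSequence(
        codons=tuple(codons[i] for i in five_idx),
        source_label=f"{transcript.transcript_id}:5prime",
        offsets=tuple(3 * i for i in five_idx),
    )
    three = CodonSequence(
        codons=tuple(codons[i] for i in three_idx),
        source_label=f"{transcript.transcript_id}:3prime",
        offsets=tuple(3 * i for i in three_idx),
    )
    return BoundaryWindows(
        five_prime_window=five, three_prime_window=three, buffer_nt=buffer_nt
    ), None


def cds_in_last_exon(transcript: TranscriptModel) -> bool:
    """True iff every coding nucleotide lies within the final exon
    (multi-exon transcripts only)."""
    if transcript.exon_count < 2:
        raise ValueError("cds_in_last_exon is defined for multi-exon transcripts")
    last = transcript.exon_count - 1
    return bool(transcript.nt_exon) and all(
        xi == last for xi in transcript.nt_exon
    )


def hexamer_coverage(seq: str, hexamers: Iterable[str]) -> np.ndarray:
    """Boolean array marking positions covered by >=1 hexamer occurrence."""
    hexset = {h.upper() for h in hexamers}
    if not hexset:
        raise ValueError("hexamer set is empty")
    seq = seq.upper()
    covered = np.zeros(len(seq), dtype=bool)
    for i in range(len(seq) - 5):
        if seq[i : i + 6] in hexset:
            covered[i : i + 6] = True
    return covered


def ese_density(seq: str, hexamers: Iterable[str]) -> float:
    """Fraction of nucleotide positions covered by >=1 hexamer (overlaps merged)."""
    if len(seq) < 6:
        return 0.0
    covered = hexamer_coverage(seq, hexamers)
    return float(covered.sum() / len(seq))


def partition_codons_by_ese(
    codons: CodonSequence,
    hexamers: Iterable[str],
    sequence: str,
) -> tuple[CodonSequence, CodonSequence]:
    """Split codons into (overlapping, external) by hexamer coverage of
    ``sequence``, the nucleotide string in whose frame the codon offsets
    are expressed.  A codon overlaps if any of its 3 nt is covered."""
    covered = (
        hexamer_coverage(sequence, hexamers)
        if len(sequence) >= 6
        else np.zeros(len(sequence), dtype=bool)
    )
    over_c, over_o, ext_c, ext_o = [], [], [], []
    for codon, off in zip(codons.codons, codons.positions):
        if covered[off : off + 3].any():
            over_c.append(codon)
            over_o.append(off)
        else:
            ext_c.append(codon)
            ext_o.append(off)
    label = codons.source_label
    return (
        CodonSequence(tuple(over_c), f"{label}:ese", tuple(over_o)),
        CodonSequence(tuple(ext_c), f"{label}:non_ese", tuple(ext_o)),
    )


def read_hexamers(path) -> frozenset[str]:
    """One 6-mer per line; blank lines and '#' comments ignored."""
    hexamers = set()
    with open(path) as fh:
        for line in fh:
            line = line.strip().upper()
            if not line or line.startswith("#"):
                continue
            if len(line) != 6 or set(line) - set("ACGT"):
                raise ValueError(f"not a DNA hexamer: {line!r}")
            hexamers.add(line)
    return frozenset(hexamers)


def fop(
    codons: CodonSequence,
    optimal_codons: Iterable[str],
    mode: str = "raw",
) -> MetricValue:
    """Fraction of optimal codons.

    ``raw``: optimal codons over all codons of amino acids with >=2
    synonyms.  ``gc_controlled``: NFCU-style unweighted mean of optimal
    fractions within GC-matched synonymous subgroups that contain both
    optimal and non-optimal codons.
    """
    optimal = {c.upper() for c in optimal_codons}
    if not optimal:
        raise ValueError("optimal codon set is empty")
    from collections import Counter

    counts = Counter(codons.codons)
    n_skipped = sum(
        n for c, n in counts.items()
        if set(c) - _ACGT or c in gcode.STOP_CODONS
    )
    if mode == "raw":
        num = den = 0
        for codon, n in counts.items():
            if set(codon) - _ACGT or codon in gcode.STOP_CODONS:
                continue
            if len(gcode.synonymous_codons(gcode.GENETIC_CODE[codon])) < 2:
                continue
            den += n
            if codon in optimal:
                num += n
        value = num / den if den else None
        return MetricValue("Fop", value, (("all", num, den),), den, n_skipped)
    if mode == "gc_controlled":
        per_group, fractions, n_used = [], [], 0
        for aa in gcode.AMINO_ACIDS:
            fam = gcode.synonymous_codons(aa)
            if len(fam) < 2:
                continue
            by_gc: dict[int, list[str]] = {}
            for c in fam:
                by_gc.setdefault(gcode.gc_count(c), []).append(c)
            for gc, members in sorted(by_gc.items()):
                opt = [c for c in members if c in optimal]
                non = [c for c in members if c not in optimal]
                if not opt or not non:
                    continue
                den = sum(counts[c] for c in members)
                num = sum(counts[c] for c in opt)
                per_group.append((f"{aa}-GC{gc}", num, den))
                n_used += den
                if den:
                    fractions.append(num / den)
        value = sum(fractions) / len(fractions) if fractions else None
        return MetricValue(
            "Fop_GC", value, tuple(per_group), n_used, n_skipped
        )
    raise ValueError(f"unknown fop mode: {mode!r}")


_ACGT = frozenset("ACGT")


def structural_table(
    models: Sequence[TranscriptModel],
    hexamers: Iterable[str] | None = None,
    optimal_codons: Iterable[str] | None = None,
):
    """Per-gene structural summary table (one representative per gene)."""
    import pandas as pd

    rows = []
    for t in models:
        row = {
            "gene_id": t.gene_id,
            "transcript_id": t.transcript_id,
            "exon_count": t.exon_count,
            "cds_len_nt": t.cds_length_nt,
            "reliable_last_exon": (
                is_reliable_last_exon(t) if t.exon_count >= 2 else False
            ),
            "cds_in_last_exon": (
                cds_in_last_exon(t) if t.exon_count >= 2 else False
            ),
            "utr3_len": t.utr3_length,
            "flags": ",".join(t.flags),
        }
        coding = "".join(t.codons.codons)
        if hexamers is not None:
            row["ese_density"] = ese_density(coding, hexamers)
        if optimal_codons is not None:
            mv = fop(t.codons, optimal_codons, mode="raw")
            row["fop"] = mv.value
        rows.append(row)
    return pd.DataFrame(rows)
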