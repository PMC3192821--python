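"""Synthetic gene models with controllable fragile-codon/amino-acid usage.

Generates FASTA + GFF3 + a truth manifest so every pipeline stage can be
tested at desk scale.  Three approximately orthogonal knobs per gene class:

* ``phi`` -- multiplier on fragile codons within each synonymous family,
  applied per region (upstream exons vs last exon) so intragenic depletion
  is controllable;
* ``psi`` -- multiplier on fragile amino-acid frequencies;
* ``gc_target`` -- bias on codon choice among equal-fragility synonyms
  (GC-matched group members share total GC, so the within-group fragile
  odds stay exactly ``phi * f : r``).

Closed forms: a group with ``f`` fragile and ``r`` robust members at equal
base weight has expected fragile fraction ``phi*f / (phi*f + r)``; with
uniform base amino-acid frequencies the expected FAU is
``6*psi / (6*psi + 14)``.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Sequence

import numpy as np
from scipy.optimize import brentq

from . import genetic_code as gcode
from . import metrics

_NT = np.array(list("ACGT"))


# ---------------------------------------------------------------------------
# closed forms and calibration helpers

def _group_fraction(group, phi: float) -> float:
    f = len(group.fragile_members)
    r = len(group.members) - f
    return phi * f / (phi * f + r)


def expected_nfcu(phi: float, groups=None) -> float:
    """Expected per-group-averaged NFCU under fragile weight ``phi``."""
    if groups is None:
        groups = gcode.nfcu_groups("canonical")
    return float(np.mean([_group_fraction(g, phi) for g in groups]))


def phi_for_nfcu(target: float, groups=None) -> float:
    """Invert :func:`expected_nfcu` (strictly increasing in phi)."""
    if not 0.0 < target < 1.0:
        raise ValueError("target NFCU must be in (0, 1)")
    return float(
        brentq(lambda p: expected_nfcu(p, groups) - target, 1e-9, 1e9)
    )


def expected_fau(psi: float) -> float:
    """Expected FAU with uniform base amino-acid frequencies."""
    n_fragile = len(gcode.fragile_amino_acids())
    n_other = len(gcode.AMINO_ACIDS) - n_fragile
    if psi == 0:
        return 0.0
    return psi * n_fragile / (psi * n_fragile + n_other)


# ---------------------------------------------------------------------------
# sequence sampling primitives

def sample_peptide(
    length: int,
    psi: float,
    rng: np.random.Generator,
    base_freqs: dict[str, float] | None = None,
) -> str:
    """Random peptide; fragile amino acids drawn with frequency ~ psi * base."""
    if length < 1:
        raise ValueError("length must be >= 1")
    aas = np.array(gcode.AMINO_ACIDS)
    fragile = gcode.fragile_amino_acids()
    if base_freqs is None:
        base = np.ones(len(aas))
    else:
        base = np.array([base_freqs.get(aa, 0.0) for aa in aas])
    weights = base * np.array([psi if aa in fragile else 1.0 for aa in aas])
    if weights.sum() <= 0:
        raise ValueError("all amino-acid weights are zero")
    probs = weights / weights.sum()
    return "".join(rng.choice(aas, size=length, p=probs))


def _codon_weights(phi: float, gc_target: float) -> dict[str, tuple[np.ndarray, np.ndarray]]:
    """Per-amino-acid codon arrays and normalized choice probabilities."""
    if phi < 0:
        raise ValueError("phi must be >= 0")
    if not 0.0 < gc_target < 1.0:
        raise ValueError("gc_target must lie strictly between 0 and 1")
    out = {}
    for aa in gcode.AMINO_ACIDS:
        codons = np.array(gcode.synonymous_codons(aa))
        w = np.array(
            [
                (phi if gcode.is_fragile(c) else 1.0)
                * gc_target ** gcode.gc_count(c)
                * (1.0 - gc_target) ** (3 - gcode.gc_count(c))
                for c in codons
            ]
        )
        if w.sum() <= 0:  # phi == 0 and every codon fragile (e.g. Lys)
            w = np.array(
                [
                    gc_target ** gcode.gc_count(c)
                    * (1.0 - gc_target) ** (3 - gcode.gc_count(c))
                    for c in codons
                ]
            )
        out[aa] = (codons, w / w.sum())
    return out


_WEIGHT_CACHE: dict[tuple[float, float], dict] = {}


def _weights(phi: float, gc_target: float):
    key = (float(phi), float(gc_target))
    if key not in _WEIGHT_CACHE:
        _WEIGHT_CACHE[key] = _codon_weights(*key)
    return _WEIGHT_CACHE[key]


def reverse_translate(
    peptide: str,
    phi: float,
    gc_target: float,
    rng: np.random.Generator,
) -> list[str]:
    """Choose codons for a peptide with fragile weight ``phi`` and GC bias."""
    table = _weights(phi, gc_target)
    out = [""] * len(peptide)
    by_aa: dict[str, list[int]] = {}
    for i, aa in enumerate(peptide):
        by_aa.setdefault(aa, []).append(i)
    for aa, idxs in by_aa.items():
        codons, probs = table[aa]
        draws = rng.choice(codons, size=len(idxs), p=probs)
        for i, c in zip(idxs, draws):
            out[i] = str(c)
    return out


def random_dna(length: int, gc: float, rng: np.random.Generator) -> str:
    if length <= 0:
        return ""
    p = np.array([(1 - gc) / 2, gc / 2, gc / 2, (1 - gc) / 2])
    return "".join(rng.choice(_NT, size=length, p=p))


# ---------------------------------------------------------------------------
# configuration and gene records

@dataclass(frozen=True)
class ClassParams:
    """Generative parameters for one gene class."""

    n_genes: int
    single_exon: bool = False
    exon_count_range: tuple[int, int] = (3, 8)
    cds_length_range: tuple[int, int] = (150, 600)  # codons, stop excluded
    phi_upstream: float = 1.0
    phi_last: float = 1.0
    psi: float = 1.0
    gc_target: float = 0.5
    utr3_length_range: tuple[int, int] = (120, 400)
    short_utr3_fraction: float = 0.0  # genes given a 3' UTR under 100 nt
    downstream_noncoding_exon_fraction: float = 0.0
    last_exon_min_codons: int | None = None

    def __post_init__(self) -> None:
        if self.phi_upstream < 0 or self.phi_last < 0 or self.psi < 0:
            raise ValueError("weights must be non-negative")
        if self.n_genes < 0:
            raise ValueError("n_genes must be >= 0")


@dataclass(frozen=True)
class SyntheticConfig:
    classes: dict[str, ClassParams]
    seed: int = 0
    intron_length_range: tuple[int, int] = (60, 300)
    utr5_length_range: tuple[int, int] = (20, 100)
    intergenic_length_range: tuple[int, int] = (200, 500)
    genes_per_contig: int = 200
    base_aa_freqs: dict[str, float] | None = None


_MIN_CHUNK_NT = 30  # minimum coding nucleotides per upstream exon


@dataclass(frozen=True)
class GeneRecord:
    """In-memory truth for one synthetic gene."""

    gene_id: str
    gene_class: str
    strand: str
    codons: tuple[str, ...]  # sense codons, stop excluded
    peptide: str
    stop_codon: str
    junctions: tuple[int, ...]  # CDS-nt positions (stop included frame)
    utr5_len: int
    utr3_len: int
    intron_lens: tuple[int, ...]
    gc_target: float
    phi_upstream: float
    phi_last: float
    psi: float
    has_downstream_noncoding_exon: bool = False

    @property
    def exon_count(self) -> int:
        return (
            len(self.junctions)
            + 1
            + (1 if self.has_downstream_noncoding_exon else 0)
        )

    @property
    def cds_len_nt(self) -> int:
        return 3 * len(self.codons) + 3

    @property
    def last_junction(self) -> int | None:
        return self.junctions[-1] if self.junctions else None

    def region_of_codon(self, i: int) -> str:
        """'last' if codon i lies fully within the last coding exon."""
        j = self.last_junction
        if j is None:
            return "single"
        return "last" if 3 * i >= j else "upstream"

    def last_exon_codons(self) -> tuple[str, ...]:
        j = self.last_junction
        if j is None:
            return self.codons
        return tuple(c for i, c in enumerate(self.codons) if 3 * i >= j)

    def upstream_codons(self) -> tuple[str, ...]:
        """Codons fully upstream of the last junction (spanning codon omitted)."""
        j = self.last_junction
        if j is None:
            return ()
        return tuple(
            c for i, c in enumerate(self.codons) if 3 * i + 3 <= j
        )


def _sample_int(rng: np.random.Generator, lo_hi: tuple[int, int]) -> int:
    lo, hi = lo_hi
    return int(rng.integers(lo, hi + 1))


def _min_last_len(p: ClassParams) -> int:
    return (
        3 * (p.last_exon_min_codons + 2)
        if p.last_exon_min_codons is not None
        else _MIN_CHUNK_NT
    )


def _sample_last_len(
    p: ClassParams, cds_nt_len: int, rng: np.random.Generator
) -> int:
    """Coding nucleotides allotted to the last exon (stop included)."""
    min_last = _min_last_len(p)
    if min_last + _MIN_CHUNK_NT > cds_nt_len:
        raise ValueError(
            f"CDS of {cds_nt_len} nt cannot host a last exon of "
            f"{min_last} nt plus an upstream exon"
        )
    last_len = max(min_last, int(rng.uniform(0.3, 0.6) * cds_nt_len))
    return min(last_len, cds_nt_len - _MIN_CHUNK_NT)


def expected_last_codon_fraction(
    p: ClassParams, n: int = 4000, seed: int = 12345
) -> float:
    """Median fraction of codons fully inside the last exon under the
    class's structural distributions (Monte Carlo, deterministic seed)."""
    rng = np.random.default_rng(seed)
    fracs = np.empty(n)
    for i in range(n):
        length = _sample_int(rng, p.cds_length_range)
        cds_nt_len = 3 * length + 3
        last_len = _sample_last_len(p, cds_nt_len, rng)
        j = cds_nt_len - last_len
        n_last = length - (j + 2) // 3  # codons i with 3*i >= j
        fracs[i] = n_last / length
    return float(np.median(fracs))


def generate_genes(config: SyntheticConfig) -> list[GeneRecord]:
    """Sample all gene records (deterministic given config and seed)."""
    rng = np.random.default_rng(config.seed)
    records: list[GeneRecord] = []
    counter = 0
    for cls_name in sorted(config.classes):
        params = config.classes[cls_name]
        for _ in range(params.n_genes):
            counter += 1
            records.append(
                _generate_gene(
                    f"g{counter:06d}", cls_name, params, config, rng
                )
            )
    return records


def _generate_gene(
    gene_id: str,
    cls_name: str,
    p: ClassParams,
    config: SyntheticConfig,
    rng: np.random.Generator,
) -> GeneRecord:
    length = _sample_int(rng, p.cds_length_range)
    peptide = sample_peptide(length, p.psi, rng, config.base_aa_freqs)
    cds_nt_len = 3 * length + 3
    if p.single_exon:
        junctions: tuple[int, ...] = ()
        intron_lens: tuple[int, ...] = ()
        codons = reverse_translate(peptide, p.phi_upstream, p.gc_target, rng)
    else:
        n_exons = _sample_int(rng, p.exon_count_range)
        if n_exons < 2:
            raise ValueError("multi-exon class needs exon_count_range >= 2")
        last_len = _sample_last_len(p, cds_nt_len, rng)
        upstream_len = cds_nt_len - last_len
        n_up = min(n_exons - 1, max(1, upstream_len // _MIN_CHUNK_NT))
        extra = upstream_len - _MIN_CHUNK_NT * n_up
        alloc = rng.multinomial(extra, [1.0 / n_up] * n_up)
        chunk_lens = _MIN_CHUNK_NT + alloc
        junctions = tuple(int(x) for x in np.cumsum(chunk_lens))
        intron_lens = tuple(
            _sample_int(rng, config.intron_length_range)
            for _ in range(len(junctions))
        )
        jlast = junctions[-1]
        regions = [
            "last" if 3 * i >= jlast else "upstream" for i in range(length)
        ]
        codons = [""] * length
        for region, phi in (("upstream", p.phi_upstream), ("last", p.phi_last)):
            idxs = [i for i, r in enumerate(regions) if r == region]
            if not idxs:
                continue
            sub = reverse_translate(
                "".join(peptide[i] for i in idxs), phi, p.gc_target, rng
            )
            for i, c in zip(idxs, sub):
                codons[i] = c

    has_noncoding = (
        not p.single_exon
        and rng.random() < p.downstream_noncoding_exon_fraction
    )
    if has_noncoding:
        intron_lens = intron_lens + (
            _sample_int(rng, config.intron_length_range),
        )
    short = rng.random() < p.short_utr3_fraction
    utr3 = int(rng.integers(20, 80)) if short else _sample_int(
        rng, p.utr3_length_range
    )
    if has_noncoding:
        utr3 = max(utr3, 140)  # room to split across the extra exon
    stop = str(rng.choice(np.array(sorted(gcode.STOP_CODONS))))
    return GeneRecord(
        gene_id=gene_id,
        gene_class=cls_name,
        strand="+" if rng.random() < 0.5 else "-",
        codons=tuple(codons),
        peptide=peptide,
        stop_codon=stop,
        junctions=junctions,
        utr5_len=_sample_int(rng, config.utr5_length_range),
        utr3_len=utr3,
        intron_lens=intron_lens,
        gc_target=p.gc_target,
        phi_upstream=p.phi_upstream,
        phi_last=p.phi_last,
        psi=p.psi,
        has_downstream_noncoding_exon=has_noncoding,
    )


# ---------------------------------------------------------------------------
# genome assembly and file emission

@dataclass
class _TxLayout:
    sequence: str
    exons: list[tuple[int, int]]
    cds: list[tuple[int, int, int]]  # start, end, phase
    utr5: tuple[int, int] | None
    utr3: list[tuple[int, int]]


def _layout_transcript(
    rec: GeneRecord, config: SyntheticConfig, rng: np.random.Generator
) -> _TxLayout:
    """Transcript-oriented gene sequence plus local feature intervals."""
    cds_nt = "".join(rec.codons) + rec.stop_codon
    cuts = [0, *rec.junctions, len(cds_nt)]
    chunks = [cds_nt[a:b] for a, b in zip(cuts[:-1], cuts[1:])]
    gc = rec.gc_target
    utr5 = random_dna(rec.utr5_len, gc, rng)
    utr3 = random_dna(rec.utr3_len, gc, rng)

    parts: list[str] = []
    exons: list[tuple[int, int]] = []
    cds_ivs: list[tuple[int, int, int]] = []
    utr3_ivs: list[tuple[int, int]] = []
    pos = 0
    exon_start = 0
    parts.append(utr5)
    pos += len(utr5)
    utr5_iv = (0, len(utr5)) if utr5 else None
    acc = 0
    n_coding_introns = len(rec.junctions)
    for k, chunk in enumerate(chunks):
        phase = (3 - acc % 3) % 3
        cds_ivs.append((pos, pos + len(chunk), phase))
        acc += len(chunk)
        parts.append(chunk)
        pos += len(chunk)
        if k < len(chunks) - 1:
            exons.append((exon_start, pos))
            ilen = rec.intron_lens[k]
            parts.append(_intron(ilen, gc, rng))
            pos += ilen
            exon_start = pos
    if rec.has_downstream_noncoding_exon:
        head, tail = utr3[:60], utr3[60:]
        parts.append(head)
        pos += len(head)
        utr3_ivs.append((pos - len(head), pos))
        exons.append((exon_start, pos))
        ilen = rec.intron_lens[-1]
        parts.append(_intron(ilen, gc, rng))
        pos += ilen
        exon_start = pos
        parts.append(tail)
        pos += len(tail)
        utr3_ivs.append((exon_start, pos))
        exons.append((exon_start, pos))
    else:
        parts.append(utr3)
        pos += len(utr3)
        if utr3:
            utr3_ivs.append((pos - len(utr3), pos))
        exons.append((exon_start, pos))
    return _TxLayout(
        sequence="".join(parts),
        exons=exons,
        cds=cds_ivs,
        utr5=utr5_iv,
        utr3=utr3_ivs,
    )


def _intron(length: int, gc: float, rng: np.random.Generator) -> str:
    if length < 4:
        raise ValueError("introns must be at least 4 nt for GT..AG ends")
    return "GT" + random_dna(length - 4, gc, rng) + "AG"


_COMPLEMENT = str.maketrans("ACGT", "TGCA")


def _revcomp(seq: str) -> str:
    return seq.translate(_COMPLEMENT)[::-1]


@dataclass
class SyntheticGenome:
    records: list[GeneRecord]
    fasta_path: Path
    gff3_path: Path
    manifest_path: Path
    manifest: "object"  # pandas DataFrame


def build_genome(config: SyntheticConfig, out_dir) -> SyntheticGenome:
    """Emit FASTA + GFF3 + truth manifest for a sampled gene set.

    Byte-identical output for identical config and seed.  Gene placement
    uses non-overlapping coordinates with both strands; the layout RNG is
    separate from the gene-content RNG so structural knobs do not perturb
    sequence-level truth.
    """
    import pandas as pd

    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    records = generate_genes(config)
    rng = np.random.default_rng(config.seed + 1)

    contigs: list[tuple[str, str]] = []
    gff_lines: list[str] = [
        "##gff-version 3",
    ]
    cur_parts: list[str] = []
    cur_len = 0
    cur_name = "ctg00001"
    n_on_contig = 0

    def flush_contig():
        nonlocal cur_parts, cur_len, cur_name, n_on_contig
        if cur_parts:
            contigs.append((cur_name, "".join(cur_parts)))
            cur_name = f"ctg{len(contigs) + 1:05d}"
            cur_parts, cur_len, n_on_contig = [], 0, 0

    manifest_rows = []
    for rec in records:
        layout = _layout_transcript(rec, config, rng)
        spacer = random_dna(
            _sample_int(rng, config.intergenic_length_range), 0.4, rng
        )
        cur_parts.append(spacer)
        cur_len += len(spacer)
        offset = cur_len
        glen = len(layout.sequence)
        if rec.strand == "+":
            cur_parts.append(layout.sequence)
            conv = lambda iv: (offset + iv[0], offset + iv[1])
        else:
            cur_parts.append(_revcomp(layout.sequence))
            conv = lambda iv: (offset + glen - iv[1], offset + glen - iv[0])
        cur_len += glen

        tid = f"{rec.gene_id}.t1"
        gs, ge = conv((0, glen))
        attrs = [
            (
                "gene",
                gs,
                ge,
                ".",
                f"ID={rec.gene_id};gene_class={rec.gene_class}",
            ),
            ("mRNA", gs, ge, ".", f"ID={tid};Parent={rec.gene_id}"),
        ]
        for iv in layout.exons:
            s, e = conv(iv)
            attrs.append(("exon", s, e, ".", f"Parent={tid}"))
        for s0, e0, phase in layout.cds:
            s, e = conv((s0, e0))
            attrs.append(("CDS", s, e, str(phase), f"Parent={tid}"))
        if layout.utr5 is not None:
            s, e = conv(layout.utr5)
            attrs.append(("five_prime_UTR", s, e, ".", f"Parent={tid}"))
        for iv in layout.utr3:
            s, e = conv(iv)
            attrs.append(("three_prime_UTR", s, e, ".", f"Parent={tid}"))
        for ftype, s, e, phase, attr in attrs:
            gff_lines.append(
                "\t".join(
                    [
                        cur_name,
                        "txrobust_sim",
                        ftype,
                        str(s + 1),
                        str(e),
                        ".",
                        rec.strand,
                        phase,
                        attr,
                    ]
                )
            )

        mv_nfcu = metrics.nfcu(metrics.CodonSequence(rec.codons))
        mv_fau = metrics.fau(rec.peptide)
        row = {
            "gene_id": rec.gene_id,
            "class": rec.gene_class,
            "chrom": cur_name,
            "strand": rec.strand,
            "exon_count": rec.exon_count,
            "cds_len_nt": rec.cds_len_nt,
            "phi_upstream": rec.phi_upstream,
            "phi_last": rec.phi_last,
            "psi": rec.psi,
            "gc_target": rec.gc_target,
            "utr3_len": rec.utr3_len,
            "realized_nfcu": mv_nfcu.value,
            "realized_fau": mv_fau.value,
            "seed": config.seed,
        }
        manifest_rows.append(row)
        n_on_contig += 1
        if n_on_contig >= config.genes_per_contig:
            tail = random_dna(
                _sample_int(rng, config.intergenic_length_range), 0.4, rng
            )
            cur_parts.append(tail)
            cur_len += len(tail)
            flush_contig()
    if cur_parts:
        tail = random_dna(
            _sample_int(rng, config.intergenic_length_range), 0.4, rng
        )
        cur_parts.append(tail)
        cur_len += len(tail)
        flush_contig()

    fasta_path = out_dir / "genome.fa"
    with open(fasta_path, "w") as fh:
        for name, seq in contigs:
            fh.write(f">{name}\n")
            for i in range(0, len(seq), 80):
                fh.write(seq[i : i + 80] + "\n")
    gff3_path = out_dir / "annotation.gff3"
    with open(gff3_path, "w") as fh:
        fh.write("\n".join(gff_lines) + "\n")
    manifest = pd.DataFrame(manifest_rows)
    manifest_path = out_dir / "manifest.tsv"
    manifest.to_csv(manifest_path, sep="\t", index=False)
    return SyntheticGenome(
        records=records,
        fasta_path=fasta_path,
        gff3_path=gff3_path,
        manifest_path=manifest_path,
        manifest=manifest,
    )


# ---------------------------------------------------------------------------
# ortholog simulation

def _variant_tables():
    syn: dict[str, list[str]] = {}
    nonsyn: dict[str, list[str]] = {}
    for codon in gcode.SENSE_CODONS:
        aa = gcode.GENETIC_CODE[codon]
        s_list, n_list = [], []
        for pos in range(3):
            for nt in gcode.NUCLEOTIDES:
                if nt == codon[pos]:
                    continue
                mut = codon[:pos] + nt + codon[pos + 1 :]
                if mut in gcode.STOP_CODONS:
                    continue
                (s_list if gcode.GENETIC_CODE[mut] == aa else n_list).append(mut)
        syn[codon] = s_list
        nonsyn[codon] = n_list
    return syn, nonsyn


_SYN_VARIANTS, _NONSYN_VARIANTS = _variant_tables()


def simulate_ortholog(
    codons: Sequence[str],
    target_ks: float,
    omega: float,
    rng: np.random.Generator,
) -> tuple[str, ...]:
    """Mutate a CDS to approximate Ks = target_ks and Ka = omega * target_ks.

    Poisson numbers of synonymous and nonsynonymous substitution events are
    applied at sites drawn proportionally to each codon's current
    synonymous/nonsynonymous change counts; changes creating stop codons
    are never applied.  Multiple hits arise naturally and are handled by
    the estimator's multiple-hit correction.
    """
    if target_ks < 0 or omega < 0:
        raise ValueError("target_ks and omega must be non-negative")
    if target_ks > 1.5:
        warnings.warn("target_ks > 1.5: synonymous sites near saturation")
    from .evolution import syn_site_count

    seq = list(codons)
    total_sites = 3.0 * len(seq)
    S0 = sum(syn_site_count(c) for c in seq)
    N0 = total_sites - S0
    n_syn = int(rng.poisson(target_ks * S0))
    n_non = int(rng.poisson(omega * target_ks * N0))
    events = ["s"] * n_syn + ["n"] * n_non
    rng.shuffle(events)
    syn_w = np.array([len(_SYN_VARIANTS[c]) for c in seq], dtype=float)
    non_w = np.array([len(_NONSYN_VARIANTS[c]) for c in seq], dtype=float)
    for kind in events:
        w = syn_w if kind == "s" else non_w
        total = w.sum()
        if total == 0:
            continue
        i = int(rng.choice(len(seq), p=w / total))
        table = _SYN_VARIANTS if kind == "s" else _NONSYN_VARIANTS
        options = table[seq[i]]
        seq[i] = options[int(rng.integers(len(options)))]
        syn_w[i] = len(_SYN_VARIANTS[seq[i]])
        non_w[i] = len(_NONSYN_VARIANTS[seq[i]])
    return tuple(seq)


def random_cds(length: int, rng: np.random.Generator) -> tuple[str, ...]:
    """Uniform random sense codons (no stops), e.g. for estimator tests."""
    codons = np.array(gcode.SENSE_CODONS)
    return tuple(str(c) for c in rng.choice(codons, size=length))


# ---------------------------------------------------------------------------
# ready-made configurations

def recovery_config(
    n_multi: int = 2000,
    n_single: int = 500,
    n_histone: int = 0,
    single_multi_ratio: float = 1.0,
    last_upstream_ratio: float = 1.0,
    histone_multi_ratio: float | None = None,
    seed: int = 0,
    cds_length_range: tuple[int, int] = (150, 600),
    **overrides,
) -> SyntheticConfig:
    """Config whose generator-truth NFCU ratios match the requested targets.

    ``single_multi_ratio`` sets the expected single/multi-exon NFCU ratio
    at the gene level (accounting for the fact that a multi-exon gene's
    CDS mixes upstream codons at phi = 1 with last-exon codons at
    ``phi_last``); ``last_upstream_ratio`` sets the expected
    last-exon/upstream-exon ratio within multi-exon genes.
    """
    base = expected_nfcu(1.0)
    phi_last = phi_for_nfcu(base * last_upstream_ratio)
    structural = ClassParams(n_genes=1, cds_length_range=cds_length_range)
    lam = expected_last_codon_fraction(structural)
    groups = gcode.nfcu_groups("canonical")
    multi_expected = float(
        np.mean(
            [
                (1.0 - lam) * _group_fraction(g, 1.0)
                + lam * _group_fraction(g, phi_last)
                for g in groups
            ]
        )
    )
    phi_single = phi_for_nfcu(multi_expected * single_multi_ratio)
    classes = {
        "multi": ClassParams(
            n_genes=n_multi,
            cds_length_range=cds_length_range,
            phi_last=phi_last,
            **overrides,
        ),
        "single": ClassParams(
            n_genes=n_single,
            single_exon=True,
            cds_length_range=cds_length_range,
            phi_upstream=phi_single,
            **{k: v for k, v in overrides.items() if k != "exon_count_range"},
        ),
    }
    if n_histone:
        ratio = (
            histone_multi_ratio
            if histone_multi_ratio is not None
            else single_multi_ratio
        )
        classes["histone"] = ClassParams(
            n_genes=n_histone,
            single_exon=True,
            cds_length_range=(100, 200),
            phi_upstream=phi_for_nfcu(base * ratio),
        )
    return SyntheticConfig(classes=classes, seed=seed)
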