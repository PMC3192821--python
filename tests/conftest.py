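"""Shared fixtures: hand-assembled toy genomes written as FASTA + GFF3.

The builder here is deliberately independent of txrobust.synthetic_data so
that loader tests exercise a second, hand-checked code path.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import pytest

_COMPLEMENT = str.maketrans("ACGT", "TGCA")


def revcomp(seq: str) -> str:
    return seq.translate(_COMPLEMENT)[::-1]


# repeating non-stop codons used to fill hand-made coding sequences
_FILL = ["GCT", "GAA", "TCA", "CTG", "GGT", "ATG", "CAT", "TCT"]


def make_cds(n_codons: int, stop: str = "TAA") -> str:
    """Deterministic CDS of n sense codons plus a terminal stop."""
    codons = [_FILL[i % len(_FILL)] for i in range(n_codons)]
    return "".join(codons) + stop


@dataclass
class ToyGene:
    gene_id: str
    cds: str  # includes the terminal stop (or not, for bad fixtures)
    chunk_lens: list[int]  # CDS nt per exon, sums to len(cds)
    strand: str = "+"
    utr5: str = "ACGTACGTAC"
    utr3: str = "CT" * 75  # 150 nt, comfortably >= 100
    intron: str = "GT" + "ATAT" * 9 + "AG"  # 40 nt
    extra_noncoding_exon: bool = False  # splits the 3' UTR over a new exon
    utr5_own_exon: bool = False  # put the 5' UTR in a pure-UTR first exon


def _layout(gene: ToyGene):
    assert sum(gene.chunk_lens) == len(gene.cds), "chunks must cover the CDS"
    cuts = [0]
    for c in gene.chunk_lens:
        cuts.append(cuts[-1] + c)
    chunks = [gene.cds[a:b] for a, b in zip(cuts[:-1], cuts[1:])]
    parts, exons, cds_ivs, utr3_ivs = [], [], [], []
    pos, exon_start, acc = 0, 0, 0
    parts.append(gene.utr5)
    pos += len(gene.utr5)
    utr5_iv = (0, len(gene.utr5))
    if gene.utr5_own_exon:
        exons.append((0, pos))
        parts.append(gene.intron)
        pos += len(gene.intron)
        exon_start = pos
    for k, chunk in enumerate(chunks):
        phase = (3 - acc % 3) % 3
        cds_ivs.append((pos, pos + len(chunk), phase))
        acc += len(chunk)
        parts.append(chunk)
        pos += len(chunk)
        if k < len(chunks) - 1:
            exons.append((exon_start, pos))
            parts.append(gene.intron)
            pos += len(gene.intron)
            exon_start = pos
    if gene.extra_noncoding_exon:
        head, tail = gene.utr3[:50], gene.utr3[50:]
        parts.append(head)
        pos += len(head)
        utr3_ivs.append((pos - len(head), pos))
        exons.append((exon_start, pos))
        parts.append(gene.intron)
        pos += len(gene.intron)
        exon_start = pos
        parts.append(tail)
        pos += len(tail)
        utr3_ivs.append((exon_start, pos))
        exons.append((exon_start, pos))
    else:
        parts.append(gene.utr3)
        pos += len(gene.utr3)
        utr3_ivs.append((pos - len(gene.utr3), pos))
        exons.append((exon_start, pos))
    return "".join(parts), exons, cds_ivs, utr5_iv, utr3_ivs


def write_genome(tmp_path, genes, contig="chrT", spacer="T" * 100):
    """Write toy genes to FASTA + GFF3; returns (fasta_path, gff3_path)."""
    seq_parts = []
    gff = ["##gff-version 3"]
    pos = 0
    for gene in genes:
        seq_parts.append(spacer)
        pos += len(spacer)
        local_seq, exons, cds_ivs, utr5_iv, utr3_ivs = _layout(gene)
        glen = len(local_seq)
        offset = pos
        if gene.strand == "+":
            seq_parts.append(local_seq)
            conv = lambda iv: (offset + iv[0], offset + iv[1])
        else:
            seq_parts.append(revcomp(local_seq))
            conv = lambda iv: (offset + glen - iv[1], offset + glen - iv[0])
        pos += glen
        tid = f"{gene.gene_id}.t1"
        gs, ge = conv((0, glen))
        rows = [
            ("gene", gs, ge, ".", f"ID={gene.gene_id}"),
            ("mRNA", gs, ge, ".", f"ID={tid};Parent={gene.gene_id}"),
        ]
        for iv in exons:
            s, e = conv(iv)
            rows.append(("exon", s, e, ".", f"Parent={tid}"))
        for s0, e0, phase in cds_ivs:
            s, e = conv((s0, e0))
            rows.append(("CDS", s, e, str(phase), f"Parent={tid}"))
        s, e = conv(utr5_iv)
        rows.append(("five_prime_UTR", s, e, ".", f"Parent={tid}"))
        for iv in utr3_ivs:
            s, e = conv(iv)
            rows.append(("three_prime_UTR", s, e, ".", f"Parent={tid}"))
        for ftype, s, e, phase, attr in rows:
            gff.append(
                f"{contig}\ttest\t{ftype}\t{s + 1}\t{e}\t.\t{gene.strand}\t{phase}\t{attr}"
            )
    seq_parts.append(spacer)
    fasta_path = tmp_path / "toy.fa"
    gff3_path = tmp_path / "toy.gff3"
    fasta_path.write_text(f">{contig}\n" + "".join(seq_parts) + "\n")
    gff3_path.write_text("\n".join(gff) + "\n")
    return fasta_path, gff3_path


@pytest.fixture
def toy_genome_factory(tmp_path):
    def factory(genes, **kwargs):
        return write_genome(tmp_path, genes, **kwargs)

    return factory
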