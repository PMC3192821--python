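"""Pairwise Ka/Ks estimation (Nei-Gojobori 1986 with Jukes-Cantor correction).

Synonymous/nonsynonymous site counting treats substitutions that create a
stop codon as nonsynonymous, so that per sequence the two site classes sum
exactly to three times the codon count.  Multi-hit codons are resolved by
averaging over all substitution pathways that avoid stop-codon
intermediates (all pathways, if none avoids a stop).

An externally supplied Ka/Ks table can substitute for the built-in
estimator throughout the pipeline.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from functools import lru_cache
from itertools import permutations
from typing import Sequence

import numpy as np

from . import genetic_code as gcode

FLAG_SATURATED_SYN = "saturated_synonymous"
FLAG_SATURATED_NONSYN = "saturated_nonsynonymous"
FLAG_KS_ZERO = "ks_zero"


@dataclass(frozen=True)
class CodonAlignment:
    """A gapless, equal-length pair of codon sequences."""

    seq_a: tuple[str, ...]
    seq_b: tuple[str, ...]
    pair_id: str = ""

    def __post_init__(self) -> None:
        if len(self.seq_a) != len(self.seq_b):
            raise ValueError("aligned sequences differ in codon count")
        if not self.seq_a:
            raise ValueError("empty alignment")
        for codon in (*self.seq_a, *self.seq_b):
            if codon in gcode.STOP_CODONS:
                raise ValueError(f"stop codon in alignment: {codon}")
            if codon not in gcode.GENETIC_CODE:
                raise ValueError(f"invalid or ambiguous codon: {codon!r}")

    @classmethod
    def from_nt(cls, a: str, b: str, pair_id: str = "") -> "CodonAlignment":
        if len(a) != len(b) or len(a) % 3:
            raise ValueError("sequences must be equal length multiples of 3")
        split = lambda s: tuple(s[i : i + 3] for i in range(0, len(s), 3))
        sa, sb = split(a.upper()), split(b.upper())
        # drop a shared terminal stop if present
        if sa and sa[-1] in gcode.STOP_CODONS and sb[-1] in gcode.STOP_CODONS:
            sa, sb = sa[:-1], sb[:-1]
        return cls(seq_a=sa, seq_b=sb, pair_id=pair_id)


@dataclass(frozen=True)
class RatePair:
    ka: float | None
    ks: float | None
    ratio: float | None
    syn_sites: float
    nonsyn_sites: float
    syn_diffs: float
    nonsyn_diffs: float
    flags: tuple[str, ...] = ()


@lru_cache(maxsize=None)
def syn_site_count(codon: str) -> float:
    """Synonymous sites of one codon: per position, the fraction of the
    three possible changes that preserve the amino acid (changes to stop
    codons count as nonsynonymous)."""
    aa = gcode.GENETIC_CODE[codon]
    syn = 0
    for pos in range(3):
        for nt in gcode.NUCLEOTIDES:
            if nt == codon[pos]:
                continue
            mutant = codon[:pos] + nt + codon[pos + 1 :]
            if gcode.GENETIC_CODE[mutant] == aa:  # stops are "*", never equal
                syn += 1
    return syn / 3.0


@lru_cache(maxsize=None)
def codon_path_differences(a: str, b: str) -> tuple[float, float]:
    """(synonymous, nonsynonymous) differences between two sense codons,
    averaged over substitution pathways avoiding stop intermediates."""
    diff_pos = [i for i in range(3) if a[i] != b[i]]
    if not diff_pos:
        return 0.0, 0.0
    valid: list[tuple[int, int]] = []
    fallback: list[tuple[int, int]] = []
    for order in permutations(diff_pos):
        cur = a
        sd = nd = 0
        through_stop = False
        for pos in order:
            nxt = cur[:pos] + b[pos] + cur[pos + 1 :]
            if nxt in gcode.STOP_CODONS:
                through_stop = True
            if gcode.GENETIC_CODE[cur] == gcode.GENETIC_CODE[nxt]:
                sd += 1
            else:
                nd += 1
            cur = nxt
        (fallback if through_stop else valid).append((sd, nd))
    paths = valid or fallback
    sd = sum(p[0] for p in paths) / len(paths)
    nd = sum(p[1] for p in paths) / len(paths)
    return sd, nd


def jukes_cantor(p: float) -> float | None:
    """JC69 distance; ``None`` when the correction is undefined (p >= 3/4)."""
    if p < 0:
        raise ValueError("negative proportion")
    if p >= 0.75:
        return None
    return -0.75 * math.log1p(-4.0 * p / 3.0)


def ng86(pair: CodonAlignment) -> RatePair:
    """Nei-Gojobori (1986) Ka/Ks for one pairwise codon alignment."""
    s_a = sum(syn_site_count(c) for c in pair.seq_a)
    s_b = sum(syn_site_count(c) for c in pair.seq_b)
    total = 3.0 * len(pair.seq_a)
    S = 0.5 * (s_a + s_b)
    N = total - S
    sd = nd = 0.0
    for ca, cb in zip(pair.seq_a, pair.seq_b):
        d = codon_path_differences(ca, cb)
        sd += d[0]
        nd += d[1]
    ps = sd / S if S > 0 else 0.0
    pn = nd / N if N > 0 else 0.0
    flags: list[str] = []
    ks = jukes_cantor(ps)
    ka = jukes_cantor(pn)
    if ks is None:
        flags.append(FLAG_SATURATED_SYN)
    if ka is None:
        flags.append(FLAG_SATURATED_NONSYN)
    ratio: float | None = None
    if ks is not None and ka is not None:
        if ks == 0.0:
            flags.append(FLAG_KS_ZERO)
        else:
            ratio = ka / ks
    return RatePair(
        ka=ka,
        ks=ks,
        ratio=ratio,
        syn_sites=S,
        nonsyn_sites=N,
        syn_diffs=sd,
        nonsyn_diffs=nd,
        flags=tuple(flags),
    )


def pairwise_ks_matrix(
    seqs: Sequence[tuple[str, Sequence[str]]],
) -> tuple[list[str], np.ndarray]:
    """Symmetric Ks matrix over pre-aligned equal-length codon sequences.

    Cells for pairs whose estimate fails (saturation) are ``nan``.
    Returns (ids, matrix) with zero diagonal.
    """
    ids = [name for name, _ in seqs]
    n = len(seqs)
    mat = np.zeros((n, n))
    for i in range(n):
        for j in range(i + 1, n):
            try:
                rp = ng86(
                    CodonAlignment(
                        seq_a=tuple(seqs[i][1]),
                        seq_b=tuple(seqs[j][1]),
                        pair_id=f"{ids[i]}|{ids[j]}",
                    )
                )
                ks = rp.ks if rp.ks is not None else np.nan
            except ValueError:
                ks = np.nan
            mat[i, j] = mat[j, i] = ks
    return ids, mat


def cluster_by_ks(
    ids: Sequence[str], matrix: np.ndarray, threshold: float
) -> list[list[str]]:
    """Single-linkage clusters of sequences with pairwise Ks below
    ``threshold`` (redundancy filtering of near-identical paralogs)."""
    n = len(ids)
    parent = list(range(n))

    def find(i: int) -> int:
        while parent[i] != i:
            parent[i] = parent[parent[i]]
            i = parent[i]
        return i

    for i in range(n):
        for j in range(i + 1, n):
            if np.isfinite(matrix[i, j]) and matrix[i, j] < threshold:
                parent[find(i)] = find(j)
    clusters: dict[int, list[str]] = {}
    for i, name in enumerate(ids):
        clusters.setdefault(find(i), []).append(name)
    return sorted(clusters.values(), key=lambda c: c[0])


def select_longest_partner(
    candidates: Sequence[tuple[str, str]],
) -> tuple[str, str]:
    """Among (id, CDS) co-ortholog candidates keep the longest sequence,
    breaking length ties by identifier order (deterministic stand-in for a
    random choice)."""
    if not candidates:
        raise ValueError("no candidate sequences")
    return min(candidates, key=lambda item: (-len(item[1]), item[0]))


def rate_table(pairs: Sequence[tuple[str, RatePair]]):
    import pandas as pd

    return pd.DataFrame(
        {
            "pair_id": [pid for pid, _ in pairs],
            "ka": [rp.ka for _, rp in pairs],
            "ks": [rp.ks for _, rp in pairs],
            "ratio": [rp.ratio for _, rp in pairs],
            "flags": [",".join(rp.flags) for _, rp in pairs],
        }
    )


def load_kaks_table(path):
    """Read an externally computed Ka/Ks TSV (gene_id, ka, ks, ratio)."""
    import pandas as pd

    df = pd.read_csv(path, sep="\t")
    required = {"gene_id", "ka", "ks"}
    if missing := required - set(df.columns):
        raise ValueError(f"Ka/Ks table missing columns: {sorted(missing)}")
    if "ratio" not in df.columns:
        with np.errstate(divide="ignore", invalid="ignore"):
            df["ratio"] = np.where(df["ks"] > 0, df["ka"] / df["ks"], np.nan)
    return df
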