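"""Pairwise Ka/Ks estimation by the Nei–Gojobori (NG86) counting method.

For each codon, the number of synonymous sites is the sum over the three
positions of the fraction of possible single-base changes that preserve the
amino acid, computed over non-stop changes only (mutations to stop codons
are excluded from both numerator and denominator, so every position carries
weight 1 and each codon contributes exactly 3 sites).  Differences between
two codons are classified by averaging over all mutational pathways
(orderings of the mismatched positions), discarding pathways that pass
through a stop codon.  Proportions pN = Nd/N and pS = Sd/S are corrected
for multiple hits with the Jukes–Cantor formula d = −(3/4)·ln(1 − 4p/3).

The genetic code is NCBI translation table 11 (plastid/bacterial).  A
Ka/Ks ratio > 1 indicates positive (diversifying) selection, ≈ 1 neutral
evolution, < 1 purifying selection.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from itertools import combinations, permutations
from typing import Sequence

from .composition import GENETIC_CODE, STOP_CODONS
from .core_io import SequenceRecord

__all__ = [
    "count_sites",
    "count_differences",
    "KaKsResult",
    "kaks_pair",
    "classify_selection",
    "kaks_matrix",
]

_BASES = "ACGT"
_GAPS = frozenset("-.")


def _check_sense_codon(codon: str) -> None:
    if len(codon) != 3 or any(b not in _BASES for b in codon):
        raise ValueError(f"not an unambiguous codon: {codon!r}")
    if codon in STOP_CODONS:
        raise ValueError(f"stop codon {codon!r} has no defined site counts")


def count_sites(codon: str) -> tuple[float, float]:
    """Fractional (synonymous, nonsynonymous) site counts of one codon.

    Each position contributes the fraction of its non-stop single-base
    changes that are synonymous; the two counts always sum to 3.
    """
    _check_sense_codon(codon)
    aa = GENETIC_CODE[codon]
    syn = 0.0
    for pos in range(3):
        n_syn = n_valid = 0
        for b in _BASES:
            if b == codon[pos]:
                continue
            mutant = codon[:pos] + b + codon[pos + 1 :]
            if mutant in STOP_CODONS:
                continue
            n_valid += 1
            if GENETIC_CODE[mutant] == aa:
                n_syn += 1
        # every sense codon has ≥1 non-stop neighbour per position
        syn += n_syn / n_valid
    return syn, 3.0 - syn


def count_differences(codon_a: str, codon_b: str) -> tuple[float, float]:
    """Fractional (synonymous, nonsynonymous) differences between codons.

    Averages the per-step classification over all orderings of the
    mismatched positions; pathways passing through a stop codon are
    discarded (if every pathway is blocked, all are used as a fallback).
    The two counts sum to the Hamming distance.
    """
    _check_sense_codon(codon_a)
    _check_sense_codon(codon_b)
    diff_pos = [i for i in range(3) if codon_a[i] != codon_b[i]]
    if not diff_pos:
        return 0.0, 0.0
    pathways: list[tuple[int, int]] = []  # (syn steps, nonsyn steps)
    blocked: list[tuple[int, int]] = []
    for order in permutations(diff_pos):
        current = codon_a
        syn = nonsyn = 0
        hit_stop = False
        for pos in order:
            nxt = current[:pos] + codon_b[pos] + current[pos + 1 :]
            if nxt in STOP_CODONS:
                hit_stop = True
            if GENETIC_CODE.get(nxt, "*") == GENETIC_CODE[current]:
                syn += 1
            else:
                nonsyn += 1
            current = nxt
        (blocked if hit_stop else pathways).append((syn, nonsyn))
    used = pathways or blocked
    k = len(used)
    return sum(p[0] for p in used) / k, sum(p[1] for p in used) / k


def _jukes_cantor(p: float) -> float:
    """JC69 multiple-hit correction of a proportion of differences."""
    if p == 0.0:
        return 0.0
    return -0.75 * math.log(1.0 - 4.0 * p / 3.0)


@dataclass(frozen=True)
class KaKsResult:
    """NG86 estimates for one sequence pair (one gene)."""

    pair: tuple[str, str]
    gene: str
    n_codons: int
    S_sites: float
    N_sites: float
    Sd: float
    Nd: float
    pS: float
    pN: float
    Ks: float | None
    Ka: float | None
    ratio: float | None
    saturated: bool = False

    @property
    def defined(self) -> bool:
        return self.ratio is not None

    def selection_class(self, delta: float = 0.1) -> str:
        return classify_selection(self.ratio, delta)


def _codon_columns(seq_a: str, seq_b: str, name_a: str, name_b: str) -> list[tuple[str, str]]:
    if len(seq_a) != len(seq_b):
        raise ValueError(
            f"aligned sequences differ in length: {name_a!r} {len(seq_a)} bp, "
            f"{name_b!r} {len(seq_b)} bp"
        )
    if len(seq_a) % 3 != 0:
        raise ValueError("aligned length not divisible by 3")
    cols = []
    for i in range(0, len(seq_a), 3):
        ca, cb = seq_a[i : i + 3], seq_b[i : i + 3]
        # pairwise deletion: skip codon columns with gaps, ambiguity or stops
        if set(ca) & _GAPS or set(cb) & _GAPS:
            continue
        if any(b not in _BASES for b in ca + cb):
            continue
        if ca in STOP_CODONS or cb in STOP_CODONS:
            continue
        cols.append((ca, cb))
    return cols


def kaks_pair(
    cds_a: SequenceRecord | str,
    cds_b: SequenceRecord | str,
    gene: str = "",
) -> KaKsResult:
    """NG86 Ka, Ks and Ka/Ks for one codon-aligned CDS pair.

    Site counts are averaged over the two sequences; the ratio is flagged
    undefined when Ks = 0, and the result is marked saturated (rates set
    to None) when either proportion reaches the JC69 ceiling p ≥ 3/4.
    """
    name_a, seq_a = _as_named_seq(cds_a, "a")
    name_b, seq_b = _as_named_seq(cds_b, "b")
    cols = _codon_columns(seq_a, seq_b, name_a, name_b)
    if not cols:
        raise ValueError(f"no comparable codon columns for pair ({name_a!r}, {name_b!r})")
    S_a = N_a = S_b = N_b = Sd = Nd = 0.0
    for ca, cb in cols:
        sa, na = count_sites(ca)
        sb, nb = count_sites(cb)
        S_a += sa
        N_a += na
        S_b += sb
        N_b += nb
        sd, nd = count_differences(ca, cb)
        Sd += sd
        Nd += nd
    S = (S_a + S_b) / 2.0
    N = (N_a + N_b) / 2.0
    pS = Sd / S if S > 0 else 0.0
    pN = Nd / N if N > 0 else 0.0
    # each rate is corrected independently; only a proportion at or past
    # the JC69 ceiling leaves its own rate (and hence the ratio) undefined
    saturated = pS >= 0.75 or pN >= 0.75
    Ks = _jukes_cantor(pS) if pS < 0.75 else None
    Ka = _jukes_cantor(pN) if pN < 0.75 else None
    ratio = Ka / Ks if (Ka is not None and Ks is not None and Ks > 0) else None
    return KaKsResult(
        pair=(name_a, name_b),
        gene=gene,
        n_codons=len(cols),
        S_sites=S,
        N_sites=N,
        Sd=Sd,
        Nd=Nd,
        pS=pS,
        pN=pN,
        Ks=Ks,
        Ka=Ka,
        ratio=ratio,
        saturated=saturated,
    )


def _as_named_seq(
    cds: SequenceRecord | str | tuple[str, str], fallback: str
) -> tuple[str, str]:
    # aligned input may carry gap columns, which SequenceRecord forbids,
    # so (name, sequence) tuples are accepted alongside records
    if isinstance(cds, SequenceRecord):
        return cds.id, cds.sequence
    if isinstance(cds, tuple):
        return cds[0], cds[1].upper()
    return fallback, cds.upper()


def classify_selection(ratio: float | None, delta: float = 0.1) -> str:
    """Map a Ka/Ks ratio to a selection regime.

    ``positive`` for ratio > 1+delta, ``purifying`` for ratio < 1−delta,
    ``neutral`` inside the band, ``undetermined`` for an undefined ratio.
    """
    if ratio is None:
        return "undetermined"
    if ratio > 1.0 + delta:
        return "positive"
    if ratio < 1.0 - delta:
        return "purifying"
    return "neutral"


def kaks_matrix(
    gene: str,
    cds_set: Sequence[SequenceRecord | tuple[str, str]],
) -> list[KaKsResult]:
    """All-unordered-pairs NG86 results for a mutually aligned CDS set."""
    if len(cds_set) < 2:
        raise ValueError("need at least two sequences")
    ids = [_as_named_seq(r, str(i))[0] for i, r in enumerate(cds_set)]
    if len(set(ids)) != len(ids):
        raise ValueError("duplicate sequence ids")
    results = []
    for (ia, a), (ib, b) in combinations(zip(ids, cds_set), 2):
        try:
            results.append(kaks_pair(a, b, gene=gene))
        except ValueError as exc:
            raise ValueError(f"pair ({ia!r}, {ib!r}): {exc}") from exc
    return results
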