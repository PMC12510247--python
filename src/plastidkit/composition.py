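"""Nucleotide composition and codon-usage analysis.

Composition statistics (GC content, AT skew and its sliding-window profile)
describe base asymmetries of the plastome.  Codon-usage bias is quantified
as relative synonymous codon usage (RSCU): the observed count of a codon
divided by the mean count of its synonymous family, so RSCU = 1 means no
bias within the family.  Cross-species RSCU matrices are clustered by UPGMA
on Euclidean distances, the convention used for plastome codon heatmaps.

The genetic code is NCBI translation table 11 (plastid/bacterial).  By
default stop codons and the single-codon families (ATG/Met, TGG/Trp) are
excluded from RSCU matrices since they carry no synonymous choice.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from Bio.Data import CodonTable
from Bio.Seq import Seq
from scipy.cluster import hierarchy
from scipy.spatial.distance import pdist, squareform

from .core_io import SequenceRecord

__all__ = [
    "GENETIC_CODE",
    "STOP_CODONS",
    "SYNONYMOUS_FAMILIES",
    "gc_content",
    "at_skew",
    "windowed_at_skew",
    "CodonExtraction",
    "extract_codons",
    "rscu",
    "CodonUsageProfile",
    "rscu_matrix",
    "ClusterDendrogram",
    "upgma",
]

_TABLE = CodonTable.unambiguous_dna_by_id[11]
ALL_CODONS = tuple(a + b + c for a in "TCAG" for b in "TCAG" for c in "TCAG")
STOP_CODONS = frozenset(_TABLE.stop_codons)
#: codon → amino-acid letter ('*' for stops), translation table 11
GENETIC_CODE: dict[str, str] = {
    c: (_TABLE.forward_table[c] if c not in STOP_CODONS else "*") for c in ALL_CODONS
}
#: amino acid → tuple of synonymous codons
SYNONYMOUS_FAMILIES: dict[str, tuple[str, ...]] = {}
for _codon, _aa in GENETIC_CODE.items():
    SYNONYMOUS_FAMILIES.setdefault(_aa, ())
    SYNONYMOUS_FAMILIES[_aa] += (_codon,)

_SINGLE_CODON_FAMILIES = frozenset(
    c for aa, fam in SYNONYMOUS_FAMILIES.items() if aa != "*" and len(fam) == 1 for c in fam
)


# ---------------------------------------------------------------------------
# base composition
# ---------------------------------------------------------------------------

def gc_content(seq: str) -> float:
    """(G+C) / (A+C+G+T); N's are ignored on both sides of the ratio."""
    seq = seq.upper()
    counts = {b: seq.count(b) for b in "ACGT"}
    denom = sum(counts.values())
    if denom == 0:
        raise ValueError("sequence has no unambiguous bases")
    return (counts["G"] + counts["C"]) / denom


def at_skew(seq: str) -> float:
    """AT skew = (A − T) / (A + T); positive means A-rich."""
    seq = seq.upper()
    a, t = seq.count("A"), seq.count("T")
    if a + t == 0:
        raise ValueError("AT skew undefined: sequence contains no A or T")
    return (a - t) / (a + t)


def windowed_at_skew(
    seq: str,
    window: int = 500,
    step: int = 200,
    circular: bool = True,
) -> list[tuple[int, float]]:
    """Sliding-window AT skew; returns (1-based window start, skew) pairs.

    In circular mode windows starting near the end wrap across the origin,
    so every start position 1, 1+step, ... up to the sequence length yields
    a full-length window.
    """
    if window < 1 or step < 1:
        raise ValueError("window and step must be ≥ 1")
    n = len(seq)
    if not circular and window > n:
        raise ValueError(f"window {window} longer than sequence ({n} bp)")
    out: list[tuple[int, float]] = []
    if circular:
        doubled = seq + seq
        starts = range(0, n, step)
        for s in starts:
            out.append((s + 1, at_skew(doubled[s : s + window])))
    else:
        for s in range(0, n - window + 1, step):
            out.append((s + 1, at_skew(seq[s : s + window])))
    return out


# ---------------------------------------------------------------------------
# codon extraction and RSCU
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class CodonExtraction:
    """Codons of one CDS in reading frame, with stop-codon bookkeeping."""

    codons: tuple[str, ...]
    has_terminal_stop: bool
    internal_stop_indices: tuple[int, ...] = ()

    @property
    def sense_codons(self) -> tuple[str, ...]:
        """Codons without the terminal stop (internal stops retained)."""
        return self.codons[:-1] if self.has_terminal_stop else self.codons


def extract_codons(cds: SequenceRecord | str, strand: str = "+") -> CodonExtraction:
    """Split a CDS into consecutive triplets; minus-strand input is
    reverse-complemented first.

    The terminal stop codon is retained but flagged; internal stops raise a
    warning (annotation slippage, not fatal).  Length not divisible by 3 is
    an error naming the gene.
    """
    if isinstance(cds, SequenceRecord):
        name, seq = cds.id, cds.sequence
    else:
        name, seq = "<anonymous>", cds.upper()
    if strand == "-":
        seq = str(Seq(seq).reverse_complement())
    elif strand != "+":
        raise ValueError("strand must be + or -")
    if len(seq) % 3 != 0:
        raise ValueError(f"CDS {name!r}: length {len(seq)} not divisible by 3")
    codons = tuple(seq[i : i + 3] for i in range(0, len(seq), 3))
    has_terminal_stop = bool(codons) and codons[-1] in STOP_CODONS
    internal = tuple(
        i for i, c in enumerate(codons[:-1] if has_terminal_stop else codons)
        if c in STOP_CODONS
    )
    if internal:
        warnings.warn(
            f"CDS {name!r}: internal stop codon(s) at codon index {internal}",
            stacklevel=2,
        )
    return CodonExtraction(codons, has_terminal_stop, internal)


def rscu(
    codon_counts: Mapping[str, int],
    include_stops: bool = False,
    include_single_codon_families: bool = False,
) -> dict[str, float]:
    """RSCU per codon: count divided by the mean count of its family.

    Families with zero total usage map to 0.0 for every member.  Stop
    codons and single-codon families are excluded by default (they carry
    no synonymous signal); flags restore them.
    """
    for c, n in codon_counts.items():
        if c not in GENETIC_CODE:
            raise ValueError(f"unknown codon {c!r}")
        if n < 0:
            raise ValueError(f"negative count for codon {c!r}")
    out: dict[str, float] = {}
    for aa, family in SYNONYMOUS_FAMILIES.items():
        if aa == "*" and not include_stops:
            continue
        if not include_single_codon_families and set(family) <= _SINGLE_CODON_FAMILIES:
            continue
        total = sum(codon_counts.get(c, 0) for c in family)
        for c in family:
            out[c] = 0.0 if total == 0 else codon_counts.get(c, 0) * len(family) / total
    return out


@dataclass
class CodonUsageProfile:
    """Per-species 64-codon counts and the derived RSCU vector."""

    species_id: str
    codon_counts: dict[str, int]
    include_stops: bool = False
    include_single_codon_families: bool = False
    rscu: dict[str, float] = field(init=False)

    def __post_init__(self) -> None:
        self.codon_counts = {c: int(self.codon_counts.get(c, 0)) for c in ALL_CODONS}
        self.rscu = rscu(
            self.codon_counts,
            include_stops=self.include_stops,
            include_single_codon_families=self.include_single_codon_families,
        )

    @property
    def total_codons(self) -> int:
        return sum(self.codon_counts.values())

    @property
    def zero_usage_families(self) -> tuple[str, ...]:
        """Amino acids whose whole synonymous family is unused."""
        return tuple(
            aa
            for aa, fam in SYNONYMOUS_FAMILIES.items()
            if aa != "*" and all(self.codon_counts[c] == 0 for c in fam)
        )

    @classmethod
    def from_cds(
        cls,
        species_id: str,
        cds_records: Iterable[SequenceRecord],
        strands: Mapping[str, str] | None = None,
        **kwargs,
    ) -> "CodonUsageProfile":
        """Count codons over a species' CDS set (terminal stops dropped)."""
        counts: dict[str, int] = {}
        for rec in cds_records:
            strand = (strands or {}).get(rec.id, "+")
            for codon in extract_codons(rec, strand).sense_codons:
                if "N" in codon:
                    continue
                counts[codon] = counts.get(codon, 0) + 1
        return cls(species_id, counts, **kwargs)


def rscu_matrix(profiles: Sequence[CodonUsageProfile]) -> pd.DataFrame:
    """Species × codon RSCU matrix (rows: species, columns: retained codons)."""
    if len(profiles) < 2:
        raise ValueError("need at least two species for a cross-species matrix")
    ids = [p.species_id for p in profiles]
    if len(set(ids)) != len(ids):
        raise ValueError("duplicate species ids")
    flags = {(p.include_stops, p.include_single_codon_families) for p in profiles}
    if len(flags) != 1:
        raise ValueError("profiles built with inconsistent exclusion policies")
    columns = sorted(profiles[0].rscu)
    data = [[p.rscu.get(c, 0.0) for c in columns] for p in profiles]
    return pd.DataFrame(data, index=ids, columns=columns)


# ---------------------------------------------------------------------------
# UPGMA clustering
# ---------------------------------------------------------------------------

@dataclass
class ClusterDendrogram:
    """UPGMA result: merge order plus the resulting leaf permutation.

    Heights follow the ultrametric convention (merge distance / 2), so
    leaf-to-root path length equals half the cophenetic distance.
    """

    labels: list[str]
    merges: list[tuple[tuple[str, ...], tuple[str, ...], float]]
    leaf_order: list[str]
    linkage: np.ndarray

    def to_newick(self) -> str:
        n = len(self.labels)
        nodes: dict[int, tuple[str, float]] = {
            i: (lbl, 0.0) for i, lbl in enumerate(self.labels)
        }
        for k, (i, j, dist, _count) in enumerate(self.linkage):
            h = dist / 2.0
            (li, hi), (lj, hj) = nodes[int(i)], nodes[int(j)]
            nodes[n + k] = (f"({li}:{h - hi:.6g},{lj}:{h - hj:.6g})", h)
        return nodes[2 * n - 2][0] + ";"


def upgma(
    dist: pd.DataFrame | np.ndarray,
    labels: Sequence[str] | None = None,
) -> ClusterDendrogram:
    """Average-linkage (UPGMA) clustering of a symmetric distance matrix.

    Ties are broken deterministically by sorting labels lexicographically
    before agglomeration.  Heights are merge distance / 2.
    """
    if isinstance(dist, pd.DataFrame):
        labels = list(dist.index)
        mat = dist.to_numpy(dtype=float)
    else:
        mat = np.asarray(dist, dtype=float)
        labels = list(labels) if labels is not None else [str(i) for i in range(len(mat))]
    if mat.ndim != 2 or mat.shape[0] != mat.shape[1]:
        raise ValueError("distance matrix must be square")
    if np.any(np.abs(np.diag(mat)) > 1e-9):
        raise ValueError("distance matrix diagonal must be zero")
    if np.max(np.abs(mat - mat.T)) > 1e-9:
        raise ValueError("distance matrix is not symmetric (tolerance 1e-9)")
    if np.any(mat < 0):
        raise ValueError("distances must be non-negative")
    order = np.argsort(np.asarray(labels, dtype=object))
    labels_sorted = [labels[i] for i in order]
    mat = mat[np.ix_(order, order)]
    Z = hierarchy.linkage(squareform(mat, checks=False), method="average")
    n = len(labels_sorted)
    members: dict[int, tuple[str, ...]] = {i: (l,) for i, l in enumerate(labels_sorted)}
    merges: list[tuple[tuple[str, ...], tuple[str, ...], float]] = []
    for k, (i, j, d, _cnt) in enumerate(Z):
        a, b = members[int(i)], members[int(j)]
        merges.append((a, b, d / 2.0))
        members[n + k] = tuple(sorted(a + b))
    leaf_order = [labels_sorted[i] for i in hierarchy.leaves_list(Z)]
    return ClusterDendrogram(labels_sorted, merges, leaf_order, Z)


def euclidean_distance_matrix(matrix: pd.DataFrame) -> pd.DataFrame:
    """Pairwise Euclidean distances between matrix rows (species)."""
    d = squareform(pdist(matrix.to_numpy(dtype=float), metric="euclidean"))
    return pd.DataFrame(d, index=matrix.index, columns=matrix.index)
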