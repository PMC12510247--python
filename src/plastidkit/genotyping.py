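"""SNP-profile genotyping of a breeding population.

Individuals are compared by their call profiles over a panel of chloroplast
SNP loci.  Because conifer chloroplasts are paternally inherited and
non-recombining, a profile is a single haplotype; two individuals with
identical profiles cannot be told apart by the panel and form a duplicate
group (candidate same-father offspring).

Symbol semantics: ``'-'`` (reference) is an informative value, and an
ambiguous ``'N'`` call is treated as its own literal symbol — both for
profile equality and for counting an individual as variant-bearing.  An
'N'-as-wildcard reading would merge distinct near-reference profiles and
is deliberately not used.
"""

from __future__ import annotations

from dataclasses import dataclass
from decimal import ROUND_HALF_UP, Decimal

from .composition import gc_content
from .core_io import GenotypeMatrix, PrimerPair

__all__ = [
    "DiscriminationReport",
    "discriminate",
    "greedy_panel",
    "amplicon_length",
    "primer_gc",
    "PrimerCheck",
    "validate_primer_table",
]


@dataclass
class DiscriminationReport:
    """How well a SNP panel separates the individuals of a population."""

    n_individuals: int
    n_with_variants: int
    n_reference_matching: int
    n_distinguished: int
    duplicate_groups: list[tuple[str, ...]]

    @property
    def n_grouped(self) -> int:
        return sum(len(g) for g in self.duplicate_groups)

    @property
    def distinguished_fraction(self) -> float:
        return self.n_distinguished / self.n_individuals

    def __post_init__(self) -> None:
        if self.n_distinguished + self.n_grouped != self.n_individuals:
            raise ValueError("distinguished + grouped must equal population size")


def discriminate(gm: GenotypeMatrix) -> DiscriminationReport:
    """Partition individuals into unique profiles and duplicate groups.

    Profiles are compared by strict symbol equality over all loci; an
    individual is "distinguished" iff its profile is unique.  The all-'-'
    profile counts as reference-matching (and is distinguishable like any
    other unique profile).
    """
    if gm.n_individuals == 0:
        raise ValueError("empty genotype matrix")
    by_profile: dict[tuple[str, ...], list[str]] = {}
    for ind, row in zip(gm.individuals, gm.calls):
        by_profile.setdefault(tuple(row), []).append(ind)
    groups = sorted(
        (tuple(inds) for inds in by_profile.values() if len(inds) >= 2),
        key=lambda g: (-len(g), g),
    )
    n_distinguished = sum(1 for inds in by_profile.values() if len(inds) == 1)
    n_ref = sum(1 for row in gm.calls if all(s == "-" for s in row))
    n_var = gm.n_individuals - n_ref
    return DiscriminationReport(
        n_individuals=gm.n_individuals,
        n_with_variants=n_var,
        n_reference_matching=n_ref,
        n_distinguished=n_distinguished,
        duplicate_groups=groups,
    )


def _distinguished_count(gm: GenotypeMatrix, loci: list[int]) -> int:
    if not loci:
        # zero loci: every individual shares the empty profile
        return 1 if gm.n_individuals == 1 else 0
    seen: dict[tuple[str, ...], int] = {}
    for row in gm.calls:
        key = tuple(row[j] for j in loci)
        seen[key] = seen.get(key, 0) + 1
    return sum(1 for n in seen.values() if n == 1)


def greedy_panel(gm: GenotypeMatrix, max_loci: int) -> tuple[list[str], int]:
    """Greedy forward selection of a minimal discriminating locus panel.

    At each step the locus giving the largest gain in distinguished
    individuals is added (ties broken by leftmost column); selection stops
    at ``max_loci`` or when no locus improves the count.  Returns the
    chosen locus ids in selection order and the panel's distinguished
    count.
    """
    if max_loci < 1:
        raise ValueError("max_loci must be ≥ 1")
    chosen: list[int] = []
    current = _distinguished_count(gm, chosen)
    while len(chosen) < max_loci:
        best_j, best_score = None, current
        for j in range(gm.n_loci):
            if j in chosen:
                continue
            score = _distinguished_count(gm, chosen + [j])
            if score > best_score:
                best_j, best_score = j, score
        if best_j is None:
            break
        chosen.append(best_j)
        current = best_score
    return [gm.locus_ids[j] for j in chosen], current


def amplicon_length(forward_start: int, reverse_start: int) -> int:
    """PCR product length between two 1-based inclusive primer starts."""
    if forward_start > reverse_start:
        raise ValueError("forward primer must start before (or at) the reverse primer")
    return reverse_start - forward_start + 1


def primer_gc(seq: str) -> float:
    """GC percentage of a primer, half-up rounded to 2 decimals."""
    seq = seq.upper()
    if not seq:
        raise ValueError("empty primer sequence")
    if set(seq) - set("ACGT"):
        raise ValueError(f"primer contains ambiguous bases: {seq!r}")
    pct = Decimal(100 * gc_content(seq))
    return float(pct.quantize(Decimal("0.01"), rounding=ROUND_HALF_UP))


@dataclass(frozen=True)
class PrimerCheck:
    """Recomputed vs declared primer arithmetic for one pair."""

    pair_id: str
    computed_length: int
    declared_length: int
    computed_gc_f: float
    declared_gc_f: float
    computed_gc_r: float
    declared_gc_r: float

    @property
    def length_ok(self) -> bool:
        return self.computed_length == self.declared_length

    @property
    def gc_ok(self) -> bool:
        return (
            abs(self.computed_gc_f - self.declared_gc_f) < 0.005
            and abs(self.computed_gc_r - self.declared_gc_r) < 0.005
        )

    @property
    def ok(self) -> bool:
        return self.length_ok and self.gc_ok


def validate_primer_table(primers: list[PrimerPair]) -> list[PrimerCheck]:
    """Recompute amplicon length and GC% per pair against declared values."""
    return [
        PrimerCheck(
            pair_id=p.pair_id,
            computed_length=amplicon_length(p.forward_start, p.reverse_start),
            declared_length=p.declared_amplicon_length,
            computed_gc_f=primer_gc(p.forward_seq),
            declared_gc_f=p.declared_gc_f,
            computed_gc_r=primer_gc(p.reverse_seq),
            declared_gc_r=p.declared_gc_r,
        )
        for p in primers
    ]
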