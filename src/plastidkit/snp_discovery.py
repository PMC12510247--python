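"""Variant detection from pooled allele counts, gene/IGS annotation, and
mutation-table summary statistics.

The pooled-sequencing design mixes the population's chloroplast DNA and
sequences it as one library, so a variant's "rate" is the fraction of reads
carrying the alternate allele at that site — not a fraction of individuals.
Sites where more than one alternate base passes the thresholds collapse
into a single dual-allele record, as mutation tables print them
("C/G" with "0.11/0.01").

Annotation follows the gene table: a coordinate inside an annotated gene
(including tRNA genes) is genic; anything else is assigned to the
intergenic spacer ``left~right`` between its nearest flanking genes.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

from .core_io import GeneFeature, SequenceRecord, VariantRecord

__all__ = [
    "AlleleCounts",
    "call_pooled_variants",
    "annotate_variant",
    "VariantSummary",
    "summarize_variants",
]

_BASES = ("A", "C", "G", "T")


@dataclass(frozen=True)
class AlleleCounts:
    """Pooled read counts per base at one reference coordinate."""

    coordinate: int
    counts: Mapping[str, int]

    def __post_init__(self) -> None:
        for b, n in self.counts.items():
            if b not in _BASES:
                raise ValueError(f"site {self.coordinate}: unknown base {b!r}")
            if n < 0:
                raise ValueError(f"site {self.coordinate}: negative count")

    @property
    def coverage(self) -> int:
        return sum(self.counts.values())


def call_pooled_variants(
    ref: SequenceRecord,
    counts: Iterable[AlleleCounts],
    min_rate: float = 0.01,
    min_coverage: int = 10,
) -> list[VariantRecord]:
    """Call SNPs from pooled allele counts against the reference.

    At each site every non-reference base whose read fraction is at least
    ``min_rate`` becomes an alternate allele (rate rounded to 2 decimals);
    sites below ``min_coverage`` are skipped.  Multiple passing alternates
    yield one dual-allele record, ordered by descending rate.
    """
    variants: list[VariantRecord] = []
    for site in sorted(counts, key=lambda s: s.coordinate):
        if not 1 <= site.coordinate <= len(ref):
            raise ValueError(
                f"site {site.coordinate} outside reference 1..{len(ref)}"
            )
        total = site.coverage
        if total == 0:
            raise ValueError(f"site {site.coordinate}: zero coverage")
        if total < min_coverage:
            continue
        ref_base = ref.sequence[site.coordinate - 1]
        passing: list[tuple[str, float]] = []
        for base in _BASES:
            if base == ref_base:
                continue
            rate = site.counts.get(base, 0) / total
            if rate >= min_rate:
                passing.append((base, round(rate, 2)))
        if not passing:
            continue
        passing.sort(key=lambda t: (-t[1], t[0]))
        variants.append(
            VariantRecord(
                coordinate=site.coordinate,
                ref_allele=ref_base,
                alt_alleles=tuple(b for b, _ in passing),
                rates=tuple(r for _, r in passing),
                kind="SNP",
            )
        )
    return variants


def annotate_variant(
    v: VariantRecord,
    features: Sequence[GeneFeature],
    circular: bool = False,
) -> VariantRecord:
    """Attach a gene or intergenic-spacer annotation to a variant.

    A coordinate inside a feature takes that gene's name; otherwise the
    annotation is ``"left~right"`` from the nearest flanking genes in
    genome order.  On a linear genome, positions before the first or after
    the last gene use the sentinels ``START`` and ``END``; on a circular
    genome the spacer wraps (last gene ~ first gene).
    """
    if not features:
        raise ValueError("empty feature list")
    feats = sorted(features, key=lambda f: (f.start, f.end))
    for f in feats:
        if v.coordinate in f:
            return _with_annotation(v, f.name)
    left = None
    for f in feats:
        if f.end < v.coordinate:
            left = f
    right = next((f for f in feats if f.start > v.coordinate), None)
    if circular:
        left_name = left.name if left else feats[-1].name
        right_name = right.name if right else feats[0].name
    else:
        left_name = left.name if left else "START"
        right_name = right.name if right else "END"
    return _with_annotation(v, f"{left_name}~{right_name}")


def _with_annotation(v: VariantRecord, annotation: str) -> VariantRecord:
    return VariantRecord(
        coordinate=v.coordinate,
        ref_allele=v.ref_allele,
        alt_alleles=v.alt_alleles,
        rates=v.rates,
        kind=v.kind,
        annotation=annotation,
    )


DEFAULT_RATE_BINS: tuple[tuple[float, float], ...] = (
    (0.0, 0.15),
    (0.15, 0.30),
    (0.30, 0.50),
    (0.50, 1.01),
)


@dataclass
class VariantSummary:
    """Mutation-table summary: counts by kind, gene and pooled-rate bin.

    Indels are excluded from the per-gene SNP counts and rate bins; a
    dual-allele SNP is binned once, by its maximum alternate rate.
    """

    n_snps: int
    n_indels: int
    per_gene: dict[str, int]
    rate_bins: dict[tuple[float, float], int]
    max_rate: float
    max_rate_coordinate: int
    max_rate_annotation: str
    n_genic_snps: int = 0
    n_intergenic_snps: int = 0

    def gene_fraction(self, gene: str) -> float:
        """Share of all SNPs annotated to one gene (e.g. the ycf1 share)."""
        return self.per_gene.get(gene, 0) / self.n_snps if self.n_snps else 0.0


def summarize_variants(
    variants: Sequence[VariantRecord],
    bins: Sequence[tuple[float, float]] = DEFAULT_RATE_BINS,
) -> VariantSummary:
    """Summarize a variant collection the way mutation tables are read."""
    bins = [tuple(b) for b in bins]
    for (lo1, hi1), (lo2, hi2) in zip(bins, bins[1:]):
        if hi1 > lo2:
            raise ValueError(f"overlapping rate bins [{lo1},{hi1}) and [{lo2},{hi2})")
    snps = [v for v in variants if v.kind == "SNP"]
    indels = [v for v in variants if v.kind == "indel"]
    per_gene: dict[str, int] = {}
    genic = intergenic = 0
    for v in snps:
        if v.is_intergenic:
            intergenic += 1
        else:
            genic += 1
        per_gene[v.annotation] = per_gene.get(v.annotation, 0) + 1
    rate_bins: dict[tuple[float, float], int] = {b: 0 for b in bins}
    for v in snps:
        r = v.max_rate
        for lo, hi in bins:
            if lo <= r < hi:
                rate_bins[(lo, hi)] += 1
                break
    if snps:
        top = max(snps, key=lambda v: v.max_rate)
        max_rate, max_coord, max_ann = top.max_rate, top.coordinate, top.annotation
    else:
        max_rate, max_coord, max_ann = 0.0, -1, ""
    return VariantSummary(
        n_snps=len(snps),
        n_indels=len(indels),
        per_gene=per_gene,
        rate_bins=rate_bins,
        max_rate=max_rate,
        max_rate_coordinate=max_coord,
        max_rate_annotation=max_ann,
        n_genic_snps=genic,
        n_intergenic_snps=intergenic,
    )
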