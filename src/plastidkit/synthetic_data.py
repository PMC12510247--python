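"""Seedable generators for every input the pipeline consumes.

The generators emulate the data-generating processes of a pooled
chloroplast resequencing study on a conifer breeding population:

* a circular plastome (default 121,530 bp at GC 0.385, 71 protein-coding
  genes) with non-overlapping CDS features;
* per-individual haploid genotypes at planted polymorphic sites, pooled
  read counts at a target mean depth (default 200×), and a Sanger-style
  call matrix with a small rate of ambiguous 'N' calls (default 0.006,
  the observed rate in the packaged genotype table);
* CDS pairs diverged under a controlled nonsynonymous/synonymous rate
  ratio ω for Ka/Ks estimator checks;
* a random binary tree with alignments evolved under JC69, from which a
  contiguous "gene" slice can be cut for the marker-congruence experiment.

All randomness flows through ``numpy.random.default_rng(seed)``: a fixed
seed gives bit-identical output.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np

from .composition import GENETIC_CODE, STOP_CODONS
from .core_io import GeneFeature, GenotypeMatrix, SequenceRecord
from .phylo import TreeTopology, parse_newick
from .snp_discovery import AlleleCounts

__all__ = [
    "SimConfig",
    "simulate_plastome",
    "simulate_population",
    "simulate_divergent_cds",
    "simulate_tree_and_alignments",
]

_BASES = np.array(list("ACGT"))
_SENSE_CODONS = tuple(c for c in GENETIC_CODE if c not in STOP_CODONS)


@dataclass
class SimConfig:
    """Study-condition defaults for the simulators.

    ``site_freq_spectrum`` lists (coordinate, alt base, population alt
    frequency) for the planted polymorphic sites; frequencies are the
    probability that an individual chloroplast carries the alternate.
    ``omega`` is the nonsynonymous/synonymous rate ratio and
    ``divergence`` the expected substitutions per nucleotide site used by
    the CDS-divergence simulator.
    """

    seed: int = 0
    genome_length: int = 121_530
    gc: float = 0.385
    n_genes: int = 71
    gene_length_range: tuple[int, int] = (300, 1500)
    n_individuals: int = 33
    site_freq_spectrum: tuple[tuple[int, str, float], ...] = ()
    coverage: float = 200.0
    n_ambiguous_rate: float = 0.006
    omega: float = 1.0
    divergence: float = 0.05
    linked_sites: bool = False

    def __post_init__(self) -> None:
        if not 0 < self.gc < 1:
            raise ValueError("gc must be in (0,1)")
        if self.omega <= 0:
            raise ValueError("omega must be > 0")
        for coord, alt, freq in self.site_freq_spectrum:
            if not 1 <= coord <= self.genome_length:
                raise ValueError(f"planted site {coord} outside genome")
            if alt not in "ACGT":
                raise ValueError(f"planted alt {alt!r} is not a base")
            if not 0 < freq <= 1:
                raise ValueError(f"planted frequency {freq} outside (0,1]")


def _random_bases(rng: np.random.Generator, n: int, gc: float) -> np.ndarray:
    p = np.array([(1 - gc) / 2, gc / 2, gc / 2, (1 - gc) / 2])  # A C G T
    return rng.choice(_BASES, size=n, p=p)


_CODON_GC = np.array([sum(b in "GC" for b in c) / 3 for c in _SENSE_CODONS])


def _raw_codon_probs(x: float) -> np.ndarray:
    base_p = {"A": (1 - x) / 2, "C": x / 2, "G": x / 2, "T": (1 - x) / 2}
    w = np.array([base_p[a] * base_p[b] * base_p[c] for a, b, c in _SENSE_CODONS])
    return w / w.sum()


def _sense_codon_probs(gc: float) -> np.ndarray:
    # excluding the AT-rich stop codons shifts realized GC upward, so
    # solve (bisection) for the per-base GC that makes the sense-codon
    # mixture hit the requested GC exactly
    lo, hi = 1e-6, 1.0 - 1e-6
    for _ in range(60):
        mid = 0.5 * (lo + hi)
        if float(_raw_codon_probs(mid) @ _CODON_GC) < gc:
            lo = mid
        else:
            hi = mid
    return _raw_codon_probs(0.5 * (lo + hi))


def simulate_plastome(cfg: SimConfig) -> tuple[SequenceRecord, list[GeneFeature]]:
    """Random circular plastome with non-overlapping CDS features.

    Gene lengths are multiples of 3 in ``gene_length_range``; each gene is
    ATG + GC-matched sense codons + TAA on the forward strand, embedded in
    GC-matched background sequence.
    """
    rng = np.random.default_rng(cfg.seed)
    L = cfg.genome_length
    seq = _random_bases(rng, L, cfg.gc)
    lo, hi = cfg.gene_length_range
    lo, hi = max(6, lo - lo % 3), hi - hi % 3
    lengths = (rng.integers(lo // 3, hi // 3 + 1, size=cfg.n_genes) * 3).astype(int)
    total = int(lengths.sum())
    free = L - total
    if cfg.n_genes > 0 and free < cfg.n_genes:
        raise ValueError(
            f"cannot pack {cfg.n_genes} genes totalling {total} bp into {L} bp"
        )
    features: list[GeneFeature] = []
    if cfg.n_genes > 0:
        # distribute the slack as random intergenic gaps (≥1 bp each)
        cuts = np.sort(rng.choice(np.arange(1, free), size=cfg.n_genes, replace=False))
        gaps = np.diff(np.concatenate([[0], cuts]))
        codon_p = _sense_codon_probs(cfg.gc)
        pos = 0
        for g in range(cfg.n_genes):
            pos += int(gaps[g])
            start = pos + 1  # 1-based
            n_codons = int(lengths[g]) // 3
            interior = rng.choice(len(_SENSE_CODONS), size=n_codons - 2, p=codon_p)
            gene_seq = "ATG" + "".join(_SENSE_CODONS[i] for i in interior) + "TAA"
            seq[pos : pos + lengths[g]] = list(gene_seq)
            features.append(
                GeneFeature(
                    name=f"gene{g + 1:03d}",
                    start=start,
                    end=start + int(lengths[g]) - 1,
                    strand="+",
                    kind="CDS",
                )
            )
            pos += int(lengths[g])
    record = SequenceRecord(id=f"synthetic_plastome_seed{cfg.seed}",
                            sequence="".join(seq), circular=True)
    return record, features


def simulate_population(
    ref: SequenceRecord,
    features: Sequence[GeneFeature],
    cfg: SimConfig,
) -> tuple[list[AlleleCounts], GenotypeMatrix]:
    """Haploid individuals, pooled read counts and a Sanger-style call
    matrix at the planted sites.

    Individuals carry the alternate at a site with the planted frequency.
    By default sites are independent across individuals; with
    ``linked_sites`` each individual draws one uniform variate u and
    carries the alternate wherever u < frequency, giving the nested
    haplotype-block structure of a non-recombining genome.  Pooled counts
    are Poisson(coverage) read depths split binomially by the realized
    individual allele fraction.  'N' calls are injected uniformly at
    ``n_ambiguous_rate``.
    """
    rng = np.random.default_rng(cfg.seed)
    sites = sorted(cfg.site_freq_spectrum)
    n_ind, n_sites = cfg.n_individuals, len(sites)
    ref_bases = [ref.sequence[coord - 1] for coord, _, _ in sites]
    for (coord, alt, _), rb in zip(sites, ref_bases):
        if alt == rb:
            raise ValueError(f"site {coord}: alt equals reference base {rb}")
    freqs = np.array([f for _, _, f in sites])
    if cfg.linked_sites:
        u = rng.random(n_ind)
        carries = u[:, None] < freqs[None, :]
    else:
        carries = rng.random((n_ind, n_sites)) < freqs[None, :]
    pooled: list[AlleleCounts] = []
    for j, (coord, alt, _freq) in enumerate(sites):
        depth = max(1, int(rng.poisson(cfg.coverage)))
        pool_fraction = carries[:, j].mean() if n_ind else 0.0
        alt_reads = int(rng.binomial(depth, pool_fraction))
        counts = {ref_bases[j]: depth - alt_reads, alt: alt_reads}
        if ref_bases[j] == alt:  # unreachable; guarded above
            counts = {alt: depth}
        pooled.append(AlleleCounts(coordinate=coord, counts=counts))
    feature_name = _feature_name_lookup(features)
    locus_ids = [f"{feature_name(coord)}_{coord}" for coord, _, _ in sites]
    calls = [
        [alt if carries[i, j] else "-" for j, (_, alt, _) in enumerate(sites)]
        for i in range(n_ind)
    ]
    if cfg.n_ambiguous_rate > 0 and n_sites:
        mask = rng.random((n_ind, n_sites)) < cfg.n_ambiguous_rate
        for i in range(n_ind):
            for j in range(n_sites):
                if mask[i, j]:
                    calls[i][j] = "N"
    gm = GenotypeMatrix(
        locus_ids=locus_ids,
        reference_calls=ref_bases,
        individuals=[f"I{i + 1:03d}" for i in range(n_ind)],
        calls=calls,
        positions=[coord for coord, _, _ in sites],
    )
    return pooled, gm


def _feature_name_lookup(features: Sequence[GeneFeature]):
    feats = sorted(features, key=lambda f: f.start)

    def name(coordinate: int) -> str:
        for f in feats:
            if coordinate in f:
                return f.name
        return "IGS"

    return name


def simulate_divergent_cds(
    cds: SequenceRecord,
    omega: float,
    divergence: float,
    seed: int,
) -> SequenceRecord:
    """Diverge a CDS under a nonsynonymous/synonymous rate ratio ω.

    Random single-base codon changes are proposed; synonymous proposals
    are accepted with probability min(1, 1/ω) and nonsynonymous ones with
    probability min(1, ω), so the accepted-rate ratio is ω regardless of
    its magnitude.  Proposals creating stop codons are always rejected.
    The walk stops after ``divergence × length`` accepted substitutions
    (expected substitutions per site, multiple hits allowed).
    """
    if omega < 0:
        raise ValueError("omega must be ≥ 0 (0 = strictly synonymous walk)")
    if divergence < 0:
        raise ValueError("divergence must be ≥ 0")
    rng = np.random.default_rng(seed)
    seq = list(cds.sequence)
    if len(seq) % 3 != 0:
        raise ValueError(f"CDS {cds.id!r}: length not divisible by 3")
    n_codons = len(seq) // 3
    target = int(round(divergence * len(seq)))
    p_syn = min(1.0, 1.0 / omega) if omega > 0 else 1.0
    p_non = min(1.0, omega)
    accepted = 0
    while accepted < target:
        ci = int(rng.integers(n_codons))
        codon = "".join(seq[3 * ci : 3 * ci + 3])
        if codon in STOP_CODONS:
            continue  # terminal stop, if present, is left untouched
        pos = int(rng.integers(3))
        base = "ACGT"[int(rng.integers(4))]
        if base == codon[pos]:
            continue
        mutant = codon[:pos] + base + codon[pos + 1 :]
        if mutant in STOP_CODONS:
            continue
        synonymous = GENETIC_CODE[mutant] == GENETIC_CODE[codon]
        if rng.random() < (p_syn if synonymous else p_non):
            seq[3 * ci + pos] = base
            accepted += 1
    return SequenceRecord(id=f"{cds.id}_omega{omega:g}", sequence="".join(seq))


def simulate_tree_and_alignments(
    n_taxa: int,
    genome_sites: int,
    gene_fraction: float,
    seed: int,
    branch_length_mean: float = 0.05,
) -> tuple[TreeTopology, dict[str, str], dict[str, str]]:
    """Random binary tree plus JC69 alignments for the congruence study.

    Returns the true topology, a genome alignment of ``genome_sites``
    sites, and a "gene" alignment that is the contiguous leading slice of
    ``gene_fraction`` of those sites.  Branch lengths are exponential with
    the given mean (substitutions/site).
    """
    if n_taxa < 4:
        raise ValueError("need ≥ 4 taxa")
    if not 0 < gene_fraction <= 1:
        raise ValueError("gene_fraction must be in (0,1]")
    rng = np.random.default_rng(seed)
    labels = [f"t{i + 1}" for i in range(n_taxa)]

    # random rooted binary shape by sequential random insertion:
    # start from a 2-leaf tree, attach each new leaf to a random edge
    children: dict[int, tuple[int, int]] = {}
    lengths: dict[int, float] = {}
    next_id = n_taxa
    edges: list[int] = [0, 1]  # node ids that have a parent edge
    parent: dict[int, int] = {}
    root = next_id
    children[root] = (0, 1)
    parent[0] = parent[1] = root
    next_id += 1
    for leaf in range(2, n_taxa):
        target = int(edges[rng.integers(len(edges))])
        new_internal = next_id
        next_id += 1
        old_parent = parent[target]
        a, b = children[old_parent]
        children[old_parent] = (new_internal, b) if a == target else (a, new_internal)
        children[new_internal] = (target, leaf)
        parent[target] = new_internal
        parent[leaf] = new_internal
        parent[new_internal] = old_parent
        edges.extend([leaf, new_internal])
    for node in parent:
        lengths[node] = float(rng.exponential(branch_length_mean))

    # evolve sites down the tree under JC69 (vectorized per edge)
    base_idx = {b: i for i, b in enumerate("ACGT")}
    root_seq = rng.integers(4, size=genome_sites)
    seqs: dict[int, np.ndarray] = {}

    def evolve(parent_seq: np.ndarray, t: float) -> np.ndarray:
        p_change = 0.75 * (1.0 - np.exp(-4.0 * t / 3.0))
        out = parent_seq.copy()
        hit = rng.random(genome_sites) < p_change
        n_hit = int(hit.sum())
        if n_hit:
            out[hit] = (out[hit] + rng.integers(1, 4, size=n_hit)) % 4
        return out

    stack = [(root, root_seq)]
    while stack:
        node, s = stack.pop()
        if node < n_taxa:
            seqs[node] = s
            continue
        for child in children[node]:
            stack.append((child, evolve(s, lengths[child])))

    genome_aln = {
        labels[i]: "".join("ACGT"[b] for b in seqs[i]) for i in range(n_taxa)
    }
    n_gene = max(1, int(round(gene_fraction * genome_sites)))
    gene_aln = {k: v[:n_gene] for k, v in genome_aln.items()}

    def newick(node: int) -> str:
        if node < n_taxa:
            return labels[node]
        a, b = children[node]
        return f"({newick(a)}:{lengths[a]:.6g},{newick(b)}:{lengths[b]:.6g})"

    true_tree = parse_newick(newick(root) + ";")
    return true_tree, genome_aln, gene_aln
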