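"""Determinism and statistical structure of the synthetic-data generators."""

import numpy as np
import pytest

from plastidkit.composition import GENETIC_CODE, STOP_CODONS, extract_codons, gc_content
from plastidkit.core_io import SequenceRecord
from plastidkit.kaks import count_differences, kaks_pair
from plastidkit.phylo import congruence_experiment, nj_tree, p_distance_matrix, rf_distance
from plastidkit.snp_discovery import call_pooled_variants
from plastidkit.synthetic_data import (
    SimConfig,
    simulate_divergent_cds,
    simulate_plastome,
    simulate_population,
    simulate_tree_and_alignments,
)

SENSE = sorted(c for c in GENETIC_CODE if c not in STOP_CODONS)


def _toy_cfg(**kw):
    defaults = dict(seed=3, genome_length=30_000, n_genes=12)
    defaults.update(kw)
    return SimConfig(**defaults)


# -- plastome ----------------------------------------------------------------

def test_zero_genes_gives_bare_sequence():
    ref, feats = simulate_plastome(_toy_cfg(n_genes=0))
    assert feats == [] and len(ref) == 30_000 and ref.circular


def test_plastome_deterministic_under_seed():
    a = simulate_plastome(_toy_cfg())
    b = simulate_plastome(_toy_cfg())
    assert a[0] == b[0] and a[1] == b[1]


def test_plastome_gc_near_request_at_100kb():
    cfg = SimConfig(seed=5, genome_length=100_000, n_genes=58, gc=0.385)
    ref, _ = simulate_plastome(cfg)
    assert abs(gc_content(ref.sequence) - 0.385) < 0.01


def test_genes_are_clean_nonoverlapping_cds():
    ref, feats = simulate_plastome(_toy_cfg())
    assert len(feats) == 12
    for prev, nxt in zip(feats, feats[1:]):
        assert prev.end < nxt.start
    for f in feats:
        cds = ref.sequence[f.start - 1 : f.end]
        assert len(cds) % 3 == 0
        ext = extract_codons(SequenceRecord(f.name, cds))
        assert ext.codons[0] == "ATG"
        assert ext.has_terminal_stop
        assert ext.internal_stop_indices == ()


def test_infeasible_packing_rejected():
    with pytest.raises(ValueError, match="pack"):
        simulate_plastome(SimConfig(seed=0, genome_length=5_000, n_genes=10,
                                    gene_length_range=(900, 1500)))


# -- population --------------------------------------------------------------

def _planted(ref, spec):
    sites = []
    for coord, freq in spec:
        alt = "G" if ref.sequence[coord - 1] != "G" else "A"
        sites.append((coord, alt, freq))
    return tuple(sites)


def test_fixed_frequency_one_makes_every_individual_alternate():
    ref, feats = simulate_plastome(_toy_cfg())
    cfg = _toy_cfg(n_ambiguous_rate=0.0)
    cfg.site_freq_spectrum = _planted(ref, [(1000, 1.0)])
    pooled, gm = simulate_population(ref, feats, cfg)
    assert all(s != "-" for row in gm.calls for s in row)
    (site,) = pooled
    alt = cfg.site_freq_spectrum[0][1]
    assert site.counts[alt] / site.coverage > 0.99


def test_no_ambiguous_calls_when_rate_zero():
    ref, feats = simulate_plastome(_toy_cfg())
    cfg = _toy_cfg(n_ambiguous_rate=0.0)
    cfg.site_freq_spectrum = _planted(ref, [(500, 0.5), (700, 0.2)])
    _, gm = simulate_population(ref, feats, cfg)
    assert not any(s == "N" for row in gm.calls for s in row)


def test_pooled_rate_within_sampling_error_of_planted_frequency():
    ref, feats = simulate_plastome(_toy_cfg())
    cfg = _toy_cfg(seed=9)
    freq = 0.5
    cfg.site_freq_spectrum = _planted(ref, [(2000, freq)])
    pooled, _ = simulate_population(ref, feats, cfg)
    (site,) = pooled
    alt = cfg.site_freq_spectrum[0][1]
    rate = site.counts[alt] / site.coverage
    sigma = np.sqrt(freq * (1 - freq) * (1 / cfg.n_individuals + 1 / cfg.coverage))
    assert abs(rate - freq) < 3 * sigma


def test_population_roundtrip_recovers_planted_sites_exactly():
    ref, feats = simulate_plastome(_toy_cfg(seed=17))
    cfg = _toy_cfg(seed=17)
    spec = [(1111, 0.1), (7000, 0.35), (15000, 0.48), (22222, 0.9)]
    cfg.site_freq_spectrum = _planted(ref, spec)
    pooled, _ = simulate_population(ref, feats, cfg)
    variants = call_pooled_variants(ref, pooled, min_rate=0.05)
    assert [v.coordinate for v in variants] == [c for c, _ in spec]
    for v, (coord, freq) in zip(variants, spec):
        sigma = np.sqrt(freq * (1 - freq) * (1 / cfg.n_individuals + 1 / cfg.coverage))
        assert abs(v.max_rate - freq) < 3 * sigma + 0.005  # 0.005 = rounding grain


def test_no_false_positive_calls_at_unplanted_sites():
    ref, feats = simulate_plastome(_toy_cfg(seed=17))
    cfg = _toy_cfg(seed=17)
    cfg.site_freq_spectrum = _planted(ref, [(5000, 0.5)])
    pooled, _ = simulate_population(ref, feats, cfg)
    variants = call_pooled_variants(ref, pooled, min_rate=0.05)
    assert {v.coordinate for v in variants} == {5000}


def test_linked_sites_mode_gives_nested_haplotypes():
    ref, feats = simulate_plastome(_toy_cfg())
    cfg = _toy_cfg(seed=8, linked_sites=True, n_ambiguous_rate=0.0)
    cfg.site_freq_spectrum = _planted(ref, [(100, 0.3), (200, 0.6), (300, 0.9)])
    _, gm = simulate_population(ref, feats, cfg)
    # carriers of a rarer allele are a subset of carriers of a commoner one
    carriers = [
        {i for i, row in enumerate(gm.calls) if row[j] != "-"} for j in range(3)
    ]
    assert carriers[0] <= carriers[1] <= carriers[2]


# -- CDS divergence ----------------------------------------------------------

def _random_cds(n_codons, seed):
    rng = np.random.default_rng(seed)
    return SequenceRecord("cds", "ATG" + "".join(rng.choice(SENSE, n_codons - 1)))


def test_zero_divergence_is_identity():
    cds = _random_cds(100, 1)
    assert simulate_divergent_cds(cds, 1.0, 0.0, 5).sequence == cds.sequence


def test_divergence_deterministic_under_seed():
    cds = _random_cds(200, 2)
    a = simulate_divergent_cds(cds, 0.5, 0.05, 7)
    b = simulate_divergent_cds(cds, 0.5, 0.05, 7)
    assert a.sequence == b.sequence


def test_omega_zero_walk_is_strictly_synonymous():
    cds = _random_cds(300, 3)
    derived = simulate_divergent_cds(cds, 0.0, 0.03, 9)
    total_nonsyn = 0.0
    for i in range(0, len(cds.sequence), 3):
        ca, cb = cds.sequence[i : i + 3], derived.sequence[i : i + 3]
        if ca != cb:
            _, nd = count_differences(ca, cb)
            total_nonsyn += nd
    assert total_nonsyn == 0.0
    assert kaks_pair(cds, derived).Ka == 0.0


def test_divergence_never_creates_stop_codons():
    cds = _random_cds(300, 4)
    derived = simulate_divergent_cds(cds, 3.0, 0.1, 11)
    codons = extract_codons(derived).codons
    assert all(c not in STOP_CODONS for c in codons)


def test_omega_estimates_recover_rank_order():
    cds = _random_cds(2000, 6)
    estimates = {}
    for i, omega in enumerate((0.2, 1.0, 3.0)):
        derived = simulate_divergent_cds(cds, omega, 0.05, 31 + i)
        estimates[omega] = kaks_pair(cds, derived).ratio
    assert estimates[0.2] < estimates[1.0] < estimates[3.0]


# -- tree + alignment simulation --------------------------------------------

def test_gene_fraction_one_reproduces_genome_alignment():
    tree, genome, gene = simulate_tree_and_alignments(6, 1000, 1.0, 13)
    assert gene == genome
    assert tree.n_leaves == 6


def test_tree_alignments_deterministic():
    a = simulate_tree_and_alignments(6, 500, 0.5, 19)
    b = simulate_tree_and_alignments(6, 500, 0.5, 19)
    assert a[0].splits == b[0].splits and a[1] == b[1] and a[2] == b[2]


def test_nj_on_long_genome_recovers_true_topology():
    true_tree, genome_aln, _ = simulate_tree_and_alignments(
        12, 50_000, 0.1, 29, branch_length_mean=0.05
    )
    t = nj_tree(p_distance_matrix(genome_aln))
    assert rf_distance(t, true_tree).rf == 0


def test_unrelated_alignments_are_incongruent():
    rng = np.random.default_rng(37)
    taxa = [f"t{i}" for i in range(10)]
    a1 = {t: "".join(rng.choice(list("ACGT"), 2000)) for t in taxa}
    a2 = {t: "".join(rng.choice(list("ACGT"), 2000)) for t in taxa}
    res = congruence_experiment(a1, a2)
    assert res.gene_vs_genome.normalized > 0.7
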