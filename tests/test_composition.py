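"""Composition statistics, codon extraction, RSCU and UPGMA."""

import math

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from plastidkit.composition import (
    SYNONYMOUS_FAMILIES,
    CodonUsageProfile,
    at_skew,
    euclidean_distance_matrix,
    extract_codons,
    gc_content,
    rscu,
    rscu_matrix,
    upgma,
    windowed_at_skew,
)
from plastidkit.core_io import SequenceRecord

dna = st.text(alphabet="ACGT", min_size=1, max_size=200)


# -- gc / skew ---------------------------------------------------------------

@pytest.mark.parametrize(
    "seq, expected",
    [
        ("ATGC", 0.5),
        ("TGGTGGAGATGGTGAAGATG", 0.5),            # panel primer F3 → 50.00%
        ("CGGATATGTCCATGATTCACTA", 9 / 22),        # panel primer R6 → 40.91%
        ("ANNG", 0.5),                             # N excluded both sides
    ],
)
def test_gc_content(seq, expected):
    assert gc_content(seq) == pytest.approx(expected)


def test_gc_content_rejects_all_ambiguous():
    with pytest.raises(ValueError):
        gc_content("NNN")


@pytest.mark.parametrize("seq, expected", [("AATT", 0.0), ("AAAT", 0.5), ("TTTA", -0.5)])
def test_at_skew_values(seq, expected):
    assert at_skew(seq) == pytest.approx(expected)


def test_at_skew_undefined_without_a_or_t():
    with pytest.raises(ValueError):
        at_skew("GGCC")


@given(dna)
@settings(max_examples=100, deadline=None)
def test_reverse_complement_negates_at_skew_and_preserves_gc(seq):
    comp = {"A": "T", "T": "A", "G": "C", "C": "G"}
    rc = "".join(comp[b] for b in reversed(seq))
    if seq.count("A") + seq.count("T"):
        assert at_skew(rc) == pytest.approx(-at_skew(seq))
        assert abs(at_skew(seq)) <= 1.0
    assert gc_content(rc) == pytest.approx(gc_content(seq))
    assert gc_content(seq) + (seq.count("A") + seq.count("T")) / len(seq) == pytest.approx(1.0)


def test_windowed_skew_linear():
    assert windowed_at_skew("AAAATTTT", window=4, step=4, circular=False) == [
        (1, 1.0),
        (5, -1.0),
    ]


def test_windowed_skew_uniform_alternating_is_zero():
    rows = windowed_at_skew("AT" * 50, window=10, step=5, circular=False)
    assert all(s == 0.0 for _, s in rows)


def test_windowed_skew_window_longer_than_linear_sequence():
    with pytest.raises(ValueError):
        windowed_at_skew("ACGT", window=10, step=1, circular=False)


def test_circular_windows_wrap_origin():
    # rotation-invariant content: circular scan of seq and any rotation
    # yields the same multiset of window skews
    seq = "AAAATTGTC" * 4
    rot = seq[7:] + seq[:7]
    w1 = sorted(s for _, s in windowed_at_skew(seq, window=9, step=3, circular=True))
    w2 = sorted(s for _, s in windowed_at_skew(rot, window=9, step=3, circular=True))
    assert w1 == pytest.approx(w2)


# -- codon extraction --------------------------------------------------------

def test_extract_codons_flags_terminal_stop():
    ext = extract_codons("ATGTTTTAA")
    assert ext.codons == ("ATG", "TTT", "TAA")
    assert ext.has_terminal_stop
    assert ext.sense_codons == ("ATG", "TTT")


def test_minus_strand_extraction_matches_forward():
    fwd = "ATGTTTTAA"
    rc = "TTAAAACAT"
    assert extract_codons(rc, strand="-").codons == extract_codons(fwd).codons


def test_extraction_requires_codon_multiple():
    with pytest.raises(ValueError, match="gene7"):
        extract_codons(SequenceRecord("gene7", "ATGTTTT"))


def test_internal_stop_warns_not_errors():
    with pytest.warns(UserWarning, match="internal stop"):
        ext = extract_codons("ATGTAATTTTAA")
    assert ext.internal_stop_indices == (1,)


def test_extraction_distributes_over_concatenation():
    a, b = "ATGTTT", "CCCGGG"
    assert (
        extract_codons(a + b).codons
        == extract_codons(a).codons + extract_codons(b).codons
    )


# -- RSCU --------------------------------------------------------------------

def test_uniform_family_usage_gives_rscu_one():
    counts = {c: 5 for fam in SYNONYMOUS_FAMILIES.values() for c in fam}
    values = rscu(counts)
    assert values and all(v == pytest.approx(1.0) for v in values.values())


def test_skewed_twofold_family():
    values = rscu({"TTT": 10, "TTC": 0})
    assert values["TTT"] == pytest.approx(2.0)
    assert values["TTC"] == pytest.approx(0.0)


def test_toy_cds_phe_bias():
    # ATG TTT TTT TTC: Phe family used 2:1
    counts = {"ATG": 1, "TTT": 2, "TTC": 1}
    values = rscu(counts)
    assert values["TTT"] == pytest.approx(4 / 3)
    assert values["TTC"] == pytest.approx(2 / 3)


def test_stops_and_single_codon_families_excluded_by_default():
    values = rscu({"TAA": 3, "ATG": 5, "TGG": 2, "TTT": 1})
    assert {"TAA", "TAG", "TGA", "ATG", "TGG"}.isdisjoint(values)
    full = rscu({"TAA": 3}, include_stops=True, include_single_codon_families=True)
    assert "ATG" in full and "TAA" in full


@given(
    st.dictionaries(
        st.sampled_from(sorted({c for f in SYNONYMOUS_FAMILIES.values() for c in f})),
        st.integers(min_value=0, max_value=1000),
        max_size=64,
    )
)
@settings(max_examples=200, deadline=None)
def test_rscu_family_sums_equal_family_size(counts):
    values = rscu(counts, include_stops=True, include_single_codon_families=True)
    for aa, family in SYNONYMOUS_FAMILIES.items():
        total = sum(counts.get(c, 0) for c in family)
        fam_sum = sum(values[c] for c in family)
        expected = len(family) if total > 0 else 0.0
        assert fam_sum == pytest.approx(expected, abs=1e-9)


def test_profile_zero_usage_family_flagged():
    prof = CodonUsageProfile("sp", {"TTT": 4})
    assert "G" in prof.zero_usage_families  # glycine never used
    assert all(prof.rscu[c] == 0.0 for c in SYNONYMOUS_FAMILIES["G"])


def test_profile_from_cds_counts_and_total():
    recs = [SequenceRecord("g1", "ATGTTTTTTTTCTAA")]
    prof = CodonUsageProfile.from_cds("sp", recs)
    assert prof.total_codons == 4  # terminal stop dropped
    assert prof.rscu["TTT"] == pytest.approx(4 / 3)


def test_rscu_matrix_rows_and_duplicate_rejection():
    p1 = CodonUsageProfile("a", {"TTT": 2, "TTC": 1})
    p2 = CodonUsageProfile("b", {"TTT": 2, "TTC": 1})
    m = rscu_matrix([p1, p2])
    assert (m.loc["a"] == m.loc["b"]).all()
    with pytest.raises(ValueError, match="duplicate"):
        rscu_matrix([p1, CodonUsageProfile("a", {"TTT": 1})])


def test_opposite_twofold_biases_have_closed_form_distance():
    # each opposed two-fold family contributes (2-0)² + (0-2)² = 8
    fams = [("TTT", "TTC"), ("CAA", "CAG"), ("GAA", "GAG")]
    c1 = {a: 10 for a, _ in fams}
    c2 = {b: 10 for _, b in fams}
    m = rscu_matrix([CodonUsageProfile("x", c1), CodonUsageProfile("y", c2)])
    d = euclidean_distance_matrix(m)
    assert d.loc["x", "y"] == pytest.approx(math.sqrt(8 * len(fams)))


# -- UPGMA -------------------------------------------------------------------

def test_upgma_two_points_single_merge():
    d = pd.DataFrame([[0, 3], [3, 0]], index=["A", "B"], columns=["A", "B"])
    dend = upgma(d)
    assert dend.merges == [(("A",), ("B",), 1.5)]


def test_upgma_three_point_heights():
    d = pd.DataFrame(
        [[0, 1, 4], [1, 0, 4], [4, 4, 0]],
        index=list("ABC"), columns=list("ABC"),
    )
    dend = upgma(d)
    assert dend.merges[0] == (("A",), ("B",), 0.5)
    (a, b, h) = dend.merges[1]
    assert {a, b} == {("A", "B"), ("C",)} and h == pytest.approx(2.0)


def test_upgma_reproduces_ultrametric():
    # heights of an ultrametric tree: ((A,B):1,(C,D):2):3 semantics
    labels = list("ABCD")
    u = np.array(
        [[0, 2, 6, 6], [2, 0, 6, 6], [6, 6, 0, 4], [6, 6, 4, 0]], dtype=float
    )
    dend = upgma(u, labels=labels)
    heights = sorted(h for _, _, h in dend.merges)
    assert heights == pytest.approx([1.0, 2.0, 3.0])


def test_upgma_invariant_to_permutation():
    rng = np.random.default_rng(0)
    x = rng.random((6, 3))
    d = np.linalg.norm(x[:, None] - x[None, :], axis=-1)
    labels = [f"s{i}" for i in range(6)]
    perm = rng.permutation(6)
    d2 = d[np.ix_(perm, perm)]
    m1 = upgma(d, labels=labels).merges
    m2 = upgma(d2, labels=[labels[i] for i in perm]).merges
    canon = lambda ms: sorted((tuple(sorted(a + b)), round(h, 9)) for a, b, h in ms)
    assert canon(m1) == canon(m2)


def test_upgma_rejects_asymmetry():
    with pytest.raises(ValueError, match="symmetric"):
        upgma(np.array([[0.0, 1.0], [1.1, 0.0]]), labels=["a", "b"])


def test_dendrogram_newick_has_all_leaves():
    d = pd.DataFrame(
        [[0, 1, 4], [1, 0, 4], [4, 4, 0]], index=list("ABC"), columns=list("ABC")
    )
    nwk = upgma(d).to_newick()
    assert all(leaf in nwk for leaf in "ABC") and nwk.endswith(";")
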