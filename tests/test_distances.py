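"""K2P / p-distance computation, divergence summaries and the barcode gap."""

import math

import numpy as np
import pandas as pd
import pytest
from hypothesis import given
from hypothesis import strategies as st

import barcodelim as bl
from barcodelim.distances import SitePatternCount, gap_frame, summary_frame
from barcodelim.records import BarcodeAlignment, DistanceMatrix, SequenceRecord

PURINES = {"A", "G"}
PYRIMIDINES = {"C", "T"}


def _classify_site(x, y):
    """Independent per-site oracle."""
    if x not in "ACGT" or y not in "ACGT":
        return "masked"
    if x == y:
        return "same"
    if {x, y} <= PURINES or {x, y} <= PYRIMIDINES:
        return "transition"
    return "transversion"


def _k2p_closed_form(ts, tv, n):
    p, q = ts / n, tv / n
    arg1, arg2 = 1 - 2 * p - q, 1 - 2 * q
    if arg1 <= 0 or arg2 <= 0:
        return None
    return -0.5 * math.log(arg1 * math.sqrt(arg2))


def test_count_site_patterns_examples():
    assert bl.count_site_patterns("ACGT", "ACGT") == SitePatternCount(0, 0, 4)
    assert bl.count_site_patterns("ACGT", "GCGT") == SitePatternCount(1, 0, 4)
    # gap/N/ambiguity sites are deleted pairwise
    assert bl.count_site_patterns("ACGT-N", "ATGTAN") == SitePatternCount(1, 0, 4)


def test_count_site_patterns_random_pairs_match_site_oracle(rng):
    alphabet = np.array(list("ACGTRN-"))
    for _ in range(20):
        a = "".join(rng.choice(alphabet, size=626))
        b = "".join(rng.choice(alphabet, size=626))
        got = bl.count_site_patterns(a, b)
        kinds = [_classify_site(x, y) for x, y in zip(a, b)]
        assert got.n_transitions == kinds.count("transition")
        assert got.n_transversions == kinds.count("transversion")
        assert got.n_compared == len(kinds) - kinds.count("masked")


def test_k2p_matches_closed_form_on_grid():
    for n in (10, 20, 50):
        for ts in range(n + 1):
            for tv in range(n + 1 - ts):
                got = bl.k2p_distance(SitePatternCount(ts, tv, n))
                want = _k2p_closed_form(ts, tv, n)
                if want is None:
                    assert got is None
                else:
                    assert got == pytest.approx(want, abs=1e-12)


def test_k2p_boundaries():
    assert bl.k2p_distance(SitePatternCount(0, 0, 20)) == 0.0
    assert bl.k2p_distance(SitePatternCount(10, 0, 20)) is None  # P = 0.5
    assert bl.k2p_distance(SitePatternCount(0, 10, 20)) is None  # Q = 0.5
    assert bl.k2p_distance(SitePatternCount(0, 0, 0)) is None
    got = bl.k2p_distance(SitePatternCount(2, 1, 20))
    assert got == pytest.approx(-0.5 * math.log(0.75 * math.sqrt(0.9)), abs=1e-12)


def test_p_distance_definition():
    assert bl.p_distance(SitePatternCount(0, 0, 626)) == 0.0
    assert bl.p_distance(SitePatternCount(3, 1, 626)) == pytest.approx(4 / 626)
    assert bl.p_distance(SitePatternCount(0, 0, 0)) is None


@given(
    n=st.integers(1, 626),
    ts=st.integers(0, 626),
    tv=st.integers(0, 626),
)
def test_correction_only_inflates(n, ts, tv):
    """K2P >= p on every defined pair; equality only at distance zero."""
    if ts + tv > n:
        return
    counts = SitePatternCount(ts, tv, n)
    k2p, p = bl.k2p_distance(counts), bl.p_distance(counts)
    if k2p is None:
        return
    assert k2p >= p - 1e-15
    if p > 0:
        assert k2p > p


def test_distance_matrix_identical_records():
    recs = [
        SequenceRecord(f"r{i}", "S", "G", "F", "O", "C", "ACGT" * 20) for i in range(2)
    ]
    dmat = bl.distance_matrix(BarcodeAlignment(recs), "K2P")
    assert np.array_equal(dmat.values, np.zeros((2, 2)))


def test_distance_matrix_matches_per_pair_recomputation(small_dataset):
    aln, _, _ = small_dataset
    for model, func in (("K2P", bl.k2p_distance), ("P_DIST", bl.p_distance)):
        dmat = bl.distance_matrix(aln, model)
        for i, a in enumerate(aln.records):
            for j, b in enumerate(aln.records):
                if i >= j:
                    continue
                want = func(bl.count_site_patterns(a.seq, b.seq))
                assert dmat.values[i, j] == pytest.approx(want, abs=1e-12)


def test_k2p_dominates_p_entrywise(default_dataset):
    aln, _, _ = default_dataset
    k2p = bl.distance_matrix(aln, "K2P").values
    p = bl.distance_matrix(aln, "P_DIST").values
    assert np.all(k2p >= p - 1e-15)


def test_matrix_permutation_consistency(small_dataset, rng):
    aln, _, _ = small_dataset
    dmat = bl.distance_matrix(aln, "K2P")
    perm = list(rng.permutation(len(aln)))
    shuffled = BarcodeAlignment([aln.records[i] for i in perm])
    dmat2 = bl.distance_matrix(shuffled, "K2P")
    for a in dmat.labels:
        for b in dmat.labels:
            assert dmat.get(a, b) == pytest.approx(dmat2.get(a, b), abs=1e-15)


# -- rank summaries --------------------------------------------------------


def _toy_taxonomy(rows):
    return pd.DataFrame(rows).set_index("id")


def test_rank_summary_pair_set_definitions():
    tax = _toy_taxonomy(
        [
            {"id": "a", "species": "S1", "genus": "G", "family": "F"},
            {"id": "b", "species": "S2", "genus": "G", "family": "F"},
        ]
    )
    dmat = DistanceMatrix(["a", "b"], np.array([[0, 0.08], [0.08, 0]]), "K2P")
    out = {s.level: s for s in bl.rank_divergence_summary(dmat, tax)}
    assert out["within_species"].n_pairs == 0
    assert out["within_species"].mean is None
    assert out["within_genus"].n_pairs == 1
    assert out["within_genus"].mean == pytest.approx(8.0)
    assert out["within_family"].n_pairs == 0


def test_rank_summary_ordering_on_synthetic(default_dataset, default_k2p):
    _, tax, _ = default_dataset
    out = {s.level: s for s in bl.rank_divergence_summary(default_k2p, tax)}
    assert (
        out["within_species"].mean
        < out["within_genus"].mean
        < out["within_family"].mean
    )
    for s in out.values():
        assert s.min <= s.mean <= s.max
        assert s.se >= 0
    frame = summary_frame(list(out.values()))
    assert list(frame["level"]) == ["within_species", "within_genus", "within_family"]


def test_rank_summary_all_identical_sequences():
    recs = [
        SequenceRecord(f"r{i}", "S", "G", "F", "O", "C", "ACGT" * 10) for i in range(4)
    ]
    aln = BarcodeAlignment(recs)
    out = bl.rank_divergence_summary(
        bl.distance_matrix(aln, "K2P"), aln.taxonomy_frame()
    )
    within = next(s for s in out if s.level == "within_species")
    assert within.mean == 0.0 and within.max == 0.0


# -- barcode gap -----------------------------------------------------------


def _gap_matrix(d_intra, d_inter):
    """Species A (2 seqs, intra d_intra); B and C singletons d_inter apart.

    A is placed far (20%) from B and C so its nearest neighbor is unambiguous.
    """
    labels = ["A1", "A2", "B1", "C1"]
    v = np.full((4, 4), 0.20)
    np.fill_diagonal(v, 0.0)
    v[0, 1] = v[1, 0] = d_intra
    v[2, 3] = v[3, 2] = d_inter
    tax = _toy_taxonomy(
        [
            {"id": "A1", "species": "A", "genus": "GA", "family": "F"},
            {"id": "A2", "species": "A", "genus": "GA", "family": "F"},
            {"id": "B1", "species": "B", "genus": "GB", "family": "F"},
            {"id": "C1", "species": "C", "genus": "GB", "family": "F"},
        ]
    )
    return DistanceMatrix(labels, v, "K2P"), tax


def test_gap_overlap_when_min_inter_below_max_intra():
    """Max intra 1.4% vs min inter 1.22% -> the dataset has no absolute gap."""
    dmat, tax = _gap_matrix(0.014, 0.0122)
    records, summary = bl.barcode_gap_report(dmat, tax)
    assert summary["overall_max_intra"] == pytest.approx(1.4)
    assert summary["overall_min_inter"] == pytest.approx(1.22)
    assert summary["overlap"] is True
    by_species = {r.species: r for r in records}
    assert by_species["B"].nn_species == "C"
    assert by_species["B"].nn_distance == pytest.approx(1.22)
    assert by_species["B"].has_gap is False  # singleton: max_intra undefined
    assert by_species["A"].has_gap is True  # 1.4% intra vs 20% to neighbors


def test_gap_restored_when_close_pair_excluded():
    """With the 1.22% pair removed the minimum congeneric distance is 4.9%."""
    dmat, tax = _gap_matrix(0.014, 0.049)
    _, summary = bl.barcode_gap_report(dmat, tax)
    assert summary["overall_min_inter"] == pytest.approx(4.9)
    assert summary["overlap"] is False


def test_gap_records_structure(default_dataset, default_k2p):
    _, tax, truth = default_dataset
    records, summary = bl.barcode_gap_report(default_k2p, tax)
    assert len(records) == truth.n_species
    for r in records:
        assert r.nn_species != r.species
        if r.max_intra is not None:
            assert r.has_gap == (r.nn_distance > r.max_intra)
    frame = gap_frame(records)
    assert set(frame.columns) >= {"species", "max_intra_pct", "nn_distance_pct"}


def test_gap_report_needs_two_species():
    recs = [
        SequenceRecord(f"r{i}", "S", "G", "F", "O", "C", "ACGT" * 10) for i in range(3)
    ]
    aln = BarcodeAlignment(recs)
    with pytest.raises(Exception):
        bl.barcode_gap_report(bl.distance_matrix(aln, "K2P"), aln.taxonomy_frame())
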