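import math

import numpy as np
import pytest
from hypothesis import given, strategies as st

from coevmi import (
    Alignment,
    FilterParams,
    column_distribution,
    normalize_matrix,
    pair_alignments,
    pair_mi,
    score_comparison,
)
from oracles import naive_pair_mi

LN2 = math.log(2.0)


class TestColumnDistribution:
    @pytest.mark.parametrize(
        "column, expected",
        [
            (list("AACC"), {"A": 0.5, "C": 0.5}),
            (list("AAAC"), {"A": 0.75, "C": 0.25}),
            (list("A-A-"), {"A": 1.0}),  # gaps excluded from the denominator
            (list("AXA*"), {"A": 1.0}),  # non-standard residues excluded too
            (list("--"), {}),  # all-excluded column: empty distribution
        ],
    )
    def test_frequencies(self, column, expected):
        assert column_distribution(column) == pytest.approx(expected)

    def test_frequencies_sum_to_one_over_counted_species(self):
        dist = column_distribution(list("AACDE--X"))
        assert sum(dist.values()) == pytest.approx(1.0)


class TestPairMI:
    def test_independent_columns_score_exactly_zero(self):
        # every joint frequency equals its independence expectation
        assert pair_mi(list("AACC"), list("DEDE"), FilterParams(0, 0)) == 0.0

    def test_perfectly_coupled_binary_columns(self):
        mi = pair_mi(list("AACC"), list("DDEE"), FilterParams(0, 0))
        assert mi == pytest.approx(LN2, abs=1e-15)

    def test_marginal_filter_removes_rare_residue_terms(self):
        # only the (A, D) term survives tau = 0.3
        mi = pair_mi(list("AAAC"), list("DDDE"), FilterParams(0.3, 0))
        assert mi == pytest.approx(0.75 * math.log(0.75 / 0.5625), abs=1e-15)

    def test_unfiltered_equals_textbook_mutual_information(self):
        # asymmetric joint with a negative partial term: filters dropped entirely
        col1, col2 = list("AACCC"), list("DEEDE")
        from sklearn.metrics import mutual_info_score

        expected = mutual_info_score(col1, col2)
        assert pair_mi(col1, col2, filters=None) == pytest.approx(expected, abs=1e-12)
        # whereas the r=0 joint filter drops the negative terms
        assert pair_mi(col1, col2, FilterParams(0, 0)) >= pair_mi(col1, col2, None)

    def test_gapped_species_excluded_pairwise(self):
        # species 2 has a gap in column 1 only; both residues must be standard
        mi = pair_mi(list("A-CC"), list("DDEE"), FilterParams(0, 0))
        assert mi == pytest.approx(naive_pair_mi(list("A-CC"), list("DDEE"), 0, 0))

    def test_all_excluded_pair_scores_zero(self):
        assert pair_mi(list("--"), list("AA"), FilterParams(0, 0)) == 0.0

    def test_filtered_scores_are_non_negative(self):
        rng = np.random.default_rng(11)
        aas = np.array(list("ACDE"))
        for _ in range(200):
            c1 = list(rng.choice(aas, 8))
            c2 = list(rng.choice(aas, 8))
            r = float(rng.uniform(0, 60))
            assert pair_mi(c1, c2, FilterParams(0.0, r)) >= 0.0

    def test_matches_bruteforce_summation_on_random_columns(self):
        # oracle equivalence across random columns, sizes and filter settings
        rng = np.random.default_rng(42)
        aas = np.array(list("ACDEFG-X"))
        for _ in range(400):
            n = int(rng.integers(1, 11))
            c1 = list(rng.choice(aas, n))
            c2 = list(rng.choice(aas, n))
            if rng.random() < 0.25:
                tau, r = None, None
            else:
                tau = float(rng.choice([0.0, 0.1, 0.2, 0.3, 0.5]))
                r = float(rng.choice([0.0, 10.0, 22.0, 35.0, 49.0]))
            filters = None if tau is None else FilterParams(tau, r)
            got = pair_mi(c1, c2, filters)
            want = naive_pair_mi(c1, c2, tau, r)
            assert got == pytest.approx(want, abs=1e-12)

    @given(
        st.lists(st.sampled_from("ACDE"), min_size=2, max_size=10),
        st.data(),
    )
    def test_symmetry_in_arguments(self, col1, data):
        col2 = data.draw(
            st.lists(st.sampled_from("KLMN"), min_size=len(col1), max_size=len(col1))
        )
        f = FilterParams(0.1, 20.0)
        assert pair_mi(col1, col2, f) == pytest.approx(pair_mi(col2, col1, f), abs=1e-14)


class TestNormalization:
    def test_mean_scaling_arithmetic(self):
        normalized, no_signal = normalize_matrix(np.array([[1.0, 2.0], [3.0, 2.0]]))
        assert not no_signal
        assert normalized.tolist() == [[5000.0, 10000.0], [15000.0, 10000.0]]

    def test_all_zero_matrix_flags_no_signal(self):
        normalized, no_signal = normalize_matrix(np.zeros((3, 2)))
        assert no_signal
        assert (normalized == 0).all()

    def test_normalized_mean_is_ten_thousand(self):
        rng = np.random.default_rng(0)
        raw = rng.exponential(size=(7, 5))
        normalized, _ = normalize_matrix(raw)
        assert normalized.mean() == pytest.approx(10_000.0, abs=1e-9)


def _paired(columns1, columns2, n_min=2):
    """Build a PairedAlignment whose species rows realize the given columns."""
    n = len(columns1[0])
    recs1 = {f"s{i}": "".join(col[i] for col in columns1) for i in range(n)}
    recs2 = {f"s{i}": "".join(col[i] for col in columns2) for i in range(n)}
    return pair_alignments(Alignment(recs1), Alignment(recs2), ref="s0", min_common=n_min)


class TestScoreComparison:
    def test_swapping_proteins_transposes_matrix(self):
        cols1 = [list("AACC"), list("ADAD"), list("CCCC")]
        cols2 = [list("DDEE"), list("KLKL")]
        f = FilterParams(0, 0)
        sm = score_comparison(_paired(cols1, cols2), f)
        sm_t = score_comparison(_paired(cols2, cols1), f)
        assert np.allclose(sm.normalized, sm_t.normalized.T)
        assert sm.top[2] == pytest.approx(sm_t.top[2])

    def test_top_tie_breaks_toward_smallest_positions(self):
        # two identical perfectly-coupled pairs -> equal maximal cells
        cols1 = [list("AACC"), list("AACC")]
        cols2 = [list("DDEE"), list("DDEE")]
        sm = score_comparison(_paired(cols1, cols2), FilterParams(0, 0))
        assert sm.top[:2] == (1, 1)

    def test_conserved_alignment_has_no_signal(self):
        cols1 = [list("AAAA"), list("CCCC")]
        cols2 = [list("DDDD")]
        sm = score_comparison(_paired(cols1, cols2), FilterParams(0, 0))
        assert sm.no_signal
        assert sm.top[2] == 0.0

    def test_normalized_matrix_invariant_to_log_base(self):
        rng = np.random.default_rng(5)
        aas = np.array(list("ACDEKLMN"))
        cols1 = [list(rng.choice(aas, 12)) for _ in range(4)]
        cols2 = [list(rng.choice(aas, 12)) for _ in range(3)]
        pa = _paired(cols1, cols2)
        nat = score_comparison(pa, FilterParams(0, 10.0))
        two = score_comparison(pa, FilterParams(0, 10.0), base=2.0)
        assert np.allclose(nat.normalized, two.normalized, rtol=1e-9)

    def test_only_reference_positions_are_scored(self):
        # protein 1 reference has a gap in column 1 -> that column is skipped
        recs1 = {"s0": "A-C", "s1": "ADC", "s2": "CDA", "s3": "CEA"}
        recs2 = {"s0": "KL", "s1": "KL", "s2": "ML", "s3": "MN"}
        pa = pair_alignments(Alignment(recs1), Alignment(recs2), "s0", min_common=2)
        sm = score_comparison(pa, FilterParams(0, 0))
        assert sm.shape == (2, 2)
        assert list(sm.positions1) == [1, 2]
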