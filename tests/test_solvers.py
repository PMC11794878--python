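import math
from collections import Counter

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from acrfs import (
    RunConfig,
    compute_chi_square,
    compute_mutual_information,
    compute_pcc,
    score_all,
)


# ---------------------------------------------------------------------------
# Independent brute-force oracles: explicit probability / contingency
# enumeration and direct formula arithmetic, no vectorization shared with
# the implementation.
# ---------------------------------------------------------------------------

def mi_oracle(x, y):
    """Plug-in MI in bits from explicit joint/marginal probability loops."""
    n = len(x)
    joint = Counter(zip(x, y))
    px = Counter(x)
    py = Counter(y)
    total = 0.0
    for (a, b), c in joint.items():
        p_ab = c / n
        p_a = px[a] / n
        p_b = py[b] / n
        total += p_ab * math.log2(p_ab / (p_a * p_b))
    return total


def chi2_frequency_oracle(x, y):
    """Per-class mass chi-square by direct loops."""
    classes = sorted(set(y))
    total = sum(x)
    stat = 0.0
    for c in classes:
        observed = sum(xi for xi, yi in zip(x, y) if yi == c)
        expected = total * sum(1 for yi in y if yi == c) / len(y)
        stat += (observed - expected) ** 2 / expected
    return stat


def pcc_oracle(x, y):
    n = len(x)
    mx = sum(x) / n
    my = sum(y) / n
    num = sum((xi - mx) * (yi - my) for xi, yi in zip(x, y))
    den = math.sqrt(
        sum((xi - mx) ** 2 for xi in x) * sum((yi - my) ** 2 for yi in y)
    )
    return 0.0 if den == 0 else num / den


def binary_vectors_from_table(a, b, c, d):
    """x, y vectors realizing joint counts (x=0,y=0)=a, (0,1)=b, (1,0)=c, (1,1)=d."""
    x = [0] * (a + b) + [1] * (c + d)
    y = [0] * a + [1] * b + [0] * c + [1] * d
    return np.array(x, dtype=float), np.array(y, dtype=int)


def all_2x2_tables(max_cell=5):
    for a in range(max_cell + 1):
        for b in range(max_cell + 1):
            for c in range(max_cell + 1):
                for d in range(max_cell + 1):
                    if a + b + c + d >= 2:
                        yield a, b, c, d


class TestMutualInformation:
    def test_perfectly_dependent_balanced_binary_is_one_bit(self):
        x = np.array([0.0, 0.0, 1.0, 1.0])
        y = np.array([0, 0, 1, 1])
        assert compute_mutual_information(x, y, bins=2) == pytest.approx(1.0)

    def test_constant_feature_carries_no_information(self):
        assert compute_mutual_information(np.full(6, 3.0), np.array([0, 1] * 3)) == 0.0

    def test_known_2x2_joint_value(self):
        # joint counts {(0,0):2, (0,1):1, (1,0):1, (1,1):2} over n=6
        x, y = binary_vectors_from_table(2, 1, 1, 2)
        got = compute_mutual_information(x, y, bins=2)
        assert got == pytest.approx(0.08170416594551, abs=1e-10)
        assert got == pytest.approx(mi_oracle(x.tolist(), y.tolist()), abs=1e-12)

    def test_matches_oracle_on_all_small_2x2_tables(self):
        for a, b, c, d in all_2x2_tables():
            x, y = binary_vectors_from_table(a, b, c, d)
            got = compute_mutual_information(x, y, bins=2)
            want = mi_oracle(x.tolist(), y.tolist())
            assert got == pytest.approx(want, abs=1e-10), (a, b, c, d)

    def test_symmetry_on_discrete_inputs(self, rng):
        for _ in range(50):
            x = rng.integers(0, 4, size=40).astype(float)
            y = rng.integers(0, 2, size=40)
            forward = compute_mutual_information(x, y, bins=4)
            backward = compute_mutual_information(y.astype(float), x.astype(int), bins=4)
            assert forward == pytest.approx(backward, abs=1e-12)

    def test_invariant_to_increasing_affine_rescaling(self, rng):
        x = rng.normal(size=200)
        y = rng.integers(0, 2, size=200)
        base = compute_mutual_information(x, y, bins=10)
        scaled = compute_mutual_information(3.5 * x + 11.0, y, bins=10)
        assert scaled == pytest.approx(base, abs=1e-12)

    def test_length_mismatch_and_empty_rejected(self):
        with pytest.raises(ValueError):
            compute_mutual_information(np.zeros(3), np.zeros(4))
        with pytest.raises(ValueError):
            compute_mutual_information(np.array([]), np.array([]))


class TestChiSquare:
    def test_known_frequency_value(self):
        stat, p = compute_chi_square(
            np.array([1.0, 2.0, 3.0, 4.0]), np.array([0, 0, 1, 1]), mode="frequency"
        )
        # observed (3, 7) vs expected (5, 5): (4+4)/5 = 1.6, df=1
        assert stat == pytest.approx(1.6, abs=1e-12)
        assert p == pytest.approx(0.20590321073206, abs=1e-10)

    def test_observed_equal_expected_gives_zero(self):
        stat, p = compute_chi_square(
            np.array([2.0, 3.0, 3.0, 2.0]), np.array([0, 0, 1, 1]), mode="frequency"
        )
        assert stat == pytest.approx(0.0, abs=1e-12)
        assert p == pytest.approx(1.0)

    def test_negative_values_rejected_in_frequency_mode(self):
        with pytest.raises(ValueError, match="non-negative"):
            compute_chi_square(np.array([1.0, -2.0]), np.array([0, 1]), mode="frequency")

    def test_zero_total_mass_rejected(self):
        with pytest.raises(ValueError, match="zero total"):
            compute_chi_square(np.zeros(4), np.array([0, 0, 1, 1]), mode="frequency")

    def test_matches_oracle_on_all_small_2x2_tables(self):
        for a, b, c, d in all_2x2_tables():
            if (a + b == 0 and c + d == 0) or c + d == 0:
                continue  # zero feature mass
            if a + c == 0 or b + d == 0:
                continue  # single class
            x, y = binary_vectors_from_table(a, b, c, d)
            stat, _ = compute_chi_square(x, y, mode="frequency")
            want = chi2_frequency_oracle(x.tolist(), y.tolist())
            assert stat == pytest.approx(want, abs=1e-10), (a, b, c, d)

    def test_p_value_decreases_as_statistic_grows(self):
        from scipy.stats import chi2 as chi2_dist

        stats_grid = [0.1, 0.5, 1.0, 2.0, 5.0, 20.0]
        pvals = [chi2_dist.sf(s, 1) for s in stats_grid]
        assert all(p1 > p2 for p1, p2 in zip(pvals, pvals[1:]))

    def test_binned_mode_invariant_to_affine_rescaling(self, rng):
        x = rng.normal(size=300)
        y = rng.integers(0, 2, size=300)
        s1, _ = compute_chi_square(x, y, mode="binned", bins=8)
        s2, _ = compute_chi_square(2.0 * x + 7.0, y, mode="binned", bins=8)
        assert s1 == pytest.approx(s2, abs=1e-10)


class TestPcc:
    def test_perfect_positive_and_negative_linearity(self):
        y = np.array([0, 1, 0, 1])
        assert compute_pcc(y.astype(float), y) == pytest.approx(1.0)
        signed = np.where(y == 1, 1.0, -1.0)
        assert compute_pcc(-signed, y) == pytest.approx(-1.0)

    def test_known_three_point_value(self):
        got = compute_pcc(np.array([1.0, 2.0, 3.0]), np.array([0, 0, 1]))
        assert got == pytest.approx(math.sqrt(3) / 2, abs=1e-12)

    def test_constant_feature_warns_and_returns_zero(self):
        with pytest.warns(UserWarning, match="zero-variance"):
            assert compute_pcc(np.full(4, 2.0), np.array([0, 1, 0, 1])) == 0.0

    def test_matches_oracle_on_random_vectors(self, rng):
        for _ in range(200):
            n = int(rng.integers(3, 30))
            x = rng.normal(size=n)
            y = rng.integers(0, 2, size=n)
            if len(np.unique(y)) < 2:
                continue
            got = compute_pcc(x, y)
            assert got == pytest.approx(pcc_oracle(x.tolist(), y.tolist()), abs=1e-10)

    def test_absolute_value_invariant_to_affine_rescaling(self, rng):
        x = rng.normal(size=100)
        y = rng.integers(0, 2, size=100)
        assert abs(compute_pcc(-4.0 * x + 3.0, y)) == pytest.approx(
            abs(compute_pcc(x, y)), abs=1e-12
        )


@settings(max_examples=200, derandomize=True)
@given(
    st.lists(st.integers(0, 3), min_size=4, max_size=40),
    st.data(),
)
def test_solvers_match_oracles_on_random_small_vectors(codes, data):
    """MI and PCC agree with brute-force formula evaluation on arbitrary
    small discrete vectors (chi-square is covered by the 2x2 sweep)."""
    y = data.draw(st.lists(st.integers(0, 1), min_size=len(codes), max_size=len(codes)))
    x = np.array(codes, dtype=float)
    y = np.array(y, dtype=int)
    got_mi = compute_mutual_information(x, y, bins=4)
    assert got_mi == pytest.approx(mi_oracle(codes, y.tolist()), abs=1e-10)
    if len(set(codes)) > 1 and len(np.unique(y)) > 1:
        assert compute_pcc(x, y) == pytest.approx(
            pcc_oracle(list(map(float, codes)), y.tolist()), abs=1e-10
        )


class TestScoreAll:
    def test_three_score_vectors_with_directions(self, small_dataset):
        scores = score_all(small_dataset, RunConfig())
        assert [s.solver_name for s in scores] == [
            "mutual_information", "chi_square", "pcc",
        ]
        assert [s.direction for s in scores] == [
            "higher_better", "lower_better", "higher_better",
        ]
        for s in scores:
            assert len(s.values) == small_dataset.n_features
        mi, chi, pcc = scores
        assert (mi.values >= 0).all()
        assert ((chi.values >= 0) & (chi.values <= 1)).all()
        assert ((pcc.values >= 0) & (pcc.values <= 1)).all()

    def test_feature_identical_to_label_dominates(self, tiny_dataset):
        scores = score_all(tiny_dataset, RunConfig(mi_bins=2))
        for s in scores:
            best = s.values.argmax() if s.direction == "higher_better" else s.values.argmin()
            assert tiny_dataset.feature_names[best] == "binary" or s.values[best] == pytest.approx(
                s.values[tiny_dataset.feature_names.index("binary")]
            )

    def test_permuting_columns_permutes_scores(self, small_dataset):
        from acrfs import Dataset

        perm = np.random.default_rng(5).permutation(small_dataset.n_features)
        permuted = Dataset(
            small_dataset.features[:, perm],
            small_dataset.labels,
            [small_dataset.feature_names[j] for j in perm],
            small_dataset.label_name,
        )
        base = score_all(small_dataset, RunConfig())
        moved = score_all(permuted, RunConfig())
        for s_base, s_perm in zip(base, moved):
            np.testing.assert_allclose(s_perm.values, s_base.values[perm], atol=1e-12)

    def test_failure_names_the_offending_feature(self, small_dataset):
        from acrfs import Dataset

        bad = small_dataset.features.copy()
        bad[:, 2] = -np.abs(bad[:, 2])  # negative mass breaks frequency-mode chi2
        ds = Dataset(bad, small_dataset.labels, small_dataset.feature_names)
        with pytest.raises(ValueError, match=ds.feature_names[2]):
            score_all(ds, RunConfig(chi2_mode="frequency"))
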