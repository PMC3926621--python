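import itertools

import numpy as np
import pytest

from eegcs.redundancy import (
    DifferenceBlock,
    PairList,
    apply_differences,
    correlation_matrix,
    invert_differences,
    select_pairs,
)
from eegcs.sensing import MeasurementBlock


def _random_block(rng, M=16, C=4, corr=0.0):
    base = rng.normal(size=(M, 1))
    Y = corr * base + (1 - corr) * rng.normal(size=(M, C))
    return MeasurementBlock(Y)


class TestCorrelationMatrix:
    def test_identical_and_negated_channels(self, rng):
        y = rng.normal(size=16)
        Y = MeasurementBlock(np.column_stack([y, y, -y]))
        R = correlation_matrix(Y).R
        assert R[0, 1] == pytest.approx(1.0)
        assert R[0, 2] == pytest.approx(-1.0)
        np.testing.assert_allclose(R, R.T)
        np.testing.assert_allclose(np.diag(R), 1.0)

    def test_against_scipy_pearson(self, rng):
        from scipy.stats import pearsonr

        Y = MeasurementBlock(rng.normal(size=(20, 3)))
        R = correlation_matrix(Y).R
        for i, j in itertools.combinations(range(3), 2):
            assert R[i, j] == pytest.approx(pearsonr(Y.Y[:, i], Y.Y[:, j])[0])

    def test_zero_variance_column(self, rng):
        Y = np.column_stack([rng.normal(size=12), np.full(12, 3.0)])
        with pytest.warns(UserWarning, match="zero-variance"):
            R = correlation_matrix(MeasurementBlock(Y)).R
        assert R[0, 1] == 0.0 and R[1, 1] == 1.0


def _brute_force_greedy(R, variances, T):
    """Independent re-implementation of the greedy selection for small C."""
    C = R.shape[0]
    entries, rows = [], []

    def rank_of(rs):
        return np.linalg.matrix_rank(np.array(rs), tol=1e-8)

    pool = sorted(
        (
            (i, j)
            for i in range(C)
            for j in range(i + 1, C)
            if abs(R[i, j]) >= T
        ),
        key=lambda ij: (-abs(R[ij[0], ij[1]]), ij),
    )
    for i, j in pool:
        if len(entries) == C:
            break
        s = 1 if R[i, j] > 0 else -1
        row = np.zeros(C)
        row[i], row[j] = 1.0, -s
        if rank_of(rows + [row]) > len(rows):
            rows.append(row)
            entries.append((i + 1, j + 1, s))
    for c in sorted(range(C), key=lambda c: (variances[c], c)):
        if len(entries) == C:
            break
        row = np.zeros(C)
        row[c] = 1.0
        if rank_of(rows + [row]) > len(rows):
            rows.append(row)
            entries.append((c + 1, 0, 1))
    return entries


class TestSelectPairs:
    def test_single_channel_singleton(self, rng):
        Y = MeasurementBlock(rng.normal(size=(8, 1)))
        p = select_pairs(correlation_matrix(Y))
        assert p.entries == [(1, 0, 1)]

    def test_highest_correlation_first(self, rng):
        # construct Y with controlled correlation ordering
        base = rng.normal(size=16)
        Y = MeasurementBlock(
            np.column_stack(
                [
                    base,
                    base + 0.05 * rng.normal(size=16),
                    base + 0.8 * rng.normal(size=16),
                ]
            )
        )
        corr = correlation_matrix(Y)
        p = select_pairs(corr, T=0.1)
        assert p.entries[0][:2] == (1, 2)

    def test_matches_brute_force_oracle(self, rng):
        for t in range(30):
            C = int(rng.integers(2, 7))
            Y = _random_block(rng, M=12, C=C, corr=0.7)
            corr = correlation_matrix(MeasurementBlock(Y.Y))
            ours = select_pairs(corr, T=0.3).entries
            oracle = _brute_force_greedy(corr.R, corr.variances, T=0.3)
            assert ours == oracle

    def test_full_rank_always(self, rng):
        for t in range(50):
            C = int(rng.integers(2, 10))
            p = select_pairs(correlation_matrix(_random_block(rng, C=C, corr=0.5)))
            A = p.incidence_matrix()
            assert np.linalg.matrix_rank(A, tol=1e-8) == C

    def test_anticorrelated_pair_gets_negative_sign(self, rng):
        y = rng.normal(size=16)
        Y = MeasurementBlock(np.column_stack([y, -y + 0.01 * rng.normal(size=16)]))
        p = select_pairs(correlation_matrix(Y))
        i, j, s = p.entries[0]
        assert (i, j, s) == (1, 2, -1)


class TestDifferences:
    def test_identical_channels_zero_difference(self, rng):
        y = rng.normal(size=16)
        Y = MeasurementBlock(np.column_stack([y, y]))
        p = PairList(entries=[(1, 2, 1), (2, 0, 1)])
        Yt = apply_differences(Y, p)
        np.testing.assert_allclose(Yt.Ytilde[:, 0], 0.0)
        np.testing.assert_allclose(Yt.Ytilde[:, 1], y)

    def test_negative_sign_adds(self, rng):
        Y = MeasurementBlock(rng.normal(size=(8, 2)))
        p = PairList(entries=[(1, 2, -1), (2, 0, 1)])
        Yt = apply_differences(Y, p)
        np.testing.assert_allclose(Yt.Ytilde[:, 0], Y.Y[:, 0] + Y.Y[:, 1])

    def test_back_substitution_example(self):
        a = np.array([3.0, 1.0])
        b = np.array([2.0, -4.0])
        p = PairList(entries=[(1, 2, 1), (2, 0, 1)])
        Yt = DifferenceBlock(np.column_stack([a - b, b]))
        Y = invert_differences(Yt, p)
        np.testing.assert_allclose(Y.Y, np.column_stack([a, b]), atol=1e-12)

    def test_all_singletons_identity(self, rng):
        Y = MeasurementBlock(rng.normal(size=(8, 3)))
        p = PairList(entries=[(1, 0, 1), (2, 0, 1), (3, 0, 1)])
        np.testing.assert_array_equal(
            invert_differences(apply_differences(Y, p), p).Y, Y.Y
        )

    def test_round_trip_random_schedules(self, rng):
        for t in range(40):
            C = int(rng.integers(2, 12))
            Y = _random_block(rng, M=10, C=C, corr=0.6)
            p = select_pairs(correlation_matrix(Y), T=0.2)
            back = invert_differences(apply_differences(Y, p), p)
            np.testing.assert_allclose(back.Y, Y.Y, atol=1e-9)

    def test_singular_schedule_raises(self, rng):
        Y = MeasurementBlock(rng.normal(size=(8, 2)))
        bad = PairList(entries=[(1, 2, 1), (1, 2, 1)])
        Yt = apply_differences(Y, bad)
        with pytest.raises(ValueError, match="singular"):
            invert_differences(Yt, bad)


def test_variance_narrowing_on_correlated_channels(rng):
    """Sign-matched differencing narrows the measurement distribution when
    channels are strongly correlated."""
    n_narrower = 0
    n_pairs = 0
    for t in range(100):
        base = rng.normal(size=(16, 1))
        Y = MeasurementBlock(
            0.95 * base + 0.05 * rng.normal(size=(16, 4))
        )
        p = select_pairs(correlation_matrix(Y), T=0.6)
        Yt = apply_differences(Y, p)
        for k, (i, j, s) in enumerate(p.entries):
            if j == 0:
                continue
            n_pairs += 1
            if Yt.Ytilde[:, k].var() < Y.Y[:, i - 1].var():
                n_narrower += 1
    assert n_pairs > 100
    assert n_narrower == n_pairs
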