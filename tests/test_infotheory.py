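"""Mutual information, Blahut-Arimoto capacity, MMI and CV."""

import itertools

import numpy as np
import pytest

from fflcap import (
    DiscreteChannel,
    FixtureSpec,
    arimoto_blahut,
    channel_from_samples,
    coefficient_of_variation,
    estimate_channel,
    joint_channel,
    make_channel,
    make_ensemble,
    mmi,
    mutual_information,
)


def mi_brute(p_s, cond):
    """Independent hand evaluation of I(R;S) by direct double summation."""
    p_r = np.zeros(cond.shape[1])
    for j, i in itertools.product(range(cond.shape[0]), range(cond.shape[1])):
        p_r[i] += p_s[j] * cond[j, i]
    total = 0.0
    for j, i in itertools.product(range(cond.shape[0]), range(cond.shape[1])):
        if p_s[j] > 0 and cond[j, i] > 0:
            total += p_s[j] * cond[j, i] * np.log2(cond[j, i] / p_r[i])
    return total


def capacity_grid_2input(cond, n_grid=20001):
    """Brute-force capacity of a 2-input channel by scanning p in [0,1]."""
    best = 0.0
    for p in np.linspace(0.0, 1.0, n_grid):
        best = max(best, mi_brute(np.array([p, 1 - p]), cond))
    return best


class TestMutualInformation:
    def test_noiseless_identity_uniform(self):
        ch = DiscreteChannel(tuple(range(12)), np.eye(12))
        p = np.full(12, 1 / 12)
        assert mutual_information(p, ch) == pytest.approx(np.log2(12), abs=1e-12)

    def test_identical_rows_carry_nothing(self):
        ch = DiscreteChannel((0, 1, 2), np.tile([0.25, 0.25, 0.5], (3, 1)))
        assert mutual_information(np.array([0.2, 0.3, 0.5]), ch) == pytest.approx(0.0, abs=1e-12)

    def test_matches_hand_summation(self):
        cond = np.array([[0.9, 0.1], [0.2, 0.8]])
        ch = DiscreteChannel((0, 1), cond)
        p = np.array([0.5, 0.5])
        assert mutual_information(p, ch) == pytest.approx(mi_brute(p, cond), abs=1e-12)

    def test_invalid_inputs_rejected(self):
        ch = DiscreteChannel((0, 1), np.array([[1.0, 0.0], [0.0, 1.0]]))
        with pytest.raises(ValueError):
            mutual_information(np.array([0.5, 0.5, 0.0]), ch)
        with pytest.raises(ValueError):
            mutual_information(np.array([0.7, 0.7]), ch)


class TestArimotoBlahut:
    def test_identity_12(self):
        res = arimoto_blahut(DiscreteChannel(tuple(range(12)), np.eye(12)))
        assert res.converged
        assert res.cc_bits == pytest.approx(np.log2(12), abs=1e-6)
        assert np.allclose(res.p_star, 1 / 12, atol=1e-6)

    def test_binary_symmetric_closed_form(self):
        ch, c_true = make_channel(FixtureSpec("bsc", parameters={"crossover": 0.25}))
        res = arimoto_blahut(ch)
        assert res.cc_bits == pytest.approx(c_true, abs=1e-6)
        assert c_true == pytest.approx(1 - (-0.25 * np.log2(0.25) - 0.75 * np.log2(0.75)))

    def test_uniform_rows_zero_capacity(self):
        ch = DiscreteChannel((0, 1, 2), np.tile([0.1, 0.4, 0.5], (3, 1)))
        assert arimoto_blahut(ch).cc_bits == pytest.approx(0.0, abs=1e-9)

    @pytest.mark.parametrize(
        "cond",
        [
            np.array([[0.9, 0.1], [0.2, 0.8]]),
            np.array([[0.6, 0.3, 0.1], [0.1, 0.2, 0.7]]),
            np.array([[0.5, 0.5], [0.5, 0.5]]),
        ],
    )
    def test_matches_brute_force_grid_on_2_inputs(self, cond):
        res = arimoto_blahut(DiscreteChannel((0, 1), cond))
        assert res.cc_bits == pytest.approx(capacity_grid_2input(cond), abs=1e-3)

    def test_maximization_beats_uniform(self):
        rng = np.random.default_rng(5)
        for _ in range(10):
            cond = rng.dirichlet(np.ones(6), size=4)
            ch = DiscreteChannel(tuple(range(4)), cond / cond.sum(1, keepdims=True))
            cc = arimoto_blahut(ch).cc_bits
            assert cc >= mutual_information(np.full(4, 0.25), ch) - 1e-9
            assert 0.0 <= cc <= 2.0 + 1e-9

    def test_bin_merge_never_increases_capacity(self):
        """Data-processing: merging response bins cannot add information."""
        rng = np.random.default_rng(7)
        cond = rng.dirichlet(np.ones(8), size=5)
        ch = DiscreteChannel(tuple(range(5)), cond)
        merged = cond.reshape(5, 4, 2).sum(axis=2)
        ch2 = DiscreteChannel(tuple(range(5)), merged)
        assert arimoto_blahut(ch2).cc_bits <= arimoto_blahut(ch).cc_bits + 1e-9


class TestChannelEstimation:
    def test_deterministic_levels_give_one_hot_rows(self):
        samples = {s: np.full(100, 100.0 * s) for s in (1, 2, 3)}
        ch = channel_from_samples(samples, bins=16)
        assert np.allclose(ch.cond.sum(axis=1), 1.0)
        for row in ch.cond:
            assert row.max() == 1.0
        assert not np.allclose(ch.cond[0], ch.cond[1])

    def test_degenerate_range_is_single_bin(self):
        samples = {s: np.full(50, 7.0) for s in (0, 1)}
        ch = channel_from_samples(samples, bins=64)
        assert ch.n_bins == 1
        assert np.allclose(ch.cond, 1.0)

    def test_poisson_rows_match_binned_pmf(self):
        from scipy.stats import poisson

        ens = make_ensemble(FixtureSpec("poisson_map", n_inputs=3, n_samples=4000, seed=11))
        ch = estimate_channel(ens, "X", 0.0, bins=64)
        lams = [10.0, 20.0, 30.0]
        edges = ch.bin_edges
        for j, lam in enumerate(lams):
            # exact binned pmf on the same edges (right-closed last bin)
            counts = np.arange(0, 200)
            pmf = poisson.pmf(counts, lam)
            idx = np.clip(np.searchsorted(edges, counts, side="right") - 1, 0, ch.n_bins - 1)
            expected = np.bincount(idx, weights=pmf, minlength=ch.n_bins)
            tv = 0.5 * np.abs(ch.cond[j] - expected).sum()
            # expected TV of an empirical pmf over ~k occupied cells is
            # ~sqrt(k/(2 pi n)); 4000 samples put 0.05 comfortably above it
            assert tv < 0.05

    def test_empty_or_single_input_rejected(self):
        ens = make_ensemble(FixtureSpec("poisson_map", n_inputs=1, n_samples=10, seed=0))
        with pytest.raises(ValueError):
            estimate_channel(ens, "X", 0.0)


class TestMmi:
    def test_single_channel_reduces_to_mi(self):
        cond = np.array([[0.7, 0.3], [0.2, 0.8]])
        ch = DiscreteChannel((0, 1), cond)
        p = np.array([0.4, 0.6])
        assert mmi([ch], p) == pytest.approx(mutual_information(p, ch), abs=1e-12)

    def test_uninformative_channels_give_zero(self):
        ch = DiscreteChannel((0, 1), np.tile([0.5, 0.5], (2, 1)))
        assert mmi([ch, ch, ch], np.array([0.5, 0.5])) == pytest.approx(0.0, abs=1e-9)

    def test_three_one_hot_channels_resolve_all_inputs(self):
        n = 12
        ch = DiscreteChannel(tuple(range(n)), np.eye(n))
        p = np.full(n, 1 / n)
        assert mmi([ch, ch, ch], p) == pytest.approx(np.log2(n), abs=1e-9)

    def test_mmi_at_least_best_single_and_at_most_input_entropy(self):
        rng = np.random.default_rng(3)
        p = rng.dirichlet(np.ones(4))
        chans = [
            DiscreteChannel(tuple(range(4)), rng.dirichlet(np.ones(5), size=4))
            for _ in range(3)
        ]
        val = mmi(chans, p)
        best_single = max(mutual_information(p, ch) for ch in chans)
        h_s = -(p * np.log2(p)).sum()
        assert val >= best_single - 1e-9
        assert val <= h_s + 1e-9

    def test_default_input_distribution_is_joint_capacity(self):
        chans = [
            DiscreteChannel((0, 1), np.array([[0.9, 0.1], [0.3, 0.7]])),
            DiscreteChannel((0, 1), np.array([[0.8, 0.2], [0.1, 0.9]])),
        ]
        joint = joint_channel(chans)
        assert mmi(chans) == pytest.approx(arimoto_blahut(joint).cc_bits, abs=1e-9)

    def test_mismatched_labels_rejected(self):
        a = DiscreteChannel((0, 1), np.eye(2))
        b = DiscreteChannel((1, 2), np.eye(2))
        with pytest.raises(ValueError):
            mmi([a, b], np.array([0.5, 0.5]))


class TestCoefficientOfVariation:
    def test_constant_ensemble_is_zero(self):
        ens = make_ensemble(FixtureSpec("deterministic_map", n_inputs=2, n_samples=50))
        assert coefficient_of_variation(ens[0], "X", 0.0) == 0.0

    def test_poisson_cv_is_inverse_sqrt_lambda(self):
        ens = make_ensemble(
            FixtureSpec("poisson_map", n_inputs=1, n_samples=4000, seed=2,
                        parameters={"lams": [400.0]})
        )
        cv = coefficient_of_variation(ens[0], "X", 0.0)
        assert cv == pytest.approx(0.05, rel=0.1)

    def test_zero_mean_undefined(self):
        ens = make_ensemble(
            FixtureSpec("deterministic_map", n_inputs=1, n_samples=10,
                        parameters={"levels": [0]})
        )
        assert np.isnan(coefficient_of_variation(ens[0], "X", 0.0))


class TestChannelInvariants:
    def test_rows_sum_to_one_within_tolerance(self):
        rng = np.random.default_rng(9)
        samples = {s: rng.normal(10 * s, 3, 500) for s in range(6)}
        ch = channel_from_samples(samples, bins=64)
        assert np.max(np.abs(ch.cond.sum(axis=1) - 1.0)) <= 1e-12

    def test_invalid_rows_rejected(self):
        with pytest.raises(ValueError):
            DiscreteChannel((0, 1), np.array([[0.5, 0.4], [0.5, 0.5]]))
        with pytest.raises(ValueError):
            DiscreteChannel((0, 1), np.array([[1.1, -0.1], [0.5, 0.5]]))


def test_channel_csv_export(tmp_path):
    samples = {1.0: np.arange(100.0), 2.0: np.arange(100.0) + 50.0}
    ch = channel_from_samples(samples, bins=8)
    path = tmp_path / "channel.csv"
    ch.to_csv(path)
    lines = path.read_text().strip().splitlines()
    assert len(lines) == 3
    import json
    sidecar = json.loads((tmp_path / "channel.csv.json").read_text())
    assert sidecar["input_labels"] == [1.0, 2.0]
    assert len(sidecar["bin_edges"]) == 9
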