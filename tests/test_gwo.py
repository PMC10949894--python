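import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from hemopipe.features import FeatureMatrix
from hemopipe.gwo import (
    FitnessConfig,
    GAConfig,
    GWOConfig,
    HoldoutSplit,
    Leaders,
    binarize_step,
    combine_leader,
    encircling_coefficient,
    ga_select,
    gwo_select,
    leader_distance,
    load_mask,
    save_history,
    save_mask,
    selection_fitness,
    step_size,
    stochastic_crossover,
    update_leaders,
)
from hemopipe.synthetic import PlantedFeatureSpec, make_feature_dataset


class TestPrimitives:
    @pytest.mark.parametrize("t,t_max,expected", [(0, 100, 2.0), (100, 100, 0.0), (50, 100, 1.0)])
    def test_encircling_coefficient(self, t, t_max, expected):
        assert encircling_coefficient(t, t_max) == pytest.approx(expected)

    def test_encircling_coefficient_rejects_overrun(self):
        with pytest.raises(ValueError):
            encircling_coefficient(101, 100)

    @pytest.mark.parametrize("c,lead,wolf,expected", [(2.0, 1, 0, 2.0), (1.0, 0, 0, 0.0), (1.5, 1, 1, 0.5)])
    def test_leader_distance(self, c, lead, wolf, expected):
        assert leader_distance(c, lead, wolf) == pytest.approx(expected)

    def test_step_size_midpoint_and_limit(self):
        assert step_size(1.0, 0.5) == pytest.approx(0.5)
        assert step_size(1.0, 1e6) == pytest.approx(1.0)
        assert step_size(0.6, 1.0) == pytest.approx(1 / (1 + np.exp(-1.0)))

    @pytest.mark.parametrize("s,r,expected", [(0.9, 0.5, 1), (0.1, 0.5, 0), (0.4, 0.4, 1)])
    def test_binarize_step_boundary_inclusive(self, s, r, expected):
        assert binarize_step(s, r) == expected

    @pytest.mark.parametrize("lead,step,expected", [(1, 0, 1), (0, 0, 0), (1, 1, 1), (0, 1, 1)])
    def test_combine_leader_is_or(self, lead, step, expected):
        assert combine_leader(lead, step) == expected

    @pytest.mark.parametrize("r,expected", [(0.1, "z1"), (0.5, "z2"), (0.9, "z3"), (1 / 3, "z2")])
    def test_stochastic_crossover_thirds(self, r, expected):
        assert stochastic_crossover("z1", "z2", "z3", r) == expected


class TestFitness:
    def test_empty_mask_scores_one(self, small_planted):
        fm, _ = small_planted
        assert selection_fitness(np.zeros(fm.n_features), fm) == 1.0

    def test_zero_error_all_features(self, small_planted):
        """Perfectly separable fixture, everything selected: Gamma = alpha2."""
        fm, _ = small_planted
        rng = np.random.default_rng(0)
        g = selection_fitness(np.ones(fm.n_features), fm, rng=rng)
        assert g == pytest.approx(0.01)

    def test_zero_error_half_features(self, small_planted):
        fm, truth = small_planted
        mask = np.zeros(fm.n_features)
        mask[truth] = 1  # informative columns separate the classes perfectly
        mask[: fm.n_features // 2] = np.maximum(mask[: fm.n_features // 2], 1)
        mask[truth] = 1
        q_s = int(mask.sum())
        g = selection_fitness(mask, fm, rng=np.random.default_rng(0))
        assert g == pytest.approx(0.01 * q_s / fm.n_features)

    def test_mask_length_checked(self, small_planted):
        fm, _ = small_planted
        with pytest.raises(ValueError):
            selection_fitness(np.ones(3), fm)

    def test_too_few_training_rows_rejected(self):
        fm = FeatureMatrix(np.random.default_rng(0).random((5, 4)), np.array([0, 0, 0, 1, 1]))
        split = HoldoutSplit(train_idx=np.array([0, 3]), test_idx=np.array([1, 2, 4]))
        with pytest.raises(ValueError):
            selection_fitness(np.ones(4), fm, FitnessConfig(k=5), split=split)

    @settings(max_examples=20, deadline=None)
    @given(st.integers(0, 2**20 - 1))
    def test_gamma_decomposition(self, bits):
        """Gamma always lies in [0,1] and decomposes as a1*e + a2*qs/qt."""
        fm, _ = make_feature_dataset(
            PlantedFeatureSpec(classes=2, per_class=20, dims=20, informative=5, effect=4.0, seed=5)
        )
        mask = np.array([(bits >> i) & 1 for i in range(20)], dtype=np.int8)
        split = HoldoutSplit.draw(fm.labels, 0.2, np.random.default_rng(1))
        g = selection_fitness(mask, fm, split=split)
        assert 0.0 <= g <= 1.0
        if mask.sum() > 0:
            parsimony = 0.01 * mask.sum() / 20
            err = (g - parsimony) / 0.99
            assert -1e-12 <= err <= 1 + 1e-12


class TestUpdateLeaders:
    def test_first_candidate_becomes_alpha(self):
        leaders = Leaders.initial(4)
        mask = np.array([1, 0, 1, 0], dtype=np.int8)
        out = update_leaders(leaders, mask, 0.4)
        assert out.f_alpha == 0.4
        np.testing.assert_array_equal(out.v_alpha, mask)

    def test_alpha_improvement_demotes_alpha_to_beta(self):
        leaders = Leaders(
            v_alpha=np.array([1, 1], dtype=np.int8),
            v_beta=np.array([0, 1], dtype=np.int8),
            v_delta=np.array([1, 0], dtype=np.int8),
            f_alpha=0.3, f_beta=0.5, f_delta=0.7,
        )
        out = update_leaders(leaders, np.array([0, 0]), 0.2)
        assert (out.f_alpha, out.f_beta, out.f_delta) == (0.2, 0.3, 0.7)
        np.testing.assert_array_equal(out.v_beta, leaders.v_alpha)

    def test_beta_improvement_demotes_beta_to_delta(self):
        leaders = Leaders(
            v_alpha=np.zeros(2, np.int8), v_beta=np.ones(2, np.int8),
            v_delta=np.zeros(2, np.int8), f_alpha=0.1, f_beta=0.5, f_delta=0.7,
        )
        out = update_leaders(leaders, np.array([1, 0]), 0.3)
        assert (out.f_alpha, out.f_beta, out.f_delta) == (0.1, 0.3, 0.5)
        np.testing.assert_array_equal(out.v_delta, leaders.v_beta)

    def test_tie_with_alpha_goes_to_beta_slot(self):
        leaders = Leaders(
            v_alpha=np.zeros(2, np.int8), v_beta=np.ones(2, np.int8),
            v_delta=np.zeros(2, np.int8), f_alpha=0.3, f_beta=0.5, f_delta=0.7,
        )
        out = update_leaders(leaders, np.array([1, 1]), 0.3)
        # strict <: alpha unchanged, candidate ranks below it
        assert out.f_alpha == 0.3
        np.testing.assert_array_equal(out.v_alpha, leaders.v_alpha)
        assert out.f_beta == 0.3

    def test_ordering_invariant_under_random_stream(self, rng):
        leaders = Leaders.initial(6)
        for _ in range(200):
            cand = rng.integers(0, 2, 6).astype(np.int8)
            leaders = update_leaders(leaders, cand, float(rng.random()))
            assert leaders.f_alpha <= leaders.f_beta <= leaders.f_delta


class TestOptimizers:
    def test_gwo_deterministic(self, small_planted):
        fm, _ = small_planted
        cfg = GWOConfig(n_pop=5, t_max=3)
        m1, h1 = gwo_select(fm, cfg, seed=7)
        m2, h2 = gwo_select(fm, cfg, seed=7)
        np.testing.assert_array_equal(m1, m2)
        assert h1.f_alpha == h2.f_alpha

    def test_gwo_history_non_increasing_and_binary(self, small_planted):
        fm, _ = small_planted
        mask, hist = gwo_select(fm, GWOConfig(n_pop=6, t_max=8), seed=1)
        assert all(b <= a for a, b in zip(hist.f_alpha, hist.f_alpha[1:]))
        assert set(np.unique(mask)) <= {0, 1}
        assert mask.sum() > 0  # empty mask never wins on a learnable fixture

    def test_gwo_rejects_single_class(self):
        fm = FeatureMatrix(np.random.default_rng(0).random((10, 4)), np.zeros(10, dtype=int))
        with pytest.raises(ValueError):
            gwo_select(fm, GWOConfig(n_pop=5, t_max=2), seed=0)

    def test_ga_deterministic_and_monotone(self, small_planted):
        fm, _ = small_planted
        cfg = GAConfig(n_pop=8, t_max=6)
        m1, h1 = ga_select(fm, cfg, seed=2)
        m2, h2 = ga_select(fm, cfg, seed=2)
        np.testing.assert_array_equal(m1, m2)
        assert h1.f_alpha == h2.f_alpha
        assert all(b <= a for a, b in zip(h1.f_alpha, h1.f_alpha[1:]))

    def test_vectorized_update_matches_scalar_chain(self, small_planted):
        """One position update recomputed bit-by-bit with the public primitives."""
        fm, _ = small_planted
        d = fm.n_features
        rng = np.random.default_rng(33)
        leaders = Leaders(
            v_alpha=rng.integers(0, 2, d).astype(np.int8),
            v_beta=rng.integers(0, 2, d).astype(np.int8),
            v_delta=rng.integers(0, 2, d).astype(np.int8),
            f_alpha=0.1, f_beta=0.2, f_delta=0.3,
        )
        wolf = rng.integers(0, 2, d).astype(np.int8)
        a = encircling_coefficient(3, 10)
        draws = np.random.default_rng(44).random((d, 10))
        expected = np.empty(d, dtype=np.int8)
        stack = (leaders.v_alpha, leaders.v_beta, leaders.v_delta)
        for k in range(d):
            z = []
            for i in range(3):
                a_i = 2.0 * a * draws[k, i] - a
                c_i = 2.0 * draws[k, 3 + i]
                dist = leader_distance(c_i, int(stack[i][k]), int(wolf[k]))
                z.append(combine_leader(int(stack[i][k]),
                                        binarize_step(step_size(a_i, dist), draws[k, 6 + i])))
            expected[k] = stochastic_crossover(z[0], z[1], z[2], draws[k, 9])
        # vectorized form as used inside gwo_select
        stack_f = np.stack(stack, axis=1).astype(float)
        a_coefs = 2.0 * a * draws[:, 0:3] - a
        c_coefs = 2.0 * draws[:, 3:6]
        dist = np.abs(c_coefs * stack_f - wolf[:, None])
        s = 1.0 / (1.0 + np.exp(-10.0 * (a_coefs * dist - 0.5)))
        zmat = ((stack_f + (s >= draws[:, 6:9])) >= 1).astype(np.int8)
        pick = np.where(draws[:, 9] < 1 / 3, 0, np.where(draws[:, 9] < 2 / 3, 1, 2))
        got = zmat[np.arange(d), pick]
        np.testing.assert_array_equal(got, expected)


class TestMaskIO:
    def test_round_trip(self, tmp_path, rng):
        mask = rng.integers(0, 2, 30).astype(np.int8)
        save_mask(mask, tmp_path / "mask.txt", gamma=0.0123)
        back = load_mask(tmp_path / "mask.txt")
        np.testing.assert_array_equal(back, mask)

    def test_history_file(self, tmp_path, small_planted):
        fm, _ = small_planted
        _, hist = gwo_select(fm, GWOConfig(n_pop=5, t_max=3), seed=0)
        save_history(hist, tmp_path / "hist.tsv")
        rows = (tmp_path / "hist.tsv").read_text().splitlines()
        assert rows[0].split("\t") == ["iteration", "f_alpha", "q_s"]
        assert len(rows) == 4
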