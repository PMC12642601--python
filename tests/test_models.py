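"""Linear-model taxonomy: oracles, recovery, gates, and nesting."""

import numpy as np
import pandas as pd
import pytest

from crossformat import (
    archetype_population,
    bin_rates,
    classify_population,
    condition_means,
    fit_models_cv,
    make_design,
    simulate_spikes,
    task_relevant_subset,
)
from crossformat.models import (
    UnitClassification,
    _pooled_cv_r2,
    applicable_models,
    best_model,
    build_design_matrix,
    make_folds,
    model_param_count,
    permutation_gate,
    window_means,
)
from conftest import rates_from_values


def _constant_rates(trials, fn, noise=0.0, seed=0, n_units=1):
    rng = np.random.default_rng(seed)
    mean = np.array([fn(r) for r in trials.itertuples()], dtype=float)
    vals = np.tile(mean[None, :, None], (n_units, 1, 30)) + rng.normal(0, noise, (n_units, len(trials), 30))
    return rates_from_values(vals)


class TestConditionMeans:
    def test_constant_unit_gives_constant_means(self):
        design, trials = make_design("main", reps_per_condition=2, seed=0)
        rates = _constant_rates(trials, lambda r: 10.0)
        cm = condition_means(rates, trials, design)
        assert cm.shape == (1, 24)
        assert np.allclose(cm.to_numpy(), 10.0)

    def test_hand_computed_toy_means(self):
        design, trials = make_design("main", reps_per_condition=2, seed=1)
        vals = np.zeros((1, len(trials), 30))
        # two trials of one cell get window rates 3 and 7 -> mean 5
        cell = trials[(trials.format == "intention") & (trials.hand == "left")
                      & (trials.action == "lift") & (trials.direction == "left")].index
        vals[0, cell[0], :] = 3.0
        vals[0, cell[1], :] = 7.0
        cm = condition_means(rates_from_values(vals), trials, design)
        assert cm.loc["u0000", ("intention", "left|lift|left")] == pytest.approx(5.0)

    def test_window_disjoint_from_response_is_zero(self):
        design, trials = make_design("main", reps_per_condition=2, seed=2)
        vals = np.zeros((1, len(trials), 30))
        vals[0, :, 15:] = 8.0  # active only after 1.5 s
        cm = condition_means(rates_from_values(vals), trials, design, window=(0.0, 1.0))
        assert np.allclose(cm.to_numpy(), 0.0)

    def test_missing_cell_is_named(self):
        design, trials = make_design("main", reps_per_condition=1, seed=3)
        drop = trials[(trials.format == "observation") & (trials.action == "rotate")].index[:1]
        trials.loc[drop, "included"] = False
        rates = _constant_rates(trials, lambda r: 1.0)
        with pytest.raises(ValueError, match="observation"):
            condition_means(rates, trials, design)


class TestModelFamily:
    def test_null_nested_in_every_model(self):
        design, trials = make_design("main", reps_per_condition=1, seed=4)
        for m in applicable_models(design):
            X = build_design_matrix(m, trials, design)
            # the all-ones column is in the span: residual of projecting 1 on X is 0
            ones = np.ones(len(trials))
            beta, *_ = np.linalg.lstsq(X, ones, rcond=None)
            assert np.allclose(X @ beta, ones)

    def test_param_counts(self):
        design, _ = make_design("main", reps_per_condition=1)
        expected = {"null": 1, "invariant": 5, "action3": 3, "hand": 2, "direction": 2,
                    "action6": 6, "mixed": 12, "idiosyncratic": 24,
                    "single_intention": 6, "single_observation": 6}
        for m, k in expected.items():
            assert model_param_count(m, design) == k
            X = build_design_matrix(m, make_design("main", 1)[1], design)
            assert X.shape[1] == k

    def test_noiseless_action_unit_won_by_action3(self):
        design, trials = make_design("main", reps_per_condition=5, seed=5)
        rates = _constant_rates(trials, lambda r: 10.0 + 5.0 * (r.action == "lift"))
        cv = fit_models_cv(rates, trials, design, seed=6, n_repeats=1)
        assert cv.loc["u0000", "action3"] == pytest.approx(1.0, abs=1e-12)
        assert best_model(cv.loc["u0000"], design) == "action3"  # ties go to fewer parameters

    def test_single_intention_beats_shared_models(self):
        design, trials = make_design("main", reps_per_condition=6, seed=7)
        rates = _constant_rates(
            trials, lambda r: 20.0 * ((r.action == "lift") and (r.format == "intention")),
            noise=3.0, seed=8,
        )
        cv = fit_models_cv(rates, trials, design, seed=9)
        assert best_model(cv.loc["u0000"], design) == "single_intention"

    def test_pure_noise_unit_ends_unselective(self):
        design, trials = make_design("main", reps_per_condition=5, seed=10)
        rates = _constant_rates(trials, lambda r: 0.0, noise=5.0, seed=11, n_units=10)
        cls = classify_population(rates, trials, design, n_perm=200, seed=12)
        assert (cls.table.label == "unselective").mean() >= 0.9


class TestCvR2Oracle:
    def test_pooled_r2_matches_brute_force_leave_one_condition_out(self):
        """24 cells, one trial each, leave-one-out folds: our vectorized pooled
        R^2 must equal a directly coded computation to 1e-10."""
        design, trials = make_design("main", reps_per_condition=1, seed=13)
        rng = np.random.default_rng(14)
        y = rng.normal(10, 3, len(trials))
        X = build_design_matrix("invariant", trials, design)
        splits = [(np.delete(np.arange(24), i), np.array([i])) for i in range(24)]
        ours = _pooled_cv_r2(X, y[:, None], splits)[0]
        ss_res = ss_tot = 0.0
        for i in range(24):
            tr = [j for j in range(24) if j != i]
            beta, *_ = np.linalg.lstsq(X[tr], y[tr], rcond=None)
            pred = X[i] @ beta
            ss_res += (y[i] - pred) ** 2
            ss_tot += (y[i] - np.mean(y[tr])) ** 2
        brute = 1 - ss_res / ss_tot
        assert abs(ours - brute) < 1e-10


class TestPermutationGate:
    def test_strong_effect_attains_minimum_p(self):
        design, trials = make_design("main", reps_per_condition=5, seed=15)
        rates = _constant_rates(trials, lambda r: 10.0 * (r.hand == "left"), noise=0.5, seed=16)
        sub = trials
        y = window_means(rates)[0]
        X = build_design_matrix("hand", sub, design)
        splits = make_folds(sub, design, 5, seed=17)
        r2 = _pooled_cv_r2(X, y[:, None], splits)[0]
        p = permutation_gate(y, X, splits, r2, n_perm=200, seed=18)
        assert p == pytest.approx(1 / 201)

    def test_zero_permutations_rejected(self):
        with pytest.raises(ValueError):
            permutation_gate(np.zeros(4), np.ones((4, 1)), [], 0.0, n_perm=0)

    def test_null_p_is_roughly_uniform(self):
        design, trials = make_design("main", reps_per_condition=5, seed=19)
        rng = np.random.default_rng(20)
        sub = trials
        X = build_design_matrix("hand", sub, design)
        splits = make_folds(sub, design, 5, seed=21)
        ps = []
        for k in range(60):
            y = rng.normal(size=len(sub))
            r2 = _pooled_cv_r2(X, y[:, None], splits)[0]
            ps.append(permutation_gate(y, X, splits, r2, n_perm=99, seed=22 + k))
        from scipy import stats

        assert stats.kstest(ps, "uniform").pvalue > 0.01


class TestClassifyPopulation:
    def test_gate_one_rejects_tiny_r2(self):
        table = pd.DataFrame(
            {"unit_id": ["u0"], "best_model": ["hand"], "cv_r2": [0.009], "perm_p": [0.001]}
        )
        # replicate the three-gate rule on a hand-built row
        ok = (table.cv_r2 > 0.01) & (table.perm_p < 0.05) & (table.best_model != "null")
        assert not ok.iloc[0]

    def test_planted_mixture_recovered_within_20pct(self):
        design, trials = make_design("main", reps_per_condition=6, seed=23)
        eff = 3 * np.sqrt(10 / 1.0 + 10 / 0.5)
        specs = archetype_population(
            {"shared_action3": 20, "shared_hand": 20, "single_intention": 20},
            seed=24, effect_size=eff, observation_gain=1.0,
        ) + archetype_population({"unselective": 80}, seed=25, effect_size=eff)
        spikes, _ = simulate_spikes(design, trials, specs, seed=26)
        rates = bin_rates(spikes, design)
        cls = classify_population(rates, trials, design, n_perm=300, seed=27)
        counts = cls.label_counts()
        for label, planted in (("action3", 20), ("hand", 20), ("single_intention", 20), ("unselective", 80)):
            assert abs(counts.get(label, 0) - planted) <= 0.2 * planted

    def test_task_relevant_subset_excludes_single_format_and_unselective(self):
        t = pd.DataFrame(
            {
                "unit_id": list("abcdef"),
                "label": ["action3", "unselective", "single_intention",
                          "single_observation", "idiosyncratic", "mixed"],
            }
        )
        cls = UnitClassification(table=t, q=0.05, r2_threshold=0.01)
        assert task_relevant_subset(cls) == ["a", "e", "f"]


class TestNestingAndControls:
    def test_action3_usually_beats_mixed_on_action3_data(self):
        wins = 0
        n_seeds = 8
        for seed in range(n_seeds):
            design, trials = make_design("main", reps_per_condition=5, seed=30 + seed)
            rates = _constant_rates(
                trials, lambda r: 5.0 * (r.action == "rotate"), noise=3.0, seed=40 + seed
            )
            cv = fit_models_cv(rates, trials, design, seed=50 + seed)
            wins += cv.loc["u0000", "action3"] > cv.loc["u0000", "mixed"]
        assert wins >= 0.7 * n_seeds

    def test_action6_vs_action3_control(self):
        design, trials = make_design("main", reps_per_condition=6, seed=60)
        # direction-specific action tuning -> action6; direction-invariant -> action3
        r6 = _constant_rates(
            trials, lambda r: 8.0 * ((r.action == "lift") and (r.direction == "left")),
            noise=2.0, seed=61,
        )
        r3 = _constant_rates(trials, lambda r: 8.0 * (r.action == "lift"), noise=2.0, seed=62)
        cv6 = fit_models_cv(r6, trials, design, seed=63)
        cv3 = fit_models_cv(r3, trials, design, seed=64)
        assert best_model(cv6.loc["u0000"], design) == "action6"
        assert best_model(cv3.loc["u0000"], design) == "action3"
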