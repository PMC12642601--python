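"""LDA decoding: oracles, generalization maps, permutation masks, leakage."""

import numpy as np
import pandas as pd
import pytest
from sklearn.discriminant_analysis import LinearDiscriminantAnalysis

from crossformat import (
    archetype_population,
    bin_rates,
    cross_format_decode,
    cross_time_decode,
    decode_timecourse,
    dissociation_decode,
    make_design,
    sessionwise_decode,
    simulate_spikes,
)
from conftest import rates_from_values


def _simulated(counts, reps=8, seed=0, variant="main", **kw):
    design, trials = make_design(variant, reps_per_condition=reps, seed=seed)
    specs = archetype_population(counts, seed=seed + 1, **kw)
    spikes, _ = simulate_spikes(design, trials, specs, seed=seed + 2)
    return design, trials, bin_rates(spikes, design)


class TestFisherOracle:
    def test_lda_boundary_matches_closed_form_fisher_discriminant(self):
        """On a 2-class, 2-feature Gaussian toy the fitted LDA direction must
        be parallel to pooled_cov^-1 (mu1 - mu0) and place the threshold at
        the pooled midpoint."""
        rng = np.random.default_rng(0)
        n = 400
        cov = np.array([[1.0, 0.4], [0.4, 2.0]])
        L = np.linalg.cholesky(cov)
        X0 = rng.normal(size=(n, 2)) @ L.T
        X1 = rng.normal(size=(n, 2)) @ L.T + np.array([1.5, -1.0])
        X = np.vstack([X0, X1])
        y = np.r_[np.zeros(n), np.ones(n)]
        lda = LinearDiscriminantAnalysis().fit(X, y)
        mu0, mu1 = X0.mean(0), X1.mean(0)
        Sw = (np.cov(X0.T, bias=False) * (n - 1) + np.cov(X1.T, bias=False) * (n - 1)) / (2 * n - 2)
        w = np.linalg.solve(Sw, mu1 - mu0)
        cos = np.dot(lda.coef_[0], w) / (np.linalg.norm(lda.coef_[0]) * np.linalg.norm(w))
        assert cos == pytest.approx(1.0, abs=1e-10)
        # identical predictions as the explicit Fisher rule with equal priors
        proj = (X - (mu0 + mu1) / 2) @ w
        np.testing.assert_array_equal(proj > 0, lda.predict(X) == 1)


class TestDecodeTimecourse:
    def test_separable_classes_reach_high_accuracy(self):
        design, trials, rates = _simulated({"shared_action3": 12}, seed=1, effect_size=30.0,
                                           observation_gain=1.0)
        r = decode_timecourse(rates, trials, design, "action", format="intention", seed=2)
        resp = (r.window_centers_s > 0.8) & (r.window_centers_s < 1.9)
        assert r.accuracies[resp].min() > 0.95
        assert np.allclose(r.confusion.sum(axis=1), 1.0)

    def test_shuffled_labels_decode_at_chance(self):
        design, trials, rates = _simulated({"shared_action3": 10}, reps=6, seed=3, effect_size=30.0)
        rng = np.random.default_rng(4)
        accs = []
        for k in range(8):
            sh = trials.copy()
            sh["action"] = rng.permutation(sh["action"].to_numpy())
            r = decode_timecourse(rates, sh, design, "action", format="intention", seed=5 + k)
            accs.append(r.accuracies[6])  # one fixed mid-trial window
        mean = np.mean(accs)
        n_eff = 8 * 72
        assert abs(mean - 1 / 3) < 3 * np.sqrt((1 / 3) * (2 / 3) / n_eff)

    def test_two_identical_classes_sit_at_one_half(self):
        rng = np.random.default_rng(6)
        design, trials = make_design("main", reps_per_condition=6, seed=7)
        rates = rates_from_values(rng.normal(size=(10, len(trials), 30)))
        r = decode_timecourse(rates, trials, design, "hand", format="intention", seed=8)
        assert abs(r.accuracies.mean() - 0.5) < 0.1

    def test_single_class_errors(self):
        design, trials, rates = _simulated({"unselective": 3}, reps=6, seed=9)
        only_left = trials.copy()
        only_left["hand"] = "left"
        with pytest.raises(ValueError, match="two classes"):
            decode_timecourse(rates, only_left, design, "hand", format="intention", seed=10)


class TestCrossTime:
    def test_diagonal_equals_timecourse_exactly(self):
        design, trials, rates = _simulated({"shared_hand": 8}, reps=6, seed=11, effect_size=25.0)
        tc = decode_timecourse(rates, trials, design, "hand", format="intention", seed=12)
        gm = cross_time_decode(rates, trials, design, "hand", format="intention", seed=12)
        np.testing.assert_allclose(np.diag(gm.matrix), tc.accuracies, atol=1e-12)

    def test_time_stable_code_generalizes_broadly(self):
        design, trials = make_design("main", reps_per_condition=6, seed=13)
        rng = np.random.default_rng(14)
        left = (trials["hand"] == "left").to_numpy()
        vals = 5.0 * left[None, :, None] * np.ones((8, 1, 30)) * rng.uniform(0.5, 1.5, (8, 1, 1))
        vals += rng.normal(0, 1.0, vals.shape)
        gm = cross_time_decode(rates_from_values(vals), trials, design, "hand",
                               format="intention", seed=15)
        diag = np.diag(gm.matrix)
        assert gm.matrix.min() > diag.mean() - 0.05

    def test_sign_flipping_code_dips_below_chance_off_diagonal(self):
        design, trials = make_design("main", reps_per_condition=6, seed=16)
        rng = np.random.default_rng(17)
        left = (trials["hand"] == "left").to_numpy().astype(float) * 2 - 1
        vals = np.zeros((8, len(trials), 30))
        vals[:, :, :16] = 5.0 * left[None, :, None]
        vals[:, :, 16:] = -5.0 * left[None, :, None]
        vals += rng.normal(0, 1.0, vals.shape)
        gm = cross_time_decode(rates_from_values(vals), trials, design, "hand",
                               format="intention", seed=18)
        assert np.diag(gm.matrix).min() > 0.9          # within-time perfect
        assert gm.matrix[0, -1] < 0.2                  # anti-generalization across the flip


class TestCrossFormat:
    def test_shared_population_generalizes_in_both_directions(self):
        design, trials, rates = _simulated({"shared_action3": 16}, seed=19, effect_size=30.0,
                                           observation_gain=1.0)
        for direction in ("intention", "observation"):
            gm = cross_format_decode(rates, trials, design, "action", train_format=direction,
                                     n_perm=4999, window_bins=2, seed=20)
            assert gm.n_significant > 0
            # the matched response-time cell must be among the significant ones
            resp = (gm.train_centers_s > 0.8) & (gm.train_centers_s < 1.9)
            assert gm.mask[np.ix_(resp, resp)].all()
        assert gm.matrix.max() > 0.9

    def test_single_format_population_never_generalizes(self):
        design, trials, rates = _simulated({"single_intention": 16}, seed=21, effect_size=30.0)
        gm = cross_format_decode(rates, trials, design, "action", train_format="intention",
                                 n_perm=4999, window_bins=2, seed=22)
        assert gm.n_significant == 0

    def test_permutation_seed_does_not_alter_observed_map(self):
        # no leakage: shuffling test labels only moves the null, never the
        # trained models or the observed accuracies
        design, trials, rates = _simulated({"shared_hand": 8}, reps=6, seed=23, effect_size=25.0)
        a = cross_format_decode(rates, trials, design, "hand", n_perm=20, window_bins=2, seed=24)
        b = cross_format_decode(rates, trials, design, "hand", n_perm=20, window_bins=2, seed=999)
        np.testing.assert_array_equal(a.matrix, b.matrix)


class TestDissociationDecode:
    def test_requires_dissociation_variant(self):
        design, trials, rates = _simulated({"unselective": 3}, reps=6, seed=25)
        with pytest.raises(ValueError, match="dissociation"):
            dissociation_decode(rates, trials, design, source="video")

    def test_gated_population_video_decoding_follows_relevance(self):
        for relevance, expect_high in ((True, True), (False, False)):
            design, trials, rates = _simulated({"gated_observer": 14}, reps=10, seed=26,
                                               variant="dissociation_probe", effect_size=30.0)
            trials = trials.assign(relevance=relevance)
            specs = archetype_population({"gated_observer": 14}, seed=27, effect_size=30.0)
            d2, t2 = design, trials
            from crossformat import simulate_spikes as sim
            spikes, _ = sim(d2, t2, specs, seed=28)
            r = dissociation_decode(bin_rates(spikes, d2), t2, d2, source="video",
                                    folds=5, seed=29)
            if expect_high:
                assert r.peak_accuracy > 0.6
            else:
                assert r.peak_accuracy < 0.45

    def test_conflict_chance_without_conflict_coding(self):
        design, trials, rates = _simulated({"shared_hand": 10}, reps=10, seed=30,
                                           variant="dissociation_probe", effect_size=25.0)
        r = dissociation_decode(rates, trials, design, source="conflict", folds=5, seed=31)
        assert r.accuracies.mean() < 0.25 + 0.1


class TestSessionwise:
    def test_per_session_peaks_reported(self):
        design, trials = make_design("main", reps_per_condition=5, n_sessions=2, seed=32)
        specs = archetype_population({"shared_action3": 8}, seed=33, effect_size=30.0)
        spikes, _ = simulate_spikes(design, trials, specs, seed=34)
        rates = bin_rates(spikes, design)
        out = sessionwise_decode(rates, trials, design, label_defs=("action",), folds=5, seed=35)
        assert set(out["session_id"]) == {"S0", "S1"}
        assert (out["peak_accuracy"] > 0.9).all()
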