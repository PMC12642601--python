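"""PCA trajectories, Procrustes alignment, and UMAP embeddings."""

import numpy as np
import pandas as pd
import pytest

from crossformat import (
    all_units_geometry_control,
    archetype_population,
    bin_rates,
    embed_trials,
    make_design,
    pca_trajectories,
    procrustes_distance,
    procrustes_report,
    simulate_spikes,
)
from conftest import rates_from_values


def _traj_rates(trials, fn, n_units=8, noise=0.0, seed=0, n_bins=30, t0=-0.5):
    """fn(row, unit, bin_times) -> timecourse contribution per trial."""
    rng = np.random.default_rng(seed)
    times = t0 + 0.1 * (np.arange(n_bins) + 0.5)
    vals = np.zeros((n_units, len(trials), n_bins))
    for i, row in enumerate(trials.itertuples()):
        for u in range(n_units):
            vals[u, i] = fn(row, u, times)
    vals += rng.normal(0, noise, vals.shape)
    return rates_from_values(vals, t0=t0)


def _simulated(counts, reps=6, seed=0, **kw):
    design, trials = make_design("main", reps_per_condition=reps, seed=seed)
    specs = archetype_population(counts, seed=seed + 1, **kw)
    spikes, _ = simulate_spikes(design, trials, specs, seed=seed + 2)
    return design, trials, bin_rates(spikes, design, window=(-0.5, 3.0))


class TestPcaTrajectories:
    def test_rank_two_population_fully_captured_by_three_components(self):
        design, trials = make_design("main", reps_per_condition=4, seed=1)
        rng = np.random.default_rng(2)
        loads = rng.normal(size=(2, 8))
        rates = _traj_rates(
            trials,
            lambda r, u, t: (np.sin(2 * t) * (r.action == "lift") * loads[0, u]
                             + np.cos(t) * (r.hand == "left") * loads[1, u]),
        )
        traj = pca_trajectories(rates, trials, design, grouping="action")
        assert traj.variance_explained["combined"].sum() == pytest.approx(1.0, abs=1e-9)

    def test_identical_formats_give_coincident_projections(self):
        design, trials = make_design("main", reps_per_condition=4, seed=3)
        rates = _traj_rates(trials, lambda r, u, t: np.sin(t + u) * (r.action == "lift"))
        traj = pca_trajectories(rates, trials, design, grouping="action")
        for lev in ("lift", "slide", "rotate"):
            np.testing.assert_allclose(
                traj.trajectories[(lev, "intention")], traj.trajectories[(lev, "observation")],
                atol=1e-9,
            )

    def test_format_specific_subspace_reduces_captured_variance(self):
        design, trials = make_design("main", reps_per_condition=4, seed=4)
        # each (format, action) drives its own random high-rank pattern on a
        # format-private unit block: no 3-dim space can serve both formats
        rng = np.random.default_rng(20)
        times = -0.5 + 0.1 * (np.arange(30) + 0.5)
        curves = {}
        for fmt in ("intention", "observation"):
            for act in ("lift", "slide", "rotate"):
                curves[(fmt, act)] = rng.normal(size=(8, 1)) * np.sin(
                    rng.uniform(1, 6) * times + rng.uniform(0, 6)
                )
        vals = np.zeros((16, len(trials), 30))
        for i, row in enumerate(trials.itertuples()):
            block = slice(0, 8) if row.format == "intention" else slice(8, 16)
            vals[block, i, :] = curves[(row.format, row.action)]
        traj = pca_trajectories(rates_from_values(vals, t0=-0.5), trials, design, grouping="action")
        ve = traj.variance_explained
        assert min(ve["intention"][0], ve["observation"][0]) < 0.75

    def test_too_few_units_rejected(self):
        design, trials = make_design("main", reps_per_condition=2, seed=5)
        rates = _traj_rates(trials, lambda r, u, t: t, n_units=2)
        with pytest.raises(ValueError, match="units"):
            pca_trajectories(rates, trials, design)

    def test_rates_must_cover_the_window(self):
        design, trials = make_design("main", reps_per_condition=2, seed=6)
        rates = _traj_rates(trials, lambda r, u, t: t, t0=0.0)  # starts at 0, not -0.5
        with pytest.raises(ValueError, match="cover"):
            pca_trajectories(rates, trials, design)


class TestProcrustes:
    def test_exact_similarity_transform_has_zero_distance(self):
        rng = np.random.default_rng(7)
        a = rng.normal(size=(30, 3))
        Q, _ = np.linalg.qr(rng.normal(size=(3, 3)))
        b = 2.5 * a @ Q + np.array([1.0, -2.0, 0.5])
        d, tf = procrustes_distance(a, b)
        assert d < 1e-10
        assert procrustes_distance(a, a)[0] == 0.0

    def test_distance_symmetric(self):
        rng = np.random.default_rng(8)
        a, b = rng.normal(size=(20, 3)), rng.normal(size=(20, 3))
        assert procrustes_distance(a, b)[0] == pytest.approx(procrustes_distance(b, a)[0], abs=1e-12)

    def test_matches_scipy_oracle_and_separates_independent_walks(self):
        """d equals scipy's standardized Procrustes disparity, and for
        independent random walks it stays well above the near-zero values of
        transform-related pairs (Monte-Carlo oracle)."""
        from scipy.spatial import procrustes as scipy_procrustes

        rng = np.random.default_rng(9)
        ds = []
        for _ in range(300):
            a = np.cumsum(rng.normal(size=(30, 3)), axis=0)
            b = np.cumsum(rng.normal(size=(30, 3)), axis=0)
            d, _ = procrustes_distance(a, b)
            _, _, disparity = scipy_procrustes(a, b)
            assert d == pytest.approx(disparity, abs=1e-12)
            ds.append(d)
        assert np.percentile(ds, 5) > 0.15
        assert np.median(ds) > 0.4

    def test_constant_trajectory_rejected(self):
        with pytest.raises(ValueError, match="constant"):
            procrustes_distance(np.ones((10, 3)), np.random.default_rng(0).normal(size=(10, 3)))

    def test_reflection_toggle(self):
        rng = np.random.default_rng(10)
        a = rng.normal(size=(25, 3))
        b = a @ np.diag([1.0, 1.0, -1.0])  # pure reflection
        assert procrustes_distance(a, b, allow_reflection=True)[0] < 1e-12
        assert procrustes_distance(a, b, allow_reflection=False)[0] > 0.01

    def test_shared_population_aligns_better_than_idiosyncratic(self):
        design, trials, shared = _simulated({"shared_action3": 12}, seed=11,
                                            effect_size=25.0, observation_gain=1.0)
        _, _, idio = _simulated({"idiosyncratic": 12}, seed=12, effect_size=25.0)
        d_shared = procrustes_report(
            pca_trajectories(shared, trials, design, grouping="action")).table["d"].mean()
        d_idio = procrustes_report(
            pca_trajectories(idio, trials, design, grouping="action")).table["d"].mean()
        assert d_shared < d_idio

    def test_all_units_control_runs_the_same_pipeline(self):
        design, trials, rates = _simulated({"shared_hand": 8}, seed=13, effect_size=25.0)
        rep = all_units_geometry_control(rates, trials, design, grouping="hand")
        assert set(rep.table["level"]) == {"left", "right"}
        assert ((rep.table["d"] >= 0) & (rep.table["d"] <= 1)).all()


class TestEmbedding:
    def test_embedding_reproducible_and_separates_planted_clusters(self):
        design, trials, rates = _simulated({"shared_action3": 12}, reps=6, seed=14,
                                           effect_size=40.0, observation_gain=1.0)
        a = embed_trials(rates, trials, design, grouping="action", seed=15)
        b = embed_trials(rates, trials, design, grouping="action", seed=15)
        np.testing.assert_allclose(a.coords, b.coords)
        # planted action clusters should be far apart relative to their spread
        cents = a.ellipses.groupby("level")[["cx", "cy"]].mean().to_numpy()
        spread = np.hypot(a.ellipses["ax1_x"], a.ellipses["ax1_y"]).max()
        dists = [np.linalg.norm(cents[i] - cents[j]) for i in range(3) for j in range(i + 1, 3)]
        assert min(dists) > spread

    def test_too_few_trials_rejected(self):
        design, trials = make_design("main", reps_per_condition=2, seed=16)
        rates = _traj_rates(trials.iloc[:10], lambda r, u, t: t, n_units=4)
        with pytest.raises(ValueError, match="trials"):
            embed_trials(rates, trials.iloc[:10].reset_index(drop=True), design, seed=17)
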