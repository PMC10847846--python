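"""Regime classification, ensemble bookkeeping, smoothing and delay embedding."""

import numpy as np
import pytest

from microdaisy import (
    classify_trajectory,
    delay_embed,
    ensemble_experiment,
    sample_community,
    smooth_frequencies,
)
from microdaisy.dynamics import LABELS, default_survival_floor
from microdaisy.trajectory import Trajectory


def synthetic_trajectory(series: np.ndarray) -> Trajectory:
    series = np.atleast_2d(series).T if series.ndim == 1 else series
    T = series.shape[0]
    return Trajectory(t=np.arange(T, dtype=float), abundances=series, pH_f=np.full(T, 7.0))


@pytest.fixture(scope="module")
def spec():
    return sample_community(3, seed=0)  # floor = 2*eps/delta = 0.02


class TestClassify:
    def test_constant_series_is_fixed_point(self, spec):
        traj = synthetic_trajectory(np.full((100, 3), 0.3))
        c = classify_trajectory(traj, spec)
        assert c.label == "fixed_point"
        assert c.survivors == 3
        assert c.survivor_fraction == 1.0

    def test_sinusoid_is_oscillatory(self, spec):
        t = np.arange(200, dtype=float)
        x = np.full((200, 3), 0.3)
        x[:, 0] = 0.3 + 0.1 * np.sin(2 * np.pi * t / 20)  # relative amplitude ~1/3
        c = classify_trajectory(synthetic_trajectory(x), spec)
        assert c.label == "oscillatory_chaotic"

    def test_immigration_floor_is_collapse(self, spec):
        level = spec.epsilon / spec.delta  # below the survival floor by construction
        c = classify_trajectory(synthetic_trajectory(np.full((100, 3), level)), spec)
        assert c.label == "collapse"
        assert c.survivors == 0
        assert c.survivor_fraction == 0.0

    def test_collapse_never_coexists_with_survivors(self, spec):
        rng = np.random.default_rng(0)
        for _ in range(20):
            x = rng.uniform(0, 0.2, size=(50, 3))
            c = classify_trajectory(synthetic_trajectory(x), spec)
            assert (c.label == "collapse") == (c.survivors == 0)

    def test_relabelling_invariance(self, spec):
        rng = np.random.default_rng(1)
        x = rng.uniform(0, 0.5, size=(80, 3))
        a = classify_trajectory(synthetic_trajectory(x), spec)
        b = classify_trajectory(synthetic_trajectory(x[:, ::-1]), spec)
        assert a.label == b.label
        assert a.survivors == b.survivors

    def test_time_rescaling_invariance(self, spec):
        rng = np.random.default_rng(2)
        x = rng.uniform(0, 0.5, size=(80, 3))
        traj = synthetic_trajectory(x)
        scaled = Trajectory(t=traj.t * 37.0, abundances=traj.abundances, pH_f=traj.pH_f)
        assert classify_trajectory(traj, spec).label == classify_trajectory(scaled, spec).label

    def test_window_too_short_raises(self, spec):
        traj = synthetic_trajectory(np.full((3, 3), 0.3))
        with pytest.raises(ValueError):
            classify_trajectory(traj, spec, window_fraction=0.01)

    def test_default_floor_above_immigration_level(self, spec):
        assert default_survival_floor(spec) == pytest.approx(2 * spec.epsilon / spec.delta)


@pytest.fixture(scope="module")
def small():
    return ensemble_experiment(sizes=(2, 4), replicas=6, master_seed=3, t_end=400.0)


class TestEnsemble:
    def test_frequencies_sum_to_one(self, small):
        sums = small.frequencies[list(LABELS)].sum(axis=1)
        np.testing.assert_allclose(sums, 1.0)

    def test_reproducible_from_master_seed(self, small):
        again = ensemble_experiment(sizes=(2, 4), replicas=6, master_seed=3, t_end=400.0)
        assert small.records.equals(again.records)
        assert small.frequencies.equals(again.frequencies)

    def test_different_seed_differs(self, small):
        other = ensemble_experiment(sizes=(2, 4), replicas=6, master_seed=4, t_end=400.0)
        assert not small.records["seed"].equals(other.records["seed"])

    def test_records_complete(self, small):
        assert len(small.records) == 2 * 6
        assert set(small.records.columns) == {
            "n", "replica", "seed", "label", "survivors", "survivor_fraction",
        }
        assert small.records["survivor_fraction"].between(0, 1).all()

    def test_summary_serializes(self, small):
        d = small.to_dict()
        assert d["sizes"] == [2, 4]
        assert set(d["frequencies"]) == {"2", "4"}


class TestSmoothing:
    def test_constant_curve_fits_constant(self):
        fitted, coef = smooth_frequencies(np.full(10, 0.4), degree=4)
        np.testing.assert_allclose(fitted, 0.4, atol=1e-9)
        np.testing.assert_allclose(coef[1:], 0.0, atol=1e-9)

    def test_residuals_invariant_to_point_order(self):
        rng = np.random.default_rng(0)
        x = np.arange(12.0)
        y = rng.uniform(0, 1, 12)
        perm = rng.permutation(12)
        f1, _ = smooth_frequencies(y, degree=3, x=x)
        f2, _ = smooth_frequencies(y[perm], degree=3, x=x[perm])
        assert np.sum((f1 - y) ** 2) == pytest.approx(np.sum((f2 - y[perm]) ** 2))

    def test_underdetermined_fit_raises(self):
        with pytest.raises(ValueError):
            smooth_frequencies(np.ones(3), degree=4)


class TestDelayEmbed:
    def test_length_arithmetic(self):
        pts = delay_embed(np.arange(100.0), T=10)
        assert pts.shape == (80, 3)

    def test_constant_series_sits_on_diagonal(self):
        pts = delay_embed(np.full(50, 1.5), T=5)
        np.testing.assert_array_equal(pts[:, 0], pts[:, 1])
        np.testing.assert_array_equal(pts[:, 1], pts[:, 2])

    def test_quarter_period_sinusoid_closes_into_a_cycle(self):
        # x(t), x(t+P/4), x(t+P/2) = (sin, cos, -sin): points satisfy
        # x^2 + y^2 = 1 and z = -x exactly — a closed planar ellipse
        P = 40
        t = np.arange(400)
        x = np.sin(2 * np.pi * t / P)
        pts = delay_embed(x, T=P // 4)
        np.testing.assert_allclose(pts[:, 0] ** 2 + pts[:, 1] ** 2, 1.0, atol=1e-9)
        np.testing.assert_allclose(pts[:, 2], -pts[:, 0], atol=1e-9)

    def test_too_short_series_raises(self):
        with pytest.raises(ValueError):
            delay_embed(np.arange(20.0), T=10)
        with pytest.raises(ValueError):
            delay_embed(np.arange(20.0), T=0)
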