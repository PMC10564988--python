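"""RBF lattices, deterministic-learning identification, pattern storage."""

import numpy as np
import pytest

from fohrlearn.errors import WeightDivergenceError
from fohrlearn.learning import (
    DynamicPattern,
    LatticeSpec,
    LearningConfig,
    PatternBase,
    PatternDimension,
    RBFNetwork,
    build_lattice,
    eval_learned_dynamics,
    extract_constant_weights,
    identify_dynamics,
    rbf_eval,
)
from fohrlearn.trajectory import Trajectory


class TestRBFEvaluation:
    def test_unit_response_at_own_center_zero_weights(self):
        net = build_lattice(LatticeSpec(((0.0, 1.0, 0.5),)), 0.3)
        phi, out = rbf_eval(net, [0.5])
        assert phi[1] == pytest.approx(1.0)
        assert out == 0.0

    def test_localization_far_from_lattice(self):
        net = build_lattice(LatticeSpec(((0.0, 1.0, 0.5),)), 0.3)
        net.weights[:] = 1.0
        _, out = rbf_eval(net, [50.0])
        assert abs(out) < 1e-12

    def test_single_center_closed_form(self):
        net = RBFNetwork(np.array([[0.0]]), np.array([1.0]), np.array([2.5]))
        _, out = rbf_eval(net, [0.7])
        assert out == pytest.approx(2.5 * np.exp(-0.49))

    def test_dimension_mismatch_rejected(self):
        net = build_lattice(LatticeSpec(((0.0, 1.0, 0.5), (0.0, 1.0, 0.5))), 0.3)
        with pytest.raises(ValueError):
            rbf_eval(net, [0.5])

    def test_separable_lattice_matches_dense_evaluation(self):
        spec = LatticeSpec(((-1.0, 1.0, 0.4), (0.0, 2.0, 0.5)))
        net = build_lattice(spec, (0.4, 0.5))
        dense = RBFNetwork(net.centers, net.widths, net.weights)  # no axes
        pts = np.random.default_rng(1).uniform([-1, 0], [1, 2], (40, 2))
        assert np.allclose(net.regressors(pts), dense.regressors(pts), atol=1e-14)


class TestLattice:
    def test_one_dimensional_grid(self):
        net = build_lattice(LatticeSpec(((0.0, 1.0, 0.5),)), 0.3)
        assert net.centers[:, 0] == pytest.approx([0.0, 0.5, 1.0])

    def test_two_by_two_grid(self):
        net = build_lattice(LatticeSpec(((0.0, 1.0, 1.0), (0.0, 1.0, 1.0))), 0.5)
        assert net.n_centers == 4

    def test_canonical_adaptation_grid_has_225_nodes(self):
        net = build_lattice(LatticeSpec(((-2.1, 2.1, 0.3), (0.9, 5.1, 0.3))), 0.3)
        assert net.n_centers == 15 * 15

    def test_spacing_larger_than_range_rejected(self):
        with pytest.raises(ValueError):
            LatticeSpec(((0.0, 1.0, 2.0),))

    def test_from_box_padding(self):
        spec = LatticeSpec.from_box([0.0], [1.0], n_points=11, pad=0.1)
        (lo, hi, sp) = spec.dims[0]
        assert lo == pytest.approx(-0.1)
        assert hi == pytest.approx(1.1)
        assert len(spec.axes()[0]) == 11


class TestConstantWeights:
    def test_constant_history(self):
        t = np.linspace(0, 10, 11)
        w = np.tile([1.5, -2.0], (11, 1))
        assert extract_constant_weights(t, w, 2.0, 8.0) == pytest.approx([1.5, -2.0])

    def test_linear_ramp_averages_to_midpoint(self):
        t = np.linspace(0.0, 1.0, 101)
        w = t[:, None]
        assert extract_constant_weights(t, w, 0.0, 1.0)[0] == pytest.approx(0.5)

    def test_sinusoid_over_full_periods_averages_to_offset(self):
        t = np.linspace(0.0, 4 * np.pi, 4001)
        w = (0.7 + 0.3 * np.sin(t))[:, None]
        got = extract_constant_weights(t, w, 0.0, 4 * np.pi)[0]
        assert got == pytest.approx(0.7, abs=1e-3)

    def test_bad_window_rejected(self):
        t = np.linspace(0, 1, 11)
        w = np.zeros((11, 1))
        with pytest.raises(ValueError):
            extract_constant_weights(t, w, 0.8, 0.2)
        with pytest.raises(ValueError):
            extract_constant_weights(t, w, 5.0, 6.0)


def _sine_orbit(duration=40 * np.pi, h=0.01):
    t = np.arange(0.0, duration, h)
    return Trajectory(t, np.sin(t), ("x",))


RECOVERY_LATTICE = LatticeSpec(((-1.2, 1.2, 0.1),))
RECOVERY_CONFIG = LearningConfig(estimator_gain=10.0, adapt_gain=10.0, leakage=1e-4)


class TestIdentification:
    def test_recovers_known_linear_dynamics_along_orbit(self):
        """Forced plant dx/dt = 2x + v with x(t) = sin t: the converged
        constant weights reproduce f(x) = 2x along the visited interval."""
        traj = _sine_orbit()
        net = build_lattice(RECOVERY_LATTICE, 0.15)
        res = identify_dynamics(
            traj,
            0,
            net,
            RECOVERY_CONFIG,
            q=1.0,
            input_dims=(0,),
            known_term=lambda t, s: np.cos(t) - 2.0 * np.sin(t),
        )
        learned = build_lattice(RECOVERY_LATTICE, 0.15)
        learned.weights = res.constant_weights
        xs = np.linspace(-1.0, 1.0, 201)[:, None]
        err = np.abs(learned.output(xs) - 2.0 * xs[:, 0])
        assert err.max() < 0.1  # 5% of max |f| = 2
        assert learned.output(np.array([0.5])) == pytest.approx(1.0, abs=0.05)
        assert res.settling_ratio() < 0.05

    def test_zero_dynamics_keeps_weights_near_zero(self):
        t = np.arange(0.0, 50.0, 0.01)
        traj = Trajectory(t, np.full(t.size, 0.3), ("x",))
        net = build_lattice(LatticeSpec(((-1.0, 1.0, 0.25),)), 0.3)
        res = identify_dynamics(
            traj, 0, net, RECOVERY_CONFIG, q=1.0, input_dims=(0,)
        )
        assert np.abs(res.constant_weights).max() < 1e-3

    def test_monotone_improvement_with_longer_adaptation(self):
        errs = []
        for periods in (6, 24):
            traj = _sine_orbit(duration=2 * np.pi * periods)
            net = build_lattice(RECOVERY_LATTICE, 0.15)
            res = identify_dynamics(
                traj,
                0,
                net,
                RECOVERY_CONFIG,
                q=1.0,
                input_dims=(0,),
                known_term=lambda t, s: np.cos(t) - 2.0 * np.sin(t),
            )
            learned = build_lattice(RECOVERY_LATTICE, 0.15)
            learned.weights = res.constant_weights
            xs = np.linspace(-1.0, 1.0, 201)[:, None]
            errs.append(np.abs(learned.output(xs) - 2.0 * xs[:, 0]).mean())
        assert errs[1] <= errs[0] + 0.01

    def test_identification_is_deterministic(self):
        traj = _sine_orbit(duration=6 * np.pi)
        runs = []
        for _ in range(2):
            net = build_lattice(RECOVERY_LATTICE, 0.15)
            res = identify_dynamics(
                traj, 0, net, RECOVERY_CONFIG, q=1.0, input_dims=(0,)
            )
            runs.append(res.constant_weights)
        assert np.array_equal(runs[0], runs[1])

    def test_weight_divergence_raises(self):
        traj = _sine_orbit(duration=6 * np.pi)
        net = build_lattice(RECOVERY_LATTICE, 0.15)
        config = LearningConfig(
            estimator_gain=10.0, adapt_gain=1e6, weight_bound=10.0
        )
        with pytest.raises(WeightDivergenceError):
            identify_dynamics(traj, 0, net, config, q=1.0, input_dims=(0,))


def _toy_pattern() -> DynamicPattern:
    spec = LatticeSpec(((-1.0, 1.0, 0.5), (0.0, 2.0, 0.5)))
    weights = np.linspace(-1.0, 1.0, 5 * 5)
    return DynamicPattern(
        "toy",
        {2: PatternDimension((0, 2), spec, np.array([0.5, 0.5]), weights)},
        {"I": 2.0, "q": 0.98},
    )


class TestPatternStorage:
    def test_round_trip_preserves_evaluation(self, tmp_path):
        base = PatternBase([_toy_pattern()])
        path = tmp_path / "base.json"
        base.to_json(path)
        loaded = PatternBase.from_json(path)
        pts = np.random.default_rng(0).uniform([-1, -1, 0], [1, 1, 2], (20, 3))
        a = base.get("toy").evaluate(2, pts)
        b = loaded.get("toy").evaluate(2, pts)
        assert np.allclose(a, b, atol=1e-15)
        assert loaded.get("toy").metadata["I"] == 2.0

    def test_duplicate_ids_rejected(self):
        with pytest.raises(ValueError):
            PatternBase([_toy_pattern(), _toy_pattern()])

    def test_missing_dimension_rejected(self):
        with pytest.raises(KeyError):
            eval_learned_dynamics(_toy_pattern(), 1, [0.0, 0.0, 1.0])

    def test_far_field_bounded_by_weight_mass(self):
        pat = _toy_pattern()
        far = eval_learned_dynamics(pat, 2, [30.0, 0.0, 30.0])
        assert abs(far) < 1e-6
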