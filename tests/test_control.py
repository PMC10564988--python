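"""Sliding surface, control laws, and closed-loop structural properties."""

import math

import numpy as np
import pytest

from fohrlearn.control import (
    ControllerConfig,
    compute_sliding_surface,
    model_based_control_law,
    relearning_step,
    synchronize,
)
from fohrlearn.fractional import TimeGrid
from fohrlearn.hindmarsh_rose import HRParameters, MasterSlaveSystem
from fohrlearn.learning import (
    DynamicPattern,
    LatticeSpec,
    PatternBase,
    PatternDimension,
)


class TestSlidingSurface:
    def test_zero_error_zero_surface(self):
        s = compute_sliding_surface(np.zeros((100, 3)), 1.0, 0.98, 0.01)
        assert np.abs(s).max() == 0.0

    def test_integer_order_collapses_to_proportional(self):
        e = np.random.default_rng(0).normal(size=(50, 3))
        s = compute_sliding_surface(e, 1.5, 1.0, 0.01)
        assert np.allclose(s, 2.5 * e)

    def test_ramp_error_half_order_power_rule(self):
        """e(t) = t, q = 0.5, c = 1: s = Gamma(2)/Gamma(1.5) sqrt(t) + t."""
        h = 1e-3
        t = np.arange(0.0, 1.0 + h / 2, h)
        s = compute_sliding_surface(t, 1.0, 0.5, h)
        exact = math.gamma(2.0) / math.gamma(1.5) * math.sqrt(1.0) + 1.0
        assert s[-1] == pytest.approx(exact, abs=5e-3)


class TestControlLaws:
    def test_hand_evaluated_control(self):
        u = model_based_control_law(
            e=0.3, s=0.5, f_m=2.0, compensation=1.2, reach_gain=1.0, surface_gain=1.0
        )
        assert u == pytest.approx(-0.5)

    def test_surface_sign_flip_only_flips_reaching_term(self):
        kw = dict(e=0.3, f_m=2.0, compensation=1.2, reach_gain=1.0, surface_gain=1.0)
        up = model_based_control_law(s=0.5, **kw)
        un = model_based_control_law(s=-0.5, **kw)
        assert un - up == pytest.approx(2.0)  # 2 * eta * sgn

    def test_all_terms_cancel_at_equilibrium(self):
        u = model_based_control_law(
            e=0.0, s=0.0, f_m=1.7, compensation=1.7, reach_gain=1.0, surface_gain=1.0
        )
        assert u == 0.0

    def test_boundary_layer_smoothing(self):
        u_sharp = model_based_control_law(
            e=0.0, s=1e-6, f_m=0.0, compensation=0.0, reach_gain=1.0,
            surface_gain=1.0, epsilon=0.0,
        )
        u_smooth = model_based_control_law(
            e=0.0, s=1e-6, f_m=0.0, compensation=0.0, reach_gain=1.0,
            surface_gain=1.0, epsilon=0.1,
        )
        assert u_sharp == pytest.approx(-1.0)
        assert abs(u_smooth) < 1e-4

    def test_relearning_update_vanishes_on_surface(self):
        w = np.array([0.2, -0.1])
        phi = np.array([0.5, 0.5])
        out = relearning_step(0.0, phi, w, adapt_gain=2.0, leakage=0.01, h=0.01)
        assert np.array_equal(out, w)

    def test_relearning_single_euler_step(self):
        w = np.zeros(2)
        phi = np.array([1.0, 0.5])
        out = relearning_step(0.3, phi, w, adapt_gain=2.0, leakage=0.0, h=0.01)
        assert out == pytest.approx(2.0 * phi * 0.3 * 0.01)


def _zero_pattern() -> DynamicPattern:
    spec = LatticeSpec(((-2.0, 2.0, 1.0), (-12.0, 2.0, 2.0), (0.0, 5.0, 1.0)))
    dims = {}
    for d, idx in {0: (0, 1, 2), 1: (0, 1), 2: (0, 2)}.items():
        sub = LatticeSpec(tuple(spec.dims[i] for i in range(len(idx))))
        n = int(np.prod([len(a) for a in sub.axes()]))
        dims[d] = PatternDimension(idx, sub, sub.spacings, np.zeros(n))
    return DynamicPattern("blank", dims, {"q": 0.98})


class TestClosedLoop:
    def test_identical_pair_with_true_compensation_stays_put(self):
        sys_ = MasterSlaveSystem(
            master=HRParameters(I=2.0), slave=HRParameters(I=2.0), q=0.98
        )
        res = synchronize(
            sys_,
            None,
            ControllerConfig(t_on=10.0),
            TimeGrid.from_duration(60.0, 0.01),
            x0_master=(0.3, 1, 3),
            x0_slave=(0.3, 1, 3),
            compensation="true",
        )
        assert np.abs(res.errors).max() < 1e-9

    def test_control_zero_before_onset_and_modes_scheduled(self):
        sys_ = MasterSlaveSystem(
            master=HRParameters(I=1.5), slave=HRParameters(I=2.5), q=0.98
        )
        base = PatternBase([_zero_pattern()])
        res = synchronize(
            sys_,
            base,
            ControllerConfig(t_on=20.0, mode="relearning", t_switch=40.0),
            TimeGrid.from_duration(60.0, 0.01),
            x0_master=(0.3, 1, 3),
            x0_slave=(0.35, 1, 3),
            compensation="pattern:blank",
        )
        pre = res.times < 20.0
        assert np.abs(res.control[pre]).max() == 0.0
        assert set(res.mode_trace[pre]) == {0}
        mid = (res.times >= 20.0) & (res.times < 40.0)
        assert set(res.mode_trace[mid]) == {1}
        post = (res.times >= 40.0) & (res.times < 60.0)
        assert set(res.mode_trace[post]) == {2}
        assert res.weight_snaps is not None

    def test_states_continuous_across_mode_switches(self):
        sys_ = MasterSlaveSystem(
            master=HRParameters(I=1.5), slave=HRParameters(I=2.5), q=0.98
        )
        base = PatternBase([_zero_pattern()])
        res = synchronize(
            sys_,
            base,
            ControllerConfig(t_on=20.0, mode="relearning", t_switch=40.0),
            TimeGrid.from_duration(60.0, 0.01),
            x0_master=(0.3, 1, 3),
            x0_slave=(0.35, 1, 3),
            compensation="pattern:blank",
        )
        jumps = np.abs(np.diff(res.slave.states, axis=0)).max(axis=1)
        assert jumps.max() < 0.2  # bounded by h * max rate; no state jumps

    def test_recognized_compensation_requires_base(self):
        from fohrlearn.errors import FohrlearnError

        sys_ = MasterSlaveSystem(
            master=HRParameters(I=1.5), slave=HRParameters(I=2.5), q=0.98
        )
        with pytest.raises(FohrlearnError):
            synchronize(
                sys_,
                None,
                ControllerConfig(t_on=1.0),
                TimeGrid.from_duration(2.0, 0.01),
                x0_master=(0.3, 1, 3),
                x0_slave=(0.3, 1, 3),
                compensation="recognized",
            )

    def test_schedule_validation(self):
        with pytest.raises(ValueError):
            ControllerConfig(mode="relearning", t_on=100.0, t_switch=50.0)
        with pytest.raises(ValueError):
            ControllerConfig(reach_gain=0.0)

    def test_sync_result_files(self, tmp_path):
        sys_ = MasterSlaveSystem(
            master=HRParameters(I=2.0), slave=HRParameters(I=2.0), q=0.98
        )
        res = synchronize(
            sys_,
            None,
            ControllerConfig(t_on=5.0),
            TimeGrid.from_duration(10.0, 0.01),
            x0_master=(0.3, 1, 3),
            x0_slave=(0.3, 1, 3),
            compensation="true",
        )
        res.write(tmp_path / "run.csv", tmp_path / "run.json")
        header = (tmp_path / "run.csv").read_text().splitlines()[0]
        assert header == "t,e1,e2,e3,s1,s2,s3,u1,u2,u3,mode"
        import json

        sidecar = json.loads((tmp_path / "run.json").read_text())
        assert sidecar["config"]["t_on"] == 5.0
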