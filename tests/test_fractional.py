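"""Grünwald-Letnikov coefficients, differintegral and solver."""

import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy.special import binom

from fohrlearn.errors import DivergenceError
from fohrlearn.fractional import (
    MemoryPolicy,
    TimeGrid,
    gl_coefficients,
    gl_derivative,
    solve_classical,
    solve_fode,
)
from fohrlearn.hindmarsh_rose import HRParameters, hr_vector_field
from fohrlearn.trajectory import Trajectory


def mittag_leffler(z: float, alpha: float, terms: int = 300) -> float:
    """Independent truncated series E_alpha(z) = sum z^k / Gamma(alpha k + 1)."""
    total = 0.0
    for k in range(terms):
        total += z**k / math.gamma(alpha * k + 1.0)
    return total


# -- coefficients ------------------------------------------------------------


@pytest.mark.parametrize(
    "q, n, expected",
    [
        (1.0, 3, [1.0, -1.0, 0.0, 0.0]),
        (0.0, 2, [1.0, 0.0, 0.0]),
        (0.5, 2, [1.0, -0.5, -0.125]),
    ],
)
def test_gl_coefficient_examples(q, n, expected):
    assert gl_coefficients(q, n) == pytest.approx(expected, abs=1e-15)


@given(st.integers(1, 10))
@settings(deadline=None, max_examples=10, derandomize=True)
def test_gl_coefficients_match_direct_binomial(iq):
    """The O(n) recursion equals (-1)^r binom(q, r) for r <= 50."""
    q = iq / 10.0
    c = gl_coefficients(q, 50)
    direct = np.array([(-1.0) ** r * binom(q, r) for r in range(51)])
    assert np.allclose(c, direct, atol=1e-10)


def test_gl_coefficients_negative_n_rejected():
    with pytest.raises(ValueError):
        gl_coefficients(0.5, -1)


# -- derivative operator -----------------------------------------------------


def test_order_zero_is_identity():
    rng = np.random.default_rng(7)
    x = rng.normal(size=200)
    out = gl_derivative(x, 0.0, h=0.05)
    assert np.allclose(out, x, atol=1e-14)


def test_ramp_first_derivative():
    h = 1e-3
    t = np.arange(0.0, 1.0 + h / 2, h)
    out = gl_derivative(t, 1.0, h=h)
    assert np.allclose(out[1:], 1.0, atol=1e-9)


@pytest.mark.parametrize("h", [1e-2, 1e-3])
def test_power_rule_half_order(h):
    """D^{1/2} t^2 = Gamma(3)/Gamma(2.5) t^{1.5}, error shrinking with h."""
    t = np.arange(0.0, 1.0 + h / 2, h)
    out = gl_derivative(t**2, 0.5, h=h)
    exact = math.gamma(3.0) / math.gamma(2.5) * t[-1] ** 1.5
    assert out[-1] == pytest.approx(exact, abs=3.0 * h)


def test_semigroup_composition_is_exact_discretely():
    """D^0.3 (D^0.4 f) equals D^0.7 f on the grid to rounding error.

    The discrete GL kernels are binomial expansions of (1-z)^q, so
    composing orders adds them exactly at any step size.
    """
    h = 0.01
    t = np.arange(0.0, 4.0 + h / 2, h)
    f = np.sin(t)
    once = gl_derivative(gl_derivative(f, 0.4, h=h), 0.3, h=h)
    direct = gl_derivative(f, 0.7, h=h)
    assert np.abs(once - direct).max() < 1e-10


def test_semigroup_composition_converges_to_analytic():
    """The composed differintegral approaches the continuous power rule."""
    exact = lambda t: math.gamma(3.0) / math.gamma(2.3) * t**1.3  # noqa: E731
    errs = []
    for h in (1e-2, 1e-3):
        t = np.arange(0.0, 1.0 + h / 2, h)
        once = gl_derivative(gl_derivative(t**2, 0.4, h=h), 0.3, h=h)
        errs.append(abs(once[-1] - exact(1.0)))
    assert errs[1] < errs[0]
    assert errs[1] < 1e-2


def test_empty_signal_rejected():
    with pytest.raises(ValueError):
        gl_derivative(np.empty(0), 0.5, h=0.1)


def test_trajectory_in_trajectory_out():
    tr = Trajectory(np.arange(0, 1, 0.01), np.arange(0, 1, 0.01) ** 2)
    out = gl_derivative(tr, 0.5)
    assert isinstance(out, Trajectory)
    assert out.times is tr.times


# -- solver ------------------------------------------------------------------


def test_zero_field_constant():
    grid = TimeGrid.from_duration(1.0, 0.01)
    tr = solve_fode(lambda x, t: 0.0 * x, 1.0, [5.0], grid)
    assert np.allclose(tr.states, 5.0)


def test_exponential_decay_first_order():
    grid = TimeGrid.from_duration(1.0, 1e-3)
    tr = solve_fode(lambda x, t: -x, 1.0, [1.0], grid)
    assert tr.states[-1, 0] == pytest.approx(math.exp(-1.0), abs=1e-3)


def test_half_order_relaxation_hits_mittag_leffler():
    """D^0.5 x = -x, x(0)=1 -> E_{1/2}(-sqrt(t)); oracle = truncated series."""
    target = mittag_leffler(-1.0, 0.5)
    errs = []
    for h in (1e-2, 1e-3):
        grid = TimeGrid.from_duration(1.0, h)
        tr = solve_fode(lambda x, t: -x, 0.5, [1.0], grid, MemoryPolicy(mode="full"))
        errs.append(abs(tr.states[-1, 0] - target))
    assert errs[0] < 5e-3
    assert errs[1] < errs[0] / 5  # roughly O(h)


def test_short_memory_equals_full_when_window_covers_run():
    grid = TimeGrid.from_duration(2.0, 0.01)
    field = lambda x, t: -x + 0.3 * np.sin(t)  # noqa: E731
    full = solve_fode(field, 0.7, [0.5], grid, MemoryPolicy(mode="full"))
    short = solve_fode(
        field, 0.7, [0.5], grid, MemoryPolicy(mode="short", length=grid.n_steps)
    )
    assert np.array_equal(full.states, short.states)


def test_auto_memory_tail_rule():
    pol = MemoryPolicy()
    L = pol.resolve(0.98, 200_000)
    c = gl_coefficients(0.98, 200_000)
    tail = np.abs(np.cumsum(c))
    assert tail[L] < 1e-6
    assert tail[L - 1] >= 1e-6  # smallest such L


def test_integer_order_solver_converges_to_adaptive_reference():
    """GL at q=1 (explicit Euler) approaches the LSODA reference as h -> 0."""
    params = HRParameters(I=1.5)
    field = lambda x, t: hr_vector_field(x, params)  # noqa: E731
    x0 = (0.1, 1.0, 0.2)
    sups = []
    for h in (0.02, 0.005):
        grid = TimeGrid.from_duration(10.0, h)
        gl = solve_fode(field, 1.0, x0, grid)
        ref = solve_classical(field, x0, grid)
        sups.append(np.abs(gl.states - ref.states).max())
    assert sups[1] < sups[0]


def test_divergence_error_names_step():
    grid = TimeGrid.from_duration(5.0, 0.1)
    with pytest.raises(DivergenceError) as exc:
        solve_fode(lambda x, t: x**3, 1.0, [5.0], grid)
    assert exc.value.step >= 1


@pytest.mark.parametrize("bad_q", [-0.1, 0.0, 1.5])
def test_solver_rejects_bad_order(bad_q):
    grid = TimeGrid.from_duration(1.0, 0.1)
    with pytest.raises(ValueError):
        solve_fode(lambda x, t: -x, bad_q, [1.0], grid)


def test_time_grid_validation():
    with pytest.raises(ValueError):
        TimeGrid(0.0, -0.1, 10)
    with pytest.raises(ValueError):
        TimeGrid(0.0, 0.1, 0)
    grid = TimeGrid.from_duration(1.0, 0.25)
    assert grid.n_steps == 4
    assert np.allclose(grid.times, [0, 0.25, 0.5, 0.75, 1.0])
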