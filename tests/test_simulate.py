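"""Spatial operators, fluxes, rates, steppers, nondimensionalization."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from gogrownet import (
    DimensionlessParams,
    ExperimentConfig,
    FieldState,
    build_grid,
    generate_reference_dataset,
    make_benchmark,
    run_experiment_battery,
)
from gogrownet.gogrow import make_custom
from gogrownet.simulate import (
    EULER_TABLEAU,
    HEUN_TABLEAU,
    RK4_TABLEAU,
    DimensionalParams,
    IntegratorSpec,
    NondimScaling,
    SpatialOperators,
    battery_configs,
    build_difference_operator,
    cell_flux,
    generalized_midpoint_step,
    nondimensionalize,
    redimensionalize,
    rk_step,
    semidiscrete_rhs,
    simulate_with_stepper,
    step_explicit_rk,
    step_generalized_midpoint,
)


def grow_only():
    return make_custom(
        lambda x: np.stack([np.zeros_like(x), np.ones_like(x)], axis=-1)
    )


def go_only():
    return make_custom(
        lambda x: np.stack([np.ones_like(x), np.zeros_like(x)], axis=-1)
    )


# ---------------------------------------------------------------------------
# grids and operators
# ---------------------------------------------------------------------------

@pytest.mark.parametrize(
    "l,dxi,tau,dtau,n_x,n_t",
    [(50, 1.0, 10, 0.01, 51, 1001), (2, 1.0, 0.1, 0.05, 3, 3)],
)
def test_build_grid_counts(l, dxi, tau, dtau, n_x, n_t):
    grid = build_grid(l, dxi, tau, dtau)
    assert (grid.n_x, grid.n_t) == (n_x, n_t)
    assert grid.l == pytest.approx(l)


def test_build_grid_rejects_nondivisible():
    with pytest.raises(ValueError, match="integer multiples"):
        build_grid(50, 0.7, 10, 0.01)


def test_difference_operator_is_second_order_and_linear():
    grid = build_grid(10, 1.0, 1, 0.1)
    D = build_difference_operator(grid)
    xi = grid.xi
    np.testing.assert_allclose(D @ np.full(11, 3.0), 0.0, atol=1e-13)
    np.testing.assert_allclose(D @ (2 * xi), 2.0, atol=1e-12)
    # quadratic: exact everywhere (one-sided ends are second order)
    np.testing.assert_allclose(D @ xi**2, 2 * xi, atol=1e-11)
    v, w = np.sin(xi), np.cos(xi)
    np.testing.assert_allclose(D @ (2 * v + 3 * w), 2 * (D @ v) + 3 * (D @ w))


def test_divergence_operator_annihilates_trapezoid_weights():
    """w @ A = 0 makes the semidiscrete cell mass exactly conserved."""
    grid = build_grid(20, 1.0, 1, 0.1)
    ops = SpatialOperators(grid)
    w = np.full(grid.n_x, grid.dxi)
    w[0] = w[-1] = grid.dxi / 2
    np.testing.assert_allclose(w @ ops.A, 0.0, atol=1e-14)


# ---------------------------------------------------------------------------
# flux and rates
# ---------------------------------------------------------------------------

def test_cell_flux_cases():
    grid = build_grid(50, 1.0, 1, 0.1)
    ops = SpatialOperators(grid)
    params = DimensionlessParams()
    xi = grid.xi
    uniform = FieldState(u1=np.full(51, 2.0), u2=np.full(51, 3.0))
    np.testing.assert_allclose(
        cell_flux(uniform, params, np.ones(51), ops), 0.0, atol=1e-13
    )
    # chemotaxis off: flux reduces to pedesis
    state = FieldState(u1=np.sin(xi), u2=xi)
    np.testing.assert_allclose(
        cell_flux(state, params, np.zeros(51), ops),
        params.D1 * (ops.D @ state.u1),
    )
    # uniform cells on the k=4 initial oxygen ramp (2 -> 0 over 50)
    state = FieldState(u1=np.full(51, 2.0), u2=2.0 - 0.04 * xi)
    f1 = cell_flux(state, params, np.ones(51), ops)
    np.testing.assert_allclose(f1[1:-1], 0.08, atol=1e-12)


def test_cell_flux_length_mismatch():
    grid = build_grid(10, 1.0, 1, 0.1)
    ops = SpatialOperators(grid)
    state = FieldState(u1=np.ones(11), u2=np.ones(11))
    with pytest.raises(ValueError, match="mismatch"):
        cell_flux(state, DimensionlessParams(), np.ones(5), ops)


def test_rhs_zero_cells_linear_oxygen_is_stationary():
    grid = build_grid(50, 1.0, 1, 0.1)
    ops = SpatialOperators(grid)
    state = FieldState(u1=np.zeros(51), u2=4.0 * grid.xi / 50.0)
    du1, du2 = semidiscrete_rhs(state, DimensionlessParams(), grow_only(), ops)
    np.testing.assert_allclose(du1, 0.0, atol=1e-13)
    np.testing.assert_allclose(du2, 0.0, atol=1e-13)


def test_rhs_uniform_logistic_reaction():
    grid = build_grid(50, 1.0, 1, 0.1)
    ops = SpatialOperators(grid)
    state = FieldState(u1=np.full(51, 2.0), u2=np.full(51, 100.0))
    du1, _ = semidiscrete_rhs(state, DimensionlessParams(), grow_only(), ops)
    np.testing.assert_allclose(du1, 0.5 * 2.0 * (1 - 0.2), atol=1e-12)


def test_rhs_michaelis_menten_half_saturation():
    grid = build_grid(50, 1.0, 1, 0.1)
    ops = SpatialOperators(grid)
    params = DimensionlessParams()  # km = 2
    state = FieldState(u1=np.full(51, 2.0), u2=np.full(51, 2.0))
    _, du2 = semidiscrete_rhs(state, params, go_only(), ops)
    np.testing.assert_allclose(du2[1:-1], -0.05 * 0.5 * 2.0, atol=1e-12)
    assert du2[0] == 0.0 and du2[-1] == 0.0  # Dirichlet rows carry no rate


def test_rhs_rejects_nonfinite():
    grid = build_grid(10, 1.0, 1, 0.1)
    ops = SpatialOperators(grid)
    state = FieldState(u1=np.full(11, np.nan), u2=np.ones(11))
    with pytest.raises(ValueError, match="non-finite"):
        semidiscrete_rhs(state, DimensionlessParams(), grow_only(), ops)


# ---------------------------------------------------------------------------
# time steppers
# ---------------------------------------------------------------------------

def test_midpoint_rule_scalar_cases():
    f = lambda y: -y
    y0 = np.array([1.0])
    assert generalized_midpoint_step(f, y0, 0.01, beta=1.0)[0] == pytest.approx(0.99)
    assert generalized_midpoint_step(f, y0, 0.01, beta=0.0)[0] == pytest.approx(
        1 / 1.01, abs=1e-10
    )
    with pytest.raises(ValueError):
        generalized_midpoint_step(f, y0, 0.01, beta=1.5)


def test_rk4_matches_exponential_to_fourth_order():
    y = rk_step(lambda y: -y, np.array([1.0]), 0.1, RK4_TABLEAU)
    assert abs(y[0] - np.exp(-0.1)) < 1e-7


def test_heun_is_second_order_by_richardson():
    f = lambda y: -(y**2)
    exact = 1.0 / (1.0 + 1.0)  # y' = -y^2, y(0)=1 at t=1

    def integrate(h):
        y = np.array([1.0])
        for _ in range(int(round(1.0 / h))):
            y = rk_step(f, y, h, HEUN_TABLEAU)
        return y[0]

    e1 = abs(integrate(0.01) - exact)
    e2 = abs(integrate(0.005) - exact)
    assert e1 / e2 == pytest.approx(4.0, rel=0.15)


def test_tableau_validation():
    with pytest.raises(ValueError, match="lower triangular"):
        IntegratorSpec(scheme="explicit_rk", a=[[0.5]], b=[1.0], c=[0.0])
    with pytest.raises(ValueError, match="sum to 1"):
        IntegratorSpec(scheme="explicit_rk", a=[[0.0]], b=[0.9], c=[0.0])


def test_euler_tableau_equals_beta1_midpoint_on_fields(coarse_params, mm_truth):
    grid = build_grid(10, 1.0, 0.5, 0.01)
    ops = SpatialOperators(grid)
    config = ExperimentConfig(o2_left=0.0, o2_right=4.0)
    state = config.initial_state(grid)
    a = step_generalized_midpoint(
        state, coarse_params, mm_truth, 0.01, 1.0, config=config, ops=ops
    )
    b = step_explicit_rk(
        state, coarse_params, mm_truth, 0.01, EULER_TABLEAU, config=config, ops=ops
    )
    np.testing.assert_array_equal(a.u1, b.u1)
    np.testing.assert_array_equal(a.u2, b.u2)


# ---------------------------------------------------------------------------
# reference datasets and the battery
# ---------------------------------------------------------------------------

def test_symmetric_config_has_constant_initial_oxygen(coarse_params, mm_truth):
    grid = build_grid(10, 1.0, 0.1, 0.01)
    ds = generate_reference_dataset(
        ExperimentConfig(o2_left=1.0, o2_right=1.0), coarse_params, mm_truth, grid
    )
    np.testing.assert_allclose(ds.data[0, :, 1], 1.0)
    np.testing.assert_allclose(ds.data[0, :, 0], 2.0)


def test_dirichlet_columns_pinned_all_times(gradient_dataset):
    np.testing.assert_array_equal(gradient_dataset.data[:, 0, 1], 0.0)
    np.testing.assert_array_equal(gradient_dataset.data[:, -1, 1], 4.0)


def test_reference_solution_stays_essentially_nonnegative(gradient_dataset):
    assert gradient_dataset.data.min() >= -1e-8


def test_mass_conserved_without_growth():
    """No-flux walls + switched-off growth: trapezoidal cell mass constant."""
    grid = build_grid(50, 1.0, 10.0, 0.01)
    model = make_custom(
        lambda x: np.stack([1.0 / (1.0 + x), np.zeros_like(x)], axis=-1)
    )
    ds = generate_reference_dataset(
        ExperimentConfig(o2_left=0.0, o2_right=4.0),
        DimensionlessParams(),
        model,
        grid,
    )
    mass = ds.cell_mass()
    assert np.max(np.abs(mass - mass[0])) / mass[0] < 1e-4


def test_oxygen_linear_steady_state_without_cells():
    grid = build_grid(50, 1.0, 10.0, 0.1)
    ds = generate_reference_dataset(
        ExperimentConfig(o2_left=1.0, o2_right=3.0, c_init=0.0),
        DimensionlessParams(),
        grow_only(),
        grid,
    )
    expected = 1.0 + 2.0 * grid.xi / 50.0
    assert np.max(np.abs(ds.data[-1, :, 1] - expected)) < 1e-3


def test_battery_registry_matches_expected_rows():
    configs = battery_configs()
    assert len(configs) == 11
    assert [c.label for c in configs] == list(range(1, 12))
    assert configs[3].boundary_at(0.0) == (2.0, 0.0)  # k = 4
    assert len(battery_configs(rows=[1, 3])) == 2


def test_battery_subset_runs_and_labels(coarse_params, mm_truth):
    grid = build_grid(10, 1.0, 0.1, 0.01)
    datasets = run_experiment_battery(coarse_params, mm_truth, grid, rows=[1, 3])
    assert [ds.config.label for ds in datasets] == [1, 3]
    assert all(ds.data.shape == (11, 11, 2) for ds in datasets)


def test_fixed_step_simulation_matches_reference(coarse_params, mm_truth):
    grid = build_grid(10, 1.0, 0.5, 0.01)
    config = ExperimentConfig(o2_left=0.0, o2_right=4.0)
    ref = generate_reference_dataset(config, coarse_params, mm_truth, grid)
    rk4 = simulate_with_stepper(config, coarse_params, mm_truth, grid, RK4_TABLEAU)
    assert np.max(np.abs(rk4.data - ref.data)) < 1e-6


# ---------------------------------------------------------------------------
# nondimensionalization
# ---------------------------------------------------------------------------

def test_identity_scaling_is_identity_map():
    dim = DimensionalParams(D1=1, chi=1, alpha1=0.5, cs=10, D2=1, alpha2=0.05,
                            km=2, l=50)
    nd = nondimensionalize(dim, NondimScaling())
    assert nd == DimensionlessParams()


def test_growth_rate_scales_with_time():
    dim = DimensionalParams(D1=1, chi=1, alpha1=0.5, cs=10, D2=1, alpha2=0.05,
                            km=2, l=50)
    nd = nondimensionalize(dim, NondimScaling(T=1.0))
    assert nd.alpha1 == pytest.approx(0.5)


@settings(deadline=None, max_examples=30, derandomize=True)
@given(
    vals=st.lists(st.floats(1e-3, 1e3), min_size=8, max_size=8),
    scales=st.lists(st.floats(1e-2, 1e2), min_size=4, max_size=4),
)
def test_nondimensionalization_round_trip(vals, scales):
    dim = DimensionalParams(*vals)
    s = NondimScaling(*scales)
    back = redimensionalize(nondimensionalize(dim, s), s)
    for name in ("D1", "chi", "alpha1", "cs", "D2", "alpha2", "km", "l"):
        assert getattr(back, name) == pytest.approx(getattr(dim, name), rel=1e-12)


def test_scaling_rejects_nonpositive():
    with pytest.raises(ValueError):
        NondimScaling(T=0.0)
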