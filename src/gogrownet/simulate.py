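"""Finite-difference model of a 1-D glioblastoma-on-chip culture.

The chamber of dimensionless length ``l`` holds a cell density field ``u1``
and an oxygen field ``u2`` governed by a coupled advection-diffusion-reaction
system: cells undergo random motility (pedesis), oxygen-gradient chemotaxis
gated by ``pi_go(u2)``, and logistic growth gated by ``pi_gr(u2)``; oxygen
diffuses and is consumed by cells with Michaelis-Menten kinetics.  Oxygen is
held at Dirichlet values at the two lateral channels; the walls are
impermeable to cells (zero cell flux).

Space is discretised by the method of lines on a uniform node grid with a
second-order first-derivative operator ``D`` (central interior, one-sided
ends).  The cell equation is advanced in divergence form: the nodal flux

    f1 = D1 * D u1 - chi * pi_go * u1 * D u2

is assembled, forced to zero at the walls, and differentiated again by a
divergence operator whose wall rows use a mirrored ghost flux — this makes
the trapezoidal cell mass exactly conserved at the semidiscrete level when
growth is off.  Time integration offers a generalized midpoint rule
(beta = 1 forward Euler, beta = 0 backward Euler), explicit Runge-Kutta
tableaus, and a high-accuracy stiff reference solve used for data
generation.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Callable, Optional, Sequence, Union

import numpy as np
from scipy.integrate import solve_ivp

from .gogrow import GoGrowModel, eval_pi

__all__ = [
    "DimensionlessParams",
    "DimensionalParams",
    "NondimScaling",
    "GridSpec",
    "ExperimentConfig",
    "FieldState",
    "SimulationDataset",
    "IntegratorSpec",
    "EULER_TABLEAU",
    "HEUN_TABLEAU",
    "RK4_TABLEAU",
    "DEFAULT_BATTERY",
    "build_grid",
    "build_difference_operator",
    "build_divergence_operator",
    "SpatialOperators",
    "cell_flux",
    "semidiscrete_rhs",
    "generalized_midpoint_step",
    "rk_step",
    "step_generalized_midpoint",
    "step_explicit_rk",
    "generate_reference_dataset",
    "run_experiment_battery",
    "nondimensionalize",
    "redimensionalize",
]

BoundaryValue = Union[float, Callable[[float], float]]


@dataclass(frozen=True)
class DimensionlessParams:
    """The seven dimensionless PDE coefficients plus chamber length.

    Defaults are the values used throughout the benchmark study: they are
    chosen so that pedesis, chemotaxis, growth, diffusion and consumption
    all matter on the tau in [0, 10] horizon of a 50-unit chamber.
    """

    D1: float = 1.0      # cell pedesis (random motility)
    chi: float = 1.0     # chemotactic sensitivity
    alpha1: float = 0.5  # logistic growth rate
    cs: float = 10.0     # carrying capacity
    D2: float = 1.0      # oxygen diffusion
    alpha2: float = 0.05  # oxygen consumption rate
    km: float = 2.0      # Michaelis half-saturation
    l: float = 50.0      # chamber length

    def __post_init__(self) -> None:
        for name in ("D1", "chi", "alpha1", "cs", "D2", "alpha2", "km", "l"):
            if not getattr(self, name) > 0:
                raise ValueError(f"{name} must be strictly positive")


@dataclass(frozen=True)
class DimensionalParams:
    """Physical-units counterpart of :class:`DimensionlessParams`."""

    D1: float
    chi: float
    alpha1: float
    cs: float
    D2: float
    alpha2: float
    km: float
    l: float


@dataclass(frozen=True)
class NondimScaling:
    """Characteristic scales: time T, length L, cell U1, oxygen U2."""

    T: float = 1.0
    L: float = 1.0
    U1: float = 1.0
    U2: float = 1.0

    def __post_init__(self) -> None:
        for name in ("T", "L", "U1", "U2"):
            if not getattr(self, name) > 0:
                raise ValueError(f"{name} must be strictly positive")


def nondimensionalize(dim: DimensionalParams, s: NondimScaling) -> DimensionlessParams:
    """Map dimensional coefficients to their dimensionless counterparts."""
    return DimensionlessParams(
        D1=dim.D1 * s.T / s.L**2,
        chi=dim.chi * s.T * s.U2 / s.L**2,
        alpha1=dim.alpha1 * s.T,
        cs=dim.cs / s.U1,
        D2=dim.D2 * s.T / s.L**2,
        alpha2=dim.alpha2 * s.T * s.U1 / s.U2,
        km=dim.km / s.U2,
        l=dim.l / s.L,
    )


def redimensionalize(nd: DimensionlessParams, s: NondimScaling) -> DimensionalParams:
    """Inverse of :func:`nondimensionalize`."""
    return DimensionalParams(
        D1=nd.D1 * s.L**2 / s.T,
        chi=nd.chi * s.L**2 / (s.T * s.U2),
        alpha1=nd.alpha1 / s.T,
        cs=nd.cs * s.U1,
        D2=nd.D2 * s.L**2 / s.T,
        alpha2=nd.alpha2 * s.U2 / (s.T * s.U1),
        km=nd.km * s.U2,
        l=nd.l * s.L,
    )


@dataclass(frozen=True)
class GridSpec:
    """Uniform space-time sampling grid; node j sits at xi = j * dxi."""

    dxi: float
    dtau: float
    n_x: int
    n_t: int
    tau_star: float

    @property
    def l(self) -> float:
        return (self.n_x - 1) * self.dxi

    @property
    def xi(self) -> np.ndarray:
        return np.arange(self.n_x) * self.dxi

    @property
    def taus(self) -> np.ndarray:
        return np.arange(self.n_t) * self.dtau


def build_grid(l: float, dxi: float, tau_star: float, dtau: float) -> GridSpec:
    """Validate divisibility and return the grid (n_x = l/dxi + 1 nodes)."""
    if dxi <= 0 or dtau <= 0:
        raise ValueError("steps must be positive")
    nx = l / dxi
    nt = tau_star / dtau
    if abs(nx - round(nx)) > 1e-9 or abs(nt - round(nt)) > 1e-9:
        raise ValueError(
            f"domain/duration must be integer multiples of the steps "
            f"(l/dxi={nx}, tau*/dtau={nt})"
        )
    return GridSpec(
        dxi=dxi, dtau=dtau, n_x=int(round(nx)) + 1, n_t=int(round(nt)) + 1,
        tau_star=tau_star,
    )


@dataclass(frozen=True)
class ExperimentConfig:
    """One oxygenation scenario: boundary oxygen plus initial profiles.

    ``o2_left``/``o2_right`` may be constants or functions of tau (the
    benchmark battery uses constants).  The default initial cell profile is
    the constant 2; the default initial oxygen is the linear interpolant
    between the two boundary values at tau = 0.
    """

    o2_left: BoundaryValue = 0.0
    o2_right: BoundaryValue = 0.0
    c_init: Union[float, Callable[[np.ndarray], np.ndarray]] = 2.0
    o2_init: Optional[Callable[[np.ndarray], np.ndarray]] = None
    label: Optional[int] = None

    def boundary_at(self, tau: float) -> tuple[float, float]:
        left = self.o2_left(tau) if callable(self.o2_left) else self.o2_left
        right = self.o2_right(tau) if callable(self.o2_right) else self.o2_right
        if left < 0 or right < 0:
            raise ValueError("boundary oxygen must be nonnegative")
        return float(left), float(right)

    def initial_state(self, grid: GridSpec) -> "FieldState":
        xi = grid.xi
        if callable(self.c_init):
            u1 = np.asarray(self.c_init(xi), dtype=float)
        else:
            u1 = np.full(grid.n_x, float(self.c_init))
        left, right = self.boundary_at(0.0)
        if self.o2_init is not None:
            u2 = np.asarray(self.o2_init(xi), dtype=float)
        else:
            u2 = left + (right - left) * xi / grid.l
        u2 = u2.copy()
        u2[0], u2[-1] = left, right
        return FieldState(u1=u1, u2=u2, tau=0.0)


#: The eleven oxygenation scenarios of the benchmark battery, k = 1..11:
#: symmetric and gradient configurations at low/medium/high oxygen.
DEFAULT_BATTERY: tuple[tuple[int, float, float], ...] = (
    (1, 0.0, 0.0), (2, 0.0, 1.0), (3, 1.0, 1.0), (4, 2.0, 0.0), (5, 2.0, 2.0),
    (6, 3.0, 0.0), (7, 3.0, 3.0), (8, 4.0, 0.0), (9, 4.0, 4.0),
    (10, 5.0, 0.0), (11, 5.0, 5.0),
)


def battery_configs(rows: Optional[Sequence[int]] = None) -> list[ExperimentConfig]:
    """Experiment configs for the (optionally subset) benchmark battery."""
    selected = []
    wanted = set(rows) if rows is not None else None
    for k, left, right in DEFAULT_BATTERY:
        if wanted is None or k in wanted:
            selected.append(ExperimentConfig(o2_left=left, o2_right=right, label=k))
    return selected


@dataclass
class FieldState:
    """Nodal (u1, u2) vectors at one instant."""

    u1: np.ndarray
    u2: np.ndarray
    tau: float = 0.0

    def __post_init__(self) -> None:
        self.u1 = np.asarray(self.u1, dtype=float)
        self.u2 = np.asarray(self.u2, dtype=float)
        if self.u1.shape != self.u2.shape or self.u1.ndim != 1:
            raise ValueError("u1 and u2 must be 1-D vectors of equal length")


@dataclass
class SimulationDataset:
    """A [n_t, n_x, 2] space-time array (channel 0 = cell, 1 = oxygen)."""

    data: np.ndarray
    grid: GridSpec
    config: ExperimentConfig
    ground_truth: Optional[GoGrowModel] = None
    provenance: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data, dtype=float)
        expected = (self.grid.n_t, self.grid.n_x, 2)
        if self.data.shape != expected:
            raise ValueError(f"data shape {self.data.shape} != grid shape {expected}")

    @property
    def n_pairs(self) -> int:
        return self.grid.n_t - 1

    def pairs(self) -> tuple[np.ndarray, np.ndarray]:
        """Consecutive-time (input, output) sample arrays, [n_t-1, n_x, 2]."""
        return self.data[:-1], self.data[1:]

    def state_at(self, index: int) -> FieldState:
        return FieldState(
            u1=self.data[index, :, 0].copy(),
            u2=self.data[index, :, 1].copy(),
            tau=index * self.grid.dtau,
        )

    def cell_mass(self) -> np.ndarray:
        """Trapezoidal integral of the cell profile at every stored time."""
        return np.trapezoid(self.data[:, :, 0], dx=self.grid.dxi, axis=1)


# ---------------------------------------------------------------------------
# spatial operators
# ---------------------------------------------------------------------------

def build_difference_operator(grid: GridSpec) -> np.ndarray:
    """Second-order first-derivative matrix D on the node grid.

    Central stencil in the interior, one-sided second-order stencils at the
    two ends; exact for affine nodal fields.
    """
    n = grid.n_x
    if n < 3:
        raise ValueError("need at least 3 nodes")
    h = grid.dxi
    D = np.zeros((n, n))
    for j in range(1, n - 1):
        D[j, j - 1] = -0.5 / h
        D[j, j + 1] = 0.5 / h
    D[0, 0], D[0, 1], D[0, 2] = -1.5 / h, 2.0 / h, -0.5 / h
    D[-1, -1], D[-1, -2], D[-1, -3] = 1.5 / h, -2.0 / h, 0.5 / h
    return D


def build_divergence_operator(grid: GridSpec) -> np.ndarray:
    """Divergence matrix A applied to the nodal cell flux.

    Interior rows are the central first-derivative stencil.  The wall rows
    impose the no-flux condition with a mirrored ghost flux
    (f[-1] = -f[1], f[n+1] = -f[n-1]) and the wall flux itself is treated
    as zero (columns 0 and n-1 are empty), so that w @ A = 0 for the
    trapezoidal quadrature weights w — cell mass is conserved exactly
    whenever growth vanishes.
    """
    n = grid.n_x
    if n < 3:
        raise ValueError("need at least 3 nodes")
    h = grid.dxi
    A = np.zeros((n, n))
    for j in range(1, n - 1):
        A[j, j - 1] = -0.5 / h
        A[j, j + 1] = 0.5 / h
    A[0, 1] = 1.0 / h       # (f1 - (-f1)) / (2h) with f0 = 0
    A[-1, -2] = -1.0 / h
    A[:, 0] = 0.0
    A[:, -1] = 0.0
    return A


class SpatialOperators:
    """Precomputed D (gradient) and A (flux divergence) for one grid."""

    def __init__(self, grid: GridSpec):
        self.grid = grid
        self.D = build_difference_operator(grid)
        self.A = build_divergence_operator(grid)
        self.DD = self.D @ self.D  # oxygen diffusion: D applied twice

    def explicit_stability_limit(self, params: DimensionlessParams) -> float:
        return self.grid.dxi**2 / (2.0 * max(params.D1, params.D2))


def _evaluate_pi(model, u2: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Nodal (pi_go, pi_gr) from a GoGrowModel or any net with eval_pairs."""
    if isinstance(model, GoGrowModel):
        pi = eval_pi(model, u2)
        return pi[..., 0], pi[..., 1]
    # duck-typed: explanatory networks expose eval_pairs(u2) -> [n, 2]
    pi = model.eval_pairs(u2)
    return pi[..., 0], pi[..., 1]


def cell_flux(
    state: FieldState,
    params: DimensionlessParams,
    pi_go: np.ndarray,
    ops: SpatialOperators,
) -> np.ndarray:
    """Nodal cell flux f1 = D1 * D u1 - chi * pi_go * u1 * D u2."""
    pi_go = np.asarray(pi_go, dtype=float)
    if pi_go.shape != state.u1.shape:
        raise ValueError("pi_go length mismatch")
    return params.D1 * (ops.D @ state.u1) - params.chi * pi_go * state.u1 * (
        ops.D @ state.u2
    )


def semidiscrete_rhs(
    state: FieldState,
    params: DimensionlessParams,
    model,
    ops: SpatialOperators,
) -> tuple[np.ndarray, np.ndarray]:
    """Method-of-lines rates (du1/dtau, du2/dtau).

    The oxygen Dirichlet rows get zero rate; the caller is responsible for
    having imposed the boundary values on ``state.u2``.
    """
    if not (np.all(np.isfinite(state.u1)) and np.all(np.isfinite(state.u2))):
        raise ValueError("non-finite field values")
    pi_go, pi_gr = _evaluate_pi(model, state.u2)
    f1 = cell_flux(state, params, pi_go, ops)
    du1 = ops.A @ f1 + params.alpha1 * pi_gr * state.u1 * (1.0 - state.u1 / params.cs)
    du2 = params.D2 * (ops.DD @ state.u2) - params.alpha2 * (
        state.u2 / (state.u2 + params.km)
    ) * state.u1
    du2[0] = 0.0
    du2[-1] = 0.0
    return du1, du2


# ---------------------------------------------------------------------------
# time steppers (generic vector-field versions + field-state wrappers)
# ---------------------------------------------------------------------------

def generalized_midpoint_step(
    f: Callable[[np.ndarray], np.ndarray],
    y: np.ndarray,
    dt: float,
    beta: float = 1.0,
    tol: float = 1e-10,
    max_iter: int = 100,
) -> np.ndarray:
    """One step of y' = f(y) by the generalized midpoint rule.

    ``beta = 1`` is forward Euler (explicit); ``beta < 1`` solves the
    implicit relation y+ = y + dt * f(beta*y + (1-beta)*y+) by damped
    fixed-point iteration to residual norm < ``tol``.
    """
    if not 0.0 <= beta <= 1.0:
        raise ValueError("beta must lie in [0, 1]")
    y = np.asarray(y, dtype=float)
    if beta == 1.0:
        return y + dt * f(y)
    y_new = y + dt * f(y)  # explicit predictor
    for _ in range(max_iter):
        proposal = y + dt * f(beta * y + (1.0 - beta) * y_new)
        res = np.linalg.norm(proposal - y_new)
        y_new = 0.5 * (y_new + proposal)  # damping for stiff modes
        if res < tol:
            return proposal
    raise RuntimeError(f"implicit midpoint iteration failed (residual {res:.3e})")


@dataclass(frozen=True)
class IntegratorSpec:
    """Time scheme: generalized midpoint (with beta) or an explicit tableau."""

    scheme: str = "generalized_midpoint"
    beta: float = 1.0
    a: Optional[np.ndarray] = None
    b: Optional[np.ndarray] = None
    c: Optional[np.ndarray] = None

    def __post_init__(self) -> None:
        if self.scheme not in ("generalized_midpoint", "explicit_rk"):
            raise ValueError(f"unknown scheme {self.scheme!r}")
        if self.scheme == "generalized_midpoint":
            if not 0.0 <= self.beta <= 1.0:
                raise ValueError("beta must lie in [0, 1]")
        else:
            a = np.asarray(self.a, dtype=float)
            b = np.asarray(self.b, dtype=float)
            if a.ndim != 2 or a.shape[0] != a.shape[1] or a.shape[0] != b.size:
                raise ValueError("inconsistent tableau")
            if not np.allclose(np.triu(a), 0.0):
                raise ValueError("tableau must be strictly lower triangular")
            if abs(b.sum() - 1.0) > 1e-12:
                raise ValueError("RK weights must sum to 1")


def _tableau(a, b, c=None) -> IntegratorSpec:
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    c = a.sum(axis=1) if c is None else np.asarray(c, dtype=float)
    return IntegratorSpec(scheme="explicit_rk", a=a, b=b, c=c)


EULER_TABLEAU = _tableau([[0.0]], [1.0])
HEUN_TABLEAU = _tableau([[0.0, 0.0], [1.0, 0.0]], [0.5, 0.5])
RK4_TABLEAU = _tableau(
    [[0, 0, 0, 0], [0.5, 0, 0, 0], [0, 0.5, 0, 0], [0, 0, 1, 0]],
    [1 / 6, 1 / 3, 1 / 3, 1 / 6],
)


def rk_step(
    f: Callable[[np.ndarray], np.ndarray],
    y: np.ndarray,
    dt: float,
    spec: IntegratorSpec,
) -> np.ndarray:
    """One explicit Runge-Kutta step of y' = f(y)."""
    if spec.scheme != "explicit_rk":
        raise ValueError("rk_step requires an explicit tableau")
    a, b = spec.a, spec.b
    s = b.size
    y = np.asarray(y, dtype=float)
    k = np.empty((s,) + y.shape)
    for i in range(s):
        stage = y.copy()
        for j in range(i):
            if a[i, j] != 0.0:
                stage = stage + dt * a[i, j] * k[j]
        k[i] = f(stage)
    return y + dt * np.tensordot(b, k, axes=1)


def _pack(state: FieldState) -> np.ndarray:
    return np.concatenate([state.u1, state.u2])


def _field_rhs(params, model, ops, config) -> Callable[[np.ndarray], np.ndarray]:
    n = ops.grid.n_x

    def f(y: np.ndarray) -> np.ndarray:
        st = FieldState(u1=y[:n], u2=y[n:], tau=0.0)
        du1, du2 = semidiscrete_rhs(st, params, model, ops)
        return np.concatenate([du1, du2])

    return f


def _impose_dirichlet(u2: np.ndarray, config: ExperimentConfig, tau: float) -> None:
    left, right = config.boundary_at(tau)
    u2[0], u2[-1] = left, right


def step_generalized_midpoint(
    state: FieldState,
    params: DimensionlessParams,
    model,
    dtau: float,
    beta: float = 1.0,
    config: Optional[ExperimentConfig] = None,
    ops: Optional[SpatialOperators] = None,
) -> FieldState:
    """Advance the coupled fields one step; re-imposes oxygen Dirichlet values."""
    if ops is None:
        raise ValueError("ops (SpatialOperators) is required")
    f = _field_rhs(params, model, ops, config)
    y = generalized_midpoint_step(f, _pack(state), dtau, beta)
    n = ops.grid.n_x
    new = FieldState(u1=y[:n], u2=y[n:], tau=state.tau + dtau)
    if config is not None:
        _impose_dirichlet(new.u2, config, new.tau)
    return new


def step_explicit_rk(
    state: FieldState,
    params: DimensionlessParams,
    model,
    dtau: float,
    tableau: IntegratorSpec,
    config: Optional[ExperimentConfig] = None,
    ops: Optional[SpatialOperators] = None,
) -> FieldState:
    """Advance one explicit RK step with the switch re-evaluated per stage."""
    if ops is None:
        raise ValueError("ops (SpatialOperators) is required")
    f = _field_rhs(params, model, ops, config)
    y = rk_step(f, _pack(state), dtau, tableau)
    n = ops.grid.n_x
    new = FieldState(u1=y[:n], u2=y[n:], tau=state.tau + dtau)
    if config is not None:
        _impose_dirichlet(new.u2, config, new.tau)
    return new


# ---------------------------------------------------------------------------
# reference data generation
# ---------------------------------------------------------------------------

def generate_reference_dataset(
    config: ExperimentConfig,
    params: DimensionlessParams,
    model: GoGrowModel,
    grid: GridSpec,
    rtol: float = 1e-8,
    atol: float = 1e-10,
    method: str = "LSODA",
) -> SimulationDataset:
    """High-accuracy method-of-lines solve sampled on the storage grid.

    The same 51-node spatial operator the learning machinery uses is
    integrated in time by an adaptive stiff solver (rtol 1e-8), then
    sampled every ``dtau``.  Oxygen Dirichlet rows carry zero rate, so
    constant boundary values persist exactly.
    """
    ops = SpatialOperators(grid)
    state0 = config.initial_state(grid)
    f = _field_rhs(params, model, ops, config)
    sol = solve_ivp(
        lambda t, y: f(y),
        (0.0, grid.tau_star),
        _pack(state0),
        t_eval=grid.taus,
        method=method,
        rtol=rtol,
        atol=atol,
    )
    if not sol.success:
        raise RuntimeError(f"reference solve failed: {sol.message}")
    n = grid.n_x
    data = np.stack([sol.y[:n].T, sol.y[n:].T], axis=-1)
    if not np.all(np.isfinite(data)):
        raise RuntimeError("non-finite reference solution")
    # pin the Dirichlet columns to the exact boundary values
    for i, tau in enumerate(grid.taus):
        left, right = config.boundary_at(tau)
        data[i, 0, 1] = left
        data[i, -1, 1] = right
    return SimulationDataset(
        data=data,
        grid=grid,
        config=config,
        ground_truth=model,
        provenance={"solver": method, "rtol": rtol, "atol": atol},
    )


def run_experiment_battery(
    params: DimensionlessParams,
    model: GoGrowModel,
    grid: GridSpec,
    rows: Optional[Sequence[int]] = None,
    **solver_kwargs,
) -> list[SimulationDataset]:
    """Reference datasets for the (optionally subset) oxygenation battery."""
    datasets = []
    for config in battery_configs(rows):
        try:
            datasets.append(
                generate_reference_dataset(config, params, model, grid, **solver_kwargs)
            )
        except Exception as exc:  # noqa: BLE001 - annotate failing config
            raise RuntimeError(f"battery configuration k={config.label} failed") from exc
    return datasets


def simulate_with_stepper(
    config: ExperimentConfig,
    params: DimensionlessParams,
    model,
    grid: GridSpec,
    integrator: Optional[IntegratorSpec] = None,
) -> SimulationDataset:
    """Fixed-step simulation storing every step (Euler/midpoint or RK)."""
    integrator = integrator or IntegratorSpec(beta=1.0)
    ops = SpatialOperators(grid)
    state = config.initial_state(grid)
    data = np.empty((grid.n_t, grid.n_x, 2))
    data[0, :, 0], data[0, :, 1] = state.u1, state.u2
    for i in range(1, grid.n_t):
        if integrator.scheme == "explicit_rk":
            state = step_explicit_rk(
                state, params, model, grid.dtau, integrator, config=config, ops=ops
            )
        else:
            state = step_generalized_midpoint(
                state, params, model, grid.dtau, integrator.beta, config=config, ops=ops
            )
        data[i, :, 0], data[i, :, 1] = state.u1, state.u2
    return SimulationDataset(
        data=data, grid=grid, config=config,
        ground_truth=model if isinstance(model, GoGrowModel) else None,
        provenance={"integrator": integrator.scheme, "beta": integrator.beta},
    )
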