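"""Recovery and prediction metrics, rollouts, and the benchmark study.

Two error functionals quantify the two capacities of the method:

* explanatory — ``E_pi``, the L2 distance between the learned and the true
  switch component over the oxygen range visited by the experiment battery
  ([0, 5]);
* predictive — ``E_cell``, the L2 distance between predicted and reference
  cell profiles across the chamber at a chosen evaluation time, with the
  learned switch plugged back into a time integrator and rolled out from
  the initial condition (beyond the training horizon).

``run_benchmark_study`` orchestrates the full comparison: for each
ground-truth switch family it generates the battery, trains the
nonparametric network and the single-threshold parametric baseline over
several seeds, and tabulates both metrics across hypoxic / gradient /
normoxic prediction scenarios.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Callable, Optional, Sequence

import numpy as np
import pandas as pd

from .gogrow import GoGrowModel, GoGrowParams, make_benchmark
from .network import (
    TrainingConfig,
    fit_parametric_baseline,
    train_pgnniv,
)
from .simulate import (
    RK4_TABLEAU,
    DimensionlessParams,
    ExperimentConfig,
    GridSpec,
    IntegratorSpec,
    SimulationDataset,
    build_grid,
    generate_reference_dataset,
    run_experiment_battery,
    simulate_with_stepper,
)

__all__ = [
    "PredictionScenario",
    "DEFAULT_SCENARIOS",
    "EvaluationReport",
    "StudyConfig",
    "model_error",
    "max_deviation",
    "rollout",
    "cell_error",
    "run_benchmark_study",
]


@dataclass(frozen=True)
class PredictionScenario:
    """A named oxygenation condition used to probe predictive skill."""

    name: str
    o2_left: float
    o2_right: float
    horizon: float = 20.0

    def __post_init__(self) -> None:
        if self.o2_left < 0 or self.o2_right < 0:
            raise ValueError("boundary oxygen must be nonnegative")

    def config(self) -> ExperimentConfig:
        return ExperimentConfig(o2_left=self.o2_left, o2_right=self.o2_right)


DEFAULT_SCENARIOS = (
    PredictionScenario("hypoxic", 0.0, 0.0),
    PredictionScenario("gradient", 0.0, 4.0),
    PredictionScenario("normoxic", 4.0, 4.0),
)


def _as_component_evaluator(model) -> Callable[[np.ndarray], np.ndarray]:
    if isinstance(model, GoGrowModel):
        return lambda x: model(x)
    return lambda x: model.eval_pairs(x)


def model_error(
    pi_hat,
    pi_true,
    upper: float = 5.0,
    n_quad: int = 501,
) -> tuple[float, float]:
    """L2 switch-recovery error per component over oxygen in [0, upper].

    Returns ``(E_pi_go, E_pi_gr)`` where each is the square root of the
    trapezoidal approximation of the integrated squared difference.
    """
    if n_quad < 2:
        raise ValueError("n_quad must be at least 2")
    x = np.linspace(0.0, upper, n_quad)
    d = _as_component_evaluator(pi_hat)(x) - _as_component_evaluator(pi_true)(x)
    e2 = np.trapezoid(d**2, x, axis=0)
    return float(np.sqrt(e2[0])), float(np.sqrt(e2[1]))


def max_deviation(
    pi_hat, pi_true, upper: float = 5.0, n_quad: int = 501
) -> tuple[float, float]:
    """Sup-norm deviation per component on the same quadrature grid."""
    x = np.linspace(0.0, upper, n_quad)
    d = np.abs(_as_component_evaluator(pi_hat)(x) - _as_component_evaluator(pi_true)(x))
    return float(d[:, 0].max()), float(d[:, 1].max())


def rollout(
    pi_evaluator,
    config: ExperimentConfig,
    params: DimensionlessParams,
    grid: GridSpec,
    horizon: Optional[float] = None,
    integrator: Optional[IntegratorSpec] = None,
) -> SimulationDataset:
    """Integrate the discrete physics with an arbitrary switch evaluator.

    The evaluator (a trained net, the parametric ramp, or a benchmark
    model) is treated as a one-input/two-output black box inside the
    stepper (classical RK4 by default).  ``horizon`` may exceed the
    duration the training data covered.
    """
    if horizon is not None and horizon != grid.tau_star:
        grid = build_grid(grid.l, grid.dxi, horizon, grid.dtau)
    return simulate_with_stepper(
        config, params, pi_evaluator, grid, integrator or RK4_TABLEAU
    )


def cell_error(
    pred: SimulationDataset, truth: SimulationDataset, at_tau: float
) -> float:
    """L2 distance between cell profiles at time ``at_tau`` over the chamber."""
    if pred.grid.n_x != truth.grid.n_x or pred.grid.dxi != truth.grid.dxi:
        raise ValueError("grid mismatch between prediction and truth")
    diffs = []
    for ds in (pred, truth):
        idx = at_tau / ds.grid.dtau
        if abs(idx - round(idx)) > 1e-9 or not 0 <= round(idx) < ds.grid.n_t:
            raise ValueError(f"tau={at_tau} not stored in dataset")
        diffs.append(ds.data[int(round(idx)), :, 0])
    d = diffs[0] - diffs[1]
    return float(np.sqrt(np.trapezoid(d**2, dx=pred.grid.dxi)))


# ---------------------------------------------------------------------------
# the four-family benchmark study
# ---------------------------------------------------------------------------

_FAMILY_PARAMS = {
    "heaviside": GoGrowParams(theta=2.0),
    "relu": GoGrowParams(theta=2.0),
    "michaelis_menten": GoGrowParams(k=2.0),
    "logistic": GoGrowParams(theta=2.0, delta_theta=2.0),
}


@dataclass(frozen=True)
class StudyConfig:
    """Scope and budgets of the recovery/prediction study."""

    families: tuple[str, ...] = tuple(_FAMILY_PARAMS)
    seeds: tuple[int, ...] = (0, 1, 2)
    epochs: int = 1000
    scenarios: tuple[PredictionScenario, ...] = DEFAULT_SCENARIOS
    eval_taus: tuple[float, ...] = (10.0, 20.0)
    include_prediction: bool = True


@dataclass
class EvaluationReport:
    """Tidy table of all computed errors plus study metadata."""

    table: pd.DataFrame
    metadata: dict = field(default_factory=dict)

    def median(self, family: str, method: str, metric: str, **filters) -> float:
        mask = (
            (self.table.family == family)
            & (self.table.method == method)
            & (self.table.metric == metric)
        )
        for col, val in filters.items():
            mask &= self.table[col] == val
        return float(self.table.loc[mask, "value"].median())

    def to_csv(self, path) -> None:
        self.table.to_csv(path, index=False)


def _study_grid() -> GridSpec:
    return build_grid(l=50.0, dxi=1.0, tau_star=10.0, dtau=0.01)


def run_benchmark_study(
    study: Optional[StudyConfig] = None,
    params: Optional[DimensionlessParams] = None,
    grid: Optional[GridSpec] = None,
    progress: Optional[Callable[[str], None]] = None,
) -> EvaluationReport:
    """Generate -> train -> evaluate for every ground-truth family and seed.

    Per (family, seed): the full experiment battery is simulated with the
    ground-truth switch, both learners are trained on it, the recovery
    errors ``E_pi`` (both components) and sup deviations are computed, and
    — if enabled — rollout prediction errors ``E_cell`` for each scenario
    at each evaluation time.  Failures in any cell of the table are
    recorded (value NaN, error message in the ``note`` column) and the
    study continues.
    """
    study = study or StudyConfig()
    params = params or DimensionlessParams()
    grid = grid or _study_grid()
    say = progress or (lambda msg: None)
    rows: list[dict] = []

    def add(family, method, seed, metric, value, scenario="", tau=np.nan, note=""):
        rows.append(
            dict(
                family=family, method=method, seed=seed, metric=metric,
                scenario=scenario, tau=tau, value=value, note=note,
            )
        )

    truth_rollouts: dict[tuple, SimulationDataset] = {}
    for family in study.families:
        truth = make_benchmark(family, _FAMILY_PARAMS[family])
        say(f"[{family}] generating battery")
        battery = run_experiment_battery(params, truth, grid)
        if study.include_prediction:
            for sc in study.scenarios:
                horizon = max(study.eval_taus + (sc.horizon,))
                ref_grid = build_grid(grid.l, grid.dxi, horizon, grid.dtau)
                truth_rollouts[(family, sc.name)] = generate_reference_dataset(
                    sc.config(), params, truth, ref_grid
                )
        for seed in study.seeds:
            cfg = TrainingConfig(epochs=study.epochs, seed=seed)
            for method, fit in (
                ("pgnniv", train_pgnniv),
                ("parametric", fit_parametric_baseline),
            ):
                say(f"[{family}] seed {seed}: training {method}")
                try:
                    learned, _hist = fit(battery, cfg, params=params)
                except Exception as exc:  # noqa: BLE001
                    add(family, method, seed, "E_pi_gr", np.nan, note=str(exc))
                    continue
                e_go, e_gr = model_error(learned, truth)
                dev_go, dev_gr = max_deviation(learned, truth)
                add(family, method, seed, "E_pi_go", e_go)
                add(family, method, seed, "E_pi_gr", e_gr)
                add(family, method, seed, "max_dev_go", dev_go)
                add(family, method, seed, "max_dev_gr", dev_gr)
                if not study.include_prediction:
                    continue
                for sc in study.scenarios:
                    truth_ds = truth_rollouts[(family, sc.name)]
                    try:
                        pred = rollout(
                            learned, sc.config(), params, grid,
                            horizon=truth_ds.grid.tau_star,
                        )
                        for tau in study.eval_taus:
                            add(
                                family, method, seed, "E_cell",
                                cell_error(pred, truth_ds, tau),
                                scenario=sc.name, tau=tau,
                            )
                    except Exception as exc:  # noqa: BLE001
                        for tau in study.eval_taus:
                            add(
                                family, method, seed, "E_cell", np.nan,
                                scenario=sc.name, tau=tau, note=str(exc),
                            )
    table = pd.DataFrame(rows)
    return EvaluationReport(
        table=table,
        metadata={
            "families": study.families,
            "seeds": study.seeds,
            "epochs": study.epochs,
            "grid": dict(
                n_x=grid.n_x, n_t=grid.n_t, dxi=grid.dxi, dtau=grid.dtau
            ),
        },
    )
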