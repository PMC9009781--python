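"""Go-or-grow metabolic switch families.

Glioblastoma cells are believed to trade migration against proliferation
depending on local oxygen tension (the *go-or-grow* hypothesis): under
hypoxia cells migrate towards better-oxygenated regions, under normoxia
they proliferate.  In the population model this switch enters through two
dimensionless activation functions of the oxygen concentration ``u2``,

* ``pi_go(u2)`` — modulates chemotactic migration, nonincreasing in oxygen;
* ``pi_gr(u2)`` — modulates logistic proliferation, nondecreasing in oxygen;

both bounded in [0, 1].  This module provides the four closed-form
benchmark families used as ground truths for data generation and recovery
experiments (binary step, piecewise-linear ramp, Michaelis–Menten,
logistic/tanh), all complementary (``pi_go + pi_gr = 1``), plus support
for arbitrary user-supplied switch models.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Callable, Optional

import numpy as np

__all__ = [
    "BENCHMARK_FAMILIES",
    "GoGrowParams",
    "GoGrowModel",
    "make_benchmark",
    "eval_pi",
    "verify_model_properties",
    "export_pi_csv",
]

BENCHMARK_FAMILIES = ("heaviside", "relu", "michaelis_menten", "logistic")


@dataclass(frozen=True)
class GoGrowParams:
    """Dimensionless parameters of a switch family.

    Attributes
    ----------
    theta : float, optional
        Oxygen threshold of the step / ramp / logistic transition.
    delta_theta : float, optional
        Transition width of the logistic family.
    k : float, optional
        Half-saturation constant of the Michaelis–Menten family.
    """

    theta: Optional[float] = None
    delta_theta: Optional[float] = None
    k: Optional[float] = None

    def __post_init__(self) -> None:
        for name in ("theta", "delta_theta", "k"):
            value = getattr(self, name)
            if value is not None and not (np.isfinite(value) and value > 0):
                raise ValueError(f"{name} must be strictly positive, got {value!r}")

    def require(self, *names: str) -> None:
        missing = [n for n in names if getattr(self, n) is None]
        if missing:
            raise ValueError(f"missing required parameter(s): {', '.join(missing)}")


@dataclass(frozen=True)
class GoGrowModel:
    """A named switch model mapping oxygen to the pair (pi_go, pi_gr).

    ``evaluator`` maps a nonnegative float array to an array of shape
    ``x.shape + (2,)`` with components (pi_go, pi_gr).  Negative inputs
    (transients of an explicit time stepper) are clamped to zero before
    evaluation, matching the ``u2 <= 0`` branch of the ramp definitions.
    """

    family: str
    params: GoGrowParams = field(default_factory=GoGrowParams)
    evaluator: Callable[[np.ndarray], np.ndarray] = None  # type: ignore[assignment]

    def __call__(self, x):
        return eval_pi(self, x)


def _heaviside(theta: float) -> Callable[[np.ndarray], np.ndarray]:
    # right-closed convention: pi_gr = 1 at exactly x = theta
    def ev(x: np.ndarray) -> np.ndarray:
        gr = (x >= theta).astype(float)
        return np.stack([1.0 - gr, gr], axis=-1)

    return ev


def _relu(theta: float) -> Callable[[np.ndarray], np.ndarray]:
    def ev(x: np.ndarray) -> np.ndarray:
        gr = np.clip(x / theta, 0.0, 1.0)
        return np.stack([1.0 - gr, gr], axis=-1)

    return ev


def _michaelis_menten(k: float) -> Callable[[np.ndarray], np.ndarray]:
    def ev(x: np.ndarray) -> np.ndarray:
        gr = x / (x + k)
        return np.stack([1.0 - gr, gr], axis=-1)

    return ev


def _logistic(theta: float, delta_theta: float, printed_orientation: bool) -> Callable:
    def ev(x: np.ndarray) -> np.ndarray:
        s = 0.5 * (1.0 + np.tanh((x - theta) / delta_theta))
        go = s if printed_orientation else 1.0 - s
        return np.stack([go, 1.0 - go], axis=-1)

    return ev


def make_benchmark(
    family: str,
    params: GoGrowParams | None = None,
    *,
    printed_orientation: bool = False,
    **kwargs: float,
) -> GoGrowModel:
    """Build one of the four closed-form benchmark switch models.

    Parameters
    ----------
    family : {"heaviside", "relu", "michaelis_menten", "logistic"}
    params : GoGrowParams, optional
        May instead be given as keyword arguments (``theta=2`` etc.).
    printed_orientation : bool
        The logistic family admits two sign conventions; the default makes
        ``pi_go`` nonincreasing in oxygen, consistent with the other three
        families.  Set True for the opposite (increasing ``pi_go``)
        orientation.

    Returns
    -------
    GoGrowModel
        Complementary model (``pi_go + pi_gr = 1`` pointwise).
    """
    if params is None:
        params = GoGrowParams(**kwargs)
    elif kwargs:
        raise TypeError("pass either a GoGrowParams or keyword parameters, not both")

    if family == "heaviside":
        params.require("theta")
        ev = _heaviside(params.theta)
    elif family == "relu":
        params.require("theta")
        ev = _relu(params.theta)
    elif family == "michaelis_menten":
        params.require("k")
        ev = _michaelis_menten(params.k)
    elif family == "logistic":
        params.require("theta", "delta_theta")
        ev = _logistic(params.theta, params.delta_theta, printed_orientation)
    else:
        raise ValueError(
            f"unknown family {family!r}; expected one of {BENCHMARK_FAMILIES}"
        )
    return GoGrowModel(family=family, params=params, evaluator=ev)


def make_custom(
    evaluator: Callable[[np.ndarray], np.ndarray],
    params: GoGrowParams | None = None,
) -> GoGrowModel:
    """Wrap an arbitrary oxygen -> (pi_go, pi_gr) map as a GoGrowModel."""
    return GoGrowModel(
        family="custom", params=params or GoGrowParams(), evaluator=evaluator
    )


def eval_pi(model: GoGrowModel, x) -> np.ndarray:
    """Evaluate (pi_go, pi_gr) at scalar or vector oxygen values.

    Vector input maps elementwise (the switch is pointwise in space).
    Negative values are clamped to zero; non-finite input raises.
    """
    arr = np.asarray(x, dtype=float)
    if not np.all(np.isfinite(arr)):
        raise ValueError("oxygen input must be finite")
    out = model.evaluator(np.maximum(arr, 0.0))
    return out


def verify_model_properties(model: GoGrowModel, grid) -> dict:
    """Check range, monotonicity and complementarity on an oxygen grid.

    Parameters
    ----------
    grid : array_like
        Sorted ascending, nonnegative oxygen values (at least one point).

    Returns
    -------
    dict with booleans ``range_ok``, ``go_nonincreasing``,
    ``gr_nondecreasing``, ``complementarity`` (the latter to 1e-12).
    """
    g = np.asarray(grid, dtype=float)
    if g.size == 0:
        raise ValueError("empty oxygen grid")
    if np.any(np.diff(g) < 0) or np.any(g < 0):
        raise ValueError("grid must be sorted ascending and nonnegative")
    pi = eval_pi(model, g)
    go, gr = pi[..., 0], pi[..., 1]
    return {
        "range_ok": bool(np.all((pi >= 0.0) & (pi <= 1.0))),
        "go_nonincreasing": bool(np.all(np.diff(go) <= 1e-12)),
        "gr_nondecreasing": bool(np.all(np.diff(gr) >= -1e-12)),
        "complementarity": bool(np.all(np.abs(go + gr - 1.0) <= 1e-12)),
    }


def export_pi_csv(model, path, upper: float = 5.0, n: int = 501) -> int:
    """Write a sampled (x, pi_go, pi_gr) table; returns the row count.

    Accepts a GoGrowModel or any trained switch exposing ``eval_pairs``.
    """
    x = np.linspace(0.0, upper, n)
    pi = eval_pi(model, x) if isinstance(model, GoGrowModel) else model.eval_pairs(x)
    header = "x,pi_go,pi_gr"
    np.savetxt(
        path,
        np.column_stack([x, pi[:, 0], pi[:, 1]]),
        delimiter=",",
        header=header,
        comments="",
    )
    return n
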