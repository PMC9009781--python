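"""Physics-guided network with internal variables for switch discovery.

The learning problem: given space-time snapshots of cell density and
oxygen at consecutive times, recover the hidden metabolic switch
``u2 -> (pi_go, pi_gr)``.  The pair is never observed — it is an internal
variable constrained only through the discrete physics.  The predictive
pipeline Y composes an *explanatory* subnetwork H (two small multilayer
perceptrons applied pointwise at every spatial node, like a width-1
convolution over collocation points) with the known finite-difference
operators and an explicit Euler step:

    u_hat^{n+1} = u^n + dtau * F(u^n, H(u2^n))

and the loss is the summed squared mismatch between predicted and observed
next states — equivalently the squared norm of the discrete-physics
residual.  Because the stepper is explicit, the gradient of the loss with
respect to the network parameters factors through the nodal (pi_go, pi_gr)
values analytically; backpropagation through the two perceptron heads is
implemented here directly (the network is tiny: 97 weights per head).

The single-parameter baseline replaces H by the complementary linear ramp
family with one trainable threshold ``theta``, trained by the identical
pipeline, for the parametric-vs-nonparametric comparison.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np

from .gogrow import GoGrowModel
from .simulate import (
    DimensionlessParams,
    ExperimentConfig,
    FieldState,
    GridSpec,
    IntegratorSpec,
    SimulationDataset,
    SpatialOperators,
    step_generalized_midpoint,
)

__all__ = [
    "ExplanatoryNet",
    "ParametricRamp",
    "TrainingConfig",
    "TrainingHistory",
    "init_explanatory_net",
    "explanatory_forward",
    "predict_step",
    "pgnniv_loss",
    "pgnniv_loss_and_grad",
    "residual",
    "train_pgnniv",
    "fit_parametric_baseline",
]


# ---------------------------------------------------------------------------
# explanatory subnetwork: two pointwise perceptron heads
# ---------------------------------------------------------------------------

def _sigmoid(z: np.ndarray) -> np.ndarray:
    out = np.empty_like(z)
    pos = z >= 0
    out[pos] = 1.0 / (1.0 + np.exp(-z[pos]))
    ez = np.exp(z[~pos])
    out[~pos] = ez / (1.0 + ez)
    return out


class _MLPHead:
    """Scalar-in/scalar-out perceptron: tanh hidden layers, logistic output."""

    def __init__(self, widths: Sequence[int], rng: np.random.Generator):
        if widths[0] != 1 or widths[-1] != 1 or any(w <= 0 for w in widths):
            raise ValueError("head widths must be positive with scalar input/output")
        self.widths = tuple(int(w) for w in widths)
        self.W: list[np.ndarray] = []
        self.b: list[np.ndarray] = []
        for fan_in, fan_out in zip(self.widths[:-1], self.widths[1:]):
            # variance-scaling (Glorot) uniform initialization
            limit = np.sqrt(6.0 / (fan_in + fan_out))
            self.W.append(rng.uniform(-limit, limit, size=(fan_out, fan_in)))
            self.b.append(np.zeros(fan_out))

    @property
    def n_params(self) -> int:
        return sum(w.size + b.size for w, b in zip(self.W, self.b))

    def forward(self, x: np.ndarray):
        """x: flat sample vector -> (output in [0,1], cache for backward)."""
        a = x[:, None]
        activations = [a]
        for i, (W, b) in enumerate(zip(self.W, self.b)):
            z = a @ W.T + b
            a = _sigmoid(z) if i == len(self.W) - 1 else np.tanh(z)
            activations.append(a)
        return a[:, 0], activations

    def backward(self, activations, d_out: np.ndarray):
        """Accumulate parameter grads given dL/d(output); returns grad lists."""
        out = activations[-1][:, 0]
        delta = (d_out * out * (1.0 - out))[:, None]  # logistic derivative
        gW = [np.empty_like(w) for w in self.W]
        gb = [np.empty_like(b) for b in self.b]
        for i in range(len(self.W) - 1, -1, -1):
            a_prev = activations[i]
            gW[i] = delta.T @ a_prev
            gb[i] = delta.sum(axis=0)
            if i > 0:
                delta = (delta @ self.W[i]) * (1.0 - activations[i] ** 2)
        return gW, gb


class ExplanatoryNet:
    """Juxtaposition of two perceptrons mapping oxygen to (pi_go, pi_gr).

    Applied independently at every spatial node; outputs squashed to [0, 1]
    by the logistic output activation.  No complementarity constraint is
    imposed — whether pi_go + pi_gr = 1 holds is left for the data to
    reveal.
    """

    def __init__(self, widths: Sequence[int] = (1, 8, 8, 1), seed: int = 0):
        rng = np.random.default_rng(seed)
        self.widths = tuple(int(w) for w in widths)
        self.head_go = _MLPHead(self.widths, rng)
        self.head_gr = _MLPHead(self.widths, rng)
        self.seed = seed

    @property
    def n_params(self) -> int:
        return self.head_go.n_params + self.head_gr.n_params

    # -- flat parameter vector (optimizer / serialization / FD checks) -----
    def get_flat(self) -> np.ndarray:
        chunks = []
        for head in (self.head_go, self.head_gr):
            for W, b in zip(head.W, head.b):
                chunks.append(W.ravel())
                chunks.append(b.ravel())
        return np.concatenate(chunks)

    def set_flat(self, theta: np.ndarray) -> None:
        i = 0
        for head in (self.head_go, self.head_gr):
            for li in range(len(head.W)):
                for arr in (head.W[li], head.b[li]):
                    arr.flat[:] = theta[i : i + arr.size]
                    i += arr.size
        if i != theta.size:
            raise ValueError("flat parameter vector has wrong length")

    @staticmethod
    def _flatten_grads(grads) -> np.ndarray:
        chunks = []
        for gW, gb in grads:
            for w, b in zip(gW, gb):
                chunks.append(w.ravel())
                chunks.append(b.ravel())
        return np.concatenate(chunks)

    # -- evaluation --------------------------------------------------------
    def forward(self, u2_flat: np.ndarray):
        go, cache_go = self.head_go.forward(u2_flat)
        gr, cache_gr = self.head_gr.forward(u2_flat)
        return go, gr, (cache_go, cache_gr)

    def backward(self, cache, d_go: np.ndarray, d_gr: np.ndarray) -> np.ndarray:
        cache_go, cache_gr = cache
        g_go = self.head_go.backward(cache_go, d_go)
        g_gr = self.head_gr.backward(cache_gr, d_gr)
        return self._flatten_grads([g_go, g_gr])

    def eval_pairs(self, u2) -> np.ndarray:
        """Nodal [n, 2] switch values; the simulator duck-types on this."""
        u2 = np.asarray(u2, dtype=float)
        if not np.all(np.isfinite(u2)):
            raise ValueError("non-finite oxygen input")
        flat = u2.ravel()
        go, gr, _ = self.forward(flat)
        return np.stack([go, gr], axis=-1).reshape(u2.shape + (2,))


class ParametricRamp:
    """Single-parameter complementary ramp switch (trainable threshold).

    pi_gr = clip(u2/theta, 0, 1), pi_go = 1 - pi_gr: the classical
    hypoxic-threshold model with theta_go = theta_gr = theta.
    """

    def __init__(self, theta: float = 1.0):
        if theta <= 0:
            raise ValueError("theta must be positive")
        self.theta = float(theta)

    n_params = 1

    def eval_pairs(self, u2) -> np.ndarray:
        u2 = np.asarray(u2, dtype=float)
        gr = np.clip(np.maximum(u2, 0.0) / self.theta, 0.0, 1.0)
        return np.stack([1.0 - gr, gr], axis=-1)

    def forward(self, u2_flat: np.ndarray):
        x = np.maximum(u2_flat, 0.0)
        gr = np.clip(x / self.theta, 0.0, 1.0)
        return 1.0 - gr, gr, x

    def backward(self, cache, d_go: np.ndarray, d_gr: np.ndarray) -> np.ndarray:
        x = cache
        active = (x > 0.0) & (x < self.theta)
        dgr_dtheta = np.where(active, -x / self.theta**2, 0.0)
        return np.array([np.sum((d_gr - d_go) * dgr_dtheta)])

    def get_flat(self) -> np.ndarray:
        return np.array([self.theta])

    def set_flat(self, theta: np.ndarray) -> None:
        self.theta = float(max(theta[0], 1e-6))  # keep the threshold positive


def init_explanatory_net(
    widths: Sequence[int] = (1, 8, 8, 1), seed: int = 0
) -> ExplanatoryNet:
    """Seeded explanatory network (default two 1-8-8-1 heads, 194 params)."""
    return ExplanatoryNet(widths=widths, seed=seed)


def explanatory_forward(net: ExplanatoryNet, u2_nodal) -> np.ndarray:
    """Nodal switch pairs [n_x, 2]; pointwise (row j sees only u2[j])."""
    return net.eval_pairs(u2_nodal)


# ---------------------------------------------------------------------------
# physics-composed prediction, loss, residual
# ---------------------------------------------------------------------------

def predict_step(
    net,
    state: FieldState,
    params: DimensionlessParams,
    grid: GridSpec,
    integrator: Optional[IntegratorSpec] = None,
    config: Optional[ExperimentConfig] = None,
    ops: Optional[SpatialOperators] = None,
) -> FieldState:
    """One predicted state: the explanatory net composed with the stepper."""
    integrator = integrator or IntegratorSpec(beta=1.0)
    ops = ops or SpatialOperators(grid)
    return step_generalized_midpoint(
        state, params, net, grid.dtau, integrator.beta, config=config, ops=ops
    )


class _PhysicsWorkspace:
    """Cached operators and vectorized batched Euler prediction."""

    def __init__(self, params: DimensionlessParams, grid: GridSpec):
        self.params = params
        self.grid = grid
        ops = SpatialOperators(grid)
        self.Dt = ops.D.T
        self.At = ops.A.T
        self.DDt = ops.DD.T
        self.A = ops.A

    def predict(self, u1, u2, pi_go, pi_gr):
        """Batched explicit Euler prediction; all arrays [B, n_x]."""
        p, dt = self.params, self.grid.dtau
        du1dx = u1 @ self.Dt
        du2dx = u2 @ self.Dt
        f1 = p.D1 * du1dx - p.chi * pi_go * u1 * du2dx
        growth = p.alpha1 * pi_gr * u1 * (1.0 - u1 / p.cs)
        u1_hat = u1 + dt * (f1 @ self.At + growth)
        du2 = p.D2 * (u2 @ self.DDt) - p.alpha2 * (u2 / (u2 + p.km)) * u1
        du2[:, 0] = 0.0
        du2[:, -1] = 0.0
        u2_hat = u2 + dt * du2
        return u1_hat, u2_hat, du2dx


def pgnniv_loss_and_grad(
    model,
    inputs: np.ndarray,
    targets: np.ndarray,
    ws: _PhysicsWorkspace,
    reduction: str = "sum",
    complementarity_penalty: float = 0.0,
):
    """Loss and its gradient w.r.t. the trainable parameters.

    ``inputs``/``targets`` are [B, n_x, 2] consecutive-pair arrays.  With
    the explicit (beta = 1) stepper only the cell-channel prediction
    depends on the switch, through (a) the growth term, diagonally in
    pi_gr, and (b) the chemotactic flux divergence, linearly in pi_go; both
    adjoints are formed in closed form before backpropagating through the
    pointwise heads.

    ``complementarity_penalty`` optionally adds p * sum (pi_go + pi_gr - 1)^2,
    a soft energetic-budget constraint tying the two heads; zero (off) by
    default — the relation between the heads is normally left to the data.
    """
    if inputs.size == 0:
        raise ValueError("empty batch")
    u1, u2 = inputs[..., 0], inputs[..., 1]
    B, n = u1.shape
    go_flat, gr_flat, cache = model.forward(u2.ravel())
    pi_go = go_flat.reshape(B, n)
    pi_gr = gr_flat.reshape(B, n)
    u1_hat, u2_hat, du2dx = ws.predict(u1, u2, pi_go, pi_gr)
    r1 = u1_hat - targets[..., 0]
    r2 = u2_hat - targets[..., 1]
    loss = float(np.sum(r1**2) + np.sum(r2**2))
    scale = 1.0
    if reduction == "mean":
        scale = 1.0 / (B * n)
        loss *= scale
    elif reduction != "sum":
        raise ValueError("reduction must be 'sum' or 'mean'")

    p, dt = ws.params, ws.grid.dtau
    d_hat1 = (2.0 * scale * dt) * r1
    d_pi_gr = d_hat1 * p.alpha1 * u1 * (1.0 - u1 / p.cs)
    d_f1 = d_hat1 @ ws.A  # adjoint of f1 @ A^T
    d_pi_go = d_f1 * (-p.chi * u1 * du2dx)
    if complementarity_penalty > 0.0:
        c = pi_go + pi_gr - 1.0
        loss += complementarity_penalty * scale * float(np.sum(c**2))
        d_c = (2.0 * complementarity_penalty * scale) * c
        d_pi_go = d_pi_go + d_c
        d_pi_gr = d_pi_gr + d_c
    grad = model.backward(cache, d_pi_go.ravel(), d_pi_gr.ravel())
    if not np.isfinite(loss):
        raise FloatingPointError("non-finite training loss")
    return loss, grad


def pgnniv_loss(
    net,
    batch: tuple[np.ndarray, np.ndarray],
    params: DimensionlessParams,
    grid: GridSpec,
    reduction: str = "sum",
    complementarity_penalty: float = 0.0,
) -> float:
    """Summed squared one-step prediction error over a batch of pairs."""
    inputs, targets = batch
    ws = _PhysicsWorkspace(params, grid)
    loss, _ = pgnniv_loss_and_grad(
        net, inputs, targets, ws, reduction, complementarity_penalty
    )
    return loss


def residual(
    u_n: FieldState,
    u_np1: FieldState,
    model,
    params: DimensionlessParams,
    grid: GridSpec,
    beta: float = 1.0,
) -> np.ndarray:
    """Discrete-physics residual R(u^n, u^{n+1}) as an [n_x, 2] array.

    R = u^{n+1} - u^n - dtau * F(beta u^n + (1-beta) u^{n+1}, Pi), with the
    switch evaluated at the same convex combination.  Zero exactly when the
    pair satisfies the generalized-midpoint update under the given switch.
    """
    from .simulate import semidiscrete_rhs  # local import to avoid cycle noise

    ops = SpatialOperators(grid)
    mid = FieldState(
        u1=beta * u_n.u1 + (1.0 - beta) * u_np1.u1,
        u2=beta * u_n.u2 + (1.0 - beta) * u_np1.u2,
        tau=u_n.tau,
    )
    du1, du2 = semidiscrete_rhs(mid, params, model, ops)
    R1 = u_np1.u1 - u_n.u1 - grid.dtau * du1
    R2 = u_np1.u2 - u_n.u2 - grid.dtau * du2
    return np.stack([R1, R2], axis=-1)


# ---------------------------------------------------------------------------
# training
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class TrainingConfig:
    """Optimization protocol for both the network and the baseline.

    Defaults follow the benchmark protocol: Adam with learning rate 0.001
    and unusually low exponential-decay rates beta1 = beta2 = 0.8, a fixed
    budget of ``epochs`` passes over the experiment batches (one parameter
    update per batch, batches visited in a fresh random order each epoch),
    and a seeded 80/20 train/held-out split of the pairs within each batch.
    """

    epochs: int = 1000
    learning_rate: float = 0.001
    adam_beta1: float = 0.8
    adam_beta2: float = 0.8
    adam_eps: float = 1e-8
    train_fraction: float = 0.8
    seed: int = 0
    beta: float = 1.0  # integrator beta; training requires the explicit scheme
    loss_reduction: str = "sum"
    hidden_widths: tuple[int, ...] = (1, 8, 8, 1)
    complementarity_penalty: float = 0.0  # optional pi_go + pi_gr = 1 tie

    def __post_init__(self) -> None:
        if not 0.0 < self.train_fraction < 1.0:
            raise ValueError("train_fraction must lie in (0, 1)")
        if self.complementarity_penalty < 0.0:
            raise ValueError("complementarity_penalty must be nonnegative")
        if self.learning_rate <= 0 or self.epochs <= 0:
            raise ValueError("learning rate and epochs must be positive")
        if self.beta != 1.0:
            raise ValueError("training supports only the explicit beta = 1 stepper")


@dataclass
class TrainingHistory:
    """Per-update train losses, per-epoch held-out losses, final params."""

    train_losses: list = field(default_factory=list)
    holdout_losses: list = field(default_factory=list)
    final_params: Optional[np.ndarray] = None
    seed: int = 0
    config: Optional[TrainingConfig] = None

    @property
    def n_updates(self) -> int:
        return len(self.train_losses)


class _Adam:
    def __init__(self, n: int, cfg: TrainingConfig):
        self.m = np.zeros(n)
        self.v = np.zeros(n)
        self.t = 0
        self.cfg = cfg

    def step(self, theta: np.ndarray, grad: np.ndarray) -> np.ndarray:
        c = self.cfg
        self.t += 1
        self.m = c.adam_beta1 * self.m + (1 - c.adam_beta1) * grad
        self.v = c.adam_beta2 * self.v + (1 - c.adam_beta2) * grad**2
        m_hat = self.m / (1 - c.adam_beta1**self.t)
        v_hat = self.v / (1 - c.adam_beta2**self.t)
        return theta - c.learning_rate * m_hat / (np.sqrt(v_hat) + c.adam_eps)


def _prepare_batches(datasets: Sequence[SimulationDataset], cfg: TrainingConfig):
    """Per-dataset (train_inputs, train_targets, holdout_inputs, holdout_targets)."""
    rng = np.random.default_rng(cfg.seed)
    batches = []
    for ds in datasets:
        inputs, targets = ds.pairs()
        n_pairs = inputs.shape[0]
        perm = rng.permutation(n_pairs)
        n_train = int(round(cfg.train_fraction * n_pairs))
        n_train = min(max(n_train, 1), n_pairs - 1)
        tr, ho = perm[:n_train], perm[n_train:]
        batches.append((inputs[tr], targets[tr], inputs[ho], targets[ho]))
    return batches, rng


def _train(model, datasets, cfg: TrainingConfig) -> TrainingHistory:
    if not datasets:
        raise ValueError("need at least one dataset")
    grid = datasets[0].grid
    for ds in datasets:
        if ds.grid.n_x != grid.n_x or ds.grid.dtau != grid.dtau:
            raise ValueError("all datasets must share one space-time grid")
    batches, rng = _prepare_batches(datasets, cfg)
    history = TrainingHistory(seed=cfg.seed, config=cfg)
    theta = model.get_flat()
    opt = _Adam(theta.size, cfg)
    ws = _PhysicsWorkspace(datasets[0].physics_params, grid)
    M = len(batches)
    for _epoch in range(cfg.epochs):
        order = rng.permutation(M)  # batches sampled without replacement
        for k in order:
            tr_in, tr_tg, _, _ = batches[k]
            loss, grad = pgnniv_loss_and_grad(
                model, tr_in, tr_tg, ws, cfg.loss_reduction,
                cfg.complementarity_penalty,
            )
            theta = opt.step(theta, grad)
            model.set_flat(theta)
            history.train_losses.append(loss)
        holdout = 0.0
        for _, _, ho_in, ho_tg in batches:
            l_ho, _ = pgnniv_loss_and_grad(model, ho_in, ho_tg, ws, cfg.loss_reduction)
            holdout += l_ho
        history.holdout_losses.append(holdout)
    history.final_params = model.get_flat()
    return history


def _attach_physics(datasets, params: Optional[DimensionlessParams]):
    params = params or DimensionlessParams()
    for ds in datasets:
        ds.physics_params = params
    return params


def train_pgnniv(
    datasets: Sequence[SimulationDataset],
    config: Optional[TrainingConfig] = None,
    params: Optional[DimensionlessParams] = None,
) -> tuple[ExplanatoryNet, TrainingHistory]:
    """Train the explanatory network on a battery of experiment datasets.

    Each dataset is one batch; each epoch visits all batches in a fresh
    random order and performs one Adam update per batch on the training
    fraction of its consecutive-time pairs.  Deterministic given the seed.
    """
    config = config or TrainingConfig()
    _attach_physics(datasets, params)
    net = init_explanatory_net(config.hidden_widths, seed=config.seed)
    history = _train(net, datasets, config)
    return net, history


def fit_parametric_baseline(
    datasets: Sequence[SimulationDataset],
    config: Optional[TrainingConfig] = None,
    params: Optional[DimensionlessParams] = None,
    theta_init: float = 2.5,
) -> tuple[ParametricRamp, TrainingHistory]:
    """Fit the single-threshold ramp model with the identical pipeline.

    The threshold starts at the midpoint of the oxygen range the battery
    visits ([0, 5]), a neutral initialization given Adam's bounded step
    size.
    """
    config = config or TrainingConfig()
    _attach_physics(datasets, params)
    ramp = ParametricRamp(theta=theta_init)
    history = _train(ramp, datasets, config)
    return ramp, history
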