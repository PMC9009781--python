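# Methods

## The model

A glioblastoma culture in a 1-D microfluidic chamber of dimensionless
length `l` is described by a cell density `u1(ξ, τ)` and an oxygen
concentration `u2(ξ, τ)` obeying

```
∂u1/∂τ = ∂/∂ξ( D1 ∂u1/∂ξ − χ Π_go(u2) u1 ∂u2/∂ξ ) + α1 Π_gr(u2) u1 (1 − u1/cs)
∂u2/∂τ = D2 ∂²u2/∂ξ² − α2 (u2 / (u2 + km)) u1
```

Cells move by random pedesis (`D1`) and by chemotaxis up the oxygen
gradient (`χ`), and proliferate logistically (`α1`, carrying capacity
`cs`); oxygen diffuses (`D2`) and is consumed by cells with
Michaelis–Menten kinetics (`α2`, `km`). The go-or-grow hypothesis enters
through the two activation functions `Π_go` (nonincreasing in oxygen) and
`Π_gr` (nondecreasing), both in [0, 1]: under hypoxia migration is
switched on and proliferation off, under normoxia the reverse. Oxygen is
held at Dirichlet values at the two lateral channels; the chamber walls
are impermeable to cells (zero cell flux).

The pair `u2 ↦ (Π_go, Π_gr)` is the scientific unknown. It is not
measurable by any experiment — it only exists inside the balance
equations — which is what makes it an *internal variable*: the network
that represents it is supervised purely through the physics.

### Default parameters

All quantities are dimensionless (the `nondimensionalize` /
`redimensionalize` pair maps to and from physical units via
characteristic scales `T`, `L`, `U1`, `U2`). The data-generation values,
chosen so every biological term matters on the simulated horizon:

| parameter | meaning | default |
|---|---|---|
| `D1` | cell pedesis | 1 |
| `chi` | chemotactic sensitivity | 1 |
| `alpha1` | logistic growth rate | 0.5 |
| `cs` | carrying capacity | 10 |
| `D2` | oxygen diffusion | 1 |
| `alpha2` | consumption rate | 0.05 |
| `km` | Michaelis constant | 2 |
| `l` | chamber length | 50 |

Benchmark switch families (all complementary, `Π_go + Π_gr = 1`):
binary step (`θ = 2`), piecewise-linear ramp (`θ = 2`), Michaelis–Menten
(`k = 2`), logistic (`θ = 2`, `Δθ = 2`). The printed form of the logistic
family in the source material has `Π_go` *increasing* with oxygen, which
contradicts the stated monotonicity of the go-or-grow mechanism; the
default here uses `Π_go = ½(1 − tanh((x − θ)/Δθ))` and a
`printed_orientation` flag restores the other convention. The ramp family
saturates at 1 above the threshold (`Π_gr = clip(x/θ, 0, 1)`); the step
family is right-closed (`Π_gr(θ) = 1`).

## Discretization

Space: uniform nodes `ξ_j = j·Δξ` (defaults `Δξ = 1`, 51 nodes), with a
second-order first-derivative operator `D` (central interior, one-sided
second-order ends). The cell equation is advanced in divergence form: the
nodal flux `f1 = D1·Du1 − χ·Π_go⊙u1⊙Du2` is assembled, the wall values
are forced to zero (impermeability), and a divergence operator `A` is
applied whose wall rows use a mirrored ghost flux. This choice makes
`w·A = 0` for the trapezoidal quadrature weights `w`, so the discrete
cell mass is conserved *exactly* at the semidiscrete level whenever
growth vanishes — the natural discrete counterpart of the no-flux
condition. Oxygen diffusion applies `D` twice (matching the operator the
learning pipeline uses) and the two Dirichlet rows carry zero rate with
values re-imposed after every step.

Time: a generalized midpoint rule `y⁺ = y + Δτ f(βy + (1−β)y⁺)`
(`β = 1` forward Euler, `β = 0` backward Euler via damped fixed-point
iteration to 1e−10) and explicit Runge–Kutta tableaus (Euler, Heun,
classical RK4) with the switch re-evaluated at every stage. The explicit
stability bound `Δτ ≤ Δξ²/(2 max(D1, D2)) = 0.5` is comfortably met by
the default `Δτ = 0.01`.

Reference data are generated by adaptive stiff method-of-lines
integration (LSODA, rtol 1e−8, atol 1e−10) of the *same* 51-node spatial
operator, sampled every `Δτ = 0.01` up to `τ* = 10`, so the data and the
network physics share one discrete operator and the training loss floor
reflects only time-discretization error. Each dataset is a
`[n_t, n_x, 2]` array (1001 × 51 × 2 at defaults). The experiment battery
comprises eleven boundary-oxygen configurations `(O2L, O2R)`: symmetric
pairs at 0, 1, 2, 3, 4, 5 and gradient pairs (0,1), (2,0), (3,0), (4,0),
(5,0). Initial conditions: cells constant at 2, oxygen the linear
interpolant of the boundary values.

## The learning machinery

The explanatory subnetwork `H` is a juxtaposition of two independent
perceptrons `1 → 8 → 8 → 1` (tanh hidden, logistic output, 97 weights
each, 194 total), applied at every node — effectively a width-1
convolution over collocation points, so the architecture is independent
of the boundary conditions and one network can be trained on all
configurations at once. No complementarity constraint ties the two heads;
whether `Π_go + Π_gr = 1` is left for the data to reveal. (An optional
soft penalty `p‖Π_go + Π_gr − 1‖²` is available in the training
configuration for settings where an energetic-budget argument justifies
the tie; it is off by default.)

The predictive pipeline composes `H` with the known physics and one
explicit Euler step (`β = 1`):

```
û^{n+1} = u^n + Δτ · F(u^n, H(u2^n))
```

and the loss is `L = Σ_n Σ_i ‖û_i^{n+1} − u_i^{n+1}‖²`, identical to the
squared norm of the discrete-physics residual (both forms are implemented
and tested to agree). Because the stepper is explicit, `∂L/∂Π` is
analytic — diagonal in `Π_gr` through the growth term, and one divergence
adjoint in `Π_go` through the chemotactic flux — and backpropagation
through the two small heads is implemented directly in NumPy, verified
against central finite differences to better than 1e−5 relative. The
oxygen channel does not depend on `Π` but still enters the loss.

Training: each battery configuration is one batch (1000 consecutive-time
pairs); per epoch the eleven batches are visited in a fresh random order
without replacement with one Adam update per batch (learning rate 0.001,
β₁ = β₂ = 0.8); within each batch a seeded 80/20 split reserves held-out
pairs whose loss is recorded per epoch. A fixed epoch budget is used — no
early stopping. Initialization is variance-scaling uniform from the run
seed; everything downstream of the seed is deterministic.

The parametric baseline replaces `H` by the complementary linear ramp
with a single trainable threshold `θ` (the classical hypoxic-threshold
model with `θ_go = θ_gr = θ`), trained by the identical pipeline. The
threshold initializes at 2.5, the midpoint of the oxygen range the
battery visits, a neutral choice given Adam's bounded per-step movement.

## Evaluation

* `E_pi` — square root of the trapezoidal integral of the squared switch
  error over oxygen in [0, 5] (501 points), per component. [0, 5] is the
  range the battery actually visits; outside it the data carry no
  information about the switch.
* `E_cell` — square root of the integrated squared cell-profile
  difference across the chamber at an evaluation time, computed on the 51
  storage nodes. The prediction is a rollout: the learned switch is
  plugged as a black box into classical RK4 and integrated from the
  initial condition to horizon 20 — twice the training horizon — under
  three scenarios: hypoxic (0,0), gradient (0,4), normoxic (4,4). The
  truth is always the stiff reference solve with the ground-truth switch,
  so a perfect recovery scores only the stepper's own discretization
  error (measured < 5e−3 sup-norm at τ = 10). `E_cell` is reported at
  both τ = 10 and τ = 20; orderings are compared at τ = 10.

`run_benchmark_study` chains everything per ground-truth family and seed
and returns a tidy table; medians over seeds are the headline numbers.

## Problem sizes and budgets

Data generation always uses the full-size conditions (11 configurations,
51 nodes, `Δτ = 0.01`, `τ* = 10`). The acceptance-level study trains for
100 epochs (1 100 Adam updates) per model rather than the full 1000: at
the full budget a single network training occupies several minutes of a
single CPU, and the study covers 4 families × 3 seeds × 2 methods. At
100 epochs the ramp, Michaelis–Menten and logistic truths are recovered
to a pointwise band of ≲ 0.1 and all dominance orderings are already
stable; longer training mainly continues to sharpen transition regions.
The test fixture battery uses a coarse chamber (`l = 10`, `τ* = 0.5`,
3 configurations) generating in under two seconds.

## Known limitations

* A continuous network output cannot match the binary-step truth
  *pointwise* at its jump: the sup-norm deviation near `x = θ` remains
  ~0.5 no matter the budget (the integrated error `E_pi` still becomes
  small, and recovery away from the jump is accurate). This is a property
  of the estimator class, not of the training.
* Synthetic data are noise-free solver output on the same spatial grid
  the network uses; measurement noise, grid mismatch, imaging artifacts
  and cell-line variability present in real microfluidic data are not
  emulated, so passing tests certify the inverse machinery, not
  robustness to experimental error.
* The PDE coefficients are treated as known; only the switch is learned.
* The explicit-Euler residual (`β = 1`) is the only training scheme;
  implicit `β < 1` is supported for simulation but not for learning.
* 1-D geometry only; no positivity-preserving or flux-limited schemes.
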