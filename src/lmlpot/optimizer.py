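"""Continual resilient (CoRe) optimizer.

CoRe combines RPROP-style sign-based per-weight step sizes with Adam-style
bias-corrected moving averages, and adds three continual-learning devices:

* a step-dependent first-moment decay rate beta1(tau) that interpolates from
  an initial value beta1_a to a final value beta1_b through a Gaussian of
  width beta1_c,
* plasticity factors P in {0, 1} that freeze, per weight group, the
  n_frozen weights with the highest importance score once tau > t_hist,
* an importance score S accumulating each weight's estimated contribution
  to loss decrease (g * u * P * s), built as an equal-weight sum for the
  first t_hist steps and an exponential moving average afterwards,
* a multiplicative weight decay w <- w * (1 - d |u P s|) bounding weights
  to about 1/d in magnitude.

Each weight group (for an HDNNP: one element's weights of one type in one
layer) keeps its own step counter tau, which only advances when the group
receives a gradient -- a training subsample that lacks an element leaves
that element's networks untouched.

Well-known optimizers are exact special cases: Adam for
(beta1_a = beta1_b, n_frozen = 0, eta- = eta+ = 1, d = 0) with learning
rate s0, and sign-based RPROP without backtracking for
(beta1 = beta2 = 0, n_frozen = 0, d = 0).
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np

__all__ = ["CoReHyperparameters", "CoReGroupState", "CoReOptimizer", "beta1_schedule", "OptimizerError"]


class OptimizerError(RuntimeError):
    """Non-finite gradient or inconsistent optimizer configuration."""


@dataclass(frozen=True)
class CoReHyperparameters:
    """Per-group hyperparameters with the defaults recommended for HDNNPs."""

    beta1_a: float = 0.45
    beta1_b: float = 0.7
    beta1_c: float = 500.0
    beta2: float = 0.999
    epsilon: float = 1e-8
    eta_minus: float = 0.5
    eta_plus: float = 1.2
    s_min: float = 1e-6
    s_max: float = 1.0
    s0: float = 1e-3
    t_hist: int = 500
    n_frozen: int = 0
    weight_decay: float = 0.0
    sign_update: bool = False  # u = sgn(g) variant

    def __post_init__(self):
        if not (0 <= self.beta1_a < 1 and 0 <= self.beta1_b < 1 and 0 <= self.beta2 < 1):
            raise OptimizerError("decay rates must lie in [0, 1)")
        if self.beta1_c <= 0 or self.t_hist <= 0:
            raise OptimizerError("beta1_c and t_hist must be positive")
        if not (0 < self.eta_minus <= 1 <= self.eta_plus):
            raise OptimizerError("require 0 < eta- <= 1 <= eta+")
        if not (0 < self.s_min <= self.s0 <= self.s_max):
            raise OptimizerError("require 0 < s_min <= s0 <= s_max")
        if self.n_frozen < 0:
            raise OptimizerError("n_frozen must be >= 0")
        if not (0 <= self.weight_decay < 1.0 / self.s_max):
            raise OptimizerError("weight decay must lie in [0, 1/s_max)")


def beta1_schedule(tau: int, hp: CoReHyperparameters) -> float:
    """Gaussian interpolation from beta1_a (tau = 1) to beta1_b (tau -> inf)."""
    x = (tau - 1) / hp.beta1_c
    return hp.beta1_b + (hp.beta1_a - hp.beta1_b) * float(np.exp(-x * x))


@dataclass
class CoReGroupState:
    """Per-weight optimizer state for one weight group."""

    tau: int
    g: np.ndarray  # first-moment moving average
    h: np.ndarray  # second-moment moving average
    s: np.ndarray  # per-weight step size
    score: np.ndarray  # importance score S
    hp: CoReHyperparameters = field(default_factory=CoReHyperparameters)

    @classmethod
    def zeros(cls, shape, hp: CoReHyperparameters) -> "CoReGroupState":
        return cls(0, np.zeros(shape), np.zeros(shape), np.full(shape, hp.s0), np.zeros(shape), hp)


def _plasticity(state: CoReGroupState) -> np.ndarray:
    """P in {0, 1}: freeze the n_frozen highest-score weights after t_hist."""
    hp = state.hp
    p = np.ones_like(state.g)
    if state.tau <= hp.t_hist or hp.n_frozen == 0:
        return p
    if hp.n_frozen > state.g.size:
        raise OptimizerError("n_frozen exceeds the group size")
    flat = state.score.ravel()
    # highest scores win; ties broken by the lower flat index (stable)
    order = np.lexsort((np.arange(flat.size), -flat))
    p.ravel()[order[: hp.n_frozen]] = 0.0
    return p


class CoReOptimizer:
    """CoRe over a dictionary of named parameter arrays.

    ``params`` maps a group id to its (live) numpy array; updates happen in
    place. Per-group hyperparameter overrides are given via ``group_hp``.
    """

    def __init__(self, params: dict, hp: CoReHyperparameters | None = None, group_hp: dict | None = None):
        self.params = params
        base = hp or CoReHyperparameters()
        self.state: dict = {}
        for gid, arr in params.items():
            ghp = (group_hp or {}).get(gid, base)
            self.state[gid] = CoReGroupState.zeros(np.shape(arr), ghp)

    def step(self, grads: dict) -> None:
        """Apply one optimization step to every group present in ``grads``.

        Groups absent from ``grads`` keep their state and counter unchanged.
        """
        for gid, grad in grads.items():
            if grad is None:
                continue
            if gid not in self.params:
                raise OptimizerError(f"gradient for unknown weight group {gid!r}")
            grad = np.asarray(grad, dtype=float)
            if not np.all(np.isfinite(grad)):
                raise OptimizerError(f"non-finite gradient in weight group {gid!r}")
            st = self.state[gid]
            hp = st.hp
            st.tau += 1
            tau = st.tau
            b1 = beta1_schedule(tau, hp)
            g_prev = st.g.copy()
            st.g = b1 * st.g + (1.0 - b1) * grad
            st.h = hp.beta2 * st.h + (1.0 - hp.beta2) * grad * grad
            if hp.sign_update:
                u = np.sign(st.g)
            else:
                bc1 = 1.0 - b1**tau
                bc2 = 1.0 - hp.beta2**tau
                g_hat = st.g / bc1 if bc1 > 0 else st.g
                h_hat = st.h / bc2 if bc2 > 0 else st.h
                u = g_hat / (np.sqrt(h_hat) + hp.epsilon)
            p = _plasticity(st)
            # sign-based step-size adaptation; skipped where P, g or g_prev is 0
            prod = st.g * g_prev * p
            grow = prod > 0
            shrink = prod < 0
            st.s = np.where(grow, np.minimum(hp.eta_plus * st.s, hp.s_max), st.s)
            st.s = np.where(shrink, np.maximum(hp.eta_minus * st.s, hp.s_min), st.s)
            update = u * p * st.s
            w = self.params[gid]
            w *= 1.0 - hp.weight_decay * np.abs(update)
            w -= update
            # importance score: equal-weight sum for tau <= t_hist, EMA after
            contrib = st.g * update
            if tau <= hp.t_hist:
                st.score = st.score + contrib / hp.t_hist
            else:
                st.score = (1.0 - 1.0 / hp.t_hist) * st.score + contrib / hp.t_hist


def hdnnp_group_hyperparameters(model, base: CoReHyperparameters | None = None) -> dict:
    """Group-specific hyperparameters for an HDNNP following the published
    recipe: n_frozen = 1% of the group size for hidden-layer weights/biases
    (0 for the output layer and for alpha/beta); weight decay 0.1 for hidden
    layers, 0 for the output layer, 0.01 for alpha/beta."""
    base = base or CoReHyperparameters()
    group_hp = {}
    for (el, kind, layer), arr in model.parameters().items():
        net = model.networks[el]
        if kind in ("alpha", "beta"):
            group_hp[(el, kind, layer)] = replace(base, n_frozen=0, weight_decay=0.01)
        elif layer == net.n_layers - 1:  # output layer
            group_hp[(el, kind, layer)] = replace(base, n_frozen=0, weight_decay=0.0)
        else:
            group_hp[(el, kind, layer)] = replace(
                base, n_frozen=int(0.01 * arr.size), weight_decay=0.1
            )
    return group_hp
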