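"""High-dimensional neural network potential with trainable standardization.

The total energy of a conformation is the sum of atomic energy contributions,
one feed-forward network per chemical element evaluated on that atom's
descriptor vector G:

    E = sum_m sum_n  NN_m( alpha_m * (G_n^m - beta_m) )

The per-input shift ``beta`` (initialized to the mean descriptor value over
the initial training data) and scale ``alpha`` (initialized to the inverse
standard deviation) are trainable weights of their own, kept separate from
the layer weights. Hidden layers use the activation f(x) = 1.59223 tanh(x),
whose slope at the origin is close to one for standardized inputs; the
output neuron is linear.

Atomic forces are the negative gradient of the energy with respect to the
positions, obtained by chaining the network input gradient dE/dG with the
descriptor Jacobian dG/dr. Training on forces additionally needs the
derivative of that input gradient with respect to the weights; this module
implements the required forward-over-reverse pass explicitly (a tangent
propagation through the network followed by backpropagation through both
the primal and tangent computations), so no autodiff framework is needed.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .descriptors import DescriptorConfig, DescriptorMatrix, descriptor_matrix

__all__ = [
    "ACTIVATION_SCALE",
    "activation",
    "AtomicNetwork",
    "HDNNPModel",
    "init_model",
    "descriptor_stats",
    "total_energy",
    "forces",
    "energy_and_forces",
    "UnsupportedElementError",
]

ACTIVATION_SCALE = 1.59223

# alpha initialization is clamped to avoid huge scales on near-constant inputs
ALPHA_CLAMP = (1e-3, 1e3)


class UnsupportedElementError(KeyError):
    """A scored conformation contains an element without a network."""


def activation(x):
    """Scaled hyperbolic tangent, f(x) = 1.59223 tanh(x)."""
    return ACTIVATION_SCALE * np.tanh(x)


def _act_d(t):
    # derivative given t = tanh(x)
    return ACTIVATION_SCALE * (1.0 - t * t)


def _act_dd(t):
    # second derivative given t = tanh(x)
    return ACTIVATION_SCALE * (-2.0 * t * (1.0 - t * t))


@dataclass
class AtomicNetwork:
    """Feed-forward network for one element.

    ``weights[l]`` has shape (n_l, n_{l-1}) and ``biases[l]`` shape (n_l,);
    the last layer is the linear output neuron. ``alpha``/``beta`` hold the
    standardization scale/shift applied to the raw descriptor input.
    """

    layer_sizes: list[int]
    weights: list[np.ndarray]
    biases: list[np.ndarray]
    alpha: np.ndarray
    beta: np.ndarray

    @property
    def n_layers(self) -> int:
        return len(self.weights)

    def copy(self) -> "AtomicNetwork":
        return AtomicNetwork(
            list(self.layer_sizes),
            [w.copy() for w in self.weights],
            [b.copy() for b in self.biases],
            self.alpha.copy(),
            self.beta.copy(),
        )

    # ---- forward/backward machinery ------------------------------------

    def forward(self, G: np.ndarray):
        """Atomic energies for stacked descriptor rows G (n_atoms, n_G).

        Returns (y, cache); the cache holds the tanh values needed by the
        backward passes.
        """
        x = self.alpha * (G - self.beta)
        tanhs = []
        for l in range(self.n_layers - 1):
            a = x @ self.weights[l].T + self.biases[l]
            t = np.tanh(a)
            tanhs.append(t)
            x = ACTIVATION_SCALE * t
        y = x @ self.weights[-1].T + self.biases[-1]
        return y[:, 0], (G, tanhs)

    def input_gradient(self, cache):
        """dy/dG for every atom row, shape (n_atoms, n_G)."""
        G, tanhs = cache
        delta = np.repeat(self.weights[-1], len(G), axis=0)  # (n_atoms, n_{L-1})
        for l in range(self.n_layers - 2, -1, -1):
            delta = (delta * _act_d(tanhs[l])) @ self.weights[l]
        return delta * self.alpha

    def parameter_gradients(self, cache, c_e: np.ndarray, U: np.ndarray | None):
        """Gradient of Phi = sum_n [ c_e[n] * y_n + ydot_n(U[n]) ] w.r.t. all
        network parameters, where ydot is the directional derivative of y
        along descriptor tangent U[n] (forward-over-reverse pass).

        The first term carries the energy part of a loss gradient, the
        second the force part (U already contracted with the descriptor
        Jacobian and residual weights). Returns a dict with keys
        ("a", l) / ("b", l) / "alpha" / "beta".
        """
        G, tanhs = cache
        with_tangent = U is not None
        # -- primal forward is in the cache; recompute layer inputs --
        xs = [self.alpha * (G - self.beta)]
        for l in range(self.n_layers - 1):
            xs.append(ACTIVATION_SCALE * tanhs[l])
        # -- tangent forward --
        if with_tangent:
            xdots = [self.alpha * U]
            adots = []
            for l in range(self.n_layers - 1):
                adot = xdots[-1] @ self.weights[l].T
                adots.append(adot)
                xdots.append(_act_d(tanhs[l]) * adot)
        grads: dict = {}
        n_out = self.n_layers - 1
        # -- reverse through the output layer --
        ga = c_e @ xs[n_out]
        if with_tangent:
            ga = ga + xdots[n_out].sum(axis=0)
        grads[("a", n_out)] = np.atleast_2d(ga)
        grads[("b", n_out)] = np.array([c_e.sum()])
        dx = np.outer(c_e, self.weights[-1][0])
        dxdot = np.repeat(self.weights[-1], len(G), axis=0) if with_tangent else None
        # -- reverse through hidden layers --
        for l in range(self.n_layers - 2, -1, -1):
            fd = _act_d(tanhs[l])
            da = dx * fd
            if with_tangent:
                da = da + dxdot * _act_dd(tanhs[l]) * adots[l]
                dadot = dxdot * fd
                grads[("a", l)] = da.T @ xs[l] + dadot.T @ xdots[l]
            else:
                grads[("a", l)] = da.T @ xs[l]
            grads[("b", l)] = da.sum(axis=0)
            dx = da @ self.weights[l]
            if with_tangent:
                dxdot = dadot @ self.weights[l]
        # -- standardization weights --
        # x0 = alpha*(G-beta), x0dot = alpha*U
        grads["alpha"] = (dx * (G - self.beta)).sum(axis=0)
        if with_tangent:
            grads["alpha"] = grads["alpha"] + (dxdot * U).sum(axis=0)
        grads["beta"] = -(dx * self.alpha).sum(axis=0)
        return grads


@dataclass
class HDNNPModel:
    """Per-element atomic networks sharing one descriptor configuration."""

    networks: dict[str, AtomicNetwork]
    descriptor_config: DescriptorConfig
    metadata: dict = field(default_factory=dict)

    @property
    def elements(self) -> list[str]:
        return sorted(self.networks)

    def copy(self) -> "HDNNPModel":
        return HDNNPModel(
            {el: net.copy() for el, net in self.networks.items()},
            self.descriptor_config,
            dict(self.metadata),
        )

    def network_for(self, element: str) -> AtomicNetwork:
        try:
            return self.networks[element]
        except KeyError:
            raise UnsupportedElementError(
                f"no atomic network for element {element!r}"
            ) from None

    def parameters(self) -> dict:
        """Flat view of all trainable arrays keyed by (element, kind, layer).

        kind is "a"/"b" with a layer index, or "alpha"/"beta" (layer None).
        The returned arrays are the live parameter buffers.
        """
        params = {}
        for el, net in self.networks.items():
            for l in range(net.n_layers):
                params[(el, "a", l)] = net.weights[l]
                params[(el, "b", l)] = net.biases[l]
            params[(el, "alpha", None)] = net.alpha
            params[(el, "beta", None)] = net.beta
        return params


def descriptor_stats(dataset, config: DescriptorConfig) -> dict[str, tuple[np.ndarray, np.ndarray]]:
    """Per-element mean and standard deviation of descriptor values over all
    atoms of each element in the dataset."""
    rows: dict[str, list[np.ndarray]] = {}
    for conf in dataset:
        mat = descriptor_matrix(conf, config)
        for k, el in enumerate(conf.elements):
            rows.setdefault(el, []).append(mat.values[k])
    stats = {}
    for el, lst in rows.items():
        arr = np.array(lst)
        stats[el] = (arr.mean(axis=0), arr.std(axis=0))
    return stats


def init_model(
    stats: dict[str, tuple[np.ndarray, np.ndarray]],
    config: DescriptorConfig,
    hidden: tuple[int, ...] = (102, 61, 44),
    seed: int = 0,
) -> HDNNPModel:
    """Initialize one atomic network per element present in ``stats``.

    beta_i is set to the mean descriptor value, alpha_i to the inverse
    standard deviation (clamped to [1e-3, 1e3] so a constant feature cannot
    produce an infinite scale). Layer weights are drawn uniformly with a
    1/sqrt(fan_in) scale so pre-activations on standardized inputs have
    roughly unit variance; biases start at zero except the output bias.
    """
    if not stats:
        raise ValueError("descriptor stats are empty: no atoms to initialize from")
    rng = np.random.default_rng(seed)
    networks = {}
    n_g = config.n_g
    for el in sorted(stats):
        mean, std = stats[el]
        if mean.shape != (n_g,):
            raise ValueError(f"stats for {el!r} do not match the descriptor length {n_g}")
        inv_std = np.where(std > 0, 1.0 / np.where(std > 0, std, 1.0), np.inf)
        alpha = np.clip(inv_std, *ALPHA_CLAMP)
        beta = mean.copy()
        sizes = [n_g, *hidden, 1]
        weights, biases = [], []
        for l in range(len(sizes) - 1):
            fan_in = sizes[l]
            bound = np.sqrt(3.0 / fan_in)  # uniform(-b, b) has variance b^2/3 = 1/fan_in
            weights.append(rng.uniform(-bound, bound, size=(sizes[l + 1], sizes[l])))
            biases.append(np.zeros(sizes[l + 1]))
        networks[el] = AtomicNetwork(sizes, weights, biases, alpha, beta)
    return HDNNPModel(networks, config)


# --------------------------------------------------------------------------
# Prediction
# --------------------------------------------------------------------------


def _element_rows(conf):
    """Group atom indices of a conformation by element, preserving order."""
    groups: dict[str, list[int]] = {}
    for k, el in enumerate(conf.elements):
        groups.setdefault(el, []).append(k)
    return {el: np.array(idx) for el, idx in groups.items()}


def total_energy(conf, model: HDNNPModel, descriptors: DescriptorMatrix | None = None) -> float:
    """Total energy (eV) as the sum of atomic network outputs."""
    if descriptors is None:
        descriptors = descriptor_matrix(conf, model.descriptor_config)
    e = 0.0
    for el, idx in _element_rows(conf).items():
        y, _ = model.network_for(el).forward(descriptors.values[idx])
        e += y.sum()
    return float(e)


def energy_and_forces(conf, model: HDNNPModel, descriptors: DescriptorMatrix | None = None):
    """Energy (eV) and analytic forces (eV/Angstrom, shape (N, 3)).

    F_{a,beta} = - sum_{n,i} (dE/dG_{n,i}) * dG_{n,i}/dr_{a,beta}
    """
    if descriptors is None or descriptors.jacobian is None:
        descriptors = descriptor_matrix(conf, model.descriptor_config, with_jacobian=True)
    n_atoms = conf.n_atoms
    e = 0.0
    dE_dG = np.zeros_like(descriptors.values)
    for el, idx in _element_rows(conf).items():
        net = model.network_for(el)
        y, cache = net.forward(descriptors.values[idx])
        e += y.sum()
        dE_dG[idx] = net.input_gradient(cache)
    f = -np.einsum("ni,niab->ab", dE_dG, descriptors.jacobian)
    return float(e), f


def forces(conf, model: HDNNPModel, descriptors: DescriptorMatrix | None = None) -> np.ndarray:
    """Analytic forces only; see :func:`energy_and_forces`."""
    return energy_and_forces(conf, model, descriptors)[1]
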