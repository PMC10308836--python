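"""Loss function, training loop, and error metrics.

The loss over a subsample of N conformations balances per-atom energy
errors against force-component errors with the hyperparameter q:

    L = (1/N) sum_r [ (dE_r / N_atom_r)^2 + (q / (3 N_atom_r)) sum |dF|^2 ]

Each epoch draws a subsample through the lifelong adaptive data selection,
accumulates analytic loss gradients for all weights of the elements present
in the subsample, applies one CoRe step (per-group step counters advance
only for those elements), and updates the selection history. New
conformations can be injected at any epoch (lifelong mode); they enter the
selection pool with S_hist = 1 and no loss history.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .data import Conformation, Dataset
from .descriptors import descriptor_matrix
from .model import HDNNPModel, _element_rows
from .optimizer import CoReOptimizer
from .selection import (
    SelectionState,
    choose_subsample,
    per_conformation_loss,
    update_history,
    update_p_good,
)

__all__ = ["LossConfig", "TrainingHistory", "batch_loss", "loss_gradients", "train", "rmse"]


@dataclass(frozen=True)
class LossConfig:
    q: float = 10.9  # energy/force balance
    n_fit: int = 10  # conformations fitted per epoch
    epochs: int = 1000

    def __post_init__(self):
        if self.q < 0 or self.n_fit < 1 or self.epochs < 1:
            raise ValueError("require q >= 0, n_fit >= 1, epochs >= 1")


@dataclass
class TrainingHistory:
    epochs: list[int] = field(default_factory=list)
    total_loss: list[float] = field(default_factory=list)
    pool_size: list[int] = field(default_factory=list)
    p_good: list[float] = field(default_factory=list)


class _DescriptorCache:
    """Descriptor values and Jacobians per conformation id, computed once."""

    def __init__(self, config):
        self.config = config
        self._store: dict[str, object] = {}

    def get(self, conf: Conformation):
        if conf.id not in self._store:
            self._store[conf.id] = descriptor_matrix(conf, self.config, with_jacobian=True)
        return self._store[conf.id]


def _predict_batch(confs, model: HDNNPModel, cache: _DescriptorCache):
    """Energies, forces, and per-atom caches for a list of conformations."""
    results = []
    for conf in confs:
        desc = cache.get(conf)
        n_atoms = conf.n_atoms
        e = 0.0
        dE_dG = np.zeros_like(desc.values)
        caches = {}
        for el, idx in _element_rows(conf).items():
            net = model.network_for(el)
            y, c = net.forward(desc.values[idx])
            e += y.sum()
            dE_dG[idx] = net.input_gradient(c)
            caches[el] = (idx, c)
        f = -np.einsum("ni,niab->ab", dE_dG, desc.jacobian)
        results.append((e, f, desc, caches))
    return results


def batch_loss(confs, model: HDNNPModel, q: float, cache: _DescriptorCache | None = None):
    """Total loss and per-conformation contributions for a batch.

    Returns (L, per_conf) where L is the mean of the per-conformation
    contributions (the quantity minimized) and per_conf aligns with confs.
    """
    cache = cache or _DescriptorCache(model.descriptor_config)
    per_conf = []
    for conf in confs:
        if conf.energy is None or conf.forces is None:
            raise ValueError(f"conformation {conf.id!r} lacks reference energy/forces")
        desc = cache.get(conf)
        e = 0.0
        dE_dG = np.zeros_like(desc.values)
        for el, idx in _element_rows(conf).items():
            net = model.network_for(el)
            y, c = net.forward(desc.values[idx])
            e += y.sum()
            dE_dG[idx] = net.input_gradient(c)
        f = -np.einsum("ni,niab->ab", dE_dG, desc.jacobian)
        de = e - conf.energy
        df = f - conf.forces
        per_conf.append(per_conformation_loss(de * de, float((df * df).sum()), q, conf.n_atoms))
    per_conf = np.array(per_conf)
    return float(per_conf.mean()), per_conf


def loss_gradients(confs, model: HDNNPModel, q: float, cache: _DescriptorCache):
    """Analytic loss gradients for every weight group touched by the batch.

    Returns (L, per_conf_losses, grads) with grads keyed like
    ``model.parameters()``. The force part of the gradient is computed by a
    forward-over-reverse pass through each atomic network, with the
    descriptor Jacobian contracted into the input tangents.
    """
    n_batch = len(confs)
    predictions = _predict_batch(confs, model, cache)
    grads: dict = {}
    per_conf = np.zeros(n_batch)
    for r, (conf, (e, f, desc, caches)) in enumerate(zip(confs, predictions)):
        if conf.energy is None or conf.forces is None:
            raise ValueError(f"conformation {conf.id!r} lacks reference energy/forces")
        n_atoms = conf.n_atoms
        de = e - conf.energy
        df = f - conf.forces
        per_conf[r] = per_conformation_loss(de * de, float((df * df).sum()), q, n_atoms)
        # dL/dE coefficient per atom and dL/dF residual weights
        c_energy = 2.0 * de / (n_atoms * n_atoms * n_batch)
        c_force = 2.0 * q / (3.0 * n_atoms * n_batch)
        # descriptor-space tangent: U[n, i] = -c_force * sum_{a,b} dF[a,b] J[n,i,a,b]
        U = -c_force * np.einsum("ab,niab->ni", df, desc.jacobian)
        for el, (idx, net_cache) in caches.items():
            net = model.network_for(el)
            g = net.parameter_gradients(net_cache, np.full(len(idx), c_energy), U[idx])
            for key, val in g.items():
                if key == "alpha":
                    gid = (el, "alpha", None)
                elif key == "beta":
                    gid = (el, "beta", None)
                else:
                    gid = (el, key[0], key[1])
                grads[gid] = grads.get(gid, 0.0) + val
    return float(per_conf.mean()), per_conf, grads


def train(
    dataset: Dataset,
    model: HDNNPModel,
    optimizer: CoReOptimizer,
    selection: SelectionState,
    loss_config: LossConfig,
    rng: np.random.Generator,
    inject: dict[int, list[Conformation]] | None = None,
    cache: _DescriptorCache | None = None,
) -> TrainingHistory:
    """Run the lifelong training loop; the model is updated in place.

    ``inject`` maps epoch numbers to lists of new conformations that become
    available at the start of that epoch.
    """
    cache = cache or _DescriptorCache(model.descriptor_config)
    inject = inject or {}
    by_id = {c.id: c for c in dataset}
    history = TrainingHistory()
    for epoch in range(1, loss_config.epochs + 1):
        if epoch in inject:
            new_confs = inject[epoch]
            dataset.extend(new_confs)
            selection.add_conformations([c.id for c in new_confs])
            by_id.update({c.id: c for c in new_confs})
        n_fit = min(loss_config.n_fit, selection.n_active)
        if n_fit == 0:
            raise RuntimeError(f"epoch {epoch}: selection pool exhausted")
        choice = choose_subsample(selection, n_fit, rng)
        confs = [by_id[cid] for cid in choice.fit_ids]
        try:
            total, per_conf, grads = loss_gradients(confs, model, loss_config.q, cache)
            optimizer.step(grads)
        except Exception as exc:
            raise RuntimeError(f"epoch {epoch}: {exc}") from exc
        update_p_good(selection, total)
        update_history(selection, choice.fit_ids, per_conf, total)
        history.epochs.append(epoch)
        history.total_loss.append(total)
        history.pool_size.append(selection.n_active)
        history.p_good.append(selection.p_good)
    return history


def rmse(predictions, references, n_atoms=None) -> float:
    """Root-mean-square error; with ``n_atoms`` given, each energy residual
    is divided by the atom count first (the per-atom convention used for
    reporting energy errors)."""
    predictions = np.asarray(predictions, dtype=float)
    references = np.asarray(references, dtype=float)
    if predictions.shape != references.shape:
        raise ValueError("prediction/reference shape mismatch")
    res = predictions - references
    if n_atoms is not None:
        res = res / np.asarray(n_atoms, dtype=float)
    return float(np.sqrt(np.mean(res * res)))
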