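"""High-level training workflows: single potentials and ensembles.

Each ensemble member gets its own random train/test split (90/10 by
default), weight initialization, and data-selection stream; the committee
mean is the production prediction and the spread quantifies model
variance. After training, the ensemble's reference-set RMSEs become the
uncertainty floors.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np

from .data import Dataset
from .descriptors import DescriptorConfig
from .model import HDNNPModel, descriptor_stats, init_model
from .optimizer import CoReHyperparameters, CoReOptimizer, hdnnp_group_hyperparameters
from .selection import SelectionHyperparameters, SelectionState
from .training import LossConfig, TrainingHistory, _DescriptorCache, train
from .uq import EnsembleModel, ensemble_predict

__all__ = ["TrainSetup", "train_potential", "train_ensemble", "evaluate"]


@dataclass
class TrainSetup:
    """Everything needed to train one potential on one dataset."""

    descriptor_config: DescriptorConfig
    hidden: tuple = (102, 61, 44)
    optimizer_hp: CoReHyperparameters = field(default_factory=CoReHyperparameters)
    selection_hp: SelectionHyperparameters = field(default_factory=SelectionHyperparameters)
    loss: LossConfig = field(default_factory=LossConfig)
    test_fraction: float = 0.1
    fit_fraction: float | None = 0.1  # overrides loss.n_fit when set


def split_dataset(dataset: Dataset, test_fraction: float, rng) -> tuple[Dataset, Dataset]:
    """Random train/test split preserving conformation identity."""
    n = len(dataset)
    n_test = int(round(test_fraction * n))
    perm = rng.permutation(n)
    test_idx = set(perm[:n_test].tolist())
    train_confs = [dataset[i].copy() for i in range(n) if i not in test_idx]
    test_confs = [dataset[i].copy() for i in range(n) if i in test_idx]
    return Dataset(train_confs, dataset.provenance), Dataset(test_confs, dataset.provenance)


def train_potential(
    dataset: Dataset,
    setup: TrainSetup,
    seed: int,
    inject: dict | None = None,
    cache: _DescriptorCache | None = None,
):
    """Initialize and train one potential; returns (model, history, splits).

    ``inject`` maps epochs to conformation lists added during training
    (these are excluded from the initial standardization statistics, as
    they would be in a genuine lifelong setting).
    """
    rng = np.random.default_rng(seed)
    train_set, test_set = split_dataset(dataset, setup.test_fraction, rng)
    stats = descriptor_stats(train_set, setup.descriptor_config)
    # elements that only arrive with injected data still need networks;
    # fall back to injected-data statistics for them
    if inject:
        injected = [c for confs in inject.values() for c in confs]
        extra = descriptor_stats(Dataset([c.copy() for c in injected]), setup.descriptor_config)
        for el, st in extra.items():
            stats.setdefault(el, st)
    model = init_model(stats, setup.descriptor_config, hidden=setup.hidden, seed=seed)
    optimizer = CoReOptimizer(
        model.parameters(),
        hp=setup.optimizer_hp,
        group_hp=hdnnp_group_hyperparameters(model, setup.optimizer_hp),
    )
    selection = SelectionState(ids=list(train_set.ids), hp=setup.selection_hp)
    loss_cfg = setup.loss
    if setup.fit_fraction is not None:
        # the per-epoch fraction counts all training conformations, including
        # those that only become available at a late epoch
        n_total = len(train_set) + (sum(len(v) for v in inject.values()) if inject else 0)
        n_fit = max(1, int(round(setup.fit_fraction * n_total)))
        loss_cfg = replace(loss_cfg, n_fit=n_fit)
    history = train(
        train_set, model, optimizer, selection, loss_cfg, rng, inject=inject, cache=cache
    )
    return model, history, (train_set, test_set)


def train_ensemble(
    dataset: Dataset,
    setup: TrainSetup,
    n_members: int,
    seed: int,
    c: float = 2.0,
    inject_factory=None,
) -> tuple[EnsembleModel, list[TrainingHistory]]:
    """Train ``n_members`` potentials with member-specific seeds and build
    the committee; the uncertainty floors are set to the ensemble RMSEs on
    the full reference set.

    ``inject_factory(member_seed)`` may supply a lifelong injection
    schedule per member.
    """
    members, histories = [], []
    cache = _DescriptorCache(setup.descriptor_config)
    for p in range(n_members):
        member_seed = seed + 1000 * p
        inject = inject_factory(member_seed) if inject_factory else None
        model, history, _ = train_potential(dataset, setup, member_seed, inject=inject, cache=cache)
        members.append(model)
        histories.append(history)
    ensemble = EnsembleModel(members, c=c)
    e_rmse, f_rmse = evaluate(ensemble, dataset)
    ensemble.floor_energy = e_rmse
    ensemble.floor_forces = f_rmse
    return ensemble, histories


def evaluate(model, dataset: Dataset) -> tuple[float, float]:
    """Energy RMSE (eV) and force-component RMSE (eV/Angstrom) of a model
    or ensemble on a labelled dataset."""
    from .model import energy_and_forces

    e_res, f_res = [], []
    for conf in dataset:
        if isinstance(model, EnsembleModel):
            pred = ensemble_predict(conf, model)
            e, f = pred.energy, pred.forces
        else:
            e, f = energy_and_forces(conf, model)
        e_res.append(e - conf.energy)
        f_res.extend((f - conf.forces).ravel())
    e_res = np.asarray(e_res)
    f_res = np.asarray(f_res)
    return float(np.sqrt(np.mean(e_res**2))), float(np.sqrt(np.mean(f_res**2)))
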