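"""Ensemble (committee) prediction and uncertainty quantification.

The prediction of an ensemble of independently trained potentials is the
member mean; its uncertainty is the sample standard deviation across
members, scaled by a confidence factor c and floored by the reference
root-mean-square error of the ensemble (spread can vanish where members
agree, but the model is never better than its residual error):

    E      = mean_p E_p
    dE     = max( c * std_{p}(E_p; ddof=1), RMSE(E) )

and componentwise analogously for the atomic forces.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .model import HDNNPModel, energy_and_forces

__all__ = ["EnsembleModel", "ensemble_predict", "EnsemblePrediction"]


@dataclass(frozen=True)
class EnsemblePrediction:
    energy: float
    forces: np.ndarray
    energy_uncertainty: float
    force_uncertainty: np.ndarray
    member_energies: np.ndarray


@dataclass
class EnsembleModel:
    """Committee of HDNNPs with an uncertainty scaling factor and floors.

    ``floor_energy``/``floor_forces`` are the minimal uncertainties,
    conventionally the reference-set RMSEs of the ensemble prediction.
    """

    members: list[HDNNPModel]
    c: float = 2.0
    floor_energy: float = 0.0
    floor_forces: float = 0.0
    metadata: dict = field(default_factory=dict)

    def __post_init__(self):
        if not self.members:
            raise ValueError("an ensemble needs at least one member")
        if len(self.members) < 2 and self.c > 0:
            raise ValueError(
                "uncertainty from a single member is undefined; use c = 0 to "
                "rely on the floor alone"
            )

    @property
    def n_members(self) -> int:
        return len(self.members)

    def predict(self, conf) -> EnsemblePrediction:
        return ensemble_predict(conf, self)


def ensemble_predict(conf, ensemble: EnsembleModel) -> EnsemblePrediction:
    """Mean prediction with scaled-spread, floored uncertainties."""
    energies = np.empty(ensemble.n_members)
    forces = np.empty((ensemble.n_members, conf.n_atoms, 3))
    for p, member in enumerate(ensemble.members):
        energies[p], forces[p] = energy_and_forces(conf, member)
    e_mean = float(energies.mean())
    f_mean = forces.mean(axis=0)
    if ensemble.n_members > 1:
        de = max(ensemble.c * float(energies.std(ddof=1)), ensemble.floor_energy)
        df = np.maximum(ensemble.c * forces.std(axis=0, ddof=1), ensemble.floor_forces)
    else:
        de = ensemble.floor_energy
        df = np.full((conf.n_atoms, 3), ensemble.floor_forces)
    return EnsemblePrediction(e_mean, f_mean, de, df, energies)
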