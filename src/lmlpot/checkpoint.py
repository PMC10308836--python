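"""Single-file HDF5 checkpoints for continuable training.

To continue a training later, the final weights alone are not enough: the
per-weight optimizer state (tau, g, h, s, S), the per-conformation
selection state (L_old, S_hist, X), the total loss and p_good, and the
conformations themselves must all persist. One HDF5 file holds all of it:

    /model/<element>/{weights_l, biases_l, alpha, beta}
    /model/descriptor_config (JSON attribute)
    /optimizer/<group>/{tau, g, h, s, score, hyperparameters}
    /selection/{ids, s_hist, l_old, strikes, p_good, l_old_total, ...}
    /dataset/<id>/{elements, positions, energy, forces}
"""

from __future__ import annotations

import json
from dataclasses import asdict

import h5py
import numpy as np

from .data import Conformation, Dataset
from .descriptors import DescriptorConfig
from .model import AtomicNetwork, HDNNPModel
from .optimizer import CoReGroupState, CoReHyperparameters, CoReOptimizer
from .selection import SelectionHyperparameters, SelectionState

__all__ = ["save_checkpoint", "load_checkpoint"]


def _config_to_json(config: DescriptorConfig) -> str:
    return json.dumps(asdict(config))


def _config_from_json(blob: str) -> DescriptorConfig:
    d = json.loads(blob)
    for key in ("eta_rad", "eta_ang", "lambdas", "zetas", "element_list"):
        d[key] = tuple(d[key])
    d["radial_terms"] = tuple(tuple(t) for t in d["radial_terms"])
    d["angular_terms"] = tuple(tuple(t) for t in d["angular_terms"])
    return DescriptorConfig(**d)


def _gid_to_str(gid) -> str:
    el, kind, layer = gid
    return f"{el}|{kind}|{'' if layer is None else layer}"


def _gid_from_str(s: str):
    el, kind, layer = s.split("|")
    return (el, kind, None if layer == "" else int(layer))


def save_checkpoint(
    path,
    model: HDNNPModel | None = None,
    optimizer: CoReOptimizer | None = None,
    selection: SelectionState | None = None,
    dataset: Dataset | None = None,
) -> None:
    with h5py.File(path, "w") as f:
        if model is not None:
            g = f.create_group("model")
            g.attrs["descriptor_config"] = _config_to_json(model.descriptor_config)
            g.attrs["metadata"] = json.dumps(model.metadata)
            for el, net in model.networks.items():
                ng = g.create_group(el)
                ng.attrs["layer_sizes"] = net.layer_sizes
                for l in range(net.n_layers):
                    ng.create_dataset(f"weights_{l}", data=net.weights[l])
                    ng.create_dataset(f"biases_{l}", data=net.biases[l])
                ng.create_dataset("alpha", data=net.alpha)
                ng.create_dataset("beta", data=net.beta)
        if optimizer is not None:
            g = f.create_group("optimizer")
            for gid, st in optimizer.state.items():
                sg = g.create_group(_gid_to_str(gid))
                sg.attrs["tau"] = st.tau
                sg.attrs["hyperparameters"] = json.dumps(asdict(st.hp))
                for name in ("g", "h", "s", "score"):
                    sg.create_dataset(name, data=getattr(st, name))
        if selection is not None:
            g = f.create_group("selection")
            g.create_dataset("ids", data=np.array(selection.ids, dtype="S"))
            g.create_dataset("s_hist", data=selection.s_hist)
            g.create_dataset("l_old", data=selection.l_old)
            g.create_dataset("strikes", data=selection.strikes)
            g.attrs["p_good"] = selection.p_good
            g.attrs["l_old_total"] = selection.l_old_total
            g.attrs["hyperparameters"] = json.dumps(asdict(selection.hp))
        if dataset is not None:
            g = f.create_group("dataset")
            g.attrs["provenance"] = dataset.provenance
            for k, conf in enumerate(dataset):
                cg = g.create_group(f"conf_{k:06d}")
                cg.attrs["id"] = conf.id
                cg.create_dataset("elements", data=np.array(conf.elements, dtype="S"))
                cg.create_dataset("positions", data=conf.positions)
                if conf.energy is not None:
                    cg.attrs["energy"] = conf.energy
                if conf.forces is not None:
                    cg.create_dataset("forces", data=conf.forces)


def load_checkpoint(path) -> dict:
    """Load whatever sections the file holds; returns a dict with any of
    the keys "model", "optimizer", "selection", "dataset".

    The optimizer is returned re-bound to the loaded model's parameter
    arrays (both must be present to restore an optimizer)."""
    out: dict = {}
    with h5py.File(path, "r") as f:
        if "model" in f:
            g = f["model"]
            config = _config_from_json(g.attrs["descriptor_config"])
            networks = {}
            for el in g:
                ng = g[el]
                sizes = list(ng.attrs["layer_sizes"])
                n_layers = len(sizes) - 1
                networks[el] = AtomicNetwork(
                    sizes,
                    [ng[f"weights_{l}"][...] for l in range(n_layers)],
                    [ng[f"biases_{l}"][...] for l in range(n_layers)],
                    ng["alpha"][...],
                    ng["beta"][...],
                )
            out["model"] = HDNNPModel(networks, config, json.loads(g.attrs["metadata"]))
        if "optimizer" in f and "model" in out:
            opt = CoReOptimizer(out["model"].parameters())
            for key in f["optimizer"]:
                gid = _gid_from_str(key)
                sg = f["optimizer"][key]
                hp = CoReHyperparameters(**json.loads(sg.attrs["hyperparameters"]))
                opt.state[gid] = CoReGroupState(
                    int(sg.attrs["tau"]), sg["g"][...], sg["h"][...], sg["s"][...], sg["score"][...], hp
                )
            out["optimizer"] = opt
        if "selection" in f:
            g = f["selection"]
            hp = SelectionHyperparameters(**json.loads(g.attrs["hyperparameters"]))
            out["selection"] = SelectionState(
                ids=[s.decode() for s in g["ids"][...]],
                hp=hp,
                s_hist=g["s_hist"][...],
                l_old=g["l_old"][...],
                strikes=g["strikes"][...].astype(int),
                p_good=float(g.attrs["p_good"]),
                l_old_total=float(g.attrs["l_old_total"]),
            )
        if "dataset" in f:
            g = f["dataset"]
            confs = []
            for key in sorted(g):
                cg = g[key]
                confs.append(
                    Conformation(
                        [s.decode() for s in cg["elements"][...]],
                        cg["positions"][...],
                        energy=float(cg.attrs["energy"]) if "energy" in cg.attrs else None,
                        forces=cg["forces"][...] if "forces" in cg else None,
                        id=str(cg.attrs["id"]),
                    )
                )
            out["dataset"] = Dataset(confs, provenance=str(g.attrs["provenance"]))
    return out
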