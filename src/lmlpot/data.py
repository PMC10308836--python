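"""Conformation and dataset containers with extended-XYZ input/output.

Units are fixed throughout the package: coordinates in Angstrom, energies in
eV, force components in eV/Angstrom. Reference energies are whatever the file
provides as training target; by the usual convention for interatomic
potentials this is the total energy minus the neutral free-atom energies, but
the library does not subtract atomic energies itself.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

__all__ = [
    "Conformation",
    "Dataset",
    "read_extxyz",
    "write_extxyz",
    "filter_force_cap",
    "ParseError",
]


class ParseError(ValueError):
    """Malformed extended-XYZ input; the message names the offending line."""


@dataclass
class Conformation:
    """One molecular geometry with optional reference energy and forces."""

    elements: list[str]
    positions: np.ndarray  # (N, 3) Angstrom
    energy: float | None = None  # eV
    forces: np.ndarray | None = None  # (N, 3) eV/Angstrom
    id: str = ""
    metadata: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.positions = np.asarray(self.positions, dtype=float)
        if self.positions.ndim != 2 or self.positions.shape[1] != 3:
            raise ValueError("positions must have shape (N, 3)")
        if len(self.elements) != len(self.positions):
            raise ValueError("elements and positions lengths differ")
        if self.n_atoms < 1:
            raise ValueError("a conformation needs at least one atom")
        if not np.all(np.isfinite(self.positions)):
            raise ValueError("positions must be finite")
        if self.forces is not None:
            self.forces = np.asarray(self.forces, dtype=float)
            if self.forces.shape != self.positions.shape:
                raise ValueError("forces shape must match positions")

    @property
    def n_atoms(self) -> int:
        return len(self.positions)

    def copy(self) -> "Conformation":
        return Conformation(
            list(self.elements),
            self.positions.copy(),
            self.energy,
            None if self.forces is None else self.forces.copy(),
            self.id,
            dict(self.metadata),
        )


class Dataset:
    """Ordered collection of conformations with unique ids."""

    def __init__(self, conformations: list[Conformation] | None = None, provenance: str = ""):
        self.conformations: list[Conformation] = []
        self.provenance = provenance
        self._ids: set[str] = set()
        for conf in conformations or []:
            self.append(conf)

    def append(self, conf: Conformation) -> None:
        if not conf.id:
            conf.id = f"conf{len(self.conformations)}"
        if conf.id in self._ids:
            raise ValueError(f"duplicate conformation id {conf.id!r}")
        self._ids.add(conf.id)
        self.conformations.append(conf)

    def extend(self, confs) -> None:
        for conf in confs:
            self.append(conf)

    def __len__(self) -> int:
        return len(self.conformations)

    def __iter__(self):
        return iter(self.conformations)

    def __getitem__(self, i) -> Conformation:
        return self.conformations[i]

    @property
    def ids(self) -> list[str]:
        return [c.id for c in self.conformations]

    def energies(self) -> np.ndarray:
        return np.array([c.energy for c in self.conformations], dtype=float)


_ENERGY_KEYS = ("energy", "Energy", "E", "total_energy")

# key="quoted value" | key=bare
_KV_RE = re.compile(r'(\S+?)=(?:"([^"]*)"|(\S+))')


def _parse_comment(line: str) -> dict[str, str]:
    return {m.group(1): m.group(2) if m.group(2) is not None else m.group(3) for m in _KV_RE.finditer(line)}


def read_extxyz(path) -> Dataset:
    """Read an extended-XYZ file into a :class:`Dataset`.

    The reader is tolerant: the energy is taken from the first of the keys
    ``energy``/``Energy``/``E``/``total_energy`` on the comment line, and
    per-atom force columns 5-7 (after symbol, x, y, z) are read when present.
    """
    path = Path(path)
    lines = path.read_text().splitlines()
    dataset = Dataset(provenance=str(path))
    i = 0
    frame = 0
    while i < len(lines):
        if not lines[i].strip():
            i += 1
            continue
        try:
            n_atoms = int(lines[i].strip())
        except ValueError:
            raise ParseError(f"{path}:{i + 1}: expected atom count, got {lines[i]!r}") from None
        if i + 1 >= len(lines):
            raise ParseError(f"{path}:{i + 1}: missing comment line")
        kv = _parse_comment(lines[i + 1])
        energy = None
        for key in _ENERGY_KEYS:
            if key in kv:
                energy = float(kv[key])
                break
        conf_id = kv.get("id", f"{path.stem}:{frame}")
        elements: list[str] = []
        positions = []
        forces = []
        has_forces = True
        for j in range(n_atoms):
            lineno = i + 2 + j
            if lineno >= len(lines):
                raise ParseError(f"{path}:{lineno + 1}: truncated frame ({n_atoms} atoms expected)")
            parts = lines[lineno].split()
            if len(parts) < 4:
                raise ParseError(f"{path}:{lineno + 1}: expected 'symbol x y z [fx fy fz]'")
            elements.append(parts[0])
            try:
                positions.append([float(v) for v in parts[1:4]])
                if len(parts) >= 7:
                    forces.append([float(v) for v in parts[4:7]])
                else:
                    has_forces = False
            except ValueError:
                raise ParseError(f"{path}:{lineno + 1}: non-numeric coordinate/force field") from None
        dataset.append(
            Conformation(
                elements,
                np.array(positions, dtype=float),
                energy=energy,
                forces=np.array(forces, dtype=float) if has_forces and forces else None,
                id=conf_id,
            )
        )
        frame += 1
        i += 2 + n_atoms
    return dataset


def write_extxyz(path, dataset: Dataset | list[Conformation]) -> None:
    """Write conformations to extended-XYZ (energy on the comment line,
    forces as per-atom columns). Numeric fields keep 17 significant digits so
    that a read/write round trip is lossless at double precision."""
    confs = list(dataset)
    out = []
    for conf in confs:
        out.append(str(conf.n_atoms))
        comment = f'id="{conf.id}"'
        if conf.energy is not None:
            comment += f" energy={conf.energy:.17g}"
        out.append(comment)
        for k in range(conf.n_atoms):
            fields = [conf.elements[k]] + [f"{v:.17g}" for v in conf.positions[k]]
            if conf.forces is not None:
                fields += [f"{v:.17g}" for v in conf.forces[k]]
            out.append(" ".join(fields))
    Path(path).write_text("\n".join(out) + ("\n" if out else ""))


def filter_force_cap(dataset: Dataset, cap: float = 15.0) -> Dataset:
    """Keep only conformations whose largest absolute force component is at
    most ``cap`` (eV/Angstrom); the default drops data that only occur under
    extreme conditions.

    Raises if a conformation carries no forces: it cannot be filtered.
    """
    if cap <= 0:
        raise ValueError("cap must be positive")
    kept = []
    for conf in dataset:
        if conf.forces is None:
            raise ValueError(f"conformation {conf.id!r} has no forces; cannot apply force cap")
        if np.max(np.abs(conf.forces)) <= cap:
            kept.append(conf.copy())
    return Dataset(kept, provenance=f"{getattr(dataset, 'provenance', '')} | force cap {cap} eV/A")
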