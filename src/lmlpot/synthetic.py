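"""Synthetic potential-energy surfaces and sampling protocols.

A toy PES with closed-form energies and exact analytic forces stands in
for an electronic-structure reference method, so that every stage of the
training pipeline can be exercised without external data. The energy is a
sum of pairwise Morse potentials

    E = sum_{i<j} D_e [ (1 - exp(-a (r - r_e)))^2 - 1 ]

plus an optional three-body term  k * sum cos(theta_jik) * exp(-(R_ij^2 +
R_ik^2)/rho^2)  that introduces angular structure. Morse wells of a few eV
give energy spreads of the order of 2 eV per atom over the sampled
geometries, with force components kept below the usual 15 eV/Angstrom cap
by a minimum-distance guard.

Two samplers emulate how reaction reference data are commonly produced:
``generate_scan_set`` scans two exchange distances of a substitution-like
cluster over 1.05-5.25 Angstrom on a grid that is denser at short range
(with jitter bounded by the adjacent grid values), and
``generate_displaced_set`` adds randomly displaced copies of existing
geometries with per-atom displacements inside spheres of given radii.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass

import numpy as np

from .data import Conformation, Dataset

__all__ = [
    "ToyPESConfig",
    "ReactionSpec",
    "toy_energy_forces",
    "generate_scan_set",
    "generate_displaced_set",
    "two_distance_grid",
]

MIN_DISTANCE_GUARD = 0.7  # Angstrom; keeps Morse forces below ~15 eV/Angstrom


@dataclass(frozen=True)
class ToyPESConfig:
    """Parameterization of the analytic toy surface.

    ``pair_params`` maps unordered element pairs (alphabetical tuples) to
    Morse parameters (well depth D_e in eV, width a in 1/Angstrom,
    equilibrium distance r_e in Angstrom).
    """

    pair_params: dict
    three_body_strength: float = 0.0  # eV
    three_body_range: float = 4.0  # Angstrom (Gaussian damping length rho)
    noise_sigma_energy: float = 0.0  # eV
    noise_sigma_forces: float = 0.0  # eV/Angstrom
    min_distance: float = MIN_DISTANCE_GUARD

    def morse(self, el1: str, el2: str):
        key = tuple(sorted((el1, el2)))
        try:
            return self.pair_params[key]
        except KeyError:
            raise ValueError(f"no Morse parameters for element pair {key}") from None


def toy_energy_forces(conf: Conformation, pes: ToyPESConfig):
    """Exact energy (eV) and analytic forces (eV/Angstrom) of the toy PES."""
    pos = conf.positions
    n = conf.n_atoms
    energy = 0.0
    grad = np.zeros_like(pos)
    for i, j in itertools.combinations(range(n), 2):
        d_e, a, r_e = pes.morse(conf.elements[i], conf.elements[j])
        rij = pos[j] - pos[i]
        r = np.linalg.norm(rij)
        ex = np.exp(-a * (r - r_e))
        energy += d_e * ((1.0 - ex) ** 2 - 1.0)
        de_dr = 2.0 * d_e * a * (1.0 - ex) * ex
        grad_j = de_dr * rij / r
        grad[j] += grad_j
        grad[i] -= grad_j
    if pes.three_body_strength != 0.0:
        k3 = pes.three_body_strength
        rho2 = pes.three_body_range**2
        for i in range(n):
            for j, l in itertools.combinations([x for x in range(n) if x != i], 2):
                u = pos[j] - pos[i]
                v = pos[l] - pos[i]
                ru = np.linalg.norm(u)
                rv = np.linalg.norm(v)
                cos = float(u @ v) / (ru * rv)
                damp = np.exp(-(ru * ru + rv * rv) / rho2)
                energy += k3 * cos * damp
                dcos_du = v / (ru * rv) - cos * u / (ru * ru)
                dcos_dv = u / (ru * rv) - cos * v / (rv * rv)
                ddamp_du = damp * (-2.0 * u / rho2)
                ddamp_dv = damp * (-2.0 * v / rho2)
                gu = k3 * (dcos_du * damp + cos * ddamp_du)
                gv = k3 * (dcos_dv * damp + cos * ddamp_dv)
                grad[j] += gu
                grad[l] += gv
                grad[i] -= gu + gv
    return float(energy), -grad


@dataclass(frozen=True)
class ReactionSpec:
    """Substitution-like cluster: a central atom flanked by a leaving group
    and a nucleophile on opposite sides of the scan axis, with optional
    spectator ligands arranged around the center."""

    central: str = "C"
    leaving: str = "Cl"
    nucleophile: str = "Cl"
    ligands: tuple = ()
    ligand_distance: float = 1.1  # Angstrom
    n_grid: tuple = (20, 20)
    d_range: tuple = (1.05, 5.25)  # Angstrom


def two_distance_grid(lo: float, hi: float, n: int) -> np.ndarray:
    """A grid over [lo, hi] that is denser at short distances (quadratic
    stretch of a uniform grid)."""
    t = np.linspace(0.0, 1.0, n)
    return lo + (hi - lo) * t * (0.4 + 0.6 * t)


def _cluster_positions(spec: ReactionSpec, d1: float, d2: float) -> tuple[list, np.ndarray]:
    elements = [spec.central, spec.leaving, spec.nucleophile]
    positions = [[0.0, 0.0, 0.0], [-d1, 0.0, 0.0], [d2, 0.0, 0.0]]
    n_lig = len(spec.ligands)
    for k, el in enumerate(spec.ligands):
        phi = 2.0 * np.pi * k / max(n_lig, 1)
        elements.append(el)
        positions.append(
            [0.15, spec.ligand_distance * np.cos(phi), spec.ligand_distance * np.sin(phi)]
        )
    return elements, np.array(positions)


def _label_and_score(conf: Conformation, pes: ToyPESConfig, rng) -> Conformation:
    e, f = toy_energy_forces(conf, pes)
    if pes.noise_sigma_energy > 0:
        e += rng.normal(0.0, pes.noise_sigma_energy)
    if pes.noise_sigma_forces > 0:
        f = f + rng.normal(0.0, pes.noise_sigma_forces, size=f.shape)
    conf.energy = float(e)
    conf.forces = f
    return conf


def _min_dist(positions: np.ndarray) -> float:
    d = np.linalg.norm(positions[None] - positions[:, None], axis=-1)
    np.fill_diagonal(d, np.inf)
    return float(d.min())


def generate_scan_set(pes: ToyPESConfig, spec: ReactionSpec, seed: int = 0) -> Dataset:
    """Two-distance constrained scan with short-range-dense grids and
    jitter bounded by the adjacent grid values."""
    rng = np.random.default_rng(seed)
    grids = []
    for n in spec.n_grid:
        base = two_distance_grid(*spec.d_range, n)
        jittered = base.copy()
        for k in range(n):
            lo = base[k - 1] if k > 0 else spec.d_range[0]
            hi = base[k + 1] if k < n - 1 else spec.d_range[1]
            # jitter stays strictly between the adjacent grid values
            jittered[k] = base[k] + rng.uniform(-0.45, 0.45) * min(base[k] - lo, hi - base[k])
        grids.append(np.clip(jittered, *spec.d_range))
    dataset = Dataset(provenance=f"toy two-distance scan seed={seed}")
    count = 0
    for d1 in grids[0]:
        for d2 in grids[1]:
            elements, positions = _cluster_positions(spec, d1, d2)
            if _min_dist(positions) < pes.min_distance:
                continue  # unphysically close; outside the sampled regime
            conf = Conformation(elements, positions, id=f"scan{count}")
            conf.metadata["d1"] = float(d1)
            conf.metadata["d2"] = float(d2)
            dataset.append(_label_and_score(conf, pes, rng))
            count += 1
    return dataset


def generate_displaced_set(
    base: Dataset,
    pes: ToyPESConfig,
    radii=(0.05, 0.1, 0.15),
    seed: int = 0,
    max_retries: int = 200,
) -> Dataset:
    """One randomly displaced copy of every base conformation per radius.

    Each atom moves uniformly within an atom-centered sphere of the given
    radius; if the displacement brings two atoms closer than the minimum
    distance guard, the whole conformation is redrawn.
    """
    if any(r < 0 for r in radii):
        raise ValueError("radii must be nonnegative")
    rng = np.random.default_rng(seed)
    out = Dataset(provenance=f"{base.provenance} + displacements {tuple(radii)}")
    for conf in base:
        for radius in radii:
            for attempt in range(max_retries + 1):
                disp = _uniform_in_spheres(rng, conf.n_atoms, radius)
                positions = conf.positions + disp
                if radius == 0.0 or _min_dist(positions) >= pes.min_distance:
                    break
            else:
                raise RuntimeError(
                    f"could not displace {conf.id!r} by {radius} Angstrom within "
                    f"{max_retries} retries"
                )
            new = Conformation(
                list(conf.elements), positions, id=f"{conf.id}:disp{radius:g}"
            )
            out.append(_label_and_score(new, pes, rng))
    return out


def _uniform_in_spheres(rng, n: int, radius: float) -> np.ndarray:
    if radius == 0.0:
        return np.zeros((n, 3))
    direction = rng.normal(size=(n, 3))
    direction /= np.linalg.norm(direction, axis=1, keepdims=True)
    r = radius * rng.uniform(0.0, 1.0, size=(n, 1)) ** (1.0 / 3.0)
    return direction * r


def default_two_element_pes() -> ToyPESConfig:
    """Morse parameterization of a two-element (C, Cl) exchange cluster with
    wells of a few eV, spanning about 2 eV per atom over the scan range."""
    # widths/depths keep the repulsive wall below the 15 eV/Angstrom force
    # cap down to the 1.05 Angstrom end of the scan range
    return ToyPESConfig(
        pair_params={
            ("C", "Cl"): (2.5, 1.0, 1.8),
            ("C", "C"): (2.0, 1.0, 1.5),
            ("Cl", "Cl"): (1.0, 0.8, 2.8),
        }
    )
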