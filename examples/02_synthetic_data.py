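"""Synthetic reference data: two-distance reaction scans on a toy surface.

Generates an exchange-reaction scan (Cl-C-Cl cluster, both carbon-halide
distances scanned over 1.05-5.25 Angstrom with denser short-range
sampling), adds randomly displaced copies, applies the force cap, and
writes extended-XYZ. Energies and forces come from an analytic Morse
surface, so every label is exact.
"""

import numpy as np

from lmlpot import filter_force_cap, write_extxyz
from lmlpot.synthetic import (
    ReactionSpec,
    default_two_element_pes,
    generate_displaced_set,
    generate_scan_set,
)

pes = default_two_element_pes()
scan = generate_scan_set(pes, ReactionSpec(n_grid=(12, 12)), seed=1)
print(f"scan conformations: {len(scan)} (12 x 12 two-distance grid)")

displaced = generate_displaced_set(scan, pes, radii=(0.05, 0.1, 0.15), seed=2)
print(f"displaced copies: {len(displaced)} (3 per scan point)")

energies = scan.energies()
n_atoms = scan[0].n_atoms
print(f"energy range: {energies.min():.2f} .. {energies.max():.2f} eV "
      f"({(energies.max() - energies.min()) / n_atoms:.2f} eV/atom)")
fmax = max(np.abs(c.forces).max() for c in scan)
print(f"largest |force component|: {fmax:.2f} eV/A")

kept = filter_force_cap(displaced, cap=15.0)
print(f"after the 15 eV/A force cap: {len(kept)} of {len(displaced)} kept")

write_extxyz("scratch_scan.xyz", scan)
print("wrote scratch_scan.xyz (atom count / comment with energy / per-atom forces)")
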