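import numpy as np
import pytest

from lmlpot.data import Conformation, Dataset
from lmlpot.descriptors import build_descriptor_config
from lmlpot.model import descriptor_stats, init_model

ELEMENTS = ["H", "C", "N", "O", "Cl"]


def random_cluster(seed, n_atoms=6, elements=ELEMENTS, spread=2.5, min_dist=0.8):
    """Random cluster with a minimum-distance guard (rejection sampling)."""
    rng = np.random.default_rng(seed)
    while True:
        pos = rng.uniform(-spread, spread, (n_atoms, 3))
        d = np.linalg.norm(pos[None] - pos[:, None], axis=-1)
        np.fill_diagonal(d, np.inf)
        if d.min() >= min_dist:
            break
    els = [elements[i] for i in rng.integers(0, len(elements), n_atoms)]
    return Conformation(els, pos, id=f"rand{seed}")


@pytest.fixture
def small_config():
    """Small eeACSF configuration, cheap enough for finite differences."""
    return build_descriptor_config(
        "eeacsf", r_c=4.0, eta_rad=(0.0, 0.1, 0.5), eta_ang=(0.0, 0.2), zetas=(1.0, 4.0)
    )


@pytest.fixture
def small_model(small_config):
    """Randomly initialized HDNNP over H/C/N/O/Cl with two hidden layers."""
    confs = [random_cluster(s, 7) for s in range(4)]
    # make sure every element occurs at least once
    confs.append(Conformation(ELEMENTS, np.eye(5, 3) * 2.0 + np.arange(5)[:, None], id="all"))
    stats = descriptor_stats(Dataset(confs), small_config)
    return init_model(stats, small_config, hidden=(10, 7), seed=42)
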