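"""Symmetry-function values, counting rules, invariances, and gradients."""

import itertools

import numpy as np
import pytest

from conftest import random_cluster
from lmlpot.data import Conformation
from lmlpot.descriptors import (
    ANGULAR_BASE_DBLOCK,
    ANGULAR_BASE_MAIN,
    ConfigError,
    DegenerateGeometryError,
    angular_element_term,
    build_descriptor_config,
    cutoff,
    cutoff_derivative,
    descriptor_matrix,
    radial_element_term,
)
from lmlpot.elements import element_info, supported_elements

RC = 4.0


# ---------------------------------------------------------------------------
# cutoff
# ---------------------------------------------------------------------------


def test_cutoff_endpoints_and_range():
    assert cutoff(0.0, RC) == 1.0
    assert cutoff(RC, RC) == 0.0
    assert cutoff(RC + 1.0, RC) == 0.0
    r = np.linspace(0, 2 * RC, 200)
    vals = cutoff(r, RC)
    assert np.all((0 <= vals) & (vals <= 1))
    assert np.all(np.diff(vals[r < RC]) <= 0)  # monotone damping


def test_cutoff_derivative_vanishes_at_cutoff():
    # derivatives of all orders vanish at R_c; numerically the slope just
    # inside the cutoff is already tiny
    assert abs(cutoff_derivative(RC - 1e-6, RC)) < 1e-3
    r = np.linspace(0.1, RC - 0.05, 50)
    h = 1e-6
    fd = (cutoff(r + h, RC) - cutoff(r - h, RC)) / (2 * h)
    np.testing.assert_allclose(cutoff_derivative(r, RC), fd, rtol=1e-6, atol=1e-9)


# ---------------------------------------------------------------------------
# element terms
# ---------------------------------------------------------------------------


def test_radial_element_term_examples():
    assert radial_element_term(element_info("C"), "const") == 1.0
    assert radial_element_term(element_info("I"), "period") == 1.0  # max period 5
    assert radial_element_term(element_info("H"), "period") == pytest.approx(0.2)


def test_radial_terms_normalized_by_brute_force_maximum():
    # H/H_max must reach exactly 1 at the table maximum and never exceed it
    for variant in ("period", "period_c", "group", "group_c"):
        vals = [radial_element_term(e, variant) for e in supported_elements()]
        assert max(vals) == pytest.approx(1.0)
        assert min(vals) >= 0.0
    for variant in ("dgroup", "dgroup_c"):
        vals = [radial_element_term(e, variant, d_block_present=True) for e in supported_elements()]
        assert max(vals) == pytest.approx(1.0)


def test_d_variant_requires_d_block_flag():
    with pytest.raises(ConfigError):
        radial_element_term(element_info("Fe"), "dgroup", d_block_present=False)


def test_angular_element_term_constant_and_symmetry():
    c, h = element_info("C"), element_info("H")
    assert angular_element_term(c, h, "const", 1) == 1.0
    with pytest.raises(ConfigError):
        angular_element_term(c, h, "const", -1)
    rng = np.random.default_rng(0)
    table = supported_elements()
    for _ in range(30):
        j, k = table[rng.integers(54)], table[rng.integers(54)]
        for variant in ANGULAR_BASE_MAIN:
            for gamma in (1, -1):
                v1 = angular_element_term(j, k, variant, gamma)
                v2 = angular_element_term(k, j, variant, gamma)
                assert v1 == v2
                assert -1.0 <= v1 <= 1.0


def test_angular_variant_counts():
    # 1 constant + 2 gamma signs per non-constant variant: 9 or 11 terms
    assert 1 + 2 * len(ANGULAR_BASE_MAIN) == 9
    assert 1 + 2 * len(ANGULAR_BASE_DBLOCK) == 11


# ---------------------------------------------------------------------------
# counting rules
# ---------------------------------------------------------------------------

ETA9 = tuple(np.linspace(0.0, 1.1, 9))
ETA5 = tuple(np.linspace(0.0, 1.1, 5))
ANG = dict(eta_ang=(0.0, 0.1), lambdas=(-1.0, 1.0), zetas=(1.0, 2.0, 4.0))  # 12 combos


@pytest.mark.parametrize(
    "kwargs,expected",
    [
        (dict(flavor="eeacsf", eta_rad=ETA5, **ANG), (25, 108)),
        (dict(flavor="eeacsf", eta_rad=ETA5, d_block_present=True, **ANG), (35, 132)),
        (dict(flavor="eeacsf", eta_rad=ETA9, **ANG), (45, 108)),  # total 153
        (dict(flavor="acsf", eta_rad=ETA5, element_list=("H", "C", "Cl", "I"), **ANG), (20, 120)),
        (dict(flavor="acsf", eta_rad=ETA9, element_list=("H", "C", "Cl", "I"), **ANG), (36, 120)),
    ],
)
def test_descriptor_counts(kwargs, expected):
    cfg = build_descriptor_config(r_c=12.0, **kwargs)
    assert (cfg.n_radial, cfg.n_angular) == expected


def test_eeacsf_length_independent_of_element_count():
    lengths = []
    for n_elem in (1, 4, 10):
        elements = [e.symbol for e in supported_elements() if e.d == 0][:n_elem]
        cfg = build_descriptor_config("eeacsf", r_c=RC, eta_rad=ETA5, **ANG)
        conf = random_cluster(n_elem, n_atoms=10, elements=elements)
        mat = descriptor_matrix(conf, cfg)
        lengths.append(mat.values.shape[1])
    assert lengths == [133, 133, 133]


def test_acsf_length_follows_combinatorial_formula():
    for n_elem in (2, 4, 10):
        elements = tuple(e.symbol for e in supported_elements() if e.d == 0)[:n_elem]
        cfg = build_descriptor_config("acsf", r_c=RC, eta_rad=ETA9, element_list=elements, **ANG)
        assert cfg.n_g == n_elem * 9 + n_elem * (n_elem + 1) // 2 * 12


def test_acsf_requires_element_list():
    with pytest.raises(ConfigError):
        build_descriptor_config("acsf", eta_rad=ETA5, **ANG)


# ---------------------------------------------------------------------------
# values
# ---------------------------------------------------------------------------


def _single_config(**kw):
    base = dict(r_c=RC, eta_rad=(0.3,), eta_ang=(0.2,), lambdas=(1.0,), zetas=(2.0,))
    base.update(kw)
    return build_descriptor_config("eeacsf", **base)


def test_isolated_atom_has_zero_descriptors():
    cfg = _single_config()
    conf = Conformation(["C", "O"], [[0, 0, 0], [RC + 1, 0, 0]])
    assert np.allclose(descriptor_matrix(conf, cfg).values, 0.0)


def test_single_neighbor_radial_closed_form():
    cfg = _single_config()
    r = 1.7
    conf = Conformation(["C", "C"], [[0, 0, 0], [r, 0, 0]])
    mat = descriptor_matrix(conf, cfg)
    const_idx = cfg.radial_terms.index(("const", 0.3))
    expected = np.sqrt(np.exp(-0.3 * r * r) * cutoff(r, RC))
    assert mat.values[0, const_idx] == pytest.approx(expected, rel=1e-12)


def test_two_atom_conformation_has_zero_angular_block():
    cfg = _single_config()
    conf = Conformation(["C", "O"], [[0, 0, 0], [1.4, 0, 0]])
    mat = descriptor_matrix(conf, cfg)
    assert np.allclose(mat.values[:, cfg.n_radial :], 0.0)


def test_equilateral_triangle_matches_brute_force_double_loop():
    """Hand-coded neighbor-pair summation oracle for the angular eeACSF."""
    cfg = _single_config(lambdas=(-1.0, 1.0), zetas=(1.0, 4.0))
    a = 1.8
    pos = np.array([[0, 0, 0], [a, 0, 0], [a / 2, a * np.sqrt(3) / 2, 0]])
    conf = Conformation(["C", "C", "C"], pos)
    mat = descriptor_matrix(conf, cfg)
    for t, (variant, gamma, eta, lam, zeta) in enumerate(cfg.angular_terms):
        if variant != "const":
            continue
        for center in range(3):
            acc = 0.0
            others = [x for x in range(3) if x != center]
            for j, k in itertools.combinations(others, 2):
                u = pos[j] - pos[center]
                v = pos[k] - pos[center]
                rj, rk = np.linalg.norm(u), np.linalg.norm(v)
                rjk = np.linalg.norm(pos[j] - pos[k])
                cos = u @ v / (rj * rk)
                acc += (
                    2.0 ** (1 - zeta)
                    * (1 + lam * cos) ** zeta
                    * np.exp(-eta * (rj**2 + rk**2 + rjk**2))
                    * cutoff(rj, RC)
                    * cutoff(rk, RC)
                    * cutoff(rjk, RC)
                )
            assert mat.values[center, cfg.n_radial + t] == pytest.approx(np.sqrt(acc), rel=1e-12)


def test_each_contribution_before_sqrt_is_at_most_one():
    # one radial interaction and one angular interaction: squared value <= 1
    cfg = _single_config(lambdas=(-1.0, 1.0), zetas=(1.0,))
    rng = np.random.default_rng(1)
    for seed in range(20):
        conf = random_cluster(seed, n_atoms=3, spread=1.8)
        mat = descriptor_matrix(conf, cfg)
        # angular block has exactly one neighbor pair per center
        assert np.all(mat.values[:, cfg.n_radial :] ** 2 <= 1.0 + 1e-12)
        two = Conformation(conf.elements[:2], conf.positions[:2])
        assert np.all(descriptor_matrix(two, cfg).values ** 2 <= 1.0 + 1e-12)


# ---------------------------------------------------------------------------
# invariances
# ---------------------------------------------------------------------------


def _random_rotation(rng):
    q, _ = np.linalg.qr(rng.normal(size=(3, 3)))
    if np.linalg.det(q) < 0:
        q[:, 0] *= -1
    return q


@pytest.mark.parametrize("flavor", ["eeacsf", "acsf"])
def test_rotation_translation_invariance(flavor, small_config):
    cfg = (
        small_config
        if flavor == "eeacsf"
        else build_descriptor_config(
            "acsf", r_c=RC, eta_rad=(0.0, 0.3), eta_ang=(0.1,), zetas=(2.0,),
            element_list=("H", "C", "N", "O", "Cl"),
        )
    )
    rng = np.random.default_rng(7)
    for seed in range(25):
        conf = random_cluster(seed, n_atoms=6)
        ref = descriptor_matrix(conf, cfg).values
        rot = _random_rotation(rng)
        shift = rng.uniform(-5, 5, 3)
        moved = Conformation(conf.elements, conf.positions @ rot.T + shift)
        np.testing.assert_allclose(descriptor_matrix(moved, cfg).values, ref, atol=1e-10)


def test_same_element_permutation_permutes_rows_only(small_config):
    conf = random_cluster(11, n_atoms=6, elements=["C"])
    ref = descriptor_matrix(conf, small_config).values
    perm = np.array([2, 0, 1, 5, 4, 3])
    permuted = Conformation([conf.elements[i] for i in perm], conf.positions[perm])
    np.testing.assert_allclose(descriptor_matrix(permuted, small_config).values, ref[perm], atol=1e-12)


def test_monotone_damping_under_outward_scaling(small_config):
    cfg = small_config
    conf = random_cluster(3, n_atoms=5, spread=1.5)
    const_cols = [i for i, (v, _) in enumerate(cfg.radial_terms) if v == "const"]
    prev = descriptor_matrix(conf, cfg).values[:, const_cols]
    for scale in (1.15, 1.4, 1.8):
        cur = descriptor_matrix(Conformation(conf.elements, conf.positions * scale), cfg).values[
            :, const_cols
        ]
        assert np.all(cur <= prev + 1e-12)
        prev = cur


def test_locality_far_atom_leaves_rows_unchanged(small_config):
    conf = random_cluster(13, n_atoms=5)
    ref = descriptor_matrix(conf, small_config).values
    far = Conformation(
        conf.elements + ["O"], np.vstack([conf.positions, [100.0, 0.0, 0.0]])
    )
    got = descriptor_matrix(far, small_config).values
    np.testing.assert_array_equal(got[:5], ref)


def test_degenerate_geometry_raises(small_config):
    conf = Conformation(["H", "H"], [[0, 0, 0], [0, 0, 1e-9]])
    with pytest.raises(DegenerateGeometryError):
        descriptor_matrix(conf, small_config)


# ---------------------------------------------------------------------------
# Jacobian
# ---------------------------------------------------------------------------


@pytest.mark.parametrize("flavor", ["eeacsf", "acsf"])
def test_jacobian_matches_central_finite_differences(flavor):
    cfg = (
        build_descriptor_config("eeacsf", r_c=RC, eta_rad=(0.0, 0.3), eta_ang=(0.1,), zetas=(1.0, 3.0))
        if flavor == "eeacsf"
        else build_descriptor_config(
            "acsf", r_c=RC, eta_rad=(0.0, 0.3), eta_ang=(0.1,), zetas=(1.0, 3.0),
            element_list=("H", "C", "N", "O", "Cl"),
        )
    )
    conf = random_cluster(21, n_atoms=8)
    jac = descriptor_matrix(conf, cfg, with_jacobian=True).jacobian
    h = 1e-5
    worst = 0.0
    for a in range(8):
        for b in range(3):
            pp, pm = conf.positions.copy(), conf.positions.copy()
            pp[a, b] += h
            pm[a, b] -= h
            fd = (
                descriptor_matrix(Conformation(conf.elements, pp), cfg).values
                - descriptor_matrix(Conformation(conf.elements, pm), cfg).values
            ) / (2 * h)
            scale = max(np.abs(fd).max(), 1e-10)
            worst = max(worst, np.abs(jac[:, :, a, b] - fd).max() / scale)
    assert worst < 1e-5


def test_jacobian_vanishes_beyond_twice_cutoff(small_config):
    positions = np.array([[0, 0, 0], [1.5, 0, 0], [2 * RC + 3.0, 0, 0]])
    conf = Conformation(["C", "O", "H"], positions)
    jac = descriptor_matrix(conf, small_config, with_jacobian=True).jacobian
    assert np.allclose(jac[0, :, 2], 0.0) and np.allclose(jac[2, :, 0], 0.0)
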