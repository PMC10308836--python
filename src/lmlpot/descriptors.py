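"""Atom-centered symmetry functions, conventional and element-embracing.

Conventional ACSFs (Behler-style) dedicate separate descriptors to each
element (radial) or unordered element pair (angular), so the descriptor
vector grows with the number of chemical elements. Element-embracing ACSFs
(eeACSFs) instead weight every neighbor contribution by normalized
periodic-table descriptors of the neighbor elements (period number ``n``,
main-group number ``m``, d-group number ``d``), which keeps the vector
length constant no matter how many elements occur.

Functional forms
----------------
Radial, center atom ``c``, neighbors ``j`` within the cutoff ``R_c``::

    G_rad = sqrt( sum_j  (H_j / H_max) * exp(-eta R_cj^2) * f_c(R_cj) )

Angular, unordered neighbor pairs ``(j, k)`` with angle ``theta`` at ``c``::

    G_ang = sqrt( sum_{j<k} (H_jk / H_max) * 2^(1-zeta) (1 + lambda cos theta)^zeta
                  * exp(-eta (R_cj^2 + R_ck^2 + R_jk^2))
                  * f_c(R_cj) f_c(R_ck) f_c(R_jk) )

The square root moderates the effect of the neighbor count on the value;
conventional ACSFs use the same kernels without element weight and without
the square root. Every single-interaction contribution before the square
root lies in [0, 1] because the element terms are normalized by their
maximum possible value over the supported element table.

The cutoff is the compactly supported bump

    f_c(R) = exp(1 - 1 / (1 - (R/R_c)^2))   for R < R_c, else 0,

whose derivatives of all orders vanish at ``R_c``.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field
from functools import lru_cache

import numpy as np

from .elements import ElementInfo, element_info, supported_elements

__all__ = [
    "DescriptorConfig",
    "DescriptorMatrix",
    "build_descriptor_config",
    "cutoff",
    "cutoff_derivative",
    "radial_element_term",
    "angular_element_term",
    "descriptor_matrix",
    "eeacsf_radial",
    "eeacsf_angular",
    "DegenerateGeometryError",
    "ConfigError",
    "RADIAL_VARIANTS_MAIN",
    "RADIAL_VARIANTS_DBLOCK",
    "ANGULAR_BASE_MAIN",
    "ANGULAR_BASE_DBLOCK",
]

MIN_DISTANCE = 1e-8  # Angstrom; closer atom pairs raise instead of NaN


class DegenerateGeometryError(ValueError):
    """Two atoms (nearly) coincide; distances/angles are undefined."""


class ConfigError(ValueError):
    """Inconsistent descriptor configuration."""


# --------------------------------------------------------------------------
# Element-dependent terms
# --------------------------------------------------------------------------

# Radial variants: constant, period n and its complement, main group m and
# its complement; with d-block systems the d-group and its complement join.
RADIAL_VARIANTS_MAIN = ("const", "period", "period_c", "group", "group_c")
RADIAL_VARIANTS_DBLOCK = RADIAL_VARIANTS_MAIN + ("dgroup", "dgroup_c")

# Angular variants combine the constant term (gamma = +1 only) with the
# gamma = +/-1 product combinations of each non-constant variant; with
# d-block systems one d variant is added: 1 + 4*2 = 9 or 1 + 5*2 = 11 terms.
ANGULAR_BASE_MAIN = ("period", "period_c", "group", "group_c")
ANGULAR_BASE_DBLOCK = ANGULAR_BASE_MAIN + ("dgroup",)


def _raw_term(variant: str, info: ElementInfo) -> float:
    # Complements use (max+1) - value so they stay positive for every
    # element on which the base descriptor is defined.
    if variant == "const":
        return 1.0
    if variant == "period":
        return float(info.n)
    if variant == "period_c":
        return float(6 - info.n)
    if variant == "group":
        return float(info.m)
    if variant == "group_c":
        return float(9 - info.m) if info.m > 0 else 0.0
    if variant == "dgroup":
        return float(info.d)
    if variant == "dgroup_c":
        return float(13 - info.d) if info.d > 0 else 0.0
    raise ConfigError(f"unknown element-term variant {variant!r}")


@lru_cache(maxsize=None)
def _radial_h_max(variant: str) -> float:
    """Maximum possible raw term value over the supported element table."""
    return max(_raw_term(variant, e) for e in supported_elements())


def radial_element_term(info: ElementInfo, variant: str, d_block_present: bool = False) -> float:
    """Normalized radial element weight ``H / H_max`` in [0, 1]."""
    if variant.startswith("dgroup") and not d_block_present:
        raise ConfigError(f"variant {variant!r} requires d_block_present=True")
    if variant not in (RADIAL_VARIANTS_DBLOCK if d_block_present else RADIAL_VARIANTS_MAIN):
        raise ConfigError(f"unknown radial variant {variant!r}")
    return _raw_term(variant, info) / _radial_h_max(variant)


@lru_cache(maxsize=None)
def _angular_h_max(variant: str, gamma: int) -> float:
    best = 0.0
    for ej in supported_elements():
        vj = _raw_term(variant, ej) / _radial_h_max(variant)
        for ek in supported_elements():
            vk = _raw_term(variant, ek) / _radial_h_max(variant)
            raw = vj * vk if gamma == 1 else (1.0 - vj) * (1.0 - vk)
            best = max(best, raw)
    return best


def angular_element_term(j: ElementInfo, k: ElementInfo, variant: str, gamma: int = 1) -> float:
    """Normalized angular element weight, symmetric in ``j <-> k``.

    ``gamma = +1`` weights by the product of the two normalized neighbor
    values, ``gamma = -1`` by the product of their complements (the two
    linear combinations ((v_j v_k + w_j w_k) +/- (v_j v_k - w_j w_k))/2 with
    w = 1 - v); both are normalized by their maximum over element pairs.
    """
    if gamma not in (-1, 1):
        raise ConfigError("gamma must be +1 or -1")
    if variant == "const":
        if gamma != 1:
            raise ConfigError("the constant angular term only allows gamma = +1")
        return 1.0
    vj = _raw_term(variant, j) / _radial_h_max(variant)
    vk = _raw_term(variant, k) / _radial_h_max(variant)
    raw = vj * vk if gamma == 1 else (1.0 - vj) * (1.0 - vk)
    return raw / _angular_h_max(variant, gamma)


# --------------------------------------------------------------------------
# Cutoff
# --------------------------------------------------------------------------


def cutoff(r, r_c: float):
    """Compactly supported bump cutoff; 1 at R=0, exactly 0 for R >= R_c."""
    r = np.asarray(r, dtype=float)
    out = np.zeros_like(r)
    inside = r < r_c
    x2 = np.square(r[inside] / r_c)
    out[inside] = np.exp(1.0 - 1.0 / (1.0 - x2))
    return out if out.ndim else float(out)


def cutoff_derivative(r, r_c: float):
    """d f_c / dR; vanishes (with all higher orders) at R = R_c."""
    r = np.asarray(r, dtype=float)
    out = np.zeros_like(r)
    inside = r < r_c
    x = r[inside] / r_c
    t = 1.0 - x * x
    out[inside] = np.exp(1.0 - 1.0 / t) * (-2.0 * x / (r_c * t * t))
    return out if out.ndim else float(out)


# --------------------------------------------------------------------------
# Configuration
# --------------------------------------------------------------------------


@dataclass(frozen=True)
class DescriptorConfig:
    """Full enumeration of a descriptor vector.

    The ordering is deterministic: the radial block first, then the angular
    block; element terms (or elements/element pairs for conventional ACSFs)
    are the outer loop, parameter grids the inner loops (eta outermost, then
    lambda, then zeta).
    """

    flavor: str  # "eeacsf" | "acsf"
    r_c: float = 12.0  # Angstrom
    eta_rad: tuple = ()  # 1/Angstrom^2
    eta_ang: tuple = ()
    lambdas: tuple = (-1.0, 1.0)
    zetas: tuple = ()
    d_block_present: bool = False
    element_list: tuple = ()
    radial_terms: tuple = field(default=(), repr=False)  # eeACSF: (variant, eta); ACSF: (element, eta)
    angular_terms: tuple = field(default=(), repr=False)  # eeACSF: (variant, gamma, eta, lam, zeta); ACSF: (e1, e2, eta, lam, zeta)

    @property
    def n_radial(self) -> int:
        return len(self.radial_terms)

    @property
    def n_angular(self) -> int:
        return len(self.angular_terms)

    @property
    def n_g(self) -> int:
        return self.n_radial + self.n_angular


def build_descriptor_config(
    flavor: str,
    r_c: float = 12.0,
    eta_rad=(),
    eta_ang=(),
    lambdas=(-1.0, 1.0),
    zetas=(),
    d_block_present: bool = False,
    element_list=(),
) -> DescriptorConfig:
    """Enumerate a descriptor vector from parameter grids.

    For eeACSFs the vector length is independent of the number of elements:
    ``n_rad = n_variants * |eta_rad|`` with 5 (main-group) or 7 (d-block)
    radial variants and ``n_ang = n_ang_variants * |eta_ang| * |lambda| *
    |zeta|`` with 9 or 11 angular variants. For conventional ACSFs it is
    ``N_elem * |eta_rad| + N_elem (N_elem + 1)/2 * |eta_ang| * |lambda| * |zeta|``.
    """
    flavor = flavor.lower()
    if flavor not in ("eeacsf", "acsf"):
        raise ConfigError(f"unknown descriptor flavor {flavor!r}")
    if r_c <= 0:
        raise ConfigError("cutoff radius must be positive")
    eta_rad = tuple(float(e) for e in eta_rad)
    eta_ang = tuple(float(e) for e in eta_ang)
    lambdas = tuple(float(l) for l in lambdas)
    zetas = tuple(float(z) for z in zetas)
    if not eta_rad or not eta_ang or not lambdas or not zetas:
        raise ConfigError("parameter grids must be nonempty")
    if any(e < 0 for e in eta_rad + eta_ang):
        raise ConfigError("eta values must be >= 0")
    if any(l not in (-1.0, 1.0) for l in lambdas):
        raise ConfigError("lambda values must be +1 or -1")
    if any(z < 1 for z in zetas):
        raise ConfigError("zeta values must be >= 1")

    if flavor == "eeacsf":
        rad_variants = RADIAL_VARIANTS_DBLOCK if d_block_present else RADIAL_VARIANTS_MAIN
        ang_base = ANGULAR_BASE_DBLOCK if d_block_present else ANGULAR_BASE_MAIN
        ang_variants = [("const", 1)] + [(v, g) for v in ang_base for g in (1, -1)]
        radial_terms = tuple((v, eta) for v in rad_variants for eta in eta_rad)
        angular_terms = tuple(
            (v, g, eta, lam, zeta)
            for (v, g) in ang_variants
            for eta in eta_ang
            for lam in lambdas
            for zeta in zetas
        )
        element_list = ()
    else:
        if not element_list:
            raise ConfigError("conventional ACSFs require an element_list")
        element_list = tuple(element_list)
        for sym in element_list:
            element_info(sym)  # validates
        radial_terms = tuple((sym, eta) for sym in element_list for eta in eta_rad)
        pairs = [
            (element_list[i], element_list[j])
            for i in range(len(element_list))
            for j in range(i, len(element_list))
        ]
        angular_terms = tuple(
            (e1, e2, eta, lam, zeta)
            for (e1, e2) in pairs
            for eta in eta_ang
            for lam in lambdas
            for zeta in zetas
        )
    return DescriptorConfig(
        flavor=flavor,
        r_c=r_c,
        eta_rad=eta_rad,
        eta_ang=eta_ang,
        lambdas=lambdas,
        zetas=zetas,
        d_block_present=d_block_present,
        element_list=element_list,
        radial_terms=radial_terms,
        angular_terms=angular_terms,
    )


@dataclass
class DescriptorMatrix:
    """Per-atom descriptor values and (optionally) their position Jacobian.

    ``values[c, i]`` is descriptor ``i`` of center atom ``c`` and
    ``jacobian[c, i, a, beta]`` is its derivative with respect to Cartesian
    coordinate ``beta`` of atom ``a`` (1/Angstrom).
    """

    values: np.ndarray
    jacobian: np.ndarray | None = None


# --------------------------------------------------------------------------
# Evaluation
# --------------------------------------------------------------------------


def _geometry(conf):
    pos = np.asarray(conf.positions, dtype=float)
    n = len(pos)
    diff = pos[None, :, :] - pos[:, None, :]  # diff[i, j] = r_j - r_i
    dist = np.linalg.norm(diff, axis=-1)
    off = ~np.eye(n, dtype=bool)
    if n > 1 and dist[off].min() < MIN_DISTANCE:
        i, j = divmod(int(np.argmin(np.where(off, dist, np.inf))), n)
        raise DegenerateGeometryError(
            f"atoms {i} and {j} are closer than {MIN_DISTANCE} Angstrom"
        )
    return pos, diff, dist


def _radial_weights(conf, config: DescriptorConfig):
    """Per-variant neighbor weight arrays, shape (N,)."""
    infos = [element_info(s) for s in conf.elements]
    variants = RADIAL_VARIANTS_DBLOCK if config.d_block_present else RADIAL_VARIANTS_MAIN
    return {
        v: np.array([radial_element_term(e, v, config.d_block_present) for e in infos])
        for v in variants
    }


def _angular_weight_matrix(conf, variant: str, gamma: int, d_block_present: bool):
    infos = [element_info(s) for s in conf.elements]
    if variant == "const":
        n = len(infos)
        return np.ones((n, n))
    v = np.array([_raw_term(variant, e) / _radial_h_max(variant) for e in infos])
    raw = np.outer(v, v) if gamma == 1 else np.outer(1.0 - v, 1.0 - v)
    return raw / _angular_h_max(variant, gamma)


def descriptor_matrix(conf, config: DescriptorConfig, with_jacobian: bool = False) -> DescriptorMatrix:
    """Evaluate the full descriptor vector (and Jacobian) for every atom."""
    pos, diff, dist = _geometry(conf)
    n_atoms = len(pos)
    n_g = config.n_g
    values = np.zeros((n_atoms, n_g))
    jac = np.zeros((n_atoms, n_g, n_atoms, 3)) if with_jacobian else None

    r_c = config.r_c
    fc = cutoff(dist, r_c)
    dfc = cutoff_derivative(dist, r_c) if with_jacobian else None
    np.fill_diagonal(fc, 0.0)

    ee = config.flavor == "eeacsf"
    if ee:
        rad_w = _radial_weights(conf, config)
        ang_w = {
            (v, g): _angular_weight_matrix(conf, v, g, config.d_block_present)
            for (v, g) in {(t[0], t[1]) for t in config.angular_terms}
        }
    else:
        elems = np.array(conf.elements)

    for c in range(n_atoms):
        nb = np.where((dist[c] < r_c) & (np.arange(n_atoms) != c))[0]
        # ---- radial block ----
        for i, term in enumerate(config.radial_terms):
            if len(nb) == 0:
                continue
            if ee:
                variant, eta = term
                w = rad_w[variant][nb]
                sel = nb
            else:
                sym, eta = term
                sel = nb[elems[nb] == sym]
                if len(sel) == 0:
                    continue
                w = np.ones(len(sel))
            r = dist[c, sel]
            gauss = np.exp(-eta * r * r)
            contrib = w * gauss * fc[c, sel]
            pre = contrib.sum()
            values[c, i] = np.sqrt(pre) if ee else pre
            if with_jacobian and pre > 0.0:
                dpre_dr = w * gauss * (dfc[c, sel] - 2.0 * eta * r * fc[c, sel])
                scale = dpre_dr / (2.0 * np.sqrt(pre)) if ee else dpre_dr
                unit = diff[c, sel] / r[:, None]  # center -> neighbor
                grads = scale[:, None] * unit  # dG/dr_j
                jac[c, i, sel] += grads
                jac[c, i, c] -= grads.sum(axis=0)

        # ---- angular block ----
        if len(nb) < 2:
            continue
        pair_j, pair_k = map(np.array, zip(*itertools.combinations(nb, 2)))
        rjk = dist[pair_j, pair_k]
        keep = rjk < r_c
        pair_j, pair_k, rjk = pair_j[keep], pair_k[keep], rjk[keep]
        if len(pair_j) == 0:
            continue
        u = diff[c, pair_j]  # center -> j
        v = diff[c, pair_k]  # center -> k
        rj = dist[c, pair_j]
        rk = dist[c, pair_k]
        cos = np.clip(np.einsum("ij,ij->i", u, v) / (rj * rk), -1.0, 1.0)
        fcj, fck, fcjk = fc[c, pair_j], fc[c, pair_k], cutoff(rjk, r_c)
        cut = fcj * fck * fcjk
        r2sum = rj * rj + rk * rk + rjk * rjk
        if with_jacobian:
            dfcj, dfck, dfcjk = dfc[c, pair_j], dfc[c, pair_k], cutoff_derivative(rjk, r_c)
            # geometric derivative pieces reused by every angular descriptor
            dcos_dj = v / (rj * rk)[:, None] - (cos / (rj * rj))[:, None] * u
            dcos_dk = u / (rj * rk)[:, None] - (cos / (rk * rk))[:, None] * v
            uhat = u / rj[:, None]
            vhat = v / rk[:, None]
            what = (u - v) / rjk[:, None]  # k -> j direction
            dcut_dj = (dfcj * fck * fcjk)[:, None] * uhat + (fcj * fck * dfcjk)[:, None] * what
            dcut_dk = (fcj * dfck * fcjk)[:, None] * vhat - (fcj * fck * dfcjk)[:, None] * what
            dcut_dc = -(dfcj * fck * fcjk)[:, None] * uhat - (fcj * dfck * fcjk)[:, None] * vhat
            dr2_dj = 2.0 * u + 2.0 * (u - v)
            dr2_dk = 2.0 * v + 2.0 * (v - u)
            dr2_dc = -2.0 * u - 2.0 * v

        i0 = config.n_radial
        for i, term in enumerate(config.angular_terms):
            if ee:
                variant, gamma, eta, lam, zeta = term
                w = ang_w[(variant, gamma)][pair_j, pair_k]
                sel = slice(None)
            else:
                e1, e2, eta, lam, zeta = term
                ej, ek = elems[pair_j], elems[pair_k]
                mask = ((ej == e1) & (ek == e2)) | ((ej == e2) & (ek == e1))
                if not mask.any():
                    continue
                sel = mask
                w = np.ones(int(mask.sum()))
            base = 1.0 + lam * cos[sel]
            ang = 2.0 ** (1.0 - zeta) * base**zeta
            gauss = np.exp(-eta * r2sum[sel])
            contrib = w * ang * gauss * cut[sel]
            pre = contrib.sum()
            col = i0 + i
            values[c, col] = np.sqrt(pre) if ee else pre
            if with_jacobian and pre > 0.0:
                dang_dcos = 2.0 ** (1.0 - zeta) * zeta * lam * base ** (zeta - 1.0)
                wg = w * gauss
                # d(term)/dr for r in {j, k, c}
                def _accum(dcos, dcut, dr2):
                    return (
                        (wg * dang_dcos * cut[sel])[:, None] * dcos
                        + (wg * ang)[:, None] * dcut
                        + (w * ang * gauss * cut[sel] * (-eta))[:, None] * dr2
                    )

                gj = _accum(dcos_dj[sel], dcut_dj[sel], dr2_dj[sel])
                gk = _accum(dcos_dk[sel], dcut_dk[sel], dr2_dk[sel])
                gc = _accum(-(dcos_dj[sel] + dcos_dk[sel]), dcut_dc[sel], dr2_dc[sel])
                scale = 1.0 / (2.0 * np.sqrt(pre)) if ee else 1.0
                np.add.at(jac[c, col], pair_j[sel], gj * scale)
                np.add.at(jac[c, col], pair_k[sel], gk * scale)
                jac[c, col, c] += gc.sum(axis=0) * scale

    return DescriptorMatrix(values=values, jacobian=jac)


# Convenience single-descriptor evaluators used in tests and exploration.


def eeacsf_radial(conf, center: int, eta: float, variant: str, config: DescriptorConfig) -> float:
    """One radial eeACSF value for one center atom."""
    cfg = build_descriptor_config(
        "eeacsf",
        r_c=config.r_c,
        eta_rad=(eta,),
        eta_ang=config.eta_ang,
        lambdas=config.lambdas,
        zetas=config.zetas,
        d_block_present=config.d_block_present,
    )
    idx = cfg.radial_terms.index((variant, float(eta)))
    return float(descriptor_matrix(conf, cfg).values[center, idx])


def eeacsf_angular(
    conf, center: int, eta: float, lam: float, zeta: float, variant: str, gamma: int, config: DescriptorConfig
) -> float:
    """One angular eeACSF value for one center atom."""
    cfg = build_descriptor_config(
        "eeacsf",
        r_c=config.r_c,
        eta_rad=config.eta_rad,
        eta_ang=(eta,),
        lambdas=(lam,),
        zetas=(zeta,),
        d_block_present=config.d_block_present,
    )
    idx = cfg.n_radial + cfg.angular_terms.index((variant, gamma, float(eta), float(lam), float(zeta)))
    return float(descriptor_matrix(conf, cfg).values[center, idx])
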