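"""Lifelong adaptive data selection.

Training subsamples are drawn stochastically, balancing "bad" (new or
poorly represented) against "good" (well represented) conformations, while
per-conformation adaptive selection factors S_hist track the training
history and eventually exclude redundant data (persistently easy) and
inconsistent data (persistent outliers).

Subsample choice
----------------
The probability of being drawn as bad data is proportional to
(L_old / L_old_max) * S_hist, with never-evaluated conformations weighted
by max(S_hist). Good data are drawn from the remainder with probability
proportional to 1 - L_old / L_old_max; entries at the maximal loss or never
evaluated receive eps' times the smallest nonzero weight. The number of
good draws is floor(p_good * N_fit), where p_good (initialized at 0) grows
by one quantum p_good_max / N_p whenever the total subsample loss went up
and shrinks by one quantum when it went down.

History update
--------------
After the loss evaluation, L_rel = loss / (mean subsample loss) is compared
to thresholds T_F1 < 1 < T_F2 < T_F3 < T_X:

* L_rel > T_X increments a strike counter; N_X consecutive strikes set
  S_hist = 0 (outlier exclusion). Any other evaluation resets the counter.
* S_hist is reset to one whenever L_rel crosses to the other side of the
  band [T_F1, T_F2] relative to its current value, or lies inside it.
* Well-represented data (L_rel < T_F1) are decayed by F-- = S_min^(1/N_F--)
  if their loss did not increase, else by the gentler F- = S_min^(1/N_F-);
  poorly represented data with increased loss grow by F+ = S_max^(1/N_F+)
  for T_F2 <= L_rel < T_F3 and by F++ = S_max^(1/N_F++) for L_rel >= T_F3.
* S_hist < S_min excludes as redundant; S_hist > S_max excludes as
  inconsistent. S_hist = 0 is absorbing.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "SelectionHyperparameters",
    "SelectionState",
    "SubsampleChoice",
    "bad_probabilities",
    "good_probabilities",
    "choose_subsample",
    "per_conformation_loss",
    "update_history",
    "update_p_good",
    "SelectionError",
]


class SelectionError(RuntimeError):
    """Exhausted selection pool or inconsistent ids."""


@dataclass(frozen=True)
class SelectionHyperparameters:
    s_min: float = 0.1
    s_max: float = 100.0
    n_f_minus_minus: int = 30
    n_f_minus: int = 100
    n_f_plus: int = 500
    n_f_plus_plus: int = 150
    t_f1: float = 0.5
    t_f2: float = 2.0
    t_f3: float = 5.0
    t_x: float = 10.0
    n_x: int = 5
    n_p: int = 20
    p_good_max: float = 0.5
    eps_prime: float = 1e-6

    def __post_init__(self):
        if not (self.t_f1 < 1 < self.t_f2 < self.t_f3 < self.t_x):
            raise ValueError("thresholds must satisfy T_F1 < 1 < T_F2 < T_F3 < T_X")
        if not (0 < self.s_min < 1 < self.s_max):
            raise ValueError("require 0 < S_min < 1 < S_max")

    @property
    def f_minus_minus(self) -> float:
        return self.s_min ** (1.0 / self.n_f_minus_minus)

    @property
    def f_minus(self) -> float:
        return self.s_min ** (1.0 / self.n_f_minus)

    @property
    def f_plus(self) -> float:
        return self.s_max ** (1.0 / self.n_f_plus)

    @property
    def f_plus_plus(self) -> float:
        return self.s_max ** (1.0 / self.n_f_plus_plus)

    @property
    def p_quantum(self) -> float:
        return self.p_good_max / self.n_p


@dataclass
class SelectionState:
    """Selection bookkeeping for an ordered list of conformation ids."""

    ids: list[str]
    hp: SelectionHyperparameters = field(default_factory=SelectionHyperparameters)
    s_hist: np.ndarray = None  # type: ignore[assignment]
    l_old: np.ndarray = None  # type: ignore[assignment]  # NaN = never evaluated
    strikes: np.ndarray = None  # type: ignore[assignment]
    p_good: float = 0.0
    l_old_total: float = np.inf

    def __post_init__(self):
        n = len(self.ids)
        if self.s_hist is None:
            self.s_hist = np.ones(n)
        if self.l_old is None:
            self.l_old = np.full(n, np.nan)
        if self.strikes is None:
            self.strikes = np.zeros(n, dtype=int)
        self._index = {cid: k for k, cid in enumerate(self.ids)}
        if len(self._index) != n:
            raise SelectionError("conformation ids must be unique")

    def add_conformations(self, new_ids) -> None:
        """Register conformations injected during lifelong training; they
        enter the pool with S_hist = 1 and no loss history."""
        new_ids = list(new_ids)
        for cid in new_ids:
            if cid in self._index:
                raise SelectionError(f"duplicate conformation id {cid!r}")
        self.ids.extend(new_ids)
        k = len(new_ids)
        self.s_hist = np.concatenate([self.s_hist, np.ones(k)])
        self.l_old = np.concatenate([self.l_old, np.full(k, np.nan)])
        self.strikes = np.concatenate([self.strikes, np.zeros(k, dtype=int)])
        self._index = {cid: i for i, cid in enumerate(self.ids)}

    def indices(self, ids) -> np.ndarray:
        try:
            return np.array([self._index[c] for c in ids], dtype=int)
        except KeyError as exc:
            raise SelectionError(f"unknown conformation id {exc.args[0]!r}") from None

    @property
    def active(self) -> np.ndarray:
        return self.s_hist > 0

    @property
    def n_active(self) -> int:
        return int(np.count_nonzero(self.active))


@dataclass(frozen=True)
class SubsampleChoice:
    fit_ids: list[str]
    n_bad: int
    n_good: int


def bad_probabilities(state: SelectionState) -> np.ndarray:
    """Selection probabilities for the bad-data draw over all conformations
    (excluded entries have probability exactly 0)."""
    active = state.active
    if not active.any():
        raise SelectionError("all conformations are excluded from training")
    p = np.zeros(len(state.ids))
    l = state.l_old
    evaluated = active & ~np.isnan(l)
    if evaluated.any():
        l_max = l[evaluated].max()
        if l_max > 0:
            p[evaluated] = (l[evaluated] / l_max) * state.s_hist[evaluated]
        else:
            p[evaluated] = state.s_hist[evaluated]
    fresh = active & np.isnan(l)
    if fresh.any():
        p[fresh] = state.s_hist[active].max()
    total = p.sum()
    if total <= 0:  # all active entries have zero stored loss
        p[active] = state.s_hist[active]
        total = p.sum()
    return p / total


def good_probabilities(state: SelectionState, remaining: np.ndarray) -> np.ndarray:
    """Selection probabilities for the good-data draw over ``remaining``
    (a boolean mask or index array of not-yet-chosen conformations)."""
    mask = np.zeros(len(state.ids), dtype=bool)
    mask[remaining] = True
    mask &= state.active
    if not mask.any():
        raise SelectionError("no conformations left for the good-data draw")
    p = np.zeros(len(state.ids))
    l = state.l_old
    evaluated = mask & ~np.isnan(l)
    l_max = l[evaluated].max() if evaluated.any() else np.nan
    if evaluated.any() and l_max > 0:
        p[evaluated] = 1.0 - l[evaluated] / l_max
    positive = p[mask] > 0
    if positive.any():
        p_floor = state.hp.eps_prime * p[mask][positive].min()
        # entries at the maximal loss or never evaluated get the tiny floor
        floor_mask = mask & (p <= 0)
        p[floor_mask] = p_floor
    else:
        # every candidate sits at the maximal loss (or none evaluated):
        # uniform tiny weights normalize to a uniform distribution
        p[mask] = 1.0
    return p / p.sum()


def choose_subsample(state: SelectionState, n_fit: int, rng: np.random.Generator) -> SubsampleChoice:
    """Draw the training subsample for one epoch (without replacement)."""
    if n_fit < 1:
        raise SelectionError("N_fit must be >= 1")
    if n_fit > state.n_active:
        raise SelectionError(
            f"N_fit = {n_fit} exceeds the {state.n_active} non-excluded conformations"
        )
    n_good = int(np.floor(state.p_good * n_fit))
    n_bad = n_fit - n_good
    ids = np.arange(len(state.ids))
    p_bad = bad_probabilities(state)
    bad_idx = _draw(ids, n_bad, p_bad, state.active, rng)
    chosen = set(bad_idx.tolist())
    if n_good > 0:
        remaining = np.array([i for i in ids if i not in chosen and state.active[i]])
        mask = np.zeros(len(ids), dtype=bool)
        mask[remaining] = True
        p_good = good_probabilities(state, remaining)
        good_idx = _draw(ids, n_good, p_good, mask, rng)
    else:
        good_idx = np.array([], dtype=int)
    fit = np.concatenate([bad_idx, good_idx]).astype(int)
    return SubsampleChoice([state.ids[i] for i in fit], n_bad=n_bad, n_good=n_good)


def _draw(ids, k, p, active, rng):
    if k == 0:
        return np.array([], dtype=int)
    if int(np.count_nonzero(p)) < k:
        # fewer nonzero-probability entries than draws (e.g. stored losses of
        # exactly zero): give zero-weight ACTIVE entries a uniform tiny mass;
        # excluded conformations keep probability 0 forever
        p = p.copy()
        floor = p[p > 0].min() * 1e-12 if (p > 0).any() else 1.0
        p[active & (p <= 0)] = floor
        p = p / p.sum()
    return rng.choice(ids, size=k, replace=False, p=p)


def per_conformation_loss(energy_sq_error: float, force_sq_error: float, q: float, n_atoms: int) -> float:
    """Per-conformation loss contribution.

    ``energy_sq_error`` is (E_pred - E_ref)^2 and ``force_sq_error`` the sum
    of squared force-component residuals. The energy term is normalized per
    atom twice (matching an error-per-atom squared), the force term by the
    3 N components, weighted by the balance hyperparameter q:

        l = (E_sq / N + q * F_sq / 3) / N
    """
    if n_atoms < 1:
        raise ValueError("n_atoms must be >= 1")
    return (energy_sq_error / n_atoms + q * force_sq_error / 3.0) / n_atoms


def update_history(state: SelectionState, fit_ids, new_losses, total_loss: float) -> None:
    """Apply the post-evaluation update rules to the fitted conformations.

    ``new_losses`` must align with ``fit_ids``; ``total_loss`` is the mean
    per-conformation loss of the subsample (the denominator of L_rel).
    """
    idx = state.indices(fit_ids)
    new_losses = np.asarray(new_losses, dtype=float)
    if len(idx) != len(new_losses):
        raise SelectionError("new_losses must align with fit_ids")
    hp = state.hp
    if total_loss <= 0:
        total_loss = np.finfo(float).tiny
    for i, loss in zip(idx, new_losses):
        if state.s_hist[i] == 0:  # exclusion is absorbing
            state.l_old[i] = loss
            continue
        l_rel = loss / total_loss
        prev = state.l_old[i]
        # 1) outlier strike counter
        if l_rel > hp.t_x:
            state.strikes[i] += 1
            if state.strikes[i] >= hp.n_x:
                state.s_hist[i] = 0.0
                state.l_old[i] = loss
                continue
        else:
            state.strikes[i] = 0
        # 2) reset-to-one rules around the band [T_F1, T_F2]
        if l_rel >= hp.t_f1 and state.s_hist[i] < 1:
            state.s_hist[i] = 1.0
        if l_rel <= hp.t_f2 and state.s_hist[i] > 1:
            state.s_hist[i] = 1.0
        # 3) multiplicative factors (skipped on the first evaluation)
        if not np.isnan(prev):
            increased = loss > prev
            if l_rel < hp.t_f1:
                state.s_hist[i] *= hp.f_minus if increased else hp.f_minus_minus
            elif l_rel >= hp.t_f3 and increased:
                state.s_hist[i] *= hp.f_plus_plus
            elif l_rel >= hp.t_f2 and increased:
                state.s_hist[i] *= hp.f_plus
        # 4) exclusion thresholds
        if 0 < state.s_hist[i] < hp.s_min:
            state.s_hist[i] = 0.0  # redundant
        elif state.s_hist[i] > hp.s_max:
            state.s_hist[i] = 0.0  # inconsistent
        state.l_old[i] = loss


def update_p_good(state: SelectionState, new_total_loss: float) -> None:
    """Move p_good by one quantum toward more rehearsal when the total loss
    increased, toward more bad data when it decreased; clamp to
    [0, p_good_max]. Stores the new total."""
    hp = state.hp
    if new_total_loss > state.l_old_total:
        state.p_good = min(state.p_good + hp.p_quantum, hp.p_good_max)
    else:
        state.p_good = max(state.p_good - hp.p_quantum, 0.0)
    state.l_old_total = float(new_total_loss)
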