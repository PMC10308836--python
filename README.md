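# lmlpot — lifelong machine-learning potentials

`lmlpot` is a library (plus a thin CLI) for building **machine-learning
interatomic potentials that keep learning**: instead of retraining from
scratch whenever new reference calculations arrive, a potential absorbs new
conformations during training while rehearsing old ones, pruning redundant
and inconsistent data, and reporting uncertainties so its predictions can be
trusted at every stage. It is aimed at method developers and computational
chemists who want the individual ingredients — descriptors, model, optimizer,
data selection, uncertainty — as composable, tested pieces.

## What is inside

**Element-embracing descriptors (eeACSFs).** Atomic environments are encoded
with atom-centered symmetry functions whose neighbor contributions are
weighted by normalized periodic-table descriptors of the neighbor element
(period *n*, main group *m*, d-group *d*) instead of being split by element
pair. Radial functions take the form

    G_rad = sqrt( Σ_j (H_j / H_max) · exp(−η R_cj²) · f_c(R_cj) )

with the bump cutoff f_c(R) = exp(1 − 1/(1 − (R/R_c)²)) whose derivatives of
all orders vanish at R_c, and the angular analog carries a
2^(1−ζ)(1 + λ cos θ)^ζ kernel over neighbor pairs. The descriptor vector
length is therefore **independent of the number of chemical elements**
(153 at the production resolution), while conventional ACSFs grow to 750 for
ten elements at the same resolution. Conventional ACSFs are included for
comparison. All descriptors come with analytic position Jacobians.

**High-dimensional neural network potential (HDNNP).** The total energy is a
sum of atomic energies, one feed-forward network per element
(E = Σ_m Σ_n E_atom,n^m), with trainable per-input standardization weights
α (inverse std) and β (mean), activation f(x) = 1.59223·tanh(x), and a
linear output neuron. Forces are exact negative gradients through the
descriptor Jacobian; the force part of the training gradient is computed by
an explicit forward-over-reverse pass (no autodiff framework required).

**CoRe optimizer.** A continual resilient first-order optimizer combining
RPROP-style per-weight sign-adaptive step sizes with Adam-style
bias-corrected moving averages, plus a Gaussian β₁(τ) schedule, importance
scores with plasticity-based weight freezing against forgetting, and a
multiplicative weight decay. Adam and sign-based RPROP (without
backtracking) are exact special cases, verified in the test suite.

**Lifelong adaptive data selection.** Each epoch draws a subsample that
balances poorly-represented ("bad") and well-represented ("good")
conformations from loss-history-based probabilities; per-conformation
factors S_hist track the history, excluding persistently trivial data as
redundant and persistent outliers (strike counter) as inconsistent.

**Ensemble uncertainty.** Committees of independently trained potentials
predict via the member mean; the uncertainty is c·(sample std) floored by
the reference RMSE, which covers in-distribution errors and flags
extrapolation.

**Synthetic reaction surface.** A Morse-based toy PES with exact analytic
forces emulates exchange-reaction reference data (two-distance scans over
1.05–5.25 Å, random sphere displacements, 15 eV Å⁻¹ force cap), so the whole
pipeline is testable end to end without any external data.

## Worked example

`examples/03_train_potential.py` trains one potential on a 400-conformation
synthetic Cl–C–Cl exchange scan (energies span ≈2.2 eV per atom):

```
dataset: 400 conformations, energy std 1.423 eV
loss: epoch 1 = 116, epoch 300 = 0.00624
selection pool: 360 -> 360 conformations, p_good = 0.12
held-out energy RMSE: 11.8 meV (0.8% of the energy std)
held-out force-component RMSE: 21.3 meV/A
```

The loss falls four orders of magnitude in 300 epochs; the held-out energy
error lands at ~12 meV (3 atoms, i.e. ~4 meV per atom), about 1% of the
dataset's energy spread, and p_good shows the selection shifting a fraction
of each subsample to rehearsal as training converges. The other examples
cover descriptors (`01`), synthetic data generation (`02`), the optimizer
and its Adam/RPROP reductions (`04`), and ensemble uncertainties (`05`).

A CLI wraps the same workflows:

```bash
lmlpot synth --seed 1 --out scan.xyz
lmlpot train scan.xyz --members 3 --out model.h5
lmlpot predict model.h5 scan.xyz
lmlpot evaluate model.h5 scan.xyz
```

## Layout

```
src/lmlpot/
  elements.py     periodic-table descriptors (n, m, d) for H–Xe
  data.py         Conformation/Dataset, extended-XYZ I/O, force cap
  descriptors.py  eeACSF + ACSF values and analytic Jacobians
  model.py        per-element networks, energies, forces, gradients
  optimizer.py    CoRe (Adam/RPROP as special cases)
  selection.py    lifelong adaptive data selection
  training.py     loss, training loop, RMSE metrics
  uq.py           committee prediction and uncertainties
  synthetic.py    Morse toy PES, scan/displacement samplers
  workflows.py    train_potential / train_ensemble / evaluate
  checkpoint.py   single-file HDF5 persistence of all training state
  cli.py          `lmlpot` command group
```

See `docs/methods.md` for the model conventions, default hyperparameters,
and the design choices behind the numerical methods.
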