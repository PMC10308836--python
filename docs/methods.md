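# Methods

This note records the model conventions, default parameters, and numerical
choices implemented in `lmlpot`, including the places where the design was
genuinely open and a convention had to be fixed.

## Units and data model

Coordinates are in Å, energies in eV, force components in eV Å⁻¹
throughout; conversions to meV (per atom) happen only in reporting. A
`Conformation` is one geometry with optional reference energy and forces;
reference energies are treated as opaque training targets (by convention
total energies minus neutral free-atom energies — the library does not
subtract atomic energies itself). Extended-XYZ files carry the energy as an
`energy=` key on the comment line (aliases `Energy`, `E`, `total_energy`
accepted on read) and forces as per-atom columns 5–7; numeric fields are
written with 17 significant digits so round trips are lossless at double
precision. Conformations without force columns simply have no forces.
Datasets can be pre-filtered with a force cap (default 15 eV Å⁻¹) that drops
conformations whose largest absolute force component exceeds the cap.

## Element descriptors and symmetry functions

Every supported element (periods 1–5, H–Xe) carries integers *n* (period),
*m* (main group 1–8, with He = 8, and 0 for the d-block) and *d* (IUPAC
d-block group 3–12, 0 for the main group). Heavier elements raise an
`UnsupportedElementError`; extending the table with f-block descriptors
would follow the same pattern.

**Radial element terms.** Five variants for main-group-only systems —
constant 1, *n*, 6−*n*, *m*, 9−*m* — and two more (*d*, 13−*d*) when
d-block elements are enabled. Each raw value is divided by its maximum over
the full element table (brute-force, cached), so every weight lies in
(0, 1] on the elements where it applies; complements are defined as
(max+1)−value so they never vanish on their own block. The complement
variants weight light elements up where the plain variants weight heavy
elements up, balancing contributions of light/heavy and few/many-valence-
electron elements.

**Angular element terms.** The constant term (γ = +1 only) plus, for each
non-constant variant v (one d variant when the d-block is enabled), the two
γ = ±1 linear combinations ½[(v_j v_k + v̄_j v̄_k) ± (v_j v_k − v̄_j v̄_k)]
with v̄ = 1 − v, i.e. the product of the two neighbor values and the product
of their complements, each normalized by its maximum over element pairs.
This yields 9 terms (11 with d-block), keeps every weight in [0, 1], and is
symmetric under neighbor exchange. Keeping the weights nonnegative is what
allows the square root below to be total.

**Functional forms.** With the compactly supported bump cutoff
f_c(R) = exp(1 − 1/(1 − (R/R_c)²)) for R < R_c (exactly 0 beyond, all
derivatives vanishing at R_c, f_c(0) = 1):

    G_rad(c; η, v)        = sqrt( Σ_j  w_v(j) · e^{−η R_cj²} · f_c(R_cj) )
    G_ang(c; η, λ, ζ, v, γ) = sqrt( Σ_{j<k} W_{vγ}(j,k) · 2^{1−ζ}(1 + λ cos θ_jck)^ζ
                                     · e^{−η (R_cj² + R_ck² + R_jk²)}
                                     · f_c(R_cj) f_c(R_ck) f_c(R_jk) )

Every single-interaction term before the square root lies in [0, 1]; the
square root moderates the growth of the value with the neighbor count.
Conventional ACSFs use the same kernels without element weights and without
the square root, split per element (radial) and unordered element pair
(angular, including same-element pairs). The angular kernel damps all three
pair distances (the "G4" convention); an alternative without the R_jk
factor would change values but none of the counting or invariance
properties.

**Enumeration order** is deterministic — radial block first, then angular;
variants (or elements/pairs) outermost, then η, λ, ζ — so a trained model
is portable across runs. Counts: eeACSF n_G = n_variants·|η_rad| +
n_ang_variants·|η_ang|·|λ|·|ζ| independent of the element count (153 for
9 radial η and the 2·2·3 angular grid); ACSF n_G = N_elem·|η_rad| +
N_elem(N_elem+1)/2·|η_ang|·|λ|·|ζ| (156 for 4 elements, 750 for 10 at the
same resolution).

**Gradients.** Analytic Jacobians ∂G/∂r are assembled per center from the
pair/triple geometric derivatives and verified against central finite
differences (h = 10⁻⁵ Å) to relative error < 10⁻⁵ in the tests. Atom pairs
closer than 10⁻⁸ Å raise a degenerate-geometry error rather than produce
NaNs; cos θ is clipped to [−1, 1] against roundoff.

## The potential

Each element has its own feed-forward network applied to that atom's
descriptor vector; the total energy is the sum of atomic outputs. The input
is standardized as x = α ⊙ (G − β) with trainable α, β; β is initialized to
the per-element mean descriptor value over the initial training data and α
to the inverse standard deviation, clamped to [10⁻³, 10³] so constant
features cannot produce infinite scales. α and β belong to their own weight
groups, separate from the layer weights. Hidden layers use
f(x) = 1.59223·tanh(x) (slope ≈ 1.59 at the origin, keeping the variance of
standardized signals roughly unit through depth); the output neuron is
linear. The reference architecture is n_G–102–61–44–1; the synthetic-data
tests use smaller stacks (e.g. 25–20–15) fitting the 3-atom toy systems.

Layer weights are initialized uniformly in ±sqrt(3/fan_in) (unit-variance
pre-activations on standardized inputs), biases at zero; the scheme is
seeded and bit-reproducible.

Forces are F = −(∂E/∂G)·(∂G/∂r). Training on forces requires
∂²E/(∂θ ∂G) contracted with a tangent; this is implemented as an explicit
forward tangent propagation (ẋ_l through the layers) followed by
backpropagation through both the primal and tangent computations. The whole
gradient is verified against finite differences of the loss in the tests.

## Loss

The printed form of the loss normalization was not fully recoverable, so
the following convention is fixed and used consistently:

    L = (1/N_batch) Σ_r [ (ΔE_r / N_r)² + (q / (3 N_r)) Σ_{n,α} ΔF_{α,n,r}² ]

with q = 10.9 by default (balancing energies against forces). The same
per-conformation quantity ℓ_r is the selection algorithm's loss
contribution, and L_rel = ℓ_r / mean(ℓ) over the subsample, so that
well-represented data sit below 1 and outliers far above it.

## CoRe optimizer

Per weight ξ, with step counter τ advancing only when the weight's group
receives a gradient:

* g ← β₁(τ) g + (1−β₁(τ)) ∇L, h ← β₂ h + (1−β₂) (∇L)², with the schedule
  β₁(τ) = β₁ᵇ + (β₁ᵃ − β₁ᵇ)·exp(−((τ−1)/β₁ᶜ)²) interpolating from β₁ᵃ at
  τ = 1 to β₁ᵇ (the exact printed form of the Gaussian was not recoverable;
  this realization matches the stated endpoints and shape).
* u = ĝ / (√ĥ + ε) with bias corrections 1−β₁(τ)^τ and 1−β₂^τ (the
  scheduled β₁ raised to τ).
* Plasticity P ∈ {0,1}: all ones while τ ≤ t_hist; afterwards the n_frozen
  highest-score weights per group are frozen for the step, ties broken by
  the lower index for determinism.
* Step size: s grows by η₊ (capped at s_max) when g^τ g^{τ−1} > 0, shrinks
  by η₋ (floored at s_min) when < 0, and is left unchanged when P, g^τ or
  g^{τ−1} is zero; g^{τ−1} is cached before the moving-average update
  overwrites it.
* Update: w ← w·(1 − d·|u P s|) − u P s. The decay bounds |w| by 1/d when
  |u| ≤ 1 (a fixed point of the iteration, asserted in the tests).
* Score: S accumulates g·u·P·s — an equal-weight sum of the first t_hist
  contributions, an exponential moving average with decay 1 − 1/t_hist
  afterwards; positive S estimates realized loss decrease.

Defaults: β₁ᵃ = 0.45, β₁ᵇ = 0.7, β₁ᶜ = 500, β₂ = 0.999, ε = 10⁻⁸,
η₋ = 0.5, η₊ = 1.2, s_min = 10⁻⁶, s_max = 1, s⁰ = 10⁻³, t_hist = 500. For
HDNNPs, groups are (element, weight type, layer); n_frozen is 1% of the
group size for hidden-layer weights/biases and 0 for the output layer and
α/β; weight decay is 0.1 for hidden layers, 0.01 for α/β, 0 for the output
layer (atomic energies must be unrestricted).

Adam is the exact special case (β₁ᵃ = β₁ᵇ, η± = 1, n_frozen = 0, d = 0;
learning rate s⁰) and sign-based RPROP without backtracking the special
case β₁ = β₂ = 0, n_frozen = 0, d = 0 (exact for ε = 0; with ε > 0 the
update factor differs from the sign by |g|/(|g|+ε)). A `sign_update` flag
switches u to sgn(g) directly.

## Lifelong adaptive data selection

Defaults: S_min = 0.1, S_max = 100, N_F−− = 30, N_F− = 100, N_F+ = 500,
N_F++ = 150, N_X = 5, N_p = 20, ε′ = 10⁻⁶; the factors are
F∓(∓) = S_min^(1/N_F∓(∓)) and F±(±) = S_max^(1/N_F±(±)). The thresholds
T_F1 = 0.5, T_F2 = 2, T_F3 = 5, T_X = 10 and p_good_max = 0.5 are this
package's choices satisfying the required ordering T_F1 < 1 < T_F2 < T_F3
< T_X; they are exposed as configuration.

Bad-data probabilities are ∝ (L_old/L_old_max)·S_hist with never-evaluated
conformations weighted by max(S_hist); good-data probabilities over the
remainder are ∝ 1 − L_old/L_old_max, with maximal-loss and unevaluated
entries floored at ε′·(minimum nonzero weight), the floor computed after
the 1 − L/L_max weights. N_good = floor(p_good·N_fit) (the remainder is
drawn as bad data); draws are without replacement within an epoch. p_good
starts at 0 and moves by p_good_max/N_p per epoch — up when the subsample
loss increased, down when it decreased (the initial total of +∞ counts as a
decrease, keeping p_good at 0).

The post-evaluation update applies, in this order: the outlier strike
counter (L_rel > T_X increments, anything else resets; N_X consecutive
strikes exclude); the reset-to-one rules around the band [T_F1, T_F2];
the multiplicative factors (F−− for non-increasing well-represented data,
F− otherwise below T_F1; F+ for increased loss in [T_F2, T_F3); F++ for
increased loss at ≥ T_F3), skipped on a conformation's first evaluation;
and the exclusion thresholds (below S_min: redundant; above S_max:
inconsistent). Exclusion (S_hist = 0) is absorbing. The prose description
of the algorithm does not fully serialize these rules; the order above is
fixed here and tested.

The per-epoch subsample size counts all training conformations including
those that only become available at a late epoch, so rehearsal throughput
does not shrink relative to the eventual data volume — without this
convention, injected data is systematically under-trained.

## Ensembles and uncertainty

The committee prediction is the member mean; the uncertainty is
ΔE = max(c·std_{p}(E_p; ddof = 1), RMSE_floor) with c = 2 by default, and
componentwise analogously for forces. The floors are the ensemble's RMSEs
on its reference data (the model is never more certain than its residual
error). Production ensembles use 10 members; the tests use 3–5 for speed.
Each member gets its own 90/10 train/test split, weight initialization, and
selection stream from a member-specific seed; the per-epoch subsample is
10% of the training conformations by default.

## Synthetic reference data

The toy surface is a sum of pairwise Morse terms
D_e[(1 − e^{−a(r − r_e)})² − 1] with an optional three-body
k·cos θ·e^{−(R_ij²+R_ik²)/ρ²} term, chosen because it is short-ranged,
smooth, parameterizable per element pair, and has closed-form forces. The
default two-element parameterization (C–Cl: D_e = 2.5 eV, a = 1.0 Å⁻¹,
r_e = 1.8 Å; Cl–Cl: 1.0, 0.8, 2.8; C–C: 2.0, 1.0, 1.5) gives a Cl–C–Cl
exchange cluster an energy spread of ≈ 2.2 eV per atom over the sampled
range while keeping every force component below the 15 eV Å⁻¹ cap.

The scan sampler grids both exchange distances over [1.05, 5.25] Å with a
quadratically stretched (short-range-dense) grid and applies jitter bounded
by 0.45 of the gap to each adjacent grid value, so the jittered grid can
never reorder. The displacement sampler moves every atom uniformly inside
an atom-centered sphere (radii 0.05/0.1/0.15 Å by default, three copies per
base conformation) and redraws the whole conformation if any distance falls
below the 0.7 Å guard.

What the generator emulates: reaction-path-plus-distortion sampling, a
realistic energy scale, exact force labels, multiple elements. What it does
not: electronic-structure noise and method inconsistency, conformational
diversity of larger molecules, long-range electrostatics, and charged- or
spin-state physics. Tests passing on this data therefore demonstrate the
correctness and interplay of the algorithms, not chemical accuracy on real
systems.

## Scale of the shipped experiments

The end-to-end committee test trains 5-member ensembles on a 400-
conformation two-element scan for 300 epochs (subsample 10% per epoch,
n_G = 97 descriptor resolution, 25–20–15 hidden layers) — small enough to
run in about a minute on one CPU while exercising every component: on this
clean surface the held-out energy RMSE lands near 1% of the data's energy
spread, lifelong injection of 50% more data at epoch 150 matches training
on all data from scratch, the committee beats its median member, and the
c = 2 uncertainty covers more than 90% of in-distribution errors while
growing several-fold outside the sampled grid.

## Known limitations

* No periodic boundary conditions (molecular systems only), no
  electrostatics or charge/spin conditioning.
* Descriptor evaluation is plain numpy, adequate for clusters of tens of
  atoms; large production systems would need neighbor lists and compiled
  kernels.
* The f-block is not parameterized (elements above Xe are rejected).
* Eq-level bit compatibility with other implementations of the same ideas
  is not guaranteed where this note fixes a convention (loss normalization,
  β₁ schedule, element-term sets, threshold values).
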