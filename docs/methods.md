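# Methods

This note records the model titrakit implements, the numerical choices
behind it, and what the synthetic experiments do and do not demonstrate.

## Chemical model

A system is a set of free components plus complexes with integer
stoichiometric coefficients (matrix **M**, components × complexes) and,
optionally, homopolymers of a single component.  Every complex has a
global association constant β_j = σ_j·Π_k v_k^(e_kj): σ_j is a statistical
factor (default 1; binomial coefficients in the non-cooperative preset),
the v_k are shared positive variables, and the exponents e_kj may be
negative or fractional — needed to express, e.g., a squared denaturant
constant for a doubly solvated species or an effective molarity entering
with exponent −1.  Units of β_j are M^(1−Σ_i M_ij) by construction; all
concentrations are molar and all volumes litres, in files as in memory.

Polymers follow the K₂/K_n convention: chains of length n ≥ 2 with
c_n = K₂·K_n^(n−2)·s^n (dimerisation constant K₂, elongation constant K_n,
both M⁻¹; the isodesmic model ties them to one variable).  The geometric
series give closed forms used throughout, valid for u = K_n·s < 1:

    Σ c_n   = K₂s²/(1−u)            (number of chains; the free-energy term)
    Σ n·c_n = K₂s²(2−u)/(1−u)²      (monomer sequestered; mass balance)
    Σ n²c_n = K₂s²(4−3u+u²)/(1−u)³  (curvature term)

These are the package's own reconstruction of the polymer contribution to
the speciation function; the test suite validates them against
term-by-term summation to 1e-9 relative up to u = 0.99.

## Speciation solver

With x_i = ln(s_i/c°) (c° = 1 M), the mass-balance constraints
t = s + Mc(s) are the stationarity conditions of

    F(x) = Σ_i s_i + Σ_j c_j(s) − Σ_i t_i x_i + Σ_polymers K₂s²/(1−K_n s),

which is convex in x (a sum of exponentials of linear forms minus a linear
form), so the equilibrium is its unique minimum and the gradient at the
solution equals the physical mass-balance error.  The solver is a
projected damped-Newton iteration on the exact Hessian
H = diag(s + Σn²c_n) + M·diag(c)·Mᵀ inside a stability box:

* upper bounds s_i ≤ t_i, and s_i ≤ (1−1e-9)/K_n for polymer components
  (series convergence);
* lower bounds ln s_i ≥ ln t_i − 500 (underflow guard);
* components with t_i = 0 are eliminated along with every complex
  containing them — no epsilon substitution, hence no log singularities.

Three details matter in practice.  (1) Newton steps are capped at 100 nats
per coordinate: when an iterate underflows deep below the solution the
Hessian row vanishes and the raw step would be astronomically long.
(2) Near the minimum the decrease of F falls below its floating-point
resolution before the gradient reaches its target; there the line search
is replaced by full Newton steps accepted on gradient decrease alone
(quadratic contraction regime).  (3) Tolerances are per component:
convergence requires |∂F/∂x_i| ≤ max(1e-10·t_i, 1e-22 M) for every i, and
the iteration aims three decades lower, so trace components (picomolar
binding sites next to millimolar ligands) are balanced to the same
*relative* accuracy as abundant ones.  A scalar tolerance scaled only by
max(t) would silently leave the trace components' balance wrong by parts
in 1e-5.  scipy's L-BFGS-B (bounded, with the analytic gradient) serves as
a fallback when the Newton path stalls, followed by another Newton polish.
Warm starts (the previous addition's solution, clipped into the new box)
accelerate titration sweeps.  Non-convergence is always flagged on the
result, never silent.

## Observation models and the linear inner problem

The observed matrix is Y = A·X.  Under slow exchange (and for UV/vis or
fluorescence) A holds molar state concentrations; a polymer state carries
the monomer concentration sequestered in chains, so its spectrum is per
repeat unit.  Under fast exchange each signal declares a reference
component and A holds the mole fractions of that component across its
states (a complex with m copies contributes m·c/t_ref); rows then sum to 1
and the solved X entries are chemical shifts.  The map is built once, with
a deterministic state ordering (free components, then complexes in
declaration order, then polymers) so all matrices are reproducible.

Relationships between spectra are rows of a matrix R over named spectral
variables: the additive preset writes spectrum(complex with k bound
guests) = spectrum(free host) + k·Δ; custom fractional rows express
population-weighted shifts (used in the denaturation scenario); known
spectra become fixed offsets and leave the variable set.  R must have full
column rank or the model is rejected at build time, naming the
unidentifiable variables.

Given A, the spectra are solved exactly per signal by ordinary least
squares (numpy lstsq), or by NNLS when nonnegative absorbances are
enforced; masked (NaN) cells are excluded from both the solve and the RMSE
denominator.  The RMSE pools all signals with equal weight by default — an
optional per-signal weight vector exists, since instruments with mixed
units (ppm next to intensity) may warrant it.

## Outer optimisation

Equilibrium variables are searched as log₁₀ values; unknown concentrations
("?" cells) as log₁₀ M bounded to [1e-12, 10] M, or to two decades either
side of a "~" guess.  Initial guesses default to 1 in the variable's
natural unit unless the variable or cell carries one; guesses within two
orders of magnitude of the optimum are ample in practice.  The search is
Nelder–Mead with one automatic restart from the incumbent at tightened
tolerances (simplex spread < 1e-12·(1+rmse) in objective, ~1e-6 relative
in parameters).  A failed inner speciation returns a penalty of 1e6 times
the data scale, keeping the simplex alive, and is logged.  An optional
multi-start takes an explicit seed; the default is a single deterministic
start.  The estimator front end (`TitrationFitter`) wraps this in the
scikit-learn fit/predict contract.

## Evaluation tools

The RMSE profile fixes one variable across a grid (default 25 log-spaced
points over ±2 decades around the fitted value) and re-optimises the rest,
sweeping left-to-right then right-to-left with warm starts and keeping the
lower of the two passes, which guards against hysteresis of the
derivative-free inner fits.  Grid points whose fit fails are marked, not
fatal.  Normalised plots rescale each signal by its observed first-to-last
change (purely data-driven; signals with change below 1e-12 of the data
scale are flagged and skipped).  Population tables report the fraction of
a reference component in each containing species; rows sum to 1 within the
speciation tolerance.

## Synthetic data

The simulator runs the exact forward model (speciation → A → A·R·X_true)
and adds iid Gaussian noise per cell — the simplest defensible error
model.  It does not emulate baseline drift, heteroscedastic or
correlated instrument noise, volume errors, or impurities; passing
recovery tests therefore demonstrates the correctness and conditioning of
the estimator under the stated noise model, not robustness to systematic
experimental error.

Packaged scenarios (all parameter values chosen to resemble published
supramolecular systems; sizes chosen so the full suite runs in minutes):

* `uv_1to1` — plain 1:1, K = 5000 M⁻¹, 0.1 mM host (K·t = 0.5), 15
  additions to 20 guest equivalents, 8 wavelengths.  The recovery
  workhorse: at 2% (of each signal's change) noise, the median error of K
  over 50 replicates is ~3%.
* `uv_1to1_guest` — 1:1 with an absorbing guest (K = 3800 M⁻¹): three
  species contribute per wavelength, and the free-guest absorbance is
  nearly collinear with the isotherm tail, a deliberate conditioning
  stress.
* `nmr_1to2` — fast-exchange 1:2 (K₁ = 328 M⁻¹, K₂ = 34800 M⁻²), three
  signals with very different sensitivity to the second binding event; the
  normalised plot separates them.
* `tight_1to2_stock` — 1:2 in the tight-binding regime (host ≫ 10/K₁,
  stocks nominally 1.11/25.0 mM) where the true host stock is 16% below
  the nominal value.  Fitting with the wrong fixed stock corrupts K₁ by
  >100%; flagging the stock "~" restores K₁ to <1% and pins the host/guest
  stock ratio to ~0.1% — while K₂ remains poorly determined at realistic
  noise, as expected when most points lie on the two straight-line
  asymptotes.  Guest additions extend to ~40 equivalents so the weak
  second event (K₂/K₁ ≈ 5 M⁻¹) is populated at all.
* `displacement_partial` — fluorescence displacement with two site types
  (66%/34% split, ~81 pM total sites), only one of which binds the silent
  competitor; the reporter's bound emission is one shared spectral
  variable, its free emission a fixed known spectrum, and both site
  concentrations are optimised.
* `denaturation_network` — ten stoichiometric species (two free + eight
  complexes) of a duplex denatured by a competing solvent.  Eight global
  constants derive from six variables (one optimised, five fixed) with
  statistical factors of 2 for the degenerate singly-solvated modes and a
  squared solvent constant for doubly solvated species; the shifts of five
  species are fractional combinations of two variables (δ_f, δ_b) and one
  dimer shift is a fixed known value.  Exercises every constraint
  mechanism at once.

## Design choices and limitations

* The spectral state ordering, CSV dialect (comma, "." decimal, UTF-8) and
  the acceptance of both "~" and the typeset "∼" are fixed for
  reproducibility and copy-paste robustness; there is no locale sniffing.
* Stocks-and-volumes plans treat the first volumes row as the initial cell
  contents drawn from the same stock table; a solvent blank is a stock of
  zeros.  This keeps the dilution bookkeeping a single cumulative sum.
* Monotonicity caveat: raising one β_j always (weakly) raises c_j, but
  need *not* lower the free concentration of every component in complex j
  — with a limiting partner, shifting it into higher-stoichiometry
  complexes can release the other component.  The tests assert only the
  true statement.
* Model comparison is deliberately diagnostic (profiles, normalised plots,
  populations); F-tests, information criteria and bootstrap error bounds
  are out of scope.  So are activity corrections, ionic strength,
  temperature dependence, and vendor file formats (a converter registry is
  the extension point).
* The outer search is local; a redundant parameterisation (e.g. a product
  of two constants where only the product is identifiable) yields a flat
  RMSE profile rather than an error, and that is the intended diagnostic.
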