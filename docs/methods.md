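# Methods

`abfekit` implements an adaptive window-allocation protocol for absolute
alchemical binding free-energy (ABFE) calculations, the free-energy
estimators it relies on, the restraint and standard-state bookkeeping that
turns leg free energies into a standard binding free energy, a binned 2D
free-energy-surface (FES) estimator for umbrella-sampled collective
variables, and the two-state thermodynamic cycle that links
macrostate-resolved binding free energies to disorder–order population
shifts. Everything runs against synthetic sampling backends with exact
analytic ground truth, so the statistical behaviour of the protocol can be
tested quantitatively on a desk-scale budget.

## Reduced potentials and estimators

All estimators consume a reduced-potential table `u[k, n]`: every sample
`n`, drawn from whichever window, evaluated in the Hamiltonian of every
window `k` and divided by kT. Free energies are dimensionless (kT units)
with the gauge `f[0] = 0`; multiplying by kT (0.59248368 kcal/mol at
298.15 K with R = 0.0019872 kcal/mol/K) converts to energies.

**MBAR.** The multistate Bennett acceptance ratio solves

```
f_k = -ln Σ_n exp(-u_kn) / Σ_l n_l exp(f_l - u_ln)
```

Numerically we interleave damped Newton steps on the convex MBAR objective
`Σ_n ln Σ_l n_l exp(f_l - u_ln) - Σ_k n_k f_k` (Hessian
`diag(rowsum B) - B Bᵀ` with `B_kn = n_k exp(f_k - u_kn)/D_n`, gauge fixed
by pinning `f[0]`) with self-consistent sweeps, terminating when the
max-norm of the self-consistent update drops below `tol` (default 1e-10;
`max_iter` 10 000). The solve is deterministic and independent of sample
order; a non-converged solve is returned flagged, never silently. Windows
with essentially no overlap are detected by comparing forward and reverse
exponential-averaging estimates per adjacent pair and reported through a
warning flag on the results object.

**BAR and EXP.** The two-state Bennett estimator is solved independently
by bracketed root finding on the Bennett implicit equation (the K = 2
fixed point of MBAR, so the two agree to solver tolerance — a cross-check
the tests exercise). One-sided exponential (Zwanzig) averaging is kept as
a bracketing oracle; all averages use log-sum-exp.

**Replicate spread.** The adaptive protocol's convergence statistic is the
sample standard deviation (n−1 denominator) of a pair free-energy change
across independent replicates. The standard error (sd/√n) is also exposed
but is not the default: with quintuplicate runs and a threshold of
0.1 kcal/mol, the per-replicate spread is the scale the protocol's
threshold is calibrated against.

## Lambda schedule and ABFE assembly

Double decoupling uses two legs (ligand in the protein site, ligand in
solution), each with an electrostatic stage followed by a Lennard-Jones
stage. The default schedule is 12 coulomb + 26 vdw windows per leg — 76
windows total — uniformly spaced in λ per stage (spacing is configurable
with explicit lists; the endpoints 0 and 1 are mandatory). Stage and leg
boundaries join identical physical states, so adjacent-pair estimation
never crosses a boundary and the boundary free-energy change is
identically zero by convention.

Assembly follows the documented sign convention (decoupling free energies
are G(decoupled) − G(coupled)):

```
dG°_bind = dG_decouple_free - dG_decouple_bound
           - dG_restraint_on_bound - dG_standard_state
```

The restraint-switching free energy in the bound state is accepted as an
input component; the package does not re-derive it from trajectories.

**Boresch standard-state correction.** For a six-degree-of-freedom
harmonic orientational restraint (distance r, angles θA/θB, dihedrals
φA/φB/φC) the stiff-restraint closed form is

```
dG_ss = -RT ln[ 8π² V° √(k_r k_θA k_θB k_φA k_φB k_φC)
                / ( r0² sinθA0 sinθB0 (2πRT)³ ) ]
```

with V° = 1660.54 Å³ (1 M). The tests verify it against a brute-force
quadrature oracle — the restrained configurational integral factorises
into six 1D integrals with the r² and sinθ Jacobians — to ≤ 0.01 kcal/mol
over a grid of force constants (5–250 kcal/mol/Å² or rad²), reference
angles and temperatures. The approximation degrades for soft restraints
(RMS fluctuation comparable to r0 or sinθ0); a diagnostics ratio triggers
a warning above 0.3.

## Adaptive protocol

One *epoch* is a fixed slab of sampling per active window per replicate
(default 200 samples — the engine-agnostic stand-in for the 5 ns epoch of
an MD implementation; a static 50 ns/window reference run is then 10
epochs). After each epoch, every non-retired adjacent pair is re-estimated
per replicate from **all** samples accumulated so far for that replicate,
and the across-replicate spread is compared against τ (default
0.100 kcal/mol). Pairs at or below τ retire — permanently — and a window
keeps sampling only while it belongs to at least one live pair (a flagged
pair keeps *both* member windows active). Termination at `max_epochs`
(default 15) or when all pairs have retired. Design choices made where the
protocol description left room:

- **Premature-termination guard.** A pair may retire only after
  `min_epochs` (default 2) epochs of data: one-epoch spread estimates with
  4 degrees of freedom are too noisy to trust on their own. The guard is
  configurable.
- **Pairwise BAR by default.** The per-epoch pair estimates use the
  two-window BAR solve; a full-leg MBAR route (`pair_estimator="mbar"`,
  per contiguous stage) gives the same pair-delta definition and is kept
  for cross-checking, but per-epoch full-leg solves are disproportionate
  at the problem sizes this package targets.
- **Final re-estimation.** The final per-pair free-energy changes are
  recomputed from every sample each window ever accumulated. A pair whose
  neighbourhood kept sampling after it retired benefits from the extra
  data; for fully stopped pairs this reproduces the frozen value.
- **Seeding.** One master seed spawns an independent RNG stream per
  (window, replicate) via `SeedSequence.spawn`, so retiring a window never
  perturbs any other stream; raising τ yields sample streams that are
  prefixes of lower-τ runs, making τ-monotonicity of the budget testable
  exactly. Runs are byte-for-byte reproducible from (spec, config, seed).
- **Resumability.** An epoch's draws are committed only once complete; a
  backend failure mid-epoch leaves the controller at the previous epoch
  and `run()` resumes.

The static reference protocol shares the sampling and estimation path with
retirement disabled; `savings_factor` is the ratio of total samples drawn.

## Synthetic ladder backend

Alchemical ensembles are emulated by one-dimensional harmonic windows
`u_k(x) = (x - c_k)²/(2 w_k²)`, whose partition functions are closed-form:
the exact pair free-energy change is `ln(w_i/w_j)` kT. The reference
76-window ladder grows widths geometrically (ratio 1.5) and drifts centres
by 0.8 widths per step within each (leg, stage) block, giving every pair
the same moderate overlap: the across-replicate spread of a well-behaved
pair sits below τ after the two-epoch guard, so well-behaved windows
retire early, as they should.

Two adjacent windows in the middle of the bound-leg vdw stage are
designated *slow*, emulating the partially decoupled Lennard-Jones states
whose frustrated water exchange dominates the sampling cost of a real
binding site. Their coordinate streams follow a stationary AR(1) process
(lag-1 autocorrelation φ = 0.95, cutting the effective sample size ~39×)
with the sampled marginal inflated by a factor 1.5 in variance. The AR(1)
part models kinetic frustration and leaves estimators consistent; the
variance inflation adds a controlled sampling-distribution mismatch so
that slow-pair spreads start several-fold above τ. Both protocols see the
identical mismatch, so adaptive-vs-static comparisons are unaffected;
truth-recovery tests use backends without inflation. The two slow windows
are adjacent so that the slow–slow pair (two autocorrelated streams)
outlasts the mixed fast–slow pairs, concentrating samples on the slow
windows themselves.

What the ladder does **not** emulate: multidimensional configuration
spaces, softcore functional forms, replica exchange, or equilibration
transients. Passing the protocol tests shows the controller allocates
samples where the statistical noise is and introduces no allocation bias —
it says nothing about force fields or conformational sampling of real
systems.

The per-seed adaptive-vs-static comparison is noisy (the early-retired
pairs carry ~kT/10-scale residuals by construction), so the
resource-concentration property — slow windows accumulate strictly more
samples than every fast window — is asserted on the sampling ledger
aggregated over the 50 seeds; in an individual seed a lucky 4-dof spread
estimate can retire a slow pair early with small probability.

## 2D free-energy surface

The umbrella-sampling fixture is a two-basin truth surface over the two
lid collective variables (end-to-end distance, lid–core distance, both Å):
a broad "closed and disordered" basin at (12, 8) (σ = 3.0, 2.5 Å) and a
tighter "open and ordered" basin at (26, 17) (σ = 2.0 Å), with basin
integrals separated by 1.4 kcal/mol (a ~92/8 split at 298.15 K). Because
the truth density is a Gaussian mixture and the umbrella biases are
harmonic (default 0.4 kcal/mol/Å², 12 × 9 window grid, 400
samples/window), every biased window density is again an exact Gaussian
mixture: samples are drawn directly, with no Markov-chain error, and truth
populations for arbitrary regions come from fine-grid numerical
integration of the analytic density.

`UmbrellaPMF` unbiases the data on a half-open-bin grid (default 1 Å)
either by a sample-level MBAR solve over the bias Hamiltonians followed by
histogramming the unbiased weights (default), or by the classic WHAM
histogram iteration with biases at bin centres. The two solve the same
fixed-point equations at matched discretisation (the tests verify ≤ 0.05
kcal/mol agreement on bin-snapped data); at sample-level resolution the
MBAR route is strictly finer and the two may differ by a few tenths of
kcal/mol in sparse high-free-energy bins. Unvisited bins carry NaN
sentinels, are excluded from every partition function and are never
interpolated; every population is accompanied by the grid coverage.

Macrostate populations are Boltzmann sums over user-supplied polygon masks
(shipped defaults: disjoint rectangles over the two basins), gaps are
`-RT ln(pA/pB)`, and uncertainties re-run the estimator on the first and
second halves of every window's stream (σ = |half₁ − half₂|/2 per
reported quantity). Note that a ±3σ band built from a single
half-difference is *not* a 99.7% interval: for independent Gaussian half
errors the coverage of the full-data estimate is (2/π)·arctan(3) ≈ 0.795,
and the calibration tests on the synthetic fixture measure ≈ 0.80.
Treat these σ values as scale indicators, as error bars of this kind
usually are, not as calibrated confidence intervals.

## Two-state population cycle

With `dG_conf = G_ordered - G_disordered` (positive = order disfavoured)
and ligand preference `Δ = dG_bind_disordered - dG_bind_ordered` (positive
= ligand prefers the ordered state), cycle closure gives
`dG_conf_complex = dG_conf_apo - Δ`, and populations follow from the
logistic two-state Boltzmann factor. At the package defaults (T = 298.15 K,
R = 0.0019872 kcal/mol/K) an apo gap of 1.5 kcal/mol puts the ordered
state at 7.4% (7% to the nearest percent); preferences of 0.5 and
3.0 kcal/mol lift the complex populations to 15.6% and 92.6%. The
unrounded values are always reported alongside rounded percentages; no
attempt is made to reverse-engineer any particular rounding convention,
and the apo gap is an input (both 1.4 and 1.5 kcal/mol are meaningful
choices, coming from the FES gap and the cycle analysis respectively).

The apparent (state-averaged) binding free energy is the
apo-population-weighted log-sum of the state-specific binding constants:
`-RT ln[p_ord e^(-dG_ord/RT) + p_dis e^(-dG_dis/RT)]`; it reduces to the
ordered-state value when the apo ensemble is fully ordered and is always
at least as favourable as either weighted component.

## Problem sizes and numerical defaults

The shipped study conditions are chosen so every statistical claim is
testable on a single CPU: 76 windows × 5 replicates × 200 samples/epoch
for the protocol comparisons (50 seeds), a 108-window × 400-sample
umbrella fixture for the FES tests, and ~2000–20 000-sample tables for
estimator unit tests. Tolerances: MBAR/WHAM self-consistency 1e-10/1e-8,
BAR root 1e-12, Boresch-vs-quadrature 0.01 kcal/mol, population recovery
0.02 absolute. Degenerate inputs (empty windows, zero-overlap pairs,
disconnected umbrella graphs, unvisited bins, θ0 ∈ {0, π}) raise typed
errors or warning flags rather than returning silent numbers.

## Known limitations

- The ladder backend is one-dimensional; overlap pathologies of real
  alchemical transformations (e.g. endpoint singularities) are outside its
  reach, and the variance-inflation knob introduces a deliberate, shared
  estimator inconsistency when set above 1.
- The split-half σ is a 1-degree-of-freedom scale estimate (see above).
- The FES estimator assumes the umbrella windows form one connected
  component; it refuses disconnected designs rather than stitching them.
- No automatic decorrelation or equilibration discard is applied by
  default anywhere; the AR(1) backend makes the cost of that choice
  visible in the spread trajectories.
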