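# Methods

## Model

The state of one cell is the integer triple `(L, S, R_L)` — active
autonomous (L1) copies, active non-autonomous (Alu) copies, and free
machinery complexes — evolving as a continuous-time Markov jump process
with the six channels listed in the README (eight with a second predator
`S2`).  Time is measured in cell generations; `V` converts copy numbers to
concentrations (`ℓ = L/V`).  The mean-field ODEs are the first-moment
equations under the factorization `E[R_L·S] ≈ E[R_L]·E[S]`.

The machinery production law `v_R` distinguishes the variants.  The
saturating (ribosome-limited) form is a quasi-steady-state reduction of an
explicit binding scheme: L1 mRNA `mL` and the pooled mRNA of all other
genes `mq` bind free ribosomes `E` reversibly and are translated from the
bound complexes.  Eliminating the complexes at stationarity (valid when
translation is much slower than unbinding, `k₂ ≪ k₋₁`) and assuming
`mL = c₂·L` gives `v_R = v_max·L/(k_r + L)` with `v_max = k₂·E_tot` and
`k_r = c₁·c₂·K_d`, `c₁ = 1 + mq/K̂_d`.  `ribosome.qss_complex_occupancy`
exposes both the closed form and a brute-force ODE mode used to
cross-validate the reduction; `c₂` never needs a numerical value in the
reduced model (it is absorbed into `k_r`).

Energy limitation multiplies translation-side rates by `e/(k_tr+e)` and
integration rates by `e/(k_int+e)`.

### Units in the stochastic production channel

`v_max = 300` and `k_r = 149` are concentration-scale values: they
reproduce the basic model's rates at the stationary concentration
`L̄ = 1`, which is what makes `k_r = 149` the "normal conditions"
reference.  The SSA propensity of the production channel is therefore the
volume-scaled rate law at the current concentration,
`V·v_max·(L/V)/(k_r + L/V)`.  Applying the saturating law to raw counts
instead (`v_max·L/(k_r+L)`) would saturate ~V times too early and break
the correspondence with the mean-field model; that literal form remains
available via `literal_counts=True` for comparison only.

## Parameters

| symbol | meaning | default | unit |
|--------|---------|---------|------|
| `b_R`  | machinery production per L1 copy | 2 | 1/generation |
| `b_L`, `b_S`, `b_S2` | insertion rate constants | 1, 1, 0.98 | 1/generation |
| `d_R`  | machinery degradation | 2 | 1/generation |
| `d_L`, `d_S` | silencing of active copies | 0.5 | 1/generation |
| `V`    | cell volume (copies per concentration unit) | 500 | — |
| `v_max`| maximal translation rate | 300 | concentration/generation |
| `k_r`  | ribosome-competition strength | 149 | concentration |
| `e`    | available energy | run argument | arbitrary |
| `k_tr`, `k_int` | energy half-saturations (translation, integration) | 0.2, 3.2 | energy |

`v_max` follows from a translation speed of 5 aa/s on a 2000-aa transcript
(`k₂ = 0.0025 s⁻¹`), `E_tot = 50 000` ribosomes, a 20-minute generation
and division by `V`: `0.0025 × 50 000 × 1200 / 500 = 300`.  `b_S2 =
0.98·b_S` makes the second predator 2% slower, enough for competitive
exclusion on a few-hundred-generation scale.

## Deterministic analysis

Stationary solutions are enumerated from closed-form branch seeds rather
than multistart root finding, which guarantees the full branch structure:

- trivial `(0,0,0)`;
- Alu-free: `v_R(L̄) = (b_L+d_R)·d_L·L̄/b_L`, giving `L̄ = 200 − k_r` at
  reference constants (a finite branch exists only for the saturating
  law);
- coexistence: `R̄ = d_S/b_S` (the predator's balance pins the machinery
  level), `L̄ = b_L·R̄/d_L`, and `S̄` from the machinery balance —
  `S̄ = 600/(k_r+1) − 3` at reference constants.

Seeds are refined by a Newton-type root finder; a reported point must
satisfy `‖RHS‖∞ < 1e-10`.  Stability uses the analytic Jacobian: stable
iff all `Re λ < −1e-9`, flagged marginal within `±1e-9` (this occurs
exactly at bifurcation points).  The quasi-cycle period is
`2π/|Im λ|` of the complex pair with the largest real part.

Bifurcations are located by bracketing sign changes of (i) a branch
component's closed-form continuation and (ii) the leading eigenvalue's
real part between grid points, refined by bisection to `1e-6`.  With the
stated energy constants the coexistence-existence condition reduces to
`e² − 7e − 1.28 > 0`, i.e. a threshold at `e* ≈ 7.178`; we report this
analytic value (a nearby round value of 7.3 sometimes quoted for this
setting is not reproducible from the constants themselves, which are
anyway only order-of-magnitude choices).

A caveat on the mixed-model stability map: the critical `k_r(e)` boundary
is `600e²/((0.2+e)(3e+6.4)) − 1`, which decreases with decreasing `e` but
stays positive for all `e > 0` — at low energy the coexistence state
survives at small `k_r`, because the saturating production law at small
`k_r` exceeds the linear law of the energy-only model.  The energy-only
threshold `e*` therefore does not bound the mixed model's behavior
uniformly in `k_r`.

ODE integration uses LSODA with `rtol 1e-8, atol 1e-10` and the analytic
Jacobian; the positive orthant is invariant, so negativity is asserted
(to solver tolerance) rather than clipped.

## Stochastic engine

Exact direct-method Gillespie simulation, compiled with numba.  States
are recorded at every integer generation (the state after the last event
at or before that time), the resolution of all downstream statistics.
Reproducibility is bit-exact in `(parameters, initial state, seed)`;
population runs spawn per-cell 32-bit seeds deterministically from one
master seed via `numpy.random.SeedSequence`, and each recorded cell can
be re-simulated in isolation from its stored seed.  An optional
tau-leaping engine (fixed leap, Poisson updates, step halving on
negativity, single-event fallback) is available for large sweeps; all
results quoted here and in the tests use the exact engine.

### Population protocol

The reference protocol is 3000 independent cells started at
`(L, S, R_L) = (250, 250, 100)`, a 100-generation buffer discarded to
wash out initial conditions, and exclusion of cells that lost all active
elements within the buffer; generation 101 is the first analysis
generation.  Tests and examples scale the population down (60–300 cells)
to keep runtimes in minutes; statistics at that scale are asserted as
orderings and tolerances, never as exact values.

### Extinction and pools

Alu is extinct at the first recorded generation with `S = 0` (the
insertion channel needs `S ≥ 1`, so the state is absorbing).  L1 is
extinct only when `L = 0` **and** `R_L = 0`: machinery alone can
regenerate L via the insertion channel, so `L = 0` with `R_L > 0` is
recoverable.  The exclusion rule and pool-3 entry use this absorbing-set
definition; a `literal_exclusion` flag applies the plain `L = S = 0`
test instead.  Pool labels per generation: 1 (both active), 2 (L1
active, Alu extinct), 3 (L1 extinct — with the machinery gone neither
element can replicate, so the rare transient with `S > 0` after L1 death
is labeled 3).

## Population statistics

The survival of each element type is the product-limit estimate
`F(i) = Π(1 − d_i/n_{i−1})` over post-buffer generations, where cells
extinct during the buffer never enter the at-risk set; with no censoring
this equals the empirical surviving fraction exactly (a property test
checks this, and lifelines serves as an independent cross-check).

Per-pool means and coefficients of variation attribute cells to pools
per generation by default (cells drifting between pools contribute to
each pool the generations spent there); a whole-window mode labels each
cell by its status at the window's end.  Oscillation metrics take each
cell's longest contiguous stay in the pool, provided it spans at least
one frame — near the bifurcation no cell remains in pool 1 for a whole
600-generation window, so whole-window membership would leave the
estimator without data.  Amplitude is the mean over sliding frames
(default 100 generations, stepped by 10) of max − min; the period is the
lag of the highest local autocorrelation maximum after the first zero
crossing, averaged over cells (truncated to the shortest contributing
segment), reported next to the linearized `2π/|Im λ|` prediction and
labeled with the estimation method.  Default analysis windows are
generations 101–700 (101–400 for 300-generation averages); they are
configurable since figure-level window choices are conventions.

## Accuracy of the mean-field correspondence

The ensemble mean of the jump process follows `V ×` (ODE solution) only
to leading order in `1/V`: the bilinear insertion channel contributes a
`Cov(R_L, S)` term to the exact moment equations that the mean-field
factorization drops.  At `V = 500`, during the damped-oscillation
transient from `(250, 250, 100)`, this systematic offset is ~1–2% of the
copy numbers (measured at generation 50 with 1000 replicates: stochastic
mean `(496.6, 575.2, 240.4)` vs mean-field `(488.2, 559.5, 237.5)`), and
it exceeds the Monte-Carlo standard error once more than a few hundred
replicates are averaged.  Started exactly at the stationary state the
mean shows no measurable bias (z < 0.4 at n = 1000).  Consistency tests
therefore assert leading-order agreement (5% relative during the
transient, 2% for a V×100 volume scaling averaged over 5 replicates) and
the unbiased stationary control, rather than a 3-standard-error match
during the transient, which the `O(1/V)` term makes unattainable at
large replicate counts.

## What the simulations do and do not show

All inputs are model parameters; there is no external data.  The
population is a set of independent, identical cells — no division,
lineage or spatial structure — so population statistics quantify the
model's intrinsic demographic noise, not biological cell-to-cell
heterogeneity.  Rate constants are order-of-magnitude estimates (the
translation-side numbers are bacterial); results are qualitative
statements about regimes and trends, not calibrated predictions for a
specific cell type.  Pseudogene formation and competitive binding of two
predators to the same machinery molecule are outside the implemented
reaction set.

## Problem sizes

Default test and example runs use: 60–300 cells × 700 generations for
population phenomena, 1000 single-cell replicates for moment checks, 100
cells × 2000 generations for two-predator exclusion, and 20–100-point
grids for bifurcation scans.  These sizes were chosen so the full suite
runs on a single CPU in well under half an hour while leaving every
qualitative conclusion stable under the fixed master seed.
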