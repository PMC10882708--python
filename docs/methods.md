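# Methods

## The kinetic model

Transcription of a runoff template by T7 RNA polymerase is modelled as
a single lumped reaction producing full-length transcript at rate `v`
(μM transcript/min). The rate law is an extended Michaelis–Menten
form: per-NTP saturation terms multiply, because all four nucleotides
must be available for the elongating polymerase; an initiation bracket
`[1 + K_d,GTP/c_GTP]` sits in the GTP denominator because every
transcript initiates with GTP binding at the promoter; a promoter
saturation term `c_D/(K_MD + c_D)` covers template limitation; and
every NTP and pyrophosphate competes for the nucleotide binding site,
entering as competitive factors `α_i = 1 + Σ_{j≠i} c_j/K_I,j +
c_PPi/K_I,PPi` that scale each Michaelis constant.

Three modelling conventions follow from how the constants are measured:

- **Apparent mode is the default.** The Michaelis constants shipped in
  the reference parameter set (140.4, 71.5, 165.5, 101.5 μM for
  A/C/G/U; vmax 0.358 μM/min) are *apparent* constants, fitted with
  the other NTPs in excess, so the competitive-inhibition sums are
  already absorbed into them and must not be applied twice. In
  `KineticParams` the inhibition constants (`Ki`, `Ki_PPi`), the
  initiation constant (`Kd_GTP`) and the promoter constant (`Km_D`)
  are optional; `None` removes the corresponding term, and the
  defaults are all `None`.
- **vmax is per transcript.** Whether the maximum rate refers to
  transcript or nucleotide production is not observable from the rate
  law alone; this package fixes μM mRNA/min and converts where needed.
  The fixed 8 U/μL polymerase loading of the reference conditions is
  folded into vmax.
- **The promoter term defaults to saturated.** Runoff transcription
  uses excess template whose molar concentration is typically unknown
  (mass loadings are quoted instead); an explicit molar `c_D` input
  activates the term.

### Reduction to plain Michaelis–Menten

With three NTPs in excess and PPi held near zero by pyrophosphatase,
the full law reduces to `v = vmax_app·c/(K_app + c)` in the varied
NTP. `reduce_to_apparent` makes the mapping explicit: `K_app =
K_m·α` for the varied NTP (for GTP, additionally the half-saturation
root of the bracketed denominator, `c² − Kα·c − Kα·K_d = 0`), and
`vmax_app` anchors the reduced curve to the full law at a reference
concentration (default 10 mM, the top assay level), absorbing the
excess NTPs' saturation factors. The reduction is exact in apparent
mode; with finite cross-inhibition the varied NTP feeds back on the
excess terms and agreement degrades smoothly (within 2% over the assay
range for inhibition constants ≳ 20 mM).

A consequence worth knowing: with finite cross-inhibition the full
rate is *not* globally monotone in each NTP — past a point, raising
one nucleotide suppresses the other three saturation terms more than
it helps its own. Monotonicity holds in apparent mode and is asserted
there.

## Mass balances and integration

Per transcript synthesised, `f_i·n` molecules of NTP i are consumed
and `n` PPi released (`f_i` = base fraction, `n` = length in nt);
pyrophosphatase removes PPi at `k_PPiase·c_PPase·c_PPi/(K_M,PPi +
c_PPi)`; template is conserved. Two invariants follow and are tested:
`Σ_i c_NTP,i + n·c_mRNA` is constant, and with the phosphatase off
`c_PPi = n·c_mRNA` exactly. The stoichiometric plateau `min_i
c_NTP,i(0)/(f_i·n)` bounds the final transcript concentration.

Integration uses `scipy.integrate.solve_ivp` with LSODA (automatic
stiff switching), rtol 1e-8 and atol 1e-10 μM; state values are
clamped at zero inside the right-hand side and clipped after
integration with a counted warning — near substrate exhaustion the
solver may step a few 1e-10-scale values below zero. Against the
classical integrated Michaelis–Menten closed form `K·ln(s0/s) +
(s0−s) = vmax_s·t` (solved independently by bracketed root-finding),
single-limiting-substrate trajectories agree to 1e-4 relative.

The pyrophosphatase constants are literature-style configuration
values, not fitted here: `K_M,PPi` = 50 μM and `k_PPiase` = 1e6 μM/min
per (U/μL) — the unit definition of enzyme activity. At the reference
0.002 U/μL loading the hydrolysis capacity (2000 μM/min) outruns peak
PPi release, holding free PPi below 1% of its phosphatase-free level;
a warning is logged whenever these defaults are used.

Units are fixed package-wide — time in min, concentrations in μM,
yields in g/L — and the molar/mass converters are the only place unit
constants appear. Residue masses default to the NMP-residue values
(329.2/305.2/345.2/306.2 g/mol for A/C/G/U).

## Initial rates and parameter estimation

The initial-rate window is the longest prefix of ≥3 points whose OLS
fit reaches R² ≥ 0.99 and whose endpoint has consumed <10% of the
varied substrate (when the substrate level and stoichiometry are
supplied); if no prefix qualifies the first three points are used with
a flag. "Linear range at the beginning" is thereby made operational
without a hand-picked cutoff.

All four estimators are unweighted by default (the nonlinear fit
accepts a 1/v² weighting flag); standard errors of transformed
parameters come from the delta method on the regression covariance,
and the nonlinear fit reports asymptotic errors from the Jacobian.
Datasets with fewer than three distinct levels still fit but carry a
degeneracy flag and undefined standard errors. The headline estimate
is the nonlinear fit; linearizations are diagnostics, and under
constant-σ rate noise the Lineweaver–Burk transform is demonstrably
the most biased (its reciprocal inflates low-rate errors), which the
test suite verifies by simulation.

**Identifiability caveat.** The reference assay levels (2.5–10 mM)
sit 15–140× above the Michaelis constants being estimated, so K_app
is weakly identified from any single noisy dataset: at 2% measurement
CV the dispersion of the K estimate is tens of percent, a property of
the design, not of the optimizer (the reciprocal-plot slope SE is
~50% of the true slope at K = 100 μM). The estimator is
median-unbiased under these conditions — the median signed K error
over 500 simulated repeats is ≲1.5% — and that is the recovery
property the suite asserts; no estimator could deliver a small median
*absolute* error from this design.

## Monte Carlo envelopes

Parameter precision is propagated by simulating `n` (default 30)
independent draws: each of vmax and the four K values is perturbed
normally with its standard error, truncated at a floor of 1e-6× its
mean (parameters without reported errors stay fixed; no covariance is
available, so draws are independent). Draw 0 is always the nominal
set, so the min/max band contains the nominal trajectory by
construction; a 5–95% quantile mode is available. Bands are
bit-reproducible under a fixed seed, and the common-random-number
deviates are generated row-wise so the envelope of `n` draws nests
inside that of `n+k` draws on the same seed. Sensitivity is measured
as the peak band width over the transient: at late times trajectories
sit on the stoichiometric plateau, which no kinetic parameter moves.

## Segmented-flow scheduling and detection

The reactor is modelled by bookkeeping, not fluid mechanics: slugs
injected at Δt, 2Δt, … (the tube is pre-filled with the oil phase, so
the first slug enters one interval after start-up) each exit τ minutes
later, and a slug counts as produced iff its outlet time is within the
horizon — `floor((T−τ)/Δt)` produced slugs versus `floor(T/τ)`
sequential batches. τ is a direct input: the nominal tube geometry and
flow rate do not pin it down exactly, so deriving it would be false
precision. Slug detection thresholds at the midpoint between a robust
baseline (median) and robust peak (95th percentile) with 10%-of-span
hysteresis and a minimum-duration filter; it recovers generated slug
trains exactly at signal-to-noise ≥ 10 (asserted by test).

## Response-surface screening

The 15-run, three-center default template is a Box–Behnken layout (12
cube-edge midpoints + centers): it is the three-factor design
consistent with 15 runs including 3 center replicates that also makes
all pure-quadratic terms estimable, which the screening analysis
requires; a corners-plus-centers template ships behind a flag for
comparison (its quadratic columns are aliased, and the fit reports
them by name). Backward elimination removes the worst removable term
with p > α (default α = 0.05, a conventional choice) one at a time,
refitting each round; hierarchy is enforced, so a main effect stays
while any of its interactions or its quadratic survives. Exactly-zero
coefficients with zero standard error (constant responses, noise-free
surfaces) are assigned p = 1 so elimination can discard them instead
of propagating 0/0 t-statistics. Desirability ramps span each
response's predicted range over the search grid (no anchor values are
assumed), the composite is the geometric mean, and the optimum is
located by exhaustive grid search on the coded cube (default 21³) —
checked against a finer grid to one grid step in the tests.

## Synthetic data: what it emulates, and what not

Generators are pure functions of (configuration, seed) and always emit
their generating truth in a sidecar, so tests recover known answers
rather than reverse-engineering data. Defaults encode the reference
study conditions: initial-rate assays at 2.5/5/7.5/10 mM; apparent
constants 140.4/71.5/165.5/101.5 μM and vmax 0.358 μM/min as generator
truth; a 4284-nt transcript; 10 mM NTP production runs at the ~10 g/L
yield scale; slug trains spaced 6.6 min; measurement noise of 2% CV
(matching the ~2% run-to-run reproducibility of segmented-flow
operation). The 4284-nt transcript's base composition (A 0.30, C 0.27,
G 0.27, U 0.16 — U least frequent) and the alternative 1800-nt
cross-validation construct are package choices; real constructs should
be loaded from sequence via the FASTA reader.

Not emulated, hence not demonstrated by passing tests: abortive/
truncated transcript formation mechanisms (truncated fractions are
generated as two-peak area tables, not mechanistically), dsRNA
formation, magnesium–pyrophosphate precipitation, temperature
dependence inside the rate law (temperature enters only as a DoE
factor), two-phase fluid mechanics of slug flow, and detector
physics beyond smoothed pulses with drift and Gaussian noise.

## Problem sizes

The suite runs batch simulations on grids of ≤ 181 points, Monte Carlo
envelopes at 5–30 draws, estimator studies at 200–500 simulated
repeats and desirability searches up to a 101³ oracle grid — sizes
chosen so every statistical assertion has comfortable resolution while
the whole suite stays interactive.
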