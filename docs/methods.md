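# Methods

## The case table and the retention statistic

The packaged table (`shepherdsim/data/transmission_cases.csv`, 34 rows)
collects documented parent→offspring transmissions of a supernumerary
marker chromosome (SMC) or comparable structural variant (SV) in which the
offspring is mosaic. Each row records the SMC type, the offspring mosaic
ratio (abnormal metaphases / metaphases scored), the parental carrier
status (100% constitutional, a mosaic percentage, a percentage range, or
"mosaic, proportion not recorded"), the parental origin, phenotypes, and
the source (PMID or the public sSMC database). Ratio cells are parsed into
a three-way `RatioValue` (point / range / unrecorded); ranges are reduced
to midpoints for scoring while both endpoints are retained for reporting.
Karyotype strings are treated as opaque clone labels: only the bracketed
ISCN cell counts are interpreted, and no band-nomenclature validation or
pathogenicity assessment is attempted. Some sources describe 35 families;
the transcribed table has 34 rows, of which 33 have a recorded parental
proportion — the one row with an unrecorded parent is excluded from every
scored denominator.

Each usable pair is classified by d = offspring − parent (effective
ratios): `LOWER` (d < 0), `COMPARABLE` (0 ≤ d ≤ tolerance), `HIGHER`
(d > tolerance). The comparability tolerance defaults to 10 percentage
points: "comparable" has no canonical clinical definition, and a symmetric
10-point band is the simplest rule consistent with how these reports
describe offspring levels "comparable to" the parent's; it is exposed as a
parameter everywhere it is used. On the packaged table this gives 21
strictly lower, 3 comparable, and 9 higher of 33 (24/33 ≈ 72.7% lower or
comparable). Comparisons carry a 1e-9 slack because ratios are reported at
percent precision and binary floating point would otherwise misclassify a
pair sitting exactly on the band's edge (0.80 vs 0.70).

Display rounding of clone counts is half-up to integer percent (45/99 →
45%, 17/30 → 57%), matching clinical reporting practice.

## Agent-based blastocyst model

Founder cells (default 8, ~the morula-stage population that seeds the
blastocyst) divide synchronously for `n_cycles` (default 5, giving ≈256
cells, blastocyst scale). Every surviving cell produces two daughters;
each SMC/SV+ daughter independently dies with probability `s` per cycle
(mild selection against the abnormal clone), normal daughters always
survive. After the last cycle each survivor is allocated to the ICM with
probability `q` (default 0.25, roughly the ICM share of a blastocyst) for
normal cells and `q(1−a)` for abnormal ones (`a` = allocation bias),
otherwise to the TE. Selection is implemented as daughter death — the
simplest mechanism consistent with mild selection pressure; division-rate
biases are deliberately out of scope. There is no spatial geometry or
signaling: "allocation" is compartment assignment only.

The founder composition uses deterministic half-up rounding of
`p0·n_founders` so that `p0` is exactly representable at small founder
counts. Consequently the closed-form mean

    E[ICM+ fraction] = p0(1−s)^c(1−a) / (p0(1−s)^c(1−a) + (1−p0))

matches the simulator only at representable `p0`; oracle-equivalence tests
therefore use founder counts for which each grid `p0` is exact (e.g. 20
founders for 0.2/0.5/0.8). Replicate seeds in `run_sweep` derive from
`SeedSequence([base_seed, i, j, r])`, making sweeps reproducible and
order-independent. Runs in which every cell dies (possible only when
`p0 = 1` and `s = 1` in practice) yield absent fractions and a logged
warning rather than an exception; empty-ICM replicates are excluded from
sweep means and counted.

Monte-Carlo scale: the default test/example sweeps use 200–2000 replicates
per grid cell, at which the replicate-mean standard error is ~0.001–0.005,
small enough to resolve the monotone depletion trend the model predicts.

## Logistic retention curve

Offspring percentages are treated as binomial proportions with an
effective denominator `m` (default 30 — a typical number of scored
metaphases — used when a source reports only a percentage; configurable).
The weighted binomial log-likelihood is maximized by Newton scoring (IRLS)
with step-halving (≤20 halvings) so the log-likelihood never decreases;
convergence is declared when the score norm falls below 1e-8 or the Newton
step falls below 1e-8 (at large weight totals the score's floating-point
floor sits above the absolute tolerance while the parameters are already
converged). Proportions of exactly 0 or 1 are clamped to `1/(2m)` and
`1 − 1/(2m)`. Complete separation or non-convergence returns a fit flagged
`converged=False` with a warning rather than raising. Standard errors come
from the inverse observed information.

Deviation from random transmission is summarized as the mean of
|fitted(x) − x| over an even grid on [0, 1] (default 101 points), with a
case-resampling bootstrap (default 1000 replicates, fixed seed,
bit-reproducible) for the interval. Degenerate bootstrap resamples with a
single distinct x are skipped. No alternative links, regularization, or
covariates: a single univariate curve is the model.

## Beta-binomial reduction test

Success is defined per transmission (pair-level Bernoulli): the offspring
ratio fell. The default success rule is strict lowering and the default
prior is the uniform Beta(1,1), both configurable; the threshold is fixed
at 1/2, the random-inheritance null under which a fall is as likely as a
rise. On the packaged table the strict rule gives 21/33 and a posterior of
Beta(22, 13), with P(θ > 1/2) = 0.9393; the lower-or-comparable rule gives
24/33 and a still larger probability. Tail probabilities and quantiles use
the regularized incomplete beta function; tests cross-check them against
the integer-parameter binomial-tail identity and 10⁶-draw Monte Carlo.
No hierarchical structure over families and no modeling of ratio
magnitudes — only the direction of change enters.

## Absorbing Markov chain

States: PROLIFERATING (transient), CLEARED, TE, ICM (absorbing). The
literature motivating the chain names the states but not the transition
probabilities; the defaults (0.2, 0.2, 0.2 absorbing, 0.4 stay) are the
simplest symmetric choice, sending one third of the clone's mass to each
terminal fate — and hence ~33% to the ICM — and all four are configurable.
The default horizon is ten iterations; because "equilibrium" could mean
either the ten-step snapshot or the absorbing limit, both are computed
(they differ by `p_stay^10 ≈ 1e-4` of the mass). Semantics are
distributional (a mass vector), not per-cell; a per-cell Monte-Carlo
sampler exists only as a test oracle. Closed forms used throughout:
proliferating mass `p_stay^k`, absorbing shares `p_a/(1 − p_stay)`, mean
absorption time `1/(1 − p_stay)`.

## Synthetic-data generator

`generate_case_table` emulates the structure of the literature table:
parents are constitutional (ratio 1.0) with probability
`prob_constitutional` (default 0.5, matching the roughly half
constitutional parents in the real table) or mosaic with a Beta(2, 2) draw
(symmetric, mid-range, as observed); the latent offspring mean applies the
selection closed form (default `s_eff = 0.05` over `c = 5` cycles, the
mild-selection regime); and the observed offspring ratio is a binomial
draw over a metaphase count uniform on 20–100 (the range typical of
clinical karyotyping). The ground truth (selection parameters and each
case's latent mean) is returned alongside, so end-to-end tests can check
parameter recovery. The generator models binomial sampling noise only — no
inter-tissue variance (amniotic fluid vs cord blood differences are real
but unmodeled), no karyotype-content simulation, and no
formation-mechanism (e.g. trisomy-rescue) structure. Passing tests on
synthetic tables therefore demonstrate that the pipeline detects and
calibrates the modeled selection signal under metaphase-sampling noise,
not that real transmissions lack additional structure.

Null calibration is evaluated on all-mosaic tables
(`prob_constitutional = 0`): a constitutional parent's offspring is
observed at exactly 100% and can never register as strictly lower, so
under the default mixture the strict-success rate is bounded near 1/2 ×
P(fall | mosaic) and the posterior probability collapses toward 0 even
without selection — a property of the success definition, not a
miscalibration. Restricted to mosaic parents, the no-selection posterior
probability across 20 seeds averages ≈0.45, i.e. the test is calibrated,
and per-cycle selection of only 2–5% drives it to ≈1 at 500 cases.

## Design notes and limitations

- Problem sizes in tests and examples (2000 agent-based replicates per
  grid cell, 1000 bootstrap replicates, 10⁶ posterior draws, 500-case
  synthetic tables × 20 seeds) were chosen so Monte-Carlo error is well
  below each assertion's tolerance while the full suite runs in seconds.
- The pipeline isolates stage failures: a misconfigured model marks its
  stage failed in the report while the others still run, and the report's
  `ok` flag (and the CLI exit status) reflects the failure.
- All stochastic stages derive their seeds from one master seed; a config
  plus seed reproduces the JSON report byte for byte.
- The heatmap sweep and the retention-curve deviation are qualitative
  reproductions (a monotone depletion trend; a curve bending away from
  y = x): no numeric parameter values exist to match for either, so tests
  assert the trend and the sign, not magnitudes.
- The four models share the selection hypothesis but are deliberately not
  unified into one likelihood; their value is convergence of independent
  formalizations, not joint inference.
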