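# Methods

This note documents the models, the synthetic-data generator, the numerical
choices and the known limitations of the `ecotoxrisk` pipeline. It states
no empirical result that the test suite or `scripts/acceptance.py` does not
itself compute.

## Dose–response model

Percent effect along a concentration (or % v/v dilution) series is modelled
with the two-parameter log-logistic (Hill) function on the percent scale,

    E(c) = 100 / (1 + (EC50 / c)^h),        c > 0, h > 0,

with floor 0 and ceiling 100, so `E(EC50) = 50` exactly and the curve is
monotone non-decreasing. This is the canonical model family behind the
commercial acute-test analysis tools used for the algal, duckweed and
daphnid batteries; 3/4-parameter variants (free floor/ceiling, hormesis)
are deliberately out of scope. Controls (c = 0) never enter the log-scale
fit; they define the normalisation.

**Percent effects.** Growth endpoints use growth increments over the test
(final − initial optical density, or frond area in mm²):
`E = 100·(1 − G_treat/Ḡ_ctrl)`. Yield increments rather than specific
growth rates are used because the duckweed validity criterion is itself
stated as area growth in mm²; this choice is recorded in output metadata.
Stimulation (negative inhibition) is preserved in reports but clipped to 0
for fitting and mixture arithmetic. Immobilisation is
`E = 100·immobilised/exposed`, pooled over vessels for level means (no
control correction: the validity gate caps control immobilisation at 10 %).

**Estimation.** Continuous endpoints: weighted least squares on level-mean
effects (weights = vessel counts), parameterised as (log EC50, h) with an
analytic Jacobian and tolerances of 1e-14, so noiseless synthetic curves
are recovered to better than 1e-6 relative error and the estimator is
scale-equivariant (initial values come from a logit–log regression, which
is covariant under rescaling of c). Quantal data: binomial maximum
likelihood on per-vessel counts (Nelder–Mead on the stable softplus
log-likelihood). Fits are refused when mean effect correlates negatively
with concentration (Spearman ρ < 0); curves whose observed effects do not
bracket 50 % are flagged `extrapolated` rather than refused.

**Confidence limits.** 95 % limits for the EC50 come from a seeded
nonparametric bootstrap over replicate vessels within each level (controls
are resampled too, so normalisation uncertainty propagates); default 1000
resamples. The interval is an *expanded* percentile interval: percentile
distances from the bootstrap median on the log scale are inflated by
`sqrt(n̄/(n̄−1)) · t_ν(0.975)/z(0.975)`, with n̄ the mean vessels per level
and ν the residual degrees of freedom of the level-mean fit (levels − 2),
the standard small-sample convention for regression intervals. The plain
percentile interval is systematically narrow with triplicate vessels
(resampling n = 3 values underestimates sampling variance by (n−1)/n, and
normal-range quantiles ignore the variance estimate's small-sample t-ness):
in a calibration study on the standard five-level triplicate design the
plain interval covered the true EC50 in ~82 % of simulations and a
bootstrap-t variant with delta-method standard errors did not improve on
it, while the expanded interval restores ~96–97 % coverage (a pooled
within-level df convention, ν = Σ(nᵢ−1), was also evaluated and left
coverage at ~91 %, still short of nominal). The test suite and acceptance
script re-measure coverage (300 simulations × 200 resamples).

**Validity gates.** Pure predicates on control data, thresholds inclusive:
algal 72 h/0 h density ratio ≥ 16 (requires the time-0 control density,
carried as `control_t0`); duckweed mean control frond growth ≥ 10 mm²;
daphnid control immobilisation ≤ 10 %.

## Mixture partitioning and interaction

Response addition (independent action) composes effects on the 0–1 scale:
`E_total = 1 − (1 − E_ion)(1 − E_particle)`. The particulate contribution
is recovered by inversion, `E_particle = 1 − (1 − E_total)/(1 − E_ion)`;
negative results (ion effect exceeding the total) are clipped to 0 and
flagged, and `E_ion = 1` leaves the particle effect undefined (flagged
`ion_saturated`). Effects entering the RA denominator are capped at 0.999
to avoid blow-up at complete kill; the cap applies only there, not to the
percent effects fed to the predictive formula.

On the percent scale the binary predictive formula
`P(E) = P_x + P_y − P_x·P_y/100` is the same composition; the package
keeps both forms because partitioning is naturally done on fractions and
observed-vs-expected comparison on percent effects. Observed replicate
effects are compared to `P(E)` with a one-sample two-sided t-test at
per-comparison α = 0.05 (no multiplicity correction, matching the
per-comparison convention of acute screening): p < α is synergistic or
antagonistic, signed by the mean deviation; otherwise additive. When the
replicates are numerically identical (noiseless data, saturated endpoint)
the comparison is exact up to a 1e-9 float tolerance and reported with a
degenerate-variance flag.

**Why classification needs a particle reference.** RA and the predictive
formula are algebraically identical, so an expected effect built from the
measured total and ion effects of the *same* pair equals the observed mean
by construction and can never be rejected. `mixture_report` therefore
decomposes unconditionally but classifies only against an external
particulate reference curve (a fitted curve from a particle-only exposure,
a mapping, or — in synthetic runs — the generative particle curve recorded
in the simulation manifest). Without a reference, verdicts are marked
`not_evaluated` rather than reported vacuously.

## Species sensitivity distributions

Species are ranked by ascending EC/LC50 (all in one unit; mixed units are
an error) and given Hazen plotting positions `(i − 0.5)/n` — the common
default of regulatory SSD tools — with Weibull `i/(n+1)` available. Ties
keep stable species-name order and share the midpoint of their positions.
The daphnid endpoint entering an SSD defaults to the 48 h LC50
(configurable to 24 h; with the bundled sanitiser data the two choices give
different orderings, so the choice is always explicit). An optional
log-normal fit (maximum likelihood on log10 EC50) yields the HC5; with the
typical 3-species battery this parametric step is fragile and emits a
small-sample warning.

## Risk characterisation

`PNEC = EC50/AF` with AF = 1000 for acute base-set data; `RQ = MEC/PNEC`
in consistent units (canonically µg/L internally; mg/L and ng/L are exact
power-of-ten conversions at I/O). Bands are a left-closed monotone step
function of RQ: `[0,1)` no significant risk, `[1,10)` small, `[10,100)`
significant, `[100,∞)` potential adverse effects. The boundary convention
is a package decision — prose band definitions in the screening literature
leave the edges ambiguous — and RQ = 10 is therefore "significant".

Two unit modes exist because published release-medium concentration tables
are sometimes internally inconsistent with the narrative RQ bands computed
from them: `si_strict` honours each record's printed unit; `paper_numeric`
treats the numerals as µg/L, which reproduces such narratives. Both are
labelled in every output; neither is silently preferred (the CLI defaults
to `paper_numeric` for reproduction runs). For mg/L records the two modes
differ by exactly 10³, so a band of "potential adverse" under
`paper_numeric` can only be confirmed, never weakened, under `si_strict`.
The bundled reference tables keep not-determined EC50s as an explicit `nd`
status (never zero or silently missing), and table crosses list unmatched
rows instead of dropping them.

## Synthetic-data generator

The generator emulates the standard acute battery: five exposure levels in
a 10-fold series (0.01–100 % v/v) plus controls; triplicate vessels for
algal growth and immobilisation (five neonates per beaker), octuplicate
for duckweed; durations restricted to 72 h (growth) and 24/48 h
(immobilisation).

* Continuous responses: `control_mean · (1 − E(c)/100) · ε` with ε
  lognormal, unit mean, coefficient of variation `noise_cv`. Multiplicative
  lognormal noise is used because optical densities and areas are positive
  and heteroscedastic. Published acute tables report no replicate variance,
  so the default CV 10 % is a convention chosen as typical inter-vessel
  variability for these assays, not a transcribed value.
* Immobilisation: per-vessel counts `Binomial(n, E(c)/100)`; controls at
  the background probability (default 0, configurable up to 10 % to
  exercise the validity gate).
* Paired experiments: the ion-only dataset follows its own log-logistic
  curve; the total dataset follows the RA composition of ion and particle
  curves. Interaction is injected on the effect scale as a bounded additive
  perturbation (±`interaction_strength`, clipped to [0,1]) — the simplest
  mechanism whose sign matches the synergistic/antagonistic vocabulary.
  Default mixture conditions used in the calibration studies: particle
  EC50 1.0 % v/v, ion EC50 3.0 % v/v, both with Hill slope 2 — mid-series
  half-effect points so interior levels carry information.
* Algal datasets carry a time-0 control density implied by
  `control_fold_growth` (default 20, comfortably above the 16-fold gate).
* All randomness flows through explicit integer seeds; generation is
  bit-reproducible.

What the generator does **not** emulate: particle aggregation and
dissolution kinetics, photochemistry (light/dark is a label only),
time-resolved growth, hormesis, inter-vessel density dependence, or
correlated noise between paired total/ion experiments. Passing tests
therefore demonstrate correctness of the estimators under the stated
statistical model, not robustness to those real-data features.

## Calibration studies (what the acceptance script measures)

* Classifier operating characteristics: 200 paired simulations per arm at
  the triplicate algal design, CV 10 %. Trials test the observed replicate
  effects at the mid-series level against the generative additive
  composition, normalising by the generative control mean — this isolates
  the t-test's behaviour, and its false-positive rate is ≈5 % with power
  ≈100 % at interaction strength 0.2. Normalising by the 3-vessel control
  *estimate* instead shares the normalisation error across replicates and
  inflates the per-comparison type-I error to roughly 9 %; this is a
  pipeline-level effect worth remembering when interpreting real
  per-level verdicts, not a defect of the test itself.
* Bootstrap coverage: 300 simulated triplicate experiments, 200 resamples
  each (reduced from the library default of 1000 to keep the study inside
  minutes of CPU; the interval itself is quoted to two digits).

## Known limitations

* The 2-parameter model cannot express partial maximal effects; strongly
  sub-maximal plateaus will bias EC50 upward and show in
  `residual_summary`.
* Percentile-type bootstrap intervals from 3 vessels per level remain
  approximate even after expansion; coverage ~96–97 %, not exactly 95 %
  (mildly conservative).
* Per-level interaction verdicts are per-comparison; across 5 levels the
  family-wise false-positive rate is correspondingly higher.
* The log-normal HC5 from a 3-species SSD is indicative only.
* Risk banding is deterministic screening: no distributional MEC/PNEC, no
  dilution modelling, no chronic assessment factors.
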