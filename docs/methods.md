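# Methods

## Scope and data model

All analyses operate on a tidy long-format dataset: one row per
(patient, biomarker, time) measurement, with negative times marking
pre-treatment samples, plus a per-patient table of treatment arm,
progression-free interval (PFS, days) and a progression flag. Every
patient must carry at least one pre-treatment sample per biomarker; at
most one progression sample per patient-biomarker is allowed. The
composite marker Ang1×Tie2 is defined pointwise on time-matched pairs as
`Tie2 · log2(Ang1)` and behaves as an ordinary biomarker downstream.

## Trajectory model

Concentrations are modelled on the natural-log scale, which keeps
back-transformed values positive and turns the multiplicative biology of
plasma markers into additive slopes. The mean trajectory is continuous
piecewise-linear,

y(t) = α + β·min(t⁺, τ) + γ·max(t⁺ − τ, 0),  t⁺ = max(t, 0),

so β and γ are literally the slopes before and after the inflection τ, and
pre-treatment observations are treated as replicates of the level α (no
pre-treatment trend). Slope units are log-concentration per month
throughout (1 month = 30.4375 days).

The hierarchical model pools patients within an arm; arms are fitted
independently because the scientific question is whether the inflection
structure exists *per arm*:

- α_i ~ N(0, 10²) — vague; identified by the pre-treatment replicates.
- β_i ~ N(μ_β, σ_β²), γ_i ~ N(μ_γ, σ_γ²); μ ~ N(0, 10²), σ ~ HalfNormal(5).
- τ_i ~ Uniform(0, T_i) with T_i the patient's last observation time. The
  group-level location and spread of τ reported in summaries are derived
  quantities (moments of the patient-level draws), not extra parameters —
  a uniform individual prior combined with derived summaries avoids
  boundary pathologies when an arm has no real inflection.
- σ_i ~ HalfNormal(2) per patient.

These priors are weakly informative defaults chosen for scale-freedom on
the log scale; all are configurable in `McmcSettings`.

### Sampler

Inference is Metropolis-within-Gibbs, vectorised across patients:

1. (α_i, β_i, γ_i) jointly from their exact 3-dimensional Gaussian
   conditional (batched Cholesky solves);
2. τ_i by adaptive random-walk Metropolis (two sweeps per iteration),
   proposals rejected outside (0, T_i);
3. log σ_i and the group scales log σ_β, log σ_γ by adaptive random walks
   with the half-normal prior and log-scale Jacobian;
4. μ_β, μ_γ from their conjugate normal conditionals.

Proposal scales adapt toward 44% acceptance during warm-up only, in
50-iteration windows, so the post-warm-up kernel is fixed and valid.
Chains are seeded from a spawned `SeedSequence`, making every fit
reproducible from a single integer. Convergence is summarised by
rank-normalised split-R̂ (via arviz) for every group-level quantity; values
above 1.1 raise a warning but never abort, since a flat standard-arm
trajectory legitimately leaves τ unidentified (its R̂ is reported so the
user can see exactly that). A numerical floor of 1e−6 on σ_i allows
exactly noise-free synthetic data without overflow.

Defaults of 2 chains × 1000 draws after 1000 warm-up iterations fit a
48-patient arm in a few seconds; simulation studies in the test-suite use
the same or slightly reduced sizes (2 × 800) — sizes chosen as the point
where Monte-Carlo error is clearly below the effects being measured.

### Arm comparison

The slope table reports per-arm posterior means, sds and central 95%
intervals of μ_β and μ_γ. The arm contrast is a two-sided Mann–Whitney
test of *patient-level posterior-mean* slopes between arms — a
distribution-free comparison that matches how the slope table is read
(does the experimental arm decline-and-rebound while the standard arm
does not?).

## Synthetic cohort generator

The generator emulates the trial sub-study the analyses assume: 44
standard-arm and 48 experimental-arm patients; up to 10 samples per
patient on the reconstructed calendar (days −14, −1, 0, 21, 105, 126,
183, 274, 365 for two pre-treatment draws, end of cycle-1 infusion,
pre-cycle-2, pre-cycle-6, end of cycle-6 infusion and the month visits,
assuming 3-weekly cycles — the source protocol gives visit labels, not
day numbers) truncated at each patient's PFS, plus a progression draw for
progressed patients.

Per patient and biomarker, parameters are drawn from the same hierarchy
the model fits: baseline log-level, arm-dependent slope means, and an
inflection placed at a Normal fraction of the patient's PFS (mean 0.5, sd
0.1, clipped to (0.05, 0.95)) — the inflection is parameterised on the
%PFS axis because that is the axis on which trajectories are compared.
Standard-arm trajectories default to no inflection (γ_i bound to β_i),
mirroring the expected null in that arm; this is configurable per
biomarker. Cross-biomarker correlation comes from a shared standard-normal
latent factor per correlation block acting on the baseline level with a
per-marker loading λ; the implied baseline correlation of two block
members is the product of their loadings.

PFS is log-normal (median 540 days, log-sd 0.45 — a plausible
first-line ovarian-cancer PFS scale) with administrative censoring at 730
days, giving roughly three-quarters progressed patients. Missing visits
are dropped independently per scheduled on-treatment visit at rate 0.25,
chosen so the mean usable samples per patient (≈7) matches the 6.8–7.3
per patient reported for the real cohorts; pre-treatment and progression
draws are never dropped, and one missingness draw per visit applies to
all biomarkers of that blood sample. The default three-marker panel
(Tie2, Ang1, Ca125) uses plasma-scale baselines (≈4000 and ≈9000 pg/ml,
≈250 IU/l) and modest per-month log slopes.

What the generator does *not* emulate: assay batch effects, informative
missingness, visit-time jitter around the calendar, non-piecewise-linear
kinetics, and any coupling between biomarker level and PFS. Passing tests
therefore demonstrate correctness of the machinery under the stated
generative family, not clinical performance on real patients; in
particular the absolute prediction rates printed by the pipeline describe
the synthetic cohort, whose Ca125 kinetics are deliberately simple, and
are not calibrated to reproduce any trial's printed rates.

## Correlation networks

Networks are computed on log-concentrations of time-matched samples
(a row = one blood draw with the full panel). Pre-treatment networks pool
both arms; on-treatment networks split by arm and always exclude
progression samples so edges reflect treatment effect, not progression
biology. Repeated samples per patient are pooled by default (small
cohorts need the rows); a per-patient-mean path is available by averaging
upstream. Partial correlations come from the inverse correlation matrix,
ρ_ij = −Ω_ij/√(Ω_ii Ω_jj); when samples do not outnumber biomarkers the
correlation matrix is shrunk toward the identity (Ledoit–Wolf) before
inversion, otherwise plain inversion is used and singularity is an error.
Edge display uses the conventional |r| ≥ 0.3 cut-off and reports the
maximum and median displayed |r|. No formal differential-network test is
attempted; subsets are compared by their edge tables.

## Alarm rules

Rules run on the raw concentration scale (a percent-over-nadir criterion
is scale-dependent). The nadir at step k is the running minimum up to k;
the alarm fires at the first step whose value is ≥ nadir·(1 + threshold),
with ≥ chosen as the deterministic tie-break. A positive threshold means a
fresh minimum can never alarm against itself. The GCIG-style Ca125
criterion is the threshold-1.0 (doubling) special case, used without a
confirmation sample by default because monthly pseudo-trial monitoring
would distort confirmation delays; a `require_confirmation` flag (alarm on
the second consecutive exceedance) is available. Rules combine by OR:
earliest component alarm wins.

Cohort evaluation counts a progressed patient as predicted when the alarm
is no later than progression; censored patients are excluded from the
denominator, since including them would conflate censoring with rule
failure. Prediction quality is the mean (± sd) alarm time as %PFS among
predicted patients.

## Pseudo-trials

For each progressed patient, 5000 replicates per biomarker redraw that
patient's full parameter vector from a single posterior iteration
(preserving parameter correlations; never group-level or prior draws),
impute monthly values at 30k + U(−5, +5) days up to the progression date
— uniform jitter, as the ±5-day window states no distribution — with
posterior-predictive noise from the drawn σ, and monitor them
sequentially. Replicate alarms aggregate to a per-patient alarm
probability; the cohort prediction rate is the mean probability × 100.
Because the aggregation convention is genuinely open, the majority-vote
alternative (patient predicted iff ≥ 50% of replicates alarm) is computed
alongside and reported in the same result object. Pseudo-patients are
never invented: every replicate reuses an existing patient's posterior
and PFS.

## Descriptive statistics

%PFS-axis trajectories divide each patient's sample times by their PFS;
values are natural-log ratios over the baseline, defined as the
arithmetic mean of the (up to two) pre-treatment concentrations, so the
anchor point is exactly 0 at 0% PFS. Arm comparisons interpolate each
patient's series at the midpoints of ten non-overlapping bins
((0,10], …, (90,100]) — interpolation is confined to binning, never
extrapolated beyond a patient's observed range — and apply two-sided
Mann–Whitney tests per bin. The family-wise Bonferroni cut-off is
α/(n_biomarkers × n_bins), 0.05/150 ≈ 0.0003 for the conventional
15-marker panel. The Mann–Whitney implementation enumerates the exact
permutation null (midrank statistic) whenever both groups have ≤ 8
observations and otherwise uses the tie-corrected normal approximation;
ranks make the test invariant to the log base used for display.
Response contrasts compare complete responders with stable disease
(partial responders excluded by design), each patient contributing the
on-treatment value nearest the end-of-cycle-6 assessment; Ca125 rows
additionally exclude patients whose pre-treatment Ca125 is below 30 IU/l
(tumour biochemically undetectable, so Ca125 dynamics are uninformative).

## Numerical choices and edge cases

- Exact threshold equality triggers an alarm; exact bin-edge times fall in
  the lower bin midpoint's interpolation range only if observed.
- Monitoring series require strictly increasing times and positive
  concentrations; a jittered visit landing past the progression date is
  clamped to it.
- CSV round-trips are bit-exact (`%.17g` on write, round-trip float
  parsing on read), so seeded pipelines regenerate byte-identical
  artifacts.
- Partial-correlation matrices are symmetrised and clipped to [−1, 1]
  after inversion to absorb floating-point asymmetry.

## Known limitations

- The piecewise-linear family has exactly one inflection; plateau or
  multi-phase kinetics are approximated, not represented.
- Between-patient correlation of β and γ is not modelled (independent
  hierarchies), and σ is homoscedastic within a patient.
- The arm contrast tests posterior means as data, ignoring their
  posterior uncertainty; with ≥ 3 observations per patient this is a
  minor, conservative simplification.
- Partial-correlation shrinkage biases edge magnitudes toward zero; the
  0.3 display cut-off is a convention, not an inferential threshold.
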