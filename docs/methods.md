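# Methods

## The problem

A food-effect study asks whether taking a drug after a high-fat meal changes
its rate (Cmax, tmax) or extent (AUC) of absorption. In a 2×2 crossover each
subject receives the test formulation once fed (arm A) and once fasted
(arm B), in randomised order (sequences AB and BA) across two periods
separated by a washout long enough (≥ 5 terminal half-lives; 14 days for a
~31 h half-life) to exclude carryover. The regulatory criterion is average
bioequivalence: the 90% confidence interval for the fed/fasted geometric
mean ratio of each exposure endpoint must lie within 80.00–125.00%.

## Endpoints (non-compartmental)

Per subject and arm: AUC(0–72 h) by the linear trapezoidal rule, Cmax as the
highest measured concentration, tmax as its time — the earliest time when
maxima tie. All endpoint computation uses *actual* (recorded) sampling times,
not nominal ones. If actual times overshoot 72 h the straddling segment is
linearly interpolated to exactly 72 h; if the last sample falls short, the
area is truncated there with a warning rather than extrapolated. A lin-up/
log-down trapezoid exists behind a flag (`log_down=True`) but the default is
the plain linear rule, the literal reading of "trapezoidal rule".

BLQ convention (samples below the 0.25 ng/mL quantification limit): leading
BLQ values count as 0, embedded and trailing BLQ values are excluded so the
trapezoid spans the gap. This is ordinary NCA practice; in both the emulated
study and the default simulation the only BLQ samples are pre-dose, so
results are insensitive to the choice (tested).

## Crossover ANOVA on the log scale

The engine fits, by least squares on an effect-coded (sum-to-zero) design
matrix,

    ln y = μ + sequence + subject(sequence) + period + treatment + ε .

Subject-within-sequence is a *fixed* factor; with complete data the design
is full-rank under effect coding and, for a balanced 2×2, the fit coincides
with the mixed-model analysis. The treatment contrast is coded ±½ so its
coefficient is directly Δ̂ = mean ln(A) − mean ln(B); then

    PE  = 100·exp(Δ̂)
    SE  = √(MSE·(1/n₁+1/n₂)/2)          (equals √(MSE·x'(X'X)⁻¹x) here)
    CI  = 100·exp(Δ̂ ± t(0.95, n₁+n₂−2)·SE)
    CV  = 100·√(exp(MSE)−1)

with residual df = n₁+n₂−2 (= 22 for 12+12). Natural logarithms throughout.
Subjects missing either treatment are dropped (complete-case) with a
warning; fewer than two complete subjects per sequence is an error.
Computation is at full precision; *reporting* rounds half-away-from-zero to
2 decimals, the convention of printed PK tables.

`ci_from_summary` inverts the table: from (PE, CV, n₁, n₂) it rebuilds the
CI via s_w = √(ln(1+CV²)). It is the exact inverse of the fitted interval
(round-trip tested to 1e-10) and lets published ratio tables be checked for
internal consistency without raw data.

The bioequivalence decision is closed-interval containment of the CI in the
acceptance window; equality at a limit passes.

## Nonparametric tmax comparison

tmax is discrete on the sampling grid, so the treatment comparison is
distribution-free. Each subject contributes d = (period-1 − period-2)/2;
grouped by sequence, the location shift of the AB group relative to the BA
group is exactly the treatment effect A−B in hours (period effects cancel;
the half factor keeps the original scale). The shift is estimated by the
Hodges–Lehmann statistic — the median of all n₁·n₂ between-group pairwise
differences — and the CI takes the (k, n₁n₂+1−k) order statistics of those
differences, with k the largest rank whose two-sided coverage under the
exact Mann–Whitney null distribution is at least the requested confidence.
The achieved (conservative) coverage is reported alongside the nominal one;
for 12+12 the achieved level of the nominal 90% interval is 91.1%. The
exact null distribution is computed by the standard counting recurrence
(validated against exhaustive enumeration and scipy's exact p-values); ties
are handled naturally by the order statistics.

## TOST power and sample size

On the log scale the fitted ratio is normal with SD σ_w√(2/n) and the
residual SD is an independent scaled chi. Power — the probability that both
one-sided tests at level α reject, i.e. that the 100(1−2α)% CI falls inside
the limits — is computed exactly by integrating

    Φ(z_U − t·c) − Φ(z_L + t·c)   over the density of c = s/σ_w ,

the Owen's-Q formulation (adaptive quadrature; the integrand vanishes beyond
c = (z_U−z_L)/2t). A shifted noncentral-t approximation is available via
`method="nct"`; for the designs of interest the two agree to ~1e-3 or
better, and a 1e5-replicate Monte-Carlo simulation of the crossover TOST
agrees with the exact value within 0.005 (tested). Sample size is the
smallest even total n with power ≥ target, found by doubling plus bisection
(power is monotone in n). The design verification uses the more variable
endpoint's CV (20%), the conservative choice; at GMR 1.05 and α 0.05 that
gives power 0.903 at n = 24 and a minimal n of 18.

## The synthetic-trial generator

No individual concentration data are published for this kind of study, so
the generator defines the study conditions everything downstream is tested
under: 24 subjects alternating AB/BA (12 per sequence), 4 mg single doses,
the 17-point 0–72 h schedule, LLOQ 0.25 ng/mL, ~5% proportional assay error
(the assay's reported inter-assay precision is 2–7%), and small jitter
(SD 0.02 h, clipped to ±0.08 h) between nominal and actual sampling times.

**Disposition.** The drug's plasma decline is biphasic (distribution
half-life ~2 h, terminal half-life 30–34 h). The simulator therefore uses a
two-compartment (bi-exponential) disposition with α from a 2 h half-life,
β = ln 2/31 h⁻¹, and k21 = 0.17 h⁻¹; first-order absorption with fasted
ka = 0.45 h⁻¹; central V/F = 83 L. The distribution phase is not cosmetic: a
mono-exponential 31 h decline caps the achievable fed/fasted Cmax ratio near
1.19 however fast absorption becomes, because the peak then sits on an
almost flat curve. With the fast distribution phase, doubling ka raises
Cmax by ~20%, which is what makes the study's signature result reachable.
The plain one-compartment curve (`concentration_at`, with closed-form tmax
and AUC used as test oracles) remains available by setting
`distribution_half_life=None`.

**Food effect.** Food multiplies ka by 2.0 (rate) and bioavailability by
1.08 (extent) — the mechanism is the simulator's own assumption, calibrated
so the noise-free ratios on the nominal schedule are Cmax 1.296 and
AUC(0–72 h) 1.084, with the fed peak 1.5 h earlier on the grid (2.5 h vs
4.0 h). The fasted noise-free Cmax is ≈ 27 ng/mL.

**Variability.** Between-subject lognormal SDs: CL 0.20, V 0.15, ka 0.30.
Within-subject (per-period) lognormal SDs: CL 0.09 and ka 0.70, calibrated
once so that default trials reproduce intra-subject CVs of ≈ 6% for AUC and
≈ 18% for Cmax — AUC residual noise is driven by clearance, Cmax residual
noise by absorption-rate fluctuation. Assay error is multiplicative
lognormal with σ = 0.05. An optional `carryover_log` term injects a
period-2 shift purely so tests can exercise sequence-effect behaviour; the
default is 0 (the washout excludes carryover by design).

**Seeding.** One `SeedSequence` per trial spawns one per subject, which
spawns one per period, so identical configs are bit-identical and enlarging
the trial leaves existing subjects untouched.

**What the generator does and does not emulate.** It reproduces the design,
the censoring, the ratio structure (rate up ~30%, extent up ~8%), the
intra-subject CVs, and plausible tmax behaviour. It does not reproduce the
absolute AUC level of real drospirenone data (~444 ng·h/mL fasted): with
the terminal phase pinned at 31 h and Cmax pinned at 27 ng/mL, absolute
AUC(0–72 h) comes out ≈ 860 ng·h/mL, because the real drug's deep
distribution is only coarsely captured by one peripheral compartment. All
inferential machinery operates on within-subject *ratios*, which are
matched; passing tests therefore validate the statistics, not the absolute
exposure scale. Demographics, dropout, and any BLQ beyond pre-dose are not
modelled (the emulated study had none).

**Estimand note.** Because period noise enters the kinetics nonlinearly
(truncated AUC depends on clearance through the captured fraction; Cmax is
a maximum over noisy samples), the large-sample expectation of the fitted
log-ratio differs slightly (< 1%) from the noise-free ratio. Recovery and
coverage tests therefore compare the ANOVA against this generative estimand,
computed by an independent vectorised Monte-Carlo oracle of
E[ln endpoint], rather than against the noise-free curve ratio; the
noise-free configuration targets (1.30/1.08) are asserted separately.

## Numerical conventions and problem sizes

- Full-precision computation everywhere; 2-decimal half-away-from-zero
  rounding only at the reporting layer; 12-significant-digit CSV output so
  rereading endpoint files recomputes summary tables bit-identically.
- Simulation-based tests use 500 replicate trials for coverage and
  parameter recovery (3-sigma Monte-Carlo bands), 1e4 replicates for TOST
  size at the limit, 1e5 for the power cross-check (via the exact sufficient
  statistics of the balanced 2×2, whose equivalence to the design-matrix
  fit is itself a tested identity), and 2e3 for the exact-rank coverage of
  the Hodges–Lehmann interval.
- Degenerate inputs: identical arms give PE exactly 100% with a zero-width
  CI; n = 1 descriptive statistics report SD 0; ka equal to a disposition
  exponent is rejected with a pointer to the limiting form.

## Known limitations

- Single-dose 2×2 designs only: no steady-state, replicate, or
  scaled-average-BE support.
- The fixed-subject ANOVA equals the mixed model only for complete data;
  incomplete subjects are dropped, not modelled.
- The simulator's food-effect mechanism (ka and F multipliers) is an
  assumption chosen to reproduce the rate/extent signature, not a fitted
  gastroenterological model, and absolute exposure is intentionally
  sacrificed to match peak and ratio structure (above).
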