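# Methods

## Problem and scope

A bystander sharing an indoor space with e-vapor product (EVP) users is
exposed only to what users exhale. The package models that chain:
exhaled-breath measurements → per-mg emission factors → room air
concentrations in a ventilated space → inhaled dose for a non-user, with
cigarette sidestream smoke and occupational exposure limits as reference
scales. It deliberately excludes clinical-trial conduct, puff topography,
analytical chemistry of the trapping assays, three-dimensional
(CFD/distributed) air modeling, humidity/temperature dynamics, and aerosol
microphysics beyond single-component equilibrium partitioning.

## Synthetic crossover study

The generator emulates an open-label four-way crossover: 32 subjects, four
sequences (ABDC, BCAD, CDBA, DACB — each product once per sequence, eight
subjects per sequence), one product per period, and per period a paired
sham/product collection. Collection 1 captures nicotine, propylene glycol,
glycerin and menthol; collection 2 captures formaldehyde, acetaldehyde and
acrolein. One record = subject × period × analyte; 896 records by default.

Measurement model, all masses in µg per 10-puff session:

* product value = m(analyte, product) × b(subject, analyte) × e(session),
  with b and e mean-one lognormal multipliers with coefficients of
  variation `cv_between` and `cv_within` (defaults 0.6/0.6, reflecting the
  substantial between-subject spread such studies report). b is shared
  across a subject's four periods, which induces within-subject
  correlation; multiplicative noise keeps values positive and right-skewed
  with occasional outliers.
* sham value = lognormal around a per-analyte background; only
  formaldehyde has a non-zero default background (0.2 µg — endogenous
  breath carbonyls make sham formaldehyde comparable to product sessions).
* consumption = normal truncated at zero, per product × collection
  (defaults: means 33.7–41.2 mg, SDs 8.7–14.6 mg).
* censoring: values below the analyte MDL are replaced by the MDL and
  flagged. MDLs are not published for the assay, so defaults were chosen
  once per analyte (nicotine 1, propylene glycol 10, glycerin 10, menthol
  1, formaldehyde 0.1, acetaldehyde 0.5, acrolein 0.5 µg) to reproduce the
  qualitative pattern: menthol censored in roughly half of sessions
  (non-mentholated products emit ~0.2–0.35 µg, below MDL), formaldehyde in
  roughly one in six, acetaldehyde and acrolein always.

Per-product default means are the reference least-squares means (e.g.
nicotine 89.44 / 195.70 / 168.83 / 182.65 µg for products 1–4). Randomness
is keyed per subject as `(seed, subject_index)`, so a subject's data do not
depend on how many other subjects are generated, and identical seeds give
bit-identical tables. Subject sex is not modeled: it has no role in any
downstream computation.

What the generator does *not* emulate: assay-specific error structure,
carry-over between periods, missing data/dropout, or any coupling between
consumption and exhaled mass within a session (consumption enters only as
the emission-factor divisor). Passing recovery tests therefore demonstrates
internal statistical consistency, not validity of those real-data features.

## Mixed-model ANCOVA and emission factors

Per analyte the model is

    y = μ + sequence + period + product + β·sham + subject(sequence) + ε

fit by REML (`statsmodels MixedLM`) with subject as the random grouping
factor (subjects are uniquely labelled; nesting in sequence is implicit).
The least-squares mean for a product is the fixed-effects prediction
averaged with equal weight over sequences and periods at the grand mean of
the sham covariate — the standard covariate-adjustment convention. CIs and
the test of LS mean ≠ 0 use a t reference with between-subject degrees of
freedom `n_subjects − n_sequences` (28 by default), a containment-style
choice; published CI widths may use a different (unstated) method such as
Satterthwaite, so interval widths are property-tested (coverage), not
value-matched.

Two numerical guards:

* if the sham covariate has zero variance (every sham session censored at
  the MDL), it is dropped — a constant column is absorbed by the intercept
  and otherwise makes the design singular;
* if the mixed fit fails to converge or degenerates (zero residual
  variance, perfect fit), the model falls back to ordinary least squares
  with subject fixed blocks, which preserves the LS-mean definition; a
  perfect fit reports a zero-width interval and p = 0.

Under the generator's multiplicative noise, per-product sampling variance
is proportional to the squared product mean while the model pools a single
residual variance; per-product CI coverage therefore ranges from ~89%
(highest-mean product) to ~100% (lowest), pooling to ~93–94% across the
four products. This is an inherent generator/model mismatch, kept because
both sides follow their respective conventions.

Emission factor: `EF = LS mean / reference consumption` (µg exhaled per mg
e-liquid consumed), with the reference consumption defaulting to the
observed mean session consumption for the product and collection, rounded
to whole mg. Reported factors use two decimal places at ≥ 0.1 µg/mg and
two significant figures below; full precision is retained internally.
Analytes censored in *every* sham and product session carry no information
beyond the MDL: they are reported as factor 0 with `BELOW_MDL` status so
the MDL substitution cannot manufacture a positive emission. An MDL-based
upper bound is available as an option (`mdl_upper_bound=True`) but is not
the default.

## Well-mixed box model

`V dC/dt = S(t) − λVC`, with V the space volume, λ the air-change rate and
S the release schedule. Well-mixedness assumes ventilation-driven mixing is
fast relative to the exposure window — appropriate for the high-ventilation
scenarios modeled, and the reason concentrations carry no spatial
structure. The integrator advances the exact solution of this linear ODE
per output step (exponential closed form for piecewise-constant sources;
puff events as instantaneous jumps m/V recorded as duplicated grid
instants), so trajectories are round-off accurate; the per-step mass
balance also yields an exact cumulative ventilated mass used by the
conservation audit `S_total = VΔC + λV∫C dt` (closes to machine precision;
the test tolerance is 0.1%). Output grid spacing defaults to duration/2000
and must be at most duration/100; puff mode additionally requires the step
to resolve the inter-puff gap.

Partitioning: a semivolatile constituent with saturation mass concentration
C* holds at most C* in the vapor phase; any excess condenses
(vapor = min(C, C*)). Gas–particle equilibration for submicron droplets is
sub-millisecond, so equilibrium is applied instantaneously at each output
time. All default constituents are treated as fully volatile (C* absent):
EVP constituents are high-volatility species, and time averages — the only
quantity entering intake — are unaffected by an equilibrium split of the
same total. Multicomponent (Raoult/activity) coupling and particle
deposition are out of scope; no composition-coupled parameters exist to
support them, and a first-order deposition term would break the observed
cross-constituent linearity.

Time averaging is trapezoidal on the output grid; the duplicated puff
instants make the trapezoid exact across jumps. A 30-s puff train and a
continuous source of equal mass agree on the 1-h average to well under 1%
even at λ = 60/h.

## Scenarios, intake, calibrated ventilation

Source terms: an EVP user consumes 902 mg e-liquid per 16-h waking day
(56.4 mg/h), so a room with n users releases
`n × 56.4 × EF` µg/h of a constituent; a smoker contributes sidestream
smoke at `n × 1 cigarette/h × sidestream emission` (reference-cigarette
values: nicotine 5600, formaldehyde 700, acetaldehyde 4200, acrolein
1300 µg/cigarette; none available for propylene glycol, glycerin — reported
as `NA`). Using sidestream only (no smoker-exhaled mainstream) biases the
cigarette side low; documented, not corrected. Occupant counts label the
scenario only — a well-mixed space has one concentration and people are not
modeled as sinks.

Intake over a window = time-averaged concentration × duration × 0.36 m³/h
(500 mL × 12 breaths/min), assuming complete absorption. The 8-h
limit-reference intake is `limit × 2.88 m³`, rounded to the nearest µg
(nicotine 500 µg/m³ → 1440 µg; glycerin 10,000 → 28,800; formaldehyde
920 → 2650; acetaldehyde 360,000 → 1,036,800; acrolein 250 → 720 µg).
Propylene glycol has no OSHA PEL; the 10,000 µg/m³ industrial-hygiene
guideline is used so the comparison column is complete.

Air-change rates for the four shipped scenarios are not published values.
`calibrate_ach` inverts the closed-form transient average
`C̄(λ) = S/(λV) · (1 − (1 − e^{−λT})/(λT))` — strictly decreasing in λ from
the no-ventilation bound ST/2V — against the nicotine intake column,
giving 25.06/h (car closed), 52.48/h (car open), 1.64/h (meeting room) and
4.88/h (restaurant). The config files flag these as reconstructions.
Because the box model is linear, every other constituent's intake then
follows as the nicotine intake scaled by the emission-factor ratio, and the
cigarette/EVP fold difference reduces to the per-user source-rate ratio
(≈23.5 for nicotine, ≈1496 for formaldehyde), independent of space,
duration and user count.

Known data discrepancy: the reference intake table's cigarette acetaldehyde
and acrolein rows are inconsistent with the sidestream inputs' ratios to
nicotine (they appear mutually transposed). The implementation follows the
sidestream inputs and linearity, so it prints ≈38.2 µg acetaldehyde and
≈11.8 µg acrolein for the closed car rather than the published 12.28/38.20.
Similarly, published nicotine intake fold ratios (~24.6) sit slightly above
the source-rate ratio (23.5); the residual presumably reflects unpublished
per-scenario details and is not reconciled.

## Problem sizes and determinism

Defaults throughout are the full study size (32 subjects, 896 records) and
2000-point output grids; the recovery experiment uses 100 replicates of the
full design at CVs of 0.4 (a moderate-variability setting distinct from the
generator's 0.6 default). All randomness flows from a single integer seed
through `numpy` Generator streams; reruns are bit-identical. The end-to-end
pipeline completes in a few seconds on one core; the acceptance script in
well under a minute.

## Limitations

* The ANCOVA is fit on MDL-substituted values (the stated convention), not
  a censored-likelihood model; heavily censored analytes (menthol on
  non-mentholated products) inherit the resulting bias.
* Emission factors are point estimates; ANCOVA uncertainty is not
  propagated into intakes.
* The box model has a single loss process (ventilation); deposition,
  sorption and particle dynamics are excluded, so cigarette-particle
  persistence is approximated by the same clearance as vapors.
* Calibrated air-change rates inherit rounding error from the published
  intakes they are inverted against (~0.5% for the open car).
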