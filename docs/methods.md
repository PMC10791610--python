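# Methods

This note documents the models implemented in `flashear`, the defaults and
why they were chosen, what the synthetic-data generator does and does not
emulate, and the numerical choices a maintainer should know about.

## Pulsed-beam dosimetry (`flashear.beam`)

A broad proton beam of current *I* deposits *LET* per particle per unit path
length into a slab of mass-per-path-length *A·ρ*, giving

    dose rate [Gy/s] = (I / e) · LET / (A · ρ).

The elementary charge cancels between the particle rate and the LET unit
conversion, so in mixed units the rate is `I[nA] · LET[keV/µm] / (A[mm²] ·
ρ[g/cm³])` Gy/s; all conversions are centralised in
`flashear.units.dose_rate_gy_per_s`.  The target density defaults to
water-equivalent 1 g/cm³ (standard soft-tissue assumption; configurable).

A chopper in front of the accelerator passes every *k*-th pulse of a base
frequency *f*, so the pulse-to-pulse distance is *k/f* (5 MHz and k = 2⁶ give
12.8 µs).  Mean dose rate = peak rate × duty cycle (pulse width / period);
duration = dose / mean rate.  The three default beam configurations are: a
continuous 15 nA mode (≈930 Gy/s), the same current chopped to 128 ns / 12.8 µs
(≈9.3 Gy/s), and 0.4 nA chopped to 128 ns / 51.2 µs (≈0.06 Gy/s).  The 51.2 µs
period for the conventional mode is the value consistent with a 2⁸ partition
of a 5 MHz train and the 400× peak-to-mean current ratio (0.4 nA → 0.001 nA);
the period is nevertheless a free parameter.  Note that the conventional
mode's peak rate by strict linear current scaling is 24.8 Gy/s.

`units.round_sig` rounds to a number of significant digits; display-level
rounding never feeds back into computation.

## Irradiated blood volume (`flashear.bloodvolume`)

Traced vessels are cylinders in three by-eye thickness classes with default
mean diameters 0.09 / 0.05 / 0.04 mm (class table configurable; an explicit
per-segment diameter overrides its class).  Volumes are computed in mm³ and
reported in µl (1:1).

- `static_volume`: Σ π d²/4 · length over segments — the blood inside the
  field at any instant.
- `flow_volume`: Σ π d_i²/4 · v · t over entry veins — the blood exchanged
  during the irradiation time t at venous flow speed v (default 2 mm/s).
  Entry veins should be thick or middle-class; a thin vein in the entry list
  warns but is not rejected.
- `irradiated_volume` = static + flow (exact additivity).
- `mean_blood_dose` = D · V_static / V_irr: each parcel of blood resides in
  the field for a fraction V_static/V_irr of the irradiation on average, so
  the population-mean dose is diluted by exactly that ratio.  It equals the
  prescribed dose when no blood is exchanged and never exceeds it.  (An
  alternative "present for half the irradiation" argument for intermediate
  timings gives nearly the same number — 17 vs 17.8 Gy on the calibrated
  fixture — and is not implemented as the general rule.)
- `total_blood_volume`: 10.35 ml per 100 g body weight (Balb/c); a 19.2 g
  mouse carries ≈1.99 ml.

The calibrated fixture used in tests and the acceptance script — class
lengths 16/26/38 mm (V_static ≈ 0.20 µl) and four 0.09 mm entry veins — was
chosen because it reproduces the irradiated volumes of all three beam
timings within their reported uncertainties.  It is a fixture, not measured
ground truth: the number and size of entry veins in a real ear must be read
off the photographs.

Uncertainties: `replicate_stats` gives across-ear mean, SD and SEM (SD/SEM
are reported as missing for n = 1, never as 0); `ratio_uncertainty` applies
first-order propagation for derived ratios, which is accurate to a few
percent for coefficients of variation up to ~10–15 % and degrades for
noisier denominators.

## Longitudinal cohort statistics (`flashear.cohort`)

Swelling of mouse *i* at time *t* is ES_i(t) = ET_i(t) − mean sham ET(t).
Because measurement days differ per mouse, the sham reference interpolates
each sham mouse's series linearly onto the query day (clamped to its own
observed range, never extrapolated) and averages.  Evaluated at a sham
mouse's own day this reproduces the measurement exactly, so sham-referenced
swelling averages to zero identically on the span all sham mice cover.

Group curves (`group_curve`) interpolate every mouse onto an integer-day
grid restricted to its own observed range and take per-day mean, SD, SEM and
n over the covering mice; for swelling the subtraction happens *after*
interpolation, at the grid day, which preserves the centring identity.  An
`observed` mode restricts to exactly-measured days.  SEM is missing (NaN)
where n = 1.

The maximum reaction is the maximum of the group mean curve, ties broken to
the earliest day; `reduction_analysis` searches only the fully covered span
(days where every mouse of the group contributes) so that trailing days
represented by one animal cannot produce spurious maxima.  Reduction of a
test group versus the reference:

    R = 100 (1 − m_t/m_r),
    σ_R = 100 √( (σ_t/m_r)² + (m_t σ_r/m_r²)² ).

For swelling, the peak SEMs include — in quadrature — the standard error of
the estimated sham mean at the peak day: the subtracted reference is itself
an estimate, and ignoring its sampling error leaves the propagated σ_R
undercalibrated (2σ coverage dips below nominal for small groups).  Treating
the sham error as independent between the two groups' peak days is slightly
conservative when those days nearly coincide.

Group comparison uses a two-sided pooled-variance Student t-test on
per-mouse values interpolated at the peak days (Welch available via
`equal_var=False`); degenerate zero-variance comparisons return t = 0,
p = 1 when the means agree.  p-values are raw — no multiple-testing
correction is applied, and report outputs say so.

The inflammation score sums ordinal erythema {No 0, Mild 0.5, Definite 1.5,
Severe 3} and desquamation {No 0, Dry 1, Crust formation 2, Moist 3}
grades (range 0–6); level strings are case-insensitive and in-vocabulary
numeric scores are accepted.

Known estimator properties: the maximum of a noisy mean curve is biased
upward, more so for small/noisy groups, which biases reductions slightly
downward (≈3–5 percentage points at n = 3 with 25 µm noise); and sampling
every 2–7 days undershoots the true peak by a few percent in both groups,
which largely cancels in the ratio.  Both effects are visible in, and
covered by, the recovery tests.

## qPCR ΔΔCt (`flashear.qpcr`)

Replicate Ct wells are averaged arithmetically; undetermined (NaN) wells are
dropped with a warning, never imputed; an optional QC flag warns when the
replicate spread exceeds 0.5 cycles.  With two housekeeping genes (B2M,
GAPDH) the default normaliser is the arithmetic mean of their per-sample Ct
means — equivalent to normalising expression by their geometric mean — and
single-gene normalisation is selectable.  The reference ΔCt is the sham
group's mean ΔCt for the same gene and day (no day pooling).  Exact
identities hold by construction: FC = 2^(−ΔΔCt), log2 FC = −ΔΔCt, and adding
a constant to every Ct of a sample (RNA-loading shift) leaves ΔΔCt
unchanged.  No amplification-efficiency (Pfaffl) correction and no
inferential testing beyond descriptive mean ± SD are performed.

Gene names are ASCII-normalised in code and CSVs (TGF-b1, TNF-a, IL1a,
IL1b).

## Synthetic-data generator (`flashear.simulate`)

The generator emulates the *statistical* structure the analysis assumes —
it is not a biophysical simulation of oxygen depletion, ROS chemistry or
immune kinetics.

- **Cohort**: groups (dose, rate label, n) default to the study plan
  {(23, Conv, 7), (33, Conv, 7), (23, Flash9, 9), (33, Flash9, 3),
  (23, Flash930, 7), (33, Flash930, 9), Sham 7}.  Each mouse is measured at
  day 0 and then every 2–7 days (uniform) to day 180.  Thickness is
  baseline 230 µm + A·g(day) + N(0, 25² µm²).  The response g is a
  gamma-shaped unimodal curve `x^a e^{a(1−x)}` with x = (day−12)/11 and
  a = 3: onset day 12, peak day 23 (normalised to 1), effectively zero by
  day 61.  The 33 Gy amplitudes encode true reductions of 57 % (Flash9) and
  40 % (Flash930) versus the conventional 155 µm peak; 23 Gy amplitudes are
  49/40/30 µm.  The baseline is an inert choice — only differences enter the
  analysis.  The per-measurement noise SD follows the study's day-0 spread
  figure of 25 µm (printed there as an SEM; adopted here as the
  per-measurement SD, which makes the synthetic curves somewhat *less* noisy
  than the real data's biological variability).  Ordinal grades are emitted
  by thresholding the noiseless swelling (erythema at 40/120/200 µm,
  desquamation at 100/160/220 µm), chosen so the conventional 33 Gy group
  peaks at score 2.5 and the 23 Gy groups stay below 1.
- **Vessel trace**: jagged random polylines folded into the 6.5 × 6.5 mm
  field with per-class total lengths near 16/26/38 mm; the authoritative
  segment lengths are re-measured from the generated polylines, so the
  returned true V_static is exactly what `polyline_lengths` +
  `static_volume` recompute.  Entry veins default to four of 0.09 mm.
- **qPCR plate**: housekeeping Ct ~ base (18/19) + per-sample loading shift
  N(0, 0.5); cytokine Ct = housekeeping mean + baseline ΔCt (4–7 cycles)
  − injected true log2 FC; every well gets triplicate N(0, 0.2²) read noise.
  The default scenario injects no effect anywhere, mirroring a null
  cytokine panel.

Each generator draws from its own child stream of the master seed (fixed
`SeedSequence` spawn keys), so adding a generator never perturbs another's
output, and identical seeds give identical data.

What passing recovery tests show: the analysis chain is consistent and its
uncertainty model calibrated *under this noise model* (independent Gaussian
measurement error, shared response shape, no per-mouse random effects, no
dropout, no scorer disagreement).  Real cohorts violate several of these,
so recovery here is necessary, not sufficient, evidence for real-data
performance.

## Numerical and interface choices

- All dose/volume computations run at full double precision; rounding to
  printed precision happens only at the display/report layer.
- Degenerate inputs fail loudly with typed errors (`InvalidParameterError`,
  `DataFormatError`, `MissingReferenceError`, `MissingDataError`) naming the
  offending row/column for tabular input.
- CSV dialect: comma-separated UTF-8 with header, '.' decimals; comma
  decimals are normalised on read with a warning.  Days are integers since
  irradiation (day 0 = irradiation day).
- Reports carry the seed, package version and a config hash (excluding the
  output directory), and are byte-reproducible from config + seed.
- Problem sizes in the test-suite simulations (200 cohort replicates for
  reduction coverage, 100 plates for qPCR bias, 10⁴ t-test null replicates,
  20 Monte-Carlo voxelization traces at 2×10⁵ points per cylinder) were
  chosen to keep each statistical check's own Monte-Carlo error well below
  the tolerance it asserts.

## Known limitations

- No proton transport, LET-depth or field-homogeneity modelling; dose rate
  assumes a thin target and a flat field.
- The blood model ignores pulsatility, the arterial/venous split, vessel
  overlap at crossings and any lymphocyte-kill modelling beyond mean-dose
  dilution; entry-vein counts/diameters must come from images.
- No mixed-effects longitudinal modelling; the contralateral (left) ear is
  not analysed.
- First-order uncertainty propagation degrades for reference peaks with
  coefficients of variation beyond ~15 %.
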