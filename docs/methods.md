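# Methods

`peatflux` implements the inference chain used to quantify CO2 production
from horticultural peat and growing media (peat amended with lime,
fertilisers, perlite and surfactants): closed-jar headspace incubations
give total CO2 production rates; Keeling plots give the delta13C
signature of the emitted CO2; a two-pool mixing model splits each flux
into lime-derived (abiotic carbonate dissolution) and peat-derived
(microbial) components; FT-MIR band ratios summarise humification; and
the mean biotic rate is upscaled to a national first-year emission. A
synthetic-data generator with known ground truth makes every stage
testable end to end.

## Headspace flux estimation

A jar of headspace volume V (jar volume minus sample volume, default
250 − 10 = 240 mL) accumulates CO2 at a constant rate. Mixing ratios are
converted to CO2-C mass with the ideal gas law at the incubation
temperature (23 °C) and standard pressure (101.325 kPa):

    m(c) = c·1e-6 · PV/(RT) · 12.011 g/mol,

reported in mg C. Each gas sampling withdraws `withdrawal_volume`
(default 5 mL) of fully mixed headspace and replaces it with ambient
air. The cumulative production at time t_i is reconstructed as

    M_i = m(c_i) − m(c_0) + Σ_{events j<i} φ·(m(c_j) − m(c_amb)),

with φ the withdrawn volume fraction: each event's net export of CO2-C
is added back, so with zero production the corrected series is exactly
zero and, for constant production, the corrected cumulative series is
independent of how many sampling events occurred. An OLS fit of M
against time (in days) gives the whole-jar rate; dividing by the
organic-C mass (dry mass × organic-C fraction) expresses it in
mg CO2-C g orgC⁻¹ d⁻¹. Replicates with r² ≤ 0.8 are flagged and
excluded from sample means; a degenerate fit (zero variance in M, r²
undefined) is treated as a QC failure rather than an exception so batch
processing stays total.

The regression response is cumulative corrected *mass*, not raw
concentration; with the default 4-point schedule (0, 6, 24, 48 h) and
infrequent events the two differ negligibly, but mass is the quantity
that is conserved across events, so it is the principled choice.

### Dissolved CO2 diagnostic

Because some produced CO2 stays in the sample's pore water, the
headspace-only calculation underestimates production. The equilibrium
dissolved share is computed from Henry's law (K_H = 3.4·10⁻² mol L⁻¹
atm⁻¹ at 25 °C with a van 't Hoff temperature correction, ΔH/R = 2400 K)
plus the first carbonate dissociation (pK₁ = 6.35): dissolved = CO2*(aq)
+ HCO3⁻, and the fraction is dissolved/(dissolved + headspace). It
increases with pH and with water volume and stays at or below ~20% over
the pH range relevant to these materials. It is reported as a
diagnostic only, never applied as a correction, so reported rates remain
directly comparable to headspace-based literature values.

## Keeling plots

For a mixture of an ambient pool (C_a, δ_a) and accumulating source CO2
with signature δ_s, the observed δ is linear in 1/C with intercept δ_s.
Each replicate is fitted by OLS of δ on 1/[CO2] (model-II regression was
considered and rejected as the default: the acceptance thresholds in
common use are quoted for simple OLS practice). Replicate QC follows the
standard two-stage screen: a replicate is dropped when its r² ≤ 0.90
(strict inequality, so a tie at 0.90 is excluded — mirroring the "> 0.90"
rule; "regression coefficient" is read as r², consistent with the flux
module's r² rule); a sample's signature is the mean of surviving
intercepts and is accepted only when at least two replicates survive and
the coefficient of variation of their intercepts (sample sd over
absolute mean, computed on the signed per-mil values) is below 10%.

With the 4-point isotope schedule (0, 2, 4, 6 h) the residual-estimated
OLS intercept SE has only two degrees of freedom and is itself noisy;
`KeelingResults.intercept_se` reports it regardless, but coverage
statements at instrument noise are best made against the SE evaluated at
the known noise level (0.4 permil, the CRDS standard-error bound), which
is what the recovery tests do.

## Two-pool mixing partition

The lime fraction of a total flux is

    f = (δ − δ₀) / ((δ₁ − ε) − δ₀),

with δ the Keeling intercept of the emitted CO2, δ₀ the solid-material
end-member (each sample's own solid δ13C when available, the group mean
otherwise), δ₁ the lime end-member (measured product mean −0.03 permil,
sd 0.28 permil), and ε an optional carbonate-to-CO2 fractionation
subtracted from the lime end-member — the direction in which carbonate-
derived CO2 is depleted relative to the solid carbonate. f is invariant
to adding a common constant to all three signatures. Noisy intercepts
can push f outside [0, 1]; by default it is clipped with a flag while
the raw value is retained for diagnostics. The flux split is
flux_lime = f·total, flux_biotic = (1 − f)·total, with the stored total
recomposed from the two parts so additivity is bitwise exact.

`sensitivity_sweep` evaluates f over an ε grid (default 0–12 permil; f
rises monotonically until the shifted lime end-member approaches δ₀,
past which rows are flagged invalid). `propagate_uncertainty` draws the
three signatures from independent normals (no covariance information is
available for them) and reports the Monte-Carlo mean and 95% interval of
the raw fraction; with only se(δ) nonzero it matches the delta-method
half-width 1.96·se(δ)/|δ₁ − δ₀|.

## FT-MIR humification indices

Spectra (600–4000 cm⁻¹, 2 cm⁻¹ spacing) are baseline-corrected with a
rubberband baseline — the lower convex hull of the spectrum, linearly
interpolated between support points — chosen over polynomial fitting
because it is parameter-free and removes any convex additive baseline
exactly at the support points. Spectra are then area-normalised
(integral 1 by the trapezoid rule); the indices are height ratios, so
normalisation is cosmetic but fixes the scale of intermediate files.
Band heights are the local maximum in a ±10 cm⁻¹ window around each
centre (robust to grid offsets), and the indices are

    Hi1 = 1420/1090, Hi2 = 1510/1090, Hi3 = 1630/1090, Hi4 = 1720/1090,

all relative to the 1090 cm⁻¹ polysaccharide band. The 1510 cm⁻¹
assignment for Hi2 follows the standard band list. Indices are invariant
to multiplicative rescaling exactly and to additive linear baselines up
to the hull tolerance; a zero 1090-band height after processing raises a
diagnostic error.

## Upscaling

With extraction E (Mt C yr⁻¹, default 0.45), mean biotic rate r
(mg CO2-C g orgC⁻¹ d⁻¹) and day count d (365),

    first-year emission [Mt C] = E · r·10⁻³ · d,

where 10⁻³ converts mg C per g C to a mass fraction. The 95% CI applies
the same chain to r ∓ 1.96·se(r): a normal-approximation interval, which
reproduces printed bounds that a t-interval would not. The default rate
is the unrounded partitioned biotic mean (0.19·(1 − f) ≈ 0.147 rather
than the rounded 0.15), which is what the headline 0.024 Mt figure
requires. The restoration sink converts area (ha → 10⁴ m²) times areal
uptake (g C m⁻² yr⁻¹ → 10⁻¹² Mt) into Mt C yr⁻¹. All conversion factors
live in one audited table (`peatflux.constants`). Group summaries use
mean ± se with Welch t contrasts and Spearman rank correlations
(average ranks for ties; |ρ| 0.3–0.5 moderate, > 0.5 strong); full
generalised-least-squares variance modelling is deliberately out of
scope as off-the-shelf statistics.

## Synthetic data generator

The generator emulates the laboratory design, not microbial dynamics:
per-sample rates are constants (no temperature or moisture response).

* **Design.** 28 peat + 24 growing-media samples in von Post classes
  (10, 9, 9) and (12, 6, 6), triplicate jars, ~10 g dry mass in 250 mL
  jars, concentration sampling at 0/6/24/48 h with 5 mL ambient-air
  refills, isotope sampling at 0/2/4/6 h with 25 mL CO2-free refills —
  the two schedules and refill gases are distinct, as in the laboratory
  protocol.
* **Rates.** Drawn from Gamma distributions (positive by construction;
  a truncated normal would bias the media mean upward by several
  percent): peat total mean 0.063, sd 0.024 (cv 0.38); media biotic
  mean 0.147, sd 0.083 (the between-sample sd implied by se 0.017 over
  24 samples). The media lime share is Beta-distributed with mean 0.225
  and sd 0.10, converted to a lime rate on top of the biotic rate, so
  the generated δ of emitted CO2 spans roughly −29 to −13 permil.
* **End-members.** Solid δ13C per sample ~ N(group mean, 0.15 permil);
  lime δ13C per sample ~ N(−0.03, 0.28 permil). Within the generator the
  solid value and the biotic-source signature coincide (zero biotic
  fractionation); a nonzero carbonate fractionation ε is injectable.
* **Isotope mixing.** Observed δ at total concentration C_t is computed
  from the two-pool identity with the *starting* ambient pool
  (C_a, δ_a): δ = δ_s + (C_a/C_t)(δ_a − δ_s). This keeps every noiseless
  point exactly on the Keeling line and makes intercept recovery exact
  to machine precision. It idealises refill mixing: physically a
  CO2-free refill also removes part of the ambient-derived CO2, which
  would rotate later points to slightly shallower slopes through the
  same intercept; over the 6 h isotope schedule the resulting OLS
  intercept shift is well below the instrument noise, and the
  idealisation buys an algebraically checkable generative model.
* **Noise.** Additive Gaussian: 0.4 permil on δ (the instrument-level
  standard error) and 10 ppm on concentrations — the GC precision is not
  externally constrained, so 10 ppm (~1–2% of a typical reading) is a
  realistic free choice, not a measured value. Noise enters after the
  deterministic trajectory, last.
* **Spectra.** Gaussian peaks (σ = 12 cm⁻¹) at the five index bands on a
  shallow convex quadratic baseline; peak heights are the group's index
  profile times a 0.4-absorbance reference band with 1% relative jitter.
  The convex baseline is removed exactly by the rubberband correction up
  to chord tolerance, so index round-trips are accurate to < 0.02.
* **Covariates.** pH, DOC, TDN and C:N are drawn from independent
  per-group normals around the group means. They exist only to exercise
  the correlation/summary plumbing; no joint distribution between
  covariates and rates is modelled, so correlation outputs on synthetic
  data are structurally null.

What passing tests on this generator show: the estimators invert the
generative model they were designed for (dilution correction, Keeling
intercepts, mixing fractions, index ratios) at the stated noise levels.
What they do not show: robustness to non-constant production (substrate
depletion, lag phases), drifting ambient baselines, isotope fractionation
during microbial respiration, instrument drift, or mineral interference
in spectra — real-data behaviour must be judged separately.

## Numerical choices and degenerate inputs

* OLS fits delegate to `statsmodels`; r² is set to NaN (and QC to fail)
  when the response has zero variance.
* Strict inequalities at both QC thresholds (r² > 0.8 flux, r² > 0.90
  Keeling); CV uses the sample (ddof = 1) standard deviation.
* `mixing_fraction` raises on a zero denominator; sweep rows past the
  denominator sign change are flagged rather than raised.
* The rubberband hull uses a monotone-chain lower hull on the (strictly
  increasing) wavenumber grid; collinear points are dropped from the
  hull, which leaves the interpolated baseline unchanged.
* Replicates are 0-based internally and 1-based in user-facing output.

## Problem sizes in the test suite

Recovery and coverage suites use 500–1000 synthetic replicates per
property; the end-to-end upscaling check averages ten 52-sample pipeline
runs, since a single 24-sample draw of the media biotic mean carries
~11% relative sampling error by the design's own numbers. The whole
suite runs in a few seconds on one CPU.
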