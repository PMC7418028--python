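# Methods

This note documents the models, conventions and numerical choices behind the
package, and what the synthetic-data tests do and do not demonstrate about
real measurements.

## Equilibrium calibration

Equilibrium Δ47(T) and Δ48(T) are quartic polynomials in 1/T on the CDES90
scale (CO₂ equilibrium scale, 90 °C acid reaction), valid 0–40 °C.  They are
constructed from theoretical mineral Δ63/Δ64 temperature dependences in two
constant-term shifts: first by the acid fractionation factor of each channel
(defaults 0.194‰ for Δ63→Δ47 and 0.138‰ for Δ64→Δ48, derived as
measured-minus-theoretical at 600 °C, where the theoretical mineral values are
0.018‰ and 0.002‰), then by anchoring to a measured carbonate of
independently known constant formation temperature.  The shipped default is
anchored to a vein calcite at 33.7 °C, with recorded anchor offsets of
+0.010‰ (Δ47) and −0.021‰ (Δ48).  Because both shifts touch only the constant
term, the temperature *sensitivity* is purely theoretical while the absolute
position is empirical.

Both polynomials are verified strictly monotone decreasing at construction
(0.1 K grid), which makes temperature inversion a bracketed one-dimensional
root problem; we use Brent's method (bisection-safeguarded) with a value-space
residual below 1e-10‰.  Evaluation and inversion outside the declared 0–40 °C
range warn up to a configurable extension (default ±10 K) and error beyond
it.  Both polynomials were checked to remain monotone over 203–353 K, so the
wider extensions used for kinetic diagnostics (below) stay well-posed.

A quartic Δ47-versus-Δ48 convenience fit is carried for reporting and
plotting; it agrees with the parametric pair to ≤ 0.0015‰ over the validity
range (measured maximum deviation ≈ 0.0006‰).  All projection and inversion
arithmetic uses the parametric pair, never this fit: the fit is a derived
object, and the ~0.5 °C it could contribute is avoidable.

Calibrations serialise to a flat JSON block (coefficients per channel, acid
factors, anchor record, validity range, scale label) so alternative
coefficient sets plug in without code changes.

## Kinetic diagnosis and projection

Disequilibrium offsets are measured-minus-equilibrium at the known growth
temperature, with the equilibrium values treated as exact (the measured 2 SE
pair carries through unchanged).

Projection solves g(T) = Δ47 + s·(Δ48_eq(T) − Δ48) − Δ47_eq(T) = 0 along a
process slope s (−1.0 degassing, −0.6 absorption; exogenous model results,
overridable).  For any negative slope g is strictly monotone increasing in T,
so the root is unique and bracketable; the default bracket extends 25 K
beyond the validity range because measurement scatter displaces intersections
slightly outside 0–40 °C.  Near-tangency (|g′| < 1e-5 ‰/K) is flagged.

Monte-Carlo uncertainty draws (Δ47, Δ48) from independent normals with
σ = 2 SE / 2 — the reported 2 SE being read as a 95% interval, and no
channel covariance being assumed because none is available — re-projects each
draw, and reports the 2.5/97.5 percentiles.  With a fixed negative slope the
draws are inverted simultaneously on a precomputed 0.01 K grid of the
monotone function s·Δ48_eq(T) − Δ47_eq(T) (interpolation error ≪ 1e-3 K);
with slope uncertainty enabled each draw is root-solved individually.  Slope
uncertainty is off by default (no published slope error exists).  Linearised
error propagation gives somewhat smaller half-widths than the published ±5–9
°C; the Monte-Carlo intervals land in between (e.g. ≈ ±4.3 °C for the
warm-water coral against a published ±6), and we report the Monte-Carlo
values without forcing agreement, since the published propagation method is
unstated.

The equilibrium-consistency test is a 2 SE box test: a pair is consistent if
some in-range temperature satisfies both |Δ47 − Δ47_eq(T)| ≤ 2 SE₄₇ and
|Δ48 − Δ48_eq(T)| ≤ 2 SE₄₈.  Monotonicity turns each condition into a
temperature interval, so the test is an exact interval intersection, not a
grid search.  This mirrors the "within 2 SE of the equilibrium line" language
without inventing a covariance.

Δ47-only temperatures of strongly biased samples fall far outside the
calibration range by construction (a cold-water coral Δ47 of 0.719 inverts to
≈ −12.6 °C); since quantifying that bias is the purpose of the function, its
default inversion extension is 30 K, with the standard extrapolation warning.

## Isotopologue arithmetic

Isotopic parameters follow the IUPAC/Brand assessment (¹³C/¹²C of VPDB
0.011180; ¹⁸O/¹⁶O and ¹⁷O/¹⁶O of VSMOW 0.0020052 and 0.00038475; λ = 0.528),
stored in one editable dataclass.  Bulk compositions are (δ¹³C vs VPDB, δ¹⁸O
vs VPDB-CO₂); the VPDB-CO₂ gas scale is tied to VSMOW by a constant ratio
factor (1.04143), and the 90 °C acid ¹⁸O fractionation (1.00813) is used only
when reporting carbonate δ¹⁸O, never in Δ arithmetic.

Stochastic abundance ratios R45*–R49* come from the multinomial combination
of the carbon and two oxygen positions with R17 = r17·(R18/r18)^λ.  Raw
reduction compares each sample cycle to the mean of its two bracketing
working-gas cycles (last cycle to the last working-gas cycle) — the
bracketing scheme is a documented convention, as no standard exists.  The
sample bulk composition is solved from the mean δ45/δ46 by a bracketed root
search in R18; Δi(raw) = (Ri/Ri* − 1)·1000 against the sample's own
stochastic distribution, averaged over cycles.  The working gas is treated as
stochastic at its known bulk composition; any true working-gas clumping is a
constant offset absorbed by the transfer function.  Amplifier gains cancel in
every δ and Δ because sample and working gas share cups.

## Session correction pipeline

Correction order is fixed: non-linearity → scale compression → temporal
drift.  The tests document that permuting steps on a distorted session
changes the results.

**Non-linearity (carbonate mode).**  A negative secondary-electron background
under the m/z 47–49 cups, monitored at m/z 47.5, is removed at the intensity
level: corrected_i = i + s·i₄₇.₅ per channel, with s = −1 and a negative
monitor reproducing direct subtraction of the background magnitude.  The
scaling factor per channel is root-found (Brent, bracket [−2, 0.5]) so that
the OLS slope of Δ(raw) vs δ across the ETH 1 + ETH 2 replicates vanishes —
those two standards share accepted Δ values but differ by ~12‰ in δ¹³C, which
is what makes the slope observable.  A session with no monitor signal is
reported degenerate with s = 0.  ETH 1 and ETH 2 are treated as isotopically
identical (joint accepted values 0.212/0.140‰) in every fit, consistent with
their common 600 °C equilibration; the per-standard long-term table is
retained for statistics.

**Non-linearity (gas mode).**  The Δ(raw)-vs-δ slope is estimated from CO₂
gases equilibrated at 25 °C and 1000 °C.  The two families sit at different
equilibrium Δ, so the "merged" slope is a common-slope, per-family-intercept
least squares, not a naive pool (pooling would alias the intercept contrast
into the slope).  Family slopes are compared by a z test: an α-level
discrepancy warns, a |z| ≥ 4 discrepancy is an error because merging would
then be meaningless.  A channel is corrected only when its merged slope is
resolvable (|slope| > 2 SE) — the Δ47 channel is typically flat.

**Scale compression.**  A per-channel linear transfer function maps corrected
raw Δ to CDES90, fitted by OLS from the session means of the carbonate
standards against their accepted values (carbonate mode) or from the
gas-family intercepts against theoretical gas equilibrium values (gas mode).
The theoretical gas values are configurable constants (defaults 0.920/0.027‰
Δ47 and 0.345/0.000‰ Δ48 at 25/1000 °C).

**Drift.**  Residuals of all standards against accepted values, as a
function of session time, are windowed (default 48 h), averaged per window at
the mean window time, joined piecewise-linearly, and extrapolated linearly at
the session edges — so a pure linear drift is recovered exactly everywhere.
A window wider than the session collapses to a constant model with a
warning.  Corrections exceeding 0.010‰ (Δ47) or 0.030‰ (Δ48) flag the
session.

**Aggregation and QC.**  Per sample: mean, SD (n−1), and 2 SE = 2·SD/√n
exactly; a single replicate reports undefined SD/SE.  Advisory QC: Δ49(raw)
outside the equilibrated-gas range flags contamination per replicate (flagged
replicates are excluded from sample means; a fully flagged sample is an
error); a significant Δ48–Δ49 Pearson correlation (α = 0.05) flags a sample;
Shapiro–Wilk W is reported per standard population.

## Synthetic sessions and what the tests show

The generator is the exact inverse of the correction chain: truth → drift →
inverse transfer → forward-modelled cycle intensities → injected negative
background, with Gaussian noise applied at the replicate δ/Δ level
(per-cycle shot noise exists as an option but is off by default — replicate
noise is what the pipeline sees, and it is much faster).  Default conditions:
three standards × 20 replicates interleaved with four unknowns × 8 replicates
over a 720 h session; replicate scatter 0.010‰ (Δ47) and 0.036‰ (Δ48)
matching the long-term standard statistics; background factors
(−0.988, −0.906, −0.648) on a −3 mV monitor against beam intensities set by a
resistor-ladder-like gain stack, sized so the induced Δ48 non-linearity slope
is of order −0.004 ‰/‰; transfer slopes (1.10, 1.15) and a linear drift ramp
of 0.008/0.025‰ per session.  Gas-family sessions inject the non-linearity
directly in Δ/δ space at the Δ-level record.  Everything injected is recorded
in a truth manifest.

What passing tests show: the pipeline is the exact inverse of its own forward
model at zero noise (machine precision), every injected distortion is
recoverable (scaling factors to 1e-3 noise-free; with full noise the
100-session mean recovery is unbiased within ±0.05, with per-session scatter
of ~0.03–0.08 depending on channel), and the reported 2 SE behaves as
designed: truth-in-2SE coverage of unknowns matches an independent
Monte-Carlo oracle of ≈ 0.86 — not 95%, because 2·SD_est/√n at n = 8 is
narrower than a true 95% interval and the session correction contributes a
small shared error.  What they do not show: real sessions have non-Gaussian
tails, correlated cycle noise, pressure-dependent backgrounds and
sample-specific matrix effects that the generator does not emulate; the
pipeline's statistical behaviour on real data must be judged from real
standards.

## Problem sizes

Test-suite simulations use 92-replicate sessions (seconds each), 100-session
recovery ensembles, 10⁴-draw Monte-Carlo intervals and 400-trial QC
calibrations; the acceptance script runs the nine-sample reference set with
2000-draw intervals.  All randomness flows through seeded generators, and
identical seeds reproduce identical outputs byte-for-byte.

## Known limitations

* The working gas is assumed stochastic; true working-gas clumping is
  absorbed into the transfer function rather than modelled.
* No Δ17O (¹⁷O excess) computation and no pressure-baseline model beyond the
  m/z 47.5 proxy.
* Kinetic displacement is geometric along a fixed slope; the package does not
  simulate the DIC reaction network, and the slopes are user parameters.
* The single-channel temperature of a strongly disequilibrium sample is a
  diagnostic, not a temperature; it is reported with an extrapolation warning
  when outside 0–40 °C.
* The drift model is a smoother, not a physical model; its window is a free
  parameter (default 48 h) and sessions with structure finer than the window
  will be under-corrected.
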