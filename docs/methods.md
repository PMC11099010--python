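# Methods

## The problem

Accelerator-based boron neutron capture therapy (AB-BNCT) systems that
produce neutrons with the `7Li(p,n)7Be` reaction use a solid lithium layer
as the target. Proton bombardment thins and damages that layer, so the
neutron flux per unit proton current falls with the cumulative proton
charge `m` delivered to the target — both slowly over the target's
lifetime and slightly (sub-percent) within a single ~1 h treatment.
Because clinical beam-on control integrates the proton current, a
prescription expressed as a proton charge will under-deliver neutron
fluence unless the decay is accounted for.

## The degradation model

Per target, the flux (measured as the saturated activity of an activated
gold foil, in Bq/mA/atom) is modelled empirically as

    F(m) = a · exp(−b · m) + c

with `a ≥ 0` the decaying amplitude, `b ≥ 0` the decay constant per mC,
and `c > 0` the asymptotic flux. The coefficients carry no nuclear-physics
meaning; they summarize one target's condition. The canonical charge unit
is the millicoulomb everywhere in this package (1 mAh = 3600 mC,
`MC_PER_MAH`); mixing mAh in the model with mC in prescriptions invites
silent factor-3600 errors, so conversion happens only at I/O boundaries.

The neutron fluence delivered between cumulative charges `d` and `e` is
the integral of F, available in closed form:

    NF(d, e) = (a/b) · (exp(−b d) − exp(−b e)) + c · (e − d)

Numerically the difference of exponentials is evaluated as
`−exp(−b d)·expm1(−b (e−d))`, which stays accurate for tiny `b·(e−d)`;
when `b·(e−d) < 1e−12` the limit `(a + c)(e − d)` is used outright. These
choices make the integral continuous in `b` at machine precision and agree
with adaptive quadrature to better than 1e−8 relative over physical
parameter ranges (asserted by tests).

## Fitting

`fit_flux_model` performs bounded trust-region-reflective least squares
(`scipy.optimize.least_squares`) on internally rescaled data (charges
divided by their maximum, fluxes by their median) so the optimizer works
at unit magnitude despite raw fluxes of ~1e−15. The starting point is
deterministic: `c₀` = smallest observed flux, `a₀` = first observation's
excess over `c₀`, `b₀` from a log-linear regression of
`log(flux − 0.99 c₀)` against charge, clamped to ≥ 0. When the series
carries per-point relative uncertainties, residuals are weighted by
`1/(rel_uncertainty · flux)` — the correct likelihood for multiplicative
noise, and noticeably stabler for short series. At least `n_min = 5`
points are required (3 coefficients plus 2 residual degrees of freedom);
shorter histories must fall back to the constant-flux prescription.
Non-convergence raises an error carrying diagnostics rather than
returning a silently bad model.

## Prescription and compensation

Planning assumes a constant planning flux and a tentative charge; their
exact product is the prescribed fluence NF (for the reference clinical
values 1.20e−15 Bq/mA/atom × 43.2e3 mC — 12 mA for one hour — NF =
5.184e−11 atom⁻¹, conventionally displayed as 5.18e−11). The compensated
prescription solves

    ∫_d^e F_pre(m) dm = NF

for the beam-on charge `e − d`, where `F_pre` is the tentative model
fitted to the measurements available before the treatment and `d` is the
charge already on the target. Since `F ≥ c > 0`, the solution exists, is
unique, and is bracketed by `[NF/F(d), NF/c]`; plain bisection on the
closed-form integral converges unconditionally and is run to 1e−12
relative on NF (robustness was preferred over speed; a treatment-planning
computation has no latency constraint). The naive comparator takes the
flux measured immediately before treatment as constant: charge = NF/flux.

Delivery is scored against a reference model fitted on the target's full
lifetime series: delivered fluence = reference integral over the solved
charge window, discrepancy = 100·(delivered − NF)/NF, positive meaning
over-delivery.

## Synthetic campaigns

Real lifetime measurement series for clinical Li targets are not publicly
available, so the generator emulates their statistical structure:

- 60 measurements per target (a full campaign has more than 55), at
  charges accumulated from increments uniform on (0, 86.4e3] mC — the
  protocol bound on inter-measurement charge;
- multiplicative Gaussian relative noise, sd 1.2% (truncated at ±4 sd).
  This matches the observed spread of naive constant-flux deliveries,
  into which a single measurement error propagates directly; an expanded
  single-measurement uncertainty of 2.6% can be configured instead;
- five lots with distinct coefficients: (a, c) jittered ±15% around a
  base of (1.08e−15, 0.12e−15) — fresh-target flux 1.20e−15, asymptote at
  10% of it — and decay constants calibrated per lot so the flux drop
  across one 43.2e3 mC treatment window is 0.66–0.74% (median 0.70%).
  Calibration is done at half the expected lifetime charge, which keeps
  the drop over *any* window in the target's life inside the 0.6–0.8%
  band observed clinically.

`calibrate_decay` inverts the window-drop equation for `b`. The drop is
not monotone in `b` when the window starts at positive charge (a very
fast decay is already exhausted there), so the root is taken on the
ascending branch below the argmax located by a log-spaced scan; drops
beyond the achievable maximum are a domain error.

What the generator does **not** emulate: correlated drift between
measurements, heteroscedastic uncertainty across a target's life, thermal
or current-dependent effects, and any deviation of the true curve from
the exponential-plus-constant form. Passing validation on these
synthetics therefore demonstrates the correctness and statistical
behaviour of the pipeline under the model's own assumptions, not the
clinical accuracy figures of any particular accelerator.

## Validation harness and statistics

Every measurement point of a series is treated as a treatment start. At
each point with at least 5 measurements of history the tentative model is
fitted to that history, both prescriptions are computed for the same NF,
and both are scored against the lifetime reference fit. Points with
insufficient history (or a failed tentative fit) are excluded from both
methods so the comparison stays paired.

Per target and method the harness reports median, min–max range, sample
SD (ddof = 1, NaN for a single value), and the fraction of deliveries
within 1% of NF. The test pipeline mirrors standard practice: Shapiro–
Wilk normality of the *paired differences* chooses between the paired
t-test and the Wilcoxon signed-rank test within a target; across targets,
Bartlett's variance-homogeneity test gates one-way ANOVA (p ≥ 0.05)
versus Kruskal–Wallis, run separately per method. All tests are
two-sided at α = 0.05. Degenerate inputs (identical pairs, constant
samples, < 3 values) are flagged NA instead of being forced through the
tests.

## Problem sizes and determinism

The default study conditions — 5 lots × 60 points, 1.2% noise — run the
full harness (≈550 nonlinear fits and 280 bisection solves) in a few
seconds. Property checks that pool over seeds use 20 independent
fixtures. All randomness flows from a single integer seed:
lot coefficients derive from the seed directly and campaign noise from
`seed·1000 + lot`, so every artifact (CSV, report, summary) is bitwise
reproducible.

## Known limitations

- The tentative model is fixed before each treatment and never refit
  mid-irradiation; with a 5-point history its prediction at the data edge
  has ~1% standard error, which dominates the compensated method's
  worst-case discrepancy early in a target's life.
- The exponential-plus-constant form is assumed exactly; model
  misspecification is not simulated or detected.
- No real-time hardware integration: the package computes prescriptions
  and retrospective scores only.
- Plotting of the per-target discrepancy distributions is left to the
  user; the report is plain text and the results CSV loads directly into
  pandas/matplotlib.
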