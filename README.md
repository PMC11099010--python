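# bnct-fluence

Compensatory neutron-fluence delivery for accelerator-based BNCT
(boron neutron capture therapy) systems with a solid-state lithium
target.

In `7Li(p,n)7Be` accelerator neutron sources the lithium layer degrades
under proton bombardment: the neutron flux per unit proton current falls
with the cumulative proton charge *m* on the target, slowly over the
target's lifetime and by ~0.7% within a single one-hour treatment. Beam
control integrates the proton current, so a prescription expressed as a
proton charge under-delivers neutron fluence unless the decay is
compensated. This package is for medical physicists working with such
systems: it fits the per-target degradation model, computes the beam-on
charge that delivers a prescribed fluence, and quantifies delivery
accuracy against the naive constant-flux prescription.

## Model and method

Per target the flux (gold-foil saturated activity, Bq/mA/atom) follows

```
F(m) = a · exp(−b m) + c ,        a, b ≥ 0,  c > 0
```

with `m` the cumulative proton charge in mC. The fluence delivered
between charges `d` and `e` is the closed-form integral of `F`. Planning
fixes the required fluence `NF = planning flux × tentative charge`; the
compensated prescription solves

```
∫_d^e F_pre(m) dm = NF        for the beam-on charge  e − d,
```

where `F_pre` is a tentative model fitted to the measurements available
before the treatment. The naive alternative uses the flux measured just
before treatment as a constant: charge = `NF / flux`. Deliveries are
scored retrospectively against a reference model fitted over the
target's whole lifetime, as a percent discrepancy from `NF`.

## Worked example

The clinical planning values — flux 1.20e−15 Bq/mA/atom, charge
43.2e3 mC (12 mA for one hour):

```
$ bnct-fluence plan
planning flux    : 1.2e-15 Bq/mA/atom
tentative charge : 43200 mC
required fluence : 5.18e-11 atom^-1
  (unrounded     : 5.184e-11)
```

A full validation on the default synthetic five-lot fixture (60
measurements per target, 1.2% relative measurement noise, decay
calibrated to a 0.6–0.8% flux loss per treatment window):

```
$ bnct-fluence validate --seed 1 --out-dir demo
Fluence delivery validation
  prescribed fluence NF = 5.184e-11 atom^-1 (planning flux 1.2e-15 Bq/mA/atom x 43200 mC)

  target   method            n  median%    min%    max%    sd%  |d|<=1%
  lot-1    compensated      56     0.01   -1.91    1.25   0.74    75.0%
  lot-1    constant_flux    56    -0.27   -3.11    2.07   1.10    60.7%
  lot-2    compensated      56    -0.08   -1.26    0.56   0.45    92.9%
  lot-2    constant_flux    56    -0.47   -3.45    1.28   1.01    64.3%
  ...
  Paired method comparison per target:
    lot-1: paired t-test, p = 0.342 (not significant; diff-normality p = 0.338)
    lot-2: paired t-test, p = 0.003 (significant; diff-normality p = 0.722)
  ...
```

Reading the table: at every measurement point of a target's life a
hypothetical treatment is started and both charging methods are scored.
Compensated deliveries stay within ~2.3% of the prescription here (within
1% in 75–96% of treatments), while the constant-flux method — which
ignores intra-treatment decay and inherits each single measurement's
error — drifts past −3% with per-target SDs of 1.0–1.2%. The statistics
block selects a paired t-test or Wilcoxon signed-rank per target from
Shapiro–Wilk normality of the paired differences, and gates the
across-target comparison (ANOVA vs Kruskal–Wallis) on Bartlett's test.

The same pipeline is available as a library:

```python
from bnct_fluence import (default_fixture, prescribe_fluence,
                          run_full_validation, format_report)

plan = prescribe_fluence(1.20e-15, 43.2e3)
series = [s for s, _ in default_fixture(seed=1)]
summary = run_full_validation(series, plan)
print(format_report(summary, plan))
```

Other commands: `bnct-fluence simulate` writes the synthetic fixture as
CSV with its ground-truth models; `bnct-fluence fit` fits lifetime
models for each target in a measurement CSV; all accept a YAML config
overridden by flags and log seed, config hash, and version per run.

## Documentation

`docs/methods.md` describes the model, the fitting and solver choices,
what the synthetic campaigns do and do not emulate, and known
limitations.
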