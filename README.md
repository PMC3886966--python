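# pparclock

Circadian analysis of hepatic PPARα mRNA as a tested, reusable pipeline.

Cross-sectional circadian studies — for example, rat offspring of lean vs
obese dams challenged with a high-fat diet, euthanized every 4 h over 24 h —
produce group-level rhythms of clock and metabolic transcripts.  `pparclock`
implements the full analysis such a study needs, end to end, with a
synthetic-data generator providing ground truth so every stage is testable
without any download:

* **qPCR quantification** — log-linear standard curves, reference-gene
  normalization, ChIP-qPCR percent-of-input enrichment.
* **Rhythm statistics** — 24-h trapezoidal AUC on group means with
  delta-method SEs, per-timepoint t tests, 2 × 2 factorial ANOVA (Type II)
  with Student–Newman–Keuls letter groupings.
* **Kinetic modeling** — an 8-parameter clock-forced ODE for relative
  PPARα mRNA X(t),

      dX/dt = v0 + v_p·B(t)ⁿ/(K_pⁿ + B(t)ⁿ) − v_d·X/(K_d + X) − δ_p·X,

  driven by a 24-h-periodic BMAL1 signal B(t) (empirical spline through
  measured means, or an entrained Goodwin-type oscillator).
* **Estimation** — Monte Carlo search (default 10,000 draws) followed by
  Polak–Ribière conjugate-gradient refinement, on group-mean curves.
* **Global sensitivity** — Latin-hypercube sampling with partial rank
  correlation coefficients (PRCC) at the light/dark switch points (6 AM,
  6 PM), with a built-in dummy-parameter null control.
* **Synthetic data** — cosinor datasets and clock-forced kinetic scenarios
  (including a stepwise increase in the non-specific degradation rate δ_p
  across the four groups) with full seed determinism.

See `docs/methods.md` for the model, assumptions and numerical choices.

## Worked example

`examples/` holds one short script per capability.  Closed-loop kinetic
fitting (`examples/02_fit_group_kinetics.py`) generates a dataset whose four
groups differ in v_p (reduced by maternal obesity) and δ_p (rising stepwise
toward obese-HFD), then re-estimates each group:

```
group             v_p fit  v_p true  d_p fit  d_p true  rss
lean-control      0.733     1.000    0.051     0.100  2.71e-02
lean-HFD          1.477     1.000    0.179     0.150  3.92e-03
obese-control     0.645     0.700    0.158     0.220  3.00e-03
obese-HFD         0.726     0.700    0.289     0.320  3.04e-04
```

The fitted curves match the data essentially to the noise floor, but with
six cross-sectional means against eight parameters the individual rate
estimates are only weakly identified — typical relative errors are ~15%
even inside informative search boxes, and the stepwise δ_p ordering is
recovered in roughly two-thirds of replicate datasets (see the identifiability
discussion in `docs/methods.md`).

PRCC sensitivity (`examples/03_prcc_sensitivity.py`) on the entrained model
under ±50% parameter uncertainty singles out the maximal synthesis rate
v_p (PRCC ≈ +0.92), the BMAL1 activation constant K_p (≈ −0.92) and the
non-specific degradation rate δ_p (≈ −0.92) as the dominant parameters at
both 6 AM and 6 PM, while the dummy control parameter stays null
(|PRCC| < 0.03, p ≈ 0.5).

The AUC/ANOVA example (`examples/04_auc_table_and_stats.py`) prints a
Table-style summary — per-group 24-h AUC ± SE with letter groupings — and
detects the generated obese-HFD-only suppression as a maternal × diet
interaction (the suppressed group receives its own letter `b`).

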