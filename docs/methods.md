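# Methods

Model assumptions, calibration parameters, generator scope, numerical
conventions, and limitations of the `ventpower` package.

## Index derivation

All indexes are derived per ventilator observation and aggregated per
patient by the median (derive-then-aggregate order; configurable via
`AnalysisConfig.aggregate_before_derive`).

- Dynamic driving pressure `dp_aw = ppeak − peep` (cmH2O). Records with
  `ppeak ≤ peep` are invalid.
- Dynamic lung-thorax compliance `ltc_dyn = vt_ml / dp_aw` (mL/cmH2O).
- P/F ratio `pao2 / fio2` (mmHg).
- Mechanical power, simplified pressure-controlled formula
  `mp = 0.098 · rr · vt_L · ppeak` (J/min). The constant 0.098 converts
  cmH2O·L to J. The simplified formula intentionally uses Ppeak rather
  than the full Gattinoni decomposition; it is an upper-envelope surrogate
  appropriate for pressure-controlled modes.
- PBW-normalised power `pbw_mp = mp / pbw` (J/min/kg), with Devine
  predicted body weight `50 + 0.91·(height_cm − 152.4)` for males and
  `45.5 + 0.91·(height_cm − 152.4)` for females.
- Power density `ltcdyn_mp = rr · ppeak · dp_aw` (cmH2O²/min). Algebraic
  identity: `ltcdyn_mp = mp / (0.098 · ltc_dyn/1000)`; both routes agree to
  1e-9 relative (property-tested), and the quantity is invariant to tidal
  volume at fixed pressures.
- Ventilatory ratio `vr = VE_ml/min · paco2 / (pbw · 100 · 37.5)`, using
  the measured minute ventilation when present, else `rr · vt_ml`.

## Outcome accounting

- **Total invasive duration** is the sum of all invasive episodes
  (endotracheal and tracheostomy), not wall-clock span; overlapping
  episodes are an invariant violation.
- **PMV** is strictly greater than 72 h (equality is negative). 96 h and
  7-day labels are computed alongside for sensitivity analyses.
- **Weaning scenarios**: 1 — extubation without reintubation or
  tracheostomy; 2 — reintubation followed by final extubation; 3 —
  tracheostomy after a failed extubation; 4 — primary tracheostomy (no
  preceding extubation attempt). Courses matching none are rejected.
- **Early non-invasive support (NIRS)**: any session starting within 24 h
  of the *first* extubation with ≥6 h daily use.
- **Observation window**: pressure-controlled records with
  `t ≤ min(36 h, first extubation)`, boundary inclusive.
- **Time-quartile trajectories**: each patient's windowed records are split
  into four equal-count time quartiles (patients with <4 records are
  excluded); group-level curves take medians per quartile.

## Statistics

- Spearman rho uses mid-ranks; its CI back-transforms
  `atanh(rho) ± z_{0.975}/√(n−3)` (Fisher z). Constant inputs are
  rejected.
- AUROC is the Mann–Whitney estimator (ties count ½) with the
  Hanley–McNeil variance for the CI, clipped to [0, 1].
- Youden thresholds scan midpoints of adjacent sorted unique scores plus
  ±∞ under the rule "positive if oriented score ≥ t"; ties in J resolve to
  the smallest threshold. Orientation per index is fixed a priori
  (`DEFAULT_ORIENTATION`): higher is positive for pressures, powers and
  VR; lower for P/F and compliance.
- Diagnostic panel: sensitivity, specificity, PPV, NPV, accuracy, PLR,
  NLR, DOR, F1, MCC; 0/0 forms are reported as 0 and flagged.
- Repeated CV: 2×5 label-stratified folds; the threshold is learned on
  each training fold (Youden) and all metrics are measured on the held-out
  fold; fold-mean metrics carry t-based 95% CIs; the reported threshold is
  the mean training threshold in original index units.
- Group comparisons: exact Mann–Whitney null for both groups ≤8 without
  ties, tie-corrected normal approximation otherwise; chi-square (no
  continuity correction) and Fisher exact for 2×2 tables.
- Logistic regression: forward selection by likelihood-ratio entry tests
  at α=0.05 (statsmodels `Logit`), Hosmer–Lemeshow over risk deciles,
  Nagelkerke R² from model/null deviances, odds ratios optionally per
  clinically meaningful unit.
- Mixed ANOVA: two-way split-plot sums-of-squares decomposition (between:
  group; within: time quartile), group-size weighted, requiring a complete
  within-factor; no sphericity correction is applied.

## Synthetic cohort generator

Defaults are study conditions and are frozen in `simulate.py`.

- **Quartile matching**: a log-normal is fitted to a printed
  (median, q1, q3) by `mu = ln(median)`,
  `sigma = ln(q3/q1) / (2·z_{0.75})` with `z_{0.75} ≈ 0.67449`. The
  quartile *ratio* is matched exactly; individual quartiles are matched
  exactly only when log-symmetric.
- **Durations** are drawn from *truncated* log-normals: the PMV parent is
  left-truncated at 72 h, the non-PMV parent right-truncated. Parents are
  calibrated numerically (grid plus bounded refinement over sigma, brentq
  on a standardised location parameter) so the *conditional* median equals
  the printed group median exactly (189 h / 32 h) and the conditional
  quartiles fit in least squares. The PMV upper quartile is not exactly
  attainable within a two-parameter family (fitted ≈452 h vs printed
  666 h); the median constraint takes precedence. Sampling is by inverse
  CDF, so every draw respects the 72 h boundary and labels recomputed from
  episodes always agree with the drawn group.
- **Conditional independence**: within a group, indexes and durations are
  independent; pooled correlations arise purely from the two-group
  mixture. For a binary mixture this predicts
  `rho ≈ 12·p·(1−p)·(A_X−½)·(A_Y−½)` where A are the single-index
  AUROCs — consistent with the published pooled correlations.
- **Event tree** (per group): primary tracheostomy, reintubation,
  tracheostomy-after-reintubation, and early-NIRS probabilities are
  reconciled from published marginal counts (e.g. 25/82 primary
  tracheostomies and 22/57 reintubations among PMV patients; 2/155
  reintubations otherwise). Episode splits and reintubation gaps are drawn
  from fitted log-normals.
- **Record-level mode** samples per-patient latents (RR, ΔPaw, PEEP,
  compliance, FiO2, PaO2, PaCO2) from the printed raw-variable summaries,
  derives `vt = ltc·dp` and `ppeak = peep + dp`, and emits 8 records over
  the observation window with a 5%-per-quartile multiplicative decline on
  ΔPaw and RR (median-normalised so the patient median is unaffected).
  Because medians of derived products are not products of medians, the RR
  and compliance latents carry small multiplicative corrections
  (`RECORD_LEVEL_SCALES`, e.g. 0.9807/0.9668 in the PMV group) tuned once
  against a large oracle run of the full generator-plus-index pipeline and
  frozen; the emergent per-patient medians of mechanical power and power
  density then match the calibration targets within 1%.
- The trajectory decline magnitude is configurable and excluded from
  acceptance targets: reported trajectories decline over time but no
  published magnitude exists to calibrate against.

## Numerical conventions

- All randomness flows through `numpy.random.default_rng(seed)`; derived
  seeds are taken from `SeedSequence` state reduced mod 2³¹.
- `metrics.json` is written with sorted keys and fixed indentation; a
  fixed seed reproduces the report bundle byte-for-byte.
- CSV ingestion validates schema (missing columns are named; unparsable
  cells report the row) and drops invariant-violating rows while counting
  them per table; eligibility exclusions are tallied first-match in a
  fixed flag order.

## Limitations

- The generator reproduces group-level summaries, not patient-level joint
  structure; within-group index–duration dependence is assumed away, so
  pooled correlations are mixture-induced lower-bound checks.
- The simplified power formula omits the resistive/elastic decomposition;
  absolute power values are comparable only within the same formula.
- The truncated-duration family cannot reproduce the full printed IQR of
  the PMV group (see above); downstream targets depend on the median only.
- The mixed ANOVA reports unadjusted degrees of freedom (no
  Greenhouse–Geisser correction) and requires complete quartile panels.
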