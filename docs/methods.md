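# Methods

`dwscreen` implements a harmonized cumulative screening analysis of
drinking-water contaminant mixtures across three supply chains —
private-well tapwater, public-supply tapwater, and bottled water — with
three complementary effect-weighted mixture metrics, a permutation test
for group differences, and a synthetic-scenario generator with analytic
ground truth.

## Hazard-index screening (TQ, ∑TQ)

For each detected analyte the toxicity quotient is

    TQ = C / B_eff

with C the detected concentration (μg/L) and B_eff the *most protective*
(lowest-valued) available human-health drinking-water benchmark among
MCLG, MCL, SOQ, DWHA, WHO guideline, state level, HBSL and HHBP.  Equal
minima break deterministically by type priority (MCLG > MCL > SOQ >
DWHA > WHO > STATE > HBSL > HHBP); the last six of that order follow
the protectiveness hierarchy, with MCL/SOQ slotted after MCLG because
they are the enforceable analogues of the goal value.

MCLGs of zero (set for carcinogens with no safe dose) cannot be TQ
denominators.  They are replaced by configurable substitution values:
0.1 μg/L for the inorganic-metal, DBP and VOC classes and 0.0001 μg/L
for PFOS/PFOA (per-analyte overrides).  Substitution rules are
configuration, keyed by class with analyte overrides, so the
harmonization is auditable; a selected zero MCLG without a rule is a
configuration error, not a silent drop.

Per sample, quotients combine under the non-interactive
concentration-addition model: ∑TQ = Σᵢ TQᵢ over detections with
TQ ≥ 1e-5 (the assessment-inclusion screen, applied per detection with
a per-analyte roll-up available in coverage reports).  Non-detects
contribute exactly zero — no reporting-limit imputation — but are
carried as rows so coverage can count assessed-but-undetected analytes.
∑TQ is compared against 0.1 (screening level of concern) and 1
(elevated risk), both strict `>`; individual regulatory comparisons
(MCL/SOQ) use strict `>` too, except that a zero MCLG is exceeded by
any detection.

## Bioactivity screening (EAR, ∑EAR)

The exposure–activity ratio replaces the apical benchmark with an in
vitro activity concentration at cutoff (ACC): EAR = C / ACC (both in
μg/L; μM values convert by ACC[μg/L] = ACC[μM] × MW[g/mol]).  Endpoints
flagged non-specific, baseline, or unreliable-curve are excluded before
any ratio is formed; the flags arrive precomputed in the ACC table.
Only organic analyte classes are screened.

Chemical-level aggregation defaults to the **maximum EAR across
retained endpoints**, then sums across chemicals to ∑EAR.  Because the
convention is not uniquely fixed in the screening literature, an
endpoint-wise alternative is provided (`aggregation="per_endpoint"`:
sum within endpoint across chemicals, report the maximum endpoint sum);
the choice in effect is recorded in the run manifest.  Thresholds:
∑EAR = 0.001 (potential concern; calibrated in the screening literature
as roughly equivalent to TQ = 0.1) and 1 (elevated probability of
molecular effects); chemical EARs below 1e-5 are screened out.  With a
single chemical and single endpoint, ∑EAR is structurally identical to
∑TQ computed with the ACC as benchmark — a property the tests exploit.

## Toxicokinetically adjusted screening (MED, Css₉₅, AED₉₅, ∑EAR-MED)

The EAR above assumes the water concentration approximates the
concentration at the molecular target.  The adjusted metric instead
maps both sides onto an administered-dose scale:

* **MED** (mg/kg/d) = C[μg/L] × 0.2 L/kg/d × 0.001 mg/μg, using the
  conservative birth-to-<1-month ingestion rate of 0.2 L of water per
  kg body weight per day.  (Source texts sometimes print this rate with
  a mass unit; the equation's 0.2 L/kg/d is what is implemented.)
* **Css** per unit dose from the three-compartment steady-state model
  with restrictive (unbound-fraction-scaled), well-stirred hepatic
  clearance and renal clearance by glomerular filtration:

      CLint,whole [L/h] = CLint [μL/min/10⁶ cells] × hepatocellularity
                           [10⁶ cells/g] × liver mass [g] × 60 × 1e-6
      CL_h = Q_liver · f_up · CLint,whole / (Q_liver + f_up · CLint,whole)
      CL_r = GFR · f_up
      Css [mg/L] = (dose · BW / 24) / (CL_h + CL_r);  μM = Css / MW × 1000

  Default physiology (configurable): 70 kg body weight, 90 L/h liver
  blood flow, 6.7 L/h GFR, 110×10⁶ hepatocytes/g liver, 1820 g liver —
  conventional adult reference values.  100 % oral bioavailability; no
  absorption or multi-tissue model.  Useful closed-form limits:
  CLint = 0 gives Css = dose_rate/(GFR·f_up); CLint → ∞ with f_up = 1
  gives Css = dose_rate/(GFR + Q_liver).
* **Css₉₅**: Monte Carlo over intrinsic clearance, fraction unbound,
  liver blood flow and GFR, each drawn from a normal with CV 0.3
  (default, configurable) about its central value, truncated at zero
  (f_up additionally clipped to (0,1]); the 95th percentile of the Css
  draws.  The distributions-and-CV choice is a transparent default —
  the varied parameters are fixed, their distributions were an open
  design choice.  Per-chemical seeds derive from the run seed and the
  chemical's alphabetical rank, so results are independent of table
  order.
* **AED₉₅** (mg/kg/d) = ACC[μM] / Css₉₅[μM per mg/kg/d]; per chemical
  the **5th percentile of AED₉₅ across endpoints** is the floor.  (The
  conventional AED₉₅ label names the Css quantile; the resulting dose
  is a low, population-protective value.)
* **EAR_MED** = MED / AED-floor, summed per sample to ∑EAR-MED with
  thresholds 0.001 / 1 and inclusion screen 1e-5.

Chemicals missing molecular weight, fraction unbound or intrinsic
clearance are excluded from ∑EAR-MED and counted, with a reason, in the
coverage table.  A chemical whose total clearance is zero is reported
as non-computable rather than given an infinite Css.

Both the 95th (Css) and 5th (AED floor) percentiles — and every
quantile in group summaries — use linear interpolation between order
statistics, stated here because quantile conventions change results.

## PERMANOVA

Group differences in per-sample metrics are tested by one-way
permutational multivariate ANOVA on Euclidean distances:

    SS_total  = (1/N) Σ_{i<j} d²ᵢⱼ
    SS_within = Σ_g (1/n_g) Σ_{i<j∈g} d²ᵢⱼ
    F = (SS_among/(a−1)) / (SS_within/(N−a))

with p = (1 + #{F_perm ≥ F_obs}) / (1 + m) over m seeded random label
permutations (default m = 9999).  Add-one smoothing guarantees p > 0;
the observed labelling is not re-counted among the random draws.  An
exact mode enumerates all distinct labelings of the group-size multiset
(feasible N ≲ 10) and serves as the oracle in tests.  Degenerate
conventions: all-identical points give p = 1; perfectly separated
groups give F = +∞ with p still from permutation counts.  Metrics are
compared on the raw scale by default; a log10(x+ε) option exists for
heavily skewed quotients but no claim is made that either choice
reproduces any particular published p-value.

## Synthetic scenarios and what they do (not) show

The generator draws, per sample × analyte, Bernoulli presence with
probability p, then a lognormal concentration (ln-scale mean/sd),
left-censored at the analyte's reporting limit: sub-limit draws become
non-detect rows.  This is the minimal right-skewed, censorable model
consistent with trace-contaminant data spanning orders of magnitude; it
encodes no spatial/temporal correlation, no inter-analyte correlation,
no study-to-study reporting-limit variation (a per-study option exists
in the data model), and no measurement error.  Ground truth records the
analytic detection frequency p·(1 − Φ((ln RL − μ)/σ)) and the analytic
single-analyte exceedance p·(1 − Φ((ln B_eff − μ)/σ)).

`paper_like_scenario()` packages three supplies at 98/126/30 samples
with 18 analytes whose qualitative structure follows the field's
occurrence patterns — DBP concentrated in public tapwater and
tapwater-sourced bottled brands, geogenic metals enriched in private
wells and spring-sourced bottled water, PFAS confined to tapwater,
plus a microbial pass-through row that is carried but never screened.
All numeric rates are synthetic round numbers chosen once for
qualitative realism.  Passing tests on these scenarios demonstrate the
*computational* correctness of the screening chain (sums, substitution,
censoring, recovery of analytic exceedance probabilities), not any
statement about real exposure data.

Problem sizes used in tests and in the acceptance script — 254-sample
scenarios, a 2000-sample single-driver recovery check, 9999
permutations, Monte Carlo toxicokinetics at 300–5000 draws — were
chosen as the smallest sizes at which the stochastic checks are stable
at 3-standard-error tolerances.

## Design choices that were genuinely open

* Per-detection (not per-analyte) application of the 1e-5 inclusion
  screen, with per-analyte roll-ups in coverage, because the screening
  sentence admits both readings.
* Max-endpoint chemical aggregation for ∑EAR (alternative provided).
* Add-one-smoothed permutation p (the desktop statistics programs the
  field uses do not document their convention).
* Non-detects carried as rows rather than dropped; microbial rows
  pass through unscreened.
* Analyte identity keys on CAS where available, otherwise a stable
  slug; duplicate ids are an input error.
* Configuration surface: zero-MCLG substitution values travel as a
  YAML file (`substitutions.yaml`) because they are data-like and
  shared between CLI runs; physiology and Monte Carlo variability are
  plain dataclass parameters (`Physiology`, `VariabilitySpec`) on the
  pipeline config, since they are code-level knobs with validated
  defaults.

## Known limitations

Single-route (oral) exposure only; one ingestion-rate constant rather
than age-resolved physiology; no concentration–response curve fitting
(ACC values and reliability flags are inputs); no relative-potency
mixture models beyond concentration addition; benchmarks and ACC tables
are user-supplied configuration, not a packaged chemical database.
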