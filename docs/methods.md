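# Methods

## Growth-chart model and inversion

A growth chart is a strictly monotone table of gestational age (GA, days
since last menstrual period) against the median of one biometry measurement
in mm. Forward evaluation uses shape-preserving monotone cubic
interpolation (PCHIP), which is exact at the knots and cannot introduce
spurious non-monotonicity between them. The ultrasound gestational age of a
measurement is the unique GA whose median equals it, found by bisection on
the forward curve to 1e-3 day — roughly three orders of magnitude below any
clinical resolution; bisection (rather than a derivative method) is used
because charts are tabulated, not analytic. Measurements outside a chart's
value range are *flagged* unconvertible and excluded from ratio analyses
with a logged count, never silently dropped.

The shipped default charts are synthetic: smooth monotone quadratics in
gestational weeks with magnitudes typical of second/third-trimester BPD, AC
and FL, tabulated at weekly knots over 14–43 weeks. They are deliberately
not any published chart — all quantitative claims the package tests are
chart-agnostic (round-trip and monotonicity properties), and real charts
drop in as two-column CSVs (`ga_days,median_mm`). The same applies to the
sex- and GA-week-specific 90th-percentile birth-weight table used for LGA
labelling: a synthetic concave median curve (SD 330 g, +55 g male shift),
replaceable by any `ga_week,sex,p90_g` CSV.

Estimated fetal weight defaults to the Japanese ultrasound polynomial
`EFW = 1.07·BPD³ + 0.30·AC²·FL` (inputs cm, output g); both coefficients
are configuration keys (`efw.coef_bpd3`, `efw.coef_ac2fl`) because
published variants differ in the third decimal.

## Screening cascade and cohort definition

Classification follows the two-step screen: GCT < 140 mg/dL is
screen-negative NGT with no OGTT expected; GCT ≥ 140 without an OGTT is
unclassifiable; otherwise the number of OGTT values at or above the
Carpenter–Coustan thresholds (defaults 95/180/155/140 mg/dL, inclusive,
configurable) maps 0 → NGT, 1 → one-value abnormality, ≥ 2 → GDM. The
exclusion cascade removes, in order: hypertension before 24 GW, missing
maternal weight, missing GCT, the three non-NGT glycemic classes, and
delivery elsewhere. The stage log telescopes by construction (each stage's
input equals the previous stage's survivors), which makes the published
flow arithmetic — 7820 screened → 6888 NGT → 6721 included — a pure
bookkeeping check that the test suite runs through the real cascade code.

Age × BMI strata use inclusive boundaries at 35 years and 25 kg/m²
(G1 young/non-obese … G4 older/obese). HOMA indices use the HOMA1 closed
forms (`G·I/405`, `360·I/(G−63)`); HOMA-β is reported missing when fasting
glucose ≤ 63 mg/dL makes the denominator non-positive, while HOMA-IR is
still returned. All analyses are complete-case with per-cell denominators
recorded in the report, since real chart-review cohorts have cell
denominators smaller than group sizes.

## FAO classification

The three ratios are scale-invariant (days and decimal weeks give the same
value). Empirical thresholds use the linear-interpolation-between-order-
statistics quantile — one specific, documented convention, chosen because
it makes self-classification exact: on continuous data the flagged fraction
at level 0.90 is 10% to within 1/n. At least 10 finite ratios are required
per threshold; non-finite values are dropped with a count. Fixed cutoffs
(1.080 / 1.071 / 1.069) ship for classifying external records without a
reference cohort. The headline FAO flag defaults to the GA-AC/GA-LMP
criterion (`fao.headline`, options per-ratio or union); near-term ratios
are classified against the mid-gestation thresholds by default
(`fao.rederive_near_term` re-derives them instead) because persistence of
the *same* cutoff is the clinically interpretable contrast.

## Statistics

Two-sample comparisons default to Welch's t (robust to the highly unequal
stratum sizes and variances such cohorts show; pooled available by flag).
Proportions use the pooled two-sided z-test with an unpooled Wald CI on the
difference. Pairwise stratum comparisons are Bonferroni-corrected with
family size 6 (all pairs of four groups). Crude odds ratios are the 2×2
cross-product with Woolf (log-scale Wald) 95% CIs and the Haldane–Anscombe
+0.5 correction, flagged, when any cell is zero. Adjusted odds ratios come
from maximum-likelihood logistic fits with Wald CIs; separation is detected
(non-convergence or |coefficient| > 15) and flagged with no estimate rather
than reporting a divergent number. The default adjustment set is {maternal
age, pre-pregnancy BMI, weight gain to diagnosis, GCT glucose} minus
whichever variables define the exposure — for the age × BMI strata that
leaves weight gain and GCT glucose; the resolved set is echoed in each
report block. Significance level 0.05, two-sided, throughout.

## Synthetic cohort generator

The generator's defaults are the study conditions the package assumes: four
strata mixed at (0.63, 0.03, 0.31, 0.03); per-stratum truncated-normal age
(31.0/31.2/37.2/37.5 ± ~2.3 y), BMI (20.0/27.5/20.5/27.4 ± ~2 kg/m²), GCT
glucose (109.9–118.9 ± ~21 mg/dL) and weight gains. The mid-gestation
GA-AC/GA-LMP ratio follows a planted linear model (intercept 0.9489;
slopes 0.0010/y age, 0.0015 per kg/m² BMI, 0.0008/kg gain, 0.00008 per
mg/dL GCT; residual SD 0.036), giving a population mean near 1.028 and SD
near 0.040 at the default covariate mix. The abdomen is measured by
evaluating the AC chart at GA-LMP × ratio — an overgrown abdomen "reads"
older — while BPD and FL are evaluated at GA-LMP; all three get additive
Gaussian measurement noise (2 mm), the simplest model sufficient to
exercise the inversion path. Scan timing is uniform over 24–28 weeks
(near-term: 36–38 weeks, with 70% persistence of the overgrowth signal).

Outcomes are drawn from logistic links on stratum and latent FAO status
(the planted ratio's top decile): default per-stratum odds ratios
(1, 3.0, 1.5, 2.8) for LGA, (1, 2.5, 0.95, 1.05) for macrosomia,
(1, 1.3, 1.35, 1.3) for primary cesarean, with FAO odds ratios 4.0/4.0/1.35
and baseline rates 3.5%/1.4%/19%. LGA and macrosomia are drawn with a
comonotone coupling (macrosomia ⊂ LGA), so a single birth weight can
satisfy both labels exactly against the p90 reference; both marginal odds
ratios still equal the configured links. Delivery GA is truncated at 40
weeks 6 days so the p90 reference never exceeds the 4-kg macrosomia cutoff,
keeping labels and planted flags perfectly consistent. Exclusion conditions
are planted at rates matching the reference flow (PIH 0.32%, missing weight
0.36%, missing GCT 2.5%, delivered elsewhere 2.4%; of GCT-positives, 3.8%
no OGTT, 31% GDM, 20% one-value); 76% of records carry mid-gestation
biometry.

What the generator does *not* emulate: longitudinal growth between the two
scans, twin pregnancies, sex-linked overgrowth, heavier-tailed biometry
error, treatment effects, or informative missingness (all missingness is
random). Passing pipeline tests therefore demonstrate correctness of the
estimation machinery under these idealised conditions, not robustness to
real-world measurement pathologies.

## Parameter-recovery checks

The recovery harness runs the complete chain (generation → cascade → GA
estimation → thresholds → labels → logistic fits) and asks whether each
planted per-stratum odds ratio lies inside its fitted 95% CI, adjusting for
the *pipeline's own* FAO flag — the latent flag is deliberately absent from
the cohort schema, and the ~3% misclassification of the observed flag was
measured to introduce no detectable bias (mean log-error ≈ 0 over 20
replicates of n = 20000). With nominal 95% coverage, demanding ≥ 18/20
coverage separately for each of nine odds ratios would fail about half the
time under a perfectly unbiased pipeline, so the check asserts aggregate
coverage ≥ 90% across all nine planted odds ratios plus an 80% per-OR
floor — a formulation whose false-alarm probability is below 1%.

Problem sizes used by the default test run and the acceptance script:
20 replicates of n = 20000 for recovery, 2000 null replicates for the
proportion-test type-I error, n = 5000 for quantile-classifier
calibration, 500 points per chart for round-trip error.

## Known data notes and limitations

- In the motivating cohort report, the running text gives primary-cesarean
  prevalences of 24.7% vs 19.8% while its table prints 25.7/20.9; the
  package follows table-style numerator/denominator cells, which are
  self-consistent.
- The same report splits the biometry cohort as 4637/492 in the text but
  4608/489 in its FAO table (totals 5129 vs 5097); the package always
  reports its own internally consistent counts with explicit denominators.
- Empirical thresholds depend on the quantile convention; with n ≈ 5000 the
  difference between conventions is far below the fourth decimal, but the
  convention is still pinned and tested against a brute-force oracle.
- The logistic CIs are Wald intervals; profile-likelihood intervals would
  differ for very sparse cells (those are flagged by the Haldane/separation
  paths instead).
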