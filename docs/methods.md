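# Methods

## Gating model

The cascade is a fixed composition of per-event predicates; it is
deterministic and independent of event order.

| step | rule | default |
|---|---|---|
| singlets | deviation of FSC-A/FSC-H from 1 ≤ bound; FSC-H = 0 excluded | 0.30 |
| non-debris | FSC-A ≥ min and SSC-A ≥ min | 15 000 / 10 |
| CD45⁺ | CD45 ≥ cutoff (transformed units) | 1.0 |
| P/M, lymphocytes | polygon membership in (CD45, SSC-A) | rectangles |
| myP/M | CD13 ≥ cutoff **or** CD33 ≥ cutoff | 1.5 / 1.5 |
| backbone | CD34/CD117/HLA-DR each ≥ cutoff → 8 combinations | 1.5 each |
| categories | CD13 < cutoff; CD33 < cutoff; CD7 ≥ strong; CD56 ≥ strong | 1.5 / 1.5 / 2.5 / 2.5 |

Conventions the underlying workflow leaves open, fixed here for
determinism: all threshold comparisons are inclusive (≥ counts as
positive), polygon boundaries are inside (closed regions), and deficiency
reuses the positivity cutoffs while cross-lineage aberrancy uses separate,
higher "strong" cutoffs — deficiency means true absence, cross-lineage
means strong expression.

Two structural consequences are asserted as invariants throughout the test
suite: the 8 backbone labels partition myP/M, and the category pair
{CD13⁻, CD33⁻} is unreachable for myP/M events (it contradicts the OR
gate).

**Scale.** Fixed thresholds only make sense on a stable display scale.
Fluorescence intensities are mapped by asinh(x / cofactor) (cofactor 150
per marker by default, configurable); scatter stays linear.  Data already
generated on the transformed scale (the simulator's output) uses the
identity transform.  A logicle option was considered and dropped: asinh
provides the required monotone, near-linear-at-zero behaviour with one
parameter per marker, and the fixed thresholds are calibrated to it.
The actual cutoff values are laboratory- and instrument-specific; the
defaults here (positivity 1.5, strong 2.5, CD45 1.0 on the asinh scale)
are placed so that the canonical internal controls — CD45-bright/SSC-low
lymphocytes, CD7-strong T cells — fall on the intended sides, which is
also how fixed gates are positioned in practice (from control
measurements, never from the leukemic population itself).

## Reference values

Per subpopulation, the reference value is the one-sided upper 97.5% limit
of the %CD45⁺ frequencies across leukemia-free controls, estimated
nonparametrically (`numpy.quantile`, linear interpolation between order
statistics; the method string is configurable and recorded in the panel).
Parametric (Gaussian) limits were rejected because the frequencies are
zero-inflated and heavily skewed.  Each value is attributed to the control
subcohort of the quantile-determining order statistic — the sample with
the smallest frequency at or above the interpolated quantile — with exact
cross-cohort ties broken lexicographically and flagged.  Panels are
serialized to standalone JSON (with method, n, and per-subpopulation
attribution) so that clinical calling never silently recomputes them; a
SHA-256 of the panel content is embedded in every report.

**Detectability.** The ≥20-event minimum couples sensitivity to
acquisition depth: a subpopulation at reference r (% of CD45⁺) needs
ceil(20/(r/100)) CD45⁺ events, i.e. 2,000,000 for r = 0.001%.  The
`detectability` function flags subpopulations that cannot be reliably
evaluated at a given acquisition.

## MRD calling

Positivity is strict exceedance (pct > reference) after dropping
subpopulations with fewer than `min_events` (default 20) events.  Burdens
(pct − reference, percentage points of CD45⁺) are summed within each
aberrant category; the maximum sum is the MRD load and its category the
load category (ties resolved in the fixed order CD13⁻ < CD33⁻ < CD7⁺ <
CD56⁺ and flagged).  Origin: a positive category present in the diagnostic
aLAIP set (≥10% of myP/M by default; 5/2.5/1% supported) is a
reoccurrence, otherwise ptDfN; samples without a diagnostic measurement
are reported as such.  A follow-up in which every aberrant subpopulation
falls under the event minimum is negative, with the dropped
subpopulations listed for audit.

Alternative schemes share the ≥20-event rule (configurable): the
ELN-style call restricts to the 24 immature subpopulations at a flat,
inclusive 0.1% of CD45⁺; the ImmOnly call applies the reference scheme to
those 24 (so ImmOnly-positive implies full-scheme positive); the Lo/Hi
split classifies a positive sample as Hi when any single subpopulation's
excess is ≥ 0.1 percentage points (the per-subpopulation reading of the
split; an aggregated-load reading would differ only when several small
excesses share a category).

## Inter-rater reliability

Krippendorff's α = 1 − D_o/D_e in the coincidence-matrix formulation,
with nominal (0/1), interval (squared difference) and ratio (squared
relative difference) metrics; missing ratings are allowed and units with
fewer than two ratings are excluded.  Percentages of CD45⁺ are ratio-scale
quantities, so the ratio metric is the default recommendation for
parameter (I)-style analyses, with interval exposed as an option.  When
every pairable value is identical, D_e = 0 and α is defined as 1.
Confidence intervals are out of scope.  The implementation is verified in
the tests against an independent brute-force pairwise oracle, exhaustively
over all two-rater nominal matrices with up to 6 units over 3 categories
(reduced to canonical within-unit pair multisets, which α provably
depends on).

## Synthetic marrow

The generator emulates what the panel sees in leukemia-free and AML
marrow, not marrow biology: each constituent population (T/B lymphocytes,
monocytes, granulocytes, CD34⁺ progenitors, CD45⁻ cells, debris,
doublets) is a product of independent truncated normals per marker on the
transformed scale.  Truncation enforces a guard band (default 0.05
transformed units; 5 for SSC, 500 for FSC) around every fixed threshold
and around the bounding box of the CD45/SSC regions, so no borderline
events exist and the generator's bookkeeping equals pipeline tabulation
*exactly* — this is what licenses its use as a gating oracle.  A zero
guard band re-introduces borderline events for robustness work.  The
guard-box construction is exact for the default rectangular P/M and
lymphocyte regions; non-rectangular user gates require manually placed
population specs.

Defaults per sample: 500,000 events (the targeted acquisition), 2%
doublets, 3% debris, 5% CD45⁻; the CD45⁺ pool is granulocyte-dominant
(56% granulocytes, 28% lymphocytes of which ~40% CD7-strong T cells, 8%
monocytes, 4% progenitors), renormalized after clones and background
aberrancies take their share.  Background aberrancy per subpopulation is
zero-inflated lognormal on the %CD45⁺ scale (baseline: 60% zeros,
ln-mean ln 0.003, ln-sd 1.0), modulated by compartment (×12 ln-mean
outside the CD34/CD117 immature compartment; 80% zeros and ln-mean
ln 0.0008 for HLA-DR⁻ immature subpopulations, making them the
detectability-limited ones) and by cohort (ALL molCR: heavier CD56⁺/CD13⁻
tails; hip surgery: heavier CD33⁻; PCNSL: quieter).  These choices
reproduce the qualitative facts the reference panel must exhibit —
zero-heavy distributions, references spanning roughly 0.001–2% with the
monopoietic compartment highest, and cohort-dependent attribution — and
are not fitted to any quantitative target.  The default control cohort is
30/19/32/9 BMD / ALL molCR / hip surgery / PCNSL, rescaled
proportionally for other sizes.

Clones are specified by backbone, aberrant-category set (CD13⁻ and CD33⁻
mutually exclusive — both would fail the myeloid OR gate) and fraction of
CD45⁺ events; patient pairs place the clone at 40% at diagnosis and any
residual fraction at follow-up, optionally with a shifted category set to
exercise ptDfN calls.  All randomness flows from one explicit seed per
sample (cohorts and pairs spawn child seeds deterministically).

**What passing tests do and do not show.**  The simulator omits marker
covariance, spectral spillover, acquisition drift, continuous maturation
gradients and genuinely ambiguous boundary events.  Green tests therefore
demonstrate the *logic* of the pipeline — gating hierarchy, bookkeeping,
estimator behaviour, calling rules, dose response — on idealized data;
they do not certify performance on real cytometry, where pre-gate
placement and threshold calibration dominate.

## Numerical choices and problem sizes

Quantile estimation and tabulation are exact arithmetic; the only
tolerance in the package is a 1e-9 slack inside the detectability `ceil`
guarding exact ratios against float rounding, and 1e-12 comparisons when
locating the quantile-determining order statistic.  Reports round
percentages to 4 decimals at render time only.  The test and acceptance
suites run the simulator at 4,000–300,000 events per sample and 20-sample
control cohorts — large enough that planted fractions of 10⁻⁴ stay
detectable under the 20-event rule, and small enough to keep the suites
fast; the generator's own defaults remain at the 500,000-event, 90-control
study scale.

## Known limitations

- Threshold defaults are calibration placeholders on the asinh scale; real
  deployments must set them from their own control measurements.
- The FCS reader covers list-mode FCS 3.0/3.1 with uniform bit width and
  float/integer encodings; it ignores spillover keywords (data are assumed
  compensated) and analysis segments.
- Cohort attribution reflects the single determining order statistic;
  distributional notions of "influence" (e.g. leave-one-cohort-out shifts)
  are not implemented.
- No spillover estimation, viability/time gating, per-sample automated
  gate adaptation, or survival modelling.
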