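# Methods

This note documents the statistical conventions, default parameters and
design choices behind pvsignalkit, and what the synthetic-data tests do and
do not demonstrate about real spontaneous-reporting data.

## Report databases and normalization

A spontaneous reporting system (SRS) database is normalized into three
frames keyed by an opaque `case_id`: cases (sex, age band, height, weight,
report quarter), drug mentions (name, role, dosing start date) and event
mentions (MedDRA preferred term, onset date, outcome).  Preferred terms are
treated as opaque labels; no MedDRA hierarchy is consulted.

Conventions where the source formats are underspecified:

* **One report = one unique case id.**  Duplicate case rows keep the latest
  report quarter (the usual convention for FAERS case versioning; the
  FAERS dialect without an explicit quarter keeps the last row).  Exact
  duplicate drug mentions and duplicate (case, term) event rows collapse to
  one; among duplicate event rows the one with the earliest complete onset
  date wins, which is deterministic and favors usable dates.
* **Partial dates** (year or year–month) are retained for provenance but
  excluded from time-to-onset, never imputed.
* **Height/weight bands** such as `160-169 cm` are converted to the band
  midpoint before computing BMI; numeric values pass through unchanged.
* **Role extraction** keeps `suspect` mentions (JADER dialect) or
  `primary_suspect` (FAERS dialect).  Cases that lose all drug mentions
  remain in the database: the comparator background is the full report
  population, so `n_reports` is invariant under role filtering.
* **Drug-name matching** is exact string equality after trimming and
  case-folding; no synonym dictionary is applied.
* FAERS OUTC codes are seriousness codes: only `DE` (death) and `DS`
  (disability → sequelae) translate into the recovery-outcome vocabulary;
  other codes are recorded as `unknown`, absent rows as `missing`.
  THER start dates attach case-wide to the case's drug mentions in this
  dialect (the per-mention link key of the raw archives is out of scope).

## Disproportionality screen

The 2×2 table counts unique cases.  ROR = (a·d)/(b·c); the 95% interval is
the log-normal Wald interval with z = 1.959964 — the universal
pharmacovigilance convention, since signal criteria in this field are
defined on that interval.  The signal criterion is strictly ci_low > 1.

* **Event selection**: minimum-count mode (default threshold 10 reports,
  inclusive) or top-k mode (default k = 50); ranking counts case-level
  frequencies, ties break lexicographically by preferred term so output
  order is deterministic.
* **Fisher's exact test** (used for the volcano ordinate) is the two-sided
  point-probability convention — the p-value sums hypergeometric
  probabilities of all tables with the observed margins no more probable
  than the observed one (tie tolerance 1e-7).  It is evaluated on the raw
  integer cells only.
* **Continuity correction**: whole-database screens use raw cells; screens
  inside demographic strata add 0.5 to every cell (Haldane–Anscombe),
  keeping ROR and CI finite in sparse tables.  Reported case counts stay
  uncorrected.  With the correction, |ln ROR| shrinks weakly toward 0 for
  concordant tables, a property the suite tests.
* **No multiplicity adjustment** is applied across the screened events —
  standard (if debatable) practice for hypothesis-generating
  disproportionality screens; the run log flags it.

## Stratification

Axes: sex (male/female); age under 60 vs 60+, decided on the decade lower
bound of the age band (bands through the 50s count as under 60); BMI
< 18.5, [18.5, 25.0), ≥ 25 kg/m².  Unknown values exclude a case from that
axis only.  The comparator inside a stratum is the stratum's own
background, not the whole database — otherwise stratum prevalence and
drug–event association would be conflated; callers can still pass the
whole-database event list so every stratum screens the same terms.
Signaled events roll up into six categories (hematological, infection,
tumor-related, neurological, skin-related, other) through an editable YAML
map bundled with the package; unmapped terms are "other".

## Time to onset and the Weibull fit

Onset days = (onset date − earliest dose start on or before it) + 0.5, so
same-day onset is 0.5 and every usable value is positive.  Records are
excluded — and each exclusion reason is counted, so input records always
reconcile — when dates are missing or partial, when every start postdates
the onset, or when the interval exceeds the 730-day cap (a day-730 onset,
730.5 after the offset, is just excluded; retaining it would be the
defensible alternative and is a one-line change).

The two-parameter Weibull MLE is deterministic: the shape solves the
profile-likelihood equation by bracketed root-finding, the scale then has a
closed form.  Confidence intervals come from the observed information
matrix on the (log α, log β) scale, back-transformed, so they respect
positivity.  Degenerate samples (all values equal) and samples below the
floor (default n = 10) raise instead of returning a spurious fit.  There is
no censoring model: only observed onsets are fitted, matching the
cumulative-incidence framing of onset profiling.  Hazard classification
compares the β CI against 1 (wear-out if the CI lies above, early failure
if below, random otherwise); a point-estimate rule is available via
`classify_rule="point"`.  Box summaries use linear-interpolation quartiles
and 1.5×IQR whiskers.

## Volcano plots

x = ln ROR, y = −log₁₀ p, threshold lines at 0 and 1.3 (p ≈ 0.05); color
encodes log₁₀ of the report count on a red–green–blue scale with the
most-reported events red, auto-scaled to the data.  Rendering is
deterministic (fixed SVG hash salt, no embedded timestamps).

## Synthetic report generator

Each synthetic report draws one suspect drug from a catalog and each event
term independently with background probability p0; for an injected
(drug, event) pair the event probability among that drug's reports becomes
p1 with odds(p1) = ROR_true · odds(p0), so the expected reporting odds
ratio equals the configured truth exactly.  Injections may be restricted
to one demographic level, giving stratum-specific signals.  Onset dates
add a rounded Weibull(α, β) day count to a uniformly drawn start date
(default α = 30 days, β = 1, i.e. a constant hazard with a one-month
scale — a typical early-onset toxicity profile); outcomes draw from a
configurable mix (default dominated by recovered/unrecovered with 10%
deaths); per-field missingness defaults reflect the heavy incompleteness
of real dumps (30% missing height/weight, 15% missing onset dates).
Demographics default to 55% male with an age distribution centered on the
60s–70s, matching an oncology reporting population.  A single RNG stream
per database makes generation byte-deterministic given the seed, and
`manifest.json` records the full ground truth.

Deliberate simplifications: events are conditionally independent given the
drug (no co-reporting correlation), there is one suspect drug per report
(plus optional concomitants), and no masking/competition bias is
simulated.  Passing the calibration and recovery tests therefore shows the
statistics are implemented correctly and behave as designed under the
model's assumptions — it does not show that real JADER/FAERS screens are
unbiased, where duplicate reporting, stimulated reporting and confounding
by indication all operate.

## Bundled reference tables

The published JADER and FAERS screen tables for the three vedotin ADCs are
transcribed into `pvsignalkit/data/*_reference_signals.csv` and used as
worked-example inputs: re-applying the strict criterion reproduces the
published per-drug signal counts (25/19/24 in JADER; 27/36/40 in FAERS),
and the polatuzumab/CMV-reactivation ROR is recomputed after solving the
unknown contingency cell from the published margins (29 pair reports,
2,168 drug reports, 2,200,140 total).  A handful of typographical
artifacts in the source table (decimal commas, a stray bold marker) were
normalized during transcription.  These checks are margin-consistency
reconstructions, not independent reproductions of the full-database
screens, which would require the real dumps.

## Problem sizes

The acceptance checks use 20,000-report databases (200 screened pairs for
null calibration; 100 replicates for injection recovery) and 200 Weibull
replicates at n = 500 per shape value — sizes at which the binomial and
asymptotic tolerances in the tests are informative while the whole suite
stays fast on a single CPU.

## Known limitations

* The Wald ROR interval is first-order asymptotic; for very sparse tables
  the stratified Haldane screen mitigates but does not remove its bias.
* FAERS onset dates in this dialect come from the DEMO event date, so
  FAERS time-to-onset is coarser than JADER's per-event onset dates.
* The reader accepts the documented CSV dialects, not the raw quarterly
  archive layouts (`$`-delimited legacy FAERS, zip bundles, CP932 JADER
  dumps are supported only via the `encoding` option).
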