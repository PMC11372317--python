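# Methods

## Extraction model

The extractor is a deterministic rule engine, not a learned model. A rule
set is an ordered collection of three rule kinds:

* **Keyword/regex rules** (categories: diagnosis, surgery,
  chief_complaint, gestation_history, medication, fetus_description).
  Patterns are Unicode regexes over the record's free text; every
  non-overlapping occurrence is reported with its 0-based half-open
  code-point span. Tie-breaking is the regex engine's leftmost semantics
  with alternation order inside a pattern; overlapping matches from
  *different* rules are all reported (masking later merges their
  windows). Shipped patterns avoid constructs with exponential
  backtracking.
* **Lab-threshold rules.** HCG positivity is inferred when the analyte
  matches (case-insensitive, through an alias table covering β-HCG,
  绒毛膜促性腺激素, etc.) and the value, converted through a unit
  registry, strictly exceeds the threshold — 10 ng/L in the
  mass-concentration family, 25 IU/L in the activity family
  (1 mIU/mL = 1 IU/L). "Exceeding" is read literally, so values exactly
  at a threshold are negative; the comparison lives in one place and a
  user rule set can supply different thresholds. The two unit families
  are never cross-converted: a result in an unknown unit produces a
  warning (tallied in the run metadata), never a match.
* **Exclusion rules** (否认…史 denial histories, 无…史 / 未见… negative
  findings). Semantics: within a single text field, any include-match
  whose span overlaps any exclusion-match span is flagged *suppressed*.
  Suppressed matches are retained for audit but never count as sensitive
  information and are never masked. Suppression is deliberately local to
  one field — no cross-field or discourse-level negation scope is
  attempted.

Aggregation is monotone boolean OR: record → visit → patient, plus a
(patient, sub-dataset) matrix for the frequency tables. Adding rules can
therefore never un-flag anything, and a restricted rule set always flags
a subset of what the full set flags.

### The default rule set

The authoritative production rule list is not public; the shipped
`eppgi-default` set is a reconstruction anchored on the published
category examples (the birth-event keyword alternation, gravidity/parity
shorthand, termination-procedure, induction-medication and
fetus-description vocabulary, the two HCG thresholds, denial-style
negations). It is a YAML file users are expected to replace wholesale;
every behaviour above is config-driven. Include rules are corpus-wide
(empty scope) because scattering across sub-datasets is precisely the
phenomenon of interest; the traditional fixed-site comparison arm is
expressed as `diagnosis_marital_baseline()`, which keeps only
diagnosis-category rules scoped to the diagnosis sheet and
gestation-history rules scoped to the admission marriage-history field,
so both arms share one engine.

## Masking model

Policy parameters: `window` (default 15 code points — a Chinese character
counts as one; chosen to hide enough context that the masked content
cannot be re-inferred from the surrounding phrase, while retaining the
rest of the note), `mask_char` (`*`), `preserve_length` (default true),
`merge_overlaps` (default true), `mask_structured` (default true — nulls
positive lab values; narrative and structured channels leak the same
fact, so both are redacted by default, with the switch exposed for
pipelines that only share free text).

Each active match span is expanded symmetrically, clipped to the text,
merged with neighbours, and overwritten. Because suppressed (negated)
matches are not sensitive, they are left unmasked; masked text can never
re-match a keyword rule (asterisk runs match no shipped pattern), which
makes masking idempotent and makes the coverage property checkable by
re-running the engine.

Re-identification risk replaces the original manual reviewer audit with
an automated adversary: re-running the extraction engine on the masked
corpus (an `adversary` hook accepts any corpus → patient-set callable).
Success rate = 1 − (true-positive patients still detected / true-positive
patients); undefined (not 0) when the corpus has no true positives.

## Evaluation conventions

Positive class is "has reproductive information". Confusion matrices are
oriented rows = prediction, columns = reference. Precision and recall are
kept as exact `Fraction`s; display values are percentages rounded
half-up to two decimals (the same `percentage()` helper drives the
frequency tables, so table arithmetic and metric arithmetic cannot
drift apart). Zero-denominator ratios are reported as not-applicable,
never as 0.

Patient-level tables count distinct patients per sub-dataset
(denominator: patients with ≥ 1 record there; numerator: patients flagged
there); record-level tables count records, reflecting per-visit storage.
Stratified reports assign each patient to the hospital/year of her last
visit (missing keys bucket under "unknown") and always sum cell-wise to
the global counts.

## Inclusion filtering

`filter_sample` applies the study-style inclusion rule: eligibility (sex
F, age 14–50, visit date 2010-01-01 … 2020-12-31 by default) is assessed
on each patient's **last** visit, then eligible patients are sampled
without replacement at a fraction (default-relevant value 0.70) with an
explicit seed; the sampled count is round-half-up(f·n). All records of a
sampled patient are kept. `dedup_patients` normalizes to one logical
patient per id: exact duplicate rows are dropped and conflicting sex/age
metadata is harmonized to the last-visit values (patient ids are treated
as globally unique across hospitals — reconciling colliding ids from
different sources is out of scope and documented as such).

## Synthetic corpus generator

The generator emulates the structural skeleton of a Chinese inpatient
EMR, not its prose. Text is template-based (prefix + planted phrase +
suffix from audited pools), so every planted span is exact and every
negative patient is provably negative. Defaults define the study
conditions used throughout the tests:

* `n_patients` as requested; patient-level prevalence 0.62 (also
  accepted as a year → prevalence map for stratified experiments);
* visits per patient geometric with mean 2 (capped at 6), all visits
  within the patient's enrollment year so per-year strata are clean
  cohorts; years 2010–2020; five hospitals with fixed weights;
* per-sub-dataset presence probabilities (how often a visit produces a
  record of each kind) and, for sensitive patients, per-sub-dataset hit
  probabilities ordered like the observed frequency profile — marriage
  history highest (0.63), nursing records next (0.55), down to
  laboratory reports (0.10) — without claiming exact field-level rates;
* every sensitive patient receives ≥ 1 planted signal (forced into the
  marriage-history field if no sub-dataset draws one); HCG values are
  drawn uniformly from positive ranges (all well above threshold after
  unit conversion) or negative ranges (all strictly below), across
  ng/L, ng/mL, IU/L and mIU/mL;
* negative patients receive only neutral filler and distractors:
  negated histories (否认早产史 — planted as *suppressed* matches) and
  near-miss strings (早餐, 子宫肌瘤). Distractor collisions (a negative
  patient containing a genuinely positive phrase) are off by default and
  enabled via `distractor_collision_rate` for precision stress tests.

What passing tests on this corpus do **not** show: robustness to
free-form clinical narrative, typos, OCR noise, rule-vocabulary gaps or
institution-specific phrasing — the generator's vocabulary is a subset of
the default rule set by construction (an audit test enforces this), so
recall 1.0 on synthetic data bounds nothing about real-world recall.
What they do show: the engine, aggregation, masking and metric layers
are internally correct, deterministic and consistent with their
independent oracles.

Four hand-built adversarial fixtures stress specific edges: negation-only
corpora, HCG values exactly at the thresholds across unit synonyms,
keyword pairs whose mask windows must merge, and corpora whose only
signals sit in nursing notes (invisible to the fixed-site baseline).

## Numerical and design choices

* Character offsets are Unicode code points, 0-based half-open,
  everywhere; dates are ISO-8601; JSONL is the canonical exchange format
  (free text contains newlines), CSV a faithful RFC-4180 secondary.
* Rounding is half-up via exact `Fraction` arithmetic (no binary-float
  rounding artifacts at .005 boundaries).
* Sampling and generation use `numpy.random.default_rng` seeded
  explicitly; identical config + seed reproduces a byte-identical
  corpus.
* Problem sizes in the test and acceptance runs (2,000-patient corpora,
  1,000-case oracle sweeps) were chosen as the smallest sizes at which
  the binomial confidence checks are meaningful while the whole suite
  runs in seconds.

## Known limitations

* The default rule set is a reconstruction from published examples, not
  the production list; its coverage of real clinical phrasing is
  untested by design.
* Exclusion handling is span-overlap only; hedges, family-history
  attributions and long-range negation are out of scope.
* HCG unit handling treats mass and activity families as incomparable
  (no molar-mass bridging), matching how thresholds are stated per unit.
* The re-identification adversary is the extractor itself; a human
  reader with world knowledge could still infer more from masked context
  than any keyword engine.
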