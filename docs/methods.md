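# Methods

## The scoring model

`notescore` operationalises a manual chart-review protocol for judging
whether a dementia outpatient responded to a cholinesterase inhibitor
(CEI) or an SSRI, using only what clinicians, caregivers and patients
wrote down. Two ordinal outcome scales are assigned per *medication
episode* and *symptom domain*:

- **NOTE** (3-point): 1 improved, 2 no change, 3 worse; 0 = N/A when no
  scorable comment exists; 0.5 = intolerant when the drug was stopped for
  an adverse event or added to the allergy list. Intolerance overrides any
  comment, since an aborted treatment has no evaluable effect.
- **CIBIC-plus** (7-point): direction plus intensity
  (markedly/moderately/slightly) maps improve → 1/2/3, no change → 4,
  worse → 5/6/7. A directional comment without a gradable modifier
  ("donepezil working well") is CIBIC-plus N/A while still scoring
  NOTE = 1; collapsing 1–3/4/5–7 onto 1/2/3 therefore always agrees with
  NOTE wherever both are evaluable — an invariant enforced by the
  `EpisodeScore` type and asserted over every pipeline output in tests.

The underlying assumptions are clinical: insight declines with dementia,
so attribution matters (clinician > caregiver > patient > unattributed);
cognition is expected to decline, so *stability* of cognition is neutral
("dementia stable" → no change) and counts toward CEI response, whereas
*stabilised* psychiatric symptoms are a treatment success ("agitation now
stable" → improved); and a documented improvement marks the drug effective
even when the patient later declines.

## Annotation

Sentences are segmented on sentence-final punctuation and newlines, then
matched against a controlled lexicon: drug names for both classes,
cognitive-assessment names, psychiatric and cognitive symptom cues,
direction cues and intensity modifiers. Matching is whole-token and
case-insensitive with no stemming — the inventory enumerates inflected
forms explicitly — and overlap resolves leftmost-longest, so "not helpful"
suppresses the embedded "helpful". Negation is handled entirely by such
lexicon entries; there is no general negation algorithm.

Direction entries come in two forms. Plain phrases carry their direction
alone. *Slot templates* ("working well" + drug name, "stable" + symptom
cue, "more" + symptom) only fire when a phrase from their declared slot
set co-occurs within 8 tokens, in either order. Two deliberate design
choices live here:

- The stable/controlled family is encoded as templates with different
  slots per direction — psychiatric filler → improve, cognitive filler →
  no change — rather than duplicating one phrase across direction sets.
- "more" is simultaneously an improvement template (slot: positive
  behaviors — hopeful, engaged, interactive, …) and a worsening template
  (slot: problematic symptoms, i.e. symptom cues minus the
  positive-behavior words), so "more hopeful" and "more agitation"
  resolve to opposite directions deterministically.

Per sentence, each symptom domain with a direction cue yields one
annotation fragment, paired with the direction cue nearest its symptom
cue; within a sentence, improve and worse each beat no change ("memory
slightly worse or around the same" reads as worse). A sentence with a
drug mention and a direction but no symptom cue yields a single
*unclassified* fragment. Intensity is taken from the nearest modifier
within 3 tokens of the direction cue. The 8-token slot window and 3-token
intensity window are bounded-proximity approximations of sentence-level
co-occurrence; neither is derived from a reference protocol, and both are
package constants.

## Episodes and exclusions

Within one patient and drug class, prescription records sorted by start
date (reported start when present, else the order date) merge while the
gap from the previous usage period — a same-class switch or a documented
disuse gap — is below the washout window; a gap of at least the washout
starts a new episode. Month language is fixed to day counts: washout
"3 months" ≡ 90 days, "6 months" ≡ 182 days, "3 months after the index
date" ≡ 91 days, all windows closed at both ends. A disuse gap within one
drug follows the same rule as a switch. Each included episode is an
independent observation downstream.

Exclusions are evaluated in a fixed order and the first matching reason is
recorded: start > 182 days before or > 91 days after the index date; an
SSRI started < 90 days after a prior SNRI ended; unknown start; protected
records; never started; discontinued for a diagnosis change; and finally
*no evaluable follow-up*. The last is a record-availability criterion: it
fires when the patient has no clinical note dated after the episode start.
It is deliberately distinct from NOTE = 0 (N/A), which is assigned when
follow-up notes exist but none carries a scorable comment — conflating the
two would make N/A unobservable among included episodes.

## Evidence prioritization

Among a domain's annotations inside the episode window (comments up to
90 days past a documented end still count, as carryover observation), the
selection is lexicographic:

1. direction precedence improve > worse > no change across the episode;
2. highest available author priority (clinician > caregiver > patient >
   unknown; "unknown" is ranked last as the conservative choice);
3. for the cognitive domain, comments dated within 14 days of an observed
   MMSE change win;
4. smallest |days from start − 182|, earlier date on ties.

Unclassified drug-anchored comments count only toward the drug class's
default domain — psychiatric for SSRIs, cognitive for CEIs — and only when
the episode's class is among the drugs mentioned. Responders: SSRI
episodes with NOTE 1; CEI episodes with NOTE 1 or 2; NOTE 3 is
non-response; 0.5 intolerant; 0 not evaluable.

An open tie — improve and worse comments from the same author on the same
date — resolves through step 4's earlier-date/stable-sort rule; it is
arbitrary but deterministic.

## Cognitive screens

MoCA scores are converted to MMSE equivalents through a bundled
monotone 0–30 → 0–30 crosswalk. The bundled table
(`_SYNTHETIC_MOCA_TO_MMSE`) is a constructed stand-in preserving the
qualitative shape of published equipercentile-equating tables (MoCA runs
lower than MMSE over most of the range; ceilings map to ceilings); any
published crosswalk of the same shape can be dropped in. MMSE change is
the score nearest the comment date minus the score nearest the episode
start, each within an inclusive ±14-day window, with nearest-date (then
earlier-date) tie-breaking; missing either endpoint yields no change
value rather than an imputation.

## Validation statistics

- **Krippendorff's alpha** is computed from the coincidence matrix with
  the cumulative-margin ordinal metric over {1, 2, 3}. Cells coded 0/0.5
  and missing cells count as missing; units with a single rating drop out
  of the coincidence matrix without invalidating the rest.
- **ICC(2,k)** (two-way random effects, average measures) is computed
  from the ANOVA mean squares with listwise deletion of units containing
  a 0/0.5 code. Perfect within-unit agreement (zero residual mean square)
  returns ICC as computed with p = 0; a constant matrix is reported as a
  degenerate-statistic error rather than a number.
- **Dice** per category is 2·|both = c| / (|r1 = c| + |r2 = c|),
  symmetric, omitting categories absent from both raters.
- **Spearman** uses midrank ties; codes 0/0.5 are excluded upstream, so
  only genuinely ordinal values enter.
- **BCa bootstrap** intervals are built in-package: bias correction from
  the bootstrap distribution's position around the point estimate
  (midrank handling of exact ties, clipped at ±1/(2B) to keep the normal
  quantile finite), acceleration from jackknife influence values, and
  case resampling of whole units. Resamples on which the statistic is
  undefined are skipped and counted; more than 50% skipped aborts with a
  diagnostic. A constant sample yields a zero-width interval. With the
  corrections at zero the interval reduces exactly to the percentile
  interval, which the tests assert directly. Defaults follow the analysis
  protocol: 500 resamples for reliability statistics, 10,000 for
  correlations.
- **Multinomial baseline-category logit** (statsmodels MNLogit, Newton)
  with type-II likelihood-ratio tests: each covariate's p-value compares
  the full model to the model with that covariate removed, on
  (categories − 1) × (dummy columns) degrees of freedom. Significance is
  read at 0.05 with no multiplicity correction. Exact separation makes
  the MLE divergent and is reported as non-convergence, not a p-value.

Printed percentages round half-up to one decimal (`round_half_up`), the
convention used throughout the rate tables; source tables in this
literature mix integer and one-decimal precision, which this package does
not replicate.

## The synthetic corpus

The generator emulates the observed study conditions: by default 225 SSRI
cases (6 N/A, 17 intolerant, 156 improved, 28 no change, 18 worse) and
115 CEI cases (7 N/A, 12 intolerant, 31 improved, 40 no change,
25 worse), with diagnosis-group margins (AD / VD / AD+VD / other),
sex margins and age distributions (normal, mean 73/74, SD 9.7/8.8,
clipped to 50–95) matching that population. Category counts are laid down
*exactly*; only covariates and timelines are sampled, so the headline
percentages are deterministic across seeds by construction. Comment dates
are normal around 182 days after start (SD 45, clipped to 30–360),
author roles draw from a 70/20/10 clinician/caregiver/patient mix,
and half of scorable improve/worse comments carry an intensity modifier
(`cibic_intensity_rate = 0.5`). Fifteen percent of improved cases also
document a later decline, exercising the improvement-overrides-decline
rule, and 40% of cognitive cases get pre/post MMSE screens whose change
sign matches the truth direction.

Sentences are assembled from lexicon phrases only. That is the point —
at `noise_rate = 0` the pipeline must recover 100% of case categories and
embedded comment annotations, and the test suite asserts it does on a
500-case corpus — but it is also the limit of what passing proves:
recovery on template sentences shows the rules compose correctly, not
that the lexicon covers real clinical language, with its misspellings,
abbreviations, quoted speech and attribution ambiguity. Intolerance is
signalled through structured discontinuation flags, never through text,
matching the scorer's contract. A positive `noise_rate` drops comment
keywords (making cases unrecoverable) and appends distractor sentences,
for degradation testing only; it is not a model of real noise.

## Problem sizes

The acceptance script scores the full default corpus (340 cases, ~720
notes) in a few seconds; the round-trip test uses 500 cases; reliability
oracles run on ≤ 20-unit matrices with a 10,000-unit simulation for the
alpha-near-zero check; the null-covariate simulation fits the multinomial
model at n = 2000 over 10 seeds. These sizes were chosen to exercise
every rule while keeping the suite fast enough to run on every change.

## Known limitations

- English template text only; no spelling correction, abbreviation
  expansion, coreference, or temporal expressions inside note text
  (dates come from note metadata).
- Author role must arrive as structured metadata; text quoting a
  caregiver inside a clinician note is not split.
- Memantine and SNRIs are out of scope as scored drugs (SNRIs appear only
  in the SSRI carryover exclusion).
- The bundled MoCA→MMSE crosswalk is a constructed stand-in, adequate for
  the identity/monotonicity contracts and the change-sign logic but not
  for clinical conversion of real scores.
- Equal-length overlapping lexicon phrases resolve leftmost; pathological
  constructions ("no improvement in mood" where "no improvement" and
  "improvement in" tie) are covered by this rule, but other such
  collisions would resolve silently rather than flag ambiguity.
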