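# notescore

Rule-based scoring of treatment response from free-text clinical notes of
dementia outpatients.

Cholinesterase inhibitors (CEIs) are prescribed to slow cognitive decline
and SSRIs to manage the neuropsychiatric symptoms of dementia, but outside
of trials it is rarely recorded *on a scale* whether a given patient
responded. What the medical record does contain is prose: "anxiety better",
"dementia stable", "donepezil helpful". `notescore` turns that prose into
quantitative outcome measures:

- **NOTE**, a three-point Likert scale per medication episode and symptom
  domain (psychiatric or cognitive): 1 = improved, 2 = no change,
  3 = worse, with side codes 0 = N/A (nothing scorable) and
  0.5 = intolerant (drug stopped for an adverse event or allergy-listed).
- **CIBIC-plus**, the seven-point global impression of change used in
  dementia trials (1 markedly improved … 4 unchanged … 7 markedly worse),
  assigned from the same evidence when an intensity modifier makes the
  comment gradable.

The pipeline is deliberately lexicon-driven, not statistical: a controlled
phrase inventory (drug names, psychiatric and cognitive symptom cues,
direction cues, intensity modifiers) is matched with whole-token,
longest-match rules, so every score is traceable to the exact evidence
span that produced it.

## What the pipeline does

1. **Annotate** — each sentence is classified into domain × direction ×
   intensity. Domain-dependent conventions are built in: because cognition
   is expected to decline, "dementia stable" is *no change*, while
   "agitation now stable" is an *improvement*.
2. **Episodes** — prescription records merge into medication episodes per
   patient and drug class with a 90-day washout rule: a same-class switch
   or disuse gap shorter than 90 days continues the episode, a longer one
   starts a new, independent observation. Study exclusions (start too far
   from the index date, recent SNRI before an SSRI, unknown start,
   protected records, no follow-up documentation, …) are applied per
   episode.
3. **Score** — one prioritized comment per episode and domain:
   improvement beats a later decline, improve/worse beat no change,
   clinician comments beat caregiver comments beat patient comments,
   cognitive comments dated at an observed MMSE change win, remaining
   ties resolve to the comment closest to 6 months after the start.
4. **Classify** — SSRI responders improved psychiatrically; CEI responders
   improved *or held stable* cognitively; intolerant episodes are coded
   0.5 and set aside.
5. **Validate** — Krippendorff's alpha (ordinal metric, missing data
   tolerated), ICC(2,k), per-category Dice, Spearman correlations, BCa
   bootstrap confidence intervals, and a baseline-category multinomial
   logit with type-II likelihood-ratio tests for covariate effects.

A built-in synthetic-corpus generator (`notescore.synth`) emits notes,
prescriptions and MMSE/MoCA screens with known ground truth, so the whole
pipeline is testable end to end without access to any real record.

## Worked example

```python
import datetime as dt
from notescore import ClinicalNote, PrescriptionRecord, score_corpus

notes = [
    ClinicalNote("N1", "P1", dt.date(2019, 1, 10), "clinician",
                 "Started sertraline today for mood and anxiety."),
    ClinicalNote("N2", "P1", dt.date(2019, 7, 2), "clinician",
                 "Anxiety much better. Memory about the same."),
    ClinicalNote("N3", "P1", dt.date(2020, 1, 15), "caregiver",
                 "More agitation at home recently."),
]
rx = [PrescriptionRecord("P1", "sertraline", dt.date(2019, 1, 10),
                         reported_start_date=dt.date(2019, 1, 10))]
print(score_corpus(notes, rx).scores_frame().to_string(index=False))
```

prints

```
episode_id patient_id drug_class      domain  prioritized  note_value  cibic_value evidence_date responder
 P1-SSRI-1         P1       SSRI psychiatric         True         1.0            1    2019-07-02 responder
 P1-SSRI-1         P1       SSRI   cognitive        False         2.0            4    2019-07-02      None
```

One SSRI episode was built from the prescription. The psychiatric domain
scores NOTE = 1 (improved) with CIBIC-plus = 1 (markedly improved, from
"much better"): the clinician's improvement in July outranks the
caregiver's later report of more agitation. The cognitive domain scores
NOTE = 2 / CIBIC-plus = 4 from "memory about the same". Because the drug
is an SSRI, the psychiatric domain is the prioritized one, and the episode
is classified a responder.

The same pipeline is available from the shell:

```sh
notescore run-all --seed 1 --out-dir out/        # synthetic corpus + scoring
notescore score --notes notes.jsonl --prescriptions rx.csv --out-dir out/
notescore validate --ratings ratings.csv --out report.json
```

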