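# Methods

`mibot` models a motivational-interviewing (MI) conversation between a chatbot
and an ambivalent smoker, together with the iterative human-in-the-loop
procedure that trains the chatbot's natural-language understanding. This note
documents the models and procedures, the defaults and why they were chosen,
what the synthetic population does and does not emulate, and the design
choices made where the design was genuinely open.

## The conversation model

The dialogue is a finite-state machine over an explicit
`ConversationState`, run in three stages:

1. **Introduction** — purpose statement and a permission request.
2. **Reflection** — the core. The *running head start* technique asks
   "Do you like to smoke?" to gauge sentiment, then elicits the pros and cons
   of smoking in sentiment-dependent order (a positive answer puts "What is
   good about smoking?" first; a negative one puts "What is bad about
   smoking?" first). Each free-form reason is classified into a reason
   category and reflected back in a category- and polarity-specific template.
   When a section ends, the bot summarizes it with **one line per distinct
   category, quoting every stored utterance verbatim**. Each confirmed reason
   is then probed with three *exception-case questions*, always in the order:
   a time the reason led to smoking (positive case), a time it did not
   (negative case), and what made the difference.
3. **Ending** — the verbatim free-form feedback question, then a close.

Two modes share the machine. In **training mode** every detection is read
back ("Am I right?"); the user confirms, corrects from the full category
option list, or answers "Other" and names a new category in one or two words.
These interactions are the system's labeled-data source. In **intervention
mode** the bot reflects directly and never asks for labels.

All template choice is driven by a per-session seeded generator stored in the
state, and the same template id is never used twice in a row for the same
response type (a category with a single template repeats it, and the repeat is
flagged in the state log). Consequently a transcript is fully replayable:
fixed (seed, user turns, model) implies byte-identical bot turns. Collected
reasons are stored byte-identical to what the user typed; normalization is
applied only for matching, never for storage.

Open points the flow had to settle:

* **Section termination.** The "what else?" loop closes on a small stop
  lexicon (`no`, `nothing`, `that's all`, `nope`, `none`, ...).
* **Reason cap.** At most 10 stored reasons per polarity (configurable); an
  overflow reason is acknowledged and the section closes. This bounds session
  length for users with very many reasons.
* **Sentiment fallback.** An unparseable answer to "Do you like to smoke?"
  is re-asked once; a second failure defaults to positive (good-first) and is
  logged, so the conversation never stalls.
* **Summary denial.** If the user says the summary was wrong, the bot
  re-lists each stored reason with the category options once and moves on.
* **Abstention fallback.** In training mode an abstention goes straight to
  the option list (as if the user had said "Wrong", but counted as a false
  negative); in intervention mode it gets a generic reflective
  acknowledgement.
* **Summaries per section.** Each polarity section is summarized when it
  closes (rather than one combined summary at the very end).
* **Unparseable confirmations.** "Am I right?" and the option list each
  re-ask once; a second failure stores the reason as unconfirmed, which is
  excluded from labeled data and from the live tallies.

## The classifier

The smoking-reasons classifier maps one utterance to exactly one category or
abstains. It is multinomial logistic regression over TF-IDF word 1–2-gram
features (sublinear TF), with:

* **Abstention threshold** — default 0.5 on the top softmax score,
  configurable in `ClassifierConfig`. Below it the classifier emits no
  category; in evaluation that is a false negative.
* **Regularization** — `C = 50` (weak). Utterances are short and the
  categories are topically distinct, so the classes are nearly separable and
  strong regularization would only depress the softmax scores toward the
  abstention threshold.
* **Tie-breaking** — equal top scores resolve to the lexicographically
  smallest category id, for determinism.
* **Degenerate corpora** — a single-category corpus yields a model that can
  only emit that category or abstain (there is nothing to discriminate).

Training is deterministic for a fixed corpus order, configuration, and seed;
two runs produce bit-identical serialized models, and serialization
round-trips bit-exactly.

### Evaluation

Metrics follow the chatbot's single-label micro scheme. Each evaluated
utterance contributes exactly one outcome: **TP** (correct detection),
**FP** (wrong detection), or **FN** (abstention), pooled globally across
categories:

    precision = TP / (TP + FP)
    recall    = TP / (TP + FN)
    F1        = TP / (TP + 0.5 · (FP + FN))

The F1 form is algebraically the harmonic mean of precision and recall
whenever both are defined (the suite asserts agreement to 1e-12). A zero
denominator raises `UndefinedMetricError` — never a silent zero.

`split_corpus` holds out a **fixed-size** test set (e.g. 200 of 1010, leaving
810 for training), stratified by category with largest-remainder allocation;
single-member categories stay in the training set.

## The iterative training campaign

Participants arrive in groups (the study scale is 11 groups of 11). For each
group the loop is: train on the cumulative corpus → run every session against
the live model → ingest → review → retrain. Ingestion turns training-mode
annotations into labeled samples and review items:

* confirmation → sample with the confirmed label; live **TP**;
* correction → sample with the corrected label; live **FP**;
* abstention resolved via the option list → sample; live **FN**;
* new-category proposal → queued for review; live FP if it displaced a
  detection, FN if it resolved an abstention.

Note the live metrics use the *user's* judgment as ground truth, so a user
who wrongly confirms a wrong label contaminates TP. This is deliberate — it
is exactly what a deployed training study measures — and the simulator's
`confirm_error_rate` exercises it.

The default review policy is automatic: a proposal whose normalized name
matches an existing category id, display name, or alias (the synonym table)
merges into it; anything else becomes a new category with generated
placeholder reflection templates (a category is never activated without
templates) and a valence taken from the observed polarity, widened to `both`
if the opposite polarity is later observed. Duplicate proposals within a
round collapse to one decision. An interactive policy hook accepts a callable
for human review. Retraining is always from scratch on the cumulative corpus:
deterministic and simple, at desk scale there is no need for incremental
fitting.

The campaign's initial corpus is 6 grammar-generated utterances per seed
category-polarity pair (14 pairs, 84 samples), standing in for the
researcher-synthesized examples that bootstrap the first model.
Per-round sessions cap exception-case probing at 3 reasons to keep
study-scale campaigns compact; the per-reason protocol is unchanged.

## The seed taxonomy

The packaged full taxonomy has 21 categories: 5 pro-only (boredom, cool, feel
good, in my hand, stimulation), 6 con-only (cost, dirty, fire hazard,
physical appearance, poor role model, stigma), and 10 valid as both. Each
category carries per-polarity reflection templates (≥2), example utterances,
and observed-count metadata used as the simulator's sampling weights. The
counts are population metadata, not an audited total, and are never asserted
against any corpus-size figure.

The 10-category seed taxonomy is a strict subset of the full one:
`feel_good, stimulation, stress, routine, addiction, in_my_hand, health,
cost, cool, boredom`. The classic "reasons for smoking" questionnaire names
map onto it with *pleasure* → feel good and *craving* → addiction (both kept
as aliases, so user text naming them still resolves). Because that mapping
collapses two questionnaire names onto one category, a tenth seed category is
needed for the seed set to remain ten distinct categories; *boredom* fills
it as the kind of common, expert-nominated smoking reason such a starter list
contains. The 11 categories outside the seed are exactly what a default
campaign discovers through user proposals, growing the taxonomy 10 → 21.

Category ids are normalized (Unicode NFC, casefold, non-alphanumeric runs →
underscore) so they are stable keys across files and user spellings.

## The synthetic population

A **persona** has a 50/50 sentiment, 2–5 reasons (uniform; the real
distribution of reasons per participant is unknown, so a modest symmetric
default is used) drawn without replacement from the taxonomy's
category-polarity pairs with probability proportional to the observed
counts — so stress-pro and health-con dominate, exactly as in the population
the counts describe — always with at least one pro and one con (ambivalence).
Noise defaults: `typo_rate = 0.01` per character
(substitution/deletion, producing artifacts like "somehthing"),
`confirm_error_rate = 0.02` for wrong confirmation answers. Campaign
generation additionally plants each non-seed category on one persona as a
novel reason, front-loaded over the first three quarters of the groups so the
discovery rate tapers as the taxonomy saturates, as in a real iterative
study.

Utterances come from a stem-and-frame **grammar**: each category-polarity
pair has a pool of content stems sharing that category's distinctive
vocabulary, composed with neutral filler frames ("i think …", "…, honestly").
The category signal lives entirely in the stems, so grammar output is
separable by construction; the suite audits that a model trained on grammar
output maps held-out grammar output back to its generating category with
≥ 0.95 accuracy at zero noise.

**What passing tests therefore show — and do not show.** The simulator
emulates single-category utterances at realistic frequencies, yes/no answers,
noisy confirmations, typos, and gradual category discovery. It does not
emulate compound multi-reason utterances, sarcasm, topic drift, paraphrase
outside the grammar, or dropout. Metrics on synthetic campaigns demonstrate
that the *loop* works — data accrual, taxonomy growth, retraining gains —
not that the classifier would reach the same scores on real smokers' text,
which is lexically far more diverse.

## Numerical and format choices

* All randomness flows from explicit integer seeds through
  `numpy.random.Generator`; derived streams use distinct offsets.
* Storage is UTF-8 text: transcripts as JSON Lines (header record + one
  record per turn), corpora as TSV (csv-quoted, lossless for embedded
  tabs/quotes/newlines) or JSON Lines, taxonomies and templates as YAML,
  round reports as TSV. Every file carries a schema tag and mismatches fail
  with both versions named.
* Human-readable tables round metrics to 2 decimals; machine-readable files
  keep full precision.
* Model artifacts embed the taxonomy version, configuration, and a SHA-256
  fingerprint of the training corpus.

## Known limitations

* Reflection quality is template-bound; the bot cannot condense a long
  utterance beyond its category's scripted reflections.
* The classifier is mutually exclusive: compound utterances expressing two
  reasons get one label (or a correction).
* Exception-case answers are stored and acknowledged generically; no NLU is
  applied to them.
* The auto review policy is a name-matching approximation of a human
  consensus discussion; genuinely ambiguous proposals (e.g. near-synonym
  category names outside the alias table) become separate categories where a
  human panel might merge them. Use the interactive policy hook when
  fidelity matters.
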