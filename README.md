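# mibot

A motivational-interviewing (MI) smoking-cessation chatbot toolkit: a
seedable, replayable dialogue engine built around MI's *running head start*
technique, a smoking-reasons text classifier with abstention, the iterative
human-in-the-loop training procedure that grows the reason taxonomy between
participant groups, and a synthetic-user simulator that makes the whole
train → converse → review → retrain loop reproducible with no external data.

**Who it is for.** Researchers building conversational behavior-change
interventions who need a testable reference implementation of an MI-style
reflective chatbot, and anyone studying human-in-the-loop intent-taxonomy
growth with a fully synthetic, deterministic testbed.

## The model in brief

The bot elicits a smoker's *pros* and *cons* of smoking (ordered by the
answer to "Do you like to smoke?"), classifies each free-form reason into one
of a taxonomy of reason categories (stress, cost, health, ...), reflects it
back, summarizes each section verbatim per category, and probes each reason
with three exception-case questions. In training mode it asks "Am I right?"
after every detection; confirmations, corrections, and newly named categories
become labeled data, reviewed between groups, and the classifier — logistic
regression over TF-IDF 1–2-grams, abstaining when its top softmax score falls
below a threshold — is retrained from scratch on the growing corpus.

Evaluation is single-label micro: per utterance exactly one of TP (correct
detection), FP (wrong detection), FN (abstention), pooled globally, with

```
precision = TP/(TP+FP)   recall = TP/(TP+FN)   F1 = TP/(TP + 0.5·(FP+FN))
```

## Worked example

`examples/04_iterative_campaign.py` runs a small 4-group campaign of 6
synthetic personas each, starting from the packaged 10-category seed
taxonomy:

```
group  P     R     F1    corpus      categories
    1  0.91  0.77  0.83    84 -> 112   10 -> 14
    2  0.95  0.75  0.84   112 -> 137   14 -> 18
    3  0.82  0.56  0.67   137 -> 155   18 -> 21
    4  0.93  0.70  0.80   155 -> 176   21 -> 21

final model knows 21 categories; held-out micro F1 on them: 0.75 (TP=187 FP=4 FN=119)
```

Each row is the precision/recall/F1 that group experienced live (their
confirmations = TP, corrections = FP, abstentions = FN), the cumulative
corpus size, and the taxonomy size as user-proposed categories are accepted.
Dips happen when freshly discovered categories still have almost no training
examples; the corpus and category counts never decrease. At this small scale
the held-out F1 is modest — the study-scale campaign below does better.

Other examples: `01_taxonomy_census.py` (load/grow the taxonomy),
`02_train_and_evaluate.py` (the 810/200 split convention and metric report),
`03_scripted_conversation.py` (a full scripted training-mode session,
replayed byte-identically).

There is also a CLI:

```bash
mibot gen-corpus --n-per-category 10 --seed 1 --out corpus.tsv
mibot train --corpus corpus.tsv --out model.pkl
mibot evaluate --model model.pkl --test corpus.tsv
mibot campaign --groups 11 --group-size 11 --seed 42 --out-dir out/
mibot chat --model model.pkl --mode intervention
```

## Package layout

| module | contents |
| --- | --- |
| `mibot.taxonomy` | reason categories, valences, fixtures, growth and census |
| `mibot.nlu` | classifier with abstention, micro metrics, corpus splitting |
| `mibot.dialogue` | the conversation engine, transcripts, replay |
| `mibot.training_loop` | ingest, review policy, the multi-group campaign |
| `mibot.simulator` | personas, the utterance grammar, campaign generation |
| `mibot.io` / `mibot.cli` | file formats (JSONL/TSV/YAML) and the CLI |

See `docs/methods.md` for the full account of the models, defaults, and what
the synthetic population does and does not emulate.
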