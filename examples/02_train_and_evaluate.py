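"""Train the smoking-reasons classifier and evaluate it with micro metrics.

Builds a synthetic labeled corpus of 1010 utterances over the full
21-category taxonomy, holds out 200 for testing (the 810/200 convention),
trains the TF-IDF + logistic-regression classifier with abstention, and
prints micro precision, recall, and F1. An abstention counts as a false
negative: the chatbot produced no classification for that utterance.
"""

from mibot import (
    evaluate,
    load_full_taxonomy,
    split_corpus,
    train_classifier,
)
from mibot.simulator import NoiseSettings, generate_corpus

taxonomy = load_full_taxonomy()
corpus = generate_corpus(
    taxonomy, 33, noise=NoiseSettings(typo_rate=0.01, confirm_error_rate=0.0),
    seed=7,
)[:1010]
train, test = split_corpus(corpus, test_size=200, seed=1)
print(f"corpus: {len(corpus)} utterances -> train {len(train)} / test {len(test)}")

model = train_classifier(train, taxonomy, seed=0)
counts, metrics = evaluate(model, test)
print(f"confusion counts: TP={counts.tp} FP={counts.fp} FN={counts.fn}")
print(f"Precision {metrics.precision:.2f}")
print(f"Recall    {metrics.recall:.2f}")
print(f"F1 score  {metrics.f1:.2f}")

for text in ("it calms my nerves after a long day", "so expensive these days", ""):
    pred = model.classify(text)
    label = pred.category_id if pred.detected else "(abstained)"
    print(f"  {text!r} -> {label}  confidence={pred.confidence:.2f}")
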