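"""Run a small iterative training campaign with synthetic participants.

Groups of simulated smokers converse with the chatbot in training mode; after
each group, their confirmations, corrections, and new-category proposals are
reviewed and the classifier is retrained on the cumulative corpus. The table
shows each group's live micro metrics (confirmation=TP, correction=FP,
abstention=FN) and how the corpus and taxonomy grow; the last line evaluates
the final model on an independent held-out synthetic test set.

The full study-scale configuration (11 groups of 11) runs the same way — see
scripts/acceptance.py — and grows the taxonomy from 10 to all 21 categories.
"""

from mibot import evaluate, load_full_taxonomy, load_seed_taxonomy
from mibot.simulator import NoiseSettings, generate_campaign, generate_corpus
from mibot.training_loop import CampaignConfig, run_campaign

seed_taxonomy = load_seed_taxonomy()
config = CampaignConfig()
groups = generate_campaign(seed_taxonomy, n_groups=4, group_size=6,
                           noise=config.noise, seed=42)
result = run_campaign(groups, seed=42, taxonomy=seed_taxonomy, config=config)

print("group  P     R     F1    corpus      categories")
for r in result.reports:
    print(f"{r.group_index:>5}  {r.precision:.2f}  {r.recall:.2f}  {r.f1:.2f}"
          f"  {r.corpus_before:>4} -> {r.corpus_after:<4}"
          f"  {r.categories_before} -> {r.categories_after}")

held_out = generate_corpus(
    load_full_taxonomy(), 10,
    noise=NoiseSettings(typo_rate=0.01, confirm_error_rate=0.0), seed=141,
)
# note: early in a campaign some categories are still unknown to the model
known = set(result.model.labels)
held_out = [u for u in held_out if u.category_id in known]
counts, metrics = evaluate(result.model, held_out)
print(f"\nfinal model knows {len(result.model.labels)} categories; held-out "
      f"micro F1 on them: {metrics.f1:.2f} "
      f"(TP={counts.tp} FP={counts.fp} FN={counts.fn})")
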