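"""The iterative, group-wise retraining campaign.

Participants arrive in small groups; between groups the researchers review
what the chatbot learned — confirmations of its detections, corrections from
the option list, and proposals of brand-new reason categories — then retrain
the classifier on the cumulative corpus for the next group. This module
ingests training-mode transcripts into labeled samples and a review queue,
applies a review policy (auto synonym-merge or interactive), retrains from
scratch each round, and reports each group's live micro precision/recall/F1
(confirmation = TP, correction = FP, abstention = FN, exactly as the
conversation experienced them).

Note the deliberate fidelity of the live metrics: a user who wrongly confirms
a wrong label contaminates TP, just as in a real deployment — the simulator's
``confirm_error_rate`` exercises this.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Callable, Sequence

from .dialogue import ConversationEngine, Transcript
from .nlu import (
    ClassifierConfig,
    ClassifierModel,
    ConfusionCounts,
    LabeledUtterance,
    UndefinedMetricError,
    micro_metrics,
    train_classifier,
)
from .simulator import (
    DEFAULT_NOISE,
    NoiseSettings,
    Persona,
    UtteranceGrammar,
    generate_corpus,
    simulate_session,
)
from .taxonomy import (
    Taxonomy,
    add_category,
    load_seed_taxonomy,
    normalize_id,
    widen_valence,
    _placeholder_templates,
)

REVIEW_KINDS = ("confirmation", "correction", "new_category_proposal")


@dataclass(frozen=True)
class ReviewItem:
    """One item for the between-groups researcher review."""

    kind: str  # confirmation | correction | new_category_proposal
    utterance: str
    polarity: str
    predicted_id: str | None = None
    corrected_id: str | None = None
    proposal_name: str | None = None
    group_index: int = 0

    def __post_init__(self) -> None:
        if self.kind not in REVIEW_KINDS:
            raise ValueError(f"unknown review kind {self.kind!r}")
        if self.kind == "correction" and not (self.predicted_id and self.corrected_id):
            raise ValueError("correction must carry predicted and corrected ids")
        if self.kind == "new_category_proposal" and not self.proposal_name:
            raise ValueError("proposal must carry a name")


@dataclass(frozen=True)
class RoundReport:
    """Per-group progress record (live metrics as that group experienced them)."""

    group_index: int
    classifier_tag: str
    precision: float
    recall: float
    f1: float
    corpus_before: int
    corpus_after: int
    categories_before: int
    categories_after: int


@dataclass
class IngestResult:
    samples: list[LabeledUtterance]
    review_queue: list[ReviewItem]
    counts: ConfusionCounts


def ingest(transcripts: Sequence[Transcript], group_index: int = 0) -> IngestResult:
    """Turn training-mode transcripts into labeled samples, a review queue,
    and the live TP/FP/FN tallies.

    Confirmations become samples labeled with the confirmed category;
    corrections become samples with the corrected label; new-category
    proposals are queued for review (their utterances become samples only
    once the review accepts a category for them). Abstentions resolved
    through the option list yield samples too, and count as FN.
    """
    samples: list[LabeledUtterance] = []
    queue: list[ReviewItem] = []
    tp = fp = fn = 0
    for transcript in transcripts:
        if transcript.mode != "training":
            raise ValueError(
                f"transcript {transcript.session_id!r} is from intervention mode "
                "and carries no label annotations"
            )
        for turn in transcript.turns:
            ann = turn.annotations
            if turn.speaker != "user" or not ann or "outcome" not in ann:
                continue
            outcome = ann["outcome"]
            if outcome == "confirmation":
                tp += 1
                samples.append(
                    LabeledUtterance(
                        ann["utterance"], ann["category_id"], ann["polarity"], "human"
                    )
                )
                queue.append(
                    ReviewItem(
                        "confirmation",
                        ann["utterance"],
                        ann["polarity"],
                        predicted_id=ann["predicted_id"],
                        corrected_id=ann["category_id"],
                        group_index=group_index,
                    )
                )
            elif outcome == "correction":
                fp += 1
                samples.append(
                    LabeledUtterance(
                        ann["utterance"], ann["category_id"], ann["polarity"], "human"
                    )
                )
                queue.append(
                    ReviewItem(
                        "correction",
                        ann["utterance"],
                        ann["polarity"],
                        predicted_id=ann["predicted_id"],
                        corrected_id=ann["category_id"],
                        group_index=group_index,
                    )
                )
            elif outcome == "abstained":
                fn += 1
                if ann.get("category_id"):
                    samples.append(
                        LabeledUtterance(
                            ann["utterance"], ann["category_id"], ann["polarity"],
                            "human",
                        )
                    )
            elif outcome == "new_category_proposal":
                if ann.get("predicted_id"):
                    fp += 1  # a detection the user rejected
                else:
                    fn += 1  # an abstention the user resolved with a new name
                queue.append(
                    ReviewItem(
                        "new_category_proposal",
                        ann["utterance"],
                        ann["polarity"],
                        predicted_id=ann.get("predicted_id"),
                        proposal_name=ann["proposal_name"],
                        group_index=group_index,
                    )
                )
            # "unconfirmed" outcomes could not be validated; they are dropped
    return IngestResult(samples, queue, ConfusionCounts(tp, fp, fn))


ReviewPolicy = Callable[[ReviewItem, Taxonomy], str | None]
# an interactive policy maps a proposal to an existing id, a new name, or None
# (reject); the default "auto" policy merges name-similar proposals and
# accepts the rest


def apply_reviews(
    queue: Sequence[ReviewItem],
    taxonomy: Taxonomy,
    policy: str | ReviewPolicy = "auto",
) -> tuple[Taxonomy, list[LabeledUtterance]]:
    """Apply review decisions: merge or create categories for proposals.

    Auto policy: a proposal whose normalized name matches an existing
    category id, display name, or alias (the synonym table) merges into it;
    otherwise a category is created with the proposal's name, a valence from
    the observed polarity, and generated placeholder templates (a category is
    never activated without templates). Duplicate proposals within a round
    collapse to a single decision. Returns the grown taxonomy and the
    accepted proposal utterances as labeled samples.
    """
    accepted: list[LabeledUtterance] = []
    decided: dict[str, str | None] = {}  # normalized proposal name -> category id
    for item in queue:
        if item.kind != "new_category_proposal":
            continue
        key = normalize_id(item.proposal_name)
        if key not in decided:
            if callable(policy):
                verdict = policy(item, taxonomy)
                if verdict is None:
                    decided[key] = None
                    continue
                name = verdict
            else:
                name = item.proposal_name
            existing = taxonomy.find_by_name(name)
            if existing is not None:
                decided[key] = existing.id
            else:
                result = add_category(
                    taxonomy,
                    name,
                    valence=item.polarity,
                    templates=_placeholder_templates(name),
                )
                taxonomy = result.taxonomy
                decided[key] = result.category_id
        cid = decided[key]
        if cid is None:
            continue
        taxonomy = widen_valence(taxonomy, cid, item.polarity)
        accepted.append(
            LabeledUtterance(item.utterance, cid, item.polarity, "human")
        )
    return taxonomy, accepted


def reconcile_valences(
    taxonomy: Taxonomy, samples: Sequence[LabeledUtterance]
) -> Taxonomy:
    """Widen category valences so every reviewed sample's polarity is legal."""
    for s in samples:
        if s.category_id in taxonomy:
            taxonomy = widen_valence(taxonomy, s.category_id, s.polarity)
    return taxonomy


@dataclass
class CampaignConfig:
    """Conditions of a simulated training campaign."""

    classifier: ClassifierConfig = field(default_factory=ClassifierConfig)
    noise: NoiseSettings = DEFAULT_NOISE
    initial_per_pair: int = 6  # researcher-synthesized utterances per seed pair
    reason_cap: int = 10
    exception_cap: int = 3  # probes per session kept short at campaign scale


@dataclass
class CampaignResult:
    reports: list[RoundReport]
    model: ClassifierModel
    taxonomy: Taxonomy
    corpus: list[LabeledUtterance]
    transcripts: list[Transcript]
    # the model/taxonomy pair that was live in each round, aligned with
    # ``reports`` — needed to replay that round's transcripts exactly
    live_models: list[ClassifierModel] = field(default_factory=list)
    live_taxonomies: list[Taxonomy] = field(default_factory=list)


def run_campaign(
    groups: Sequence[Sequence[Persona]],
    seed: int = 0,
    taxonomy: Taxonomy | None = None,
    base_corpus: Sequence[LabeledUtterance] | None = None,
    config: CampaignConfig | None = None,
    grammar: UtteranceGrammar | None = None,
    policy: str | ReviewPolicy = "auto",
) -> CampaignResult:
    """Run the full train → converse → review → retrain loop over groups.

    Each round trains from scratch on the cumulative corpus, runs every
    persona session against the live model, ingests the annotations, applies
    the review policy, and emits a :class:`RoundReport`. Deterministic for a
    fixed (groups, seed, config).
    """
    if not groups:
        raise ValueError("campaign needs at least one group")
    for i, g in enumerate(groups):
        if not g:
            raise ValueError(f"group {i + 1} has zero sessions")
    config = config or CampaignConfig()
    grammar = grammar or UtteranceGrammar.load()
    taxonomy = taxonomy if taxonomy is not None else load_seed_taxonomy()
    if base_corpus is None:
        base_corpus = generate_corpus(
            taxonomy,
            config.initial_per_pair,
            noise=config.noise,
            seed=seed,
            source="fixture",
            grammar=grammar,
        )
    corpus: list[LabeledUtterance] = list(base_corpus)

    reports: list[RoundReport] = []
    transcripts: list[Transcript] = []
    live_models: list[ClassifierModel] = []
    live_taxonomies: list[Taxonomy] = []
    model = train_classifier(corpus, taxonomy, config.classifier, seed=seed)
    for g, personas in enumerate(groups, start=1):
        live_models.append(model)
        live_taxonomies.append(taxonomy)
        tag = f"tfidf-lr-r{g:02d}"
        engine = ConversationEngine(
            taxonomy,
            model,
            mode="training",
            seed=seed + g,
            reason_cap=config.reason_cap,
            exception_cap=config.exception_cap,
        )
        corpus_before = len(corpus)
        categories_before = len(taxonomy)
        batch = [
            simulate_session(
                persona, engine, grammar=grammar, session_id=f"g{g:02d}s{i:02d}"
            )
            for i, persona in enumerate(personas, start=1)
        ]
        transcripts.extend(batch)
        result = ingest(batch, group_index=g)
        try:
            metrics = micro_metrics(result.counts)
            precision, recall, f1 = metrics.precision, metrics.recall, metrics.f1
        except UndefinedMetricError:
            precision = recall = f1 = 0.0
        taxonomy, proposal_samples = apply_reviews(result.review_queue, taxonomy, policy)
        new_samples = result.samples + proposal_samples
        taxonomy = reconcile_valences(taxonomy, new_samples)
        corpus.extend(new_samples)
        model = train_classifier(corpus, taxonomy, config.classifier, seed=seed)
        reports.append(
            RoundReport(
                group_index=g,
                classifier_tag=tag,
                precision=precision,
                recall=recall,
                f1=f1,
                corpus_before=corpus_before,
                corpus_after=len(corpus),
                categories_before=categories_before,
                categories_after=len(taxonomy),
            )
        )
    return CampaignResult(reports, model, taxonomy, corpus, transcripts,
                          live_models, live_taxonomies)


# ---------------------------------------------------------------------------
# Feedback-label arithmetic

def percentage(count: int, total: int, decimals: int = 1) -> float:
    """Share of ``count`` in ``total`` as a percentage, rounded for display
    (1 decimal place by default, matching how rates are reported)."""
    if total <= 0:
        raise ValueError("total must be positive")
    return round(100.0 * count / total, decimals)


def feedback_label_census(
    transcripts: Sequence[Transcript],
) -> dict[str, tuple[int, float]]:
    """Counts and percentages of the four mutually inclusive feedback labels
    over all sessions (the denominator is every session, answered or not)."""
    total = len(transcripts)
    out: dict[str, tuple[int, float]] = {}
    for label in ("improvement", "enjoyment", "benefit", "frustration"):
        n = sum(1 for t in transcripts if label in t.feedback_labels)
        out[label] = (n, percentage(n, total) if total else 0.0)
    return out
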