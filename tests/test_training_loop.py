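"""Ingest, review policy, and the iterative retraining campaign."""

import pytest

import mibot
from mibot.dialogue import ConversationEngine, run_session
from mibot.simulator import ZERO_NOISE, NoiseSettings, generate_campaign
from mibot.training_loop import (
    CampaignConfig,
    ReviewItem,
    apply_reviews,
    feedback_label_census,
    ingest,
    percentage,
    run_campaign,
)

BOX4_TURNS = [
    "yes", "I do",
    "Helps me to bond with other smokers and socialize", "Right",
    "I like the way the smoke tastes", "Wrong", "Other", "Flavor",
    "no", "yes",
    "yellow fingers", "Wrong", "Physical Appearance",
    "nothing else", "yes",
]


@pytest.fixture
def box4_transcript(full_taxonomy, stub_classifier):
    clf = stub_classifier({
        "Helps me to bond with other smokers and socialize": "social",
        "I like the way the smoke tastes": "feel_good",
        "yellow fingers": "health",
    })
    engine = ConversationEngine(full_taxonomy, clf, mode="training", seed=7)
    return run_session(engine, BOX4_TURNS, seed=7)


class TestIngest:
    def test_worked_example_yields_one_of_each_kind(self, box4_transcript):
        result = ingest([box4_transcript])
        kinds = sorted(i.kind for i in result.review_queue)
        assert kinds == ["confirmation", "correction", "new_category_proposal"]
        confirmation = next(i for i in result.review_queue
                            if i.kind == "confirmation")
        assert confirmation.corrected_id == "social"
        proposal = next(i for i in result.review_queue
                        if i.kind == "new_category_proposal")
        assert proposal.proposal_name == "Flavor"
        correction = next(i for i in result.review_queue if i.kind == "correction")
        assert (correction.predicted_id, correction.corrected_id) == (
            "health", "physical_appearance")
        # live tallies: confirmation=TP, correction+rejected-detection=FP
        assert (result.counts.tp, result.counts.fp, result.counts.fn) == (1, 2, 0)

    def test_empty_transcript_set(self):
        result = ingest([])
        assert result.samples == [] and result.review_queue == []
        assert result.counts.total == 0

    def test_intervention_transcript_rejected(self, full_taxonomy, stub_classifier):
        engine = ConversationEngine(full_taxonomy, stub_classifier({}),
                                    mode="intervention", seed=1)
        transcript = run_session(engine, ["yes", "I do", "whatever", "no"], seed=1)
        with pytest.raises(ValueError, match="intervention"):
            ingest([transcript])

    def test_tallies_match_planted_annotation_mix(
        self, seed_taxonomy, full_model
    ):
        """Simulated sessions with a noiseless population: the live tallies
        must equal what the planted outcomes imply (every annotation is one
        of TP, FP, FN exactly once)."""
        groups = generate_campaign(seed_taxonomy, 1, 10, noise=ZERO_NOISE, seed=3)
        engine = ConversationEngine(seed_taxonomy, full_model, mode="training")
        transcripts = [mibot.simulate_session(p, engine) for p in groups[0]]
        result = ingest(transcripts)
        planted = sum(
            1 for t in transcripts for turn in t.turns
            if turn.annotations and turn.annotations["outcome"] in
            ("confirmation", "correction", "abstained", "new_category_proposal")
        )
        assert result.counts.total == planted


class TestApplyReviews:
    def _proposal(self, name, polarity="pro", utterance="x"):
        return ReviewItem("new_category_proposal", utterance, polarity,
                          proposal_name=name)

    def test_novel_proposal_creates_category_with_templates(self, seed_taxonomy):
        grown, samples = apply_reviews([self._proposal("Flavor")], seed_taxonomy)
        assert "flavor" in grown
        cat = grown.get("flavor")
        assert cat.provenance == "grown"
        assert cat.reflection_templates["pro"]
        assert [s.category_id for s in samples] == ["flavor"]

    def test_synonym_proposal_merges(self, seed_taxonomy):
        grown, samples = apply_reviews(
            [self._proposal("stress relief", utterance="it relieves stress")],
            seed_taxonomy,
        )
        assert len(grown) == len(seed_taxonomy)
        assert samples[0].category_id == "stress"

    def test_duplicate_proposals_create_single_category(self, seed_taxonomy):
        queue = [self._proposal("boredom relief"), self._proposal("Boredom relief")]
        grown, samples = apply_reviews(queue, seed_taxonomy)
        assert len(grown) == len(seed_taxonomy)  # merges into boredom via alias
        assert len(samples) == 2
        assert {s.category_id for s in samples} == {"boredom"}

    def test_opposite_polarity_proposal_widens_valence(self, seed_taxonomy):
        grown, _ = apply_reviews([self._proposal("bored", polarity="con")],
                                 seed_taxonomy)
        assert grown.get("boredom").valence == "both"

    def test_interactive_policy_can_reject(self, seed_taxonomy):
        def policy(item, taxonomy):
            return None

        grown, samples = apply_reviews([self._proposal("Vaping")], seed_taxonomy,
                                       policy=policy)
        assert grown == seed_taxonomy and samples == []


@pytest.fixture(scope="module")
def small_campaign(seed_taxonomy):
    groups = generate_campaign(seed_taxonomy, 3, 4, seed=17)
    return run_campaign(groups, seed=17, taxonomy=seed_taxonomy,
                        config=CampaignConfig())


class TestCampaign:
    def test_one_report_per_group(self, small_campaign):
        assert len(small_campaign.reports) == 3
        assert [r.group_index for r in small_campaign.reports] == [1, 2, 3]

    def test_corpus_and_categories_grow_monotonically(self, small_campaign):
        for r in small_campaign.reports:
            assert r.corpus_after >= r.corpus_before
            assert r.categories_after >= r.categories_before
        for a, b in zip(small_campaign.reports, small_campaign.reports[1:]):
            assert b.corpus_before == a.corpus_after
            assert b.categories_before == a.categories_after

    def test_metrics_are_rates(self, small_campaign):
        for r in small_campaign.reports:
            assert 0.0 <= r.precision <= 1.0
            assert 0.0 <= r.recall <= 1.0
            assert 0.0 <= r.f1 <= 1.0

    def test_final_model_covers_grown_taxonomy(self, small_campaign):
        grown_ids = set(small_campaign.taxonomy.ids())
        assert set(small_campaign.model.labels) <= grown_ids
        assert len(grown_ids) > 10  # some novel categories accepted

    def test_campaign_is_deterministic(self, seed_taxonomy, small_campaign):
        groups = generate_campaign(seed_taxonomy, 3, 4, seed=17)
        again = run_campaign(groups, seed=17, taxonomy=seed_taxonomy,
                             config=CampaignConfig())
        assert again.reports == small_campaign.reports

    def test_single_group_campaign(self, seed_taxonomy):
        groups = generate_campaign(seed_taxonomy, 1, 2, seed=2)
        result = run_campaign(groups, seed=2, taxonomy=seed_taxonomy)
        assert len(result.reports) == 1

    def test_empty_group_rejected(self, seed_taxonomy):
        with pytest.raises(ValueError, match="zero sessions"):
            run_campaign([[]], seed=0, taxonomy=seed_taxonomy)

    def test_every_correction_relabels_exactly_one_sample(self, small_campaign):
        """Each correction contributes one sample whose label differs from
        the live prediction it corrects."""
        corrections = [
            turn.annotations
            for t in small_campaign.transcripts
            for turn in t.turns
            if turn.annotations and turn.annotations["outcome"] == "correction"
        ]
        texts = {s.text: s.category_id for s in small_campaign.corpus}
        for ann in corrections:
            assert ann["category_id"] != ann["predicted_id"]
            assert texts.get(ann["utterance"]) == ann["category_id"]


class TestFeedbackArithmetic:
    def test_percentage_matches_reported_rates(self):
        assert percentage(42, 121) == 34.7
        assert percentage(10, 121) == 8.3
        assert percentage(3, 121) == 2.5
        assert percentage(93, 121) == 76.9

    def test_percentage_requires_positive_total(self):
        with pytest.raises(ValueError):
            percentage(1, 0)

    def test_census_counts_mutually_inclusive_labels(self, seed_taxonomy,
                                                     full_model):
        groups = generate_campaign(seed_taxonomy, 1, 6, seed=4)
        engine = ConversationEngine(seed_taxonomy, full_model, mode="training")
        transcripts = [mibot.simulate_session(p, engine) for p in groups[0]]
        census = feedback_label_census(transcripts)
        assert set(census) == {"improvement", "enjoyment", "benefit", "frustration"}
        for label, (count, pct) in census.items():
            assert 0 <= count <= len(transcripts)
            assert pct == percentage(count, len(transcripts))
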