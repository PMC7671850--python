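"""Conversation-engine behavior: flow, reflections, summaries, replay."""

import pytest

import mibot
from mibot.dialogue import (
    BAD_QUESTION,
    GOOD_QUESTION,
    ConversationEngine,
    DialogueError,
    exception_questions,
    order_sections,
    parse_yes_no,
    replay_transcript,
    run_session,
)
from mibot.nlu import Prediction


@pytest.fixture
def box2_engine(full_taxonomy, stub_classifier):
    """Intervention-mode engine with the labels of the running-head-start
    worked example pinned: kill-time → distraction, relaxing → stress."""
    clf = stub_classifier({
        "It is a great way to kill some time between tasks": "distraction",
        "it is relaxing when doing somehthing stressful": "stress",
    })
    return ConversationEngine(full_taxonomy, clf, mode="intervention", seed=7)


@pytest.fixture
def box4_engine(full_taxonomy, stub_classifier):
    """Training-mode engine covering confirm / correct / new-category paths."""
    clf = stub_classifier({
        "Helps me to bond with other smokers and socialize": "social",
        "I like the way the smoke tastes": "feel_good",
        "yellow fingers": "health",
    })
    return ConversationEngine(full_taxonomy, clf, mode="training", seed=7)


class TestPrimitives:
    @pytest.mark.parametrize(
        "text, expected",
        [
            ("I do", "yes"),
            ("Yes.", "yes"),
            ("Right", "yes"),
            ("Wrong", "no"),
            ("not really", "no"),
            ("banana", "unknown"),
        ],
    )
    def test_parse_yes_no(self, text, expected):
        assert parse_yes_no(text) == expected

    def test_order_sections_follows_sentiment(self):
        assert order_sections("positive") == (GOOD_QUESTION, BAD_QUESTION)
        assert order_sections("negative") == (BAD_QUESTION, GOOD_QUESTION)
        with pytest.raises(ValueError):
            order_sections("unknown")

    def test_exception_questions_three_prompts_fixed_order(self, full_taxonomy):
        prompts = exception_questions(full_taxonomy, "stress", "pro")
        assert len(prompts) == 3
        assert prompts[0] == ("Please describe a time when you experienced "
                              "stress and ended up smoking.")
        assert "didn't end up smoking" in prompts[1]
        assert "What made it different" in prompts[2]

    def test_exception_questions_unknown_category(self, full_taxonomy):
        with pytest.raises(DialogueError):
            exception_questions(full_taxonomy, "vaping", "pro")


class TestSessionOpening:
    def test_opening_contains_purpose_and_permission(self, box2_engine):
        _, lines = box2_engine.start_session()
        assert len(lines) == 2
        assert "purpose" in lines[0] or "chatbot" in lines[0].lower()
        assert "continue" in lines[1]

    def test_same_seed_gives_identical_opening(self, box2_engine):
        _, a = box2_engine.start_session(seed=5)
        _, b = box2_engine.start_session(seed=5)
        assert a == b

    def test_missing_templates_rejected(self, full_taxonomy, stub_classifier):
        with pytest.raises(DialogueError, match="purpose"):
            ConversationEngine(full_taxonomy, stub_classifier({}),
                               templates={"permission": ["x"]})

    def test_sentiment_resolved_before_sections(self, box2_engine):
        state, _ = box2_engine.start_session()
        state, lines = box2_engine.step(state, "yes")
        assert lines == ["Do you like to smoke?"]
        assert state.sentiment == "unknown"  # not yet resolved
        state, lines = box2_engine.step(state, "I do")
        assert state.sentiment == "positive"
        assert lines == [GOOD_QUESTION]

    def test_unknown_sentiment_reasks_then_defaults_good_first(self, box2_engine):
        state, _ = box2_engine.start_session()
        state, _ = box2_engine.step(state, "yes")
        state, lines = box2_engine.step(state, "hmm")
        assert "like to smoke" in lines[0]
        state, lines = box2_engine.step(state, "hmm again")
        assert lines == [GOOD_QUESTION]
        assert any("default" in entry for entry in state.log)


def drive(engine, turns, seed=7):
    return run_session(engine, turns, seed=seed)


BOX2_TURNS = [
    "yes",  # permission
    "I do",  # likes smoking -> good first
    "It is a great way to kill some time between tasks",
    "it is relaxing when doing somehthing stressful",
    "nothing else",
    "yes",  # summary correct
]


class TestRunningHeadStart:
    def test_box2_sequence_reflection_summary_transition(
        self, box2_engine, full_taxonomy
    ):
        transcript = drive(box2_engine, BOX2_TURNS)
        bot = transcript.bot_texts()
        i_q = bot.index(GOOD_QUESTION)
        # reflection after each reason, in order, category-specific
        distraction_pro = full_taxonomy.get("distraction").reflection_templates["pro"]
        stress_pro = full_taxonomy.get("stress").reflection_templates["pro"]
        assert bot[i_q + 1] in distraction_pro
        assert bot[i_q + 3] in stress_pro
        # grouped summary with verbatim quotes, one line per category
        summary = [l for l in bot if l.startswith("You said")]
        assert len(summary) == 2
        assert "'It is a great way to kill some time between tasks'" in summary[0]
        assert "distraction" in summary[0]
        assert "'it is relaxing when doing somehthing stressful'" in summary[1]
        assert "stress" in summary[1]
        check = bot.index("Did I summarize everything back correctly?")
        assert check > bot.index(summary[1])
        # then the transition into the con section
        assert any("bad things about smoking" in l or l == BAD_QUESTION
                   for l in bot[check + 1:])

    def test_multiple_same_category_reasons_summarized_in_one_line(
        self, full_taxonomy, stub_classifier
    ):
        clf = stub_classifier({"calms nerves": "stress",
                               "relieves stress": "stress"})
        engine = ConversationEngine(full_taxonomy, clf, mode="intervention", seed=3)
        transcript = drive(engine, ["yes", "I do", "calms nerves",
                                    "relieves stress", "no", "yes"])
        summary = [l for l in transcript.bot_texts() if l.startswith("You said")]
        assert len(summary) == 1
        assert "'calms nerves'" in summary[0] and "'relieves stress'" in summary[0]

    def test_empty_section_skips_summary(self, box2_engine):
        transcript = drive(box2_engine, ["yes", "I do", "nothing"])
        bot = transcript.bot_texts()
        assert not any(l.startswith("You said") for l in bot)
        assert any("bad things" in l or l == BAD_QUESTION for l in bot)

    def test_negative_sentiment_asks_bad_first(self, box2_engine):
        transcript = drive(box2_engine, ["yes", "not really"])
        assert BAD_QUESTION in transcript.bot_texts()
        assert GOOD_QUESTION not in transcript.bot_texts()

    def test_verbatim_conservation_across_summaries(self, box2_engine):
        transcript = drive(box2_engine, BOX2_TURNS)
        bot = "\n".join(transcript.bot_texts())
        for reason in BOX2_TURNS[2:4]:
            assert bot.count(f"'{reason}'") == 1


BOX4_TURNS = [
    "yes",
    "I do",
    "Helps me to bond with other smokers and socialize",
    "Right",  # confirm social
    "I like the way the smoke tastes",
    "Wrong",  # reject feel-good
    "Other",
    "Flavor",  # teach a new category
    "no",  # end of pros
    "yes",  # summary fine
    "yellow fingers",
    "Wrong",  # reject health
    "Physical Appearance",  # correct from the option list
    "nothing else",
    "yes",
]


class TestTrainingMode:
    def test_box4_confirm_correct_and_new_category_branches(self, box4_engine):
        transcript = drive(box4_engine, BOX4_TURNS)
        bot = transcript.bot_texts()
        assert any(l.startswith("I understood 'Helps me to bond") or
                   l.startswith("You said 'Helps me to bond") for l in bot)
        assert "Am I right?" in bot
        assert any("confirm" in l.lower() for l in bot)  # thank-you line
        assert any(l.startswith("Is it one of the following options?")
                   for l in bot)
        assert "Can you please tell me what it is in one or two words?" in bot
        assert "Thank you for teaching me something new!" in bot

    def test_box4_annotations_record_outcomes(self, box4_engine):
        transcript = drive(box4_engine, BOX4_TURNS)
        outcomes = [t.annotations["outcome"] for t in transcript.turns
                    if t.annotations]
        assert outcomes == ["confirmation", "new_category_proposal", "correction"]
        correction = [t.annotations for t in transcript.turns
                      if t.annotations and t.annotations["outcome"] == "correction"][0]
        assert correction["predicted_id"] == "health"
        assert correction["category_id"] == "physical_appearance"

    def test_abstention_goes_straight_to_option_list(self, box4_engine):
        transcript = drive(box4_engine,
                           ["yes", "I do", "mystery reason", "Stress"])
        bot = transcript.bot_texts()
        assert any("not sure I understood" in l for l in bot)
        ann = [t.annotations for t in transcript.turns if t.annotations][0]
        assert ann["outcome"] == "abstained"
        assert ann["category_id"] == "stress"

    def test_unknown_confirmation_reasks_once_then_skips(self, box4_engine):
        transcript = drive(
            box4_engine,
            ["yes", "I do", "Helps me to bond with other smokers and socialize",
             "maybe", "perhaps"],
        )
        ann = [t.annotations for t in transcript.turns if t.annotations][0]
        assert ann["outcome"] == "unconfirmed"
        assert sum("yes or no" in l for l in transcript.bot_texts()) == 1

    def test_exception_protocol_three_prompts_per_confirmed_reason(
        self, box4_engine
    ):
        turns = [
            "yes", "I do",
            "Helps me to bond with other smokers and socialize", "Right",
            "no", "yes",  # pros done
            "yellow fingers", "Wrong", "Physical Appearance",
            "nothing else", "yes",  # cons done
            "answer 1", "answer 2", "answer 3",  # social probes
            "answer 4", "answer 5", "answer 6",  # appearance probes
            "make it friendlier",  # feedback
        ]
        transcript = drive(box4_engine, turns)
        bot = transcript.bot_texts()
        q1 = [l for l in bot if "and ended up smoking" in l]
        q2 = [l for l in bot if "didn't end up smoking" in l]
        q3 = [l for l in bot if "What made it different" in l]
        assert len(q1) == len(q2) == len(q3) == 2
        assert "social" in q1[0] and "physical appearance" in q1[1]
        # feedback question ends the session
        assert any(l.startswith("Before you finish the study") for l in bot)
        assert transcript.feedback_text == "make it friendlier"

    def test_reason_cap_closes_section(self, full_taxonomy, stub_classifier):
        clf = stub_classifier({f"reason {i}": "stress" for i in range(15)})
        engine = ConversationEngine(full_taxonomy, clf, mode="intervention",
                                    seed=1, reason_cap=10)
        turns = ["yes", "I do"] + [f"reason {i}" for i in range(12)]
        transcript = run_session(engine, turns, seed=1)
        stored = sum(len(f"'reason {i}'" in l for l in []) for i in range(0))
        # count stored reasons via the single grouped summary line
        summary = [l for l in transcript.bot_texts() if l.startswith("You said")]
        assert len(summary) == 1
        assert sum(f"'reason {i}'" in summary[0] for i in range(12)) == 10

    def test_summary_denial_relists_options_once(self, box4_engine):
        turns = ["yes", "I do",
                 "Helps me to bond with other smokers and socialize", "Right",
                 "no", "no"]  # deny the summary
        transcript = drive(box4_engine, turns)
        fixes = [l for l in transcript.bot_texts() if l.startswith("Sorry about that")]
        assert len(fixes) == 1
        assert "Helps me to bond" in fixes[0]


class TestReflection:
    def test_reflect_uses_category_polarity_templates(self, box2_engine):
        state, _ = box2_engine.start_session()
        state.current_polarity = "pro"
        lines = box2_engine.reflect(
            state, "it is relaxing", Prediction("detected", "stress", 0.9)
        )
        assert len(lines) == 1 and "stress" in lines[0]

    def test_consecutive_reflections_vary_template(self, box2_engine):
        state, _ = box2_engine.start_session()
        state.current_polarity = "pro"
        pred = Prediction("detected", "stress", 0.9)
        seen = {box2_engine.reflect(state, "a", pred)[0] for _ in range(6)}
        assert len(seen) >= 2
        history = [box2_engine.reflect(state, "x", pred)[0] for _ in range(8)]
        assert all(a != b for a, b in zip(history, history[1:]))

    def test_single_template_reuse_is_flagged(self, full_taxonomy, stub_classifier):
        import dataclasses
        cat = full_taxonomy.get("stress")
        slim = dataclasses.replace(
            cat, reflection_templates={"pro": ("only one stress line",),
                                       "con": cat.reflection_templates["con"]})
        tax = mibot.Taxonomy(
            tuple(slim if c.id == "stress" else c for c in full_taxonomy.categories),
            version=full_taxonomy.version,
        )
        engine = ConversationEngine(tax, stub_classifier({}), mode="intervention")
        state, _ = engine.start_session()
        state.current_polarity = "pro"
        pred = Prediction("detected", "stress", 0.9)
        a = engine.reflect(state, "x", pred)
        b = engine.reflect(state, "y", pred)
        assert a == b
        assert any("single-template reuse" in entry for entry in state.log)

    def test_missing_polarity_template_raises(self, box2_engine):
        state, _ = box2_engine.start_session()
        with pytest.raises(DialogueError, match="template"):
            box2_engine.reflect(state, "x", Prediction("detected", "boredom", 0.9),
                                polarity="con")


class TestReplay:
    def test_replay_reproduces_bot_turns_byte_identically(self, box4_engine):
        transcript = drive(box4_engine, BOX4_TURNS)
        _, ok = replay_transcript(box4_engine, transcript)
        assert ok

    def test_different_seeds_may_vary_but_each_replays(self, box2_engine):
        t1 = drive(box2_engine, BOX2_TURNS, seed=1)
        t2 = drive(box2_engine, BOX2_TURNS, seed=2)
        _, ok1 = replay_transcript(box2_engine, t1)
        _, ok2 = replay_transcript(box2_engine, t2)
        assert ok1 and ok2
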