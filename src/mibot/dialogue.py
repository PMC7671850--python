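"""The conversation engine: a seeded, replayable MI-style dialogue state machine.

The conversation runs in three stages. The *introduction* states the bot's
purpose and asks permission. The *reflection* stage is the core: a running
head start (``Do you like to smoke?`` then, ordered by the answer's sentiment,
``What is good about smoking?`` / ``What is bad about smoking?``), per-reason
reflections, a per-category verbatim summary for each section, and three
exception-case questions per confirmed reason (a time it led to smoking, a
time it did not, and what made the difference). The *ending* stage asks the
free-form feedback question and closes.

Two modes share the machine. In ``training`` mode every detection is read
back (``Am I right?``) so the user confirms, corrects from a category option
list, or names a new category — the interactions that produce labeled data
and taxonomy growth. In ``intervention`` mode the bot reflects directly and
never asks for labels.

All randomness (template variation) flows from a per-session seed held in the
state, so replaying the same user turns against the same seed reproduces the
bot turns byte for byte.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path
from typing import Callable, Iterable, Sequence

import numpy as np
import yaml

from .nlu import Prediction, normalize_text
from .taxonomy import Category, Taxonomy

TEMPLATES_SCHEMA = "mibot-templates/1"

MODES = ("training", "intervention")
FEEDBACK_LABELS = ("improvement", "enjoyment", "benefit", "frustration")

GOOD_QUESTION = "What is good about smoking?"
BAD_QUESTION = "What is bad about smoking?"

_YES = {
    "yes", "y", "yeah", "yep", "yup", "sure", "ok", "okay", "definitely",
    "absolutely", "right", "correct", "true", "i do", "yes i do", "of course",
    "indeed", "i think so", "that s right", "i like it",
}
_NO = {
    "no", "n", "nope", "nah", "wrong", "incorrect", "false", "not really",
    "i don t", "i do not", "no i don t", "never", "that s wrong",
}
_SECTION_STOP = {
    "no", "nothing", "nothing else", "that s all", "that is all", "nope",
    "none", "no more", "that s it", "done", "nothing more",
    "i can t think of anything", "i can t think of any", "not that i can think of",
}


class DialogueError(RuntimeError):
    """Raised on engine misconfiguration (missing templates, bad category)."""


def load_templates(path: str | Path | None = None) -> dict[str, list[str]]:
    """Load the bot's scripted response variants, keyed by response type."""
    if path is None:
        text = resources.files("mibot.data").joinpath("templates.yaml").read_text(
            encoding="utf-8"
        )
    else:
        text = Path(path).read_text(encoding="utf-8")
    doc = yaml.safe_load(text)
    if not isinstance(doc, dict) or doc.get("schema") != TEMPLATES_SCHEMA:
        raise DialogueError(f"unsupported templates file (expected {TEMPLATES_SCHEMA})")
    return {k: list(v) for k, v in doc["responses"].items()}


def parse_yes_no(text: str) -> str:
    """Classify a short reply as ``yes``, ``no``, or ``unknown``.

    Lexicon-based and punctuation-insensitive ("Yes." == "Yes"); "Right" and
    "Wrong" count as yes/no so confirmation answers parse directly.
    """
    tokens = normalize_text(text)
    phrase = " ".join(tokens)
    if phrase in _YES:
        return "yes"
    if phrase in _NO:
        return "no"
    if tokens and tokens[0] in ("yes", "yeah", "yep", "yup"):
        return "yes"
    if tokens and tokens[0] in ("no", "nope", "nah"):
        return "no"
    return "unknown"


def is_section_stop(text: str) -> bool:
    return " ".join(normalize_text(text)) in _SECTION_STOP


def order_sections(sentiment: str) -> tuple[str, str]:
    """Order the good/bad questions by the user's sentiment toward smoking."""
    if sentiment == "positive":
        return GOOD_QUESTION, BAD_QUESTION
    if sentiment == "negative":
        return BAD_QUESTION, GOOD_QUESTION
    raise ValueError(f"sentiment must be resolved, got {sentiment!r}")


def exception_questions(
    taxonomy: Taxonomy, category_id: str, polarity: str
) -> tuple[str, str, str]:
    """The three exception-case prompts for a confirmed reason.

    Fixed order: positive case (experienced it and smoked), negative case
    (experienced it and did not smoke), difference reflection.
    """
    if category_id not in taxonomy:
        raise DialogueError(f"unknown category {category_id!r}")
    if polarity not in ("pro", "con"):
        raise ValueError(f"polarity must be pro or con, got {polarity!r}")
    phrase = taxonomy.get(category_id).phrase
    templates = load_templates()
    return (
        templates["exception_q1"][0].format(phrase=phrase),
        templates["exception_q2"][0].format(phrase=phrase),
        templates["exception_q3"][0].format(phrase=phrase),
    )


# ---------------------------------------------------------------------------
# State

@dataclass
class CollectedReason:
    """One user-offered reason, stored verbatim with its labeling outcome."""

    utterance: str  # byte-identical to user input
    polarity: str
    category_id: str | None = None
    confirmed: bool = False
    outcome: str | None = None  # confirmation | correction | new_category_proposal
    #                             | abstained | unconfirmed | reflected | acknowledged
    predicted_id: str | None = None
    proposal_name: str | None = None


@dataclass
class PendingReason:
    utterance: str
    prediction: Prediction
    polarity: str
    reasks: int = 0


@dataclass
class ConversationState:
    """The dialogue's single source of truth, mutated in place by ``step``."""

    mode: str
    seed: int
    stage: str = "introduction"
    sub_state: str = "intro_permission"
    sentiment: str = "unknown"
    current_polarity: str = "pro"
    first_polarity: str = "pro"
    section_index: int = 0
    collected: dict[str, list[CollectedReason]] = field(
        default_factory=lambda: {"pro": [], "con": []}
    )
    pending: PendingReason | None = None
    exception_queue: list[CollectedReason] = field(default_factory=list)
    eq_reason: int = 0
    eq_question: int = 0
    exception_answers: list[tuple[str, int, str]] = field(default_factory=list)
    templates_used: dict[str, int] = field(default_factory=dict)
    sentiment_reasks: int = 0
    feedback_text: str | None = None
    last_annotation: dict | None = None
    log: list[str] = field(default_factory=list)
    rng: np.random.Generator = field(default_factory=np.random.default_rng)

    @property
    def done(self) -> bool:
        return self.sub_state == "done"

    def all_reasons(self) -> list[CollectedReason]:
        return [r for pol in ("pro", "con") for r in self.collected[pol]]


@dataclass
class Turn:
    speaker: str  # "bot" | "user"
    text: str
    t: int
    annotations: dict | None = None


@dataclass
class Transcript:
    session_id: str
    seed: int
    mode: str
    turns: list[Turn] = field(default_factory=list)
    feedback_text: str | None = None
    feedback_labels: tuple[str, ...] = ()

    def bot_texts(self) -> list[str]:
        return [t.text for t in self.turns if t.speaker == "bot"]

    def user_texts(self) -> list[str]:
        return [t.text for t in self.turns if t.speaker == "user"]


# ---------------------------------------------------------------------------
# Engine

class ConversationEngine:
    """Drives one conversation; stateless across sessions except for config."""

    def __init__(
        self,
        taxonomy: Taxonomy,
        classifier: Callable[[str], Prediction],
        templates: dict[str, list[str]] | None = None,
        mode: str = "training",
        seed: int = 0,
        reason_cap: int = 10,
        exception_cap: int = 10,
    ) -> None:
        if mode not in MODES:
            raise ValueError(f"mode must be one of {MODES}")
        self.taxonomy = taxonomy
        self.classifier = classifier
        self.templates = templates if templates is not None else load_templates()
        for required in ("purpose", "permission", "like_smoke", "feedback_q"):
            if not self.templates.get(required):
                raise DialogueError(f"templates missing response type {required!r}")
        self.mode = mode
        self.seed = seed
        self.reason_cap = reason_cap
        self.exception_cap = exception_cap

    # -- session lifecycle --------------------------------------------------

    def start_session(
        self, seed: int | None = None
    ) -> tuple[ConversationState, list[str]]:
        """Open a session: purpose statement plus permission request."""
        seed = self.seed if seed is None else seed
        state = ConversationState(
            mode=self.mode, seed=seed, rng=np.random.default_rng(seed)
        )
        lines = [self._say(state, "purpose"), self._say(state, "permission")]
        return state, lines

    def step(self, state: ConversationState, text: str) -> tuple[ConversationState, list[str]]:
        """Total transition function: consume one user turn, emit bot turns."""
        state.last_annotation = None
        handler = {
            "intro_permission": self._on_permission,
            "ask_like_smoke": self._on_like_smoke,
            "collect_reasons": self._on_reason,
            "confirm_label": self._on_confirm_label,
            "correct_label": self._on_correct_label,
            "name_new_category": self._on_new_name,
            "confirm_summary": self._on_confirm_summary,
            "exception": self._on_exception_answer,
            "feedback": self._on_feedback,
            "done": lambda s, t: [],
        }[state.sub_state]
        return state, handler(state, text)

    # -- response selection -------------------------------------------------

    def _pick(self, state: ConversationState, key: str, options: Sequence[str]) -> str:
        """Seeded random choice that never repeats the previous template id
        for the same response type (degenerate single-template sets repeat,
        flagged in the state log)."""
        if not options:
            raise DialogueError(f"no templates for response type {key!r}")
        last = state.templates_used.get(key)
        if len(options) == 1:
            idx = 0
            if last == 0:
                state.log.append(f"single-template reuse: {key}")
        else:
            candidates = [i for i in range(len(options)) if i != last]
            idx = int(state.rng.choice(candidates))
        state.templates_used[key] = idx
        return options[idx]

    def _say(self, state: ConversationState, rtype: str, **kw) -> str:
        return self._pick(state, rtype, self.templates[rtype]).format(**kw)

    def reflect(
        self,
        state: ConversationState,
        utterance: str,
        prediction: Prediction,
        polarity: str | None = None,
    ) -> list[str]:
        """A category- and polarity-specific reflective-listening response."""
        if not prediction.detected:
            raise DialogueError("reflect requires a detected prediction")
        cat = self.taxonomy.get(prediction.category_id)
        pol = polarity or state.current_polarity
        templates = cat.reflection_templates.get(pol)
        if not templates and polarity is None:
            # live fallback: predicted category does not allow the section's
            # polarity; speak its own polarity instead
            pol = cat.allowed_polarities[0]
            templates = cat.reflection_templates.get(pol)
        if not templates:
            raise DialogueError(
                f"category {cat.id!r} has no reflection template for {pol!r}"
            )
        line = self._pick(state, f"reflect:{cat.id}:{pol}", templates)
        return [line.format(phrase=cat.phrase)]

    # -- introduction -------------------------------------------------------

    def _on_permission(self, state: ConversationState, text: str) -> list[str]:
        answer = parse_yes_no(text)
        if answer == "no":
            state.stage = "ending"
            state.sub_state = "feedback"
            return [self._say(state, "decline_end"), self._say(state, "feedback_q")]
        if answer == "unknown" and state.sentiment_reasks == 0:
            state.sentiment_reasks += 1
            return [self._say(state, "permission")]
        state.sentiment_reasks = 0
        state.stage = "reflection"
        state.sub_state = "ask_like_smoke"
        return [self._say(state, "like_smoke")]

    def _on_like_smoke(self, state: ConversationState, text: str) -> list[str]:
        answer = parse_yes_no(text)
        if answer == "unknown":
            if state.sentiment_reasks == 0:
                state.sentiment_reasks += 1
                return [self._say(state, "sentiment_reask")]
            state.log.append("sentiment unresolved after re-ask; defaulting positive")
            answer = "yes"
        state.sentiment = "positive" if answer == "yes" else "negative"
        first_q, _ = order_sections(state.sentiment)
        state.first_polarity = "pro" if first_q == GOOD_QUESTION else "con"
        state.current_polarity = state.first_polarity
        state.section_index = 0
        state.sub_state = "collect_reasons"
        return [first_q]

    # -- reason collection --------------------------------------------------

    def _on_reason(self, state: ConversationState, text: str) -> list[str]:
        if is_section_stop(text):
            return self._close_section(state)
        stored = state.collected[state.current_polarity]
        if len(stored) >= self.reason_cap:
            state.log.append("reason cap reached; closing section")
            return [self._say(state, "cap_reached")] + self._close_section(state)
        prediction = self.classifier(text)
        if prediction.detected and prediction.category_id not in self.taxonomy:
            # a classifier must only speak its taxonomy's labels; treat any
            # stray prediction as an abstention rather than crash mid-dialogue
            state.log.append(
                f"prediction {prediction.category_id!r} outside taxonomy; abstaining"
            )
            prediction = Prediction("abstained", None, prediction.confidence)
        state.pending = PendingReason(text, prediction, state.current_polarity)
        if self.mode == "intervention":
            return self._intervention_reason(state)
        if prediction.detected:
            name = self.taxonomy.get(prediction.category_id).display_name
            state.sub_state = "confirm_label"
            return [
                self._say(state, "understood", utterance=text, name=name),
                self._say(state, "am_i_right"),
            ]
        state.sub_state = "correct_label"
        return [self._say(state, "abstain_options", options=self._option_list())]

    def _intervention_reason(self, state: ConversationState) -> list[str]:
        pending = state.pending
        state.pending = None
        if pending.prediction.detected:
            entry = CollectedReason(
                utterance=pending.utterance,
                polarity=pending.polarity,
                category_id=pending.prediction.category_id,
                confirmed=False,
                outcome="reflected",
                predicted_id=pending.prediction.category_id,
            )
            lines = self.reflect(state, pending.utterance, pending.prediction)
        else:
            entry = CollectedReason(
                utterance=pending.utterance,
                polarity=pending.polarity,
                outcome="acknowledged",
            )
            lines = [self._say(state, "generic_reflection")]
        state.collected[pending.polarity].append(entry)
        return lines + [self._what_else(state)]

    def _what_else(self, state: ConversationState) -> str:
        key = "what_else_pro" if state.current_polarity == "pro" else "what_else_con"
        return self._say(state, key)

    def _option_list(self) -> str:
        return ", ".join(c.display_name for c in self.taxonomy.categories)

    def _store(
        self, state: ConversationState, entry: CollectedReason
    ) -> None:
        state.collected[entry.polarity].append(entry)
        state.last_annotation = {
            "outcome": entry.outcome,
            "polarity": entry.polarity,
            "utterance": entry.utterance,
            "predicted_id": entry.predicted_id,
            "category_id": entry.category_id,
            "proposal_name": entry.proposal_name,
        }

    def _on_confirm_label(self, state: ConversationState, text: str) -> list[str]:
        pending = state.pending
        answer = parse_yes_no(text)
        if answer == "yes":
            state.pending = None
            state.sub_state = "collect_reasons"
            entry = CollectedReason(
                utterance=pending.utterance,
                polarity=pending.polarity,
                category_id=pending.prediction.category_id,
                confirmed=True,
                outcome="confirmation",
                predicted_id=pending.prediction.category_id,
            )
            self._store(state, entry)
            return (
                [self._say(state, "thanks_confirm")]
                + self.reflect(state, pending.utterance, pending.prediction)
                + [self._what_else(state)]
            )
        if answer == "no":
            state.sub_state = "correct_label"
            return [self._say(state, "options", options=self._option_list())]
        if pending.reasks == 0:
            pending.reasks += 1
            return [self._say(state, "confirm_reask")]
        return self._skip_pending(state)

    def _skip_pending(self, state: ConversationState) -> list[str]:
        pending = state.pending
        state.pending = None
        state.sub_state = "collect_reasons"
        entry = CollectedReason(
            utterance=pending.utterance,
            polarity=pending.polarity,
            outcome="unconfirmed",
            predicted_id=pending.prediction.category_id,
        )
        self._store(state, entry)
        return [self._say(state, "skip_label"), self._what_else(state)]

    def _on_correct_label(self, state: ConversationState, text: str) -> list[str]:
        pending = state.pending
        if " ".join(normalize_text(text)) == "other":
            state.sub_state = "name_new_category"
            return [self._say(state, "ask_new_name")]
        match = self.taxonomy.find_by_name(text)
        if match is not None:
            state.pending = None
            state.sub_state = "collect_reasons"
            outcome = "abstained" if pending.prediction.abstained else "correction"
            entry = CollectedReason(
                utterance=pending.utterance,
                polarity=pending.polarity,
                category_id=match.id,
                confirmed=True,
                outcome=outcome,
                predicted_id=pending.prediction.category_id,
            )
            self._store(state, entry)
            corrected = Prediction("detected", match.id, 1.0)
            return self.reflect(state, pending.utterance, corrected) + [
                self._what_else(state)
            ]
        if pending.reasks == 0:
            pending.reasks += 1
            return [self._say(state, "options_reask", options=self._option_list())]
        return self._skip_pending(state)

    def _on_new_name(self, state: ConversationState, text: str) -> list[str]:
        pending = state.pending
        name = text.strip()
        if not normalize_text(name):
            if pending.reasks == 0:
                pending.reasks += 1
                return [self._say(state, "ask_new_name")]
            return self._skip_pending(state)
        state.pending = None
        state.sub_state = "collect_reasons"
        entry = CollectedReason(
            utterance=pending.utterance,
            polarity=pending.polarity,
            outcome="new_category_proposal",
            predicted_id=pending.prediction.category_id,
            proposal_name=name,
        )
        self._store(state, entry)
        return [self._say(state, "thanks_new"), self._what_else(state)]

    # -- summaries ----------------------------------------------------------

    def summarize_section(self, state: ConversationState) -> list[str]:
        """One summary line per distinct category, quoting every stored
        utterance of that category verbatim."""
        entries = state.collected[state.current_polarity]
        groups: dict[str, list[CollectedReason]] = {}
        order: list[str] = []
        for entry in entries:
            key = entry.category_id or (
                f"proposal:{entry.proposal_name}" if entry.proposal_name else
                f"raw:{id(entry)}"
            )
            if key not in groups:
                groups[key] = []
                order.append(key)
            groups[key].append(entry)
        lines: list[str] = []
        for key in order:
            members = groups[key]
            if key.startswith("raw:"):
                lines.append(
                    self._say(
                        state, "summary_uncategorized", utterance=members[0].utterance
                    )
                )
                continue
            if key.startswith("proposal:"):
                name = members[0].proposal_name
            else:
                name = self.taxonomy.get(key).display_name.lower()
            if len(members) == 1:
                lines.append(
                    self._say(
                        state,
                        "summary_single",
                        utterance=members[0].utterance,
                        name=name,
                    )
                )
            else:
                quoted = ", and ".join(f"'{m.utterance}'" for m in members)
                lines.append(
                    self._say(state, "summary_multi", utterances=quoted, name=name)
                )
        return lines

    def _close_section(self, state: ConversationState) -> list[str]:
        lines = self.summarize_section(state)
        if not lines:
            return self._advance_section(state)
        state.sub_state = "confirm_summary"
        return lines + [self._say(state, "summary_check")]

    def _on_confirm_summary(self, state: ConversationState, text: str) -> list[str]:
        lines: list[str] = []
        if parse_yes_no(text) == "no":
            # re-list the options once per stored reason, then move on
            options = self._option_list()
            for entry in state.collected[state.current_polarity]:
                name = (
                    self.taxonomy.get(entry.category_id).display_name.lower()
                    if entry.category_id
                    else (entry.proposal_name or "something I couldn't place")
                )
                lines.append(
                    self._say(
                        state,
                        "summary_fix",
                        utterance=entry.utterance,
                        name=name,
                        options=options,
                    )
                )
        return lines + self._advance_section(state)

    def _advance_section(self, state: ConversationState) -> list[str]:
        if state.section_index == 0:
            state.section_index = 1
            state.current_polarity = "con" if state.first_polarity == "pro" else "pro"
            state.sub_state = "collect_reasons"
            transition = (
                "transition_to_con"
                if state.current_polarity == "con"
                else "transition_to_pro"
            )
            question = GOOD_QUESTION if state.current_polarity == "pro" else BAD_QUESTION
            return [self._say(state, transition), question]
        return self._start_exceptions(state)

    # -- exception-case questions -------------------------------------------

    def _start_exceptions(self, state: ConversationState) -> list[str]:
        queue = [
            r
            for r in state.all_reasons()
            if r.confirmed and r.category_id is not None
        ][: self.exception_cap]
        state.exception_queue = queue
        state.eq_reason = 0
        state.eq_question = 0
        if not queue:
            state.stage = "ending"
            state.sub_state = "feedback"
            return [self._say(state, "feedback_q")]
        state.sub_state = "exception"
        return [
            self._say(state, "exception_intro"),
            self._exception_prompt(state),
        ]

    def _exception_prompt(self, state: ConversationState) -> str:
        reason = state.exception_queue[state.eq_reason]
        phrase = self.taxonomy.get(reason.category_id).phrase
        key = ("exception_q1", "exception_q2", "exception_q3")[state.eq_question]
        return self._say(state, key, phrase=phrase)

    def _on_exception_answer(self, state: ConversationState, text: str) -> list[str]:
        state.exception_answers.append((
            state.exception_queue[state.eq_reason].category_id,
            state.eq_question,
            text,
        ))
        state.eq_question += 1
        if state.eq_question < 3:
            return [self._exception_prompt(state)]
        state.eq_question = 0
        state.eq_reason += 1
        ack = self._say(state, "exception_ack")
        if state.eq_reason < len(state.exception_queue):
            return [ack, self._exception_prompt(state)]
        state.stage = "ending"
        state.sub_state = "feedback"
        return [ack, self._say(state, "feedback_q")]

    # -- ending -------------------------------------------------------------

    def _on_feedback(self, state: ConversationState, text: str) -> list[str]:
        state.feedback_text = text
        state.sub_state = "done"
        return [self._say(state, "ending")]


# ---------------------------------------------------------------------------
# Session running and replay

def run_session(
    engine: ConversationEngine,
    responder: Iterable[str] | Callable[[ConversationState, list[str]], str],
    session_id: str = "session",
    seed: int | None = None,
    max_steps: int = 400,
) -> Transcript:
    """Drive a full session, recording a transcript.

    ``responder`` is either an iterable of scripted user turns (the session
    stops when it is exhausted) or a callable ``(state, last_bot_lines) ->
    text`` such as a simulated persona.
    """
    if callable(responder):
        ask = responder
    else:
        it = iter(responder)

        def ask(_state, _lines):  # noqa: ANN001
            return next(it)

    state, lines = engine.start_session(seed=seed)
    transcript = Transcript(
        session_id=session_id, seed=state.seed, mode=engine.mode
    )
    t = 0
    for line in lines:
        transcript.turns.append(Turn("bot", line, t))
        t += 1
    steps = 0
    while not state.done and steps < max_steps:
        try:
            text = ask(state, lines)
        except StopIteration:
            break
        user_turn = Turn("user", text, t)
        t += 1
        transcript.turns.append(user_turn)
        state, lines = engine.step(state, text)
        if state.last_annotation is not None:
            user_turn.annotations = dict(state.last_annotation)
        for line in lines:
            transcript.turns.append(Turn("bot", line, t))
            t += 1
        steps += 1
    transcript.feedback_text = state.feedback_text
    return transcript


def replay_transcript(
    engine: ConversationEngine, transcript: Transcript
) -> tuple[Transcript, bool]:
    """Re-drive a transcript's user turns through a fresh session with the
    same seed; returns the regenerated transcript and whether the bot turns
    match byte for byte."""
    replayed = run_session(
        engine,
        transcript.user_texts(),
        session_id=transcript.session_id,
        seed=transcript.seed,
    )
    return replayed, replayed.bot_texts() == transcript.bot_texts()
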