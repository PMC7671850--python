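"""Synthetic smokers: personas, utterance generation, sessions, campaigns.

The simulator stands in for recruited participants so the full
train → converse → review → retrain loop runs with no external data. A
:class:`Persona` holds a sentiment toward smoking, a list of reasons drawn
with the observed per-category frequencies of the study population, and noise
rates (typos, wrong confirmations, novel out-of-taxonomy reasons). The
:class:`UtteranceGrammar` composes category-specific content stems with
neutral filler frames into free-form utterances; because each category's
stems share distinctive vocabulary, grammar output is (by design) separable
by a text classifier — the separability is audited in the test suite rather
than assumed.

What the generator emulates: single-category pro/con utterances at realistic
relative frequencies, yes/no answers, confirmations and corrections with a
small error rate, typo artifacts, and the gradual introduction of novel
reason categories across recruitment groups. What it does not emulate:
compound multi-reason utterances, topic drift, sarcasm, or dropout.
"""

from __future__ import annotations

from dataclasses import dataclass
from importlib import resources
from pathlib import Path
from typing import Sequence

import numpy as np
import yaml

from .dialogue import ConversationEngine, ConversationState, Transcript, run_session
from .nlu import LabeledUtterance
from .taxonomy import Taxonomy, load_full_taxonomy

GRAMMAR_SCHEMA = "mibot-grammar/1"


@dataclass(frozen=True)
class NoiseSettings:
    """Noise dials for the synthetic population (all rates in [0, 1])."""

    typo_rate: float = 0.01  # per-character substitution/deletion probability
    confirm_error_rate: float = 0.02  # probability of answering a confirmation wrongly

    def __post_init__(self) -> None:
        for name in ("typo_rate", "confirm_error_rate"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name} must be in [0, 1], got {v}")


DEFAULT_NOISE = NoiseSettings()
ZERO_NOISE = NoiseSettings(typo_rate=0.0, confirm_error_rate=0.0)


class GrammarError(ValueError):
    """A category lacks paraphrase frames for a requested polarity."""


class UtteranceGrammar:
    """Stem-and-frame paraphrase generator keyed by (category id, polarity)."""

    def __init__(self, doc: dict) -> None:
        if doc.get("schema") != GRAMMAR_SCHEMA:
            raise GrammarError(f"unsupported grammar schema (want {GRAMMAR_SCHEMA})")
        self.frames: list[str] = list(doc["frames"])
        self.stems: dict[str, dict[str, list[str]]] = {
            cat: {pol: list(ss) for pol, ss in pols.items()}
            for cat, pols in doc["stems"].items()
        }
        self.exception_answers: dict[str, list[str]] = {
            k: list(v) for k, v in doc["exception_answers"].items()
        }
        self.feedback_pool: list[tuple[str, tuple[str, ...]]] = [
            (item["text"], tuple(item.get("labels", ())))
            for item in doc["feedback"]
        ]

    @classmethod
    def load(cls, path: str | Path | None = None) -> "UtteranceGrammar":
        if path is None:
            text = resources.files("mibot.data").joinpath("grammar.yaml").read_text(
                encoding="utf-8"
            )
        else:
            text = Path(path).read_text(encoding="utf-8")
        return cls(yaml.safe_load(text))

    def has(self, category_id: str, polarity: str) -> bool:
        return bool(self.stems.get(category_id, {}).get(polarity))

    def generate(
        self,
        category_id: str,
        polarity: str,
        rng: np.random.Generator,
        typo_rate: float = 0.0,
    ) -> str:
        """One utterance expressing the category at the given polarity."""
        stems = self.stems.get(category_id, {}).get(polarity)
        if not stems:
            raise GrammarError(
                f"no grammar stems for category {category_id!r} polarity {polarity!r}"
            )
        stem = stems[int(rng.integers(len(stems)))]
        frame = self.frames[int(rng.integers(len(self.frames)))]
        return apply_typos(frame.format(stem=stem), rng, typo_rate)

    def exception_answer(
        self, kind: str, phrase: str, rng: np.random.Generator
    ) -> str:
        pool = self.exception_answers[kind]
        return pool[int(rng.integers(len(pool)))].format(phrase=phrase)

    def feedback(self, rng: np.random.Generator) -> tuple[str, tuple[str, ...]]:
        return self.feedback_pool[int(rng.integers(len(self.feedback_pool)))]


_TYPO_ALPHABET = "abcdefghijklmnopqrstuvwxyz"


def apply_typos(text: str, rng: np.random.Generator, rate: float) -> str:
    """Per-character substitution/deletion noise, mimicking real typing slips."""
    if rate <= 0.0:
        return text
    out: list[str] = []
    for ch in text:
        if rng.random() < rate:
            if rng.random() < 0.5:
                continue  # deletion
            out.append(_TYPO_ALPHABET[int(rng.integers(26))])
        else:
            out.append(ch)
    return "".join(out)


# ---------------------------------------------------------------------------
# Personas

@dataclass(frozen=True)
class Persona:
    """A synthetic participant."""

    seed: int
    sentiment: str  # "positive" | "negative"
    reasons: tuple[tuple[str, str], ...]  # (category_id, polarity), in offer order
    verbosity: float = 12.0  # mean tokens per utterance (grammar-bound, informational)
    typo_rate: float = DEFAULT_NOISE.typo_rate
    confirm_error_rate: float = DEFAULT_NOISE.confirm_error_rate
    novel_reason_rate: float = 0.0
    novel_reasons: tuple[tuple[str, str, str], ...] = ()  # (category_id, polarity, name)

    def __post_init__(self) -> None:
        pols = {pol for _, pol in self.reasons} | {
            pol for _, pol, _ in self.novel_reasons
        }
        if not {"pro", "con"} <= pols:
            raise ValueError("persona must hold at least one pro and one con reason")


def _weights_table(taxonomy: Taxonomy) -> dict[str, dict[str, int]]:
    """Observed-count sampling weights (falls back to the full fixture's
    counts for ids the given taxonomy lacks metadata for)."""
    full = load_full_taxonomy()
    table: dict[str, dict[str, int]] = {}
    for cat in full.categories:
        table[cat.id] = dict(cat.observed_count)
    for cat in taxonomy.categories:
        if cat.observed_count:
            table.setdefault(cat.id, dict(cat.observed_count))
    return table


def _sample_reasons(
    rng: np.random.Generator,
    available: Sequence[str],
    weights: dict[str, dict[str, int]],
    grammar: UtteranceGrammar,
    n_reasons: int,
) -> list[tuple[str, str]]:
    pairs = [
        (cid, pol)
        for cid in available
        for pol in ("pro", "con")
        if weights.get(cid, {}).get(pol, 0) > 0 and grammar.has(cid, pol)
    ]
    w = np.array([weights[c][p] for c, p in pairs], dtype=float)

    def draw(mask: np.ndarray) -> tuple[str, str]:
        p = w * mask
        p = p / p.sum()
        return pairs[int(rng.choice(len(pairs), p=p))]

    pro_mask = np.array([1.0 if p == "pro" else 0.0 for _, p in pairs])
    con_mask = 1.0 - pro_mask
    chosen = [draw(pro_mask), draw(con_mask)]  # ambivalence: >=1 of each
    while len(chosen) < n_reasons:
        mask = np.array([0.0 if pr in chosen else 1.0 for pr in pairs])
        if mask.sum() == 0:
            break
        pick = draw(mask)
        chosen.append(pick)
    order = rng.permutation(len(chosen))
    return [chosen[int(i)] for i in order]


def make_persona(
    rng: np.random.Generator,
    available: Sequence[str],
    grammar: UtteranceGrammar,
    weights: dict[str, dict[str, int]],
    noise: NoiseSettings = DEFAULT_NOISE,
    novel: Sequence[tuple[str, str, str]] = (),
    reasons_range: tuple[int, int] = (2, 5),
) -> Persona:
    """Draw one persona: sentiment 50/50, 2–5 weighted reasons, noise rates."""
    seed = int(rng.integers(2**31 - 1))
    sentiment = "positive" if rng.random() < 0.5 else "negative"
    lo, hi = reasons_range
    n_reasons = int(rng.integers(lo, hi + 1))
    reasons = _sample_reasons(rng, available, weights, grammar, n_reasons)
    return Persona(
        seed=seed,
        sentiment=sentiment,
        reasons=tuple(reasons),
        typo_rate=noise.typo_rate,
        confirm_error_rate=noise.confirm_error_rate,
        novel_reason_rate=1.0 if novel else 0.0,
        novel_reasons=tuple(novel),
    )


# ---------------------------------------------------------------------------
# Corpus generation

def generate_corpus(
    taxonomy: Taxonomy,
    n_per_category: int,
    noise: NoiseSettings = ZERO_NOISE,
    seed: int = 0,
    source: str = "synthetic",
    grammar: UtteranceGrammar | None = None,
) -> list[LabeledUtterance]:
    """Exactly ``n_per_category`` utterances per (category, allowed polarity).

    Labels are generator ground truth; deterministic per seed.
    """
    if n_per_category < 1:
        raise ValueError("n_per_category must be >= 1")
    grammar = grammar or UtteranceGrammar.load()
    rng = np.random.default_rng(seed)
    corpus: list[LabeledUtterance] = []
    for cat in taxonomy.categories:
        for pol in cat.allowed_polarities:
            if not grammar.has(cat.id, pol):
                raise GrammarError(
                    f"taxonomy category {cat.id!r} ({pol}) has no grammar frames"
                )
            for _ in range(n_per_category):
                text = grammar.generate(cat.id, pol, rng, noise.typo_rate)
                corpus.append(LabeledUtterance(text, cat.id, pol, source))
    return corpus


# ---------------------------------------------------------------------------
# Session simulation

class PersonaResponder:
    """Callable user policy driving a training-mode engine as the persona."""

    def __init__(
        self,
        persona: Persona,
        engine: ConversationEngine,
        grammar: UtteranceGrammar | None = None,
        rng: np.random.Generator | None = None,
    ) -> None:
        self.persona = persona
        self.engine = engine
        self.grammar = grammar or UtteranceGrammar.load()
        self.rng = rng if rng is not None else np.random.default_rng(
            [persona.seed, 7]
        )
        queues: dict[str, list[tuple[str, str, str | None]]] = {"pro": [], "con": []}
        for cid, pol in persona.reasons:
            queues[pol].append((cid, pol, None))
        for cid, pol, name in persona.novel_reasons:
            queues[pol].append((cid, pol, name))
        self.queues = queues
        self.current: tuple[str, str, str | None] | None = None
        self.feedback_text, self.feedback_labels = self.grammar.feedback(self.rng)

    def _stop_phrase(self) -> str:
        pool = ["no", "nothing else", "that's all", "nope"]
        return pool[int(self.rng.integers(len(pool)))]

    def __call__(self, state: ConversationState, _lines: list[str]) -> str:
        sub = state.sub_state
        if sub == "intro_permission":
            return "yes"
        if sub == "ask_like_smoke":
            return "I do" if self.persona.sentiment == "positive" else "not really"
        if sub == "collect_reasons":
            queue = self.queues[state.current_polarity]
            if not queue:
                self.current = None
                return self._stop_phrase()
            self.current = queue.pop(0)
            cid, pol, _name = self.current
            return self.grammar.generate(cid, pol, self.rng, self.persona.typo_rate)
        if sub == "confirm_label":
            true_id = self.current[0]
            predicted = state.pending.prediction.category_id
            correct = predicted == true_id
            if self.rng.random() < self.persona.confirm_error_rate:
                correct = not correct  # user slip: wrong confirmation either way
            return "Right" if correct else "Wrong"
        if sub == "correct_label":
            cid, _pol, name = self.current
            if name is None and cid in self.engine.taxonomy:
                return self.engine.taxonomy.get(cid).display_name
            return "Other"
        if sub == "name_new_category":
            name = self.current[2]
            return name if name else "Something else"
        if sub == "confirm_summary":
            return "yes"
        if sub == "exception":
            kind = ("smoked", "resisted", "difference")[state.eq_question]
            reason = state.exception_queue[state.eq_reason]
            phrase = self.engine.taxonomy.get(reason.category_id).phrase
            return self.grammar.exception_answer(kind, phrase, self.rng)
        if sub == "feedback":
            return self.feedback_text
        return "ok"


def simulate_session(
    persona: Persona,
    engine: ConversationEngine,
    seed: int | None = None,
    grammar: UtteranceGrammar | None = None,
    session_id: str = "sim",
) -> Transcript:
    """Run one full persona-driven session and return its transcript."""
    if engine.mode != "training":
        raise ValueError("simulate_session drives a training-mode engine")
    responder = PersonaResponder(persona, engine, grammar)
    transcript = run_session(
        engine,
        responder,
        session_id=session_id,
        seed=persona.seed if seed is None else seed,
    )
    transcript.feedback_labels = responder.feedback_labels
    return transcript


# ---------------------------------------------------------------------------
# Campaign generation

def _novel_schedule(novel_ids: Sequence[str], n_groups: int) -> list[list[str]]:
    """Spread novel-category introductions over the earlier groups, mimicking
    a discovery rate that tapers as the taxonomy saturates."""
    active = max(1, int(np.ceil(0.75 * n_groups)))
    schedule: list[list[str]] = [[] for _ in range(n_groups)]
    for i, cid in enumerate(novel_ids):
        schedule[i % active].append(cid)
    return schedule


def generate_campaign(
    taxonomy_seed: Taxonomy,
    n_groups: int,
    group_size: int,
    noise: NoiseSettings = DEFAULT_NOISE,
    seed: int = 0,
    grammar: UtteranceGrammar | None = None,
    reasons_range: tuple[int, int] = (2, 5),
) -> list[list[Persona]]:
    """Persona batches for an iterative training campaign.

    Across groups the personas collectively introduce every full-fixture
    category missing from the seed taxonomy as a novel reason proposal, so a
    campaign can grow the seed taxonomy to the full category set. Personas in
    later groups draw their ordinary reasons from categories already
    introduced, emulating a population that keeps mentioning known reasons.
    """
    if n_groups < 1:
        raise ValueError("n_groups must be >= 1")
    if group_size < 1:
        raise ValueError("group_size must be >= 1")
    grammar = grammar or UtteranceGrammar.load()
    rng = np.random.default_rng(seed)
    full = load_full_taxonomy()
    weights = _weights_table(taxonomy_seed)
    seed_ids = list(taxonomy_seed.ids())
    novel_ids = [cid for cid in full.ids() if cid not in seed_ids]
    schedule = _novel_schedule(novel_ids, n_groups)

    groups: list[list[Persona]] = []
    introduced: list[str] = []
    for g in range(n_groups):
        available = seed_ids + introduced
        personas: list[Persona] = []
        planted = list(schedule[g])
        n_carriers = min(len(planted), group_size)
        carriers = (
            rng.choice(group_size, size=n_carriers, replace=False)
            if planted
            else np.array([], dtype=int)
        )
        carrier_of: dict[int, list[str]] = {}
        for i, cid in enumerate(planted):
            carrier_of.setdefault(int(carriers[i % n_carriers]), []).append(cid)
        for i in range(group_size):
            novel: list[tuple[str, str, str]] = []
            for cid in carrier_of.get(i, ()):
                cat = full.get(cid)
                pols = [
                    p
                    for p in cat.allowed_polarities
                    if grammar.has(cid, p)
                ]
                wts = np.array(
                    [max(cat.observed_count.get(p, 0), 1) for p in pols], dtype=float
                )
                pol = pols[int(rng.choice(len(pols), p=wts / wts.sum()))]
                novel.append((cid, pol, cat.display_name))
            personas.append(
                make_persona(
                    rng,
                    available,
                    grammar,
                    weights,
                    noise=noise,
                    novel=novel,
                    reasons_range=reasons_range,
                )
            )
        introduced.extend(planted)
        groups.append(personas)
    return groups
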