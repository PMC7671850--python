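"""Drive a training-mode conversation turn by turn and replay it.

The bot runs the MI running head start: it asks for permission, gauges
sentiment ("Do you like to smoke?"), collects pros and cons, reads back its
classification of each reason ("Am I right?"), summarizes each section
verbatim per category, asks three exception-case questions per confirmed
reason, and closes with the feedback question. Replaying the same user turns
with the same seed reproduces the bot turns byte for byte.
"""

from mibot import (
    ConversationEngine,
    load_full_taxonomy,
    replay_transcript,
    run_session,
    train_classifier,
)
from mibot.simulator import ZERO_NOISE, generate_corpus

taxonomy = load_full_taxonomy()
model = train_classifier(
    generate_corpus(taxonomy, 8, noise=ZERO_NOISE, seed=3), taxonomy, seed=0
)
engine = ConversationEngine(taxonomy, model, mode="training", seed=11,
                            exception_cap=1)

user_turns = [
    "yes",
    "I do",
    "it calms my nerves when work gets stressful",
    "Right",
    "nothing else",
    "yes",
    "the cost adds up to a fortune every month",
    "Right",
    "no",
    "yes",
    "deadline week, I was stressed and chain smoked",
    "on holiday I was relaxed around family and never lit up",
    "having company and no deadlines made the difference",
    "it was a thoughtful chat",
]
transcript = run_session(engine, user_turns, seed=11)
for turn in transcript.turns:
    print(f"{turn.speaker:>4}: {turn.text}")

_, identical = replay_transcript(engine, transcript)
print(f"\nreplay with the same seed reproduces all bot turns: {identical}")
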