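"""File formats: JSON Lines transcripts, TSV/JSONL corpora, TSV round reports.

Everything is UTF-8 text with ``\\n`` newlines. Each format carries a schema
tag; reading a file written by a different (e.g. future) schema version fails
loudly with both versions in the message. All writers/readers round-trip
field-for-field.
"""

from __future__ import annotations

import csv
import json
from dataclasses import dataclass
from pathlib import Path
from typing import Sequence

from .dialogue import MODES, Transcript, Turn
from .nlu import LabeledUtterance
from .training_loop import RoundReport

TRANSCRIPT_SCHEMA = "mibot-transcript/1"
CORPUS_SCHEMA = "mibot-corpus/1"
REPORT_SCHEMA = "mibot-rounds/1"

_CORPUS_FIELDS = ("text", "category_id", "polarity", "source")


class SchemaVersionError(ValueError):
    def __init__(self, found: str, expected: str) -> None:
        super().__init__(f"schema version mismatch: file has {found!r}, "
                         f"this build reads {expected!r}")
        self.found = found
        self.expected = expected


def _check_schema(found: str | None, expected: str) -> None:
    if found != expected:
        raise SchemaVersionError(str(found), expected)


# ---------------------------------------------------------------------------
# Transcripts (JSON Lines: one header record, then one record per turn)

def write_transcript(transcript: Transcript, path: str | Path) -> None:
    with Path(path).open("w", encoding="utf-8", newline="\n") as fh:
        _dump_transcript(transcript, fh)


def _dump_transcript(transcript: Transcript, fh) -> None:
    header = {
        "schema": TRANSCRIPT_SCHEMA,
        "session_id": transcript.session_id,
        "seed": transcript.seed,
        "mode": transcript.mode,
        "feedback_text": transcript.feedback_text,
        "feedback_labels": list(transcript.feedback_labels),
    }
    fh.write(json.dumps(header, ensure_ascii=False) + "\n")
    for turn in transcript.turns:
        rec = {"speaker": turn.speaker, "text": turn.text, "t": turn.t}
        if turn.annotations is not None:
            rec["annotations"] = turn.annotations
        fh.write(json.dumps(rec, ensure_ascii=False) + "\n")


def read_transcript(path: str | Path) -> Transcript:
    with Path(path).open("r", encoding="utf-8") as fh:
        lines = [json.loads(line) for line in fh if line.strip()]
    if not lines:
        raise ValueError(f"{path}: empty transcript file")
    header = lines[0]
    _check_schema(header.get("schema"), TRANSCRIPT_SCHEMA)
    turns = [
        Turn(
            speaker=rec["speaker"],
            text=rec["text"],
            t=rec["t"],
            annotations=rec.get("annotations"),
        )
        for rec in lines[1:]
    ]
    return Transcript(
        session_id=header["session_id"],
        seed=header["seed"],
        mode=header["mode"],
        turns=turns,
        feedback_text=header.get("feedback_text"),
        feedback_labels=tuple(header.get("feedback_labels") or ()),
    )


# ---------------------------------------------------------------------------
# Corpora (TSV with csv quoting — lossless for embedded tabs/quotes/newlines —
# or JSON Lines with the same fields)

def write_corpus_tsv(corpus: Sequence[LabeledUtterance], path: str | Path) -> None:
    with Path(path).open("w", encoding="utf-8", newline="") as fh:
        fh.write(f"# {CORPUS_SCHEMA}\n")
        writer = csv.writer(fh, delimiter="\t", lineterminator="\n")
        writer.writerow(_CORPUS_FIELDS)
        for u in corpus:
            writer.writerow([u.text, u.category_id, u.polarity, u.source])


def read_corpus_tsv(path: str | Path) -> list[LabeledUtterance]:
    with Path(path).open("r", encoding="utf-8", newline="") as fh:
        first = fh.readline().strip()
        _check_schema(first.lstrip("# "), CORPUS_SCHEMA)
        reader = csv.reader(fh, delimiter="\t", lineterminator="\n")
        header = next(reader)
        if tuple(header) != _CORPUS_FIELDS:
            raise ValueError(f"{path}: unexpected corpus columns {header}")
        return [LabeledUtterance(*row) for row in reader]


def write_corpus_jsonl(corpus: Sequence[LabeledUtterance], path: str | Path) -> None:
    with Path(path).open("w", encoding="utf-8", newline="\n") as fh:
        fh.write(json.dumps({"schema": CORPUS_SCHEMA}) + "\n")
        for u in corpus:
            fh.write(
                json.dumps(
                    {
                        "text": u.text,
                        "category_id": u.category_id,
                        "polarity": u.polarity,
                        "source": u.source,
                    },
                    ensure_ascii=False,
                )
                + "\n"
            )


def read_corpus_jsonl(path: str | Path) -> list[LabeledUtterance]:
    with Path(path).open("r", encoding="utf-8") as fh:
        lines = [json.loads(line) for line in fh if line.strip()]
    if not lines:
        raise ValueError(f"{path}: empty corpus file")
    _check_schema(lines[0].get("schema"), CORPUS_SCHEMA)
    return [
        LabeledUtterance(
            rec["text"], rec["category_id"], rec["polarity"], rec.get("source", "human")
        )
        for rec in lines[1:]
    ]


# ---------------------------------------------------------------------------
# Round reports (TSV; human-readable metrics rounded to 2 d.p. live in the
# CLI table — the file keeps full precision)

def write_rounds_tsv(reports: Sequence[RoundReport], path: str | Path) -> None:
    with Path(path).open("w", encoding="utf-8", newline="") as fh:
        fh.write(f"# {REPORT_SCHEMA}\n")
        writer = csv.writer(fh, delimiter="\t", lineterminator="\n")
        writer.writerow(
            [
                "group", "precision", "recall", "f1", "classifier",
                "corpus_before", "corpus_after",
                "categories_before", "categories_after",
            ]
        )
        for r in reports:
            writer.writerow(
                [
                    r.group_index, repr(r.precision), repr(r.recall), repr(r.f1),
                    r.classifier_tag, r.corpus_before, r.corpus_after,
                    r.categories_before, r.categories_after,
                ]
            )


def read_rounds_tsv(path: str | Path) -> list[RoundReport]:
    with Path(path).open("r", encoding="utf-8", newline="") as fh:
        first = fh.readline().strip()
        _check_schema(first.lstrip("# "), REPORT_SCHEMA)
        reader = csv.reader(fh, delimiter="\t", lineterminator="\n")
        next(reader)  # header
        return [
            RoundReport(
                group_index=int(row[0]),
                precision=float(row[1]),
                recall=float(row[2]),
                f1=float(row[3]),
                classifier_tag=row[4],
                corpus_before=int(row[5]),
                corpus_after=int(row[6]),
                categories_before=int(row[7]),
                categories_after=int(row[8]),
            )
            for row in reader
        ]


# ---------------------------------------------------------------------------
# Run configuration

@dataclass(frozen=True)
class RunConfig:
    """Validated settings for a CLI run."""

    mode: str = "training"
    seed: int = 0
    taxonomy_path: Path | None = None
    model_path: Path | None = None
    template_path: Path | None = None
    reason_cap: int = 10
    exception_cap: int = 10
    abstention_threshold: float = 0.5
    out_dir: Path = Path(".")

    def validate(self) -> "RunConfig":
        if self.mode not in MODES:
            raise ValueError(f"mode must be one of {MODES}")
        if not isinstance(self.seed, int):
            raise TypeError("seed must be an integer")
        if not 0.0 <= self.abstention_threshold <= 1.0:
            raise ValueError("abstention threshold must be in [0, 1]")
        for name in ("taxonomy_path", "model_path", "template_path"):
            p = getattr(self, name)
            if p is not None and not Path(p).exists():
                raise FileNotFoundError(f"{name}: {p}")
        return self
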