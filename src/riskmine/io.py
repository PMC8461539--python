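"""Reading and writing the pipeline's on-disk interchange formats.

Messages travel as JSON Lines ({"id", "text", "label"}), gold lexica as CSV
(phrase,category), cue lexica as plain text (one cue per line), configs as
YAML.  Every stage of the pipeline communicates through these files so any
stage can be re-run in isolation.
"""

from __future__ import annotations

import csv
import json
from pathlib import Path
from typing import Iterable, Iterator

__all__ = [
    "Message",
    "read_messages",
    "write_messages",
    "read_gold_lexicon_csv",
    "write_gold_lexicon_csv",
    "read_cue_list",
    "read_jsonl",
    "write_jsonl",
]


class Message(dict):
    """A raw message record: id, text and an optional veracity label."""

    @property
    def id(self) -> str:
        return self["id"]

    @property
    def text(self) -> str:
        return self["text"]

    @property
    def label(self) -> str | None:
        return self.get("label")


def read_jsonl(path) -> Iterator[dict]:
    with open(path) as fh:
        for line in fh:
            line = line.strip()
            if line:
                yield json.loads(line)


def write_jsonl(records: Iterable[dict], path) -> int:
    n = 0
    Path(path).parent.mkdir(parents=True, exist_ok=True)
    with open(path, "w") as fh:
        for rec in records:
            fh.write(json.dumps(rec, sort_keys=True) + "\n")
            n += 1
    return n


def read_messages(path) -> list[Message]:
    return [Message(rec) for rec in read_jsonl(path)]


def write_messages(messages: Iterable[dict], path) -> int:
    return write_jsonl(messages, path)


def read_gold_lexicon_csv(path) -> list[tuple[str, str]]:
    """Read (phrase, category) rows from a gold-lexicon CSV with header."""
    out: list[tuple[str, str]] = []
    with open(path, newline="") as fh:
        for row in csv.DictReader(fh):
            out.append((row["phrase"], row["category"]))
    return out


def write_gold_lexicon_csv(rows: Iterable[tuple[str, str]], path) -> None:
    Path(path).parent.mkdir(parents=True, exist_ok=True)
    with open(path, "w", newline="") as fh:
        writer = csv.writer(fh)
        writer.writerow(["phrase", "category"])
        for phrase, category in rows:
            writer.writerow([phrase, category])


def read_cue_list(path) -> list[str]:
    """Read a causal-cue lexicon: one lower-case cue per line, '#' comments."""
    cues: list[str] = []
    with open(path) as fh:
        for line in fh:
            line = line.strip().lower()
            if line and not line.startswith("#") and line not in cues:
                cues.append(line)
    return cues
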