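"""Data model and file I/O for open-ended questionnaire corpora.

The in-memory containers here are deliberately thin: a survey schema
(the ordered open-ended questions), the free-text responses keyed by
(respondent, question), matched numeric structured-questionnaire scores
(1-10 scale), a word-frequency lexicon for spelling correction, and a
word-embedding table.  Responses are stored verbatim; all preprocessing
happens downstream and is traceable back to the raw text.
"""

from __future__ import annotations

import csv
import io
import json
import warnings
from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "Question",
    "SurveySchema",
    "Response",
    "ResponseSet",
    "StructuredScores",
    "FrequencyLexicon",
    "EmbeddingTable",
    "load_responses",
    "write_responses",
    "load_scores",
    "load_lexicon",
    "load_embeddings",
    "write_embeddings",
]

SOURCES = ("digital", "transcribed")


class CorpusError(ValueError):
    """Raised for schema violations and malformed input files."""


@dataclass(frozen=True)
class Question:
    question_id: str
    prompt: str = ""
    examples: str = ""


@dataclass(frozen=True)
class SurveySchema:
    """Ordered list of open-ended questions; ids unique and non-empty."""

    questions: tuple[Question, ...]

    def __post_init__(self):
        ids = [q.question_id for q in self.questions]
        if any(not i for i in ids):
            raise CorpusError("empty question_id in schema")
        if len(set(ids)) != len(ids):
            raise CorpusError("duplicate question_ids in schema")

    @property
    def question_ids(self) -> tuple[str, ...]:
        return tuple(q.question_id for q in self.questions)

    def __contains__(self, question_id: str) -> bool:
        return question_id in self.question_ids

    @classmethod
    def from_ids(cls, ids) -> "SurveySchema":
        return cls(tuple(Question(i) for i in ids))


@dataclass(frozen=True)
class Response:
    """One verbatim free-text answer.  ``text`` is never preprocessed at rest."""

    respondent_id: str
    question_id: str
    text: str
    source: str = "digital"

    def __post_init__(self):
        if self.source not in SOURCES:
            raise CorpusError(f"unknown source {self.source!r}")

    @property
    def key(self) -> tuple[str, str]:
        return (self.respondent_id, self.question_id)

    @property
    def is_empty(self) -> bool:
        return not self.text.strip()


@dataclass
class ResponseSet:
    schema: SurveySchema
    responses: list[Response] = field(default_factory=list)

    def __post_init__(self):
        seen = set()
        for r in self.responses:
            if r.question_id not in self.schema:
                raise CorpusError(
                    f"response {r.key} references unknown question_id "
                    f"{r.question_id!r}"
                )
            if r.key in seen:
                raise CorpusError(f"duplicate (respondent, question) key {r.key}")
            seen.add(r.key)

    def __len__(self) -> int:
        return len(self.responses)

    def __iter__(self):
        return iter(self.responses)

    def by_question(self, question_id: str) -> list[Response]:
        return [r for r in self.responses if r.question_id == question_id]

    def non_empty(self) -> list[Response]:
        return [r for r in self.responses if not r.is_empty]


@dataclass(frozen=True)
class StructuredScores:
    """Matched closed-ended questionnaire scores for one (respondent, question)."""

    respondent_id: str
    question_id: str
    matched_scores: tuple[float, ...]

    def __post_init__(self):
        for s in self.matched_scores:
            if not (1.0 <= s <= 10.0):
                raise CorpusError(
                    f"score {s} for {(self.respondent_id, self.question_id)} "
                    "outside [1, 10]"
                )


class FrequencyLexicon:
    """word -> count map used as the language model for spelling correction."""

    def __init__(self, entries: dict[str, int]):
        for w, c in entries.items():
            if w != w.lower():
                raise CorpusError(f"lexicon word {w!r} not lowercase")
            if not isinstance(c, int) or c < 1:
                raise CorpusError(f"lexicon count for {w!r} must be a positive int")
        self.entries = dict(entries)

    def __contains__(self, word: str) -> bool:
        return word in self.entries

    def __len__(self) -> int:
        return len(self.entries)

    def frequency(self, word: str) -> int:
        return self.entries.get(word, 0)

    @property
    def alphabet(self) -> str:
        chars = set()
        for w in self.entries:
            chars.update(w)
        return "".join(sorted(chars)) or "abcdefghijklmnopqrstuvwxyz"


class EmbeddingTable:
    """Unit-normalised word vectors of a common dimension."""

    def __init__(self, vectors: dict[str, np.ndarray]):
        if not vectors:
            self.dimension = 0
            self.vectors: dict[str, np.ndarray] = {}
            return
        dims = {len(v) for v in vectors.values()}
        if len(dims) != 1:
            raise CorpusError(f"inconsistent embedding dimensions {sorted(dims)}")
        self.dimension = dims.pop()
        self.vectors = {}
        for w, v in vectors.items():
            v = np.asarray(v, dtype=float)
            n = np.linalg.norm(v)
            if n == 0.0:
                raise CorpusError(f"zero-norm vector for word {w!r}")
            self.vectors[w] = v / n

    def __contains__(self, word: str) -> bool:
        return word in self.vectors

    def __len__(self) -> int:
        return len(self.vectors)

    def __getitem__(self, word: str) -> np.ndarray:
        return self.vectors[word]

    def get(self, word: str):
        return self.vectors.get(word)


# ---------------------------------------------------------------------------
# readers / writers

_RESPONSE_FIELDS = ("respondent_id", "question_id", "text", "source")


def load_responses(path, schema: SurveySchema) -> ResponseSet:
    """Read responses from a UTF-8 CSV (header row) or a JSON array of objects.

    Empty / whitespace-only texts are retained (their ``is_empty`` flag is
    set); duplicate (respondent, question) keys and unknown question ids
    are rejected with an error naming the offending record.
    """
    text = _read_text(path)
    if text.lstrip().startswith("["):
        records = json.loads(text)
    else:
        records = list(csv.DictReader(io.StringIO(text)))
    responses = []
    for i, rec in enumerate(records):
        try:
            responses.append(
                Response(
                    respondent_id=str(rec["respondent_id"]),
                    question_id=str(rec["question_id"]),
                    text=str(rec.get("text") or ""),
                    source=str(rec.get("source") or "digital"),
                )
            )
        except KeyError as e:  # missing column
            raise CorpusError(f"record {i}: missing field {e}") from None
    return ResponseSet(schema, responses)


def write_responses(response_set: ResponseSet, path) -> None:
    """Write a CSV that :func:`load_responses` round-trips byte-identically."""
    with open(path, "w", encoding="utf-8", newline="") as fh:
        writer = csv.DictWriter(fh, fieldnames=_RESPONSE_FIELDS)
        writer.writeheader()
        for r in response_set:
            writer.writerow(
                {
                    "respondent_id": r.respondent_id,
                    "question_id": r.question_id,
                    "text": r.text,
                    "source": r.source,
                }
            )


def load_scores(path, schema: SurveySchema) -> list[StructuredScores]:
    """Read matched structured scores: CSV respondent_id, question_id, score.

    Multiple rows per (respondent, question) accumulate into one
    ``matched_scores`` tuple.  Scores outside [1, 10] raise a range error.
    """
    text = _read_text(path)
    grouped: dict[tuple[str, str], list[float]] = {}
    order: list[tuple[str, str]] = []
    for i, rec in enumerate(csv.DictReader(io.StringIO(text))):
        qid = str(rec["question_id"])
        if qid not in schema:
            raise CorpusError(f"row {i}: unknown question_id {qid!r}")
        try:
            score = float(rec["score"])
        except (TypeError, ValueError):
            raise CorpusError(f"row {i}: non-numeric score {rec.get('score')!r}")
        key = (str(rec["respondent_id"]), qid)
        if key not in grouped:
            grouped[key] = []
            order.append(key)
        grouped[key].append(score)
    return [
        StructuredScores(rid, qid, tuple(grouped[(rid, qid)])) for rid, qid in order
    ]


def load_lexicon(path) -> FrequencyLexicon:
    """Read a plain-text "word count" frequency lexicon (one pair per line)."""
    entries: dict[str, int] = {}
    for ln, line in enumerate(_read_text(path).splitlines(), start=1):
        line = line.strip()
        if not line:
            continue
        parts = line.split()
        if len(parts) != 2:
            raise CorpusError(f"lexicon line {ln}: expected 'word count'")
        word, count = parts[0].lower(), parts[1]
        try:
            n = int(count)
        except ValueError:
            raise CorpusError(f"lexicon line {ln}: non-numeric count {count!r}")
        entries[word] = entries.get(word, 0) + n
    if not entries:
        warnings.warn("empty frequency lexicon", stacklevel=2)
    return FrequencyLexicon(entries)


def load_embeddings(path) -> EmbeddingTable:
    """Read word vectors in word2vec text format.

    First line is ``<vocab_size> <dim>``; each following line is
    ``<word> <v1> ... <vd>``.  Vectors are unit-normalised on load;
    zero vectors and dimension mismatches are rejected.
    """
    lines = _read_text(path).splitlines()
    if not lines:
        raise CorpusError("empty embedding file")
    header = lines[0].split()
    if len(header) != 2:
        raise CorpusError("embedding header must be '<vocab_size> <dim>'")
    _, dim = int(header[0]), int(header[1])
    vectors: dict[str, np.ndarray] = {}
    for ln, line in enumerate(lines[1:], start=2):
        if not line.strip():
            continue
        parts = line.split()
        if len(parts) != dim + 1:
            raise CorpusError(
                f"embedding line {ln}: expected {dim} components, "
                f"got {len(parts) - 1}"
            )
        vectors[parts[0]] = np.array([float(x) for x in parts[1:]])
    return EmbeddingTable(vectors)


def write_embeddings(table: EmbeddingTable, path) -> None:
    with open(path, "w", encoding="utf-8") as fh:
        fh.write(f"{len(table)} {table.dimension}\n")
        for w, v in table.vectors.items():
            fh.write(w + " " + " ".join(f"{x:.8f}" for x in v) + "\n")


def _read_text(path) -> str:
    try:
        with open(path, "r", encoding="utf-8") as fh:
            return fh.read()
    except OSError as e:
        raise CorpusError(f"cannot read {path}: {e}") from e
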