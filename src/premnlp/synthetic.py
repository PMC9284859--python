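"""Ground-truthed synthetic questionnaire corpora, embeddings and typos.

The generator emulates the data regime of short open-ended
patient-experience surveys: very short answers (median 2 tokens,
interquartile range 1-11, capped at 192), a three-class sentiment mix
dominated by positive answers, latent topics planted per
(question x sentiment) stratum as disjoint word lexicons, sentiment
marker words, background noise words, and optional injected spelling
errors.  Every generated answer is tracked in a GroundTruth object so
recovery of sentiment, topics and corrected spellings can be scored
exactly.

Words are synthetic letter-only tokens (no natural-language realism);
a companion embedding generator produces unit vectors in which
same-group words have a controlled expected cosine similarity while
unrelated words are near-orthogonal, standing in for a pretrained
word2vec model.

All randomness flows from a single spec seed through named substreams
(sentiment, topic, length, compose, typo, scores), so each component is
reproducible in isolation.
"""

from __future__ import annotations

import string
from dataclasses import dataclass, field

import numpy as np

from .corpus import (
    EmbeddingTable,
    Response,
    ResponseSet,
    StructuredScores,
    SurveySchema,
)

__all__ = [
    "CorpusSpec",
    "GroundTruth",
    "EmbeddingSpec",
    "generate_corpus",
    "generate_embeddings",
    "corrupt_spelling",
    "generate_scores",
    "benchmark_spec",
    "paper_regime_spec",
]

# discretised log-normal reproducing median 2 / IQR [1, 11] after clamping:
# exp(mu) = 2 and exp(mu + 0.6745 sigma) = 11
LENGTH_MU = float(np.log(2.0))
LENGTH_SIGMA = float(np.log(11.0 / 2.0) / 0.6744897501960817)
LENGTH_CAP = 192

DEFAULT_PROPORTIONS = {
    "positive": 0.62,
    "negative": 0.08,
    "neutral": 0.20,
    "empty": 0.10,
}


def _alpha(n: int) -> str:
    """Deterministic letter-only encoding of an integer (a, b, ..., aa, ...)."""
    letters = string.ascii_lowercase
    out = letters[n % 26]
    n //= 26
    while n:
        out = letters[n % 26] + out
        n //= 26
    return out


@dataclass
class CorpusSpec:
    """Parameters of one synthetic survey corpus.

    Sentiment proportions must sum to 1; topic lexicons within (and
    across) strata are pairwise disjoint by construction so planted
    structure is unambiguous.  ``topic_word_prob`` / ``marker_prob`` /
    ``noise_prob`` govern the token mix after the guaranteed leading
    topic word of each positive/negative answer.

    ``words_per_topic`` defaults to 6, deliberately smaller than the
    10-term window used for topic coherence and descriptors: a
    component that blends two planted lexicons then necessarily shows
    words of both groups among its top ten terms, which is what makes
    the coherence-based choice of k identifiable on planted data.
    """

    schema: SurveySchema
    n_respondents: int = 500
    proportions: dict[str, float] = field(
        default_factory=lambda: dict(DEFAULT_PROPORTIONS)
    )
    topics_per_stratum: int = 4
    words_per_topic: int = 6
    n_marker_words: int = 8
    n_noise_words: int = 40
    topic_word_prob: float = 0.6
    marker_prob: float = 0.15
    noise_prob: float = 0.25
    length_mu: float = LENGTH_MU
    length_sigma: float = LENGTH_SIGMA
    length_cap: int = LENGTH_CAP
    seed: int = 0

    def __post_init__(self):
        total = sum(self.proportions.values())
        if abs(total - 1.0) > 1e-9:
            raise ValueError(f"sentiment proportions sum to {total}, not 1")
        if any(not (0.0 <= p <= 1.0) for p in self.proportions.values()):
            raise ValueError("proportions must lie in [0, 1]")
        mix = self.topic_word_prob + self.marker_prob + self.noise_prob
        if abs(mix - 1.0) > 1e-9:
            raise ValueError("token mix probabilities must sum to 1")
        q3 = int(round(np.exp(self.length_mu + 0.6744897501960817 * self.length_sigma)))
        if self.length_cap < q3:
            raise ValueError("length cap below the upper quartile of the length model")

    # --- deterministic planted vocabularies -------------------------------

    # Distinct planted words are kept at pairwise edit distance >= 3
    # (tripled index letters, three-letter sentiment codes with pairwise
    # distance >= 3), so a single-character typo never lands closer to a
    # different vocabulary word than to its own original.
    _SENT3 = {"positive": "pos", "negative": "neg", "neutral": "ztl"}

    def topic_lexicon(self, question_id: str, sentiment: str, topic: int) -> list[str]:
        qi = list(self.schema.question_ids).index(question_id)
        prefix = f"{_alpha(qi) * 3}{self._SENT3[sentiment]}{_alpha(topic) * 3}"
        return [f"top{prefix}{_alpha(w) * 3}" for w in range(self.words_per_topic)]

    def marker_lexicon(self, sentiment: str) -> list[str]:
        return [
            f"mark{self._SENT3[sentiment]}{_alpha(i) * 3}"
            for i in range(self.n_marker_words)
        ]

    def noise_lexicon(self) -> list[str]:
        return [f"noise{_alpha(i) * 3}" for i in range(self.n_noise_words)]

    def all_true_words(self) -> list[str]:
        words: list[str] = []
        for qid in self.schema.question_ids:
            for sent in ("positive", "negative"):
                for t in range(self.topics_per_stratum):
                    words.extend(self.topic_lexicon(qid, sent, t))
        for sent in ("positive", "negative", "neutral"):
            words.extend(self.marker_lexicon(sent))
        words.extend(self.noise_lexicon())
        return words


@dataclass
class GroundTruth:
    """Planted truth per (respondent, question): sentiment, topic index
    (positive/negative non-empty answers only), and injected typos."""

    sentiment: dict[tuple[str, str], str] = field(default_factory=dict)
    topic: dict[tuple[str, str], int] = field(default_factory=dict)
    typos: list[dict] = field(default_factory=list)


def _substreams(seed: int, names: tuple[str, ...]) -> dict[str, np.random.Generator]:
    children = np.random.SeedSequence(seed).spawn(len(names))
    return {n: np.random.default_rng(s) for n, s in zip(names, children)}


def _draw_length(rng: np.random.Generator, spec: CorpusSpec) -> int:
    raw = np.exp(rng.normal(spec.length_mu, spec.length_sigma))
    return int(np.clip(round(raw), 1, spec.length_cap))


def generate_corpus(spec: CorpusSpec) -> tuple[ResponseSet, GroundTruth]:
    """Generate the corpus and its ground truth, deterministically.

    Each (respondent, question) cell draws a sentiment from the spec
    proportions; non-empty positive/negative answers draw a topic
    uniformly and always start with a word from its lexicon (so every
    planted answer contains at least one topic word), then mix topic,
    marker and noise words up to a log-normal length.  Neutral answers
    mix neutral markers and noise.
    """
    rngs = _substreams(spec.seed, ("sentiment", "topic", "length", "compose"))
    classes = ("positive", "negative", "neutral", "empty")
    probs = np.array([spec.proportions.get(c, 0.0) for c in classes])
    noise = spec.noise_lexicon()
    markers = {s: spec.marker_lexicon(s) for s in ("positive", "negative", "neutral")}

    responses: list[Response] = []
    truth = GroundTruth()
    for ri in range(spec.n_respondents):
        rid = f"r{ri:04d}"
        for qid in spec.schema.question_ids:
            sent = classes[rngs["sentiment"].choice(len(classes), p=probs)]
            key = (rid, qid)
            if sent == "empty":
                truth.sentiment[key] = "empty"
                responses.append(Response(rid, qid, ""))
                continue
            truth.sentiment[key] = sent
            length = _draw_length(rngs["length"], spec)
            rng = rngs["compose"]
            if sent in ("positive", "negative"):
                t = int(rngs["topic"].integers(spec.topics_per_stratum))
                truth.topic[key] = t
                lex = spec.topic_lexicon(qid, sent, t)
                tokens = [lex[rng.integers(len(lex))]]
                mix = np.array(
                    [spec.topic_word_prob, spec.marker_prob, spec.noise_prob]
                )
                for _ in range(length - 1):
                    kind = rng.choice(3, p=mix)
                    pool = (lex, markers[sent], noise)[kind]
                    tokens.append(pool[rng.integers(len(pool))])
            else:
                pool_m, pool_n = markers["neutral"], noise
                tokens = [pool_m[rng.integers(len(pool_m))]]
                for _ in range(length - 1):
                    pool = pool_m if rng.random() < 0.6 else pool_n
                    tokens.append(pool[rng.integers(len(pool))])
            responses.append(Response(rid, qid, " ".join(tokens)))
    return ResponseSet(spec.schema, responses), truth


# ---------------------------------------------------------------------------
# embeddings


@dataclass
class EmbeddingSpec:
    """Synthetic embedding table: same-group words share a centroid.

    Each group gets a random unit centroid; each member is the
    normalised sum of the centroid and isotropic noise scaled so the
    expected pairwise cosine within the group equals
    ``within_group_cosine``.  ``singletons`` get independent random
    unit vectors (mutually near-orthogonal for d >~ 50).
    """

    groups: dict[str, list[str]]
    dimension: int = 50
    within_group_cosine: float = 0.8
    singletons: list[str] = field(default_factory=list)
    seed: int = 0

    def __post_init__(self):
        if self.dimension < 2:
            raise ValueError("dimension must be >= 2")
        if not (0.0 < self.within_group_cosine <= 1.0):
            raise ValueError("within_group_cosine must be in (0, 1]")
        if any(not words for words in self.groups.values()):
            raise ValueError("empty word group")


def generate_embeddings(spec: EmbeddingSpec) -> EmbeddingTable:
    rng = np.random.default_rng(spec.seed)
    d = spec.dimension
    if len(spec.groups) > d:
        import warnings

        warnings.warn(
            f"{len(spec.groups)} groups in dimension {d}: centroids cannot be "
            "near-orthogonal",
            stacklevel=2,
        )
    # noise scale: members m_i = (c + eps*g_i)/|...| give
    # E[cos(m_i, m_j)] ~= 1/(1 + eps^2) for isotropic unit noise
    eps = float(np.sqrt(1.0 / spec.within_group_cosine - 1.0))
    vectors: dict[str, np.ndarray] = {}
    for name in sorted(spec.groups):
        centroid = rng.standard_normal(d)
        centroid /= np.linalg.norm(centroid)
        for w in spec.groups[name]:
            g = rng.standard_normal(d)
            g /= np.linalg.norm(g)
            v = centroid + eps * g
            vectors[w] = v / np.linalg.norm(v)
    for w in spec.singletons:
        v = rng.standard_normal(d)
        vectors[w] = v / np.linalg.norm(v)
    return EmbeddingTable(vectors)


def corpus_embedding_spec(
    spec: CorpusSpec,
    dimension: int = 50,
    within_group_cosine: float = 0.8,
    seed: int | None = None,
) -> EmbeddingSpec:
    """Embedding groups matching a corpus spec: one group per planted
    topic lexicon and per sentiment marker lexicon; noise words are
    singletons."""
    groups: dict[str, list[str]] = {}
    for qid in spec.schema.question_ids:
        for sent in ("positive", "negative"):
            for t in range(spec.topics_per_stratum):
                groups[f"{qid}:{sent}:t{t}"] = spec.topic_lexicon(qid, sent, t)
    for sent in ("positive", "negative", "neutral"):
        groups[f"marker:{sent}"] = spec.marker_lexicon(sent)
    return EmbeddingSpec(
        groups=groups,
        dimension=dimension,
        within_group_cosine=within_group_cosine,
        singletons=spec.noise_lexicon(),
        seed=spec.seed + 1 if seed is None else seed,
    )


# ---------------------------------------------------------------------------
# spelling corruption


def corrupt_spelling(
    responses: ResponseSet, rate: float, seed: int = 0
) -> tuple[ResponseSet, list[dict]]:
    """Corrupt each token independently with one random character edit.

    Every corrupted token is at Levenshtein distance exactly 1 from its
    original (deletion, transposition, substitution or insertion).
    Returns the corrupted corpus and a typo log of
    (doc, position, original, corrupted) records.
    """
    if not (0.0 <= rate <= 1.0):
        raise ValueError("rate must be in [0, 1]")
    rng = np.random.default_rng(seed)
    alphabet = string.ascii_lowercase
    out = []
    log: list[dict] = []
    for r in responses:
        tokens = r.text.split()
        new_tokens = list(tokens)
        for i, tok in enumerate(tokens):
            if rng.random() >= rate:
                continue
            corrupted = _one_edit(tok, rng, alphabet)
            if corrupted == tok:
                continue
            new_tokens[i] = corrupted
            log.append(
                {
                    "doc_key": r.key,
                    "position": i,
                    "original": tok,
                    "corrupted": corrupted,
                }
            )
        out.append(Response(r.respondent_id, r.question_id, " ".join(new_tokens), r.source))
    return ResponseSet(responses.schema, out), log


def _one_edit(tok: str, rng: np.random.Generator, alphabet: str) -> str:
    kinds = ["substitute", "insert"]
    if len(tok) >= 2:
        kinds += ["delete", "transpose"]
    kind = kinds[rng.integers(len(kinds))]
    if kind == "delete":
        i = int(rng.integers(len(tok)))
        return tok[:i] + tok[i + 1 :]
    if kind == "transpose":
        choices = [i for i in range(len(tok) - 1) if tok[i] != tok[i + 1]]
        if not choices:
            return tok
        i = choices[int(rng.integers(len(choices)))]
        return tok[:i] + tok[i + 1] + tok[i] + tok[i + 2 :]
    if kind == "substitute":
        i = int(rng.integers(len(tok)))
        c = alphabet[int(rng.integers(len(alphabet)))]
        if c == tok[i]:
            c = alphabet[(alphabet.index(c) + 1) % len(alphabet)]
        return tok[:i] + c + tok[i + 1 :]
    i = int(rng.integers(len(tok) + 1))
    c = alphabet[int(rng.integers(len(alphabet)))]
    return tok[:i] + c + tok[i:]


# ---------------------------------------------------------------------------
# structured scores


def generate_scores(
    truth: GroundTruth,
    seed: int = 0,
    means: dict[str, float] | None = None,
    sd: float = 1.0,
) -> list[StructuredScores]:
    """Mean-shifted 1-10 structured scores per planted sentiment group,
    for exercising the positive-vs-negative group comparison."""
    means = means or {"positive": 9.5, "neutral": 8.5, "negative": 7.0, "empty": 8.5}
    rng = np.random.default_rng(seed)
    out = []
    for key in sorted(truth.sentiment):
        sent = truth.sentiment[key]
        score = float(np.clip(rng.normal(means[sent], sd), 1.0, 10.0))
        out.append(StructuredScores(key[0], key[1], (round(score, 1),)))
    return out


# ---------------------------------------------------------------------------
# canned specs


def paper_regime_spec(seed: int = 0, n_respondents: int = 500) -> CorpusSpec:
    """Five-question survey with the positive-dominated sentiment mix and
    short-answer length regime of a real open-ended experience survey."""
    schema = SurveySchema.from_ids(["Q1", "Q2", "Q3", "Q4", "Q5"])
    return CorpusSpec(schema=schema, n_respondents=n_respondents, seed=seed)


def benchmark_spec(seed: int = 0, n_respondents: int = 450) -> CorpusSpec:
    """Single-question planted-structure benchmark: 4 topics per stratum
    and roughly 200 documents per sentiment stratum."""
    schema = SurveySchema.from_ids(["Q1"])
    return CorpusSpec(
        schema=schema,
        n_respondents=n_respondents,
        proportions={"positive": 0.45, "negative": 0.45, "neutral": 0.05, "empty": 0.05},
        topics_per_stratum=4,
        seed=seed,
    )
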