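"""Tokenization, Norvig spelling correction, token filtering and TF-IDF.

The preprocessing chain for each answer is: tokenize -> correct spelling
against a frequency lexicon -> lemmatize (pluggable; identity by default)
-> drop non-informative tokens (stopwords, tokens shorter than three
characters, and tokens whose part of speech is not a verb, adverb, noun
or adjective) -> vectorize all 1-3-grams of the kept tokens with TF-IDF.

Every document keeps a per-token provenance trace (raw -> corrected ->
lemma -> kept?) so any matrix cell can be audited back to verbatim text.
"""

from __future__ import annotations

import re
import warnings
from dataclasses import dataclass, field

import numpy as np
import scipy.sparse as sp
from sklearn.feature_extraction.text import TfidfVectorizer

from .corpus import FrequencyLexicon

__all__ = [
    "tokenize",
    "correct_spelling",
    "normalize",
    "build_vector_space",
    "NormalizerConfig",
    "RuleListAnalyzer",
    "TokenizedDoc",
    "VectorSpace",
    "preprocess_corpus",
]

# Unicode word characters except digits and underscore; hyphens split tokens.
_TOKEN_RE = re.compile(r"[^\W\d_]+", re.UNICODE)

DEFAULT_POS_CLASSES = frozenset({"verb", "adverb", "noun", "adjective"})


def tokenize(text: str) -> list[str]:
    """Lowercased, punctuation-stripped word tokens; '' -> []."""
    return _TOKEN_RE.findall(text.lower())


# ---------------------------------------------------------------------------
# Norvig spelling correction


def _edits1(word: str, alphabet: str) -> set[str]:
    splits = [(word[:i], word[i:]) for i in range(len(word) + 1)]
    deletes = [a + b[1:] for a, b in splits if b]
    transposes = [a + b[1] + b[0] + b[2:] for a, b in splits if len(b) > 1]
    substitutes = [a + c + b[1:] for a, b in splits if b for c in alphabet]
    inserts = [a + c + b for a, b in splits for c in alphabet]
    return set(deletes + transposes + substitutes + inserts)


def correct_spelling(token: str, lexicon: FrequencyLexicon) -> str:
    """Norvig single-token correction against a word-frequency lexicon.

    Preference order: the token itself if known, then the most frequent
    known word at edit distance 1, then at edit distance 2, else the
    token unchanged.  Frequency ties break lexicographically so the
    result is deterministic.
    """
    if token in lexicon or not token:
        return token
    alphabet = lexicon.alphabet
    e1 = _edits1(token, alphabet)
    known1 = [w for w in e1 if w in lexicon]
    if known1:
        return _best(known1, lexicon)
    known2 = {w2 for w1 in e1 for w2 in _edits1(w1, alphabet) if w2 in lexicon}
    if known2:
        return _best(known2, lexicon)
    return token


def _best(candidates, lexicon: FrequencyLexicon) -> str:
    # highest frequency wins; frequency ties break lexicographically
    return min(candidates, key=lambda w: (-lexicon.frequency(w), w))


# ---------------------------------------------------------------------------
# lemmatization / POS plugin and filtering


class RuleListAnalyzer:
    """Default lemmatizer/POS plugin: lookup tables with identity fallback.

    ``lemma_rules`` maps token -> lemma; ``pos_rules`` maps lemma -> POS
    tag.  Unlisted tokens lemmatize to themselves and receive
    ``default_pos`` (noun), so with empty rule lists the plugin is a
    no-op that keeps everything.  A model-based tagger (e.g. a Stanza
    adapter) can replace this by implementing ``analyze``.
    """

    name = "rule-list"

    def __init__(self, lemma_rules=None, pos_rules=None, default_pos="noun"):
        self.lemma_rules = dict(lemma_rules or {})
        self.pos_rules = dict(pos_rules or {})
        self.default_pos = default_pos

    def analyze(self, token: str) -> tuple[str, str]:
        lemma = self.lemma_rules.get(token, token)
        return lemma, self.pos_rules.get(lemma, self.default_pos)


@dataclass
class NormalizerConfig:
    stopwords: frozenset[str] = frozenset()
    min_word_length: int = 3
    kept_pos: frozenset[str] = DEFAULT_POS_CLASSES
    plugin: object = field(default_factory=RuleListAnalyzer)

    def __post_init__(self):
        if self.min_word_length < 1:
            raise ValueError("min_word_length must be >= 1")
        if not self.kept_pos:
            raise ValueError("kept_pos must be non-empty")
        self.stopwords = frozenset(self.stopwords)
        self.kept_pos = frozenset(self.kept_pos)


def normalize(tokens: list[str], config: NormalizerConfig) -> list[str]:
    """Lemmatize then drop stopwords, short lemmas and excluded POS classes."""
    kept = []
    for tok in tokens:
        try:
            lemma, pos = config.plugin.analyze(tok)
        except Exception as e:
            name = getattr(config.plugin, "name", type(config.plugin).__name__)
            raise RuntimeError(f"lemmatizer plugin {name!r} failed on {tok!r}: {e}")
        if lemma in config.stopwords:
            continue
        if len(lemma) < config.min_word_length:
            continue
        if pos not in config.kept_pos:
            continue
        kept.append(lemma)
    return kept


# ---------------------------------------------------------------------------
# documents and TF-IDF vector space


@dataclass
class TokenizedDoc:
    doc_key: tuple[str, str]
    raw_tokens: list[str]
    corrected_tokens: list[str]
    kept_tokens: list[str]
    provenance: list[dict] = field(default_factory=list)

    def __post_init__(self):
        if len(self.corrected_tokens) != len(self.raw_tokens):
            raise ValueError("corrected_tokens must align 1:1 with raw_tokens")


def preprocess_doc(
    doc_key,
    text: str,
    lexicon: FrequencyLexicon | None = None,
    config: NormalizerConfig | None = None,
) -> TokenizedDoc:
    """Run the full tokenize/correct/normalize chain on one answer."""
    config = config or NormalizerConfig()
    raw = tokenize(text)
    corrected = [correct_spelling(t, lexicon) if lexicon else t for t in raw]
    provenance = []
    kept = []
    for r, c in zip(raw, corrected):
        lemma, pos = config.plugin.analyze(c)
        keep = (
            lemma not in config.stopwords
            and len(lemma) >= config.min_word_length
            and pos in config.kept_pos
        )
        provenance.append(
            {"raw": r, "corrected": c, "lemma": lemma, "pos": pos, "kept": keep}
        )
        if keep:
            kept.append(lemma)
    return TokenizedDoc(tuple(doc_key), raw, corrected, kept, provenance)


def preprocess_corpus(responses, lexicon=None, config=None) -> list[TokenizedDoc]:
    return [preprocess_doc(r.key, r.text, lexicon, config) for r in responses]


@dataclass
class VectorSpace:
    """TF-IDF document-term matrix over 1-3-grams of kept tokens.

    tf is the raw in-document count, idf(t) = ln((1+N)/(1+df(t))) + 1,
    and each nonzero row is L2-normalised; documents emptied by
    preprocessing keep an all-zero row and are flagged.
    """

    doc_keys: list[tuple[str, str]]
    vocabulary: list[str]
    idf: np.ndarray
    matrix: sp.csr_matrix
    empty_docs: list[bool]
    params: dict

    @property
    def shape(self):
        return self.matrix.shape

    def row(self, doc_key) -> np.ndarray:
        return self.matrix[self.doc_keys.index(tuple(doc_key))].toarray().ravel()


def _ngrams(tokens, nmin, nmax):
    out = []
    for n in range(nmin, nmax + 1):
        out.extend(
            " ".join(tokens[i : i + n]) for i in range(len(tokens) - n + 1)
        )
    return out


def build_vector_space(
    docs: list[TokenizedDoc],
    ngram_min: int = 1,
    ngram_max: int = 3,
    min_df: int = 1,
) -> VectorSpace:
    """Vectorize kept tokens as TF-IDF over contiguous n-grams.

    N-grams are built over the filtered token sequence, so gaps left by
    removed tokens close up.  Raises if every document is empty after
    preprocessing.
    """
    if not docs:
        raise ValueError("no documents")
    token_lists = [d.kept_tokens for d in docs]
    if all(not t for t in token_lists):
        raise ValueError("all documents empty after preprocessing")
    vectorizer = TfidfVectorizer(
        analyzer=lambda toks: _ngrams(toks, ngram_min, ngram_max),
        min_df=min_df,
        norm="l2",
        smooth_idf=True,
        sublinear_tf=False,
    )
    matrix = vectorizer.fit_transform(token_lists).tocsr()
    vocab_map = vectorizer.vocabulary_
    vocabulary = [t for t, _ in sorted(vocab_map.items(), key=lambda kv: kv[1])]
    row_counts = np.asarray((matrix != 0).sum(axis=1)).ravel()
    empty = [bool(c == 0) for c in row_counts]
    n_empty_input = sum(not t for t in token_lists)
    if sum(empty) > n_empty_input:
        warnings.warn(
            f"{sum(empty) - n_empty_input} documents lost all terms to min_df",
            stacklevel=2,
        )
    return VectorSpace(
        doc_keys=[d.doc_key for d in docs],
        vocabulary=vocabulary,
        idf=vectorizer.idf_.copy(),
        matrix=matrix,
        empty_docs=empty,
        params={
            "ngram_range": [ngram_min, ngram_max],
            "min_df": min_df,
            "tf": "raw_count",
            "idf": "ln((1+N)/(1+df))+1",
            "norm": "l2",
        },
    )
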