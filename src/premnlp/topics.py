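"""Per-stratum NMF topic modelling with embedding-coherence model selection.

One topic model is fitted per (question, sentiment) stratum, where the
sentiment is positive or negative (neutral answers are excluded).  For
each stratum the number of topics k is chosen adaptively: NMF is fitted
for every k in 2..15 (clipped to the matrix dimensions), the coherence
of each candidate model is the mean over topics of the mean pairwise
cosine similarity between the embedded top-10 terms of the topic, and
the k with the highest coherence wins (ties go to the smaller k).

The factorization itself is multiplicative-update NMF on the Frobenius
objective ||X - WH||_F with a deterministic NNDSVDa initialisation, so
that the per-iteration residual trajectory can be logged and is
guaranteed non-increasing.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from itertools import combinations

import numpy as np
import scipy.sparse as sp

from .corpus import EmbeddingTable

__all__ = [
    "fit_nmf",
    "topic_coherence",
    "select_k",
    "assign_topics",
    "topic_descriptors",
    "StratumTopicModel",
    "TopicModelResults",
    "StratumTooSmall",
    "UNASSIGNED",
]

UNASSIGNED = -1

DEFAULT_K_RANGE = range(2, 16)


class StratumTooSmall(ValueError):
    """Stratum has too few usable documents for any candidate k."""


# ---------------------------------------------------------------------------
# NMF


def _nndsvda(X: np.ndarray, k: int) -> tuple[np.ndarray, np.ndarray]:
    # Nonnegative double SVD init; zero entries filled with the matrix mean
    # (the "a" variant) so multiplicative updates can move every entry.
    U, S, Vt = np.linalg.svd(X, full_matrices=False)
    n, m = X.shape
    W = np.zeros((n, k))
    H = np.zeros((k, m))
    W[:, 0] = np.sqrt(S[0]) * np.abs(U[:, 0])
    H[0, :] = np.sqrt(S[0]) * np.abs(Vt[0, :])
    for j in range(1, k):
        u, v = U[:, j], Vt[j, :]
        up, un = np.clip(u, 0, None), np.clip(-u, 0, None)
        vp, vn = np.clip(v, 0, None), np.clip(-v, 0, None)
        n_p = np.linalg.norm(up) * np.linalg.norm(vp)
        n_n = np.linalg.norm(un) * np.linalg.norm(vn)
        if n_p >= n_n and n_p > 0:
            sigma = S[j] * n_p
            W[:, j] = np.sqrt(sigma) * up / np.linalg.norm(up)
            H[j, :] = np.sqrt(sigma) * vp / np.linalg.norm(vp)
        elif n_n > 0:
            sigma = S[j] * n_n
            W[:, j] = np.sqrt(sigma) * un / np.linalg.norm(un)
            H[j, :] = np.sqrt(sigma) * vn / np.linalg.norm(vn)
    mean = X.mean()
    W[W == 0] = mean
    H[H == 0] = mean
    return W, H


def fit_nmf(
    X,
    k: int,
    seed: int = 0,
    max_iter: int = 400,
    tol: float = 1e-4,
) -> tuple[np.ndarray, np.ndarray, dict]:
    """Factor a nonnegative matrix X ~ W @ H with k components.

    Multiplicative updates minimise the Frobenius reconstruction error;
    the objective never increases between iterations.  Deterministic:
    initialisation is NNDSVDa (SVD-based, seed-independent); ``seed`` is
    recorded in the info dict for provenance.  Returns (W, H, info)
    where info holds the iteration count and the logged residual
    trajectory.
    """
    X = X.toarray() if sp.issparse(X) else np.asarray(X, dtype=float)
    if X.ndim != 2:
        raise ValueError("X must be 2-dimensional")
    if (X < 0).any():
        raise ValueError("X has negative entries")
    n, m = X.shape
    if k > min(n, m):
        raise ValueError(f"k={k} exceeds min(n_docs, n_terms)={min(n, m)}")
    if k < 1:
        raise ValueError("k must be >= 1")

    norm_X = np.linalg.norm(X)
    if norm_X == 0.0:
        info = {"n_iter": 0, "residuals": [0.0], "seed": seed, "converged": True}
        return np.zeros((n, k)), np.zeros((k, m)), info

    W, H = _nndsvda(X, k)
    eps = 1e-10
    residuals = [float(np.linalg.norm(X - W @ H))]
    n_iter = 0
    for it in range(1, max_iter + 1):
        # standard Lee-Seung multiplicative updates
        H *= (W.T @ X) / (W.T @ W @ H + eps)
        W *= (X @ H.T) / (W @ (H @ H.T) + eps)
        n_iter = it
        if it % 10 == 0 or it == max_iter:
            res = float(np.linalg.norm(X - W @ H))
            prev = residuals[-1]
            residuals.append(res)
            if prev - res < tol * norm_X:
                break
    residuals.append(float(np.linalg.norm(X - W @ H)))
    info = {
        "n_iter": n_iter,
        "residuals": residuals,
        "seed": seed,
        "converged": n_iter < max_iter,
    }
    return W, H, info


# ---------------------------------------------------------------------------
# coherence


def _embed_term(term: str, embeddings: EmbeddingTable):
    vecs = [embeddings[w] for w in term.split() if w in embeddings]
    if not vecs:
        return None
    v = np.mean(vecs, axis=0)
    n = np.linalg.norm(v)
    return v / n if n > 0 else None


def topic_coherence(
    topic_terms: list[str], embeddings: EmbeddingTable, top_n: int = 10
) -> float:
    """Mean pairwise cosine similarity between embedded top terms.

    An n-gram is embedded as the renormalised mean of its in-vocabulary
    word vectors; terms with no known word are skipped.  With fewer than
    two embeddable terms the coherence is 0 (with a warning).  The value
    is invariant under permutation of the term list and lies in [-1, 1].
    """
    if top_n < 2:
        raise ValueError("top_n must be >= 2")
    embedded = []
    for t in topic_terms[:top_n]:
        v = _embed_term(t, embeddings)
        if v is not None:
            embedded.append(v)
    if len(embedded) < 2:
        warnings.warn(
            "fewer than 2 embeddable terms; coherence set to 0", stacklevel=2
        )
        return 0.0
    sims = [float(a @ b) for a, b in combinations(embedded, 2)]
    return float(np.mean(sims))


def _top_terms(h_row: np.ndarray, vocab: list[str], n: int) -> list[str]:
    # highest weight first; weight ties break lexicographically
    order = sorted(range(len(vocab)), key=lambda i: (-h_row[i], vocab[i]))
    return [vocab[i] for i in order[:n] if h_row[i] > 0]


# ---------------------------------------------------------------------------
# model selection, assignment, descriptors


def select_k(
    X,
    vocab: list[str],
    embeddings: EmbeddingTable,
    k_range=DEFAULT_K_RANGE,
    seed: int = 0,
    top_n: int = 10,
    max_iter: int = 400,
    tol: float = 1e-4,
):
    """Fit NMF for every candidate k and keep the most coherent model.

    Candidate k values are clipped to min(n_docs, n_terms); each
    candidate is fitted independently (no warm starts).  Model coherence
    is the mean of per-topic coherences.  Ties prefer the smaller k.
    Returns (k, W, H, per_topic_coherence, log) where log maps each
    candidate k to its model coherence.
    """
    X = X.toarray() if sp.issparse(X) else np.asarray(X, dtype=float)
    n_docs = int((X.sum(axis=1) > 0).sum())
    if n_docs < 3:
        raise StratumTooSmall(
            f"stratum has {n_docs} non-empty documents; need >= 3"
        )
    upper = min(X.shape)
    candidates = [k for k in k_range if 2 <= k <= upper]
    if not candidates:
        raise StratumTooSmall(
            f"no candidate k fits matrix of shape {X.shape}"
        )
    log: dict[int, float] = {}
    best = None
    for k in candidates:
        W, H, _ = fit_nmf(X, k, seed=seed, max_iter=max_iter, tol=tol)
        per_topic = [
            topic_coherence(_top_terms(H[j], vocab, top_n), embeddings, top_n)
            for j in range(k)
        ]
        coherence = float(np.mean(per_topic))
        log[k] = coherence
        if best is None or coherence > best[0] + 1e-12:
            best = (coherence, k, W, H, per_topic)
    _, k, W, H, per_topic = best
    return k, W, H, per_topic, log


def assign_topics(W: np.ndarray) -> np.ndarray:
    """Hard-assign each document to its argmax topic; all-zero rows are
    UNASSIGNED (-1).  Argmax ties resolve to the lowest topic index."""
    W = np.asarray(W)
    out = np.argmax(W, axis=1)
    out[W.sum(axis=1) == 0] = UNASSIGNED
    return out


def _is_subsequence(short: tuple, long: tuple) -> bool:
    # ordered, not necessarily contiguous
    it = iter(long)
    return all(tok in it for tok in short)


def topic_descriptors(
    h_row: np.ndarray,
    vocab: list[str],
    top_terms: int = 10,
    show: int = 5,
) -> list[str]:
    """Human-readable descriptors for one topic.

    Takes the ``top_terms`` highest-weight n-grams, sorts them by word
    count descending (stable, so equal-length terms keep their weight
    order), removes any term whose token sequence is an ordered
    subsequence of a longer retained term (so a list never contains both
    "went very well" and "went well"), and returns the first ``show``.
    """
    h_row = np.asarray(h_row)
    if len(h_row) != len(vocab):
        raise ValueError("H row length does not match vocabulary size")
    terms = _top_terms(h_row, vocab, top_terms)
    if not terms:
        warnings.warn("all-zero topic; no descriptors", stacklevel=2)
        return []
    terms.sort(key=lambda t: -len(t.split()))  # stable
    retained: list[str] = []
    for t in terms:
        toks = tuple(t.split())
        if any(
            len(toks) < len(r_toks) and _is_subsequence(toks, r_toks)
            for r_toks in (tuple(r.split()) for r in retained)
        ):
            continue
        retained.append(t)
    return retained[:show]


# ---------------------------------------------------------------------------
# model / results objects


@dataclass(frozen=True)
class Stratum:
    """One (question, sentiment) subset of answers; neutral is never a
    stratum sentiment."""

    question_id: str
    sentiment: str
    doc_keys: tuple[tuple[str, str], ...]

    def __post_init__(self):
        if self.sentiment not in ("positive", "negative"):
            raise ValueError("stratum sentiment must be positive or negative")

    def __len__(self):
        return len(self.doc_keys)


class StratumTopicModel:
    """NMF topic model for one stratum with adaptive choice of k.

    Parameters
    ----------
    X : array or sparse matrix
        Nonnegative TF-IDF document-term matrix of the stratum, rows
        aligned with ``stratum.doc_keys``.
    vocab : list of str
        N-gram vocabulary aligned with the columns of X.
    embeddings : EmbeddingTable
        Word vectors used for the coherence score.
    """

    def __init__(
        self,
        stratum: Stratum,
        X,
        vocab: list[str],
        embeddings: EmbeddingTable,
        k_range=DEFAULT_K_RANGE,
        max_iter: int = 400,
        tol: float = 1e-4,
    ):
        X = X.toarray() if sp.issparse(X) else np.asarray(X, dtype=float)
        if X.shape[0] != len(stratum):
            raise ValueError("X rows must align with stratum doc_keys")
        self.stratum = stratum
        self.X = X
        self.vocab = list(vocab)
        self.embeddings = embeddings
        self.k_range = list(k_range)
        self.max_iter = max_iter
        self.tol = tol

    def fit(self, seed: int = 0) -> "TopicModelResults":
        k, W, H, per_topic, log = select_k(
            self.X,
            self.vocab,
            self.embeddings,
            k_range=self.k_range,
            seed=seed,
            max_iter=self.max_iter,
            tol=self.tol,
        )
        assignment = assign_topics(W)
        descriptors = [topic_descriptors(H[j], self.vocab) for j in range(k)]
        return TopicModelResults(
            model=self,
            k=k,
            W=W,
            H=H,
            seed=seed,
            coherence=float(np.mean(per_topic)),
            per_topic_coherence=list(per_topic),
            coherence_by_k=log,
            assignment=assignment,
            descriptors=descriptors,
        )


@dataclass
class TopicModelResults:
    """Fitted per-stratum topic model: factors, chosen k, coherence log,
    hard assignments and display descriptors."""

    model: StratumTopicModel
    k: int
    W: np.ndarray
    H: np.ndarray
    seed: int
    coherence: float
    per_topic_coherence: list[float]
    coherence_by_k: dict[int, float]
    assignment: np.ndarray
    descriptors: list[list[str]] = field(default_factory=list)

    @property
    def stratum(self) -> Stratum:
        return self.model.stratum

    @property
    def topic_counts(self) -> list[int]:
        return [int((self.assignment == j).sum()) for j in range(self.k)]

    @property
    def n_unassigned(self) -> int:
        return int((self.assignment == UNASSIGNED).sum())

    def assignment_map(self) -> dict[tuple[str, str], int]:
        return {
            key: int(t)
            for key, t in zip(self.stratum.doc_keys, self.assignment)
        }

    def manifest(self) -> dict:
        return {
            "question_id": self.stratum.question_id,
            "sentiment": self.stratum.sentiment,
            "n_docs": len(self.stratum),
            "k_range": self.model.k_range,
            "k": self.k,
            "seed": self.seed,
            "coherence": self.coherence,
            "coherence_by_k": {str(k): v for k, v in self.coherence_by_k.items()},
            "solver": {
                "algorithm": "multiplicative-update",
                "init": "nndsvda",
                "max_iter": self.model.max_iter,
                "tol": self.model.tol,
            },
            "descriptor_rule": "top10-by-weight/len-desc/subsequence-dedup/show5",
        }

    def summary(self) -> str:
        lines = [
            f"Topic model: question {self.stratum.question_id}, "
            f"{self.stratum.sentiment} ({len(self.stratum)} answers)",
            f"  selected k = {self.k}  (coherence {self.coherence:.3f}; "
            f"candidates {min(self.coherence_by_k)}..{max(self.coherence_by_k)})",
            f"  unassigned: {self.n_unassigned}",
        ]
        for j, (count, desc) in enumerate(zip(self.topic_counts, self.descriptors)):
            lines.append(f"  topic {j} (n={count}): {', '.join(desc) or '-'}")
        return "\n".join(lines)
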