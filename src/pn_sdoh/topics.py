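"""Latent Dirichlet allocation features for navigator note text.

Each free-text note becomes a length-k vector of topic probabilities, so a
preparation strategy's feature set gains exactly k numeric attributes.  No
optimal-k selection is attempted by design: the grid simply tries
k ∈ {5, 10, 15, 20, 25, 30}.
"""

from __future__ import annotations

import re
from dataclasses import dataclass

import numpy as np
from sklearn.decomposition import LatentDirichletAllocation
from sklearn.feature_extraction.text import CountVectorizer

#: Default topic-count grid.
DEFAULT_K_GRID = (5, 10, 15, 20, 25, 30)

_PUNCT = re.compile(r"[^\w\s]", flags=re.UNICODE)


@dataclass(frozen=True)
class TopicModelSpec:
    """Topic model settings: k topics, symmetric priors, fixed seed."""

    k: int = 15
    max_iter: int = 500
    doc_topic_prior: float | None = None  # None = sklearn's symmetric 1/k
    topic_word_prior: float | None = None
    seed: int = 0

    def __post_init__(self) -> None:
        if self.k < 2:
            raise ValueError("k must be at least 2")


def tokenize(text: str) -> list[str]:
    """Lowercase, strip punctuation, split on whitespace."""
    if not text:
        return []
    return _PUNCT.sub(" ", text.lower()).split()


class TopicModel:
    """A fitted LDA model mapping any note to a k-probability vector."""

    def __init__(self, spec: TopicModelSpec, vectorizer: CountVectorizer, lda: LatentDirichletAllocation):
        self.spec = spec
        self._vectorizer = vectorizer
        self._lda = lda

    @property
    def k(self) -> int:
        return self.spec.k

    def transform(self, notes: list[str]) -> np.ndarray:
        """Topic vectors for a batch of notes (empty note -> uniform)."""
        out = np.full((len(notes), self.k), 1.0 / self.k)
        tokenized = [" ".join(tokenize(n)) for n in notes]
        nonempty = [i for i, t in enumerate(tokenized) if t]
        if nonempty:
            counts = self._vectorizer.transform([tokenized[i] for i in nonempty])
            # a note whose words are all out-of-vocabulary is also uninformative
            seen = np.asarray(counts.sum(axis=1)).ravel() > 0
            theta = self._lda.transform(counts)
            for row, i in enumerate(nonempty):
                if seen[row]:
                    out[i] = theta[row]
        return out


def fit_topics(notes: list[str], spec: TopicModelSpec | None = None) -> TopicModel:
    """Fit LDA on a corpus of notes.

    Requires at least k non-empty documents; a fixed seed makes both the
    fit and subsequent inference reproducible.
    """
    spec = spec or TopicModelSpec()
    docs = [" ".join(tokenize(n)) for n in notes]
    nonempty = [d for d in docs if d]
    if len(nonempty) < spec.k:
        raise ValueError(
            f"corpus has {len(nonempty)} non-empty documents; need at least k={spec.k}"
        )
    vectorizer = CountVectorizer(token_pattern=r"\S+", lowercase=False)
    matrix = vectorizer.fit_transform(nonempty)
    lda = LatentDirichletAllocation(
        n_components=spec.k,
        max_iter=spec.max_iter,
        doc_topic_prior=spec.doc_topic_prior,
        topic_word_prior=spec.topic_word_prior,
        random_state=spec.seed,
    )
    lda.fit(matrix)
    return TopicModel(spec, vectorizer, lda)


def note_to_vector(model: TopicModel, note: str) -> np.ndarray:
    """Topic-probability vector for one note; empty notes are uniform."""
    return model.transform([note])[0]
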