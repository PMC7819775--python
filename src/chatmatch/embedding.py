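"""Smooth-inverse-frequency (SIF) window embeddings.

Each window's text is embedded as a weighted average of pretrained word
vectors: a word ``w`` with corpus relative frequency ``p(w)`` contributes
its vector scaled by ``a / (a + p(w))``, so frequent, less meaningful
words receive lower weight.  With kept tokens ``w_1..w_n`` (those present
in both the vector store and the frequency table) the embedding is

    v = (1/n) * sum_i  a / (a + p(w_i)) * vec(w_i)

Out-of-vocabulary tokens are skipped and do not enter ``n``, so OOV
density does not shrink the vector.  A window with no embeddable token
maps to the zero vector (flagged via ``token_count == 0`` and excluded
from ranking downstream).

The smoothing constant ``a`` defaults to 1e-3, the canonical choice of
the SIF scheme.  The scheme's optional removal of the first principal
component of the embedding set is off by default and available through
:func:`first_principal_component` / :func:`remove_projection` for
experimentation.

Word vectors are read from the standard word2vec text format: a header
line ``<vocab_size> <dimension>`` followed by one ``word v1 ... vD`` row
per word.
"""

from __future__ import annotations

import logging
from collections import Counter
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np

from .corpus import RETAINED_PUNCTUATION, Chat, ChatWindow, normalize_text

__all__ = [
    "WordVectorStore",
    "FrequencyTable",
    "EmbeddingConfig",
    "WindowEmbedding",
    "load_word_vectors",
    "save_word_vectors",
    "tokenize",
    "compute_word_frequencies",
    "sif_weight",
    "sif_embed",
    "embed_windows",
    "first_principal_component",
    "remove_projection",
]

logger = logging.getLogger(__name__)


@dataclass
class WordVectorStore:
    """Pretrained word embeddings: a word -> vector mapping of one dimension.

    Lookup of an absent word returns ``None`` (distinguishable from a
    stored zero vector).
    """

    dimension: int
    vectors: dict[str, np.ndarray] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.dimension < 1:
            raise ValueError("dimension must be >= 1")
        for word, vec in self.vectors.items():
            if vec.shape != (self.dimension,):
                raise ValueError(
                    f"vector for {word!r} has shape {vec.shape}, "
                    f"expected ({self.dimension},)"
                )

    def __len__(self) -> int:
        return len(self.vectors)

    def __contains__(self, word: str) -> bool:
        return word in self.vectors

    def get(self, word: str) -> np.ndarray | None:
        return self.vectors.get(word)


@dataclass
class FrequencyTable:
    """Corpus word counts and the derived relative frequencies p(w)."""

    counts: dict[str, int]
    total: int

    def __post_init__(self) -> None:
        if self.total != sum(self.counts.values()):
            raise ValueError("total must equal the sum of counts")
        if self.total <= 0:
            raise ValueError("frequency table must contain at least one token")
        if any(c <= 0 for c in self.counts.values()):
            raise ValueError("all counts must be positive")

    def __contains__(self, word: str) -> bool:
        return word in self.counts

    def p(self, word: str) -> float:
        """Relative frequency of ``word``; raises ``KeyError`` if absent."""
        return self.counts[word] / self.total


@dataclass(frozen=True)
class EmbeddingConfig:
    """Knobs of the SIF embedding.

    ``sif_a`` is the smoothing constant a of the weight a/(a+p(w));
    larger values flatten the weighting toward a plain mean.
    ``oov_policy`` is fixed to "skip": unknown tokens are ignored.
    ``remove_common_component`` toggles removal of the first principal
    component of the corpus embedding matrix after embedding.
    """

    sif_a: float = 1e-3
    oov_policy: str = "skip"
    remove_common_component: bool = False

    def __post_init__(self) -> None:
        if self.sif_a <= 0:
            raise ValueError("sif_a must be > 0")
        if self.oov_policy != "skip":
            raise ValueError("only the 'skip' OOV policy is supported")


@dataclass(frozen=True)
class WindowEmbedding:
    """A window's vector plus the metadata needed to trace it back.

    ``token_count`` is the number of tokens actually embedded; it is zero
    exactly when ``vector`` is the zero vector.
    """

    chat_id: str
    start: int
    vector: np.ndarray
    token_count: int


# ---------------------------------------------------------------------------
# Word-vector I/O (word2vec text format)
# ---------------------------------------------------------------------------


def load_word_vectors(path: str | Path) -> WordVectorStore:
    """Read a word2vec text-format file into a :class:`WordVectorStore`.

    The first line must be ``<vocab_size> <dimension>``; every following
    row is ``word v1 ... vD``.  A row whose value count disagrees with
    the header raises an error naming the row; a duplicate word wins
    last with a logged warning.
    """
    with open(path, "r", encoding="utf-8") as handle:
        header = handle.readline()
        parts = header.split()
        if len(parts) != 2:
            raise ValueError("word-vector file header must be '<vocab> <dim>'")
        try:
            vocab_size, dimension = int(parts[0]), int(parts[1])
        except ValueError:
            raise ValueError("word-vector file header must be two integers") from None
        if dimension < 1:
            raise ValueError("word-vector dimension must be >= 1")
        vectors: dict[str, np.ndarray] = {}
        for rowno, line in enumerate(handle, start=2):
            if not line.strip():
                continue
            fields = line.split()
            if len(fields) != dimension + 1:
                raise ValueError(
                    f"row {rowno}: expected {dimension} values, "
                    f"got {len(fields) - 1}"
                )
            word = fields[0]
            if word in vectors:
                logger.warning("duplicate word %r at row %d; last wins", word, rowno)
            vectors[word] = np.array(fields[1:], dtype=np.float64)
    if len(vectors) != vocab_size:
        logger.warning(
            "header declared %d words but file holds %d", vocab_size, len(vectors)
        )
    return WordVectorStore(dimension=dimension, vectors=vectors)


def save_word_vectors(store: WordVectorStore, path: str | Path) -> None:
    """Write a store in word2vec text format (deterministic row order)."""
    with open(path, "w", encoding="utf-8") as handle:
        handle.write(f"{len(store)} {store.dimension}\n")
        for word, vec in store.vectors.items():
            values = " ".join(repr(float(v)) for v in vec)
            handle.write(f"{word} {values}\n")


# ---------------------------------------------------------------------------
# Tokenization and frequencies
# ---------------------------------------------------------------------------


def tokenize(text: str) -> list[str]:
    """Split normalized text into tokens.

    Whitespace-delimited; punctuation is stripped from token edges only
    (an internal hyphen as in ``a-b`` survives); empty tokens drop out.
    """
    tokens = []
    for raw in text.split():
        token = raw.strip(RETAINED_PUNCTUATION)
        if token:
            tokens.append(token)
    return tokens


def compute_word_frequencies(chats: Iterable[Chat]) -> FrequencyTable:
    """Tabulate token counts over all messages of all chats.

    Expects normalized chats.  Raises if the corpus contains no token at
    all, since relative frequencies would be undefined.
    """
    counts: Counter[str] = Counter()
    for chat in chats:
        for message in chat.messages:
            counts.update(tokenize(message.text))
    total = sum(counts.values())
    if total == 0:
        raise ValueError("corpus contains no tokens; frequencies are undefined")
    return FrequencyTable(counts=dict(counts), total=total)


# ---------------------------------------------------------------------------
# SIF embedding
# ---------------------------------------------------------------------------


def sif_weight(p: float, a: float) -> float:
    """The SIF weight a/(a+p): strictly decreasing in the frequency p."""
    return a / (a + p)


def _sif_embed_counted(
    tokens: Sequence[str],
    store: WordVectorStore,
    freqs: FrequencyTable,
    config: EmbeddingConfig,
) -> tuple[np.ndarray, int]:
    acc = np.zeros(store.dimension, dtype=np.float64)
    n = 0
    a = config.sif_a
    for token in tokens:
        vec = store.get(token)
        if vec is None or token not in freqs:
            continue
        acc += sif_weight(freqs.p(token), a) * vec
        n += 1
    if n == 0:
        return acc, 0
    return acc / n, n


def sif_embed(
    tokens: Sequence[str],
    store: WordVectorStore,
    freqs: FrequencyTable,
    config: EmbeddingConfig | None = None,
) -> np.ndarray:
    """Embed a token sequence as the SIF-weighted mean of its word vectors.

    Tokens absent from the store or the frequency table are skipped.  If
    nothing remains the zero vector is returned with a logged warning.
    """
    if config is None:
        config = EmbeddingConfig()
    if len(store) == 0:
        raise ValueError("word-vector store is empty")
    vec, n = _sif_embed_counted(tokens, store, freqs, config)
    if n == 0:
        logger.warning("no embeddable token among %d; returning zero vector", len(tokens))
    return vec


def embed_windows(
    windows: Sequence[ChatWindow],
    store: WordVectorStore,
    freqs: FrequencyTable,
    config: EmbeddingConfig | None = None,
) -> list[WindowEmbedding]:
    """Embed every window, preserving order and (chat_id, start) metadata.

    A window's text is the concatenation of its messages' normalized
    texts; normalization is idempotent so already-clean corpora are
    unaffected.  Zero-token windows yield zero vectors with
    ``token_count == 0``.
    """
    if config is None:
        config = EmbeddingConfig()
    if len(store) == 0:
        raise ValueError("word-vector store is empty")
    out: list[WindowEmbedding] = []
    for window in windows:
        text = normalize_text(" ".join(window.texts))
        tokens = tokenize(text)
        vec, n = _sif_embed_counted(tokens, store, freqs, config)
        if n == 0:
            logger.warning(
                "window (%s, %d) has no embeddable token", window.chat_id, window.start
            )
        out.append(
            WindowEmbedding(
                chat_id=window.chat_id, start=window.start, vector=vec, token_count=n
            )
        )
    return out


# ---------------------------------------------------------------------------
# Optional common-component removal
# ---------------------------------------------------------------------------


def first_principal_component(matrix: np.ndarray) -> np.ndarray:
    """Unit first right-singular vector of the (uncentered) embedding matrix.

    Sign is fixed so the largest-magnitude coordinate is positive, making
    the result deterministic.
    """
    if matrix.ndim != 2 or matrix.shape[0] == 0:
        raise ValueError("need a non-empty 2-D embedding matrix")
    _, _, vt = np.linalg.svd(matrix, full_matrices=False)
    u = vt[0]
    pivot = np.argmax(np.abs(u))
    if u[pivot] < 0:
        u = -u
    return u


def remove_projection(vectors: np.ndarray, component: np.ndarray) -> np.ndarray:
    """Subtract each vector's projection onto ``component`` (unit norm)."""
    component = component / np.linalg.norm(component)
    return vectors - np.outer(vectors @ component, component)
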