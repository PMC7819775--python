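"""Synthetic topic-structured chat corpora with ground truth.

Real helpline transcripts are confidential, so tests and experiments run
on generated stand-ins that reproduce the one property retrieval relies
on: conversations about the same problem use similar vocabulary, and
that vocabulary is geometrically clustered in word-vector space.

The generative model:

* every chat draws one latent topic uniformly;
* each topic owns a disjoint vocabulary; a shared vocabulary (function
  words, greetings) is common to all topics and mixed into every message
  at a fixed rate — these frequent shared words are exactly what the SIF
  weighting down-weights;
* message token counts and chat lengths are uniform over configured
  ranges; senders alternate help-seeker / counselor;
* each topic gets a random unit centroid scaled by
  ``topic_separation * noise_sd * sqrt(dimension)``; a topic word's
  vector is its centroid plus isotropic Gaussian noise of per-coordinate
  standard deviation ``noise_sd``, so ``topic_separation`` measures
  centroid distance relative to the typical within-topic noise norm.
  Shared words scatter around the centroid mean.  With separation 0 all
  topic structure vanishes; at separation ~3 topics are well separated.

Every output is a pure function of the config and seed.  Generated text
is already normalization-clean (lowercase ASCII word tokens), and chat
lengths default to [20, 40] so generated corpora pass the corpus filter
untouched.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np

from .corpus import Chat, ChatMessage, Sender
from .embedding import WordVectorStore

__all__ = [
    "SyntheticCorpusConfig",
    "GroundTruth",
    "SHARED_TOPIC",
    "generate_vectors",
    "generate_corpus",
    "generate_query",
    "generate_dataset",
    "write_ground_truth",
    "read_ground_truth",
]

#: Topic label carried by vocabulary common to all topics.
SHARED_TOPIC = "shared"


@dataclass(frozen=True)
class SyntheticCorpusConfig:
    """Knobs of the synthetic helpline corpus.

    Defaults give the standard desk-scale experiment: 200 chats of 20-40
    messages over 5 topics (~5,000 windows), 32-dimensional vectors with
    topic centroids separated at 3x the within-topic noise — small enough
    to run in seconds, structured enough to exercise ranking.

    ``vocab_per_topic`` is deliberately large relative to the tokens any
    single chat uses (a chat samples only a few percent of its topic's
    vocabulary), so two same-topic conversations rarely share content
    words.  Topical similarity is then carried by the clustered vector
    geometry rather than by literal word overlap — the regime word
    embeddings exist for — and dialing ``topic_separation`` to zero
    genuinely removes the retrievable signal instead of leaving a
    lexical shortcut.
    """

    n_chats: int = 200
    n_topics: int = 5
    chat_length_range: tuple[int, int] = (20, 40)
    vocab_per_topic: int = 6000
    shared_vocab: int = 600
    tokens_per_message_range: tuple[int, int] = (4, 12)
    shared_token_rate: float = 0.3
    vector_dimension: int = 32
    topic_separation: float = 3.0
    noise_sd: float = 1.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_chats < 1 or self.n_topics < 1:
            raise ValueError("n_chats and n_topics must be >= 1")
        lo, hi = self.chat_length_range
        if not (1 <= lo <= hi):
            raise ValueError("chat_length_range must satisfy 1 <= lo <= hi")
        tlo, thi = self.tokens_per_message_range
        if not (1 <= tlo <= thi):
            raise ValueError("tokens_per_message_range must satisfy 1 <= lo <= hi")
        if self.vocab_per_topic < 1 or self.shared_vocab < 0:
            raise ValueError("vocab_per_topic >= 1 and shared_vocab >= 0 required")
        if not (0.0 <= self.shared_token_rate <= 1.0):
            raise ValueError("shared_token_rate must be in [0, 1]")
        if self.vector_dimension < 1:
            raise ValueError("vector_dimension must be >= 1")
        if self.topic_separation < 0 or self.noise_sd <= 0:
            raise ValueError("topic_separation >= 0 and noise_sd > 0 required")

    def topic_words(self, topic: int) -> list[str]:
        return [f"t{topic}w{j}" for j in range(self.vocab_per_topic)]

    def shared_words(self) -> list[str]:
        return [f"shared{j}" for j in range(self.shared_vocab)]


@dataclass
class GroundTruth:
    """Latent labels behind a synthetic dataset.

    ``chat_topic`` maps every generated chat (and query chat) to its
    topic; ``word_topic`` maps every word to its topic or ``"shared"``.
    """

    chat_topic: dict[str, int] = field(default_factory=dict)
    word_topic: dict[str, str] = field(default_factory=dict)


# ---------------------------------------------------------------------------
# Generators
# ---------------------------------------------------------------------------
# Independent RNG streams per generator (seeded by (config.seed, tag)) so
# that generate_vectors and generate_corpus are individually deterministic
# regardless of call order.

_VECTOR_STREAM, _CORPUS_STREAM, _QUERY_STREAM = 1, 2, 3


def _centroids(config: SyntheticCorpusConfig, rng: np.random.Generator) -> np.ndarray:
    """Random unit directions scaled to the configured separation."""
    raw = rng.standard_normal((config.n_topics, config.vector_dimension))
    units = raw / np.linalg.norm(raw, axis=1, keepdims=True)
    scale = config.topic_separation * config.noise_sd * np.sqrt(config.vector_dimension)
    return units * scale


def generate_vectors(
    config: SyntheticCorpusConfig,
) -> tuple[WordVectorStore, GroundTruth]:
    """Generate topic-clustered word vectors and their topic labels.

    Each topic word's vector is the topic centroid plus Gaussian noise;
    shared words scatter around the mean of all centroids.  Deterministic
    given ``config.seed``.
    """
    rng = np.random.default_rng([config.seed, _VECTOR_STREAM])
    centroids = _centroids(config, rng)
    vectors: dict[str, np.ndarray] = {}
    word_topic: dict[str, str] = {}
    for topic in range(config.n_topics):
        words = config.topic_words(topic)
        noise = rng.normal(
            0.0, config.noise_sd, (len(words), config.vector_dimension)
        )
        for i, word in enumerate(words):
            vectors[word] = centroids[topic] + noise[i]
            word_topic[word] = str(topic)
    global_mean = centroids.mean(axis=0)
    shared = config.shared_words()
    noise = rng.normal(0.0, config.noise_sd, (len(shared), config.vector_dimension))
    for i, word in enumerate(shared):
        vectors[word] = global_mean + noise[i]
        word_topic[word] = SHARED_TOPIC
    store = WordVectorStore(dimension=config.vector_dimension, vectors=vectors)
    return store, GroundTruth(word_topic=word_topic)


def _draw_message_text(
    config: SyntheticCorpusConfig,
    topic_vocab: Sequence[str],
    shared_vocab: Sequence[str],
    rng: np.random.Generator,
) -> str:
    tlo, thi = config.tokens_per_message_range
    n_tokens = int(rng.integers(tlo, thi + 1))
    tokens = []
    for _ in range(n_tokens):
        if shared_vocab and rng.random() < config.shared_token_rate:
            tokens.append(shared_vocab[int(rng.integers(len(shared_vocab)))])
        else:
            tokens.append(topic_vocab[int(rng.integers(len(topic_vocab)))])
    return " ".join(tokens)


def _draw_chat(
    config: SyntheticCorpusConfig,
    chat_id: str,
    topic_vocab: Sequence[str],
    shared_vocab: Sequence[str],
    n_messages: int,
    rng: np.random.Generator,
) -> Chat:
    messages = []
    for i in range(n_messages):
        sender = Sender.HELPSEEKER if i % 2 == 0 else Sender.COUNSELOR
        text = _draw_message_text(config, topic_vocab, shared_vocab, rng)
        messages.append(ChatMessage(sender=sender, text=text, index=i))
    return Chat(chat_id=chat_id, messages=tuple(messages))


def generate_corpus(
    config: SyntheticCorpusConfig,
) -> tuple[list[Chat], GroundTruth]:
    """Generate the chat corpus and the chat -> topic ground truth.

    Each chat draws one topic uniformly and a length uniform over
    ``chat_length_range``; senders alternate starting with the
    help-seeker.  Deterministic given ``config.seed``.
    """
    rng = np.random.default_rng([config.seed, _CORPUS_STREAM])
    lo, hi = config.chat_length_range
    vocabs = [config.topic_words(t) for t in range(config.n_topics)]
    shared = config.shared_words()
    chats: list[Chat] = []
    chat_topic: dict[str, int] = {}
    for i in range(config.n_chats):
        topic = int(rng.integers(config.n_topics))
        n_messages = int(rng.integers(lo, hi + 1))
        chat_id = f"chat{i:04d}"
        chats.append(
            _draw_chat(config, chat_id, vocabs[topic], shared, n_messages, rng)
        )
        chat_topic[chat_id] = topic
    return chats, GroundTruth(chat_topic=chat_topic)


def generate_query(
    config: SyntheticCorpusConfig,
    topic: int,
    seed: int,
    n_messages: int = 5,
) -> Chat:
    """Generate a short ongoing-chat fixture drawn from one topic.

    Stands in for the live conversation whose tail forms the retrieval
    query.  Raises for a topic outside the configured range.
    """
    if not (0 <= topic < config.n_topics):
        raise ValueError(
            f"unknown topic {topic}; corpus has topics 0..{config.n_topics - 1}"
        )
    rng = np.random.default_rng([config.seed, _QUERY_STREAM, seed, topic])
    chat_id = f"query-t{topic}-s{seed}"
    return _draw_chat(
        config, chat_id, config.topic_words(topic), config.shared_words(),
        n_messages, rng,
    )


def generate_dataset(
    config: SyntheticCorpusConfig,
) -> tuple[list[Chat], WordVectorStore, GroundTruth]:
    """Generate corpus + vectors + merged ground truth in one call."""
    store, vec_truth = generate_vectors(config)
    chats, chat_truth = generate_corpus(config)
    truth = GroundTruth(
        chat_topic=dict(chat_truth.chat_topic),
        word_topic=dict(vec_truth.word_topic),
    )
    return chats, store, truth


# ---------------------------------------------------------------------------
# Ground-truth sidecar I/O
# ---------------------------------------------------------------------------


def write_ground_truth(truth: GroundTruth, path: str | Path) -> None:
    """Write ground truth as a JSONL sidecar, one labeled entity per line."""
    with open(path, "w", encoding="utf-8") as handle:
        for chat_id in truth.chat_topic:
            record = {"kind": "chat", "id": chat_id, "topic": truth.chat_topic[chat_id]}
            handle.write(json.dumps(record, separators=(",", ":")) + "\n")
        for word in truth.word_topic:
            record = {"kind": "word", "id": word, "topic": truth.word_topic[word]}
            handle.write(json.dumps(record, separators=(",", ":")) + "\n")


def read_ground_truth(path: str | Path) -> GroundTruth:
    """Read a ground-truth sidecar written by :func:`write_ground_truth`."""
    truth = GroundTruth()
    with open(path, "r", encoding="utf-8") as handle:
        for lineno, line in enumerate(handle, start=1):
            if not line.strip():
                continue
            record = json.loads(line)
            kind = record.get("kind")
            if kind == "chat":
                truth.chat_topic[record["id"]] = int(record["topic"])
            elif kind == "word":
                truth.word_topic[record["id"]] = str(record["topic"])
            else:
                raise ValueError(f"line {lineno}: unknown ground-truth kind {kind!r}")
    return truth
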