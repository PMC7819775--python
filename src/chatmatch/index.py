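"""Embedding index: storage and top-k cosine retrieval of chat windows.

Window embeddings are stacked into one matrix with per-row metadata
(source chat id, window start, embedded-token count).  A query — the SIF
embedding of the last few messages of an ongoing conversation — is
scored against every rankable row by cosine similarity and the top-k
windows are returned, highest first.  Rows with ``token_count == 0``
(windows with no embeddable text) are kept in the metadata but never
ranked.  Search is exact and deterministic: ties are broken by
(chat_id, start) ascending, so shuffling row order never changes a
result.

The index persists to a single versioned container file: a magic tag,
a JSON header (metadata, config snapshot, optionally the corpus
frequency table and the removed common component), then the raw
float64 matrix bytes.  ``load_index(save_index(x))`` is bit-compatible.
"""

from __future__ import annotations

import json
import logging
import struct
from dataclasses import asdict, dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np

from .corpus import Chat, ChatWindow, SegmentationConfig, normalize_text
from .embedding import (
    EmbeddingConfig,
    FrequencyTable,
    WindowEmbedding,
    WordVectorStore,
    _sif_embed_counted,
    first_principal_component,
    remove_projection,
    tokenize,
)

__all__ = [
    "EmbeddingIndex",
    "QueryConfig",
    "QueryResult",
    "cosine_similarity",
    "build_index",
    "embed_query",
    "query",
    "fetch_context",
    "save_index",
    "load_index",
    "INDEX_FORMAT_VERSION",
]

logger = logging.getLogger(__name__)

_MAGIC = b"CMIDX"
INDEX_FORMAT_VERSION = 1


@dataclass(frozen=True)
class QueryConfig:
    """Retrieval knobs.

    ``top_k`` recommendations are returned (default 10, the number shown
    to a counselor); ``context_size`` is how many trailing messages of
    the ongoing chat form the query (default 5, matching the corpus
    window).  ``dedup_per_chat`` keeps only the single best window per
    source chat; ``exclude_chat_ids`` removes chats from the candidate
    set (e.g. the ongoing chat itself when it is part of the corpus).
    """

    top_k: int = 10
    context_size: int = 5
    dedup_per_chat: bool = False
    exclude_chat_ids: frozenset[str] = frozenset()

    def __post_init__(self) -> None:
        if self.top_k < 1:
            raise ValueError("top_k must be >= 1")
        if self.context_size < 1:
            raise ValueError("context_size must be >= 1")


@dataclass(frozen=True)
class QueryResult:
    """One recommended window: 1-based rank, provenance, cosine score."""

    rank: int
    chat_id: str
    start: int
    score: float


@dataclass
class EmbeddingIndex:
    """Matrix of window embeddings plus per-row provenance.

    ``config_snapshot`` freezes the segmentation and embedding settings
    used at build time.  ``frequencies`` optionally carries the corpus
    frequency table so queries can be embedded without re-reading the
    corpus; ``common_component`` is the removed first principal
    component when that option was on; ``texts`` optionally stores each
    window's normalized text for display.
    """

    matrix: np.ndarray
    chat_ids: tuple[str, ...]
    starts: tuple[int, ...]
    token_counts: tuple[int, ...]
    config_snapshot: dict
    frequencies: FrequencyTable | None = None
    common_component: np.ndarray | None = None
    texts: tuple[str, ...] | None = None

    def __post_init__(self) -> None:
        n = self.matrix.shape[0]
        if not (len(self.chat_ids) == len(self.starts) == len(self.token_counts) == n):
            raise ValueError("metadata length must equal matrix row count")
        if self.texts is not None and len(self.texts) != n:
            raise ValueError("texts length must equal matrix row count")

    def __len__(self) -> int:
        return self.matrix.shape[0]

    @property
    def dimension(self) -> int:
        return self.matrix.shape[1]

    def rankable_mask(self) -> np.ndarray:
        """Boolean mask of rows eligible for ranking (embeddable, nonzero)."""
        norms = np.linalg.norm(self.matrix, axis=1)
        return (np.asarray(self.token_counts) > 0) & (norms > 0)


# ---------------------------------------------------------------------------
# Similarity and index construction
# ---------------------------------------------------------------------------


def cosine_similarity(u: np.ndarray, v: np.ndarray) -> float:
    """Normalized dot product of two nonzero vectors, in [-1, 1]."""
    u = np.asarray(u, dtype=np.float64)
    v = np.asarray(v, dtype=np.float64)
    if u.shape != v.shape:
        raise ValueError(f"dimension mismatch: {u.shape} vs {v.shape}")
    nu = np.linalg.norm(u)
    nv = np.linalg.norm(v)
    if nu == 0.0 or nv == 0.0:
        raise ValueError("cosine similarity is undefined for the zero vector")
    return float(u @ v / (nu * nv))


def build_index(
    embeddings: Sequence[WindowEmbedding],
    seg_config: SegmentationConfig | None = None,
    emb_config: EmbeddingConfig | None = None,
    frequencies: FrequencyTable | None = None,
    windows: Sequence[ChatWindow] | None = None,
) -> EmbeddingIndex:
    """Stack window embeddings into a queryable index.

    All embeddings must share one dimension.  Zero-vector rows are
    retained in the metadata but flagged non-rankable.  When
    ``emb_config.remove_common_component`` is set, the first principal
    component of the stacked matrix is removed from every row and stored
    so queries can be projected identically.  ``windows`` (parallel to
    ``embeddings``) optionally attaches each window's text for display.
    """
    seg_config = seg_config or SegmentationConfig()
    emb_config = emb_config or EmbeddingConfig()
    if len(embeddings) == 0:
        matrix = np.zeros((0, 1), dtype=np.float64)
        return EmbeddingIndex(
            matrix=matrix,
            chat_ids=(),
            starts=(),
            token_counts=(),
            config_snapshot=_snapshot(seg_config, emb_config),
            frequencies=frequencies,
        )
    dims = {e.vector.shape for e in embeddings}
    if len(dims) != 1:
        raise ValueError(f"embeddings have mixed dimensions: {sorted(dims)}")
    matrix = np.stack([e.vector for e in embeddings]).astype(np.float64)
    component = None
    if emb_config.remove_common_component:
        component = first_principal_component(matrix)
        matrix = remove_projection(matrix, component)
    texts = None
    if windows is not None:
        if len(windows) != len(embeddings):
            raise ValueError("windows must parallel embeddings")
        texts = tuple(normalize_text(" ".join(w.texts)) for w in windows)
    return EmbeddingIndex(
        matrix=matrix,
        chat_ids=tuple(e.chat_id for e in embeddings),
        starts=tuple(e.start for e in embeddings),
        token_counts=tuple(e.token_count for e in embeddings),
        config_snapshot=_snapshot(seg_config, emb_config),
        frequencies=frequencies,
        common_component=component,
        texts=texts,
    )


def _snapshot(seg: SegmentationConfig, emb: EmbeddingConfig) -> dict:
    return {"segmentation": asdict(seg), "embedding": asdict(emb)}


# ---------------------------------------------------------------------------
# Querying
# ---------------------------------------------------------------------------


def embed_query(
    ongoing: Chat,
    store: WordVectorStore,
    freqs: FrequencyTable,
    emb_config: EmbeddingConfig | None = None,
    query_config: QueryConfig | None = None,
    common_component: np.ndarray | None = None,
) -> np.ndarray:
    """Embed the tail of an ongoing conversation as the retrieval query.

    Only the last ``query_config.context_size`` messages are used (all of
    them if the chat is shorter), run through the identical
    normalize -> tokenize -> SIF pipeline as the corpus windows.  If the
    index was built with common-component removal, pass the stored
    component so the query lives in the same subspace.
    """
    emb_config = emb_config or EmbeddingConfig()
    query_config = query_config or QueryConfig()
    if len(ongoing) == 0:
        raise ValueError("ongoing chat is empty")
    tail = ongoing.messages[-query_config.context_size :]
    text = normalize_text(" ".join(m.text for m in tail))
    vec, n = _sif_embed_counted(tokenize(text), store, freqs, emb_config)
    if n == 0:
        raise ValueError("query has no embeddable content")
    if common_component is not None:
        vec = remove_projection(vec[None, :], common_component)[0]
    return vec


def query(
    index: EmbeddingIndex,
    query_vec: np.ndarray,
    config: QueryConfig | None = None,
) -> list[QueryResult]:
    """Return the top-k rankable windows by cosine similarity, descending.

    Exact scan over all rankable rows.  Ties break deterministically by
    (chat_id, start) ascending.  With ``dedup_per_chat`` only the best
    window of each source chat survives.  Fewer than ``top_k`` candidates
    simply yields fewer results; an empty candidate set yields an empty
    list with a logged warning.
    """
    config = config or QueryConfig()
    if len(index) == 0:
        raise ValueError("index is empty")
    query_vec = np.asarray(query_vec, dtype=np.float64)
    if query_vec.shape != (index.dimension,):
        raise ValueError(
            f"query dimension {query_vec.shape} does not match index "
            f"dimension ({index.dimension},)"
        )
    qnorm = np.linalg.norm(query_vec)
    if qnorm == 0.0:
        raise ValueError("query vector is zero; similarity undefined")

    mask = index.rankable_mask()
    if config.exclude_chat_ids:
        excluded = np.array(
            [cid in config.exclude_chat_ids for cid in index.chat_ids]
        )
        mask &= ~excluded
    candidates = np.flatnonzero(mask)
    if candidates.size == 0:
        logger.warning("no rankable candidate rows; returning empty result")
        return []

    sub = index.matrix[candidates]
    norms = np.linalg.norm(sub, axis=1)
    scores = (sub @ query_vec) / (norms * qnorm)

    order = sorted(
        range(candidates.size),
        key=lambda i: (
            -scores[i],
            index.chat_ids[candidates[i]],
            index.starts[candidates[i]],
        ),
    )

    results: list[QueryResult] = []
    seen_chats: set[str] = set()
    for i in order:
        row = candidates[i]
        cid = index.chat_ids[row]
        if config.dedup_per_chat:
            if cid in seen_chats:
                continue
            seen_chats.add(cid)
        results.append(
            QueryResult(
                rank=len(results) + 1,
                chat_id=cid,
                start=index.starts[row],
                score=float(scores[i]),
            )
        )
        if len(results) == config.top_k:
            break
    return results


def fetch_context(
    corpus: Sequence[Chat], result: QueryResult, window_size: int = 5
) -> tuple[ChatWindow, Chat]:
    """Resolve a result back to its window and full source transcript.

    Raises if the result's chat is missing from the corpus or the window
    does not fit the chat — both signal an index/corpus mismatch.
    """
    by_id = {c.chat_id: c for c in corpus}
    if result.chat_id not in by_id:
        raise KeyError(
            f"chat {result.chat_id!r} not present in corpus; "
            f"index and corpus do not match"
        )
    chat = by_id[result.chat_id]
    if result.start < 0 or result.start + window_size > len(chat):
        raise ValueError(
            f"window [{result.start}, {result.start + window_size}) does not "
            f"fit chat {result.chat_id!r} of {len(chat)} messages"
        )
    texts = tuple(
        m.text for m in chat.messages[result.start : result.start + window_size]
    )
    window = ChatWindow(chat_id=result.chat_id, start=result.start, texts=texts)
    return window, chat


# ---------------------------------------------------------------------------
# Persistence
# ---------------------------------------------------------------------------


def save_index(index: EmbeddingIndex, path: str | Path) -> None:
    """Write the index to a single versioned container file.

    Layout: 5-byte magic ``CMIDX``, little-endian uint64 header length,
    UTF-8 JSON header (sorted keys, so output is byte-deterministic),
    then the raw float64 matrix in C order.
    """
    header = {
        "version": INDEX_FORMAT_VERSION,
        "shape": list(index.matrix.shape),
        "chat_ids": list(index.chat_ids),
        "starts": list(index.starts),
        "token_counts": list(index.token_counts),
        "config_snapshot": index.config_snapshot,
        "frequencies": (
            None
            if index.frequencies is None
            else {"counts": index.frequencies.counts, "total": index.frequencies.total}
        ),
        "common_component": (
            None
            if index.common_component is None
            else [float(x) for x in index.common_component]
        ),
        "texts": None if index.texts is None else list(index.texts),
    }
    payload = json.dumps(header, sort_keys=True, separators=(",", ":")).encode("utf-8")
    body = np.ascontiguousarray(index.matrix, dtype=np.float64).tobytes()
    with open(path, "wb") as handle:
        handle.write(_MAGIC)
        handle.write(struct.pack("<Q", len(payload)))
        handle.write(payload)
        handle.write(body)


def load_index(path: str | Path) -> EmbeddingIndex:
    """Read an index container written by :func:`save_index`.

    Raises on magic/version mismatch and on truncated or oversized files.
    """
    data = Path(path).read_bytes()
    if len(data) < len(_MAGIC) + 8 or data[: len(_MAGIC)] != _MAGIC:
        raise ValueError(f"{path}: not a chatmatch index file")
    offset = len(_MAGIC)
    (header_len,) = struct.unpack_from("<Q", data, offset)
    offset += 8
    if len(data) < offset + header_len:
        raise ValueError(f"{path}: corrupt index file (truncated header)")
    try:
        header = json.loads(data[offset : offset + header_len].decode("utf-8"))
    except (json.JSONDecodeError, UnicodeDecodeError) as exc:
        raise ValueError(f"{path}: corrupt index file (bad header)") from exc
    offset += header_len
    version = header.get("version")
    if version != INDEX_FORMAT_VERSION:
        raise ValueError(
            f"{path}: index format version {version} not supported "
            f"(this build reads version {INDEX_FORMAT_VERSION})"
        )
    n, d = header["shape"]
    expected = n * d * 8
    body = data[offset:]
    if len(body) != expected:
        raise ValueError(
            f"{path}: corrupt index file (matrix bytes: {len(body)}, "
            f"expected {expected})"
        )
    matrix = np.frombuffer(body, dtype=np.float64).reshape(n, d).copy()
    freqs = None
    if header["frequencies"] is not None:
        freqs = FrequencyTable(
            counts=dict(header["frequencies"]["counts"]),
            total=int(header["frequencies"]["total"]),
        )
    component = None
    if header["common_component"] is not None:
        component = np.array(header["common_component"], dtype=np.float64)
    texts = None if header["texts"] is None else tuple(header["texts"])
    return EmbeddingIndex(
        matrix=matrix,
        chat_ids=tuple(header["chat_ids"]),
        starts=tuple(int(s) for s in header["starts"]),
        token_counts=tuple(int(t) for t in header["token_counts"]),
        config_snapshot=header["config_snapshot"],
        frequencies=freqs,
        common_component=component,
        texts=texts,
    )
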