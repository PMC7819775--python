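"""Chat transcripts: reading, cleaning, filtering, and sliding-window segmentation.

A helpline chat is an ordered two-party transcript (help-seeker and
counselor turns).  Because a single conversation typically moves through
several problems, retrieval operates on short overlapping *windows* of
consecutive messages rather than on whole chats: every run of
``window_size`` consecutive messages (default 5, stride 1) becomes one
retrieval unit.  Chats shorter than ``min_interactions`` messages
(default 20) are dropped from the corpus before segmentation.

The on-disk transcript format is JSON Lines, one chat per line::

    {"chat_id": "<id>", "messages": [{"sender": "helpseeker"|"counselor",
                                      "text": "<utterance>"}, ...]}

Message index is positional.  :func:`read_corpus` applies no text
normalization; call :func:`normalize_corpus` (or :func:`normalize_text`
per string) before computing frequencies or embeddings.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, replace
from enum import Enum
from pathlib import Path
from typing import Iterable, Sequence

__all__ = [
    "Sender",
    "ChatMessage",
    "Chat",
    "ChatWindow",
    "SegmentationConfig",
    "RETAINED_PUNCTUATION",
    "read_corpus",
    "write_corpus",
    "normalize_text",
    "normalize_chat",
    "normalize_corpus",
    "filter_chats",
    "sliding_windows",
    "segment_corpus",
]

#: Sentence punctuation kept by :func:`normalize_text`; everything else
#: outside letters / digits / whitespace is stripped.
RETAINED_PUNCTUATION = ".,?!'-"


class Sender(str, Enum):
    """Which of the two chat parties produced a message."""

    HELPSEEKER = "helpseeker"
    COUNSELOR = "counselor"


@dataclass(frozen=True)
class ChatMessage:
    """One utterance within a chat.

    ``index`` is the 0-based position of the message inside its chat;
    within a :class:`Chat` the indices run 0..m-1 with no gaps.
    """

    sender: Sender
    text: str
    index: int


@dataclass(frozen=True)
class Chat:
    """An ordered two-party transcript with a corpus-unique identifier."""

    chat_id: str
    messages: tuple[ChatMessage, ...]

    def __post_init__(self) -> None:
        for pos, msg in enumerate(self.messages):
            if msg.index != pos:
                raise ValueError(
                    f"chat {self.chat_id!r}: message at position {pos} "
                    f"carries index {msg.index}"
                )

    def __len__(self) -> int:
        return len(self.messages)


@dataclass(frozen=True)
class ChatWindow:
    """A contiguous run of messages from one chat, the retrieval unit.

    Covers message indices ``[start, start + size)``, half-open.  Two
    windows of the same chat with consecutive starts share all but one
    message.
    """

    chat_id: str
    start: int
    texts: tuple[str, ...]

    @property
    def size(self) -> int:
        return len(self.texts)


@dataclass(frozen=True)
class SegmentationConfig:
    """How a corpus is filtered and cut into windows.

    ``window_size`` is the number of consecutive messages per window,
    ``stride`` the step between window starts, and ``min_interactions``
    the minimum message count for a chat to enter the corpus (one
    interaction = one message from either party).
    """

    window_size: int = 5
    stride: int = 1
    min_interactions: int = 20

    def __post_init__(self) -> None:
        if self.window_size < 1:
            raise ValueError("window_size must be >= 1")
        if self.stride < 1:
            raise ValueError("stride must be >= 1")
        if self.min_interactions < self.window_size:
            raise ValueError("min_interactions must be >= window_size")


# ---------------------------------------------------------------------------
# Reading and writing transcripts
# ---------------------------------------------------------------------------


def _parse_chat_record(record: object, lineno: int) -> Chat:
    if not isinstance(record, dict):
        raise ValueError(f"line {lineno}: chat record is not a JSON object")
    if "chat_id" not in record:
        raise ValueError(f"line {lineno}: record missing 'chat_id' field")
    if "messages" not in record:
        raise ValueError(f"line {lineno}: record missing 'messages' field")
    chat_id = record["chat_id"]
    if not isinstance(chat_id, str) or not chat_id:
        raise ValueError(f"line {lineno}: 'chat_id' must be a non-empty string")
    raw_messages = record["messages"]
    if not isinstance(raw_messages, list):
        raise ValueError(f"line {lineno}: 'messages' must be a list")
    messages = []
    for pos, msg in enumerate(raw_messages):
        if not isinstance(msg, dict) or "sender" not in msg or "text" not in msg:
            raise ValueError(
                f"line {lineno}: message {pos} must be an object with "
                f"'sender' and 'text' fields"
            )
        try:
            sender = Sender(msg["sender"])
        except ValueError:
            raise ValueError(
                f"line {lineno}: message {pos} has unknown sender "
                f"{msg['sender']!r}"
            ) from None
        if not isinstance(msg["text"], str):
            raise ValueError(f"line {lineno}: message {pos} text is not a string")
        messages.append(ChatMessage(sender=sender, text=msg["text"], index=pos))
    return Chat(chat_id=chat_id, messages=tuple(messages))


def read_corpus(path: str | Path, format: str = "jsonl") -> list[Chat]:
    """Read a chat corpus from ``path``, preserving file and message order.

    Raises :class:`ValueError` naming the offending line for malformed
    records and for duplicate ``chat_id`` values.
    """
    if format != "jsonl":
        raise ValueError(f"unsupported corpus format: {format!r}")
    chats: list[Chat] = []
    seen: set[str] = set()
    with open(path, "r", encoding="utf-8") as handle:
        for lineno, line in enumerate(handle, start=1):
            if not line.strip():
                continue
            try:
                record = json.loads(line)
            except json.JSONDecodeError as exc:
                raise ValueError(f"line {lineno}: invalid JSON ({exc.msg})") from exc
            chat = _parse_chat_record(record, lineno)
            if chat.chat_id in seen:
                raise ValueError(
                    f"line {lineno}: duplicate chat_id {chat.chat_id!r}"
                )
            seen.add(chat.chat_id)
            chats.append(chat)
    return chats


def write_corpus(chats: Iterable[Chat], path: str | Path) -> None:
    """Write chats to ``path`` in the JSON Lines transcript format.

    Output is deterministic: keys are emitted in a fixed order with no
    whitespace padding, so identical corpora yield identical bytes.
    """
    with open(path, "w", encoding="utf-8") as handle:
        for chat in chats:
            record = {
                "chat_id": chat.chat_id,
                "messages": [
                    {"sender": m.sender.value, "text": m.text}
                    for m in chat.messages
                ],
            }
            handle.write(json.dumps(record, ensure_ascii=False, separators=(",", ":")))
            handle.write("\n")


# ---------------------------------------------------------------------------
# Normalization
# ---------------------------------------------------------------------------


def normalize_text(text: str) -> str:
    """Lowercase ``text`` and strip special symbols.

    Keeps Unicode letters, digits, whitespace, and the sentence
    punctuation ``. , ? ! ' -``; drops everything else (emoji, control
    characters, other symbols).  Runs of whitespace collapse to single
    spaces and leading/trailing whitespace is removed.  Idempotent.
    """
    lowered = text.lower()
    kept = [
        ch
        for ch in lowered
        if ch.isalpha() or ch.isdigit() or ch.isspace() or ch in RETAINED_PUNCTUATION
    ]
    return " ".join("".join(kept).split())


def normalize_chat(chat: Chat) -> Chat:
    """Return a copy of ``chat`` with every message text normalized."""
    return replace(
        chat,
        messages=tuple(
            replace(m, text=normalize_text(m.text)) for m in chat.messages
        ),
    )


def normalize_corpus(chats: Sequence[Chat]) -> list[Chat]:
    """Normalize every chat in a corpus, preserving order."""
    return [normalize_chat(c) for c in chats]


# ---------------------------------------------------------------------------
# Filtering and segmentation
# ---------------------------------------------------------------------------


def filter_chats(chats: Sequence[Chat], min_interactions: int) -> list[Chat]:
    """Keep exactly the chats with at least ``min_interactions`` messages.

    A chat of exactly ``min_interactions`` messages is retained.  Order
    is preserved and chats are not copied or mutated.
    """
    if min_interactions < 1:
        raise ValueError("min_interactions must be >= 1")
    return [c for c in chats if len(c) >= min_interactions]


def sliding_windows(
    chat: Chat, config: SegmentationConfig | None = None
) -> list[ChatWindow]:
    """Enumerate every window of ``config.window_size`` consecutive messages.

    A chat of ``m`` messages yields ``max(0, m - w + 1)`` windows at
    stride 1: starts 0, 1, ..., m - w.  The first window covers messages
    ``[0, w)``, the next drops the first message and appends the one
    after the window, and so on.  Chats shorter than the window yield an
    empty list — short query-side chats are legal at this layer.
    """
    if config is None:
        config = SegmentationConfig()
    w = config.window_size
    m = len(chat)
    windows = []
    for start in range(0, m - w + 1, config.stride):
        texts = tuple(msg.text for msg in chat.messages[start : start + w])
        windows.append(ChatWindow(chat_id=chat.chat_id, start=start, texts=texts))
    return windows


def segment_corpus(
    chats: Sequence[Chat], config: SegmentationConfig | None = None
) -> list[ChatWindow]:
    """Concatenate :func:`sliding_windows` over every chat, in corpus order."""
    if config is None:
        config = SegmentationConfig()
    out: list[ChatWindow] = []
    for chat in chats:
        out.extend(sliding_windows(chat, config))
    return out
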