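import numpy as np
import pytest
from hypothesis import settings

from chatmatch import (
    Chat,
    ChatMessage,
    FrequencyTable,
    Sender,
    WordVectorStore,
)

settings.register_profile("default", derandomize=True, max_examples=50, deadline=None)
settings.load_profile("default")


def make_chat(chat_id: str, texts) -> Chat:
    """Build a chat from plain strings, alternating senders."""
    messages = tuple(
        ChatMessage(
            sender=Sender.HELPSEEKER if i % 2 == 0 else Sender.COUNSELOR,
            text=text,
            index=i,
        )
        for i, text in enumerate(texts)
    )
    return Chat(chat_id=chat_id, messages=messages)


@pytest.fixture
def chat_factory():
    return make_chat


@pytest.fixture
def tiny_store() -> WordVectorStore:
    """Four 4-dimensional word vectors with simple integer coordinates."""
    return WordVectorStore(
        dimension=4,
        vectors={
            "hoi": np.array([1.0, 0.0, 0.0, 0.0]),
            "hoe": np.array([0.0, 1.0, 0.0, 0.0]),
            "gaat": np.array([0.0, 0.0, 1.0, 0.0]),
            "het": np.array([1.0, 1.0, 1.0, 1.0]),
        },
    )


@pytest.fixture
def tiny_freqs() -> FrequencyTable:
    return FrequencyTable(
        counts={"hoi": 10, "hoe": 20, "gaat": 30, "het": 40}, total=100
    )
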