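"""Cosine retrieval: index construction, querying, context, persistence."""

import numpy as np
import pytest

from chatmatch import (
    EmbeddingConfig,
    QueryConfig,
    SegmentationConfig,
    WindowEmbedding,
    build_index,
    compute_word_frequencies,
    cosine_similarity,
    embed_query,
    embed_windows,
    fetch_context,
    load_index,
    query,
    save_index,
    segment_corpus,
    sif_embed,
)
from chatmatch.index import INDEX_FORMAT_VERSION

from .conftest import make_chat


def brute_force_query(index, qvec, config):
    """Independent oracle: per-row cosine loop plus an explicit sort."""
    rows = []
    qvec = np.asarray(qvec, dtype=np.float64)
    mask = index.rankable_mask()
    for i in range(len(index)):
        if not mask[i] or index.chat_ids[i] in config.exclude_chat_ids:
            continue
        score = cosine_similarity(index.matrix[i], qvec)
        rows.append((score, index.chat_ids[i], index.starts[i]))
    rows.sort(key=lambda r: (-r[0], r[1], r[2]))
    out, seen = [], set()
    for score, cid, start in rows:
        if config.dedup_per_chat:
            if cid in seen:
                continue
            seen.add(cid)
        out.append((cid, start, score))
        if len(out) == config.top_k:
            break
    return out


def random_embeddings(rng, n, dim=6, n_chats=8, zero_fraction=0.1):
    out = []
    for i in range(n):
        cid = f"c{int(rng.integers(n_chats))}"
        if rng.random() < zero_fraction:
            vec, count = np.zeros(dim), 0
        else:
            vec, count = rng.standard_normal(dim), int(rng.integers(1, 20))
        out.append(WindowEmbedding(chat_id=cid, start=i, vector=vec,
                                   token_count=count))
    return out


class TestCosine:
    def test_identity_orthogonal_antipodal(self):
        u = np.array([1.0, 2.0, 2.0])
        assert cosine_similarity(u, u) == pytest.approx(1.0)
        assert cosine_similarity([1, 0], [0, 3]) == pytest.approx(0.0)
        assert cosine_similarity(u, -u) == pytest.approx(-1.0)

    def test_zero_vector_is_an_error(self):
        with pytest.raises(ValueError, match="zero vector"):
            cosine_similarity([0.0, 0.0], [1.0, 1.0])

    def test_dimension_mismatch(self):
        with pytest.raises(ValueError, match="mismatch"):
            cosine_similarity([1.0, 0.0], [1.0, 0.0, 0.0])


class TestBuildIndex:
    def test_row_count_and_zero_flagging(self):
        rng = np.random.default_rng(3)
        embeddings = random_embeddings(rng, 51, zero_fraction=0.0)
        embeddings[4] = WindowEmbedding("c0", 4, np.zeros(6), 0)
        embeddings[9] = WindowEmbedding("c1", 9, np.zeros(6), 0)
        index = build_index(embeddings)
        assert len(index) == 51
        assert index.rankable_mask().sum() == 49

    def test_mixed_dimensions_rejected(self):
        embeddings = [
            WindowEmbedding("a", 0, np.ones(3), 1),
            WindowEmbedding("b", 0, np.ones(4), 1),
        ]
        with pytest.raises(ValueError, match="mixed dimensions"):
            build_index(embeddings)

    def test_empty_index_refuses_queries(self):
        index = build_index([])
        assert len(index) == 0
        with pytest.raises(ValueError, match="empty"):
            query(index, np.ones(1))


class TestQuery:
    def test_identity_retrieval(self):
        rng = np.random.default_rng(7)
        embeddings = random_embeddings(rng, 40, zero_fraction=0.0)
        index = build_index(embeddings)
        target = embeddings[17]
        results = query(index, target.vector, QueryConfig(top_k=3))
        assert results[0].chat_id == target.chat_id
        assert results[0].start == target.start
        assert results[0].score == pytest.approx(1.0, abs=1e-9)

    def test_matches_brute_force_scan(self):
        rng = np.random.default_rng(11)
        embeddings = random_embeddings(rng, 200)
        index = build_index(embeddings)
        config = QueryConfig(top_k=10)
        qvec = rng.standard_normal(6)
        results = query(index, qvec, config)
        expected = brute_force_query(index, qvec, config)
        assert [(r.chat_id, r.start) for r in results] == [
            (cid, start) for cid, start, _ in expected
        ]
        for r, (_, _, score) in zip(results, expected):
            assert r.score == pytest.approx(score, abs=1e-9)
        assert [r.rank for r in results] == list(range(1, len(results) + 1))

    def test_truncation_when_fewer_candidates(self):
        rng = np.random.default_rng(2)
        index = build_index(random_embeddings(rng, 6, zero_fraction=0.0))
        results = query(index, np.ones(6), QueryConfig(top_k=10))
        assert len(results) == 6

    def test_scores_non_increasing_and_bounded(self):
        rng = np.random.default_rng(5)
        index = build_index(random_embeddings(rng, 120))
        results = query(index, rng.standard_normal(6), QueryConfig(top_k=20))
        scores = [r.score for r in results]
        assert all(-1.0 - 1e-12 <= s <= 1.0 + 1e-12 for s in scores)
        assert all(a >= b for a, b in zip(scores, scores[1:]))

    def test_dedup_per_chat(self):
        rng = np.random.default_rng(13)
        index = build_index(random_embeddings(rng, 100, n_chats=5))
        results = query(index, rng.standard_normal(6),
                        QueryConfig(top_k=10, dedup_per_chat=True))
        ids = [r.chat_id for r in results]
        assert len(ids) == len(set(ids))

    def test_exclude_chat_ids(self):
        rng = np.random.default_rng(17)
        index = build_index(random_embeddings(rng, 100, n_chats=4))
        results = query(
            index,
            rng.standard_normal(6),
            QueryConfig(top_k=50, exclude_chat_ids=frozenset({"c0", "c1"})),
        )
        assert all(r.chat_id in {"c2", "c3"} for r in results)

    def test_permutation_invariance(self):
        rng = np.random.default_rng(19)
        embeddings = random_embeddings(rng, 80)
        shuffled = list(embeddings)
        rng.shuffle(shuffled)
        qvec = rng.standard_normal(6)
        a = query(build_index(embeddings), qvec, QueryConfig(top_k=10))
        b = query(build_index(shuffled), qvec, QueryConfig(top_k=10))
        assert a == b

    def test_exact_ties_break_by_chat_id_then_start(self):
        v = np.array([1.0, 1.0, 0.0])
        embeddings = [
            WindowEmbedding("cB", 3, v.copy(), 1),
            WindowEmbedding("cA", 7, 2 * v, 1),  # same direction, same cosine
            WindowEmbedding("cA", 2, v.copy(), 1),
            WindowEmbedding("cC", 0, np.array([0.0, 1.0, 0.0]), 1),
        ]
        results = query(build_index(embeddings), v, QueryConfig(top_k=4))
        assert [(r.chat_id, r.start) for r in results[:3]] == [
            ("cA", 2), ("cA", 7), ("cB", 3)
        ]

    def test_dimension_mismatch_and_zero_query(self):
        rng = np.random.default_rng(23)
        index = build_index(random_embeddings(rng, 10, zero_fraction=0.0))
        with pytest.raises(ValueError, match="dimension"):
            query(index, np.ones(3))
        with pytest.raises(ValueError, match="zero"):
            query(index, np.zeros(6))


class TestEmbedQuery:
    def test_uses_only_the_last_context_messages(self, tiny_store, tiny_freqs):
        texts = ["xxxx"] * 7 + ["hoi", "hoe", "gaat", "het", "hoi hoe"]
        ongoing = make_chat("q", texts)
        qvec = embed_query(ongoing, tiny_store, tiny_freqs)
        direct = sif_embed(
            ["hoi", "hoe", "gaat", "het", "hoi", "hoe"], tiny_store, tiny_freqs
        )
        assert np.allclose(qvec, direct, rtol=0, atol=1e-15)

    def test_short_chat_uses_everything(self, tiny_store, tiny_freqs):
        ongoing = make_chat("q", ["hoi", "hoe", "gaat"])
        qvec = embed_query(ongoing, tiny_store, tiny_freqs)
        direct = sif_embed(["hoi", "hoe", "gaat"], tiny_store, tiny_freqs)
        assert np.allclose(qvec, direct, rtol=0, atol=1e-15)

    def test_query_matching_corpus_window_scores_one(self, tiny_store):
        chats = [make_chat("c", ["hoi hoe", "gaat het", "hoi", "het gaat", "hoe"] * 4)]
        freqs = compute_word_frequencies(chats)
        windows = segment_corpus(chats, SegmentationConfig())
        index = build_index(embed_windows(windows, tiny_store, freqs))
        ongoing = make_chat("q", [m.text for m in chats[0].messages[:5]])
        qvec = embed_query(ongoing, tiny_store, freqs)
        top = query(index, qvec, QueryConfig(top_k=1))[0]
        assert top.score == pytest.approx(1.0, abs=1e-9)
        assert (top.chat_id, top.start) == ("c", 0)

    def test_unembeddable_query_is_an_error(self, tiny_store, tiny_freqs):
        ongoing = make_chat("q", ["zzz", "qqq"])
        with pytest.raises(ValueError, match="no embeddable content"):
            embed_query(ongoing, tiny_store, tiny_freqs)


class TestFetchContext:
    def _corpus(self):
        return [make_chat("c1", [f"m{i}" for i in range(8)]),
                make_chat("c2", [f"n{i}" for i in range(6)])]

    def test_window_texts_match_corpus(self):
        from chatmatch import QueryResult
        corpus = self._corpus()
        result = QueryResult(rank=1, chat_id="c1", start=2, score=0.9)
        window, chat = fetch_context(corpus, result, window_size=5)
        assert window.texts == ("m2", "m3", "m4", "m5", "m6")
        assert chat.chat_id == "c1" and len(chat) == 8

    def test_unknown_chat_is_a_mismatch_error(self):
        from chatmatch import QueryResult
        result = QueryResult(rank=1, chat_id="ghost", start=0, score=0.5)
        with pytest.raises(KeyError, match="not present"):
            fetch_context(self._corpus(), result)

    def test_window_past_chat_end_rejected(self):
        from chatmatch import QueryResult
        result = QueryResult(rank=1, chat_id="c2", start=3, score=0.5)
        with pytest.raises(ValueError, match="does not fit"):
            fetch_context(self._corpus(), result, window_size=5)


class TestPersistence:
    def _build(self, seed=29):
        rng = np.random.default_rng(seed)
        chats = [make_chat(f"c{i}", ["hoi hoe gaat het"] * 20) for i in range(3)]
        freqs = compute_word_frequencies(chats)
        embeddings = random_embeddings(rng, 51)
        return build_index(embeddings, SegmentationConfig(), EmbeddingConfig(),
                           frequencies=freqs)

    def test_roundtrip_bit_compatible(self, tmp_path):
        index = self._build()
        p1, p2 = tmp_path / "a.idx", tmp_path / "b.idx"
        save_index(index, p1)
        back = load_index(p1)
        save_index(back, p2)
        assert p1.read_bytes() == p2.read_bytes()
        assert np.array_equal(back.matrix, index.matrix)
        assert back.chat_ids == index.chat_ids
        assert back.starts == index.starts
        assert back.token_counts == index.token_counts
        assert back.config_snapshot == index.config_snapshot
        assert back.frequencies.counts == index.frequencies.counts

    def test_roundtrip_preserves_query_results(self, tmp_path):
        index = self._build()
        save_index(index, tmp_path / "x.idx")
        back = load_index(tmp_path / "x.idx")
        qvec = np.random.default_rng(31).standard_normal(6)
        assert query(back, qvec, QueryConfig(top_k=10)) == query(
            index, qvec, QueryConfig(top_k=10)
        )

    def test_truncated_file_is_corrupt(self, tmp_path):
        path = tmp_path / "x.idx"
        save_index(self._build(), path)
        path.write_bytes(path.read_bytes()[:-16])
        with pytest.raises(ValueError, match="corrupt"):
            load_index(path)

    def test_future_version_rejected(self, tmp_path):
        import json, struct
        path = tmp_path / "future.idx"
        header = json.dumps({"version": INDEX_FORMAT_VERSION + 1}).encode()
        path.write_bytes(b"CMIDX" + struct.pack("<Q", len(header)) + header)
        with pytest.raises(ValueError, match="version"):
            load_index(path)

    def test_not_an_index_file(self, tmp_path):
        path = tmp_path / "junk.idx"
        path.write_bytes(b"hello world, definitely not an index")
        with pytest.raises(ValueError, match="not a chatmatch index"):
            load_index(path)
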