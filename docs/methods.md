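# Methods

## The retrieval model

`chatmatch` is a content-based recommender over archived two-party
helpline chats. Its retrieval unit is the *window*: a run of `w`
consecutive messages from one chat, enumerated at stride 1, so a chat of
`m` messages contributes `max(0, m − w + 1)` windows and consecutive
windows share `w − 1` messages. Windows rather than whole chats are
indexed because one conversation typically traverses several distinct
problems; a 5-message span is long enough to carry a topic and short
enough to stay on one.

Each window is embedded by smooth inverse frequency (SIF) weighting:
with kept tokens `w₁…wₙ` — tokens present in both the word-vector store
and the corpus frequency table —

    v = (1/n) · Σᵢ a/(a + p(wᵢ)) · vec(wᵢ)

where `p(w)` is the word's relative frequency in the (filtered) chat
corpus itself. The weight `a/(a+p)` is strictly decreasing in `p`, so
frequent function words contribute little and rare content words
dominate; as `a → ∞` the embedding converges to the plain token mean.
A query is the identical embedding of the last `context_size` messages
of an ongoing conversation, and retrieval is an exact cosine-similarity
scan returning the `top_k` windows, each traceable to its source
transcript.

Assumptions worth stating: the embedding is bag-of-words (order within
the window is ignored); both parties' messages enter the window text
with equal weight; out-of-vocabulary tokens are skipped rather than
imputed, and the `1/n` average runs over kept tokens only, so OOV
density does not shrink vectors.

## Parameters

| parameter | default | meaning / rationale |
|---|---|---|
| `window_size` | 5 messages | segment length; the span shown to the counselor |
| `stride` | 1 | every possible window is indexed |
| `min_interactions` | 20 messages | chats shorter than this are dropped; one interaction = one message from either party; a chat of exactly 20 is kept |
| `sif_a` | 1e-3 | SIF smoothing constant, the canonical choice for the scheme; only the relative ordering of weights matters for ranking |
| `oov_policy` | skip | any imputation would invent geometry |
| `remove_common_component` | off | the SIF scheme optionally removes the first principal component of the embedding set; off by default, available for experimentation (the component is stored in the index so queries are projected identically) |
| `top_k` | 10 | recommendations shown per query |
| `context_size` | 5 messages | query tail length, matching the corpus window |
| `dedup_per_chat` | off | overlapping windows of one chat may legitimately crowd the top-10; the flag keeps one best window per chat |

Tie-breaking in ranking is deterministic by `(chat_id, start)`
ascending, so results are independent of index row order.

## The synthetic corpus

Real helpline transcripts are confidential; the generator produces a
corpus with the one property retrieval depends on — conversations about
the same problem use similar vocabulary whose vectors cluster — plus
known ground truth for scoring.

Every chat draws one latent topic uniformly; messages draw tokens from
the topic's vocabulary, mixed with a shared vocabulary at rate 0.3
(shared words are ~10× more frequent per word than topic words, giving
the SIF weighting something to down-weight). Topic centroids are random
unit directions scaled by `topic_separation · noise_sd · √dimension`;
a topic word's vector is its centroid plus `N(0, noise_sd² I)` noise, so
`topic_separation` measures centroid distance relative to the typical
within-topic noise and `topic_separation = 0` removes all topic
structure from the geometry.

Defaults: 200 chats of 20–40 messages (all pass the 20-message filter),
5 topics, 4–12 tokens per message, 32-dimensional vectors, separation 3,
`vocab_per_topic = 6000`, `shared_vocab = 600`. The vocabulary is
deliberately large relative to the ~170 topic-word draws a single chat
makes: two same-topic conversations then rarely share content words, so
topical similarity must be carried by the clustered vector geometry
rather than by literal word overlap. This mirrors the situation that
motivates embedding-based retrieval in the first place (different people
describe the same problem in different words), and it makes the
separation dial honest — with a small vocabulary, lexical identity alone
lets retrieval find same-topic windows even at separation 0.

What the generator does *not* emulate: Zipfian word frequencies,
realistic dialogue structure beyond sender alternation, topic drift
within a chat (topics are chat-level), polysemy, and anything about the
emotional content of real helpline text. Passing tests therefore show
that the pipeline ranks by topical content when such content exists and
is geometrically encoded — not that it reaches any particular quality on
real conversations.

## The validity experiment

The in-silico experiment mirrors a matched-vs-random rating design: per
query (an ongoing chat generated from a known topic), 5 algorithm-matched
segments (the top-5 retrieval results) and 5 segments drawn uniformly
without replacement from the remaining rankable windows are each scored
by a ground-truth oracle — 1 if the segment's source chat shares the
query's topic, 0 otherwise. The random half is drawn excluding the
matched set to prevent label leakage. A report aggregates 3 queries ×
10 segments (30 judgments), the matched and random means, their gap, and
precision@10 of the full ranking. Oracle scores replace human similarity
ratings, so the testable content is direction and calibration: the gap
must be positive whenever topic structure exists, near the chance level
difference of zero when `topic_separation = 0`, and the random half must
sit near the 1/n_topics base rate. Per-trial records are exposed so any
downstream statistics can be run externally.

The standard experiment sizes used by the tests and by
`scripts/acceptance.py` — 20 replicates of the structured condition and
10 of the zero-separation control, each a full pipeline run over ~5,200
windows — keep every result a fresh computation while each replicate
runs in under a second.

## Numerical choices and degenerate inputs

* All vectors are float64; the index persists the raw matrix bytes, so
  save/load round-trips are bit-exact and seeded runs are byte-identical
  end to end.
* A window with no embeddable token maps to the zero vector, is flagged
  (`token_count = 0`), kept in the index metadata, and excluded from
  ranking; cosine against a zero vector is an error by contract, never a
  silent 0.
* Chats shorter than the window yield empty window sets, not errors —
  the corpus filter runs upstream, and query-side chats may be short
  (a query uses `min(m, context_size)` trailing messages).
* Text normalization is idempotent and closed over
  letters/digits/whitespace plus `. , ? ! ' -`; tokenization strips that
  punctuation from token edges only, preserving internal hyphens and
  apostrophes.
* The first-principal-component sign is fixed (largest-magnitude
  coordinate positive) so the optional common-component removal is
  deterministic.

## Known limitations

* Exact search scans the full matrix per query; fine at desk scale and
  for corpora of a few million windows, but there is no approximate
  backend.
* Frequencies and the index are static snapshots of one corpus; no
  incremental updates as new chats arrive.
* The oracle equates "same problem" with "same generated topic"; real
  similarity judgments are graded, not binary.
* The CLI's `query` needs the word-vector file alongside the index
  (vectors are an input, not part of the index artifact); the corpus
  frequency table, by contrast, travels inside the index.
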