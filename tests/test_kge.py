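import numpy as np
import pytest

from kgenfm.errors import DimensionError, LookupEntityError, SamplingError
from kgenfm.kg import EntityVocab, KnowledgeGraph, Triple
from kgenfm.kge import (
    EmbeddingTable,
    KGETrainConfig,
    corrupt_triples,
    distmult_score,
    init_embeddings,
    rank_triples,
    rescal_score,
    train_kge,
)


class TestScores:
    def test_hand_example(self):
        assert distmult_score([1, 2], [3, 4], [5, 6]) == pytest.approx(63.0)

    def test_zero_head_annihilates(self):
        rng = np.random.default_rng(0)
        r, t = rng.normal(size=5), rng.normal(size=5)
        assert distmult_score(np.zeros(5), r, t) == 0.0

    def test_head_tail_symmetry(self):
        rng = np.random.default_rng(1)
        for _ in range(20):
            h, r, t = rng.normal(size=(3, 8))
            assert distmult_score(h, r, t) == pytest.approx(distmult_score(t, r, h))

    def test_length_mismatch(self):
        with pytest.raises(DimensionError):
            distmult_score([1, 2], [1, 2, 3], [1, 2])

    def test_rescal_identity_is_dot(self):
        rng = np.random.default_rng(2)
        h, t = rng.normal(size=(2, 6))
        assert rescal_score(h, np.eye(6), t) == pytest.approx(float(h @ t))

    def test_rescal_hand_matrix(self):
        assert rescal_score([1, 0], [[0, 1], [2, 0]], [0, 1]) == pytest.approx(1.0)

    def test_rescal_reduces_to_distmult_on_diagonal(self):
        # the diagonal-restriction equivalence, over many random draws
        rng = np.random.default_rng(3)
        for _ in range(1000):
            d = int(rng.integers(1, 12))
            h, r, t = rng.normal(size=(3, d))
            assert rescal_score(h, np.diag(r), t) == pytest.approx(
                distmult_score(h, r, t), abs=1e-9
            )

    def test_rescal_shape_mismatch(self):
        with pytest.raises(DimensionError):
            rescal_score([1, 2], np.eye(3), [1, 2])


@pytest.fixture
def toy_vocab():
    kg = KnowledgeGraph(triples=[Triple("a", "r", "b"), Triple("b", "r", "c")])
    return kg, EntityVocab.from_kg(kg)


class TestCorruption:
    def test_eta_zero_empty(self, toy_vocab):
        kg, vocab = toy_vocab
        assert corrupt_triples(kg.triples, vocab, 0, 0, kg.triple_set()) == []

    def test_single_slot_changed(self, toy_vocab):
        # corruptions come back eta-per-input in order; each differs from its
        # source in exactly one of head/tail
        kg, vocab = toy_vocab
        eta = 10
        out = corrupt_triples(kg.triples, vocab, eta, 0, kg.triple_set())
        assert len(out) == eta * len(kg.triples)
        for i, src in enumerate(kg.triples):
            for c in out[i * eta : (i + 1) * eta]:
                assert c.relation == src.relation
                assert (c.head == src.head) != (c.tail == src.tail)

    def test_two_entity_exhaustive_filter(self):
        # entities {a,b}; true triples cover 3 of 4 possible -> only the
        # remaining untrue corruption may ever be produced
        kg = KnowledgeGraph(
            triples=[Triple("a", "r", "a"), Triple("a", "r", "b"), Triple("b", "r", "a")]
        )
        vocab = EntityVocab.from_kg(kg)
        known = kg.triple_set()
        # (a,r,a) itself admits no corruption: all four (h,t) combinations are known
        batch = [Triple("a", "r", "b"), Triple("b", "r", "a")]
        out = corrupt_triples(batch, vocab, 4, 0, known)
        assert out and set(out) == {Triple("b", "r", "b")}

    def test_deterministic_per_seed(self, toy_vocab):
        kg, vocab = toy_vocab
        a = corrupt_triples(kg.triples, vocab, 5, 42, kg.triple_set())
        b = corrupt_triples(kg.triples, vocab, 5, 42, kg.triple_set())
        assert a == b

    def test_singleton_vocab_impossible(self):
        kg = KnowledgeGraph(triples=[Triple("a", "r", "a")])
        with pytest.raises(SamplingError):
            corrupt_triples(kg.triples, EntityVocab.from_kg(kg), 1, 0, set())


def planted_block_kg(seed=0, size=10, p=0.6):
    """Relation holds only within two blocks; cross-block pairs behave as negatives."""
    rng = np.random.default_rng(seed)
    blocks = [[f"a{i}" for i in range(size)], [f"b{i}" for i in range(size)]]
    triples, held_out = [], []
    for block in blocks:
        for i in range(size):
            for j in range(size):
                if i == j:
                    continue
                t = Triple(block[i], "rel", block[j])
                if rng.random() < p:
                    triples.append(t)
                else:
                    held_out.append(t)
    return KnowledgeGraph(triples=triples), held_out, blocks


class TestTraining:
    CFG = dict(dim=16, epochs=150, learning_rate=0.05, eta=5, l2=1e-6, batch_size=64)

    def test_zero_epochs_is_init(self, toy_vocab):
        kg, _ = toy_vocab
        cfg = KGETrainConfig(dim=4, epochs=0, seed=9)
        out = train_kge(kg, cfg)
        ref = init_embeddings(kg, cfg)
        for e in ref.entity_vectors:
            np.testing.assert_array_equal(out.entity_vectors[e], ref.entity_vectors[e])

    def test_seed_determinism(self, toy_vocab):
        kg, _ = toy_vocab
        cfg = KGETrainConfig(dim=4, epochs=5, seed=3, batch_size=2)
        a, b = train_kge(kg, cfg), train_kge(kg, cfg)
        for e in a.entity_vectors:
            np.testing.assert_array_equal(a.entity_vectors[e], b.entity_vectors[e])

    def test_planted_blocks_separate(self):
        kg, held_out, blocks = planted_block_kg()
        emb = train_kge(kg, KGETrainConfig(seed=0, **self.CFG))
        within = [emb.score(t) for t in held_out]
        cross = [
            emb.score(Triple(a, "rel", b))
            for a in blocks[0][:5] for b in blocks[1][:5]
        ]
        assert np.mean(within) > np.mean(cross)

    def test_l2_bounds_norms(self):
        kg, _, _ = planted_block_kg()
        emb = train_kge(kg, KGETrainConfig(dim=8, epochs=60, learning_rate=0.05,
                                           eta=5, l2=1e-3, batch_size=64, seed=1))
        norms = [np.linalg.norm(v) for v in emb.entity_vectors.values()]
        assert np.isfinite(norms).all() and max(norms) < 50.0

    def test_hits_at_3_beats_random_baseline(self):
        kg, held_out, _ = planted_block_kg(seed=2)
        emb = train_kge(kg, KGETrainConfig(seed=2, **self.CFG))
        metrics = rank_triples(emb, held_out[:40], kg)
        random_hits3 = 3 / len(kg.entities())
        assert metrics["hits@3"] >= 5 * random_hits3


class TestRanking:
    def make_emb(self, scores_by_tail):
        # 1-d embeddings: h=1, r=1, tail value = desired score
        ents = {"h": np.array([1.0])}
        ents.update({k: np.array([v]) for k, v in scores_by_tail.items()})
        return EmbeddingTable(entity_vectors=ents, relation_vectors={"r": np.array([1.0])}, dim=1)

    def test_top_ranked_gives_mrr_one(self):
        emb = self.make_emb({"t": 9.0, "x": 1.0, "y": 2.0})
        kg = KnowledgeGraph(triples=[Triple("h", "r", "t")])
        assert rank_triples(emb, [Triple("h", "r", "t")], kg)["mrr"] == pytest.approx(1.0)

    def test_second_of_four_gives_half(self):
        emb = self.make_emb({"t": 3.0, "x": 9.0, "y": 2.0, "z": 1.0})
        kg = KnowledgeGraph(triples=[Triple("h", "r", "t")])
        # candidates: t,x,y,z and the entity 'h' itself -> give h a low value
        emb.entity_vectors["h"] = np.array([1.0])
        metrics = rank_triples(emb, [Triple("h", "r", "t")], kg)
        assert metrics["mrr"] == pytest.approx(0.5)

    def test_all_tied_scores_use_mean_rank(self):
        emb = self.make_emb({"t": 0.0, "x": 0.0, "y": 0.0})
        for e in emb.entity_vectors:
            emb.entity_vectors[e] = np.array([0.0])
        kg = KnowledgeGraph(triples=[Triple("h", "r", "t")])
        m = len(emb.entity_vectors)  # all candidates tie
        assert rank_triples(emb, [Triple("h", "r", "t")], kg)["mrr"] == pytest.approx(
            2.0 / (m + 1)
        )

    def test_unknown_entity_raises(self):
        emb = self.make_emb({"t": 1.0})
        kg = KnowledgeGraph(triples=[Triple("h", "r", "t")])
        with pytest.raises(LookupEntityError):
            rank_triples(emb, [Triple("h", "r", "nope")], kg)


class TestSerialization:
    def test_tsv_round_trip(self, tmp_path, toy_vocab):
        kg, _ = toy_vocab
        emb = train_kge(kg, KGETrainConfig(dim=3, epochs=2, batch_size=2, seed=0))
        path = tmp_path / "emb.tsv"
        emb.write_tsv(path)
        back = EmbeddingTable.read_tsv(path)
        assert back.dim == emb.dim
        for e, v in emb.entity_vectors.items():
            np.testing.assert_array_equal(back.entity_vectors[e], v)
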