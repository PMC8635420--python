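"""DistMult knowledge-graph embeddings.

DistMult restricts RESCAL's per-relation bilinear matrix M_r to a diagonal
diag(r), so a triple (h, r, t) scores

    f_r(h, t) = h^T diag(r) t = sum_i r_i * h_i * t_i,

which is symmetric in head and tail.  Training maximizes the score of
observed triples against "corruptions" (the same triple with head or tail
replaced by a random entity, filtered so a corruption never equals a known
fact): each scored triple contributes a binary logistic loss (positives vs.
corruptions) and all embeddings carry an L2 penalty.  Optimization is Adam
over mini-batches drawn without replacement each epoch; everything is
deterministic given the config seed.

Embedding tables serialize as TSV (id, v_1..v_d) with a one-line header
giving d.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np

from .errors import (
    DimensionError,
    LookupEntityError,
    ParseError,
    SamplingError,
    TrainingDivergedError,
)
from .kg import EntityVocab, KnowledgeGraph, Triple


def distmult_score(h: np.ndarray, r: np.ndarray, t: np.ndarray) -> float:
    """Triple product sum sum_i r_i h_i t_i; symmetric in h and t."""
    h, r, t = np.asarray(h, float), np.asarray(r, float), np.asarray(t, float)
    if not (h.shape == r.shape == t.shape and h.ndim == 1):
        raise DimensionError(
            f"distmult_score needs equal-length vectors, got {h.shape}, {r.shape}, {t.shape}"
        )
    return float(np.sum(r * h * t))


def rescal_score(h: np.ndarray, M: np.ndarray, t: np.ndarray) -> float:
    """Full bilinear score h^T M t (DistMult is the M = diag(r) special case)."""
    h, M, t = np.asarray(h, float), np.asarray(M, float), np.asarray(t, float)
    if M.ndim != 2 or M.shape != (h.shape[0], t.shape[0]):
        raise DimensionError(f"shape mismatch: h {h.shape}, M {M.shape}, t {t.shape}")
    return float(h @ M @ t)


@dataclass
class KGETrainConfig:
    dim: int = 64
    epochs: int = 100
    learning_rate: float = 0.05
    eta: int = 5  # corruptions per positive
    l2: float = 1e-6
    batch_size: int = 512
    seed: int = 0

    def __post_init__(self) -> None:
        if self.dim < 1 or self.epochs < 0 or self.eta < 0 or self.learning_rate <= 0:
            raise ValueError(f"invalid KGE config: {self}")


@dataclass
class EmbeddingTable:
    """d-dimensional vectors for every entity and relation of a KG."""

    entity_vectors: dict[str, np.ndarray]
    relation_vectors: dict[str, np.ndarray]
    dim: int

    def entity_matrix(self, ids: list[str]) -> np.ndarray:
        try:
            return np.stack([self.entity_vectors[e] for e in ids])
        except KeyError as exc:
            raise LookupEntityError(f"unknown entity {exc.args[0]!r}") from None

    def score(self, triple: Triple) -> float:
        try:
            h = self.entity_vectors[triple.head]
            t = self.entity_vectors[triple.tail]
            r = self.relation_vectors[triple.relation]
        except KeyError as exc:
            raise LookupEntityError(f"unknown id {exc.args[0]!r}") from None
        return distmult_score(h, r, t)

    def write_tsv(self, path: str | Path) -> None:
        with open(path, "w", encoding="utf-8") as fh:
            fh.write(f"# dim={self.dim}\n")
            for kind, table in (("E", self.entity_vectors), ("R", self.relation_vectors)):
                for name in sorted(table):
                    vec = "\t".join(repr(float(v)) for v in table[name])
                    fh.write(f"{kind}\t{name}\t{vec}\n")

    @classmethod
    def read_tsv(cls, path: str | Path) -> "EmbeddingTable":
        ents: dict[str, np.ndarray] = {}
        rels: dict[str, np.ndarray] = {}
        dim = None
        with open(path, encoding="utf-8") as fh:
            header = fh.readline().strip()
            if not header.startswith("# dim="):
                raise ParseError(f"{path}:1: missing '# dim=' header")
            dim = int(header.split("=", 1)[1])
            for lineno, line in enumerate(fh, start=2):
                parts = line.rstrip("\n").split("\t")
                if len(parts) != dim + 2:
                    raise ParseError(f"{path}:{lineno}: expected {dim + 2} fields")
                kind, name, vec = parts[0], parts[1], np.array(parts[2:], float)
                (ents if kind == "E" else rels)[name] = vec
        return cls(entity_vectors=ents, relation_vectors=rels, dim=dim)


def corrupt_triples(
    batch: list[Triple],
    vocab: EntityVocab,
    eta: int,
    seed: int | np.random.Generator,
    known: frozenset[Triple] | set[Triple],
) -> list[Triple]:
    """Uniform filtered head/tail corruptions, eta per input triple.

    Each corruption flips a fair coin for head vs. tail and replaces it with a
    uniform entity; draws equal to a member of ``known`` (or to the source
    triple) are rejected and resampled, so corruptions behave as negatives.
    """
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    entities = vocab.entity_ids()
    if eta == 0 or not batch:
        return []
    if len(entities) <= 1:
        raise SamplingError("cannot corrupt triples with a vocabulary of size <= 1")
    out: list[Triple] = []
    for triple in batch:
        for _ in range(eta):
            for attempt in range(1000):
                replace_head = bool(rng.integers(2))
                e = entities[int(rng.integers(len(entities)))]
                cand = (
                    Triple(e, triple.relation, triple.tail)
                    if replace_head
                    else Triple(triple.head, triple.relation, e)
                )
                if cand != triple and cand not in known:
                    out.append(cand)
                    break
            else:
                raise SamplingError(
                    f"no admissible corruption for {triple} after 1000 draws"
                )
    return out


class _Adam:
    """Minimal dense Adam for the numpy training loops."""

    def __init__(self, shapes: list[tuple[int, ...]], lr: float,
                 beta1: float = 0.9, beta2: float = 0.999, eps: float = 1e-8):
        self.lr, self.b1, self.b2, self.eps = lr, beta1, beta2, eps
        self.m = [np.zeros(s) for s in shapes]
        self.v = [np.zeros(s) for s in shapes]
        self.t = 0

    def step(self, params: list[np.ndarray], grads: list[np.ndarray]) -> None:
        self.t += 1
        for p, g, m, v in zip(params, grads, self.m, self.v):
            m *= self.b1
            m += (1 - self.b1) * g
            v *= self.b2
            v += (1 - self.b2) * g * g
            mhat = m / (1 - self.b1 ** self.t)
            vhat = v / (1 - self.b2 ** self.t)
            p -= self.lr * mhat / (np.sqrt(vhat) + self.eps)


def _sigmoid(x: np.ndarray) -> np.ndarray:
    return 0.5 * (1.0 + np.tanh(0.5 * x))


def _xavier_uniform(rng: np.random.Generator, n: int, d: int) -> np.ndarray:
    limit = np.sqrt(6.0 / d)
    return rng.uniform(-limit, limit, size=(n, d))


def init_embeddings(kg: KnowledgeGraph, cfg: KGETrainConfig) -> EmbeddingTable:
    """Seeded Xavier-uniform initialization for every entity and relation."""
    vocab = EntityVocab.from_kg(kg)
    rng = np.random.default_rng(cfg.seed)
    E = _xavier_uniform(rng, vocab.n_entities, cfg.dim)
    R = _xavier_uniform(rng, vocab.n_relations, cfg.dim)
    ents = vocab.entity_ids()
    rels = vocab.relation_ids()
    return EmbeddingTable(
        entity_vectors={e: E[i] for i, e in enumerate(ents)},
        relation_vectors={r: R[i] for i, r in enumerate(rels)},
        dim=cfg.dim,
    )


def train_kge(kg: KnowledgeGraph, cfg: KGETrainConfig) -> EmbeddingTable:
    """Fit DistMult embeddings on a KG's triple set.

    Logistic loss over positives vs. eta uniform filtered corruptions plus L2
    on all embeddings; epochs = 0 returns the seeded initialization.  Raises
    :class:`TrainingDivergedError` if the loss goes non-finite.
    """
    if len(kg) == 0:
        raise ValueError("cannot train on an empty KG")
    vocab = EntityVocab.from_kg(kg)
    rng = np.random.default_rng(cfg.seed)
    E = _xavier_uniform(rng, vocab.n_entities, cfg.dim)
    R = _xavier_uniform(rng, vocab.n_relations, cfg.dim)
    ents, rels = vocab.entity_ids(), vocab.relation_ids()

    known = kg.triple_set()
    pos = np.array(
        [
            (vocab.entity_index[h], vocab.relation_index[r], vocab.entity_index[t])
            for h, r, t in kg.triples
        ],
        dtype=np.int64,
    )
    known_idx = {tuple(row) for row in pos}
    opt = _Adam([E.shape, R.shape], cfg.learning_rate)

    def corrupt(block: np.ndarray, gen: np.random.Generator) -> np.ndarray:
        """Vectorized filtered corruption of an index block (eta per row).

        Rows whose draw reproduces a known triple are redrawn; only the
        offending rows are resampled so the filter terminates quickly.
        """
        src = np.repeat(block, cfg.eta, axis=0)
        cand = src.copy()
        pending = np.ones(len(cand), bool)
        for _ in range(1000):
            k = int(pending.sum())
            if k == 0:
                return cand
            coin = gen.integers(2, size=k).astype(bool)
            draw = gen.integers(vocab.n_entities, size=k)
            fresh = src[pending].copy()
            fresh[coin, 0] = draw[coin]
            fresh[~coin, 2] = draw[~coin]
            cand[pending] = fresh
            bad = np.fromiter(
                (tuple(row) in known_idx for row in fresh), bool, k
            )
            idx_pending = np.flatnonzero(pending)
            pending[idx_pending[~bad]] = False
        raise SamplingError("no admissible corruption found after 1000 rounds")

    n = len(pos)
    for epoch in range(cfg.epochs):
        order = rng.permutation(n)
        epoch_loss = 0.0
        for start in range(0, n, cfg.batch_size):
            idx = pos[order[start : start + cfg.batch_size]]
            neg = corrupt(idx, rng) if cfg.eta > 0 else np.empty((0, 3), np.int64)
            trip = np.concatenate([idx, neg]) if len(neg) else idx
            y = np.concatenate([np.ones(len(idx)), np.zeros(len(neg))])
            h, r, t = trip[:, 0], trip[:, 1], trip[:, 2]
            scores = np.sum(E[h] * R[r] * E[t], axis=1)
            p = _sigmoid(scores)
            # mean logistic loss; softplus written stably
            loss = float(np.mean(np.logaddexp(0.0, -scores) + (1 - y) * scores))
            epoch_loss += loss * len(trip)
            if not np.isfinite(loss):
                raise TrainingDivergedError(f"non-finite loss at epoch {epoch}")
            dscore = (p - y)[:, None] / len(trip)
            gE = np.zeros_like(E)
            gR = np.zeros_like(R)
            np.add.at(gE, h, dscore * R[r] * E[t])
            np.add.at(gE, t, dscore * R[r] * E[h])
            np.add.at(gR, r, dscore * E[h] * E[t])
            gE += 2.0 * cfg.l2 * E
            gR += 2.0 * cfg.l2 * R
            opt.step([E, R], [gE, gR])
        if not np.isfinite(epoch_loss):
            raise TrainingDivergedError(f"non-finite loss at epoch {epoch}")

    return EmbeddingTable(
        entity_vectors={e: E[i].copy() for i, e in enumerate(ents)},
        relation_vectors={r: R[i].copy() for i, r in enumerate(rels)},
        dim=cfg.dim,
    )


def rank_triples(
    emb: EmbeddingTable, tests: list[Triple], kg: KnowledgeGraph, ks: tuple[int, ...] = (1, 3, 10)
) -> dict[str, float]:
    """Filtered tail-ranking link-prediction metrics (MRR, Hits@k).

    For each test triple the true tail competes against every entity except
    those forming another known triple (filtered setting); tied scores get
    the mean rank of the tie block.
    """
    entities = sorted(emb.entity_vectors)
    E = emb.entity_matrix(entities)
    index = {e: i for i, e in enumerate(entities)}
    known = kg.triple_set() | set(tests)
    rr = []
    hits = {k: 0 for k in ks}
    for triple in tests:
        try:
            h = emb.entity_vectors[triple.head]
            r = emb.relation_vectors[triple.relation]
        except KeyError as exc:
            raise LookupEntityError(f"unknown id {exc.args[0]!r}") from None
        if triple.tail not in index:
            raise LookupEntityError(f"unknown entity {triple.tail!r}")
        scores = E @ (h * r)
        mask = np.ones(len(entities), bool)
        for j, e in enumerate(entities):
            if e != triple.tail and Triple(triple.head, triple.relation, e) in known:
                mask[j] = False
        s = scores[mask]
        target = scores[index[triple.tail]]
        higher = int(np.sum(s > target))
        ties = int(np.sum(s == target))  # includes the target itself
        rank = higher + (ties + 1) / 2.0
        rr.append(1.0 / rank)
        for k in ks:
            hits[k] += rank <= k
    out = {"mrr": float(np.mean(rr))}
    for k in ks:
        out[f"hits@{k}"] = hits[k] / len(tests)
    return out
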