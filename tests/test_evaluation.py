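import itertools

import numpy as np
import pytest

from kgenfm.errors import ConfigError, MetricError, SamplingError
from kgenfm.evaluation import (
    FoldPlan,
    aupr,
    auroc,
    boxplot_summary,
    cross_validate,
    make_folds,
    sample_negatives,
)
from kgenfm.kg import KnowledgeGraph, Triple


def auroc_oracle(labels, scores):
    """Brute force over all positive-negative pairs, ties = 1/2."""
    pos = [s for y, s in zip(labels, scores) if y == 1]
    neg = [s for y, s in zip(labels, scores) if y == 0]
    total = 0.0
    for p in pos:
        for n in neg:
            total += 1.0 if p > n else (0.5 if p == n else 0.0)
    return total / (len(pos) * len(neg))


def aupr_oracle(labels, scores):
    """Recompute precision/recall from scratch at every distinct threshold."""
    labels = np.asarray(labels)
    scores = np.asarray(scores, float)
    n_pos = int(labels.sum())
    area, prev_recall = 0.0, 0.0
    for thr in sorted(set(scores), reverse=True):
        sel = scores >= thr
        tp = int((labels[sel] == 1).sum())
        precision = tp / int(sel.sum())
        recall = tp / n_pos
        area += precision * (recall - prev_recall)
        prev_recall = recall
    return area


class TestAUROC:
    def test_perfect_separation(self):
        assert auroc([1, 1, 0, 0], [0.9, 0.8, 0.2, 0.1]) == 1.0

    def test_all_ties_half(self):
        assert auroc([1, 0, 1, 0], [0.5] * 4) == 0.5

    def test_hand_three_quarters(self):
        assert auroc([1, 0, 1, 0], [0.9, 0.8, 0.7, 0.6]) == pytest.approx(0.75)

    def test_single_class_rejected(self):
        with pytest.raises(MetricError):
            auroc([1, 1], [0.1, 0.2])

    def test_matches_pairwise_oracle(self):
        rng = np.random.default_rng(0)
        for _ in range(200):
            n = int(rng.integers(4, 51))
            labels = rng.integers(0, 2, size=n)
            if labels.min() == labels.max():
                labels[0] = 1 - labels[0]
            scores = np.round(rng.random(n), 2)  # rounding forces ties
            assert auroc(labels, scores) == pytest.approx(
                auroc_oracle(labels, scores), abs=1e-12
            )


class TestAUPR:
    def test_perfect_separation(self):
        assert aupr([1, 1, 0, 0], [0.9, 0.8, 0.2, 0.1]) == 1.0

    def test_single_positive_ranked_last(self):
        m = 8
        scores = list(range(m, 0, -1))
        labels = [0] * (m - 1) + [1]
        assert aupr(labels, scores) == pytest.approx(1.0 / m)

    def test_no_positive_rejected(self):
        with pytest.raises(MetricError):
            aupr([0, 0], [0.1, 0.2])

    def test_matches_threshold_oracle(self):
        rng = np.random.default_rng(1)
        for _ in range(200):
            n = int(rng.integers(4, 51))
            labels = rng.integers(0, 2, size=n)
            if labels.sum() == 0:
                labels[0] = 1
            scores = np.round(rng.random(n), 2)
            assert aupr(labels, scores) == pytest.approx(
                aupr_oracle(labels, scores), abs=1e-12
            )

    def test_random_scores_approach_prevalence(self):
        rng = np.random.default_rng(2)
        n, prevalence = 10_000, 1 / 11
        values = []
        for _ in range(20):
            labels = (rng.random(n) < prevalence).astype(int)
            values.append(aupr(labels, rng.random(n)))
        assert np.mean(values) == pytest.approx(prevalence, abs=0.01)


class TestNegativeSampling:
    def test_ratio_arithmetic(self):
        pos = {("d1", "p1"), ("d2", "p2"), ("d3", "p3")}
        negs = sample_negatives(pos, [f"d{i}" for i in range(20)],
                                [f"p{i}" for i in range(20)], 10.0, 0)
        assert len(negs) == 30

    def test_never_collides_with_positives(self):
        drugs = [f"d{i}" for i in range(6)]
        prots = [f"p{i}" for i in range(6)]
        pos = set(itertools.islice(itertools.product(drugs, prots), 12))
        for seed in range(20):
            negs = sample_negatives(pos, drugs, prots, 1.5, seed)
            assert not set(negs) & pos
            assert len(set(negs)) == len(negs)

    def test_pool_cap_warns(self):
        pos = {("d1", "p1"), ("d2", "p2")}
        with pytest.warns(UserWarning, match="exhausted"):
            negs = sample_negatives(pos, ["d1", "d2"], ["p1", "p2"], 10.0, 0)
        assert len(negs) == 2  # pool = 4 - 2 positives

    def test_empty_pool_rejected(self):
        with pytest.raises(SamplingError):
            sample_negatives({("d1", "p1")}, ["d1"], ["p1"], 1.0, 0)

    def test_deterministic(self):
        pos = {("d1", "p1")}
        drugs, prots = [f"d{i}" for i in range(9)], [f"p{i}" for i in range(9)]
        assert sample_negatives(pos, drugs, prots, 5.0, 7) == sample_negatives(
            pos, drugs, prots, 5.0, 7
        )


def grid_positives(n_drugs=10, n_prots=8, n_pos=30, seed=0):
    rng = np.random.default_rng(seed)
    pairs = [(f"d{i}", f"p{j}") for i in range(n_drugs) for j in range(n_prots)]
    idx = rng.choice(len(pairs), size=n_pos, replace=False)
    return {pairs[i] for i in idx}


class TestFoldPlans:
    def test_warm_partition(self):
        pos = grid_positives()
        plan = make_folds(pos, "warm", k=5, ratio=2.0, seed=0)
        test_sets = [set(p for p, y in zip(f.test_pairs, f.test_labels) if y == 1)
                     for f in plan.folds]
        assert set().union(*test_sets) == pos
        for a, b in itertools.combinations(test_sets, 2):
            assert not a & b

    def test_cold_drug_disjointness(self):
        plan = make_folds(grid_positives(), "cold_drug", k=4, ratio=2.0, seed=1)
        for f in plan.folds:
            train_drugs = {d for d, _ in f.train_pairs}
            test_drugs = {d for d, _ in f.test_pairs}
            assert not train_drugs & test_drugs

    def test_cold_protein_disjointness(self):
        plan = make_folds(grid_positives(), "cold_protein", k=4, ratio=2.0, seed=1)
        for f in plan.folds:
            train_p = {p for _, p in f.train_pairs}
            test_p = {p for _, p in f.test_pairs}
            assert not train_p & test_p

    def test_pigeonhole_one_drug_per_fold(self):
        pos = {(f"d{i}", f"p{i % 3}") for i in range(10)}
        plan = make_folds(pos, "cold_drug", k=10, ratio=1.0, seed=0)
        for f in plan.folds:
            assert len({d for d, y in zip(f.test_pairs, f.test_labels) if y == 1
                        for d in [d]}) >= 1
            test_pos_drugs = {d for (d, _), y in zip(f.test_pairs, f.test_labels) if y == 1}
            assert len(test_pos_drugs) == 1

    def test_too_few_entities_rejected(self):
        with pytest.raises(ConfigError):
            make_folds({("d1", "p1")}, "cold_drug", k=3, ratio=1.0, seed=0)

    def test_balanced_mode(self):
        plan = make_folds(grid_positives(), "warm", k=3, ratio=1.0, seed=0)
        for f in plan.folds:
            n_pos = sum(f.test_labels)
            assert len(f.test_labels) - n_pos == n_pos

    def test_json_round_trip(self, tmp_path):
        plan = make_folds(grid_positives(), "warm", k=3, ratio=1.0, seed=4)
        path = tmp_path / "plan.json"
        plan.to_json(path)
        back = FoldPlan.from_json(path)
        assert back.scenario == plan.scenario
        assert back.folds[1].test_pairs == plan.folds[1].test_pairs


class TestCrossValidate:
    def make_kg(self, pos):
        triples = [Triple(d, "dti", p) for d, p in pos]
        types = {e: ("drug" if e.startswith("d") else "protein")
                 for pair in pos for e in pair}
        return KnowledgeGraph(triples=triples, entity_types=types, dti_relation="dti")

    def test_oracle_scorer_gives_perfect_metrics(self):
        pos = grid_positives()
        kg = self.make_kg(pos)
        res = cross_validate(pos, kg, cfg=None, scenario="warm", k=4, ratio=2.0,
                             seed=0, scorer=lambda fold, kg: fold.test_labels)
        assert len(res.per_fold) == 4
        assert (res.per_fold.auroc == 1.0).all() and (res.per_fold.aupr == 1.0).all()

    def test_metrics_in_unit_interval_and_deterministic(self):
        rng = np.random.default_rng(0)
        pos = grid_positives()
        kg = self.make_kg(pos)

        def scorer(fold, kg):
            local = np.random.default_rng(len(fold.test_pairs))
            return local.random(len(fold.test_pairs))

        r1 = cross_validate(pos, kg, None, "warm", k=3, ratio=2.0, seed=5, scorer=scorer)
        r2 = cross_validate(pos, kg, None, "warm", k=3, ratio=2.0, seed=5, scorer=scorer)
        assert ((r1.per_fold.auroc >= 0) & (r1.per_fold.auroc <= 1)).all()
        assert r1.per_fold.equals(r2.per_fold)
        assert r1.summary == r2.summary

    def test_summary_consistent_with_folds(self):
        vals = np.array([0.2, 0.4, 0.6, 0.8])
        s = boxplot_summary(vals)
        assert s["median"] == pytest.approx(0.5)
        assert s["min"] == 0.2 and s["max"] == 0.8
        assert s["q1"] == pytest.approx(np.percentile(vals, 25))
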