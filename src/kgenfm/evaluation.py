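"""Evaluation protocols: negative sampling, scenario folds, AUROC/AUPR.

Three cross-validation scenarios mirror how DTI prediction is used:

* ``warm``         — train and test share drugs and proteins (repurposing);
                     test positives across folds partition the positive set.
* ``cold_drug``    — test drugs never appear in training pairs (new compounds);
                     drugs are partitioned into k groups.
* ``cold_protein`` — test proteins never appear in training pairs (new targets).

Cold entities still live in the knowledge graph (they keep their
heterogeneous edges); they only lack DTI edges at training time.  Unlabeled
pairs stand in for negatives at a configurable negative:positive ratio
(10:1 in the unbalanced setting, 1:1 in the balanced one); negatives are
sampled per fold, respect the scenario's entity split on the test side, and
never collide with any known positive (train or test).

AUROC uses the rank statistic with ties counted 1/2; AUPR is the step-wise
precision-recall area with tied scores processed as one block (no linear
interpolation).  AUPR is the primary metric under 1:10 imbalance.
"""

from __future__ import annotations

import json
import logging
import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Callable, Literal, Sequence

import numpy as np
import pandas as pd
from sklearn.metrics import average_precision_score, roc_auc_score

from .errors import ConfigError, MetricError, SamplingError
from .kg import KnowledgeGraph

logger = logging.getLogger(__name__)

Pair = tuple[str, str]
Scenario = Literal["warm", "cold_drug", "cold_protein"]
SCENARIOS: tuple[Scenario, ...] = ("warm", "cold_drug", "cold_protein")


def auroc(labels: Sequence[int], scores: Sequence[float]) -> float:
    """Probability a random positive outscores a random negative (ties = 1/2)."""
    labels = np.asarray(labels)
    if len(np.unique(labels)) < 2:
        raise MetricError("AUROC needs both classes present")
    return float(roc_auc_score(labels, np.asarray(scores, float)))


def aupr(labels: Sequence[int], scores: Sequence[float]) -> float:
    """Area under the step-wise precision-recall curve.

    Sum of precision x recall-increment over descending-score thresholds,
    ties processed as a single block; equals average precision.
    """
    labels = np.asarray(labels)
    if not np.any(labels == 1):
        raise MetricError("AUPR needs at least one positive")
    return float(average_precision_score(labels, np.asarray(scores, float)))


def sample_negatives(
    positives: set[Pair],
    drugs: Sequence[str],
    proteins: Sequence[str],
    ratio: float,
    seed: int | np.random.Generator,
    exclude: set[Pair] | None = None,
) -> list[Pair]:
    """Uniform sample without replacement from (drugs x proteins) \\ positives.

    Returns round(ratio * |positives|) pairs, capped at the pool size with a
    logged warning.  ``exclude`` removes additional pairs from the pool
    (e.g. negatives already assigned to the test side of the same fold).
    """
    if ratio <= 0:
        raise ConfigError(f"negative ratio must be > 0, got {ratio}")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    banned = set(positives) | (exclude or set())
    drugs = sorted(set(drugs))
    proteins = sorted(set(proteins))
    pool = [
        (d, p) for d in drugs for p in proteins if (d, p) not in banned
    ]
    if not pool:
        raise SamplingError("empty negative pool")
    want = int(round(ratio * len(positives)))
    if want > len(pool):
        msg = f"negative pool exhausted: wanted {want}, pool has {len(pool)}"
        logger.warning(msg)
        warnings.warn(msg, stacklevel=2)
        want = len(pool)
    idx = rng.choice(len(pool), size=want, replace=False)
    return [pool[i] for i in np.sort(idx)]


@dataclass
class Fold:
    train_pairs: list[Pair]
    train_labels: list[int]
    test_pairs: list[Pair]
    test_labels: list[int]


@dataclass
class FoldPlan:
    """Per-fold labeled train/test pair lists with scenario disjointness."""

    scenario: Scenario
    folds: list[Fold]
    ratio: float
    seed: int

    def to_json(self, path: str | Path) -> None:
        payload = {
            "scenario": self.scenario,
            "ratio": self.ratio,
            "seed": self.seed,
            "folds": [
                {
                    "train_pairs": f.train_pairs,
                    "train_labels": f.train_labels,
                    "test_pairs": f.test_pairs,
                    "test_labels": f.test_labels,
                }
                for f in self.folds
            ],
        }
        with open(path, "w", encoding="utf-8") as fh:
            json.dump(payload, fh, sort_keys=True)

    @classmethod
    def from_json(cls, path: str | Path) -> "FoldPlan":
        with open(path, encoding="utf-8") as fh:
            d = json.load(fh)
        folds = [
            Fold(
                [tuple(p) for p in f["train_pairs"]],
                f["train_labels"],
                [tuple(p) for p in f["test_pairs"]],
                f["test_labels"],
            )
            for f in d["folds"]
        ]
        return cls(scenario=d["scenario"], folds=folds, ratio=d["ratio"], seed=d["seed"])


def make_folds(
    positives: set[Pair],
    scenario: Scenario,
    k: int = 10,
    ratio: float = 10.0,
    seed: int = 0,
    drugs: Sequence[str] | None = None,
    proteins: Sequence[str] | None = None,
) -> FoldPlan:
    """k-fold plan for one scenario with per-fold negative sampling.

    ``drugs``/``proteins`` give the sampling universe for negatives; they
    default to the entities appearing in ``positives``.  Warm folds partition
    the positive set; cold folds partition the drug (resp. protein) set and
    route every positive of a test-group entity to that fold's test side.
    Test negatives only involve test-side entities in cold scenarios.
    """
    if k < 2:
        raise ConfigError(f"need k >= 2 folds, got {k}")
    if scenario not in SCENARIOS:
        raise ConfigError(f"unknown scenario {scenario!r}")
    pos = sorted(positives)
    all_drugs = sorted(set(drugs) if drugs is not None else {d for d, _ in pos})
    all_prots = sorted(set(proteins) if proteins is not None else {p for _, p in pos})
    rng = np.random.default_rng(np.random.SeedSequence([seed, SCENARIOS.index(scenario)]))

    if scenario == "warm":
        order = rng.permutation(len(pos))
        test_groups = [sorted(order[i::k]) for i in range(k)]
        splits = [
            (
                [pos[j] for j in range(len(pos)) if j not in set(g)],
                [pos[j] for j in g],
            )
            for g in test_groups
        ]
    else:
        side = 0 if scenario == "cold_drug" else 1
        entities = all_drugs if side == 0 else all_prots
        held = sorted({p[side] for p in pos})
        if len(held) < k:
            raise ConfigError(
                f"{scenario}: need >= {k} distinct entities with positives, have {len(held)}"
            )
        order = rng.permutation(len(held))
        groups = [{held[j] for j in order[i::k]} for i in range(k)]
        # entities with no positives anywhere are unseen in every training
        # set; spread them over the test groups so they widen the cold-side
        # negative pool instead of leaking into the train side
        spare = sorted(set(entities) - set(held))
        spare_order = rng.permutation(len(spare))
        for i in range(k):
            groups[i] |= {spare[j] for j in spare_order[i::k]}
        splits = []
        for g in groups:
            test = [p for p in pos if p[side] in g]
            train = [p for p in pos if p[side] not in g]
            splits.append((train, test))

    folds = []
    for i, (train_pos, test_pos) in enumerate(splits):
        frng = np.random.default_rng(
            np.random.SeedSequence([seed, SCENARIOS.index(scenario), i])
        )
        if scenario == "warm":
            test_d, test_p = all_drugs, all_prots
            train_d, train_p = all_drugs, all_prots
        elif scenario == "cold_drug":
            test_d = sorted(groups[i])
            train_d = sorted(set(all_drugs) - groups[i])
            test_p = train_p = all_prots
        else:
            test_p = sorted(groups[i])
            train_p = sorted(set(all_prots) - groups[i])
            test_d = train_d = all_drugs
        test_neg = sample_negatives(set(test_pos), test_d, test_p, ratio, frng, exclude=positives)
        train_neg = sample_negatives(
            set(train_pos), train_d, train_p, ratio, frng,
            exclude=positives | set(test_neg),
        )
        folds.append(
            Fold(
                train_pairs=list(train_pos) + train_neg,
                train_labels=[1] * len(train_pos) + [0] * len(train_neg),
                test_pairs=list(test_pos) + test_neg,
                test_labels=[1] * len(test_pos) + [0] * len(test_neg),
            )
        )
    return FoldPlan(scenario=scenario, folds=folds, ratio=ratio, seed=seed)


@dataclass
class EvalResult:
    """Per-fold metrics plus the box-plot summary statistics of the figures."""

    scenario: Scenario
    per_fold: pd.DataFrame  # columns: fold, auroc, aupr
    summary: dict[str, dict[str, float]] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if not self.summary:
            self.summary = {
                m: boxplot_summary(self.per_fold[m].to_numpy())
                for m in ("auroc", "aupr")
            }

    def write(self, tsv_path: str | Path, json_path: str | Path | None = None) -> None:
        df = self.per_fold.copy()
        df.insert(1, "scenario", self.scenario)
        df.to_csv(tsv_path, sep="\t", index=False, float_format="%.10f")
        if json_path is not None:
            with open(json_path, "w", encoding="utf-8") as fh:
                json.dump({"scenario": self.scenario, "summary": self.summary},
                          fh, sort_keys=True, indent=1)


def boxplot_summary(values: np.ndarray) -> dict[str, float]:
    """Median, quartiles (linear interpolation), min, max."""
    q1, med, q3 = np.percentile(values, [25, 50, 75])
    return {
        "median": float(med),
        "q1": float(q1),
        "q3": float(q3),
        "min": float(np.min(values)),
        "max": float(np.max(values)),
    }


def cross_validate(
    positives: set[Pair],
    kg: KnowledgeGraph,
    cfg,
    scenario: Scenario = "warm",
    k: int = 10,
    ratio: float = 10.0,
    seed: int = 0,
    scorer: Callable[[Fold, KnowledgeGraph], np.ndarray] | None = None,
) -> EvalResult:
    """k-fold cross-validation of the full pipeline under one scenario.

    Per fold the KGE is retrained on the supporting KG plus that fold's
    training positives (never on test DTIs), the NFM is fit on assembled
    train instances, and AUROC/AUPR are computed on the test side.  A
    ``scorer(fold, kg) -> test scores`` stub may replace the pipeline (used
    for plumbing tests).  Deterministic per seed.
    """
    from .pipeline import fit_predict_fold  # late import to avoid a cycle

    drugs = sorted(e for e, t in kg.entity_types.items() if t == "drug")
    prots = sorted(e for e, t in kg.entity_types.items() if t == "protein")
    plan = make_folds(positives, scenario, k=k, ratio=ratio, seed=seed,
                      drugs=drugs or None, proteins=prots or None)
    rows = []
    for i, fold in enumerate(plan.folds):
        try:
            if scorer is not None:
                scores = np.asarray(scorer(fold, kg), float)
            else:
                scores = fit_predict_fold(fold, kg, cfg, seed=seed, fold_index=i)
            rows.append(
                {"fold": i, "auroc": auroc(fold.test_labels, scores),
                 "aupr": aupr(fold.test_labels, scores)}
            )
        except Exception as exc:
            raise type(exc)(f"fold {i}: {exc}") from exc
    return EvalResult(scenario=scenario, per_fold=pd.DataFrame(rows))
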