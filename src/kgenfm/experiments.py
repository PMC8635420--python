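"""Single-split experiment runner used by examples, tests and the
reproduction script.

``run_holdout`` performs one train/test split of a benchmark under a chosen
scenario (equivalent to a single cross-validation fold), fits the pipeline in
a given ablation mode, and returns test-set AUROC/AUPR.  Heavier studies use
:func:`kgenfm.evaluation.cross_validate`; the holdout runner keeps
multi-seed direction-of-effect comparisons affordable on one CPU.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .evaluation import Scenario, auroc, aupr, make_folds
from .features import protein_feature_table
from .pipeline import PipelineConfig, fit, split_supporting_kg
from .synth import SynthBenchmark


@dataclass
class HoldoutResult:
    scenario: Scenario
    mode: str
    auroc: float
    aupr: float
    n_train: int
    n_test: int
    scores: np.ndarray
    labels: np.ndarray


def desk_config(mode: str = "full", seed: int = 0) -> PipelineConfig:
    """Desk-scale defaults: d=16 KGE trained to memorization, full-width PCA,
    k=16 NFM.  A small embedding dimension forces parameter sharing across
    entities, which is what lets the supporting graph generalize to unseen
    pairs at this scale."""
    from .kge import KGETrainConfig
    from .nfm import NFMTrainConfig

    cfg = PipelineConfig(
        kge=KGETrainConfig(dim=16, epochs=150, learning_rate=0.05, eta=5,
                           l2=1e-6, batch_size=512, seed=seed),
        nfm=NFMTrainConfig(k=16, hidden=(32,), epochs=30, learning_rate=0.01,
                           batch_size=256, dropout=0.2, l2=1e-5, seed=seed),
        pca_drug=16, pca_protein=16, mode=mode, seed=seed,
    )
    return cfg


def run_holdout(
    bench: SynthBenchmark,
    scenario: Scenario,
    mode: str = "full",
    seed: int = 0,
    cfg: PipelineConfig | None = None,
    ratio: float = 10.0,
    k: int = 5,
) -> HoldoutResult:
    """Fit on k-1 parts of a k-fold plan, evaluate on the first fold."""
    cfg = (cfg or desk_config(mode, seed)).with_seed(seed)
    plan = make_folds(
        bench.positives, scenario, k=k, ratio=ratio, seed=seed,
        drugs=sorted(bench.latent_drugs), proteins=sorted(bench.latent_proteins),
    )
    fold = plan.folds[0]
    support, _ = split_supporting_kg(bench.kg)
    prot_feats = protein_feature_table(bench.sequences)
    fp = fit(
        fold.train_pairs, fold.train_labels, support, cfg,
        drug_features=bench.drug_features, protein_features=prot_feats,
    )
    scores = fp.predict(fold.test_pairs)
    labels = np.asarray(fold.test_labels)
    return HoldoutResult(
        scenario=scenario, mode=cfg.mode,
        auroc=auroc(labels, scores), aupr=aupr(labels, scores),
        n_train=len(fold.train_pairs), n_test=len(fold.test_pairs),
        scores=scores, labels=labels,
    )


def permutation_null_sigma(
    labels: np.ndarray, scores: np.ndarray, n_perm: int = 200, seed: int = 0
) -> tuple[float, float]:
    """Mean and std of AUROC under random label permutation."""
    rng = np.random.default_rng(seed)
    labels = np.asarray(labels)
    vals = []
    for _ in range(n_perm):
        vals.append(auroc(rng.permutation(labels), scores))
    return float(np.mean(vals)), float(np.std(vals))
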