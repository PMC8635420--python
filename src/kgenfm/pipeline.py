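"""End-to-end KGE_NFM pipeline.

Fitting proceeds in three stages: (1) DistMult embeddings are trained on the
supporting knowledge graph plus the *training* DTI positives added as triples
under the DTI relation — test DTIs never enter the KGE stage; (2) the drug
and protein entity embeddings are separately reduced by PCA (widths are
independent hyperparameters); (3) a neural factorization machine is trained
on per-pair instances

    PCA(drug KGE) || PCA(protein KGE) || drug structure || protein structure

where the structural blocks (fingerprints, CTD descriptors) are min-max
scaled with training-fold statistics.  Ablation modes drop either the KGE
blocks (``structure_only``, the feature-based NFM baseline) or the
structural blocks (``kge_only``).

Cold-start entities must still exist in the KG: the method's scope covers
drugs/proteins with heterogeneous information but no known DTIs; an entity
absent from the KG raises :class:`~kgenfm.errors.ColdEntityError`.
"""

from __future__ import annotations

from dataclasses import dataclass, field as dc_field
from pathlib import Path
from typing import Literal, Sequence

import numpy as np
from sklearn.decomposition import PCA

from .errors import ColdEntityError, ConfigError, DimensionError
from .features import FeatureTable
from .kg import KnowledgeGraph, Triple
from .kge import EmbeddingTable, KGETrainConfig, train_kge
from .nfm import FieldSpec, NFMParams, NFMTrainConfig, predict_proba, train_nfm
from .nfm import _read_archive, _write_archive

Pair = tuple[str, str]
Mode = Literal["full", "kge_only", "structure_only"]


@dataclass
class PCAModel:
    """Centered orthonormal projection with a deterministic sign convention.

    The per-component sign ambiguity is fixed by forcing the
    largest-magnitude loading of each component to be positive.
    """

    mean: np.ndarray
    components: np.ndarray  # (k, dim), rows orthonormal
    explained_variance_ratio: np.ndarray

    def transform(self, vectors: np.ndarray) -> np.ndarray:
        vectors = np.atleast_2d(np.asarray(vectors, float))
        if vectors.shape[1] != self.mean.shape[0]:
            raise DimensionError(
                f"input width {vectors.shape[1]} != training width {self.mean.shape[0]}"
            )
        return (vectors - self.mean) @ self.components.T

    @property
    def k(self) -> int:
        return self.components.shape[0]


def pca_fit(matrix: np.ndarray, k: int) -> PCAModel:
    """Principal components of a row-wise entity matrix, by descending variance."""
    matrix = np.asarray(matrix, float)
    if matrix.ndim != 2 or matrix.shape[0] < 2:
        raise ConfigError("PCA needs at least 2 rows")
    if not 1 <= k <= min(matrix.shape[0] - 1, matrix.shape[1]):
        raise ConfigError(
            f"PCA width k={k} out of range for a {matrix.shape} matrix"
        )
    model = PCA(n_components=k, svd_solver="full").fit(matrix)
    comps = model.components_.copy()
    for row in comps:
        if row[np.argmax(np.abs(row))] < 0:
            row *= -1.0
    return PCAModel(
        mean=model.mean_.copy(),
        components=comps,
        explained_variance_ratio=model.explained_variance_ratio_.copy(),
    )


def pca_transform(model: PCAModel, vectors: np.ndarray) -> np.ndarray:
    return model.transform(vectors)


@dataclass
class MinMaxScaler:
    """Per-feature min-max scaling frozen at training-fold statistics."""

    lo: np.ndarray
    hi: np.ndarray

    @classmethod
    def fit(cls, X: np.ndarray) -> "MinMaxScaler":
        X = np.asarray(X, float)
        return cls(lo=X.min(axis=0), hi=X.max(axis=0))

    def transform(self, X: np.ndarray) -> np.ndarray:
        span = np.where(self.hi > self.lo, self.hi - self.lo, 1.0)
        return np.clip((np.asarray(X, float) - self.lo) / span, 0.0, 1.0)


@dataclass
class PipelineConfig:
    """One seed drives every stage; per-stage seeds are derived from it."""

    kge: KGETrainConfig = dc_field(default_factory=KGETrainConfig)
    nfm: NFMTrainConfig = dc_field(default_factory=NFMTrainConfig)
    pca_drug: int = 32
    pca_protein: int = 32
    mode: Mode = "full"
    seed: int = 0

    def __post_init__(self) -> None:
        if self.mode not in ("full", "kge_only", "structure_only"):
            raise ConfigError(f"unknown mode {self.mode!r}")

    def with_seed(self, seed: int) -> "PipelineConfig":
        kge = KGETrainConfig(**{**self.kge.__dict__, "seed": seed})
        nfm = NFMTrainConfig(**{**self.nfm.__dict__, "seed": seed + 1})
        return PipelineConfig(kge=kge, nfm=nfm, pca_drug=self.pca_drug,
                              pca_protein=self.pca_protein, mode=self.mode, seed=seed)


def kge_training_triples(
    kg_support: KnowledgeGraph, train_positives: Sequence[Pair], dti_relation: str
) -> list[Triple]:
    """Supporting-KG triples plus training positives as DTI triples.

    This is exactly the triple set the KGE stage sees; the leakage audit
    intersects it with test DTI triples and must find nothing.
    """
    extra = [Triple(d, dti_relation, p) for d, p in train_positives]
    return list(kg_support.triples) + extra


def leakage_audit(
    kg_support: KnowledgeGraph,
    train_positives: Sequence[Pair],
    test_pairs: Sequence[Pair],
    dti_relation: str,
) -> set[Triple]:
    """Test DTI triples that would leak into KGE training (must be empty)."""
    training = set(kge_training_triples(kg_support, train_positives, dti_relation))
    test_triples = {Triple(d, dti_relation, p) for d, p in test_pairs}
    return training & test_triples


def split_supporting_kg(kg: KnowledgeGraph) -> tuple[KnowledgeGraph, set[Pair]]:
    """Separate the task DTI pairs from the supporting heterogeneous graph."""
    if kg.dti_relation is None:
        raise ConfigError("KG has no designated DTI relation")
    support = kg.sub_kg([t for t in kg.triples if t.relation != kg.dti_relation])
    support.entity_types = dict(kg.entity_types)  # keep isolated entities typed
    return support, set(kg.dti_pairs())


@dataclass
class FittedPipeline:
    """Everything needed to score new (drug, protein) pairs."""

    embeddings: EmbeddingTable | None
    pca_drug: PCAModel | None
    pca_protein: PCAModel | None
    drug_features: FeatureTable | None
    protein_features: FeatureTable | None
    scaler_drug: MinMaxScaler | None
    scaler_protein: MinMaxScaler | None
    nfm_params: NFMParams
    field_spec: FieldSpec
    config: PipelineConfig

    def predict(self, pairs: Sequence[Pair]) -> np.ndarray:
        """One probability per pair, order-preserving."""
        X = assemble_matrix(pairs, self)
        return predict_proba(self.nfm_params, X)


def _kge_blocks(fp: FittedPipeline, pairs: Sequence[Pair]) -> list[np.ndarray]:
    assert fp.embeddings is not None and fp.pca_drug is not None and fp.pca_protein is not None
    for d, p in pairs:
        for e in (d, p):
            if e not in fp.embeddings.entity_vectors:
                raise ColdEntityError(
                    f"entity {e!r} is absent from the knowledge graph; the method "
                    "covers only entities that exist in the KG (with or without DTIs)"
                )
    D = fp.embeddings.entity_matrix([d for d, _ in pairs])
    P = fp.embeddings.entity_matrix([p for _, p in pairs])
    return [fp.pca_drug.transform(D), fp.pca_protein.transform(P)]


def _structure_blocks(fp: FittedPipeline, pairs: Sequence[Pair]) -> list[np.ndarray]:
    assert fp.drug_features is not None and fp.protein_features is not None
    D = fp.drug_features.matrix([d for d, _ in pairs])
    P = fp.protein_features.matrix([p for _, p in pairs])
    if fp.scaler_drug is not None:
        D = fp.scaler_drug.transform(D)
    if fp.scaler_protein is not None:
        P = fp.scaler_protein.transform(P)
    return [D, P]


def assemble_matrix(pairs: Sequence[Pair], fp: FittedPipeline) -> np.ndarray:
    """Instance matrix in fixed field order (rows follow ``pairs``)."""
    blocks: list[np.ndarray] = []
    if fp.config.mode in ("full", "kge_only"):
        blocks.extend(_kge_blocks(fp, pairs))
    if fp.config.mode in ("full", "structure_only"):
        blocks.extend(_structure_blocks(fp, pairs))
    X = np.concatenate(blocks, axis=1)
    if X.shape[1] != fp.field_spec.width:
        raise DimensionError(
            f"assembled width {X.shape[1]} != field spec {fp.field_spec.width}"
        )
    return X


def assemble_features(pair: Pair, fp: FittedPipeline):
    """Single-pair :class:`~kgenfm.nfm.InstanceVector` (see assemble_matrix)."""
    from .nfm import InstanceVector

    return InstanceVector(values=assemble_matrix([pair], fp)[0], field_spec=fp.field_spec)


def _make_field_spec(cfg: PipelineConfig, drug_width: int, protein_width: int) -> FieldSpec:
    blocks = []
    if cfg.mode in ("full", "kge_only"):
        blocks += [("drug-KGE", cfg.pca_drug), ("protein-KGE", cfg.pca_protein)]
    if cfg.mode in ("full", "structure_only"):
        blocks += [("drug-structure", drug_width), ("protein-structure", protein_width)]
    return FieldSpec(blocks)


def fit(
    train_pairs: Sequence[Pair],
    train_labels: Sequence[int],
    kg_support: KnowledgeGraph,
    cfg: PipelineConfig,
    drug_features: FeatureTable | None = None,
    protein_features: FeatureTable | None = None,
) -> FittedPipeline:
    """Fit the full pipeline on one fold's labeled training pairs.

    ``kg_support`` must not contain test DTI triples; positive training pairs
    are added to it as DTI triples before KGE training (negatives never enter
    the KG).  PCA is fit on drug and protein entity embeddings separately.
    """
    if kg_support.dti_relation is None:
        raise ConfigError("supporting KG needs a designated dti_relation")
    train_pairs = list(train_pairs)
    labels = np.asarray(train_labels, int)
    positives = [p for p, y in zip(train_pairs, labels) if y == 1]

    emb = pca_d = pca_p = None
    kge_cols: list[np.ndarray] = []
    if cfg.mode in ("full", "kge_only"):
        kg_entities = set(kg_support.entities()) | set(kg_support.entity_types)
        for d, p in positives:
            if d not in kg_entities or p not in kg_entities:
                missing = d if d not in kg_entities else p
                raise ColdEntityError(
                    f"training positive references {missing!r}, absent from the KG"
                )
        triples = kge_training_triples(kg_support, positives, kg_support.dti_relation)
        kge_kg = KnowledgeGraph(
            triples=triples,
            entity_types=dict(kg_support.entity_types),
            dti_relation=kg_support.dti_relation,
        )
        emb = train_kge(kge_kg, cfg.kge)
        drugs = sorted(e for e, t in kge_kg.entity_types.items()
                       if t == "drug" and e in emb.entity_vectors)
        prots = sorted(e for e, t in kge_kg.entity_types.items()
                       if t == "protein" and e in emb.entity_vectors)
        pca_d = pca_fit(emb.entity_matrix(drugs), cfg.pca_drug)
        pca_p = pca_fit(emb.entity_matrix(prots), cfg.pca_protein)

    sc_d = sc_p = None
    d_width = p_width = 0
    if cfg.mode in ("full", "structure_only"):
        if drug_features is None or protein_features is None:
            raise ConfigError(f"mode {cfg.mode!r} needs drug and protein feature tables")
        d_width, p_width = drug_features.width, protein_features.width
        sc_d = MinMaxScaler.fit(drug_features.matrix([d for d, _ in train_pairs]))
        sc_p = MinMaxScaler.fit(protein_features.matrix([p for _, p in train_pairs]))

    spec = _make_field_spec(cfg, d_width, p_width)
    fp = FittedPipeline(
        embeddings=emb, pca_drug=pca_d, pca_protein=pca_p,
        drug_features=drug_features, protein_features=protein_features,
        scaler_drug=sc_d, scaler_protein=sc_p,
        nfm_params=None, field_spec=spec, config=cfg,  # type: ignore[arg-type]
    )
    X = assemble_matrix(train_pairs, fp)
    fp.nfm_params = train_nfm(X, labels, cfg.nfm, field_spec=spec)
    return fp


def predict(fp: FittedPipeline, pairs: Sequence[Pair]) -> np.ndarray:
    return fp.predict(pairs)


def fit_predict_fold(fold, kg: KnowledgeGraph, cfg, seed: int = 0, fold_index: int = 0):
    """Cross-validation helper: fit on a fold's train side, score its test side.

    ``kg`` is the full KG including all DTI triples; every DTI triple is
    stripped and only the fold's training positives are re-added, so test
    DTIs (and even other folds' DTIs) never reach the KGE stage.
    """
    support, _ = split_supporting_kg(kg)
    fold_seed = int(np.random.SeedSequence([seed, 11, fold_index]).generate_state(1)[0] % (2**31))
    run_cfg = cfg.pipeline.with_seed(fold_seed) if hasattr(cfg, "pipeline") else cfg.with_seed(fold_seed)
    fp = fit(
        fold.train_pairs, fold.train_labels, support, run_cfg,
        drug_features=getattr(cfg, "drug_features", None),
        protein_features=getattr(cfg, "protein_features", None),
    )
    return fp.predict(fold.test_pairs)


@dataclass
class FoldRunConfig:
    """Bundle handed to :func:`kgenfm.evaluation.cross_validate`."""

    pipeline: PipelineConfig
    drug_features: FeatureTable | None = None
    protein_features: FeatureTable | None = None


def save_pipeline(fp: FittedPipeline, path: str | Path) -> None:
    """Serialize to a deterministic zip archive (same fit -> same bytes)."""
    arrays: dict[str, np.ndarray] = {}
    manifest: dict = {
        "mode": fp.config.mode,
        "seed": fp.config.seed,
        "field_spec": fp.field_spec.blocks,
        "kge": fp.config.kge.__dict__,
        "nfm_cfg": {**fp.config.nfm.__dict__, "hidden": list(fp.config.nfm.hidden)},
        "pca_drug_k": fp.config.pca_drug,
        "pca_protein_k": fp.config.pca_protein,
        "nfm": {"w0": fp.nfm_params.w0,
                "layers": [act for _, _, act in fp.nfm_params.layers]},
    }
    arrays["nfm/w"] = fp.nfm_params.w
    arrays["nfm/V"] = fp.nfm_params.V
    arrays["nfm/p"] = fp.nfm_params.p
    for i, (W, b, _) in enumerate(fp.nfm_params.layers):
        arrays[f"nfm/W{i}"], arrays[f"nfm/b{i}"] = W, b
    for name, model in (("pca_drug", fp.pca_drug), ("pca_protein", fp.pca_protein)):
        if model is not None:
            arrays[f"{name}/mean"] = model.mean
            arrays[f"{name}/components"] = model.components
            arrays[f"{name}/evr"] = model.explained_variance_ratio
    for name, sc in (("scaler_drug", fp.scaler_drug), ("scaler_protein", fp.scaler_protein)):
        if sc is not None:
            arrays[f"{name}/lo"], arrays[f"{name}/hi"] = sc.lo, sc.hi
    if fp.embeddings is not None:
        ents = sorted(fp.embeddings.entity_vectors)
        rels = sorted(fp.embeddings.relation_vectors)
        manifest["entities"], manifest["relations"] = ents, rels
        manifest["dim"] = fp.embeddings.dim
        arrays["emb/E"] = np.stack([fp.embeddings.entity_vectors[e] for e in ents])
        arrays["emb/R"] = np.stack([fp.embeddings.relation_vectors[r] for r in rels])
    if fp.drug_features is not None:
        ids = sorted(fp.drug_features.vectors)
        manifest["drug_feature_ids"] = ids
        arrays["feat/drug"] = fp.drug_features.matrix(ids)
    if fp.protein_features is not None:
        ids = sorted(fp.protein_features.vectors)
        manifest["protein_feature_ids"] = ids
        arrays["feat/protein"] = fp.protein_features.matrix(ids)
    _write_archive(path, manifest, arrays)


def load_pipeline(path: str | Path) -> FittedPipeline:
    manifest, arrays = _read_archive(path)
    nfm_cfg = dict(manifest["nfm_cfg"])
    nfm_cfg["hidden"] = tuple(nfm_cfg["hidden"])
    cfg = PipelineConfig(
        kge=KGETrainConfig(**manifest["kge"]),
        nfm=NFMTrainConfig(**nfm_cfg),
        pca_drug=manifest["pca_drug_k"],
        pca_protein=manifest["pca_protein_k"],
        mode=manifest["mode"],
        seed=manifest["seed"],
    )
    spec = FieldSpec([tuple(b) for b in manifest["field_spec"]])
    layers = [
        (arrays[f"nfm/W{i}"], arrays[f"nfm/b{i}"], act)
        for i, act in enumerate(manifest["nfm"]["layers"])
    ]
    params = NFMParams(w0=manifest["nfm"]["w0"], w=arrays["nfm/w"], V=arrays["nfm/V"],
                       layers=layers, p=arrays["nfm/p"], field_spec=spec)
    emb = None
    if "emb/E" in arrays:
        E, R = arrays["emb/E"], arrays["emb/R"]
        emb = EmbeddingTable(
            entity_vectors={e: E[i] for i, e in enumerate(manifest["entities"])},
            relation_vectors={r: R[i] for i, r in enumerate(manifest["relations"])},
            dim=manifest["dim"],
        )

    def pca_of(name):
        if f"{name}/mean" not in arrays:
            return None
        return PCAModel(mean=arrays[f"{name}/mean"], components=arrays[f"{name}/components"],
                        explained_variance_ratio=arrays[f"{name}/evr"])

    def scaler_of(name):
        if f"{name}/lo" not in arrays:
            return None
        return MinMaxScaler(lo=arrays[f"{name}/lo"], hi=arrays[f"{name}/hi"])

    def feats_of(name, key, block):
        if f"feat/{name}" not in arrays:
            return None
        M = arrays[f"feat/{name}"]
        ids = manifest[key]
        return FeatureTable(vectors={e: M[i] for i, e in enumerate(ids)},
                            block_name=block, width=M.shape[1])

    return FittedPipeline(
        embeddings=emb, pca_drug=pca_of("pca_drug"), pca_protein=pca_of("pca_protein"),
        drug_features=feats_of("drug", "drug_feature_ids", "drug-structure"),
        protein_features=feats_of("protein", "protein_feature_ids", "protein-structure"),
        scaler_drug=scaler_of("scaler_drug"), scaler_protein=scaler_of("scaler_protein"),
        nfm_params=params, field_spec=spec, config=cfg,
    )
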