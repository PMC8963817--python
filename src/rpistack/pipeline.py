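"""End-to-end pair-classification pipeline.

Glues the feature path (protein conjoint-triad SVD vectors, GloVe RNA
embeddings with LFS pooling, per-molecule transform remap) to the stacking
ensemble, with save/load of a trained model bundle.

By default the GloVe embedding is fitted only on the RNA sequences that
appear in the training pairs, so cross-validation folds share no corpus
information; ``embedding_scope='all'`` fits on every RNA in the dataset
instead (the common, slightly leaky practice).
"""

from __future__ import annotations

import dataclasses
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from . import __version__, ensemble as ens
from .protein_features import protein_feature_vector
from .rna_embedding import (DEFAULT_GROUPS, GloVeConfig, KmerCorpus,
                            build_cooccurrence, load_embedding_tsv,
                            rna_feature_vector, save_embedding_tsv, train_glove)
from .seqio import InteractionDataset
from .transforms import TransformSpec, make_pair_features
from .rna_embedding import GloVeModel

logger = logging.getLogger(__name__)


@dataclass
class PipelineConfig:
    """Everything needed to reproduce a run, seed included."""

    k: int = 3
    glove: GloVeConfig = field(default_factory=GloVeConfig)
    lfs_groups: int = DEFAULT_GROUPS
    scale_by_sigma: bool = True
    transform: TransformSpec = field(default_factory=TransformSpec)
    strategy: str = "stacking_adaptive"
    internal_folds: int = 4
    embedding_scope: str = "train"  # 'train' | 'all'
    seed: int = 0

    def __post_init__(self) -> None:
        if self.embedding_scope not in ("train", "all"):
            raise ValueError("embedding_scope must be 'train' or 'all'")
        # keep the GloVe seed slaved to the pipeline seed
        self.glove = dataclasses.replace(self.glove, seed=self.seed)

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)

    @classmethod
    def from_dict(cls, d: dict) -> "PipelineConfig":
        d = dict(d)
        if "glove" in d and isinstance(d["glove"], dict):
            d["glove"] = GloVeConfig(**d["glove"])
        if "transform" in d and isinstance(d["transform"], dict):
            d["transform"] = TransformSpec(**d["transform"])
        return cls(**d)

    @property
    def raw_dims(self) -> tuple:
        return (7 ** self.k, self.lfs_groups * self.glove.dim)


def compute_protein_vectors(proteins: dict, config: PipelineConfig) -> dict:
    """Raw 343-vectors for every protein record, keyed by id."""
    return {pid: protein_feature_vector(rec, k=config.k, scale_by_sigma=config.scale_by_sigma)
            for pid, rec in proteins.items()}


class InteractionPipeline:
    """Trainable end-to-end predictor for (rna_id, protein_id) pairs."""

    def __init__(self, config: PipelineConfig = None, protein_vectors: dict = None):
        self.config = config or PipelineConfig()
        self._protein_vectors = protein_vectors  # optional shared cache of raw vectors
        self.embedding: np.ndarray = None        # (64, d) fitted word embeddings
        self.glove_model: GloVeModel = None
        self.ensemble: ens.StackingEnsemble = None

    # -- feature assembly -------------------------------------------------
    def _protein_vec(self, dataset: InteractionDataset, pid: str) -> np.ndarray:
        if self._protein_vectors is None:
            self._protein_vectors = {}
        if pid not in self._protein_vectors:
            self._protein_vectors[pid] = protein_feature_vector(
                dataset.proteins[pid], k=self.config.k, scale_by_sigma=self.config.scale_by_sigma)
        return self._protein_vectors[pid]

    def _features(self, dataset: InteractionDataset, pairs) -> np.ndarray:
        cfg = self.config
        rna_cache: dict = {}
        rows = []
        for rid, pid, _ in pairs:
            if rid not in rna_cache:
                rna_cache[rid] = rna_feature_vector(
                    dataset.rnas[rid], self.embedding, G=cfg.lfs_groups, k=cfg.k)
            rows.append(make_pair_features(self._protein_vec(dataset, pid), rna_cache[rid],
                                           spec=cfg.transform, expected_dims=cfg.raw_dims))
        return np.asarray(rows)

    # -- training / prediction --------------------------------------------
    def fit(self, dataset: InteractionDataset, pairs=None) -> "InteractionPipeline":
        cfg = self.config
        pairs = list(pairs) if pairs is not None else list(dataset.pairs)
        if cfg.embedding_scope == "all":
            rna_ids = sorted(dataset.rnas)
        else:
            rna_ids = sorted({rid for rid, _, _ in pairs})
        corpus = KmerCorpus.from_records([dataset.rnas[rid] for rid in rna_ids], k=cfg.k)
        self.glove_model = train_glove(build_cooccurrence(corpus, window=cfg.glove.window), cfg.glove)
        self.embedding = self.glove_model.embedding_matrix
        X = self._features(dataset, pairs)
        y = np.array([label for _, _, label in pairs])
        self.ensemble = ens.StackingEnsemble(strategy=cfg.strategy,
                                             internal_folds=cfg.internal_folds, seed=cfg.seed)
        self.ensemble.fit(X, y)
        return self

    def _check_fitted(self) -> None:
        if self.embedding is None or self.ensemble is None:
            raise RuntimeError("pipeline is not fitted")

    def predict_proba(self, dataset: InteractionDataset, pairs) -> np.ndarray:
        self._check_fitted()
        return self.ensemble.predict_proba(self._features(dataset, pairs))

    def predict(self, dataset: InteractionDataset, pairs, threshold: float = 0.5) -> np.ndarray:
        self._check_fitted()
        return self.ensemble.predict(self._features(dataset, pairs), threshold)

    # -- persistence -------------------------------------------------------
    def save(self, path) -> None:
        self._check_fitted()
        path = Path(path)
        path.mkdir(parents=True, exist_ok=True)
        save_embedding_tsv(self.glove_model, path / "embedding.tsv")
        cfg_dict = self.config.to_dict()
        with open(path / "config.json", "w") as fh:
            json.dump(cfg_dict, fh, indent=2, sort_keys=True)
            fh.write("\n")
        ens.save_bundle(self.ensemble, path,
                        extra_manifest={"config_hash": ens.config_hash(cfg_dict),
                                        "pipeline": True})

    @classmethod
    def load(cls, path) -> "InteractionPipeline":
        path = Path(path)
        with open(path / "config.json") as fh:
            config = PipelineConfig.from_dict(json.load(fh))
        pipe = cls(config)
        pipe.embedding, _ = load_embedding_tsv(path / "embedding.tsv")
        pipe.ensemble, manifest = ens.load_bundle(path)
        logger.info("loaded pipeline bundle %s (config hash %s)", path, manifest.get("config_hash"))
        return pipe
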