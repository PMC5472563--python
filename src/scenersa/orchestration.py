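"""End-to-end pipeline runs tying all stages together.

A single seeded configuration drives: synthetic corpus -> GIST -> stimulus
selection -> feature similarity; synthetic voxel data -> LOPO MVPA ->
discrimination and noise ceilings; semantic and perceptual model matrices;
and the full RSA battery with Holm-Bonferroni correction across the three
scene ROIs. Three synthetic regions mirror the study's logic: "PPA" carries
the planted (GIST-derived) similarity structure, "OPA" carries distinct but
unstructured condition patterns (identity model), and "RSC" carries no
condition signal at all.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from . import __version__
from .core import SimilarityMatrix
from .gist import build_filterbank, gist_matrix
from .neural_patterns import (FoldRdms, NoiseCeiling, lopo_rdms,
                              noise_ceiling, within_between_discrimination)
from .perceptual_model import (counts_matrix, dot_similarity, group_average_dot,
                               make_card_subsets)
from .rsa_stats import (fisher_z, holm_bonferroni, offdiag_vector,
                        partial_correlation, rsa_correlation,
                        semipartial_correlation)
from .searchlight import PMap
from .semantic_model import default_vocabulary, semantic_matrix
from .stimulus_selection import (cluster_kmeans, fit_pca, loio_similarity_matrix,
                                 mds_embed, normalize_corpus, select_stimuli)
from .synthetic_data import (generate_cardsorts, generate_label_masks,
                             generate_texture_corpus, generate_voxel_dataset)

logger = logging.getLogger("scenersa")

_ROI_NAMES = ("PPA", "RSC", "OPA")


@dataclass
class PipelineConfig:
    """All pipeline parameters, with study defaults.

    The synthetic-scale defaults (corpus size, subjects, voxels) are chosen
    so a full run completes in minutes on one CPU while keeping the study's
    structural parameters (k = 10 clusters, 24 images per cluster, 20
    principal components, 6 cards per cluster, 10 stacks).
    """

    seed: int = 0
    # corpus and selection
    n_images: int = 2000
    image_size: int = 64
    n_groups: int = 10
    corpus_noise_sd: float = 0.05
    k: int = 10
    pca_components: int = 20
    n_per_cluster: int = 24
    kmeans_restarts: int = 10
    # neural data
    n_subjects: int = 20
    n_voxels: int = 800
    signal_sd: float = 1.0
    noise_sd: float = 1.0
    # perceptual model
    per_cluster_cards: int = 6
    n_stacks: int = 10
    cardsort_noise: float = 0.35
    # searchlight (off by default; a volume run is a separate stage)
    run_searchlight: bool = False
    radius_mm: float = 10.0
    roi_target: int = 500
    # stage toggles
    run_selection: bool = True
    run_mvpa: bool = True
    run_models: bool = True
    run_rsa: bool = True

    @classmethod
    def from_dict(cls, d: dict) -> "PipelineConfig":
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(d) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        return cls(**d)

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)

    def sha256(self) -> str:
        return hashlib.sha256(
            json.dumps(self.to_dict(), sort_keys=True).encode()).hexdigest()


def mini_config(seed: int = 0) -> PipelineConfig:
    """A reduced configuration for smoke runs (seconds, not minutes)."""
    return PipelineConfig(seed=seed, n_images=200, n_subjects=6, n_voxels=800,
                          n_per_cluster=12, kmeans_restarts=4)


@dataclass
class ResultsBundle:
    """Everything a full run produces, with provenance."""

    matrices: dict[str, SimilarityMatrix] = field(default_factory=dict)
    fold_rdms: dict[str, FoldRdms] = field(default_factory=dict)
    discrimination: pd.DataFrame | None = None
    rsa_table: pd.DataFrame | None = None
    noise_ceilings: dict[str, NoiseCeiling] = field(default_factory=dict)
    mds_coords: np.ndarray | None = None
    stimulus_counts: dict[str, int] = field(default_factory=dict)
    pmaps: dict[str, PMap] = field(default_factory=dict)
    provenance: dict = field(default_factory=dict)


def _as_model_matrix(matrix: SimilarityMatrix) -> np.ndarray:
    """Coerce a similarity matrix into a valid planted correlation model:
    symmetric, entries in [-1, 1], unit diagonal (LOIO diagonals are < 1)."""
    m = np.clip(matrix.symmetrized().entries, -1.0, 1.0)
    np.fill_diagonal(m, 1.0)
    return m


def _rsa_vector(matrix: SimilarityMatrix) -> np.ndarray:
    """Off-diagonal vector on the analysis scale for the matrix kind.

    Correlation matrices are Fisher-z transformed; dot-product matrices are
    used raw.
    """
    sym = matrix.symmetrized()
    if sym.kind == "correlation":
        return fisher_z(offdiag_vector(sym.entries).values)
    return offdiag_vector(sym.entries).values


def run_selection_stage(config: PipelineConfig) -> dict:
    """Corpus -> GIST -> normalise -> PCA -> k-means -> selection -> RDM."""
    logger.info("selection stage: %d images, %d groups", config.n_images, config.n_groups)
    corpus = generate_texture_corpus(config.n_images, config.n_groups,
                                     config.image_size, config.corpus_noise_sd,
                                     seed=config.seed)
    bank = build_filterbank(size=config.image_size)
    gists = gist_matrix(corpus.images, bank)
    normed = normalize_corpus(gists)
    n_comp = min(config.pca_components, config.n_images - 1, gists.shape[1])
    space, scores = fit_pca(normed, n_components=n_comp)
    model = cluster_kmeans(scores, k=config.k, n_restarts=config.kmeans_restarts,
                           seed=config.seed)
    stimulus_set = select_stimuli(scores, model, n_per_cluster=config.n_per_cluster)
    selected = stimulus_set.all_image_ids()
    labels = stimulus_set.cluster_labels()
    gist_rdm = loio_similarity_matrix(scores[selected], labels)
    coords = mds_embed(gist_rdm)
    return dict(corpus=corpus, pca=space, scores=scores, cluster_model=model,
                stimulus_set=stimulus_set, gist_rdm=gist_rdm, mds=coords)


def run_mvpa_stage(config: PipelineConfig, planted: SimilarityMatrix) -> dict:
    """Synthetic voxel data per ROI -> LOPO fold RDMs -> tests + ceilings."""
    logger.info("mvpa stage: %d subjects, %d voxels/ROI", config.n_subjects, config.n_voxels)
    k = planted.n_clusters
    roi_models = {
        "PPA": _as_model_matrix(planted),
        "RSC": None,                       # pure noise, no condition signal
        "OPA": np.eye(k),                  # distinct but unstructured patterns
    }
    folds: dict[str, FoldRdms] = {}
    for i, (name, model) in enumerate(roi_models.items()):
        if model is None:
            ds = generate_voxel_dataset(config.n_subjects, k, config.n_voxels,
                                        np.eye(k), signal_sd=0.0,
                                        noise_sd=config.noise_sd,
                                        seed=config.seed + 101 + i)
        else:
            ds = generate_voxel_dataset(config.n_subjects, k, config.n_voxels,
                                        model, signal_sd=config.signal_sd,
                                        noise_sd=config.noise_sd,
                                        seed=config.seed + 101 + i)
        folds[name] = lopo_rdms([], patterns=ds.subjects)
    discrimination = pd.DataFrame([
        dict(roi=name, t=res.t, df=res.df, p=res.p, d=res.d)
        for name, res in ((n, within_between_discrimination(f)) for n, f in folds.items())
    ])
    discrimination["p_holm"] = holm_bonferroni(discrimination["p"].to_numpy())
    ceilings = {name: noise_ceiling(f) for name, f in folds.items()}
    matrices = {f"mvpa_{name}": SimilarityMatrix(f.mean_symmetric(), fold_stack=f.stack)
                for name, f in folds.items()}
    return dict(folds=folds, discrimination=discrimination, ceilings=ceilings,
                matrices=matrices)


def run_models_stage(config: PipelineConfig, stimulus_set, planted: SimilarityMatrix) -> dict:
    """Semantic and perceptual model similarity matrices."""
    logger.info("models stage")
    rng = np.random.default_rng(config.seed + 201)
    vocab = default_vocabulary()
    labels = stimulus_set.cluster_labels()
    n_sel = labels.size
    proportions = []
    for c in labels:
        primary = vocab[c % len(vocab)]
        secondary = vocab[(c + 10) % len(vocab)]
        proportions.append({
            primary: 0.5 + 0.1 * rng.random(),
            secondary: 0.2 + 0.1 * rng.random(),
        })
    masks = generate_label_masks(n_sel, vocabulary=vocab, proportions=proportions,
                                 image_size=32, seed=config.seed + 202)
    sem_vectors = semantic_matrix(masks)
    semantic_rdm = loio_similarity_matrix(sem_vectors, labels)

    subsets = make_card_subsets(stimulus_set, config.n_subjects,
                                per_cluster=config.per_cluster_cards,
                                seed=config.seed + 203)
    sorts = generate_cardsorts(_as_model_matrix(planted), config.n_subjects,
                               cards_per_cluster=config.per_cluster_cards,
                               n_stacks=config.n_stacks, noise=config.cardsort_noise,
                               seed=config.seed + 204)
    dots = []
    for s, assignment in enumerate(sorts.sorts):
        sort_map = {card: int(stack) for card, stack in enumerate(assignment)}
        cluster_map = {card: int(c) for card, c in enumerate(sorts.card_clusters)}
        counts = counts_matrix(sort_map, cluster_map, sorts.n_stacks, subject_id=s)
        dots.append(dot_similarity(counts))
    perceptual_rdm = group_average_dot(dots)
    return dict(semantic_rdm=semantic_rdm, perceptual_rdm=perceptual_rdm,
                card_subsets=subsets)


def run_rsa_stage(matrices: dict[str, SimilarityMatrix]) -> pd.DataFrame:
    """The full RSA battery with Holm correction across the scene ROIs."""
    logger.info("rsa stage")
    vectors = {name: _rsa_vector(m) for name, m in matrices.items()}
    rows = []
    models = [n for n in ("gist", "semantic", "perceptual") if n in vectors]
    rois = [n for n in vectors if n.startswith("mvpa_")]
    # each model against each ROI; Holm across ROIs per model
    for model in models:
        block = []
        for roi in rois:
            res = rsa_correlation(vectors[model], vectors[roi])
            block.append(dict(x=model, y=roi, kind="simple", covariates="",
                              r=res.r, df=res.df, p=res.p))
        ps = holm_bonferroni([b["p"] for b in block])
        for b, ph in zip(block, ps):
            b["p_holm"] = ph
            rows.append(b)
    # model-model comparisons including partial/semi-partial, as in the study
    pairs = [(a, b) for i, a in enumerate(models) for b in models[i + 1:]]
    for a, b in pairs:
        res = rsa_correlation(vectors[a], vectors[b])
        rows.append(dict(x=a, y=b, kind="simple", covariates="",
                         r=res.r, df=res.df, p=res.p, p_holm=np.nan))
    if all(m in vectors for m in ("gist", "semantic", "perceptual")):
        for x, y, z in (("perceptual", "semantic", "gist"),
                        ("perceptual", "gist", "semantic")):
            pres = partial_correlation(vectors[x], vectors[y], [vectors[z]])
            rows.append(dict(x=x, y=y, kind="partial", covariates=z,
                             r=pres.r, df=pres.df, p=pres.p, p_holm=np.nan))
            sres = semipartial_correlation(vectors[x], vectors[y], vectors[z])
            rows.append(dict(x=x, y=y, kind="semipartial", covariates=z,
                             r=sres.r, df=sres.df, p=sres.p, p_holm=np.nan))
    return pd.DataFrame(rows)


def run_pipeline(config: PipelineConfig) -> ResultsBundle:
    """Execute all enabled stages and assemble a ResultsBundle."""
    bundle = ResultsBundle()
    bundle.provenance = dict(
        config=config.to_dict(), config_sha256=config.sha256(), seed=config.seed,
        versions=dict(scenersa=__version__, numpy=np.__version__),
    )
    stage = "selection"
    try:
        if not config.run_selection:
            raise RuntimeError("pipeline requires the selection stage")
        sel = run_selection_stage(config)
        bundle.matrices["gist"] = sel["gist_rdm"]
        bundle.mds_coords = sel["mds"]
        bundle.stimulus_counts = dict(
            n_selected=sel["stimulus_set"].n_images,
            n_clusters=sel["stimulus_set"].n_clusters,
        )
        planted = sel["gist_rdm"]
        if config.run_mvpa:
            stage = "mvpa"
            mv = run_mvpa_stage(config, planted)
            bundle.matrices.update(mv["matrices"])
            bundle.fold_rdms = mv["folds"]
            bundle.discrimination = mv["discrimination"]
            bundle.noise_ceilings = mv["ceilings"]
        if config.run_models:
            stage = "models"
            mo = run_models_stage(config, sel["stimulus_set"], planted)
            bundle.matrices["semantic"] = mo["semantic_rdm"]
            bundle.matrices["perceptual"] = mo["perceptual_rdm"]
        if config.run_rsa:
            stage = "rsa"
            bundle.rsa_table = run_rsa_stage(bundle.matrices)
    except Exception as exc:
        raise RuntimeError(f"pipeline failed in stage {stage!r}: {exc}") from exc
    return bundle
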