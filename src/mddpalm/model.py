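"""Two-layered SVM: per-motif-subgroup RBF classifiers whose probability
estimates feed a second-layer stacking classifier.

Each motif subgroup found by the decomposition tree gets its own
first-layer SVM trained on its positive members plus negatives sampled
from the full negative pool at roughly 1:8.  The vector of first-layer
probabilities is the input of the second-layer SVM.  Meta-features for
training the second layer are produced by k-fold cross-fitting of the
first layer so that no fragment is scored by a model that saw it.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import joblib
import numpy as np
from sklearn.model_selection import StratifiedKFold
from sklearn.svm import SVC

from . import __version__
from .evaluate import confusion, metrics
from .features import FragmentEncoder
from .mdd import (
    MDDConfig,
    MDDTree,
    assign_subgroup,
    mdd_cluster,
    read_tree,
    write_tree,
)
from .sequence_io import Fragment, FragmentDataset, ProteinRecord, extract_fragment


@dataclass(frozen=True)
class SVMParams:
    gamma: float = 2.0**-5
    cost: float = 2.0**3

    def __post_init__(self) -> None:
        if self.gamma <= 0 or self.cost <= 0:
            raise ValueError("gamma and cost must be > 0")


@dataclass
class PipelineConfig:
    """Everything needed to train the full two-layer pipeline."""

    schemes: tuple[str, ...] = ("aac", "pssm")
    svm: SVMParams = field(default_factory=SVMParams)
    meta_svm: SVMParams = field(default_factory=SVMParams)
    mdd: MDDConfig = field(default_factory=MDDConfig)
    negative_ratio: float = 8.0
    crossfit_folds: int = 3
    threshold: float = 0.5


def sample_negatives(
    n_pos: int,
    negative_pool: Sequence[Fragment],
    ratio: float = 8.0,
    seed: int = 0,
) -> list[Fragment]:
    """Uniform sample without replacement of round(ratio * n_pos) negatives.

    If the pool is smaller than requested the whole pool is returned with a
    warning.
    """
    if not negative_pool:
        raise ValueError("empty negative pool")
    want = round(ratio * n_pos)
    if want >= len(negative_pool):
        if want > len(negative_pool):
            warnings.warn(
                f"negative pool ({len(negative_pool)}) smaller than requested "
                f"({want}); using the whole pool"
            )
        return list(negative_pool)
    rng = np.random.default_rng(seed)
    idx = rng.choice(len(negative_pool), size=want, replace=False)
    return [negative_pool[i] for i in sorted(idx)]


def _fit_svc(
    X: np.ndarray,
    y: np.ndarray,
    params: SVMParams,
    seed: int,
    class_weight: str | None = None,
) -> SVC:
    if len(set(y.tolist())) < 2:
        raise ValueError("single-class training input")
    svc = SVC(
        kernel="rbf",
        C=params.cost,
        gamma=params.gamma,
        probability=True,
        class_weight=class_weight,
        random_state=seed,
    )
    with warnings.catch_warnings():
        # sklearn 1.9 deprecates probability=True; libsvm-style Platt
        # probabilities are exactly what this model stacks on.
        warnings.simplefilter("ignore", FutureWarning)
        svc.fit(X, y)
    return svc


def _positive_column(svc: SVC) -> int:
    return int(np.where(svc.classes_ == 1)[0][0])


@dataclass
class SubgroupModel:
    subgroup_id: str
    encoder: FragmentEncoder
    classifier: SVC
    params: SVMParams
    n_pos: int
    n_neg: int
    seed: int

    def predict_proba(self, fragments: Sequence[Fragment]) -> np.ndarray:
        X = self.encoder.transform(fragments)
        return self.classifier.predict_proba(X)[:, _positive_column(self.classifier)]


def train_subgroup_model(
    pos_fragments: Sequence[Fragment],
    neg_fragments: Sequence[Fragment],
    schemes: tuple[str, ...] = ("aac", "pssm"),
    params: SVMParams | None = None,
    seed: int = 0,
    subgroup_id: str = "Palm1",
    asa_table=None,
) -> SubgroupModel:
    """Train one first-layer RBF SVM with probability outputs.

    The encoder (profile components and the [-1, +1] scaler) is fitted on
    this model's own training fragments only.
    """
    if not pos_fragments or not neg_fragments:
        raise ValueError("both classes must be non-empty")
    params = params or SVMParams()
    fragments = list(pos_fragments) + list(neg_fragments)
    y = np.array([1] * len(pos_fragments) + [0] * len(neg_fragments))
    encoder = FragmentEncoder(schemes=schemes, asa_table=asa_table)
    encoder.fit(fragments, labels=y)
    svc = _fit_svc(encoder.transform(fragments), y, params, seed)
    return SubgroupModel(
        subgroup_id, encoder, svc, params, len(pos_fragments), len(neg_fragments), seed
    )


def first_layer_probabilities(
    fragments: Sequence[Fragment], models: Sequence[SubgroupModel]
) -> np.ndarray:
    """|fragments| x |models| matrix of first-layer probabilities."""
    if not models:
        raise ValueError("no subgroup models given")
    return np.column_stack([m.predict_proba(fragments) for m in models])


@dataclass
class TwoLayerModel:
    tree: MDDTree
    subgroup_models: list[SubgroupModel]
    meta_classifier: SVC
    config: PipelineConfig
    threshold: float = 0.5
    seed: int = 0

    def predict_proba(self, fragments: Sequence[Fragment]) -> np.ndarray:
        meta = first_layer_probabilities(fragments, self.subgroup_models)
        return self.meta_classifier.predict_proba(meta)[
            :, _positive_column(self.meta_classifier)
        ]


def _leaf_positive_members(
    tree: MDDTree, positives: Sequence[Fragment]
) -> dict[str, list[Fragment]]:
    members: dict[str, list[Fragment]] = {
        leaf.subgroup_id: [] for leaf in tree.leaves()
    }
    for f in positives:
        members[assign_subgroup(f, tree)].append(f)
    return members


def _train_first_layer(
    tree: MDDTree,
    positives: Sequence[Fragment],
    negatives: Sequence[Fragment],
    config: PipelineConfig,
    seed: int,
) -> list[SubgroupModel]:
    members = _leaf_positive_members(tree, positives)
    models: list[SubgroupModel] = []
    for k, (sid, pos) in enumerate(sorted(members.items())):
        if not pos:
            raise ValueError(f"subgroup {sid} has no positive members")
        neg = sample_negatives(len(pos), negatives, config.negative_ratio, seed + k)
        models.append(
            train_subgroup_model(
                pos, neg, config.schemes, config.svm, seed + k, subgroup_id=sid
            )
        )
    return models


def train_two_layer(
    dataset: FragmentDataset,
    tree: MDDTree | None = None,
    config: PipelineConfig | None = None,
    seed: int = 0,
) -> TwoLayerModel:
    """Train the full two-layer model on *dataset*.

    The motif tree is learned from the positive fragments unless one is
    supplied.  Second-layer training features come from cross-fitting the
    first layer over ``config.crossfit_folds`` stratified folds.
    """
    config = config or PipelineConfig()
    positives = dataset.positives
    negatives = dataset.negatives
    if not positives or not negatives:
        raise ValueError("dataset must contain both classes")
    if tree is None:
        mdd_config = MDDConfig(
            chi2_threshold=config.mdd.chi2_threshold,
            max_cluster_size=config.mdd.max_cluster_size,
            min_subgroup_size=config.mdd.min_subgroup_size,
            n=dataset.n,
        )
        tree = mdd_cluster(positives, config=mdd_config)

    fragments = list(positives) + list(negatives)
    y = np.array([1] * len(positives) + [0] * len(negatives))

    # Cross-fitted meta-features: each fragment is scored only by first
    # layers trained without it.
    meta = np.zeros((len(fragments), len(tree.leaves())))
    folds = min(config.crossfit_folds, int(np.bincount(y).min()))
    splitter = StratifiedKFold(n_splits=folds, shuffle=True, random_state=seed)
    for fold_idx, (train_idx, test_idx) in enumerate(
        splitter.split(np.zeros(len(y)), y)
    ):
        fold_pos = [fragments[i] for i in train_idx if y[i] == 1]
        fold_neg = [fragments[i] for i in train_idx if y[i] == 0]
        fold_models = _train_first_layer(
            tree, fold_pos, fold_neg, config, seed * 101 + fold_idx
        )
        meta[test_idx] = first_layer_probabilities(
            [fragments[i] for i in test_idx], fold_models
        )

    # Balanced class weights keep the meta SVM's decision spread healthy on
    # the 1:8 input; without them the internal Platt fit can collapse and
    # invert the probabilities when the meta features overlap heavily.
    meta_svc = _fit_svc(meta, y, config.meta_svm, seed, class_weight="balanced")
    final_models = _train_first_layer(tree, positives, negatives, config, seed)
    return TwoLayerModel(tree, final_models, meta_svc, config, config.threshold, seed)


def predict_fragments(
    fragments: Sequence[Fragment], model: TwoLayerModel
) -> np.ndarray:
    """Second-layer probabilities for a fragment batch."""
    return model.predict_proba(fragments)


@dataclass(frozen=True)
class PredictionResult:
    protein_id: str
    position: int
    residue: str
    probability: float
    call: bool
    subgroup: str
    fragment: str


def predict(
    proteins: Sequence[ProteinRecord],
    model: TwoLayerModel,
    threshold: float | None = None,
) -> list[PredictionResult]:
    """Score every cysteine of every protein with the two-layer model."""
    if not proteins:
        raise ValueError("empty sequence set")
    threshold = model.threshold if threshold is None else threshold
    n = model.tree.config.n
    fragments: list[Fragment] = []
    for protein in proteins:
        for pos, aa in enumerate(protein.sequence, start=1):
            if aa == "C":
                fragments.append(extract_fragment(protein, pos, n))
    if not fragments:
        return []
    probs = model.predict_proba(fragments)
    results = []
    for f, p in zip(fragments, probs):
        results.append(
            PredictionResult(
                f.protein_id,
                f.site_position,
                "C",
                float(p),
                bool(p >= threshold),
                assign_subgroup(f, model.tree),
                f.residues,
            )
        )
    return results


def write_predictions(results: Sequence[PredictionResult], path: str | Path) -> None:
    with open(path, "w") as fh:
        fh.write(
            "protein_id\tposition\tresidue\tprobability\tcall\tmotif_subgroup\tfragment\n"
        )
        for r in results:
            fh.write(
                f"{r.protein_id}\t{r.position}\t{r.residue}\t{r.probability:.6f}\t"
                f"{int(r.call)}\t{r.subgroup}\t{r.fragment}\n"
            )


def grid_search(
    dataset: FragmentDataset,
    gammas: Sequence[float] = tuple(2.0**k for k in range(-7, 2)),
    costs: Sequence[float] = tuple(2.0**k for k in range(-3, 8)),
    folds: int = 5,
    schemes: tuple[str, ...] = ("aac", "pssm"),
    seed: int = 0,
) -> SVMParams:
    """Pick the (gamma, cost) grid point with the best mean cross-validated
    MCC of a single-layer SVM; ties break toward smaller cost then gamma."""
    if not gammas or not costs:
        raise ValueError("empty parameter grid")
    fragments = list(dataset.fragments)
    y = np.array([1 if f.is_positive else 0 for f in fragments])
    splitter = StratifiedKFold(n_splits=folds, shuffle=True, random_state=seed)
    encoder = FragmentEncoder(schemes=schemes)

    splits = []
    for train_idx, test_idx in splitter.split(np.zeros(len(y)), y):
        enc = FragmentEncoder(schemes=schemes)
        enc.fit([fragments[i] for i in train_idx], labels=y[train_idx])
        splits.append(
            (
                enc.transform([fragments[i] for i in train_idx]),
                y[train_idx],
                enc.transform([fragments[i] for i in test_idx]),
                y[test_idx],
            )
        )

    best: tuple[float, float, float] | None = None  # (-mcc, cost, gamma)
    best_params = SVMParams(gammas[0], costs[0])
    for cost in sorted(costs):
        for gamma in sorted(gammas):
            scores = []
            for X_tr, y_tr, X_te, y_te in splits:
                svc = _fit_svc(X_tr, y_tr, SVMParams(gamma, cost), seed)
                calls = svc.predict(X_te)
                scores.append(metrics(confusion(y_te, calls)).mcc)
            key = (-float(np.mean(scores)), cost, gamma)
            if best is None or key < best:
                best = key
                best_params = SVMParams(gamma, cost)
    return best_params


# ---------------------------------------------------------------------------
# Persistence
# ---------------------------------------------------------------------------


def save_model(model: TwoLayerModel, directory: str | Path) -> None:
    """Persist a model archive: tree JSON, per-subgroup classifiers and a
    versioned manifest."""
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    write_tree(model.tree, directory / "tree.json")
    manifest = {
        "format_version": 1,
        "tool_version": __version__,
        "schemes": list(model.config.schemes),
        "threshold": model.threshold,
        "seed": model.seed,
        "subgroups": [m.subgroup_id for m in model.subgroup_models],
    }
    with open(directory / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=2)
    joblib.dump(model.subgroup_models, directory / "subgroup_models.joblib")
    joblib.dump(model.meta_classifier, directory / "meta_classifier.joblib")
    joblib.dump(model.config, directory / "config.joblib")


def load_model(directory: str | Path) -> TwoLayerModel:
    directory = Path(directory)
    with open(directory / "manifest.json") as fh:
        manifest = json.load(fh)
    if manifest.get("format_version") != 1:
        raise ValueError(
            f"unsupported model archive version {manifest.get('format_version')}"
        )
    return TwoLayerModel(
        tree=read_tree(directory / "tree.json"),
        subgroup_models=joblib.load(directory / "subgroup_models.joblib"),
        meta_classifier=joblib.load(directory / "meta_classifier.joblib"),
        config=joblib.load(directory / "config.joblib"),
        threshold=manifest["threshold"],
        seed=manifest["seed"],
    )
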