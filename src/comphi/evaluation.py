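"""Evaluation designs: cross-validation, repeated splits, taxonomic-level
accuracy, mask-driven ablations and taxon holdouts.

All splits are by phage, never by pair: each phage has one true host, so a
pair-level split would place the same phage's features on both sides and
leak. A no-leakage assertion (test phage ids disjoint from training phage
ids) runs inside every evaluation.

Two framings are reported side by side, because published metrics mix
them: binary pair metrics (Acc/Sen/Spe/AUC on labeled phage-host pairs)
and per-phage top-1 host accuracy resolved at each taxonomic rank
(species ... phylum). At rank L a prediction is correct iff the predicted
and true hosts share the taxon at L; species equals exact host identity.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace
from typing import Mapping, Sequence

import numpy as np
from sklearn.metrics import roc_auc_score
from sklearn.model_selection import KFold

from .alignment import BitScoreStore, get_backend, pairwise_bit_matrix
from .composite import (
    FULL_MASK,
    CompositeWeights,
    TrainedClassifier,
    assemble_pair_features,
    composite_score,
    grid_search_weights,
    train_classifier,
)
from .dataset_io import RANKS, DatasetBundle, TaxonomyTable

logger = logging.getLogger(__name__)

#: family-level holdout preset for the priority drug-resistant (ESKAPEE) hosts
ESKAPEE_FAMILIES = (
    "Enterococcaceae",
    "Staphylococcaceae",
    "Enterobacteriaceae",
    "Moraxellaceae",
    "Pseudomonadaceae",
)

ALIGNMENT_MODES = ("none", "ph_only", "hh_only", "ph+hh")


# ---------------------------------------------------------------------------
# Metrics


def binary_metrics(
    scores: Sequence[float], labels: Sequence[int], threshold: float = 0.5
) -> dict[str, float]:
    """Acc, Sen, Spe at the threshold plus rank-based AUC (ties get 0.5)."""
    scores = np.asarray(scores, dtype=float)
    labels = np.asarray(labels, dtype=int)
    if scores.shape != labels.shape or scores.ndim != 1:
        raise ValueError("scores and labels must be aligned 1-D arrays")
    if set(np.unique(labels)) != {0, 1}:
        raise ValueError("both classes must be present")
    pred = scores >= threshold
    tp = int(np.sum(pred & (labels == 1)))
    tn = int(np.sum(~pred & (labels == 0)))
    fp = int(np.sum(pred & (labels == 0)))
    fn = int(np.sum(~pred & (labels == 1)))
    return {
        "acc": (tp + tn) / len(labels),
        "sen": tp / (tp + fn),
        "spe": tn / (tn + fp),
        "auc": float(roc_auc_score(labels, scores)),
    }


def kfold_split(
    phage_ids: Sequence[str], k: int = 5, seed: int = 0
) -> list[tuple[list[str], list[str]]]:
    """Partition *phages* (not pairs) into k shuffled folds."""
    ids = sorted(phage_ids)
    if k > len(ids):
        raise ValueError(f"k={k} exceeds number of phages ({len(ids)})")
    folds = []
    for train_idx, test_idx in KFold(n_splits=k, shuffle=True, random_state=seed).split(ids):
        folds.append(([ids[i] for i in train_idx], [ids[i] for i in test_idx]))
    return folds


def taxonomic_accuracy(
    predictions: Mapping[str, str],
    truth: Mapping[str, str],
    taxonomy: TaxonomyTable,
) -> dict[str, float]:
    """Top-1 accuracy resolved at each rank; species = exact host match."""
    if not predictions:
        raise ValueError("empty prediction set")
    acc = {}
    for rank in RANKS:
        correct = 0
        for phage, predicted in predictions.items():
            true = truth[phage]
            if rank == "species":
                correct += int(predicted == true)
            else:
                correct += int(
                    taxonomy.taxon(predicted, rank) == taxonomy.taxon(true, rank)
                )
        acc[rank] = correct / len(predictions)
    return acc


# ---------------------------------------------------------------------------
# Pipeline configuration and per-split fitting


@dataclass
class PipelineConfig:
    """Everything one evaluation cell needs to refit the pipeline."""

    mask: tuple[str, ...] = FULL_MASK
    weights: CompositeWeights | None = None  # None -> grid search per split
    grid_metric: str = "auc"
    grid_step: float = 0.1
    alignment_mode: str = "ph+hh"
    backend: str = "auto"
    backend_kwargs: dict = field(default_factory=dict)
    rf_params: dict | None = None
    rf_seed: int = 42
    val_frac: float = 0.2

    def __post_init__(self) -> None:
        if self.alignment_mode not in ALIGNMENT_MODES:
            raise ValueError(f"unknown alignment mode {self.alignment_mode!r}")

    def mode_grids(self) -> tuple[list[float] | None, list[float] | None]:
        """(r_values, a_values) restrictions implied by the alignment mode."""
        if self.alignment_mode == "none":
            return [0.0], [0.0]
        if self.alignment_mode == "ph_only":
            return None, [0.0]
        if self.alignment_mode == "hh_only":
            return None, [1.0]
        return None, None

    def mode_weights(self, w: CompositeWeights) -> CompositeWeights:
        """Clamp fixed weights to the alignment mode."""
        if self.alignment_mode == "none":
            return CompositeWeights(0.0, 0.0)
        if self.alignment_mode == "ph_only":
            return CompositeWeights(w.r, 0.0)
        if self.alignment_mode == "hh_only":
            return CompositeWeights(w.r, 1.0)
        return w


class _Precomputed:
    """Per-bundle cache of organism features and raw bit matrices (both are
    split-independent, so they are computed once per dataset)."""

    def __init__(self, bundle: DatasetBundle, cfg: PipelineConfig):
        self.bundle = bundle
        self.phage_ids = sorted(bundle.phages)
        self.host_ids = sorted(bundle.hosts)
        self.feature_cache: dict[str, dict[str, np.ndarray]] = {}
        backend = get_backend(cfg.backend, **cfg.backend_kwargs)
        phages = [bundle.phages[p] for p in self.phage_ids]
        hosts = [bundle.hosts[h] for h in self.host_ids]
        self.pp = pairwise_bit_matrix(phages, phages, backend)
        self.ph = pairwise_bit_matrix(phages, hosts, backend)
        self.hh = pairwise_bit_matrix(hosts, hosts, backend)

    def store(
        self, reference_phages: Sequence[str], train_phages: Sequence[str]
    ) -> BitScoreStore:
        raw = BitScoreStore.from_matrices(
            self.phage_ids, self.host_ids, self.pp, self.ph, self.hh,
            reference_phages=reference_phages,
        )
        return raw.normalize(train_phages)


def precompute(bundle: DatasetBundle, cfg: PipelineConfig) -> _Precomputed:
    """Build (or fetch) the bundle's feature/bit-matrix cache."""
    key = (cfg.backend, tuple(sorted(cfg.backend_kwargs.items())))
    cache = getattr(bundle, "_comphi_precomputed", None)
    if cache is None:
        cache = {}
        object.__setattr__(bundle, "_comphi_precomputed", cache)
    if key not in cache:
        cache[key] = _Precomputed(bundle, cfg)
    return cache[key]


def _pair_rows(bundle, pairs, mask, cache):
    x = np.stack(
        [
            assemble_pair_features(bundle.phages[p], bundle.hosts[h], mask, cache)
            for p, h, _ in pairs
        ]
    )
    y = np.array([label for _, _, label in pairs], dtype=int)
    return x, y


def _alignment_arrays(pairs, store, host_of):
    ph = np.array([store.bit_ph[(p, h)] for p, h, _ in pairs])
    hh = np.array(
        [store.bit_hh[(host_of[store.nearest_phage[p]], h)] for p, h, _ in pairs]
    )
    return ph, hh


def _candidate_arrays(bundle, pre, phage_id, clf, store, host_of, mask):
    """Per-candidate-host (prm, ph, hh) arrays for one query phage."""
    phage = bundle.phages[phage_id]
    x = np.stack(
        [
            assemble_pair_features(phage, bundle.hosts[h], mask, pre.feature_cache)
            for h in pre.host_ids
        ]
    )
    prm = clf.predict_proba(x)
    ph = np.array([store.bit_ph[(phage_id, h)] for h in pre.host_ids])
    hs = host_of[store.nearest_phage[phage_id]]
    hh = np.array([store.bit_hh[(hs, h)] for h in pre.host_ids])
    return prm, ph, hh, pre.host_ids


def fit_and_evaluate_split(
    bundle: DatasetBundle,
    train_phages: Sequence[str],
    test_phages: Sequence[str],
    cfg: PipelineConfig,
    split_seed: int = 0,
) -> dict:
    """Refit the full pipeline on the training side and evaluate the test side.

    Training-side work: classifier fitting (with its min-max normalization),
    bit-score normalization statistics, nearest-phage reference restriction,
    and — when no fixed weights are supplied — the (r, a) grid search on an
    inner validation split of training phages that the classifier never saw.
    """
    train_set, test_set = set(train_phages), set(test_phages)
    assert not (train_set & test_set), "leakage: train and test phages overlap"

    pre = precompute(bundle, cfg)
    interactions = bundle.interactions
    host_of = interactions.host_of()

    if cfg.weights is None:
        rng = np.random.default_rng(split_seed)
        shuffled = list(np.array(sorted(train_set))[rng.permutation(len(train_set))])
        n_val = max(1, int(round(cfg.val_frac * len(shuffled))))

        def val_labels(n):
            return {y for p, _, y in interactions.pairs if p in set(shuffled[:n])}

        # grow the validation side until it carries both pair labels
        # (negatives are sampled per pair, so a small phage subset may not)
        while n_val < len(shuffled) - 1 and len(val_labels(n_val)) < 2:
            n_val += 1
        val_phages = set(shuffled[:n_val])
        subtrain = set(shuffled[n_val:])
        if not subtrain:
            raise ValueError("training split too small for an inner validation split")
    else:
        val_phages, subtrain = set(), train_set

    clf_pairs = [t for t in interactions.pairs if t[0] in subtrain]
    x_train, y_train = _pair_rows(bundle, clf_pairs, cfg.mask, pre.feature_cache)
    clf = train_classifier(
        x_train, y_train, cfg.mask, cfg.rf_params, seed=cfg.rf_seed
    )

    store = pre.store(reference_phages=sorted(train_set),
                      train_phages=sorted(train_set))

    if cfg.weights is None:
        r_values, a_values = cfg.mode_grids()
        if cfg.grid_metric == "top1_accuracy":
            # score every candidate host per validation phage
            prm_v, ph_v, hh_v, idx_v, true_v = [], [], [], [], []
            for i, pid in enumerate(sorted(val_phages)):
                prm, ph, hh, host_ids = _candidate_arrays(
                    bundle, pre, pid, clf, store, host_of, cfg.mask
                )
                prm_v.append(prm); ph_v.append(ph); hh_v.append(hh)
                idx_v.append(np.full(len(host_ids), i))
                true_v.append(np.array([h == host_of[pid] for h in host_ids]))
            weights = grid_search_weights(
                np.concatenate(prm_v), np.concatenate(ph_v), np.concatenate(hh_v),
                (np.concatenate(idx_v), np.concatenate(true_v)),
                metric="top1_accuracy", step=cfg.grid_step,
                r_values=r_values, a_values=a_values,
            )
        else:
            val_pairs = [t for t in interactions.pairs if t[0] in val_phages]
            x_val, y_val = _pair_rows(bundle, val_pairs, cfg.mask, pre.feature_cache)
            prm_val = clf.predict_proba(x_val)
            ph_val, hh_val = _alignment_arrays(val_pairs, store, host_of)
            weights = grid_search_weights(
                prm_val, ph_val, hh_val, y_val,
                metric=cfg.grid_metric, step=cfg.grid_step,
                r_values=r_values, a_values=a_values,
            )
    else:
        weights = cfg.mode_weights(cfg.weights)

    # binary pair metrics on the test side
    test_pairs = [t for t in interactions.pairs if t[0] in test_set]
    x_test, y_test = _pair_rows(bundle, test_pairs, cfg.mask, pre.feature_cache)
    prm_test = clf.predict_proba(x_test)
    ph_test, hh_test = _alignment_arrays(test_pairs, store, host_of)
    comp_scores = composite_score(prm_test, ph_test, hh_test, weights)
    result = {
        "weights": {"r": weights.r, "a": weights.a},
        "n_train_phages": len(train_set),
        "n_test_phages": len(test_set),
        "composite": binary_metrics(comp_scores, y_test),
        "ml_only": binary_metrics(prm_test, y_test),
    }

    # per-phage top-1 host predictions, composite and ML-only
    comp_pred, ml_pred = {}, {}
    for pid in sorted(test_set):
        prm, ph, hh, _ = _candidate_arrays(
            bundle, pre, pid, clf, store, host_of, cfg.mask
        )
        scores = composite_score(prm, ph, hh, weights)
        comp_pred[pid] = pre.host_ids[int(np.argmax(scores))]
        ml_pred[pid] = pre.host_ids[int(np.argmax(prm))]

    truth = {p: host_of[p] for p in comp_pred}
    result["rank_accuracy"] = taxonomic_accuracy(comp_pred, truth, bundle.taxonomy)
    result["rank_accuracy_ml_only"] = taxonomic_accuracy(ml_pred, truth, bundle.taxonomy)
    return result


# ---------------------------------------------------------------------------
# Reports


@dataclass
class EvaluationReport:
    """Per-split results plus their averages and the seeds that produced them."""

    per_split: list[dict]
    seeds: list[int]
    descriptor: dict = field(default_factory=dict)

    @property
    def mean(self) -> dict:
        def avg(path):
            vals = []
            for rec in self.per_split:
                v = rec
                for k in path:
                    v = v[k]
                vals.append(v)
            return float(np.mean(vals))

        out = {}
        for block in ("composite", "ml_only"):
            out[block] = {m: avg((block, m)) for m in ("acc", "sen", "spe", "auc")}
        for block in ("rank_accuracy", "rank_accuracy_ml_only"):
            out[block] = {r: avg((block, r)) for r in RANKS}
        out["weights"] = {k: avg(("weights", k)) for k in ("r", "a")}
        return out


def repeated_split_eval(
    bundle: DatasetBundle,
    cfg: PipelineConfig | None = None,
    train_frac: float = 0.7,
    repeats: int = 10,
    seed: int = 0,
) -> EvaluationReport:
    """Randomized train/test splits of the phages, repeated and averaged.

    The whole pipeline (normalization, store statistics, classifier, grid
    search) is refit per repeat on the training side only.
    """
    cfg = cfg or PipelineConfig()
    phage_ids = sorted(bundle.phages)
    if len(bundle.hosts) < 2 or not bundle.interactions.negatives:
        raise ValueError("dataset needs >= 2 hosts and both pair labels")
    rng = np.random.default_rng(seed)
    per_split, seeds = [], []
    for _ in range(repeats):
        rep_seed = int(rng.integers(2**31))
        perm = np.random.default_rng(rep_seed).permutation(len(phage_ids))
        n_train = int(round(train_frac * len(phage_ids)))
        train = [phage_ids[i] for i in perm[:n_train]]
        test = [phage_ids[i] for i in perm[n_train:]]
        per_split.append(fit_and_evaluate_split(bundle, train, test, cfg, rep_seed))
        seeds.append(rep_seed)
    return EvaluationReport(
        per_split=per_split, seeds=seeds,
        descriptor={"design": "repeated_split", "train_frac": train_frac,
                    "repeats": repeats, "seed": seed},
    )


def cross_validate(
    bundle: DatasetBundle,
    cfg: PipelineConfig | None = None,
    k: int = 5,
    seed: int = 0,
) -> EvaluationReport:
    """k-fold cross-validation over phages."""
    cfg = cfg or PipelineConfig()
    folds = kfold_split(sorted(bundle.phages), k=k, seed=seed)
    per_split = [
        fit_and_evaluate_split(bundle, train, test, cfg, seed + i)
        for i, (train, test) in enumerate(folds)
    ]
    return EvaluationReport(
        per_split=per_split, seeds=[seed + i for i in range(k)],
        descriptor={"design": "kfold", "k": k, "seed": seed},
    )


def ablation_run(
    bundle: DatasetBundle,
    masks: Mapping[str, tuple[str, ...]],
    alignment_modes: Sequence[str] = ALIGNMENT_MODES,
    cfg: PipelineConfig | None = None,
    train_frac: float = 0.7,
    repeats: int = 3,
    seed: int = 0,
) -> dict[tuple[str, str], EvaluationReport]:
    """One evaluation per (feature mask, alignment mode) cell.

    All cells share identical splits and seeds so comparisons are paired.
    """
    cfg = cfg or PipelineConfig()
    out = {}
    for mask_name, mask in masks.items():
        for mode in alignment_modes:
            if mode not in ALIGNMENT_MODES:
                raise ValueError(f"unknown alignment mode {mode!r}")
            cell_cfg = replace(cfg, mask=tuple(mask), alignment_mode=mode)
            out[(mask_name, mode)] = repeated_split_eval(
                bundle, cell_cfg, train_frac=train_frac, repeats=repeats, seed=seed
            )
    return out


def taxon_holdout_eval(
    bundle: DatasetBundle,
    rank: str,
    taxa: Sequence[str],
    mode: str = "exclude_from_train",
    cfg: PipelineConfig | None = None,
    train_frac: float = 0.7,
    repeats: int = 3,
    seed: int = 0,
) -> EvaluationReport:
    """Hold out (or restrict to) named taxa at a rank on the training side.

    The test side is unchanged; each split record flags the fraction of
    test phages whose true host belongs to the named taxa.
    """
    if rank not in RANKS:
        raise ValueError(f"unknown rank {rank!r}")
    if mode not in ("exclude_from_train", "restrict_train_to"):
        raise ValueError(f"unknown holdout mode {mode!r}")
    taxa_set = set(taxa)
    present = {bundle.taxonomy.taxon(h, rank) for h in bundle.hosts}
    missing = taxa_set - present
    if missing:
        logger.info("taxa absent from the dataset at rank %s: %s", rank, sorted(missing))

    cfg = cfg or PipelineConfig()
    host_of = bundle.interactions.host_of()

    def in_taxa(pid: str) -> bool:
        return bundle.taxonomy.taxon(host_of[pid], rank) in taxa_set

    phage_ids = sorted(bundle.phages)
    rng = np.random.default_rng(seed)
    per_split, seeds = [], []
    for _ in range(repeats):
        rep_seed = int(rng.integers(2**31))
        perm = np.random.default_rng(rep_seed).permutation(len(phage_ids))
        n_train = int(round(train_frac * len(phage_ids)))
        train = [phage_ids[i] for i in perm[:n_train]]
        test = [phage_ids[i] for i in perm[n_train:]]
        if mode == "exclude_from_train":
            train_f = [p for p in train if not in_taxa(p)]
        else:
            train_f = [p for p in train if in_taxa(p)]
        if not train_f:
            raise ValueError("taxon filter empties the training set")
        rec = fit_and_evaluate_split(bundle, train_f, test, cfg, rep_seed)
        rec["held_out_test_fraction"] = (
            sum(in_taxa(p) for p in test) / len(test) if test else 0.0
        )
        per_split.append(rec)
        seeds.append(rep_seed)
    return EvaluationReport(
        per_split=per_split, seeds=seeds,
        descriptor={"design": "taxon_holdout", "rank": rank,
                    "taxa": sorted(taxa_set), "mode": mode,
                    "train_frac": train_frac, "repeats": repeats, "seed": seed},
    )
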