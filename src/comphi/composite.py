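"""Composite phage-host scoring: RF pair classifier + alignment bit scores.

The alignment-free side is a random-forest classifier over the concatenated
pair feature vector

    phage DNA(340) | phage protein(162) | host DNA(340) | host protein(162)

(1,004 features in the unmasked layout). Its probability Prm for a
candidate host H is then blended with the normalized alignment bit scores
through the composite equation

    Pra     = BitPH(pt, H) * (1 - a) + BitHH(hs, H) * a
    Prfinal = Prm * (1 - r) + Pra * r

where pt is the query phage, hs the host of pt's most similar phage (by the
phage-phage bit scores), r weighs alignment-based against alignment-free
evidence, and a weighs the host-host term within the alignment side. The
candidate host with the highest Prfinal is the putative host. The mixing
weights default to r=0.9, a=0.4 and are re-derived by a 0.1-step grid
search in every experiment.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
from sklearn.ensemble import RandomForestClassifier

from .alignment import BitScoreStore
from .dataset_io import OrganismEntry
from .dna_features import DNA_FEATURE_NAMES, encode_dna_all
from .protein_features import (
    PROTEIN_FEATURE_NAMES,
    NormalizationModel,
    apply_minmax,
    encode_proteins_all,
    fit_minmax,
)

logger = logging.getLogger(__name__)

FEATURE_GROUPS = ("phage_dna", "phage_protein", "host_dna", "host_protein")
GROUP_DIMS = {"phage_dna": 340, "phage_protein": 162,
              "host_dna": 340, "host_protein": 162}

FULL_MASK: tuple[str, ...] = FEATURE_GROUPS
PAIR_DIM = sum(GROUP_DIMS.values())  # 1,004

#: RF hyperparameters of the reference configuration.
DEFAULT_RF_PARAMS = dict(
    n_estimators=100,
    max_depth=20,
    min_samples_split=10,
    min_samples_leaf=4,
    max_features="sqrt",
)
DEFAULT_SEED = 42


@dataclass(frozen=True)
class CompositeWeights:
    """Mixing weights of the composite equation; both in [0,1]."""

    r: float = 0.9
    a: float = 0.4

    def __post_init__(self) -> None:
        if not (0.0 <= self.r <= 1.0 and 0.0 <= self.a <= 1.0):
            raise ValueError(f"weights must lie in [0,1]: r={self.r}, a={self.a}")


def pair_feature_names(mask: Sequence[str] = FULL_MASK) -> list[str]:
    names = []
    for group in FEATURE_GROUPS:
        if group not in mask:
            continue
        side, kind = group.split("_")
        base = DNA_FEATURE_NAMES if kind == "dna" else PROTEIN_FEATURE_NAMES
        names.extend(f"{side}_{n}" for n in base)
    return names


def organism_features(
    entry: OrganismEntry, mask: Sequence[str] = FULL_MASK
) -> dict[str, np.ndarray]:
    """Per-organism DNA/protein vectors for the unmasked groups of its role."""
    out = {}
    if f"{entry.role}_dna" in mask:
        out["dna"] = encode_dna_all(entry.genome)
    if f"{entry.role}_protein" in mask:
        if not entry.proteins:
            raise ValueError(
                f"{entry.role} {entry.id!r} has no proteins but protein "
                "features are unmasked"
            )
        out["protein"] = encode_proteins_all(entry.proteins)
    return out


def assemble_pair_features(
    phage: OrganismEntry,
    host: OrganismEntry,
    mask: Sequence[str] = FULL_MASK,
    cache: dict[str, dict[str, np.ndarray]] | None = None,
) -> np.ndarray:
    """Concatenated (phage, host) feature vector in the fixed layout.

    Masked groups are omitted entirely, shrinking the vector — this is how
    the feature-group ablations are expressed. A per-organism ``cache``
    (id -> encoded features) avoids re-encoding across pairs.
    """
    invalid = set(mask) - set(FEATURE_GROUPS)
    if invalid:
        raise ValueError(f"unknown feature groups {sorted(invalid)}")
    if not mask:
        raise ValueError("mask removes every feature group")

    def feats(entry: OrganismEntry) -> dict[str, np.ndarray]:
        if cache is not None:
            if entry.id not in cache:
                cache[entry.id] = organism_features(entry, mask)
            return cache[entry.id]
        return organism_features(entry, mask)

    parts = []
    for group in FEATURE_GROUPS:
        if group not in mask:
            continue
        side, kind = group.split("_")
        entry = phage if side == "phage" else host
        parts.append(feats(entry)[kind])
    return np.concatenate(parts)


@dataclass
class TrainedClassifier:
    """Fitted RF + the normalization model and feature mask it was trained with."""

    model: RandomForestClassifier
    normalization: NormalizationModel
    mask: tuple[str, ...]
    feature_names: list[str] = field(default_factory=list)

    def predict_proba(self, x: np.ndarray) -> np.ndarray:
        """Probability of the positive (interacting) class per row."""
        x = np.atleast_2d(np.asarray(x, dtype=float))
        if x.shape[1] != self.normalization.n_features:
            raise ValueError(
                f"feature layout mismatch: classifier expects "
                f"{self.normalization.n_features} features, got {x.shape[1]}"
            )
        xn = apply_minmax(self.normalization, x)
        pos = list(self.model.classes_).index(1)
        return self.model.predict_proba(xn)[:, pos]


def train_classifier(
    x: np.ndarray,
    y: Sequence[int],
    mask: Sequence[str] = FULL_MASK,
    hyperparams: Mapping | None = None,
    seed: int = DEFAULT_SEED,
) -> TrainedClassifier:
    """Fit the RF pair classifier; min-max normalization is fitted on the
    training rows only and stored alongside the model."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=int)
    if set(np.unique(y)) != {0, 1}:
        raise ValueError("training set must contain both classes")
    params = dict(DEFAULT_RF_PARAMS)
    if hyperparams:
        params.update(hyperparams)
    norm = fit_minmax(x)
    model = RandomForestClassifier(random_state=seed, n_jobs=1, **params)
    model.fit(apply_minmax(norm, x), y)
    return TrainedClassifier(
        model=model,
        normalization=norm,
        mask=tuple(g for g in FEATURE_GROUPS if g in mask),
        feature_names=pair_feature_names(mask),
    )


def composite_score(prm, blast_ph, blast_hh, w: CompositeWeights):
    """The composite equation; accepts scalars or aligned numpy arrays."""
    prm = np.asarray(prm, dtype=float)
    blast_ph = np.asarray(blast_ph, dtype=float)
    blast_hh = np.asarray(blast_hh, dtype=float)
    for name, v in (("prm", prm), ("blast_ph", blast_ph), ("blast_hh", blast_hh)):
        if np.any(v < 0) or np.any(v > 1):
            raise ValueError(f"{name} outside [0,1]")
    pra = blast_ph * (1.0 - w.a) + blast_hh * w.a
    out = prm * (1.0 - w.r) + pra * w.r
    return float(out) if out.ndim == 0 else out


def _alignment_terms(
    phage_id: str,
    host_id: str,
    store: BitScoreStore,
    host_of: Mapping[str, str],
) -> tuple[float, float]:
    if phage_id not in store.nearest_phage:
        raise KeyError(f"phage {phage_id!r} missing from the bit-score store")
    hs = host_of[store.nearest_phage[phage_id]]
    return store.bit_ph[(phage_id, host_id)], store.bit_hh[(hs, host_id)]


def rank_hosts(
    phage: OrganismEntry,
    hosts: Sequence[OrganismEntry],
    clf: TrainedClassifier,
    store: BitScoreStore,
    w: CompositeWeights,
    host_of: Mapping[str, str],
    cache: dict | None = None,
) -> list[tuple[str, float]]:
    """Score every candidate host for one phage and sort by Prfinal.

    ``host_of`` maps phage id -> its known host (the training interactions);
    it resolves the host of the query's nearest phage for the host-host
    term. Ties sort by lexicographic host id. The store must be normalized.
    """
    if not store.normalized:
        raise ValueError("bit-score store must be normalized before ranking")
    hosts = sorted(hosts, key=lambda h: h.id)
    x = np.stack(
        [assemble_pair_features(phage, h, clf.mask, cache) for h in hosts]
    )
    prm = clf.predict_proba(x)
    ph = np.empty(len(hosts))
    hh = np.empty(len(hosts))
    for i, h in enumerate(hosts):
        ph[i], hh[i] = _alignment_terms(phage.id, h.id, store, host_of)
    scores = composite_score(prm, ph, hh, w)
    order = sorted(range(len(hosts)), key=lambda i: (-scores[i], hosts[i].id))
    return [(hosts[i].id, float(scores[i])) for i in order]


def grid_search_weights(
    prm: np.ndarray,
    blast_ph: np.ndarray,
    blast_hh: np.ndarray,
    labels_or_groups,
    metric: str = "auc",
    step: float = 0.1,
    r_values: Sequence[float] | None = None,
    a_values: Sequence[float] | None = None,
) -> CompositeWeights:
    """Grid-search (r, a) on a held-out validation set at ``step`` increments.

    The three score arrays are aligned per validation pair. For
    ``metric="auc"`` ``labels_or_groups`` is the 0/1 pair labels; for
    ``metric="top1_accuracy"`` it is a (phage_index, is_true_host) pair of
    arrays grouping the rows by query phage. Ties prefer the smallest r,
    then the smallest a. ``r_values``/``a_values`` restrict the grid (used
    by the alignment-mode ablations, e.g. a=0 for the phage-host-only mode).
    """
    from sklearn.metrics import roc_auc_score

    prm = np.asarray(prm, dtype=float)
    if prm.size == 0:
        raise ValueError("empty validation set")
    grid = np.round(np.arange(0.0, 1.0 + step / 2, step), 10)
    r_grid = grid if r_values is None else list(r_values)
    a_grid = grid if a_values is None else list(a_values)
    best, best_w = -np.inf, None
    for r in r_grid:
        for a in a_grid:
            s = composite_score(prm, blast_ph, blast_hh, CompositeWeights(r, a))
            if metric == "auc":
                labels = np.asarray(labels_or_groups)
                if labels.min() == labels.max():
                    raise ValueError("validation set must contain both pair labels")
                val = roc_auc_score(labels, s)
            elif metric == "top1_accuracy":
                phage_idx, is_true = labels_or_groups
                val = _top1_accuracy(s, np.asarray(phage_idx), np.asarray(is_true))
            else:
                raise ValueError(f"unknown metric {metric!r}")
            if val > best:
                best, best_w = val, CompositeWeights(float(r), float(a))
    return best_w


def _top1_accuracy(scores, phage_idx, is_true) -> float:
    correct, total = 0, 0
    for p in np.unique(phage_idx):
        sel = phage_idx == p
        top = np.argmax(scores[sel])
        correct += int(is_true[sel][top])
        total += 1
    return correct / total


def variable_importance(
    clf: TrainedClassifier,
) -> tuple[dict[str, float], dict[str, float]]:
    """Impurity-based feature importances and their group totals.

    Returns (per-feature importances, group totals). Group totals cover the
    four side/kind groups plus per-encoding sums (e.g. ``phage_dna/kmer``).
    """
    if not hasattr(clf.model, "feature_importances_"):
        raise ValueError("classifier is not fitted")
    imp = clf.model.feature_importances_
    per_feature = dict(zip(clf.feature_names, imp))

    groups: dict[str, float] = {}
    for name, value in per_feature.items():
        side, rest = name.split("_", 1)
        kind = "dna" if rest.split("_")[0] in (
            "kmer", "rckmer", "cksnap", "pseeiip", "nac", "dnc", "tnc"
        ) else "protein"
        if kind == "dna":
            encoding = rest.split("_")[0]
        else:
            # protein names are <operator>_<descriptor...>
            encoding = rest.split("_")[1]
        groups[f"{side}_{kind}"] = groups.get(f"{side}_{kind}", 0.0) + value
        key = f"{side}_{kind}/{encoding}"
        groups[key] = groups.get(key, 0.0) + value
    return per_feature, groups
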