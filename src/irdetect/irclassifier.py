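"""Classifier-based intron-retention detection with vote-derived labels.

Training labels come from agreement among three external IR predictors:
introns hit by at least two of the three interval lists are positive
("yes"); introns hit by none form the negative pool, from which negatives
are sampled at a fixed ratio (default 3525/741, the class balance used to
train on real data). Introns hit by exactly one list are ambiguous and enter
neither class.

Each labeled intron is a 17-dimensional vector: the 14 per-condition
features plus the deltas DIE, DIJ, DIC (pseudo-counted, sign unrestricted —
negatives legitimately have non-positive deltas). Two classifiers are
supported: a single pruned decision tree with information-gain (entropy)
splits, pruning strength chosen by internal cross-validation over the
cost-complexity path; and a bagged random forest of 10 trees, each split
drawing 5 random candidate features, aggregated by majority vote. Both are
evaluated by stratified k-fold cross-validation with pooled held-out
predictions. AUC scores use the fraction of trees voting yes (forest) or
the leaf class frequency (tree).

Feature relevance is ranked by information gain of the treatment/control
ratio of each base feature, discretized into equal-frequency bins.
"""

from __future__ import annotations

import os
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import joblib
import numpy as np
import pandas as pd
from sklearn.ensemble import RandomForestClassifier
from sklearn.metrics import roc_auc_score
from sklearn.model_selection import StratifiedKFold, cross_val_score
from sklearn.tree import DecisionTreeClassifier

from .annotation import GenomicInterval, IntronRecord

DEFAULT_NEG_RATIO = 3525.0 / 741.0
DEFAULT_FOLDS = 10
DEFAULT_BINS = 10

#: the canonical 17-column feature order of the labeled matrix
MATRIX_COLUMNS = [
    "TNintron", "TNexon", "TNjunc", "TN5ss", "TN3ss", "TNcoverage", "TNexpression",
    "CNintron", "CNexon", "CNjunc", "CN5ss", "CN3ss", "CNcoverage", "CNexpression",
    "DIE", "DIJ", "DIC",
]

BASE_FEATURES = [
    "Nintron", "Nexon", "Njunc", "N5ss", "N3ss", "Ncoverage", "Nexpression",
]


@dataclass
class VoteLabeling:
    positive_ids: list[str]
    negative_pool: list[str]
    sampled_negatives: list[str]
    seed: int
    neg_ratio: float


@dataclass(frozen=True)
class CVMetrics:
    acc: float
    sp: float
    sn: float
    auc: float


@dataclass
class TrainedModel:
    """A fitted classifier bound to the canonical feature columns."""

    kind: str
    estimator: object
    columns: list[str] = field(default_factory=lambda: list(MATRIX_COLUMNS))

    def save(self, path: str | os.PathLike) -> None:
        joblib.dump(self, path)

    @staticmethod
    def load(path: str | os.PathLike) -> "TrainedModel":
        return joblib.load(path)


def _interval_key(iv: GenomicInterval) -> tuple[str, int, int]:
    return (iv.chrom, iv.start, iv.end)


def _hit_ids(
    catalog: Sequence[IntronRecord],
    intervals: Sequence[GenomicInterval],
    match: str,
    overlap: float,
) -> set[str]:
    if match == "exact":
        keys = {_interval_key(iv) for iv in intervals}
        return {
            rec.intron_id
            for rec in catalog
            if _interval_key(rec.interval) in keys
        }
    if match == "reciprocal":
        by_chrom: dict[str, list[GenomicInterval]] = {}
        for iv in intervals:
            by_chrom.setdefault(iv.chrom, []).append(iv)
        hits = set()
        for rec in catalog:
            ri = rec.interval
            for iv in by_chrom.get(ri.chrom, []):
                inter = min(ri.end, iv.end) - max(ri.start, iv.start)
                if inter <= 0:
                    continue
                if inter >= overlap * len(ri) and inter >= overlap * len(iv):
                    hits.add(rec.intron_id)
                    break
        return hits
    raise ValueError(f"match must be 'exact' or 'reciprocal', got {match!r}")


def label_training_set(
    catalog: Sequence[IntronRecord],
    preds_a: Sequence[GenomicInterval],
    preds_b: Sequence[GenomicInterval],
    preds_c: Sequence[GenomicInterval],
    neg_ratio: float = DEFAULT_NEG_RATIO,
    seed: int = 0,
    match: str = "exact",
    overlap: float = 0.9,
) -> VoteLabeling:
    """Vote labeling: >=2 of 3 hits -> positive; 0 hits -> negative pool.

    Negatives are sampled uniformly without replacement, round(neg_ratio *
    n_positives) of them, capped at the pool size, reproducibly from the
    given seed.
    """
    hit_sets = [
        _hit_ids(catalog, preds, match, overlap)
        for preds in (preds_a, preds_b, preds_c)
    ]
    votes = {
        rec.intron_id: sum(rec.intron_id in s for s in hit_sets) for rec in catalog
    }
    positives = sorted(i for i, v in votes.items() if v >= 2)
    pool = sorted(i for i, v in votes.items() if v == 0)
    if not positives:
        raise ValueError(
            "no intron is hit by two or more prediction sets; supply larger "
            "or better-matched prediction lists"
        )
    n_neg = min(int(round(neg_ratio * len(positives))), len(pool))
    rng = np.random.default_rng(seed)
    sampled = sorted(rng.choice(pool, size=n_neg, replace=False).tolist())
    return VoteLabeling(
        positive_ids=positives,
        negative_pool=pool,
        sampled_negatives=sampled,
        seed=seed,
        neg_ratio=neg_ratio,
    )


def classifier_deltas(feature_table: pd.DataFrame, pseudo: float = 1.0) -> pd.DataFrame:
    """DIE/DIJ/DIC for every intron, pseudo-counted, sign unrestricted."""
    t = feature_table
    ie_t = (t["TNintron"] + pseudo) / (t["TNexon"] + pseudo)
    ie_c = (t["CNintron"] + pseudo) / (t["CNexon"] + pseudo)
    ij_t = (t["TNintron"] + pseudo) / (t["TNjunc"] + pseudo)
    ij_c = (t["CNintron"] + pseudo) / (t["CNjunc"] + pseudo)
    return pd.DataFrame(
        {
            "intron_id": t["intron_id"],
            "DIE": np.log2(ie_t / ie_c),
            "DIJ": np.log2(ij_t / ij_c),
            "DIC": (t["TNcoverage"] - t["CNcoverage"]) * np.log2(np.e),
        }
    )


def build_matrix(
    labeling: VoteLabeling,
    feature_table: pd.DataFrame,
    pseudo: float = 1.0,
) -> tuple[pd.DataFrame, dict[str, int]]:
    """Assemble the labeled 17-feature matrix in deterministic row order.

    Returns (matrix, exclusion_report). Rows are sorted by intron_id; the
    matrix carries the 17 canonical feature columns plus ``label``
    ("yes"/"no") and is indexed by intron_id. Labeled introns missing from
    the feature table are excluded and counted in the report.
    """
    deltas = classifier_deltas(feature_table, pseudo).set_index("intron_id")
    feats = feature_table.set_index("intron_id")
    label_of = {i: "yes" for i in labeling.positive_ids}
    label_of.update({i: "no" for i in labeling.sampled_negatives})

    rows, excluded = [], 0
    for intron_id in sorted(label_of):
        if intron_id not in feats.index or not np.isfinite(
            deltas.loc[intron_id].to_numpy()
        ).all():
            excluded += 1
            continue
        row = feats.loc[intron_id, MATRIX_COLUMNS[:14]].to_dict()
        row.update(deltas.loc[intron_id, ["DIE", "DIJ", "DIC"]].to_dict())
        row["intron_id"] = intron_id
        row["label"] = label_of[intron_id]
        rows.append(row)
    if excluded:
        import warnings

        warnings.warn(f"excluded {excluded} labeled intron(s) lacking features")
    matrix = pd.DataFrame(rows, columns=["intron_id", *MATRIX_COLUMNS, "label"])
    matrix = matrix.set_index("intron_id")
    return matrix, {"excluded_missing_features": excluded}


def _check_matrix(matrix: pd.DataFrame) -> tuple[np.ndarray, np.ndarray | None]:
    missing = [c for c in MATRIX_COLUMNS if c not in matrix.columns]
    if missing:
        raise ValueError(f"matrix is missing feature columns: {missing}")
    X = matrix[MATRIX_COLUMNS].to_numpy(dtype=float)
    y = None
    if "label" in matrix.columns:
        y = (matrix["label"] == "yes").to_numpy()
    return X, y


def _make_estimator(kind: str, seed: int, params: Mapping | None = None):
    params = dict(params or {})
    if kind == "forest":
        defaults = dict(
            n_estimators=10, max_features=5, criterion="entropy", random_state=seed
        )
        defaults.update(params)
        return RandomForestClassifier(**defaults)
    if kind == "tree":
        return DecisionTreeClassifier(
            criterion="entropy", random_state=seed, **params
        )
    raise ValueError(f"kind must be 'tree' or 'forest', got {kind!r}")


def _prune_tree(X: np.ndarray, y: np.ndarray, seed: int) -> DecisionTreeClassifier:
    # cost-complexity pruning with strength chosen by internal CV
    base = DecisionTreeClassifier(criterion="entropy", random_state=seed)
    path = base.cost_complexity_pruning_path(X, y)
    alphas = np.unique(path.ccp_alphas)
    alphas = alphas[alphas >= 0]
    if len(alphas) > 12:  # subsample the path to bound fit count
        alphas = alphas[np.linspace(0, len(alphas) - 1, 12).astype(int)]
    n_splits = int(min(5, np.bincount(y.astype(int)).min()))
    best_alpha = 0.0
    if n_splits >= 2 and len(alphas) > 1:
        cv = StratifiedKFold(n_splits=n_splits, shuffle=True, random_state=seed)
        best_score = -np.inf
        for alpha in alphas:
            tree = DecisionTreeClassifier(
                criterion="entropy", random_state=seed, ccp_alpha=float(alpha)
            )
            score = cross_val_score(tree, X, y, cv=cv).mean()
            if score > best_score + 1e-12:
                best_score = score
                best_alpha = float(alpha)
    final = DecisionTreeClassifier(
        criterion="entropy", random_state=seed, ccp_alpha=best_alpha
    )
    final.fit(X, y)
    return final


def train_classifier(
    matrix: pd.DataFrame,
    kind: str,
    seed: int = 0,
    params: Mapping | None = None,
) -> TrainedModel:
    """Fit a pruned entropy tree or a 10-tree/5-feature random forest."""
    X, y = _check_matrix(matrix)
    if y is None:
        raise ValueError("matrix has no 'label' column")
    if len(np.unique(y)) < 2:
        raise ValueError("training requires examples of both classes")
    if min((y).sum(), (~y).sum()) < 2:
        raise ValueError("training requires at least 2 examples per class")
    if kind == "tree" and not params:
        est = _prune_tree(X, y, seed)
    else:
        est = _make_estimator(kind, seed, params)
        est.fit(X, y)
    return TrainedModel(kind=kind, estimator=est)


def predict(model: TrainedModel, matrix: pd.DataFrame) -> pd.DataFrame:
    """Yes/no labels plus a positive-class score for each row."""
    if matrix.empty:
        return pd.DataFrame(columns=["label", "score"], index=matrix.index)
    X, _ = _check_matrix(matrix)
    est = model.estimator
    proba = est.predict_proba(X)
    pos_col = list(est.classes_).index(True)
    score = proba[:, pos_col]
    labels = np.where(est.predict(X), "yes", "no")
    return pd.DataFrame({"label": labels, "score": score}, index=matrix.index)


def cross_validate(
    matrix: pd.DataFrame,
    kind: str,
    folds: int = DEFAULT_FOLDS,
    seed: int = 0,
    params: Mapping | None = None,
) -> CVMetrics:
    """Stratified k-fold CV with metrics pooled over held-out predictions."""
    X, y = _check_matrix(matrix)
    if y is None:
        raise ValueError("matrix has no 'label' column")
    class_sizes = np.bincount(y.astype(int), minlength=2)
    if class_sizes.min() < folds:
        raise ValueError(
            f"smallest class has {class_sizes.min()} members, fewer than "
            f"{folds} folds; use fewer folds"
        )
    skf = StratifiedKFold(n_splits=folds, shuffle=True, random_state=seed)
    pred = np.zeros(len(y), dtype=bool)
    score = np.zeros(len(y), dtype=float)
    for train_idx, test_idx in skf.split(X, y):
        sub = matrix.iloc[train_idx]
        model = train_classifier(sub, kind, seed=seed, params=params)
        out = predict(model, matrix.iloc[test_idx])
        pred[test_idx] = out["label"].to_numpy() == "yes"
        score[test_idx] = out["score"].to_numpy()
    tp = int(np.sum(pred & y))
    tn = int(np.sum(~pred & ~y))
    fp = int(np.sum(pred & ~y))
    fn = int(np.sum(~pred & y))
    return CVMetrics(
        acc=(tp + tn) / len(y),
        sp=tn / (tn + fp) if tn + fp else 0.0,
        sn=tp / (tp + fn) if tp + fn else 0.0,
        auc=float(roc_auc_score(y, score)),
    )


def _entropy(labels: np.ndarray) -> float:
    _, counts = np.unique(labels, return_counts=True)
    p = counts / counts.sum()
    return float(-(p * np.log2(p)).sum())


def information_gain(values: np.ndarray, labels: np.ndarray, n_bins: int) -> float:
    """Label-entropy reduction from equal-frequency discretization of ``values``."""
    if n_bins < 2:
        raise ValueError("n_bins must be >= 2")
    values = np.asarray(values, dtype=float)
    labels = np.asarray(labels)
    if np.unique(values).size == 1:
        return 0.0  # degenerate single-bin feature
    bins = pd.qcut(values, q=n_bins, duplicates="drop", labels=False)
    h = _entropy(labels)
    cond = 0.0
    for b in np.unique(bins):
        mask = bins == b
        cond += mask.mean() * _entropy(labels[mask])
    return h - cond


def information_gain_ranking(
    feature_table: pd.DataFrame,
    labels: Mapping[str, str] | pd.Series,
    n_bins: int = DEFAULT_BINS,
    pseudo: float = 1.0,
) -> pd.DataFrame:
    """Rank the 7 base features by the gain of their treatment/control ratio.

    For each base feature the per-intron ratio T/(C + pseudo) is discretized
    into ``n_bins`` equal-frequency bins; gain = H(label) - H(label | bin),
    in bits. Output sorted by gain descending.
    """
    labels = pd.Series(labels)
    table = feature_table.set_index("intron_id").loc[labels.index]
    y = labels.to_numpy()
    rows = []
    for feat in BASE_FEATURES:
        ratio = table["T" + feat] / (table["C" + feat] + pseudo)
        rows.append(
            {
                "feature": feat,
                "gain": information_gain(ratio.to_numpy(), y, n_bins),
            }
        )
    out = pd.DataFrame(rows).sort_values(
        by=["gain", "feature"], ascending=[False, True], kind="mergesort"
    )
    return out.reset_index(drop=True)
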