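"""Weighted discrete learning: balancing, MDL discretization, CFS, naive Bayes.

The classification path mirrors the discrete Bayesian-network treatment of
the gait features:

* instances are reweighted so every class carries the same total weight
  (N_total / n_classes per class);
* each numeric feature is discretized by recursive entropy minimization with
  the Fayyad-Irani minimum-description-length acceptance criterion, computed
  on instance weights;
* feature subsets are scored by the CFS merit
  ``k * r_cf / sqrt(k + k (k-1) * r_ff)`` with symmetric uncertainty as the
  correlation measure, searched best-first (or exhaustively for small
  registries);
* a Laplace-smoothed (alpha = 0.5) class-conditional table per selected
  feature forms the naive-star Bayes model; missing feature values are
  skipped both in estimation and at prediction time.

Repeated stratified 10-fold cross-validation refits discretization, feature
selection, balancing and the model inside every training fold, so no
information leaks from the test fold.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field
from itertools import combinations
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

ALPHA = 0.5
CV_FOLDS = 10
CV_RUNS = 100
BEST_FIRST_STALE = 5  # non-improving expansions before the search stops


class EmptyClassError(ValueError):
    pass


# ---------------------------------------------------------------------------
# balancing
# ---------------------------------------------------------------------------

def balance_weights(labels: Sequence) -> np.ndarray:
    """Per-instance weights equalizing class totals at N_total / n_classes."""
    labels = np.asarray(labels)
    classes, counts = np.unique(labels, return_counts=True)
    if len(classes) < 2:
        raise EmptyClassError("balancing requires at least two classes")
    target = len(labels) / len(classes)
    per_class = {c: target / n for c, n in zip(classes, counts)}
    return np.array([per_class[c] for c in labels])


# ---------------------------------------------------------------------------
# MDL discretization (Fayyad-Irani), weighted
# ---------------------------------------------------------------------------

def _entropy(class_weights: np.ndarray) -> float:
    total = class_weights.sum()
    if total <= 0:
        return 0.0
    p = class_weights[class_weights > 0] / total
    return float(-(p * np.log2(p)).sum())


def _class_weight_vector(y: np.ndarray, w: np.ndarray, n_classes: int) -> np.ndarray:
    return np.bincount(y, weights=w, minlength=n_classes)


def mdl_discretize(
    values: np.ndarray, labels: Sequence, weights: np.ndarray | None = None
) -> list[float]:
    """Supervised cut points for one numeric feature.

    Recursively picks the boundary minimizing the weighted class-information
    entropy and keeps it only if the information gain passes the MDL
    acceptance test; returns a possibly-empty, strictly increasing cut list
    (empty = the feature stays in a single bin). Missing values are ignored.
    """
    values = np.asarray(values, dtype=float)
    labels = np.asarray(labels)
    if weights is None:
        weights = np.ones(len(values))
    weights = np.asarray(weights, dtype=float)
    mask = np.isfinite(values)
    values, labels, weights = values[mask], labels[mask], weights[mask]
    if values.size == 0 or np.unique(values).size < 2:
        return []
    classes, y = np.unique(labels, return_inverse=True)
    order = np.argsort(values, kind="mergesort")
    v, y, w = values[order], y[order], weights[order]
    cuts: list[float] = []
    _mdl_split(v, y, w, len(classes), cuts)
    return sorted(cuts)


def _mdl_split(v: np.ndarray, y: np.ndarray, w: np.ndarray, n_classes: int, cuts: list[float]) -> None:
    n = v.size
    if n < 2:
        return
    total_cw = _class_weight_vector(y, w, n_classes)
    total_w = total_cw.sum()
    ent_s = _entropy(total_cw)
    # candidate boundaries between distinct adjacent values
    change = np.flatnonzero(v[1:] > v[:-1]) + 1  # split before index i
    if change.size == 0:
        return
    # prefix class-weight sums for O(1) entropy at each candidate
    onehot = np.zeros((n, n_classes))
    onehot[np.arange(n), y] = w
    prefix = np.cumsum(onehot, axis=0)
    best = None
    for i in change:
        left_cw = prefix[i - 1]
        right_cw = total_cw - left_cw
        lw, rw = left_cw.sum(), right_cw.sum()
        e = (lw * _entropy(left_cw) + rw * _entropy(right_cw)) / total_w
        if best is None or e < best[1]:
            best = (i, e, left_cw, right_cw)
    i, e_split, left_cw, right_cw = best
    gain = ent_s - e_split
    k = int((total_cw > 0).sum())
    k1 = int((left_cw > 0).sum())
    k2 = int((right_cw > 0).sum())
    e1 = _entropy(left_cw)
    e2 = _entropy(right_cw)
    delta = math.log2(3**k - 2) - (k * ent_s - k1 * e1 - k2 * e2)
    threshold = (math.log2(total_w - 1) + delta) / total_w if total_w > 1 else float("inf")
    if gain <= threshold:
        return
    cuts.append(float((v[i - 1] + v[i]) / 2.0))
    _mdl_split(v[:i], y[:i], w[:i], n_classes, cuts)
    _mdl_split(v[i:], y[i:], w[i:], n_classes, cuts)


def apply_cuts(values: np.ndarray, cuts: Sequence[float]) -> np.ndarray:
    """Bin indices (0..len(cuts)); missing values map to -1."""
    values = np.asarray(values, dtype=float)
    bins = np.searchsorted(np.asarray(cuts, dtype=float), values, side="right")
    bins = bins.astype(int)
    bins[~np.isfinite(values)] = -1
    return bins


@dataclass
class DiscretizationMap:
    """Ordered cut points per feature; empty list = single bin."""

    cuts: dict[str, list[float]]

    def n_bins(self, feature: str) -> int:
        return len(self.cuts.get(feature, [])) + 1

    def transform(self, df: pd.DataFrame) -> pd.DataFrame:
        out = {}
        for col in df.columns:
            out[col] = apply_cuts(df[col].to_numpy(), self.cuts.get(col, []))
        return pd.DataFrame(out, index=df.index)


def discretize_dataset(
    df: pd.DataFrame, labels: Sequence, weights: np.ndarray | None = None
) -> DiscretizationMap:
    return DiscretizationMap(
        {col: mdl_discretize(df[col].to_numpy(), labels, weights) for col in df.columns}
    )


# ---------------------------------------------------------------------------
# CFS with symmetric uncertainty
# ---------------------------------------------------------------------------

def symmetric_uncertainty(x: np.ndarray, y: np.ndarray, w: np.ndarray) -> float:
    """SU(X, Y) = 2 (H(X) + H(Y) - H(X, Y)) / (H(X) + H(Y)) on discrete codes.

    Codes < 0 mark missing entries and are excluded pairwise.
    """
    mask = (x >= 0) & (y >= 0)
    if not mask.any():
        return 0.0
    x, y, w = x[mask], y[mask], w[mask]
    nx, ny = x.max() + 1, y.max() + 1
    joint = np.zeros((nx, ny))
    np.add.at(joint, (x, y), w)
    hx = _entropy(joint.sum(axis=1))
    hy = _entropy(joint.sum(axis=0))
    hxy = _entropy(joint.ravel())
    denom = hx + hy
    if denom <= 0:
        return 0.0
    return max(0.0, 2.0 * (hx + hy - hxy) / denom)


def cfs_merit(
    subset: Sequence[str],
    su_cf: dict[str, float],
    su_ff: dict[tuple[str, str], float],
) -> float:
    k = len(subset)
    if k == 0:
        return 0.0
    r_cf = sum(su_cf[f] for f in subset) / k
    if k == 1:
        return r_cf
    pairs = list(combinations(sorted(subset), 2))
    r_ff = sum(su_ff[p] for p in pairs) / len(pairs)
    return k * r_cf / math.sqrt(k + k * (k - 1) * r_ff)


@dataclass
class CFSResult:
    selected: list[str]
    merit: float
    trace: list[tuple[tuple[str, ...], float]] = field(default_factory=list)


def cfs_select(
    binned: pd.DataFrame,
    labels: Sequence,
    weights: np.ndarray | None = None,
    search: str = "best_first",
) -> CFSResult:
    """Correlation-based feature subset selection on discretized data.

    ``best_first`` runs a forward best-first search that stops after
    :data:`BEST_FIRST_STALE` consecutive non-improving expansions;
    ``exhaustive`` enumerates all subsets (registries of <= 15 features).
    """
    features = list(binned.columns)
    y = pd.factorize(pd.Series(labels))[0]
    if weights is None:
        weights = np.ones(len(y))
    cols = {f: binned[f].to_numpy() for f in features}
    su_cf = {f: symmetric_uncertainty(cols[f], y, weights) for f in features}
    su_ff_cache: dict[tuple[str, str], float] = {}

    def su_ff(pair: tuple[str, str]) -> float:
        if pair not in su_ff_cache:
            su_ff_cache[pair] = symmetric_uncertainty(cols[pair[0]], cols[pair[1]], weights)
        return su_ff_cache[pair]

    def merit(subset: tuple[str, ...]) -> float:
        for p in combinations(sorted(subset), 2):
            su_ff(p)
        return cfs_merit(subset, su_cf, su_ff_cache)

    if not any(v > 0 for v in su_cf.values()):
        return CFSResult([], 0.0)

    if search == "exhaustive":
        if len(features) > 15:
            raise ValueError("exhaustive search limited to <= 15 features")
        best, best_m, trace = (), 0.0, []
        for k in range(1, len(features) + 1):
            for subset in combinations(features, k):
                m = merit(subset)
                trace.append((subset, m))
                if m > best_m:
                    best, best_m = subset, m
        return CFSResult(sorted(best), best_m, trace)

    if search != "best_first":
        raise ValueError(f"unknown search {search!r}")

    open_list: list[tuple[float, tuple[str, ...]]] = [(0.0, ())]
    visited: set[tuple[str, ...]] = {()}
    best_subset: tuple[str, ...] = ()
    best_m = 0.0
    stale = 0
    trace: list[tuple[tuple[str, ...], float]] = []
    while open_list and stale < BEST_FIRST_STALE:
        open_list.sort(key=lambda t: t[0])
        _, node = open_list.pop()
        improved = False
        for f in features:
            if f in node:
                continue
            child = tuple(sorted(node + (f,)))
            if child in visited:
                continue
            visited.add(child)
            m = merit(child)
            trace.append((child, m))
            open_list.append((m, child))
            if m > best_m + 1e-12:
                best_subset, best_m = child, m
                improved = True
        stale = 0 if improved else stale + 1
    return CFSResult(sorted(best_subset), best_m, trace)


# ---------------------------------------------------------------------------
# Laplace-smoothed discrete naive Bayes
# ---------------------------------------------------------------------------

@dataclass
class CPDTable:
    """P(feature bin | class), one row per class; rows sum to 1."""

    feature: str
    classes: list
    probs: np.ndarray  # (n_classes, n_bins)


@dataclass
class NBModel:
    classes: list
    priors: np.ndarray
    cpds: list[CPDTable]
    discretization: DiscretizationMap
    alpha: float = ALPHA

    @property
    def features(self) -> list[str]:
        return [c.feature for c in self.cpds]

    def to_json(self, path: str | Path) -> None:
        payload = {
            "classes": [str(c) for c in self.classes],
            "priors": self.priors.tolist(),
            "alpha": self.alpha,
            "features": [
                {
                    "name": c.feature,
                    "cuts": self.discretization.cuts.get(c.feature, []),
                    "cpd": {
                        str(cls): c.probs[i].tolist() for i, cls in enumerate(self.classes)
                    },
                }
                for c in self.cpds
            ],
        }
        Path(path).write_text(json.dumps(payload, indent=1) + "\n")

    @classmethod
    def from_json(cls, path: str | Path) -> "NBModel":
        payload = json.loads(Path(path).read_text())
        classes = payload["classes"]
        cpds = []
        cuts = {}
        for f in payload["features"]:
            probs = np.array([f["cpd"][str(c)] for c in classes])
            cpds.append(CPDTable(f["name"], classes, probs))
            cuts[f["name"]] = list(f["cuts"])
        return cls(
            classes,
            np.array(payload["priors"]),
            cpds,
            DiscretizationMap(cuts),
            payload["alpha"],
        )


def fit_nb(
    binned: pd.DataFrame,
    labels: Sequence,
    weights: np.ndarray,
    discretization: DiscretizationMap,
    features: Sequence[str] | None = None,
    alpha: float = ALPHA,
) -> NBModel:
    """Fit class priors and per-feature conditional tables on weighted bins.

    CPD entry = (weighted count of class-c instances in the bin + alpha) /
    (class-c weight over non-missing entries + alpha * n_bins). Priors are
    proportional to class total weights (uniform after balancing).
    """
    labels = np.asarray(labels)
    classes = sorted(np.unique(labels).tolist())
    if features is None:
        features = list(binned.columns)
    class_w = np.array([weights[labels == c].sum() for c in classes])
    priors = class_w / class_w.sum()
    cpds = []
    for f in features:
        n_bins = discretization.n_bins(f)
        x = binned[f].to_numpy()
        probs = np.zeros((len(classes), n_bins))
        for i, c in enumerate(classes):
            sel = (labels == c) & (x >= 0)
            counts = np.bincount(x[sel], weights=weights[sel], minlength=n_bins)
            denom = weights[sel].sum() + alpha * n_bins
            probs[i] = (counts + alpha) / denom
        cpds.append(CPDTable(f, classes, probs))
    return NBModel(classes, priors, cpds, discretization, alpha)


def predict_proba(model: NBModel, instance: pd.Series | dict) -> pd.Series:
    """Posterior over classes; missing feature values are skipped as factors."""
    logp = np.log(model.priors.astype(float))
    for cpd in model.cpds:
        v = instance.get(cpd.feature, float("nan"))
        if v is None or (isinstance(v, float) and math.isnan(v)):
            continue
        b = int(apply_cuts(np.array([v]), model.discretization.cuts.get(cpd.feature, []))[0])
        if b < 0:
            continue
        logp = logp + np.log(cpd.probs[:, b])
    logp -= logp.max()
    p = np.exp(logp)
    p /= p.sum()
    return pd.Series(p, index=model.classes)


def predict(model: NBModel, instance: pd.Series | dict):
    """Argmax class; ties break toward the lower class label."""
    p = predict_proba(model, instance)
    return p.index[int(np.argmax(p.to_numpy()))]


# ---------------------------------------------------------------------------
# cross-validation harness
# ---------------------------------------------------------------------------

@dataclass
class ModelConfig:
    alpha: float = ALPHA
    selector: str = "cfs"  # cfs | infogain | none
    classifier: str = "nb"  # nb | knn | tree | svm | perceptron
    infogain_top_k: int = 7
    discretize: bool = True


@dataclass
class CVReport:
    fold_accuracies: np.ndarray  # percent, one entry per fold per run
    confusion: pd.DataFrame

    @property
    def mean_accuracy(self) -> float:
        return float(self.fold_accuracies.mean())

    @property
    def sd_accuracy(self) -> float:
        return float(self.fold_accuracies.std(ddof=1))


def stratified_folds(labels: np.ndarray, n_folds: int, rng: np.random.Generator):
    """Per-class round-robin assignment after a shuffle; yields test index arrays."""
    assignment = np.empty(len(labels), dtype=int)
    for ci, c in enumerate(np.unique(labels)):
        idx = np.flatnonzero(labels == c)
        rng.shuffle(idx)
        # per-class offset spreads remainders across folds
        assignment[idx] = (np.arange(len(idx)) + ci) % n_folds
    for f in range(n_folds):
        yield np.flatnonzero(assignment == f)


def _select_features(
    binned: pd.DataFrame, labels, weights, config: ModelConfig
) -> list[str]:
    if config.selector == "none":
        return list(binned.columns)
    if config.selector == "cfs":
        return cfs_select(binned, labels, weights).selected
    if config.selector == "infogain":
        y = pd.factorize(pd.Series(labels))[0]
        su = {
            f: symmetric_uncertainty(binned[f].to_numpy(), y, weights)
            for f in binned.columns
        }
        ranked = sorted(su, key=su.get, reverse=True)
        return [f for f in ranked[: config.infogain_top_k] if su[f] > 0]
    raise ValueError(f"unknown selector {config.selector!r}")


def fit_pipeline(
    features_df: pd.DataFrame, labels: Sequence, config: ModelConfig | None = None
) -> NBModel:
    """Balance, discretize, select and fit on a full dataset (no CV)."""
    config = config or ModelConfig()
    labels = np.asarray(labels)
    weights = balance_weights(labels)
    dmap = discretize_dataset(features_df, labels, weights)
    binned = dmap.transform(features_df)
    informative = [f for f in binned.columns if dmap.n_bins(f) > 1]
    selected = _select_features(binned[informative], labels, weights, config)
    if not selected:
        selected = informative or list(binned.columns)[:1]
    return fit_nb(binned, labels, weights, dmap, selected, config.alpha)


def _sklearn_classifier(name: str, seed: int):
    # thin adapters for the comparison harness only; the Bayes path above is
    # the modeled method
    if name == "knn":
        from sklearn.neighbors import KNeighborsClassifier

        return KNeighborsClassifier(n_neighbors=1)
    if name == "tree":
        from sklearn.tree import DecisionTreeClassifier

        return DecisionTreeClassifier(random_state=seed)
    if name == "svm":
        from sklearn.svm import SVC

        return SVC(random_state=seed)
    if name == "perceptron":
        from sklearn.neural_network import MLPClassifier

        return MLPClassifier(random_state=seed, max_iter=500)
    raise ValueError(f"unknown classifier {name!r}")


def cross_validate(
    features_df: pd.DataFrame,
    labels: Sequence,
    config: ModelConfig | None = None,
    folds: int = CV_FOLDS,
    runs: int = CV_RUNS,
    base_seed: int = 0,
) -> CVReport:
    """Repeated stratified k-fold accuracy (percent correctly classified).

    Discretization, feature selection, balancing and fitting happen inside
    each training fold only. The report pools accuracies over all folds of
    all runs, matching the convention of quoting the fold-level spread.
    """
    config = config or ModelConfig()
    labels = np.asarray(labels)
    if folds > len(labels):
        raise ValueError("more folds than instances")
    classes = sorted(np.unique(labels).tolist())
    confusion = pd.DataFrame(0, index=classes, columns=classes)
    accs = []
    rng = np.random.default_rng(base_seed)
    for _ in range(runs):
        run_rng = np.random.default_rng(int(rng.integers(2**31)))
        for test_idx in stratified_folds(labels, folds, run_rng):
            if test_idx.size == 0:
                continue
            train_mask = np.ones(len(labels), dtype=bool)
            train_mask[test_idx] = False
            X_tr, y_tr = features_df.iloc[train_mask.nonzero()[0]], labels[train_mask]
            X_te, y_te = features_df.iloc[test_idx], labels[test_idx]
            if config.classifier == "nb":
                model = fit_pipeline(X_tr, y_tr, config)
                pred = [predict(model, X_te.iloc[i]) for i in range(len(X_te))]
            else:
                pred = _baseline_predict(X_tr, y_tr, X_te, config, int(rng.integers(2**31)))
            correct = sum(p == t for p, t in zip(pred, y_te))
            accs.append(100.0 * correct / len(y_te))
            for p, t in zip(pred, y_te):
                confusion.loc[t, p] += 1
    return CVReport(np.array(accs), confusion)


def _baseline_predict(X_tr, y_tr, X_te, config: ModelConfig, seed: int):
    med = X_tr.median()
    Xtr = X_tr.fillna(med).fillna(0.0)
    Xte = X_te.fillna(med).fillna(0.0)
    weights = balance_weights(y_tr)
    if config.discretize or config.selector != "none":
        dmap = discretize_dataset(X_tr, y_tr, weights)
        binned = dmap.transform(X_tr)
        informative = [f for f in binned.columns if dmap.n_bins(f) > 1]
        selected = _select_features(binned[informative], y_tr, weights, config)
        if selected:
            Xtr, Xte = Xtr[selected], Xte[selected]
        if config.discretize and selected:
            Xtr = dmap.transform(X_tr[selected]).astype(float)
            Xte = dmap.transform(X_te[selected]).astype(float)
    clf = _sklearn_classifier(config.classifier, seed)
    try:
        clf.fit(Xtr, y_tr, sample_weight=weights)
    except TypeError:
        clf.fit(Xtr, y_tr)
    return list(clf.predict(Xte))


def to_binary_labels(labels: Sequence) -> np.ndarray:
    """Collapse stages 1-3 to 'PD'; controls stay 'control'."""
    return np.array(["control" if str(l) == "control" else "PD" for l in labels])
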