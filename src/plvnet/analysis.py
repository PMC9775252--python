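"""Group statistics and classification of network features.

Per-subject network metrics are aggregated into a feature table; group and
condition contrasts use two-sided permutation tests (label permutations
for independent groups, sign flips for paired contrasts) with Welch's t as
the statistic; classification runs four classifiers (SVM, decision tree,
k-nearest neighbours, random forest) under stratified k-fold
cross-validation with pooled out-of-fold predictions. Standardization is
fit inside training folds only, so cross-validation never leaks.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field
from itertools import combinations

import numpy as np
import pandas as pd
from sklearn.ensemble import RandomForestClassifier
from sklearn.neighbors import KNeighborsClassifier
from sklearn.pipeline import make_pipeline
from sklearn.preprocessing import StandardScaler
from sklearn.svm import SVC
from sklearn.tree import DecisionTreeClassifier

from .graphnet import binarize, network_metrics

POSITIVE_CLASS = "MDD"
DEFAULT_FEATURES = ("delta_mean_cc", "delta_cpl", "beta_cpl")


@dataclass
class SubjectFeatures:
    """Per-(subject, condition) network properties, one entry per band."""

    subject_id: str
    group: str
    condition: str
    mean_cc: dict            # band -> float
    cpl: dict                # band -> float
    degrees: dict            # band -> np.ndarray


@dataclass
class ComparisonResult:
    contrast: str
    band: str
    metric: str
    statistic: float
    p_value: float
    n_permutations: int
    seed: int
    paired: bool
    exhaustive: bool


@dataclass
class ClassifierReport:
    results: dict            # name -> {"accuracy", "precision", "recall"}
    folds: list              # list of index lists partitioning the sample
    seed: int
    feature_names: tuple
    n: int


def metrics_table(matrices, fraction: float = 0.8) -> list[SubjectFeatures]:
    """Binarize every connectivity matrix and collect network metrics.

    One SubjectFeatures row per (subject, condition); raises if the cohort
    is incomplete (some (subject, condition) cells miss a band).
    """
    cells: dict = {}
    for m in matrices:
        key = (m.subject_id, m.condition)
        cells.setdefault(key, {"group": m.group, "bands": {}})
        cells[key]["bands"][m.band] = m
    all_bands = sorted({m.band for m in matrices})
    missing = [
        (sid, cond, band)
        for (sid, cond), cell in cells.items()
        for band in all_bands if band not in cell["bands"]
    ]
    if missing:
        raise ValueError(f"incomplete cohort; missing cells: {missing}")
    rows = []
    for (sid, cond), cell in sorted(cells.items()):
        mean_cc, cpl, degrees = {}, {}, {}
        for band in all_bands:
            nm = network_metrics(binarize(cell["bands"][band], fraction))
            mean_cc[band] = nm.mean_cc
            cpl[band] = nm.cpl
            degrees[band] = nm.degrees
        rows.append(SubjectFeatures(sid, cell["group"], cond,
                                    mean_cc, cpl, degrees))
    return rows


def features_frame(features) -> pd.DataFrame:
    """Tidy DataFrame (subject, group, condition, band, metric, value)."""
    records = []
    for f in features:
        for band in sorted(f.mean_cc):
            records.append((f.subject_id, f.group, f.condition, band,
                            "mean_cc", f.mean_cc[band]))
            records.append((f.subject_id, f.group, f.condition, band,
                            "cpl", f.cpl[band]))
            for label_idx, deg in enumerate(f.degrees[band]):
                records.append((f.subject_id, f.group, f.condition, band,
                                f"degree_{label_idx}", float(deg)))
    return pd.DataFrame(
        records,
        columns=["subject", "group", "condition", "band", "metric", "value"],
    )


# ---------------------------------------------------------------------------
# Permutation testing

def _welch_t(a: np.ndarray, b: np.ndarray) -> float:
    """Welch's t; +-inf for zero pooled variance with nonzero mean gap."""
    va = a.var(ddof=1) / a.size
    vb = b.var(ddof=1) / b.size
    diff = a.mean() - b.mean()
    se = math.sqrt(va + vb)
    if se == 0.0:
        return 0.0 if diff == 0.0 else math.copysign(math.inf, diff)
    return diff / se


def _paired_t(d: np.ndarray) -> float:
    se = d.std(ddof=1) / math.sqrt(d.size)
    mean = d.mean()
    if se == 0.0:
        return 0.0 if mean == 0.0 else math.copysign(math.inf, mean)
    return mean / se


def group_compare(values_a, values_b, paired: bool = False,
                  n_permutations: int = 9999, seed: int = 0,
                  exhaustive: bool | None = None) -> ComparisonResult:
    """Two-sided permutation test on the mean difference.

    Unpaired: group labels are permuted over the pooled sample. Paired:
    per-pair difference signs are flipped. When the full permutation set
    is no larger than ``n_permutations`` (or ``exhaustive=True``), all
    permutations are enumerated and p = #{|T_perm| >= |T_obs|} / total;
    otherwise ``n_permutations`` random permutations give the standard
    add-one estimate p = (1 + #) / (1 + n_permutations).
    """
    a = np.asarray(values_a, dtype=np.float64)
    b = np.asarray(values_b, dtype=np.float64)
    if a.size < 3:
        raise ValueError(f"side A has {a.size} values; need >= 3")
    if b.size < 3:
        raise ValueError(f"side B has {b.size} values; need >= 3")
    if paired and a.size != b.size:
        raise ValueError("paired comparison requires equal lengths")
    rng = np.random.default_rng(seed)
    tol = 1e-12

    if paired:
        d = a - b
        t_obs = _paired_t(d)
        n = d.size
        total = 2 ** n
        do_exhaustive = exhaustive if exhaustive is not None else total <= n_permutations
        if do_exhaustive:
            signs = np.array(
                [[1 if (m >> i) & 1 else -1 for i in range(n)] for m in range(total)],
                dtype=np.float64,
            )
            t_perm = np.array([_paired_t(d * s) for s in signs])
            count = int(np.sum(np.abs(t_perm) >= abs(t_obs) - tol))
            p = count / total
            n_used, exact = total, True
        else:
            signs = rng.choice([-1.0, 1.0], size=(n_permutations, n))
            t_perm = np.array([_paired_t(d * s) for s in signs])
            count = int(np.sum(np.abs(t_perm) >= abs(t_obs) - tol))
            p = (1 + count) / (1 + n_permutations)
            n_used, exact = n_permutations, False
    else:
        t_obs = _welch_t(a, b)
        pooled = np.concatenate([a, b])
        n_a, n_tot = a.size, a.size + b.size
        total = math.comb(n_tot, n_a)
        do_exhaustive = exhaustive if exhaustive is not None else total <= n_permutations
        if do_exhaustive:
            t_perm = np.array([
                _welch_t(pooled[list(idx)],
                         pooled[[i for i in range(n_tot) if i not in set(idx)]])
                for idx in combinations(range(n_tot), n_a)
            ])
            count = int(np.sum(np.abs(t_perm) >= abs(t_obs) - tol))
            p = count / total
            n_used, exact = total, True
        else:
            t_perm = np.empty(n_permutations)
            for k in range(n_permutations):
                perm = rng.permutation(n_tot)
                t_perm[k] = _welch_t(pooled[perm[:n_a]], pooled[perm[n_a:]])
            count = int(np.sum(np.abs(t_perm) >= abs(t_obs) - tol))
            p = (1 + count) / (1 + n_permutations)
            n_used, exact = n_permutations, False

    return ComparisonResult(
        contrast="A_vs_B", band="", metric="", statistic=float(t_obs),
        p_value=float(p), n_permutations=n_used, seed=seed, paired=paired,
        exhaustive=exact,
    )


# ---------------------------------------------------------------------------
# Feature extraction and cross-validated classification

def _feature_value(f: SubjectFeatures, name: str) -> float:
    band, _, metric = name.partition("_")
    if metric == "mean_cc":
        table = f.mean_cc
    elif metric == "cpl":
        table = f.cpl
    else:
        raise KeyError(f"unknown feature {name!r}")
    if band not in table:
        raise KeyError(f"band {band!r} absent for subject {f.subject_id}")
    return table[band]


def extract_features(features, spec=DEFAULT_FEATURES, condition: str = "pre",
                     standardize: bool = True):
    """Design matrix and labels from per-subject features.

    One row per subject at the given condition; columns follow ``spec``
    (names like ``delta_mean_cc``, ``beta_cpl``). Constant columns are
    dropped with a warning when standardizing. Returns
    ``(X, y, names, subject_ids)`` with y = 1 for the MDD group.
    """
    rows = sorted((f for f in features if f.condition == condition),
                  key=lambda f: f.subject_id)
    if not rows:
        raise ValueError(f"no features for condition {condition!r}")
    names = tuple(spec)
    X = np.array([[_feature_value(f, name) for name in names] for f in rows])
    y = np.array([1 if f.group == POSITIVE_CLASS else 0 for f in rows])
    ids = tuple(f.subject_id for f in rows)
    if standardize:
        sd = X.std(axis=0)
        keep = sd > 1e-12
        if not keep.all():
            dropped = [n for n, k in zip(names, keep) if not k]
            warnings.warn(f"dropping constant feature column(s): {dropped}")
            X = X[:, keep]
            names = tuple(n for n, k in zip(names, keep) if k)
            sd = sd[keep]
        X = (X - X.mean(axis=0)) / sd
    return X, y, names, ids


def default_classifiers(seed: int = 0) -> dict:
    return {
        "SVM": SVC(kernel="rbf", C=1.0, gamma="scale"),
        "DT": DecisionTreeClassifier(random_state=seed),
        "KNN": KNeighborsClassifier(n_neighbors=3),
        "RF": RandomForestClassifier(n_estimators=100, random_state=seed),
    }


def _stratified_folds(y: np.ndarray, k: int, rng: np.random.Generator) -> list:
    """Class-interleaved folds of size differing by at most 1.

    Plain stratified k-fold breaks down when folds are smaller than the
    number of classes (10 folds on 16 subjects); interleaving shuffled
    class members before dealing keeps folds as balanced as possible.
    """
    folds: list[list[int]] = [[] for _ in range(k)]
    pos = 0
    for idx in (rng.permutation(np.flatnonzero(y == c)) for c in np.unique(y)):
        for member in idx:
            folds[pos % k].append(int(member))
            pos += 1
    return folds


def crossval_classify(X: np.ndarray, y: np.ndarray, k: int = 10, seed: int = 0,
                      classifiers: dict | None = None,
                      feature_names=()) -> ClassifierReport:
    """Stratified k-fold cross-validation with pooled out-of-fold metrics.

    Standardization is re-fit on each training fold (no leakage). Accuracy,
    precision and recall are computed on the pooled predictions with MDD
    (label 1) as the positive class.
    """
    X = np.asarray(X, dtype=np.float64)
    y = np.asarray(y)
    n = y.size
    if k > n:
        raise ValueError(f"k = {k} exceeds sample size {n}")
    if np.unique(y).size < 2:
        raise ValueError("need at least 2 classes")
    rng = np.random.default_rng(seed)
    folds = _stratified_folds(y, k, rng)
    classifiers = classifiers if classifiers is not None else default_classifiers(seed)
    results = {}
    for name, clf in classifiers.items():
        pred = np.empty(n, dtype=y.dtype)
        for fold in folds:
            if not fold:
                continue
            test = np.array(fold)
            train = np.setdiff1d(np.arange(n), test)
            model = make_pipeline(StandardScaler(), clf)
            model.fit(X[train], y[train])
            pred[test] = model.predict(X[test])
        tp = int(np.sum((pred == 1) & (y == 1)))
        fp = int(np.sum((pred == 1) & (y == 0)))
        fn = int(np.sum((pred == 0) & (y == 1)))
        results[name] = {
            "accuracy": float(np.mean(pred == y)),
            "precision": tp / (tp + fp) if tp + fp else 0.0,
            "recall": tp / (tp + fn) if tp + fn else 0.0,
        }
    return ClassifierReport(results=results, folds=[list(f) for f in folds],
                            seed=seed, feature_names=tuple(feature_names), n=n)
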