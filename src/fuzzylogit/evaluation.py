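"""Imbalance-aware evaluation: confusion metrics, CV harness, rank tests.

Sensitivity and specificity read jointly diagnose class imbalance (a large
gap between them means the classifier collapsed toward one class), while
uniformly near-perfect scores across all measures are the signature of
over-fitting from complete separation.  MCC and F1 complement them as
single-number summaries robust to imbalance.

The cross-validation harness applies repeated stratified 70/30 splits with
optional SMOTE balancing of the training part, and model comparison across
datasets uses the Friedman rank test with the Iman–Davenport refinement and
Nemenyi critical differences.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy.stats import studentized_range
from sklearn.base import clone
from sklearn.metrics import confusion_matrix as _sk_confusion
from sklearn.model_selection import StratifiedShuffleSplit
from sklearn.neighbors import NearestNeighbors

__all__ = [
    "ConfusionMatrix",
    "MetricSet",
    "CVResult",
    "RankComparison",
    "confusion",
    "metrics",
    "smote_balance",
    "repeated_split_cv",
    "friedman_test",
    "nemenyi_cd",
]


@dataclass(frozen=True)
class ConfusionMatrix:
    """Binary confusion counts with class 1 as positive."""

    TP: int
    TN: int
    FP: int
    FN: int

    def __post_init__(self) -> None:
        if min(self.TP, self.TN, self.FP, self.FN) < 0:
            raise ValueError("confusion counts must be nonnegative")

    @property
    def total(self) -> int:
        return self.TP + self.TN + self.FP + self.FN


@dataclass(frozen=True)
class MetricSet:
    """The six performance scores derived from a confusion matrix."""

    sensitivity: float
    specificity: float
    precision: float
    recall: float
    f1: float
    mcc: float

    def as_dict(self) -> dict[str, float]:
        return {"sensitivity": self.sensitivity, "specificity": self.specificity,
                "precision": self.precision, "recall": self.recall,
                "f1": self.f1, "mcc": self.mcc}


@dataclass
class CVResult:
    """Per-split and averaged metrics of a repeated-split evaluation."""

    per_split: list[tuple[int, MetricSet, ConfusionMatrix]]
    mean_metrics: MetricSet
    n_splits: int
    train_fraction: float
    smote: bool
    seed: int


@dataclass
class RankComparison:
    """Friedman / Iman–Davenport / Nemenyi comparison over a score table."""

    score_table: np.ndarray          # datasets x models
    model_names: list[str]
    avg_ranks: np.ndarray
    Q: float                         # Friedman chi-square statistic
    F_f: float                       # Iman-Davenport F statistic
    p_value: float
    CD: float | None = None
    pairwise_significant: np.ndarray | None = None
    alpha: float | None = None

    def with_nemenyi(self, alpha: float = 0.05) -> "RankComparison":
        N, k = self.score_table.shape
        cd = nemenyi_cd(N, k, alpha)
        diff = np.abs(self.avg_ranks[:, None] - self.avg_ranks[None, :])
        sig = diff > cd
        np.fill_diagonal(sig, False)
        return RankComparison(self.score_table, self.model_names,
                              self.avg_ranks, self.Q, self.F_f, self.p_value,
                              cd, sig, alpha)


def confusion(y_true, y_pred) -> ConfusionMatrix:
    """Count TP/TN/FP/FN with class 1 positive."""
    y_true = np.asarray(y_true)
    y_pred = np.asarray(y_pred)
    if y_true.shape != y_pred.shape:
        raise ValueError(
            f"length mismatch: {y_true.shape} vs {y_pred.shape}")
    vals = np.unique(np.concatenate([y_true.ravel(), y_pred.ravel()]))
    if not np.all(np.isin(vals, (0, 1))):
        raise ValueError(f"labels must be 0/1, found {vals}")
    tn, fp, fn, tp = _sk_confusion(y_true, y_pred, labels=[0, 1]).ravel()
    return ConfusionMatrix(int(tp), int(tn), int(fp), int(fn))


def _ratio(num: float, den: float, name: str) -> float:
    if den == 0:
        warnings.warn(f"zero denominator in {name}; returning 0", RuntimeWarning)
        return 0.0
    return num / den


def metrics(cm: ConfusionMatrix) -> MetricSet:
    """Sensitivity, specificity, precision, recall, F1 and MCC from counts.

    Cells with a zero denominator return 0 (with a warning); MCC with any
    zero factor under the root returns 0.
    """
    if cm.total == 0:
        raise ValueError("empty confusion matrix")
    tp, tn, fp, fn = cm.TP, cm.TN, cm.FP, cm.FN
    sens = _ratio(tp, tp + fn, "sensitivity")
    spec = _ratio(tn, tn + fp, "specificity")
    prec = _ratio(tp, tp + fp, "precision")
    rec = sens
    f1 = _ratio(2 * prec * rec, prec + rec, "F1")
    denom2 = (tp + fp) * (tp + fn) * (tn + fp) * (tn + fn)
    mcc = (tp * tn - fp * fn) / np.sqrt(denom2) if denom2 > 0 else 0.0
    return MetricSet(sens, spec, prec, rec, f1, float(mcc))


def smote_balance(X, y, k_neighbors: int = 5,
                  rng: np.random.Generator | None = None):
    """Oversample the minority class by SMOTE to exact balance.

    Each synthetic point is ``x + u·(x_nn − x)`` with ``u ~ Uniform(0,1)``
    and ``x_nn`` a random one of the ``k_neighbors`` nearest minority
    neighbours of the minority point ``x``.
    """
    rng = rng or np.random.default_rng()
    X = np.asarray(X, dtype=float)
    y = np.asarray(y)
    n0, n1 = int((y == 0).sum()), int((y == 1).sum())
    if n0 == n1:
        return X.copy(), y.copy()
    minority = 1 if n1 < n0 else 0
    need = abs(n0 - n1)
    Xm = X[y == minority]
    if len(Xm) <= 1:
        raise ValueError(
            f"minority class has {len(Xm)} sample(s); SMOTE needs at least 2")
    k = min(k_neighbors, len(Xm) - 1)
    nn = NearestNeighbors(n_neighbors=k + 1).fit(Xm)
    _, idx = nn.kneighbors(Xm)           # column 0 is the point itself
    base = rng.integers(0, len(Xm), size=need)
    pick = rng.integers(1, k + 1, size=need)
    u = rng.uniform(0.0, 1.0, size=need)
    neigh = Xm[idx[base, pick]]
    synth = Xm[base] + u[:, None] * (neigh - Xm[base])
    X_out = np.vstack([X, synth])
    y_out = np.concatenate([y, np.full(need, minority, dtype=y.dtype)])
    return X_out, y_out


def repeated_split_cv(model, X, y, n_splits: int = 10,
                      train_fraction: float = 0.7, smote: bool = False,
                      seed: int = 0, k_neighbors: int = 5) -> CVResult:
    """Repeated stratified random train/test splits with optional SMOTE.

    Stratification keeps both classes in every training part; SMOTE, when
    enabled, is applied to the training part only.  ``model`` is any
    object honouring the sklearn fit/predict contract; it is cloned per
    split (falling back to refitting the same object when not cloneable).
    """
    X = np.asarray(X, dtype=float)
    y = np.asarray(y)
    if not 0.0 < train_fraction < 1.0:
        raise ValueError(f"train_fraction must be in (0,1), got {train_fraction}")
    if len(np.unique(y)) < 2:
        raise ValueError("both classes required in y")
    splitter = StratifiedShuffleSplit(
        n_splits=n_splits, train_size=train_fraction, random_state=seed)
    rng = np.random.default_rng(seed)
    per_split = []
    for split_id, (tr, te) in enumerate(splitter.split(X, y)):
        X_tr, y_tr = X[tr], y[tr]
        if smote:
            X_tr, y_tr = smote_balance(X_tr, y_tr, k_neighbors, rng)
        try:
            mdl = clone(model)
        except TypeError:
            mdl = model
        mdl.fit(X_tr, y_tr)
        y_hat = mdl.predict(X[te])
        cm = confusion(y[te], y_hat)
        per_split.append((split_id, metrics(cm), cm))
    means = {name: float(np.mean([ms.as_dict()[name] for _, ms, _ in per_split]))
             for name in per_split[0][1].as_dict()}
    return CVResult(per_split, MetricSet(**means), n_splits, train_fraction,
                    smote, seed)


def _rank_rows(table: np.ndarray) -> np.ndarray:
    """Per-dataset ranks, best (largest) score = rank 1, ties averaged."""
    from scipy.stats import rankdata
    return np.vstack([rankdata(-row, method="average") for row in table])


def friedman_test(score_table, model_names: list[str] | None = None
                  ) -> RankComparison:
    """Friedman rank test over a datasets × models score table.

    Q = 12N/(k(k+1)) · [Σ R̄ⱼ² − k(k+1)²/4], compared against χ²(k−1);
    F_f = (N−1)Q / (N(k−1) − Q) is the Iman–Davenport refinement.
    """
    table = np.asarray(score_table, dtype=float)
    if table.ndim != 2 or table.shape[0] < 2 or table.shape[1] < 2:
        raise ValueError("score table must be at least 2 datasets x 2 models")
    N, k = table.shape
    if model_names is None:
        model_names = [f"model{j + 1}" for j in range(k)]
    ranks = _rank_rows(table)
    avg = ranks.mean(axis=0)
    Q = 12.0 * N / (k * (k + 1)) * (np.sum(avg ** 2) - k * (k + 1) ** 2 / 4.0)
    Q = float(max(Q, 0.0))
    denom = N * (k - 1) - Q
    F_f = float((N - 1) * Q / denom) if denom > 0 else float("inf")
    from scipy.stats import chi2
    p = float(chi2.sf(Q, k - 1))
    return RankComparison(table, model_names, avg, Q, F_f, p)


def nemenyi_cd(N: int, k: int, alpha: float = 0.05) -> float:
    """Nemenyi critical difference CD = q_α · sqrt(k(k+1)/(6N)).

    ``q_α`` is the α-level studentized-range quantile for k groups and
    infinite degrees of freedom divided by √2 (q(0.05, k=2) = 1.960).
    """
    if k < 2:
        raise ValueError("need at least two models")
    if N < 1:
        raise ValueError("need at least one dataset")
    q = studentized_range.ppf(1.0 - alpha, k, np.inf) / np.sqrt(2.0)
    return float(q * np.sqrt(k * (k + 1) / (6.0 * N)))
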