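"""Complete-separation diagnostics for classical logistic regression.

Complete (or quasi-complete) separation — a predictor combination that
perfectly partitions the two classes — drives maximum-likelihood logistic
estimates toward infinity.  The diagnostic here is the one practitioners
read off the optimiser: refit by iteratively reweighted least squares
(IRLS), record the coefficient vector after every iteration, and flag
predictors whose estimates diverge (grow without convergence) or end up
implausibly large on the standardised scale.

The module also provides the classical-logistic-regression (CLR) baseline
classifier used when benchmarking the fuzzy model.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.special import expit
from sklearn.base import BaseEstimator, ClassifierMixin
from sklearn.utils.validation import check_is_fitted

__all__ = [
    "IRLSTrajectory",
    "SeparationReport",
    "irls_fit",
    "detect_separation",
    "clr_predict",
    "IRLSLogisticRegression",
]


@dataclass
class IRLSTrajectory:
    """Per-iteration IRLS coefficient estimates (intercept first).

    ``estimates`` has shape (n_iter, k+1); ``deviance_path`` holds the
    model deviance after each iteration.  On separable data the deviance
    tends to 0 while coefficients grow without bound.
    """

    estimates: np.ndarray
    converged: bool
    n_iter: int
    deviance_path: list[float] = field(default_factory=list)
    center: np.ndarray | None = None
    scale: np.ndarray | None = None

    @property
    def final(self) -> np.ndarray:
        return self.estimates[-1]


@dataclass
class SeparationReport:
    """Verdict of the divergence screen.

    ``flagged_predictors`` lists (name, final standardised estimate,
    growth_flag) for every predictor tripping either rule; ``growth_flag``
    marks monotone growth across the trailing window without convergence.
    """

    flagged_predictors: list[tuple[str, float, bool]]
    verdict: str
    threshold_used: float

    @property
    def separated(self) -> bool:
        return self.verdict == "separation"


def _deviance(y: np.ndarray, p: np.ndarray) -> float:
    eps = 1e-12
    p = np.clip(p, eps, 1 - eps)
    return float(-2.0 * np.sum(y * np.log(p) + (1 - y) * np.log(1 - p)))


def irls_fit(X, y, max_iter: int = 100, tol: float = 1e-8,
             standardize: bool = True) -> IRLSTrajectory:
    """Fit logistic regression by IRLS, keeping the whole iterate path.

    Never raises on divergence: a non-convergent, growing trajectory is
    exactly the separation signal.  Raises on single-class ``y`` and on a
    rank-deficient design (naming the collinear columns), where the
    trajectory would be meaningless rather than diagnostic.
    """
    X = np.asarray(X, dtype=float)
    y = np.asarray(y, dtype=float)
    if X.ndim != 2:
        raise ValueError("X must be 2-d")
    n, k = X.shape
    if y.shape != (n,):
        raise ValueError(f"y has shape {y.shape}, expected ({n},)")
    n1 = int(y.sum())
    if n1 == 0 or n1 == n:
        raise ValueError(f"both classes required, got counts {{0: {n - n1}, 1: {n1}}}")

    center = X.mean(axis=0) if standardize else np.zeros(k)
    scale = X.std(axis=0, ddof=0) if standardize else np.ones(k)
    scale = np.where(scale == 0, 1.0, scale)
    Xs = (X - center) / scale
    D = np.column_stack([np.ones(n), Xs])

    rank = np.linalg.matrix_rank(D)
    if rank < k + 1:
        # identify columns not adding rank, scanning left to right
        bad = []
        r = 1
        for j in range(1, k + 1):
            rj = np.linalg.matrix_rank(D[:, : j + 1])
            if rj == r:
                bad.append(j - 1)
            r = rj
        raise ValueError(f"design is rank-deficient; collinear predictor "
                         f"column indices: {bad}")

    beta = np.zeros(k + 1)
    estimates, devs = [], []
    converged = False
    for _ in range(max_iter):
        eta = D @ beta
        p = expit(eta)
        w = np.clip(p * (1 - p), 1e-10, None)
        z = eta + (y - p) / w
        sw = np.sqrt(w)
        # weighted least squares step; lstsq tolerates near-singular weights
        beta_new, *_ = np.linalg.lstsq(D * sw[:, None], z * sw, rcond=None)
        step = np.max(np.abs(beta_new - beta))
        beta = beta_new
        estimates.append(beta.copy())
        devs.append(_deviance(y, expit(D @ beta)))
        if step < tol:
            converged = True
            break
    return IRLSTrajectory(np.asarray(estimates), converged, len(estimates),
                          devs, center, scale)


def detect_separation(traj: IRLSTrajectory, threshold: float = 10.0,
                      names: list[str] | None = None,
                      growth_window: int = 5) -> SeparationReport:
    """Flag predictors whose ML estimates diverge.

    Predictor j is flagged if its final standardised |estimate| exceeds
    ``threshold``, or if |estimate| grew strictly in each of the last
    ``growth_window`` iterations while IRLS failed to converge.
    """
    est = traj.estimates
    if est.size == 0:
        raise ValueError("empty trajectory")
    k = est.shape[1] - 1
    if names is None:
        names = [f"x{j + 1}" for j in range(k)]
    flagged = []
    for j in range(1, k + 1):
        path = np.abs(est[:, j])
        large = path[-1] > threshold
        growth = False
        if not traj.converged and len(path) > growth_window:
            tail = path[-(growth_window + 1):]
            growth = bool(np.all(np.diff(tail) > 0))
        if large or growth:
            flagged.append((names[j - 1], float(est[-1, j]), growth))
    verdict = "separation" if flagged else "no_separation"
    return SeparationReport(flagged, verdict, threshold)


def clr_predict(traj: IRLSTrajectory, X, cutoff: float = 0.5) -> np.ndarray:
    """Classify with the (last-iterate) CLR coefficients: 1 iff p ≥ cutoff."""
    X = np.asarray(X, dtype=float)
    beta = traj.final
    if X.shape[1] != beta.size - 1:
        raise ValueError(
            f"X has {X.shape[1]} columns, trajectory expects {beta.size - 1}")
    Xs = (X - traj.center) / traj.scale if traj.center is not None else X
    p = expit(beta[0] + Xs @ beta[1:])
    return (p >= cutoff).astype(int)


class IRLSLogisticRegression(ClassifierMixin, BaseEstimator):
    """Classical logistic regression via IRLS, exposing the iterate path.

    The scikit-learn face of :func:`irls_fit` / :func:`clr_predict`: the
    benchmark CLR classifier, with the coefficient trajectory and a
    separation report available as fitted attributes.

    Parameters
    ----------
    max_iter, tol : IRLS stopping rule (max |Δβ| < tol).
    cutoff : probability cutoff for the crisp label (``p ≥ cutoff`` → 1).
    divergence_threshold : standardised |β| above which a predictor is
        flagged as separating.

    Attributes
    ----------
    trajectory_ : IRLSTrajectory
    report_ : SeparationReport
    coef_, intercept_ : final standardised-scale estimates
    """

    def __init__(self, max_iter: int = 100, tol: float = 1e-8,
                 cutoff: float = 0.5, divergence_threshold: float = 10.0,
                 growth_window: int = 5):
        self.max_iter = max_iter
        self.tol = tol
        self.cutoff = cutoff
        self.divergence_threshold = divergence_threshold
        self.growth_window = growth_window

    def fit(self, X, y):
        X = np.asarray(X, dtype=float)
        y = np.asarray(y)
        self.trajectory_ = irls_fit(X, y, self.max_iter, self.tol)
        self.report_ = detect_separation(
            self.trajectory_, self.divergence_threshold,
            growth_window=self.growth_window)
        self.intercept_ = float(self.trajectory_.final[0])
        self.coef_ = self.trajectory_.final[1:].copy()
        self.classes_ = np.array([0, 1])
        self.n_features_in_ = X.shape[1]
        return self

    def predict_proba(self, X) -> np.ndarray:
        check_is_fitted(self, "trajectory_")
        X = np.asarray(X, dtype=float)
        t = self.trajectory_
        Xs = (X - t.center) / t.scale
        p = expit(t.final[0] + Xs @ t.final[1:])
        return np.column_stack([1 - p, p])

    def predict(self, X) -> np.ndarray:
        p = self.predict_proba(X)[:, 1]
        return (p >= self.cutoff).astype(int)
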