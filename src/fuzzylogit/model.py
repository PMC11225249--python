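"""Fuzzy logistic regression (FLR) with triangular-fuzzy coefficients.

The model is the fuzzy analogue of the logistic regression

    log( P̄ / (1 − P̄) ) = β̄₀ ⊕ β̄₁⊗X̄₁ ⊕ … ⊕ β̄ₖ⊗X̄ₖ,

where coefficients, predictors and the success probability P̄ are all
triangular fuzzy numbers.  Estimation is a bounded random search: candidate
coefficient vectors are drawn as sorted uniform triples mapped into a fixed
range Ī_β, each candidate is scored by MAE / MSE / RMSE between predicted
and observed response TFNs, the error measure whose best-per-repetition
value varies least (smallest coefficient of variation across repetitions)
is selected, and the candidate minimising that measure is kept.

Classification compares the fuzzy probability against a fuzzy threshold τ̄:
the crisp label is ``1`` iff the expected value E(P̄) reaches the threshold
vertex, and the prediction TFN spreads the label by the half-width of
P̄ ⊖ τ̄.  Because the coefficient search is confined to a bounded range, the
fit cannot chase the divergent maximum-likelihood solutions that complete
separation induces, and the fuzzy threshold comparison resists the
majority-class collapse seen under heavy class imbalance.
"""

from __future__ import annotations

import json
from dataclasses import dataclass

import numpy as np
from scipy.special import expit
from sklearn.base import BaseEstimator, ClassifierMixin
from sklearn.utils.validation import check_is_fitted

from .fuzzify import FuzzificationConfig, FuzzyDataset, fuzzify_dataset
from .tfn import TFN, defuzzify_cog, expected_value, subtract

__all__ = [
    "CoefficientSearchConfig",
    "FuzzyThreshold",
    "FuzzyPrediction",
    "FLRFit",
    "FuzzyLogisticRegression",
    "linear_predictor",
    "fuzzy_probability",
    "generate_candidate",
    "classify",
    "fit",
    "predict",
    "defuzzify_coefficients",
]


@dataclass(frozen=True)
class CoefficientSearchConfig:
    """Bounded random-search hyperparameters.

    ``I_minus``/``I_plus`` bound the coefficient range Ī_β; each of the
    ``n_repetitions`` repetitions draws ``n_candidates`` fresh candidate
    vectors.
    """

    I_minus: float = -2.0
    I_plus: float = 2.0
    n_candidates: int = 500
    n_repetitions: int = 20
    seed: int = 0

    def __post_init__(self) -> None:
        if not self.I_minus < self.I_plus:
            raise ValueError(
                f"need I_minus < I_plus, got ({self.I_minus}, {self.I_plus})"
            )
        if self.n_candidates < 1 or self.n_repetitions < 1:
            raise ValueError("n_candidates and n_repetitions must be >= 1")


@dataclass(frozen=True)
class FuzzyThreshold:
    """Fuzzy classification threshold τ̄ = (t1, t2, t3) on [0, 1]."""

    t1: float = 0.4
    t2: float = 0.5
    t3: float = 0.6

    def __post_init__(self) -> None:
        if not (0.0 <= self.t1 <= self.t2 <= self.t3 <= 1.0):
            raise ValueError(
                f"threshold must satisfy 0 <= t1 <= t2 <= t3 <= 1, "
                f"got ({self.t1}, {self.t2}, {self.t3})"
            )

    def as_tfn(self) -> TFN:
        return TFN(self.t1, self.t2, self.t3)


@dataclass(frozen=True)
class FuzzyPrediction:
    """One observation's fuzzy prediction.

    Attributes
    ----------
    p_fuzzy : TFN
        Fuzzy success probability P̄.
    p_expected : float
        Its expected value E(P̄) = (p1 + 2 p2 + p3)/4.
    d_fuzzy : TFN
        The fuzzy difference 𝔻 = P̄ ⊖ τ̄.
    d_width : float
        Spread w(𝔻) used for the prediction TFN (half of 𝔻's support).
    y_hat : TFN
        Prediction TFN (ŷ₂ − w(𝔻), ŷ₂, ŷ₂ + w(𝔻)).
    label : int
        Crisp class, ``1`` iff E(P̄) ≥ t2.
    """

    p_fuzzy: TFN
    p_expected: float
    d_fuzzy: TFN
    d_width: float
    y_hat: TFN
    label: int


@dataclass
class FLRFit:
    """Result of the coefficient search (one TFN per coefficient)."""

    coefficients: list[TFN]
    chosen_measure: str
    measure_variations: dict[str, float]
    best_error: float
    search_log: np.ndarray  # columns: candidate id, MAE, MSE, RMSE
    config: CoefficientSearchConfig

    @property
    def k(self) -> int:
        return len(self.coefficients) - 1

    def to_dict(self) -> dict:
        return {
            "coefficients": [c.to_dict() for c in self.coefficients],
            "chosen_measure": self.chosen_measure,
            "measure_variations": self.measure_variations,
            "best_error": self.best_error,
            "config": {
                "I_minus": self.config.I_minus,
                "I_plus": self.config.I_plus,
                "n_candidates": self.config.n_candidates,
                "n_repetitions": self.config.n_repetitions,
                "seed": self.config.seed,
            },
        }


# ---------------------------------------------------------------------------
# vectorised TFN kernels (last axis = the (a1, a2, a3) triple)

def _mul3(a: np.ndarray, b: np.ndarray) -> np.ndarray:
    """Broadcasted TFN product: exact vertex, α=0 support from corner products."""
    corners = np.stack(
        [a[..., 0] * b[..., 0], a[..., 0] * b[..., 2],
         a[..., 2] * b[..., 0], a[..., 2] * b[..., 2]], axis=-1)
    lo = corners.min(axis=-1)
    hi = corners.max(axis=-1)
    v = np.clip(a[..., 1] * b[..., 1], lo, hi)
    return np.stack([lo, v, hi], axis=-1)


def _eta(coef: np.ndarray, X: np.ndarray) -> np.ndarray:
    """Linear predictor TFNs for candidate stacks.

    coef : (..., k+1, 3), X : (n, k, 3)  →  (..., n, 3)
    """
    prod = _mul3(coef[..., None, 1:, :], X)       # (..., n, k, 3)
    return coef[..., None, 0, :] + prod.sum(axis=-2)


def linear_predictor(coefficients, row) -> TFN:
    """η̄ = β̄₀ ⊕ Σⱼ β̄ⱼ ⊗ X̄ⱼ for one observation."""
    coefficients = [c if isinstance(c, TFN) else TFN(*c) for c in coefficients]
    row = [x if isinstance(x, TFN) else TFN(*x) for x in row]
    if len(coefficients) != len(row) + 1:
        raise ValueError(
            f"got {len(coefficients)} coefficients for {len(row)} predictors; "
            f"expected k+1"
        )
    coef = np.stack([c.as_array() for c in coefficients])
    X = np.stack([x.as_array() for x in row])[None, :, :]
    out = _eta(coef[None, :, :], X)[0, 0]
    return TFN(*out)


def fuzzy_probability(eta) -> TFN:
    """Map a linear-predictor TFN through the logistic σ pointwise.

    σ is strictly increasing, so the triple stays ordered and the result is
    a valid probability TFN with support in (0, 1).
    """
    eta = eta if isinstance(eta, TFN) else TFN(*eta)
    return TFN(*(expit(eta.as_array())))


def generate_candidate(cfg: CoefficientSearchConfig, k: int,
                       rng: np.random.Generator) -> list[TFN]:
    """Draw one coefficient-vector candidate: k+1 TFNs inside [I⁻, I⁺].

    3(k+1) uniforms on [0,1] are grouped into consecutive triples, each
    triple sorted, then mapped affinely onto the search range.
    """
    if k < 1:
        raise ValueError("need at least one predictor")
    raw = rng.uniform(0.0, 1.0, size=(k + 1, 3))
    raw.sort(axis=1)
    mapped = cfg.I_minus + raw * (cfg.I_plus - cfg.I_minus)
    return [TFN(*t) for t in mapped]


def _search(data: FuzzyDataset, cfg: CoefficientSearchConfig) -> FLRFit:
    k = data.n_predictors
    rng = np.random.default_rng(cfg.seed)
    R, C = cfg.n_repetitions, cfg.n_candidates
    raw = rng.uniform(0.0, 1.0, size=(R * C, k + 1, 3))
    raw.sort(axis=-1)
    coefs = cfg.I_minus + raw * (cfg.I_plus - cfg.I_minus)

    eta = _eta(coefs, data.X_fuzzy)               # (R*C, n, 3)
    p = expit(eta)
    diff = p - data.Y_fuzzy[None, :, :]
    mae = np.abs(diff).mean(axis=(1, 2))
    mse = (diff * diff).mean(axis=(1, 2))
    rmse = np.sqrt(mse)

    measures = {"MAE": mae, "MSE": mse, "RMSE": rmse}
    best_per_rep = {m: v.reshape(R, C).min(axis=1) for m, v in measures.items()}
    variations = {}
    for m, bests in best_per_rep.items():
        mu = bests.mean()
        variations[m] = float(bests.std(ddof=1) / mu) if R > 1 and mu > 0 else 0.0
    chosen = min(variations, key=lambda m: (variations[m], m))
    idx = int(np.argmin(measures[chosen]))       # ties -> lowest candidate id
    best = [TFN(*t) for t in coefs[idx]]
    log = np.column_stack([np.arange(R * C), mae, mse, rmse])
    return FLRFit(best, chosen, variations, float(measures[chosen][idx]),
                  log, cfg)


def fit(data: FuzzyDataset, cfg: CoefficientSearchConfig | None = None) -> FLRFit:
    """Run the bounded random search on a fuzzified dataset."""
    cfg = cfg or CoefficientSearchConfig()
    counts = {c: int((data.y_crisp == c).sum()) for c in (0, 1)}
    if counts[0] == 0 or counts[1] == 0:
        raise ValueError(f"both classes required, got class counts {counts}")
    return _search(data, cfg)


def classify(p_fuzzy, tau: FuzzyThreshold) -> FuzzyPrediction:
    """Turn one fuzzy probability into a fuzzy prediction and crisp label.

    Label is 0 iff E(P̄) < t2 ('otherwise 1', so equality classifies as 1).
    The prediction TFN is centred on the label with spread
    w(𝔻) = (d3 − d1)/2 where 𝔻 = P̄ ⊖ τ̄.
    """
    p_fuzzy = p_fuzzy if isinstance(p_fuzzy, TFN) else TFN(*p_fuzzy)
    e = expected_value(p_fuzzy)
    label = 0 if e < tau.t2 else 1
    d = subtract(p_fuzzy, tau.as_tfn())
    w = (d.a3 - d.a1) / 2.0
    y_hat = TFN(label - w, float(label), label + w)
    return FuzzyPrediction(p_fuzzy, e, d, w, y_hat, label)


def predict(flr_fit: FLRFit, data: FuzzyDataset,
            tau: FuzzyThreshold | None = None) -> list[FuzzyPrediction]:
    """Fuzzy predictions for every row of a fuzzified dataset."""
    tau = tau or FuzzyThreshold()
    if flr_fit.k != data.n_predictors:
        raise ValueError(
            f"fit has k={flr_fit.k} predictors, data has {data.n_predictors}"
        )
    coef = np.stack([c.as_array() for c in flr_fit.coefficients])
    p = expit(_eta(coef[None, :, :], data.X_fuzzy)[0])
    return [classify(TFN(*row), tau) for row in p]


def defuzzify_coefficients(flr_fit: FLRFit,
                           names: list[str] | None = None
                           ) -> list[tuple[str, float, float]]:
    """Crisp coefficient table: (name, centre-of-gravity β, odds ratio e^β)."""
    coefs = flr_fit.coefficients
    if names is None:
        names = ["intercept"] + [f"x{j}" for j in range(1, len(coefs))]
    out = []
    for name, c in zip(names, coefs):
        beta = defuzzify_cog(c)
        out.append((name, beta, float(np.exp(beta))))
    return out


class FuzzyLogisticRegression(ClassifierMixin, BaseEstimator):
    """Fuzzy logistic regression classifier (scikit-learn interface).

    Crisp inputs are standardised and fuzzified internally; coefficients
    are TFNs estimated by bounded random search; crisp 0/1 labels come from
    comparing E(P̄) against the fuzzy threshold vertex.

    Parameters
    ----------
    m : float, default 1.0
        Degree of fuzziness injected into responses and predictors.
    r, ell : float, default 1.0
        Right/left spread factors of response fuzzification.
    I_L, I_U : float, default (0.001, 0.1)
        Uniform spread-draw limits.
    predictor_mode : {'symmetric', 'degenerate'}, default 'symmetric'
        Fuzzify predictors symmetrically or keep them crisp.
    coef_range : (float, float), default (-2.0, 2.0)
        Bounds Ī_β of the coefficient search on the standardised scale.
    n_candidates, n_repetitions : int, default (500, 20)
        Candidates per repetition and number of repetitions of the search.
    threshold : (float, float, float), default (0.4, 0.5, 0.6)
        Fuzzy classification threshold τ̄.
    random_state : int, default 0
        Master seed; fuzzification and search streams derive from it.

    Attributes
    ----------
    coefficients_ : list of TFN
        Selected TFN coefficients (intercept first).
    chosen_measure_ : str
        Error measure with the lowest variation (MAE, MSE or RMSE).
    measure_variations_ : dict
        Coefficient of variation of each measure's per-repetition best.
    best_error_ : float
        Value of the chosen measure at the selected candidate.
    center_, scale_ : ndarray
        Standardisation statistics learned on the training predictors.

    Examples
    --------
    >>> from fuzzylogit.datasets import preset_dataset_I, generate
    >>> X, y = generate(preset_dataset_I())
    >>> clf = FuzzyLogisticRegression(random_state=7).fit(X, y)
    >>> clf.predict(X[:3]).tolist()  # doctest: +SKIP
    [0, 0, 1]
    """

    def __init__(self, m: float = 1.0, r: float = 1.0, ell: float = 1.0,
                 I_L: float = 0.001, I_U: float = 0.1,
                 predictor_mode: str = "symmetric",
                 coef_range: tuple[float, float] = (-2.0, 2.0),
                 n_candidates: int = 500, n_repetitions: int = 20,
                 threshold: tuple[float, float, float] = (0.4, 0.5, 0.6),
                 random_state: int = 0):
        self.m = m
        self.r = r
        self.ell = ell
        self.I_L = I_L
        self.I_U = I_U
        self.predictor_mode = predictor_mode
        self.coef_range = coef_range
        self.n_candidates = n_candidates
        self.n_repetitions = n_repetitions
        self.threshold = threshold
        self.random_state = random_state

    # seeds for the independent random streams derived from the master seed
    _FUZZ_TRAIN, _FUZZ_PREDICT, _SEARCH = 11, 13, 17

    def _fuzz_cfg(self, seed: int) -> FuzzificationConfig:
        return FuzzificationConfig(
            m=self.m, r=self.r, ell=self.ell, I_L=self.I_L, I_U=self.I_U,
            predictor_mode=self.predictor_mode, seed=seed)

    def _derived_seed(self, salt: int) -> int:
        return int(np.random.SeedSequence(
            [int(self.random_state), salt]).generate_state(1)[0] % (2 ** 31))

    def fit(self, X, y):
        X = np.asarray(X, dtype=float)
        y = np.asarray(y)
        data = fuzzify_dataset(X, y, self._fuzz_cfg(self._derived_seed(self._FUZZ_TRAIN)))
        self.center_ = X.mean(axis=0)
        scale = X.std(axis=0, ddof=0)
        self.scale_ = np.where(scale == 0, 1.0, scale)
        cfg = CoefficientSearchConfig(
            I_minus=self.coef_range[0], I_plus=self.coef_range[1],
            n_candidates=self.n_candidates, n_repetitions=self.n_repetitions,
            seed=self._derived_seed(self._SEARCH))
        fit_ = _search(data, cfg)
        self.fit_ = fit_
        self.coefficients_ = fit_.coefficients
        self.chosen_measure_ = fit_.chosen_measure
        self.measure_variations_ = fit_.measure_variations
        self.best_error_ = fit_.best_error
        self.classes_ = np.array([0, 1])
        self.n_features_in_ = X.shape[1]
        return self

    def _fuzzify_new(self, X) -> np.ndarray:
        """Fuzzified predictor array for new data, on the training scale."""
        check_is_fitted(self, "coefficients_")
        X = np.asarray(X, dtype=float)
        if X.ndim != 2 or X.shape[1] != self.n_features_in_:
            raise ValueError(
                f"X has shape {X.shape}; expected (n, {self.n_features_in_})")
        Xs = (X - self.center_) / self.scale_
        cfg = self._fuzz_cfg(self._derived_seed(self._FUZZ_PREDICT))
        rng = np.random.default_rng(cfg.seed)
        if cfg.predictor_mode == "degenerate" or cfg.m == 0:
            spread = np.zeros_like(Xs)
        else:
            spread = cfg.m * rng.uniform(cfg.I_L, cfg.I_U, size=Xs.shape)
        return np.stack([Xs - spread, Xs, Xs + spread], axis=-1)

    def predict_fuzzy(self, X) -> list[FuzzyPrediction]:
        """Full fuzzy predictions (P̄, E(P̄), 𝔻, ŷ TFN, crisp label)."""
        Xf = self._fuzzify_new(X)
        coef = np.stack([c.as_array() for c in self.coefficients_])
        tau = FuzzyThreshold(*self.threshold)
        p = expit(_eta(coef[None, :, :], Xf)[0])
        return [classify(TFN(*row), tau) for row in p]

    def predict_proba(self, X) -> np.ndarray:
        """Expected fuzzy probabilities E(P̄) as sklearn-style (n, 2) array."""
        Xf = self._fuzzify_new(X)
        coef = np.stack([c.as_array() for c in self.coefficients_])
        p = expit(_eta(coef[None, :, :], Xf)[0])
        e = (p[:, 0] + 2.0 * p[:, 1] + p[:, 2]) / 4.0
        return np.column_stack([1.0 - e, e])

    def predict(self, X) -> np.ndarray:
        e = self.predict_proba(X)[:, 1]
        return (e >= self.threshold[1]).astype(int)

    def defuzzified_coefficients(self, names: list[str] | None = None):
        """Crisp (centre-of-gravity) coefficients and odds ratios."""
        check_is_fitted(self, "coefficients_")
        return defuzzify_coefficients(self.fit_, names)

    def to_json(self, indent: int | None = 2) -> str:
        """Serialise the fitted model (coefficients, measure, config, seed)."""
        check_is_fitted(self, "coefficients_")
        doc = self.fit_.to_dict()
        doc["params"] = self.get_params()
        doc["center"] = self.center_.tolist()
        doc["scale"] = self.scale_.tolist()
        return json.dumps(doc, indent=indent, sort_keys=True)
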