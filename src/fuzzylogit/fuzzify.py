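"""Fuzzification of crisp binary responses and numeric predictors.

Binary responses ``y ∈ {0, 1}`` are mapped to TFNs by

    F(y) = (y − m·ℓ·u,  y,  y + m·r·u),    u ~ Uniform(I_L, I_U),

so the vertex is always the observed label and the spread is controlled by
the degree of fuzziness ``m`` and the left/right symmetry factors ``ℓ`` and
``r``.  With the default limits ``(I_L, I_U) = (0.001, 0.1)`` the fuzzified
response stays inside [−1, 1].

Predictors are standardised to zero mean / unit variance and then either
kept crisp (``predictor_mode='degenerate'``) or given a symmetric spread
``m·u`` per value (``'symmetric'``).  One independent uniform draw is used
per fuzzified value.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np

from .tfn import TFN

__all__ = ["FuzzificationConfig", "FuzzyDataset", "fuzzify_response",
           "fuzzify_predictor", "fuzzify_dataset"]


@dataclass(frozen=True)
class FuzzificationConfig:
    """Hyperparameters of the crisp→fuzzy mapping.

    Attributes
    ----------
    m : float
        Degree of fuzziness; ``m=0`` reproduces crisp data exactly.
    r, ell : float
        Right and left spread factors of the response TFN (``r=ell``
        gives symmetric fuzzification).
    I_L, I_U : float
        Limits of the uniform spread draw, ``I_L < I_U``.
    predictor_mode : {'symmetric', 'degenerate'}
        Whether predictors receive a symmetric spread or stay crisp.
    clamp_response : bool
        If True, clip the response TFN support to [−1, 1].
    standardize : bool
        Standardise predictor columns before fuzzification.
    seed : int
        Seed of the fuzzification random stream.
    """

    m: float = 1.0
    r: float = 1.0
    ell: float = 1.0
    I_L: float = 0.001
    I_U: float = 0.1
    predictor_mode: str = "symmetric"
    clamp_response: bool = False
    standardize: bool = True
    seed: int = 0

    def __post_init__(self) -> None:
        if self.m < 0 or self.r < 0 or self.ell < 0:
            raise ValueError("m, r and ell must be nonnegative")
        if not self.I_L < self.I_U:
            raise ValueError(f"need I_L < I_U, got ({self.I_L}, {self.I_U})")
        if self.predictor_mode not in ("symmetric", "degenerate"):
            raise ValueError(
                f"predictor_mode must be 'symmetric' or 'degenerate', "
                f"got {self.predictor_mode!r}"
            )

    def with_seed(self, seed: int) -> "FuzzificationConfig":
        return replace(self, seed=seed)


@dataclass
class FuzzyDataset:
    """A fuzzified design: TFN predictors, TFN responses, crisp labels.

    ``X_fuzzy`` has shape (n, k, 3) and ``Y_fuzzy`` shape (n, 3); the last
    axis holds the (a1, a2, a3) triple.  Vertex slices reproduce the
    standardised crisp inputs and the 0/1 labels exactly.
    """

    X_fuzzy: np.ndarray
    Y_fuzzy: np.ndarray
    y_crisp: np.ndarray
    column_names: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.X_fuzzy = np.asarray(self.X_fuzzy, dtype=float)
        self.Y_fuzzy = np.asarray(self.Y_fuzzy, dtype=float)
        self.y_crisp = np.asarray(self.y_crisp)
        n, k = self.n_obs, self.n_predictors
        if n == 0 or k == 0:
            raise ValueError("FuzzyDataset needs at least one row and one column")
        if self.Y_fuzzy.shape != (n, 3):
            raise ValueError("Y_fuzzy must have shape (n, 3)")
        if not np.array_equal(self.Y_fuzzy[:, 1], self.y_crisp.astype(float)):
            raise ValueError("response TFN vertices must equal the crisp labels")
        for arr in (self.X_fuzzy, self.Y_fuzzy):
            flat = arr.reshape(-1, 3)
            if np.any(flat[:, 0] > flat[:, 1]) or np.any(flat[:, 1] > flat[:, 2]):
                raise ValueError("TFN ordering a1 <= a2 <= a3 violated")
        if not self.column_names:
            self.column_names = [f"x{j + 1}" for j in range(k)]

    @property
    def n_obs(self) -> int:
        return self.X_fuzzy.shape[0]

    @property
    def n_predictors(self) -> int:
        return self.X_fuzzy.shape[1]

    def row(self, i: int) -> list[TFN]:
        return [TFN(*self.X_fuzzy[i, j]) for j in range(self.n_predictors)]


def fuzzify_response(y: int, cfg: FuzzificationConfig,
                     rng: np.random.Generator) -> TFN:
    """Fuzzify one binary label via ``F(y) = (y − m·ℓ·u, y, y + m·r·u)``."""
    if y not in (0, 1):
        raise ValueError(f"response must be 0 or 1, got {y!r}")
    u = rng.uniform(cfg.I_L, cfg.I_U)
    lo, hi = y - cfg.m * cfg.ell * u, y + cfg.m * cfg.r * u
    if cfg.clamp_response:
        lo, hi = max(lo, -1.0), min(hi, 1.0)
    return TFN(lo, float(y), hi)


def fuzzify_predictor(x: float, column_scale: float, cfg: FuzzificationConfig,
                      rng: np.random.Generator) -> TFN:
    """Fuzzify one predictor value with spread ``m · column_scale · u``."""
    if column_scale <= 0:
        raise ValueError(f"column_scale must be positive, got {column_scale}")
    if cfg.predictor_mode == "degenerate" or cfg.m == 0:
        return TFN(x, x, x)
    u = rng.uniform(cfg.I_L, cfg.I_U)
    s = cfg.m * column_scale * u
    return TFN(x - s, x, x + s)


def fuzzify_dataset(X, y, cfg: FuzzificationConfig | None = None,
                    column_names: list[str] | None = None,
                    center=None, scale=None) -> FuzzyDataset:
    """Fuzzify a crisp design matrix and 0/1 response vector.

    Predictors are standardised column-wise (unless ``cfg.standardize`` is
    False); ``center``/``scale`` override the fitted statistics so test data
    can reuse a training standardisation.  Deterministic given ``cfg.seed``.
    """
    cfg = cfg or FuzzificationConfig()
    X = np.asarray(X, dtype=float)
    y = np.asarray(y)
    if X.ndim != 2:
        raise ValueError("X must be a 2-d matrix")
    n, k = X.shape
    if y.shape != (n,):
        raise ValueError(f"y has shape {y.shape}, expected ({n},)")
    bad = np.argwhere(~np.isfinite(X))
    if bad.size:
        i, j = bad[0]
        raise ValueError(f"missing/non-finite value in X at row {i}, column {j}")
    labels = np.unique(y)
    if not np.all(np.isin(labels, (0, 1))):
        raise ValueError(f"response must be binary 0/1, found values {labels}")
    counts = {int(c): int((y == c).sum()) for c in (0, 1)}
    if counts[0] == 0 or counts[1] == 0:
        raise ValueError(f"both classes required, got class counts {counts}")

    if cfg.standardize:
        center = X.mean(axis=0) if center is None else np.asarray(center, float)
        if scale is None:
            scale = X.std(axis=0, ddof=0)
        scale = np.where(np.asarray(scale, float) == 0, 1.0, scale)
        Xs = (X - center) / scale
    else:
        Xs = X

    rng = np.random.default_rng(cfg.seed)
    if cfg.predictor_mode == "degenerate" or cfg.m == 0:
        spread_x = np.zeros((n, k))
    else:
        # unit column scale: predictors are already standardised
        spread_x = cfg.m * 1.0 * rng.uniform(cfg.I_L, cfg.I_U, size=(n, k))
    X_fuzzy = np.stack([Xs - spread_x, Xs, Xs + spread_x], axis=-1)

    u_y = rng.uniform(cfg.I_L, cfg.I_U, size=n)
    yf = y.astype(float)
    lo = yf - cfg.m * cfg.ell * u_y
    hi = yf + cfg.m * cfg.r * u_y
    if cfg.clamp_response:
        lo, hi = np.maximum(lo, -1.0), np.minimum(hi, 1.0)
    Y_fuzzy = np.stack([lo, yf, hi], axis=-1)

    names = list(column_names) if column_names else None
    return FuzzyDataset(X_fuzzy, Y_fuzzy, y.astype(int), names or [])
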