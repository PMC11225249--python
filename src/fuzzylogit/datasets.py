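"""Synthetic two-predictor clinical-style datasets with controlled
imbalance and controlled complete separation.

The generator draws class-conditional normals for two predictors:

* ``X1`` — a strong, non-separating predictor: large relative mean gap
  between classes but *more* spread in the minority class
  (Var(X1|1) = 1.6·Var(X1|0)), so the classes overlap.
* ``X2`` — an age-like, all-positive, separating predictor: the minority
  class is markedly more homogeneous (Var(X2|1) = 0.3·Var(X2|0)) with a
  much larger mean (E(X2|1) = 2.33·E(X2|0)), so its class supports barely
  overlap and maximum-likelihood logistic estimates diverge.

Two presets mirror the motivating design: Dataset I (n=100, 85% class 0,
the training sample) and Dataset II (n=50, 80% class 0, weaker separation,
the "new data" sample).  Class counts are allocated deterministically from
the imbalance proportion; rows are then shuffled under the seed.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np

__all__ = ["TwoClassSpec", "preset_dataset_I", "preset_dataset_II", "generate"]


@dataclass(frozen=True)
class TwoClassSpec:
    """Generating parameters of a two-predictor binary dataset.

    ``var_ratio_xj`` is Var(Xj|Y=1) / Var(Xj|Y=0); ``truncate_x2_at_zero``
    redraws negative X2 values so the separating predictor stays positive.
    """

    n: int = 100
    prop_y0: float = 0.85
    mean_x1_y0: float = 8.7
    mean_x1_y1: float = -1.5
    mean_x2_y0: float = 32.9
    mean_x2_y1: float = 76.6
    var_x1_y0: float = 9.0
    var_x2_y0: float = 100.0
    var_ratio_x1: float = 1.6
    var_ratio_x2: float = 0.3
    truncate_x2_at_zero: bool = True
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n < 4:
            raise ValueError("n must be at least 4")
        if not 0.0 < self.prop_y0 < 1.0:
            raise ValueError("prop_y0 must lie in (0, 1)")
        if min(self.var_x1_y0, self.var_x2_y0,
               self.var_ratio_x1, self.var_ratio_x2) <= 0:
            raise ValueError("variances and variance ratios must be positive")
        n0 = round(self.n * self.prop_y0)
        if n0 < 2 or self.n - n0 < 2:
            raise ValueError(
                f"each class needs at least 2 rows; got counts "
                f"({n0}, {self.n - n0})")

    def with_seed(self, seed: int) -> "TwoClassSpec":
        return replace(self, seed=seed)


def preset_dataset_I() -> TwoClassSpec:
    """Training-sample design: n=100, 85% class 0, strong separation in X2."""
    return TwoClassSpec(n=100, prop_y0=0.85,
                        mean_x1_y0=8.7, mean_x1_y1=-1.5,
                        mean_x2_y0=32.9, mean_x2_y1=76.6)


def preset_dataset_II() -> TwoClassSpec:
    """New-data design: n=50, 80% class 0, slightly weaker separation."""
    return TwoClassSpec(n=50, prop_y0=0.80,
                        mean_x1_y0=9.6, mean_x1_y1=0.1,
                        mean_x2_y0=35.9, mean_x2_y1=65.6)


def _truncated_normal(rng, mean, sd, size) -> np.ndarray:
    """Normal draws redrawn until positive (keeps the age-like predictor > 0)."""
    out = rng.normal(mean, sd, size)
    for _ in range(1000):
        neg = out <= 0
        if not neg.any():
            return out
        out[neg] = rng.normal(mean, sd, int(neg.sum()))
    raise RuntimeError("could not draw positive X2 values; check the spec means")


def generate(spec: TwoClassSpec) -> tuple[np.ndarray, np.ndarray]:
    """Draw (X, y) under the spec; deterministic given ``spec.seed``.

    Exactly ``round(n·prop_y0)`` rows carry label 0.  Conditional on the
    label, X1 and X2 are independent normals with the spec's means and
    variances (Var(Xj|1) = var_ratio_xj · Var(Xj|0)).
    """
    rng = np.random.default_rng(spec.seed)
    n0 = round(spec.n * spec.prop_y0)
    n1 = spec.n - n0
    sd_x1 = (np.sqrt(spec.var_x1_y0),
             np.sqrt(spec.var_x1_y0 * spec.var_ratio_x1))
    sd_x2 = (np.sqrt(spec.var_x2_y0),
             np.sqrt(spec.var_x2_y0 * spec.var_ratio_x2))
    x1 = np.concatenate([rng.normal(spec.mean_x1_y0, sd_x1[0], n0),
                         rng.normal(spec.mean_x1_y1, sd_x1[1], n1)])
    if spec.truncate_x2_at_zero:
        x2 = np.concatenate([
            _truncated_normal(rng, spec.mean_x2_y0, sd_x2[0], n0),
            _truncated_normal(rng, spec.mean_x2_y1, sd_x2[1], n1)])
    else:
        x2 = np.concatenate([rng.normal(spec.mean_x2_y0, sd_x2[0], n0),
                             rng.normal(spec.mean_x2_y1, sd_x2[1], n1)])
    y = np.concatenate([np.zeros(n0, dtype=int), np.ones(n1, dtype=int)])
    order = rng.permutation(spec.n)
    return np.column_stack([x1, x2])[order], y[order]
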