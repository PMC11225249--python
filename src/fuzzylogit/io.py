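"""Dataset readers/writers and run configuration."""

from __future__ import annotations

import hashlib
import json
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .fuzzify import FuzzificationConfig
from .model import CoefficientSearchConfig, FuzzyThreshold

__all__ = ["RunConfig", "read_dataset", "write_dataset", "write_predictions",
           "read_config"]


@dataclass
class RunConfig:
    """Bundle of all tunables for a pipeline run.

    One master ``seed`` deterministically derives the seeds of every
    module's random stream, so a run is reproducible from the config alone.
    """

    fuzzification: FuzzificationConfig = field(default_factory=FuzzificationConfig)
    search: CoefficientSearchConfig = field(default_factory=CoefficientSearchConfig)
    threshold: FuzzyThreshold = field(default_factory=FuzzyThreshold)
    n_splits: int = 10
    train_fraction: float = 0.7
    smote: bool = False
    sep_max_iter: int = 100
    sep_tol: float = 1e-8
    sep_threshold: float = 10.0
    seed: int = 0
    log_level: str = "INFO"

    def derived_seed(self, salt: int) -> int:
        return int(np.random.SeedSequence(
            [int(self.seed), salt]).generate_state(1)[0] % (2 ** 31))

    def to_dict(self) -> dict:
        return asdict(self)

    def config_hash(self) -> str:
        blob = json.dumps(self.to_dict(), sort_keys=True).encode()
        return hashlib.sha256(blob).hexdigest()[:16]


_FLAT_KEYS = {
    "m", "r", "ell", "I_L", "I_U", "predictor_mode",  # fuzzification
    "I_minus", "I_plus", "n_candidates", "n_repetitions",  # search
    "t1", "t2", "t3",  # threshold
    "n_splits", "train_fraction", "smote",
    "sep_max_iter", "sep_tol", "sep_threshold", "seed", "log_level",
}


def read_config(path: str | Path) -> RunConfig:
    """Load a flat YAML key-value config file into a RunConfig."""
    raw = yaml.safe_load(Path(path).read_text()) or {}
    unknown = set(raw) - _FLAT_KEYS
    if unknown:
        raise ValueError(f"unknown config keys: {sorted(unknown)}")
    fz = {k: raw[k] for k in ("m", "r", "ell", "I_L", "I_U", "predictor_mode")
          if k in raw}
    se = {k: raw[k] for k in
          ("I_minus", "I_plus", "n_candidates", "n_repetitions") if k in raw}
    th = {k: raw[k] for k in ("t1", "t2", "t3") if k in raw}
    rest = {k: raw[k] for k in raw
            if k in ("n_splits", "train_fraction", "smote", "sep_max_iter",
                     "sep_tol", "sep_threshold", "seed", "log_level")}
    cfg = RunConfig(fuzzification=FuzzificationConfig(**fz),
                    search=CoefficientSearchConfig(**se),
                    threshold=FuzzyThreshold(**th), **rest)
    return cfg


def read_dataset(path: str | Path, response: str = "y"):
    """Read a delimited text table into (X, y, predictor_names).

    The response column must hold only 0/1; all other columns must be
    numeric.  Errors carry row/column context.
    """
    df = pd.read_csv(path)
    if response not in df.columns:
        raise ValueError(
            f"response column {response!r} not found; available columns: "
            f"{list(df.columns)}")
    y_raw = df[response]
    Xdf = df.drop(columns=[response])
    for col in Xdf.columns:
        coerced = pd.to_numeric(Xdf[col], errors="coerce")
        bad = coerced.isna() & Xdf[col].notna()
        if bad.any():
            row = int(bad.idxmax())
            raise ValueError(
                f"non-numeric value {Xdf[col][row]!r} in column {col!r}, "
                f"row {row}")
        Xdf[col] = coerced
    if not set(pd.unique(y_raw)).issubset({0, 1}):
        raise ValueError(
            f"response column {response!r} must contain only 0/1, found "
            f"{sorted(pd.unique(y_raw))}")
    return (Xdf.to_numpy(dtype=float), y_raw.to_numpy(dtype=int),
            list(Xdf.columns))


def write_dataset(path: str | Path, X, y,
                  names: list[str] | None = None) -> None:
    X = np.asarray(X)
    names = names or [f"x{j + 1}" for j in range(X.shape[1])]
    df = pd.DataFrame(X, columns=names)
    df["y"] = np.asarray(y, dtype=int)
    df.to_csv(path, index=False)


def write_predictions(path: str | Path, predictions) -> None:
    """Write fuzzy predictions as a delimited table."""
    rows = [{"y_hat_1": p.y_hat.a1, "y_hat_2": p.y_hat.a2,
             "y_hat_3": p.y_hat.a3, "p1": p.p_fuzzy.a1, "p2": p.p_fuzzy.a2,
             "p3": p.p_fuzzy.a3, "E_P": p.p_expected, "label": p.label}
            for p in predictions]
    pd.DataFrame(rows).to_csv(path, index=False)
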