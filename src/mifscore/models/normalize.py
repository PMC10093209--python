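"""Feature normalisation schemes.

Three schemes are supported, always fitted on training slides only:

* ``none`` — identity;
* ``zscore`` — per-feature (x - mean) / SD;
* ``feature_specific`` — percentile normalisation mapping the 0.01th
  percentile to 0 and the 99.9th percentile to 1 with clipping, leaving
  already-bounded features (circularity, eccentricity) unchanged.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from ..registry import BOUNDED_FEATURES

P_LOW, P_HIGH = 0.01, 99.9  # percentile bounds of the feature-specific scheme

METHODS = ("none", "zscore", "feature_specific")


def percentile_bounds(values: np.ndarray) -> tuple[float, float]:
    return float(np.percentile(values, P_LOW)), float(np.percentile(values, P_HIGH))


def percentile_normalize(values: np.ndarray, p_low: float, p_high: float) -> np.ndarray:
    """Map [p_low, p_high] -> [0, 1], clipping; degenerate bounds map to 0."""
    if p_high <= p_low:
        return np.zeros_like(np.asarray(values, dtype=float))
    return np.clip((np.asarray(values, dtype=float) - p_low) / (p_high - p_low), 0.0, 1.0)


@dataclass
class Normalizer:
    """Fitted per-feature normaliser for one of the three schemes."""

    method: str = "none"
    params: dict[str, tuple[float, float]] = field(default_factory=dict)
    passthrough: frozenset[str] = BOUNDED_FEATURES
    fitted: bool = False

    def fit(self, df: pd.DataFrame) -> "Normalizer":
        if self.method not in METHODS:
            raise ValueError(f"unknown normalisation method {self.method!r}")
        self.params = {}
        if self.method == "zscore":
            for name in df.columns:
                x = df[name].to_numpy(dtype=float)
                self.params[name] = (float(x.mean()), float(x.std(ddof=0)))
        elif self.method == "feature_specific":
            for name in df.columns:
                if name in self.passthrough:
                    continue
                self.params[name] = percentile_bounds(df[name].to_numpy(dtype=float))
        self.fitted = True
        return self

    def transform(self, df: pd.DataFrame) -> pd.DataFrame:
        if self.method == "none":
            return df.copy()
        if not self.fitted:
            raise RuntimeError("normalizer must be fitted on training data first")
        out = df.copy()
        if self.method == "zscore":
            for name in df.columns:
                mean, sd = self.params[name]
                if sd == 0:
                    warnings.warn(f"feature {name!r} has zero SD; mapped to 0")
                    out[name] = 0.0
                else:
                    out[name] = (df[name].to_numpy(dtype=float) - mean) / sd
        else:  # feature_specific
            for name in df.columns:
                if name in self.passthrough:
                    continue
                p_low, p_high = self.params[name]
                if p_high <= p_low:
                    warnings.warn(f"feature {name!r} has degenerate percentile bounds; mapped to 0")
                    out[name] = 0.0
                else:
                    out[name] = percentile_normalize(df[name].to_numpy(dtype=float), p_low, p_high)
        return out

    def fit_transform(self, df: pd.DataFrame) -> pd.DataFrame:
        return self.fit(df).transform(df)


def normalize_features(
    df: pd.DataFrame, method: str, fitted: Normalizer | None = None
) -> tuple[pd.DataFrame, Normalizer]:
    """Convenience wrapper: fit on ``df`` when no fitted normaliser is given."""
    if fitted is None:
        fitted = Normalizer(method).fit(df)
    if fitted.method != method:
        raise ValueError("method does not match the fitted normalizer")
    return fitted.transform(df), fitted
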