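"""Model-vs-measurement evaluation statistics.

Log-scale (geometric) bias after Hornung — the mean of ln(predicted) -
ln(measured) over paired observations — its percentage form
100 (exp(bias) - 1), and Pearson correlation on the raw or log scale.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
from scipy import stats as sps


@dataclass(frozen=True)
class PairedObservations:
    """Measured and predicted concentrations for a set of experiments."""

    labels: tuple[str, ...]
    measured: np.ndarray
    predicted: np.ndarray

    def __post_init__(self) -> None:
        object.__setattr__(self, "measured", np.asarray(self.measured, dtype=float))
        object.__setattr__(self, "predicted", np.asarray(self.predicted, dtype=float))
        if len(self.measured) != len(self.predicted) or len(self.labels) != len(self.measured):
            raise ValueError("labels, measured and predicted must have equal length")
        if len(self.measured) < 2:
            raise ValueError("need at least two paired observations")

    def __len__(self) -> int:
        return len(self.measured)


def hornung_bias(pairs: PairedObservations) -> float:
    """Mean log-scale difference, mean(ln predicted - ln measured)."""
    if np.any(pairs.measured <= 0) or np.any(pairs.predicted <= 0):
        raise ValueError("log-scale bias requires strictly positive values")
    return float(np.mean(np.log(pairs.predicted) - np.log(pairs.measured)))


def relative_bias(bias: float) -> float:
    """Percentage form of the geometric bias: 100 (exp(bias) - 1)."""
    return 100.0 * (np.expm1(bias))


def pearson_r(pairs: PairedObservations, scale: str = "raw") -> float:
    """Pearson product-moment correlation on the raw or log scale."""
    if len(pairs) < 3:
        raise ValueError("Pearson correlation needs at least three pairs")
    x, y = pairs.measured, pairs.predicted
    if scale == "log":
        if np.any(x <= 0) or np.any(y <= 0):
            raise ValueError("log-scale correlation requires positive values")
        x, y = np.log(x), np.log(y)
    elif scale != "raw":
        raise ValueError("scale must be 'raw' or 'log'")
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        raise ValueError("zero variance in one of the series")
    return float(sps.pearsonr(x, y).statistic)


def spearman_r(pairs: PairedObservations) -> float:
    """Spearman rank correlation between measured and predicted."""
    return float(sps.spearmanr(pairs.measured, pairs.predicted).statistic)


def evaluate(pairs: PairedObservations) -> dict:
    """Bias, relative bias and correlations for one paired data set."""
    bias = hornung_bias(pairs)
    return {
        "n": len(pairs),
        "bias": bias,
        "relative_bias_percent": relative_bias(bias),
        "pearson_r_raw": pearson_r(pairs, "raw"),
        "pearson_r_log": pearson_r(pairs, "log"),
        "spearman_r": spearman_r(pairs),
    }
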