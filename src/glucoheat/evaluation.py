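"""Accuracy metrics and Clarke error-grid analysis for glucose predictions.

Given paired reference values X_i and predictions Y_i (mmol/L):

* mARD = mean of |Y_i - X_i| / X_i x 100        (percent)
* CORR = Pearson product-moment correlation
* MAD  — two variants are reported side by side.  ``mad_printed`` is the
  mean absolute deviation of the *predictions about their own mean*,
  ``mean |Y_i - Ybar|`` (a spread measure that never looks at the
  reference); ``mad_conventional`` is the usual mean absolute error
  ``mean |Y_i - X_i|``.  Both are kept because the two definitions coexist
  in the glucose-monitoring literature and only agree for unbiased,
  reference-tracking predictors.
* RMSE = sqrt(mean (X_i - Y_i)^2)
* SEP  — standard error of prediction: the sample standard deviation of the
  residuals Y_i - X_i about their mean (divisor n - 1 by default,
  configurable to n).  SEP measures residual spread, not bias.

The Clarke error grid (Clarke et al. 1987) partitions (reference,
prediction) pairs, in mg/dL, into clinical-risk zones:

* A — prediction within 20% of the reference (inclusive), or both values in
  the hypoglycemic range below 70 mg/dL: clinically accurate.
* B — benign deviations outside 20%.
* C — overcorrection zones (e.g. normoglycemia read as needing treatment).
* D — dangerous failure to detect hypo-/hyperglycemia.
* E — predictions that would invert treatment (hypo read as hyper or vice
  versa).

Inputs in mmol/L are converted at 18.016 mg/dL per mmol/L.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field

import numpy as np
from scipy import stats

__all__ = [
    "MGDL_PER_MMOLL",
    "EvaluationReport",
    "mard",
    "corr",
    "mad_printed",
    "mad_conventional",
    "rmse",
    "sep",
    "clarke_zones",
    "zone_percentages",
    "evaluate",
    "plot_clarke",
]

MGDL_PER_MMOLL = 18.016

_ZONES = ("A", "B", "C", "D", "E")


def _paired(reference, predicted) -> tuple[np.ndarray, np.ndarray]:
    X = np.asarray(reference, dtype=float)
    Y = np.asarray(predicted, dtype=float)
    if X.shape != Y.shape or X.ndim != 1:
        raise ValueError("reference and predicted must be 1-D arrays of equal length")
    if not (np.all(np.isfinite(X)) and np.all(np.isfinite(Y))):
        raise ValueError("non-finite glucose values")
    return X, Y


def mard(reference, predicted) -> float:
    """Mean absolute relative difference, percent."""
    X, Y = _paired(reference, predicted)
    if np.any(X <= 0):
        raise ValueError("mARD requires strictly positive reference values")
    return float(np.mean(np.abs(Y - X) / X) * 100.0)


def corr(reference, predicted) -> float:
    """Pearson correlation between reference and predicted glucose."""
    X, Y = _paired(reference, predicted)
    if len(X) < 2:
        raise ValueError("correlation needs at least 2 pairs")
    if np.std(X) == 0 or np.std(Y) == 0:
        raise ValueError("correlation undefined for a constant series")
    return float(stats.pearsonr(X, Y).statistic)


def mad_printed(reference, predicted) -> float:
    """Mean absolute deviation of predictions about their own mean (mmol/L)."""
    _, Y = _paired(reference, predicted)
    return float(np.mean(np.abs(Y - Y.mean())))


def mad_conventional(reference, predicted) -> float:
    """Mean absolute error ``mean |Y_i - X_i|`` (mmol/L)."""
    X, Y = _paired(reference, predicted)
    return float(np.mean(np.abs(Y - X)))


def rmse(reference, predicted) -> float:
    """Root mean squared error (mmol/L)."""
    X, Y = _paired(reference, predicted)
    return float(np.sqrt(np.mean((X - Y) ** 2)))


def sep(reference, predicted, ddof: int = 1) -> float:
    """Standard error of prediction: std of residuals about their mean."""
    X, Y = _paired(reference, predicted)
    if len(X) < 2:
        raise ValueError("SEP needs at least 2 pairs")
    return float(np.std(Y - X, ddof=ddof))


def _clarke_zone_mgdl(x: float, y: float) -> str:
    """Zone of one (reference x, predicted y) pair, both in mg/dL."""
    # A: within 20% (inclusive — "no more than 20%"), or joint hypoglycemia.
    if abs(y - x) <= 0.20 * x or (x < 70.0 and y < 70.0):
        return "A"
    # E: treatment-inverting corners.
    if (x <= 70.0 and y >= 180.0) or (x >= 180.0 and y <= 70.0):
        return "E"
    # C: overcorrection bands.
    if (70.0 <= x <= 290.0 and y >= x + 110.0) or (
        130.0 <= x <= 180.0 and y <= (7.0 / 5.0) * x - 182.0
    ):
        return "C"
    # D: failure-to-detect bands.
    if (x >= 240.0 and 70.0 <= y <= 180.0) or (
        x <= 175.0 / 3.0 and 70.0 <= y <= 180.0
    ) or (175.0 / 3.0 <= x <= 70.0 and y >= (6.0 / 5.0) * x):
        return "D"
    return "B"


def clarke_zones(reference, predicted, units: str = "mmol/L") -> np.ndarray:
    """Per-pair Clarke zone labels ('A'..'E').

    ``units`` is the unit of the inputs: ``"mmol/L"`` (converted internally
    at 18.016) or ``"mg/dL"``.
    """
    X, Y = _paired(reference, predicted)
    if np.any(X <= 0) or np.any(Y <= 0):
        raise ValueError("glucose concentrations must be positive")
    if units == "mmol/L":
        X, Y = X * MGDL_PER_MMOLL, Y * MGDL_PER_MMOLL
    elif units != "mg/dL":
        raise ValueError(f"units must be 'mmol/L' or 'mg/dL', got {units!r}")
    return np.array([_clarke_zone_mgdl(x, y) for x, y in zip(X, Y)])


def zone_percentages(zones: np.ndarray) -> dict[str, float]:
    """Percentage of points per zone A..E; sums to 100 for nonempty input."""
    zones = np.asarray(zones)
    n = len(zones)
    if n == 0:
        raise ValueError("no zone labels")
    return {z: float(np.sum(zones == z)) / n * 100.0 for z in _ZONES}


@dataclass(frozen=True)
class EvaluationReport:
    """Full accuracy report for one prediction set."""

    n: int
    mARD: float
    CORR: float
    MAD_printed: float
    MAD_conventional: float
    RMSE: float
    SEP: float
    zone_percentages: dict[str, float] = field(default_factory=dict)

    def to_dict(self) -> dict:
        return {
            "n": self.n,
            "mARD_percent": self.mARD,
            "CORR": self.CORR,
            "MAD_printed_mmolL": self.MAD_printed,
            "MAD_conventional_mmolL": self.MAD_conventional,
            "RMSE_mmolL": self.RMSE,
            "SEP_mmolL": self.SEP,
            "clarke_zone_percent": self.zone_percentages,
        }

    def to_json(self) -> str:
        return json.dumps(self.to_dict(), indent=2)

    def summary(self) -> str:
        zp = ", ".join(f"{z}: {p:.3f}%" for z, p in self.zone_percentages.items())
        return "\n".join(
            [
                f"n                = {self.n}",
                f"mARD             = {self.mARD:.3f} %",
                f"CORR             = {self.CORR:.3f}",
                f"MAD (pred-mean)  = {self.MAD_printed:.3f} mmol/L",
                f"MAD (|Y - X|)    = {self.MAD_conventional:.3f} mmol/L",
                f"RMSE             = {self.RMSE:.3f} mmol/L",
                f"SEP              = {self.SEP:.3f} mmol/L",
                f"Clarke zones     : {zp}",
            ]
        )


def evaluate(reference, predicted, units: str = "mmol/L") -> EvaluationReport:
    """Compute every accuracy metric plus Clarke zone shares in one pass."""
    X, Y = _paired(reference, predicted)
    zones = clarke_zones(X, Y, units=units)
    return EvaluationReport(
        n=len(X),
        mARD=mard(X, Y),
        CORR=corr(X, Y),
        MAD_printed=mad_printed(X, Y),
        MAD_conventional=mad_conventional(X, Y),
        RMSE=rmse(X, Y),
        SEP=sep(X, Y),
        zone_percentages=zone_percentages(zones),
    )


def plot_clarke(reference, predicted, units: str = "mmol/L", ax=None):
    """Scatter the prediction pairs on the Clarke grid (cosmetic; the zone
    counts from :func:`clarke_zones` are the contract)."""
    import matplotlib.pyplot as plt

    X, Y = _paired(reference, predicted)
    if units == "mmol/L":
        X, Y = X * MGDL_PER_MMOLL, Y * MGDL_PER_MMOLL
    if ax is None:
        _, ax = plt.subplots(figsize=(6, 6))
    lim = max(400.0, float(max(X.max(), Y.max())) * 1.05)
    # zone boundary segments (mg/dL), the canonical piecewise lines
    segs = [
        ((0, 0), (lim, lim)),
        ((0, 70), (175 / 3, 70)),
        ((175 / 3, 70), (lim, 1.2 * lim)),
        ((0, 0), (lim, 0.8 * lim)),
        ((70, 0), (70, 56)),
        ((70, 84), (70, lim)),
        ((0, 180), (70, 180)),
        ((70, 180), (290, lim)),
        ((130, 0), (180, 70)),
        ((180, 70), (lim, 70)),
        ((240, 70), (240, 180)),
        ((240, 180), (lim, 180)),
        ((180, 0), (180, 70)),
    ]
    for (x0, y0), (x1, y1) in segs:
        ax.plot([x0, x1], [y0, y1], color="0.4", lw=0.8)
    ax.scatter(X, Y, s=14, color="tab:blue", zorder=3)
    ax.set_xlim(0, lim)
    ax.set_ylim(0, lim)
    ax.set_xlabel("reference BG (mg/dL)")
    ax.set_ylabel("predicted BG (mg/dL)")
    ax.set_title("Clarke error grid")
    return ax
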