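"""Glucose regression models on the feature vector (H, SpO2, HR, BF).

Two estimators map the four wrist-derived predictors to blood glucose
(mmol/L):

* :class:`MPR4` — fourth-degree multiple polynomial regression restricted to
  interaction terms.  With predictors x1=H, x2=SpO2, x3=HR, x4=BF the design
  holds every product of *distinct* predictors (no squares, to limit
  collinearity): 4 linear + 6 pairwise + 4 triple + 1 quadruple = 15 columns
  plus an intercept, fitted by ordinary least squares.

* :class:`BPNN` — a feedforward network with one hidden layer of tansig
  (hyperbolic-tangent) units and a linear output, sized by the Kolmogorov
  heuristic ``Nhid = 2 * Nin + 1`` (4 inputs -> 9 hidden units), trained by
  damped Levenberg–Marquardt least squares on standardized inputs and a
  [-1, 1]-scaled target.  Fully reproducible given a seed.

Both follow the Model/Results idiom: construct from data, ``fit()`` returns
a results object carrying estimates, diagnostics, ``predict`` and
``summary()``, plus human-readable JSON serialization.
"""

from __future__ import annotations

import json
import math
import warnings
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd
import statsmodels.api as sm

__all__ = [
    "FEATURE_NAMES",
    "MPR4_TERMS",
    "FeatureRecord",
    "build_design_matrix",
    "holdout_split",
    "MPR4",
    "MPR4Results",
    "BPNN",
    "BPNNResults",
    "load_results",
]

FEATURE_NAMES = ("H", "SpO2", "HR", "BF")

# Interaction terms in their canonical (and serialization) order: each entry
# lists the 0-based predictor indices multiplied together.
MPR4_TERMS: tuple[tuple[int, ...], ...] = (
    (0,), (1,), (2,), (3,),
    (0, 1), (0, 2), (0, 3), (1, 2), (1, 3), (2, 3),
    (0, 1, 2), (0, 1, 3), (0, 2, 3), (1, 2, 3),
    (0, 1, 2, 3),
)

MPR4_TERM_LABELS = tuple(
    "*".join(FEATURE_NAMES[i] for i in term) for term in MPR4_TERMS
)

# Sample-size rule for the interaction regression: n must exceed three times
# the number of variables (3 * 15 = 45).
MPR4_MIN_SAMPLES = 3 * len(MPR4_TERMS)


@dataclass(frozen=True)
class FeatureRecord:
    """One predictor vector with an optional reference glucose.

    x1..x4 correspond to H (W/m^2), SpO2 (%), HR (bpm), BF (perfusion
    units); ``bg_ref`` is the reference blood glucose in mmol/L and may be
    absent at predict time.
    """

    H: float
    SpO2: float
    HR: float
    BF: float
    bg_ref: float | None = None

    def __post_init__(self) -> None:
        for name in FEATURE_NAMES:
            v = getattr(self, name)
            if not math.isfinite(v):
                raise ValueError(f"non-finite predictor {name}={v}")
        if self.bg_ref is not None and not self.bg_ref > 0:
            raise ValueError(f"bg_ref must be positive, got {self.bg_ref}")

    @property
    def x(self) -> np.ndarray:
        return np.array([self.H, self.SpO2, self.HR, self.BF], dtype=float)


def _as_feature_matrix(records) -> np.ndarray:
    """Coerce records (FeatureRecord list / DataFrame / array) to n x 4."""
    if isinstance(records, pd.DataFrame):
        X = records.loc[:, list(FEATURE_NAMES)].to_numpy(dtype=float)
    elif len(records) and isinstance(records[0], FeatureRecord):
        X = np.array([rec.x for rec in records], dtype=float)
    else:
        X = np.asarray(records, dtype=float)
        if X.ndim == 1:
            X = X.reshape(1, -1)
    if X.shape[1] != 4:
        raise ValueError(f"expected 4 predictor columns, got {X.shape[1]}")
    bad = ~np.isfinite(X)
    if bad.any():
        i, j = np.argwhere(bad)[0]
        raise ValueError(
            f"non-finite predictor at row {i}, field {FEATURE_NAMES[j]}"
        )
    return X


def build_design_matrix(records) -> np.ndarray:
    """Interaction design matrix (n x 15), columns in ``MPR4_TERMS`` order."""
    X = _as_feature_matrix(records)
    cols = [np.prod(X[:, list(term)], axis=1) for term in MPR4_TERMS]
    return np.column_stack(cols)


def holdout_split(
    records, train_fraction: float = 118.0 / 211.0, seed: int = 0
) -> tuple[np.ndarray, np.ndarray]:
    """Seeded hold-out partition into (train_idx, test_idx).

    Returns disjoint integer index arrays whose union covers all records.
    ``train_fraction`` defaults to 118/211, the calibration share used with
    a 211-record cohort; the training count is ``round(n * fraction)``.
    """
    if not 0.0 < train_fraction < 1.0:
        raise ValueError(f"train_fraction must be in (0, 1), got {train_fraction}")
    n = len(records)
    n_train = int(round(n * train_fraction))
    n_train = min(max(n_train, 1), n - 1)
    rng = np.random.default_rng(seed)
    perm = rng.permutation(n)
    return np.sort(perm[:n_train]), np.sort(perm[n_train:])


def _extract_xy(records, endog) -> tuple[np.ndarray, np.ndarray]:
    X = _as_feature_matrix(records)
    if endog is not None:
        y = np.asarray(endog, dtype=float)
    elif isinstance(records, pd.DataFrame):
        for col in ("BG_ref", "bg_ref", "BG_ref_mmolL"):
            if col in records.columns:
                y = records[col].to_numpy(dtype=float)
                break
        else:
            raise ValueError("no reference-glucose column found in DataFrame")
    elif len(records) and isinstance(records[0], FeatureRecord):
        refs = [rec.bg_ref for rec in records]
        if any(r is None for r in refs):
            missing = [i for i, r in enumerate(refs) if r is None]
            raise ValueError(f"records {missing[:5]} lack bg_ref; cannot fit")
        y = np.asarray(refs, dtype=float)
    else:
        raise ValueError("endog (reference BG) required for array input")
    if len(y) != len(X):
        raise ValueError("endog and records lengths differ")
    if not np.all(np.isfinite(y)):
        raise ValueError("reference glucose contains non-finite values")
    return X, y


def _unit_columns(A: np.ndarray) -> np.ndarray:
    norms = np.linalg.norm(A, axis=0)
    norms[norms == 0] = 1.0
    return A / norms


def _collinear_columns(design: np.ndarray) -> list[str]:
    """Name design columns that do not add rank (greedy, in term order).

    Columns are unit-normed first so the check reflects genuine linear
    dependence, not the wildly different scales of interaction products.
    """
    culprits = []
    D = _unit_columns(design)
    kept = np.full((design.shape[0], 1), design.shape[0] ** -0.5)  # intercept
    for j in range(D.shape[1]):
        trial = np.column_stack([kept, D[:, j]])
        if np.linalg.matrix_rank(trial) == kept.shape[1]:
            culprits.append(MPR4_TERM_LABELS[j])
        else:
            kept = trial
    return culprits


class MPR4:
    """Interaction-polynomial glucose regression model.

    Parameters
    ----------
    records : DataFrame | list[FeatureRecord] | ndarray
        Predictors (columns/fields H, SpO2, HR, BF).
    endog : array-like, optional
        Reference glucose (mmol/L); taken from ``records`` when they carry it.
    """

    def __init__(self, records, endog=None):
        self.X, self.y = _extract_xy(records, endog)
        self.design = build_design_matrix(self.X)

    @classmethod
    def from_dataframe(cls, df: pd.DataFrame, target: str = "BG_ref") -> "MPR4":
        return cls(df, endog=df[target].to_numpy(dtype=float))

    def fit(self) -> "MPR4Results":
        """Ordinary least squares on intercept + 15 interaction columns.

        Refuses to fit when n <= 45 (three observations per variable is the
        minimum the interaction design justifies) and when the design is
        rank-deficient, naming the collinear columns.
        """
        n = len(self.y)
        if n <= MPR4_MIN_SAMPLES:
            raise ValueError(
                f"n={n} too small: the 15-variable interaction regression "
                f"requires more than 3 x 15 = {MPR4_MIN_SAMPLES} samples"
            )
        exog = sm.add_constant(self.design, has_constant="add")
        if np.linalg.matrix_rank(_unit_columns(exog)) < exog.shape[1]:
            raise ValueError(
                "rank-deficient design; collinear columns: "
                + ", ".join(_collinear_columns(self.design))
            )
        ols = sm.OLS(self.y, exog).fit()
        return MPR4Results(model=self, params=ols.params, bse=ols.bse, _ols=ols)


class MPR4Results:
    """Fitted interaction regression: coefficients a0..a15 and diagnostics."""

    kind = "mpr4"

    def __init__(self, model, params, bse=None, _ols=None):
        self.model = model
        self.params = np.asarray(params, dtype=float)
        if self.params.shape != (16,):
            raise ValueError("MPR4 takes exactly 16 coefficients (a0..a15)")
        self.bse = None if bse is None else np.asarray(bse, dtype=float)
        self._ols = _ols

    @property
    def intercept(self) -> float:
        return float(self.params[0])

    @property
    def coefficients(self) -> np.ndarray:
        """a1..a15 in ``MPR4_TERMS`` order."""
        return self.params[1:]

    @property
    def rsquared(self) -> float:
        return float(self._ols.rsquared) if self._ols is not None else float("nan")

    def predict(self, records) -> np.ndarray:
        design = build_design_matrix(records)
        return self.intercept + design @ self.coefficients

    @property
    def resid(self) -> np.ndarray:
        return self.model.y - self.predict(self.model.X)

    def summary(self) -> str:
        n = len(self.model.y) if self.model is not None else "?"
        lines = [
            "Interaction polynomial regression (MPR4)",
            f"n = {n}, R^2 = {self.rsquared:.4f}",
            f"{'term':>16} {'coef':>14} {'std err':>12}",
            f"{'intercept':>16} {self.intercept:>14.6g} "
            + (f"{self.bse[0]:>12.3g}" if self.bse is not None else f"{'':>12}"),
        ]
        for j, label in enumerate(MPR4_TERM_LABELS):
            se = f"{self.bse[j + 1]:>12.3g}" if self.bse is not None else f"{'':>12}"
            lines.append(f"{label:>16} {self.params[j + 1]:>14.6g} {se}")
        return "\n".join(lines)

    def to_dict(self) -> dict:
        return {
            "kind": self.kind,
            "term_order": list(MPR4_TERM_LABELS),
            "intercept": self.intercept,
            "coefficients": self.coefficients.tolist(),
            "bse": None if self.bse is None else self.bse.tolist(),
        }

    def save(self, path) -> None:
        Path(path).write_text(json.dumps(self.to_dict(), indent=2) + "\n")


# ---------------------------------------------------------------------------
# BPNN


def _nhid(n_in: int) -> int:
    """Kolmogorov hidden-layer sizing: 2 * Nin + 1."""
    return 2 * n_in + 1


@dataclass
class BPNNConfig:
    """Levenberg–Marquardt training configuration.

    max_epochs caps accepted update steps; tolerance bounds the relative
    cost improvement, the absolute cost goal and the gradient norm at which
    training stops.  weight_decay adds a ridge penalty
    ``0.5 * weight_decay * ||theta||^2`` to the squared-error objective
    (regularized Levenberg–Marquardt) — on standardized data this is the
    standard guard against a 55-parameter network overfitting a small noisy
    cohort; set it to 0 for a pure least-squares fit.  validation_fraction
    optionally holds out a seeded share of the training data and stops when
    its error rises (off by default; LM takes few, large steps, so the decay
    term is the more effective regularizer).
    """

    seed: int = 0
    max_epochs: int = 1000
    tolerance: float = 1e-8
    weight_decay: float = 0.5
    validation_fraction: float = 0.0
    patience: int = 8


class BPNN:
    """Feedforward tansig network for glucose regression (4-9-1).

    Hidden size follows ``Nhid = 2 * Nin + 1``.  Inputs are standardized and
    the target mapped to [-1, 1] using training statistics stored with the
    fit; training minimizes squared error by damped Levenberg–Marquardt.
    """

    def __init__(self, records, endog=None, config: BPNNConfig | None = None, **kw):
        self.X, self.y = _extract_xy(records, endog)
        if len(self.y) < 20:
            raise ValueError(f"BPNN needs at least 20 training records, got {len(self.y)}")
        self.config = config if config is not None else BPNNConfig(**kw)
        self.n_in = self.X.shape[1]
        self.n_hid = _nhid(self.n_in)

    @classmethod
    def from_dataframe(cls, df: pd.DataFrame, target: str = "BG_ref", **kw) -> "BPNN":
        return cls(df, endog=df[target].to_numpy(dtype=float), **kw)

    # -- parameter vector layout: W1 (nh x ni), b1 (nh), w2 (nh), b2 (1)
    def _unpack(self, theta: np.ndarray):
        ni, nh = self.n_in, self.n_hid
        W1 = theta[: nh * ni].reshape(nh, ni)
        b1 = theta[nh * ni : nh * ni + nh]
        w2 = theta[nh * ni + nh : nh * ni + 2 * nh]
        b2 = theta[-1]
        return W1, b1, w2, b2

    @staticmethod
    def _forward(Xs, W1, b1, w2, b2):
        h = np.tanh(Xs @ W1.T + b1)
        return h @ w2 + b2, h

    def _residual_jacobian(self, theta, Xs, ys):
        W1, b1, w2, b2 = self._unpack(theta)
        yhat, h = self._forward(Xs, W1, b1, w2, b2)
        e = yhat - ys
        dtan = 1.0 - h**2                      # n x nh
        back = dtan * w2                       # n x nh
        J = np.concatenate(
            [
                (back[:, :, None] * Xs[:, None, :]).reshape(len(Xs), -1),  # dW1
                back,                                                       # db1
                h,                                                          # dw2
                np.ones((len(Xs), 1)),                                      # db2
            ],
            axis=1,
        )
        alpha = self.config.weight_decay
        if alpha > 0:
            # ridge penalty as extra residuals: sqrt(alpha) * theta
            sa = np.sqrt(alpha)
            e = np.concatenate([e, sa * theta])
            J = np.vstack([J, sa * np.eye(len(theta))])
        return e, J

    def _init_theta(self, rng: np.random.Generator) -> np.ndarray:
        ni, nh = self.n_in, self.n_hid
        W1 = rng.uniform(-1, 1, (nh, ni)) * np.sqrt(3.0 / ni)
        b1 = rng.uniform(-1, 1, nh)
        w2 = rng.uniform(-1, 1, nh) * np.sqrt(3.0 / nh)
        b2 = np.zeros(1)
        return np.concatenate([W1.ravel(), b1, w2, b2])

    def fit(self) -> "BPNNResults":
        cfg = self.config
        rng = np.random.default_rng(cfg.seed)

        x_mean = self.X.mean(axis=0)
        x_std = self.X.std(axis=0)
        x_std[x_std == 0] = 1.0
        Xs_all = (self.X - x_mean) / x_std
        y_lo, y_hi = float(self.y.min()), float(self.y.max())
        y_mid = 0.5 * (y_hi + y_lo)
        y_half = 0.5 * (y_hi - y_lo) or 1.0
        ys_all = (self.y - y_mid) / y_half

        if cfg.validation_fraction > 0:
            n = len(ys_all)
            n_val = max(1, int(round(n * cfg.validation_fraction)))
            perm = rng.permutation(n)
            val_idx, tr_idx = perm[:n_val], perm[n_val:]
            Xs, ys = Xs_all[tr_idx], ys_all[tr_idx]
            Xv, yv = Xs_all[val_idx], ys_all[val_idx]
        else:
            Xs, ys = Xs_all, ys_all
            Xv = yv = None

        theta = self._init_theta(rng)
        e, J = self._residual_jacobian(theta, Xs, ys)
        cost = 0.5 * float(e @ e)
        lam = 1e-2
        converged = False
        loss_history = [cost]
        best_theta, best_val = theta.copy(), np.inf
        val_bad = 0

        for _ in range(cfg.max_epochs):
            g = J.T @ e
            if np.linalg.norm(g, np.inf) < cfg.tolerance:
                converged = True
                break
            A = J.T @ J
            accepted = False
            while lam < 1e12:
                try:
                    step = np.linalg.solve(A + lam * np.eye(len(theta)), -g)
                except np.linalg.LinAlgError:
                    lam *= 10.0
                    continue
                trial = theta + step
                e_t, J_t = self._residual_jacobian(trial, Xs, ys)
                cost_t = 0.5 * float(e_t @ e_t)
                if cost_t < cost:
                    rel_impr = (cost - cost_t) / max(cost, 1e-300)
                    theta, e, J, cost = trial, e_t, J_t, cost_t
                    lam = max(lam / 10.0, 1e-12)
                    accepted = True
                    loss_history.append(cost)
                    if rel_impr < cfg.tolerance or cost < cfg.tolerance:
                        converged = True
                    break
                lam *= 10.0
            if not accepted:
                converged = True  # damping exhausted: at a (local) minimum
                break
            if Xv is not None:
                ev = self._forward(Xv, *self._unpack(theta))[0] - yv
                vcost = 0.5 * float(ev @ ev)
                if vcost < best_val:
                    best_val, best_theta, val_bad = vcost, theta.copy(), 0
                else:
                    val_bad += 1
                    if val_bad >= cfg.patience:
                        theta = best_theta
                        converged = True
                        break
            if converged:
                break

        if not converged:
            warnings.warn(
                f"Levenberg–Marquardt did not converge in {cfg.max_epochs} epochs; "
                "returning the best model found",
                stacklevel=2,
            )
        W1, b1, w2, b2 = self._unpack(theta)
        return BPNNResults(
            model=self,
            W1=W1, b1=b1, w2=w2, b2=float(b2),
            x_mean=x_mean, x_std=x_std, y_mid=y_mid, y_half=y_half,
            x_min=self.X.min(axis=0), x_max=self.X.max(axis=0),
            seed=cfg.seed, converged=converged,
            loss_history=np.asarray(loss_history),
        )


class BPNNResults:
    """Fitted tansig network: weights, scalings and training diagnostics."""

    kind = "bpnn"

    def __init__(self, model, W1, b1, w2, b2, x_mean, x_std, y_mid, y_half,
                 x_min, x_max, seed, converged, loss_history):
        self.model = model
        self.W1 = np.asarray(W1, dtype=float)
        self.b1 = np.asarray(b1, dtype=float)
        self.w2 = np.asarray(w2, dtype=float)
        self.b2 = float(b2)
        self.x_mean = np.asarray(x_mean, dtype=float)
        self.x_std = np.asarray(x_std, dtype=float)
        self.y_mid = float(y_mid)
        self.y_half = float(y_half)
        self.x_min = np.asarray(x_min, dtype=float)
        self.x_max = np.asarray(x_max, dtype=float)
        self.seed = seed
        self.converged = bool(converged)
        self.loss_history = np.asarray(loss_history, dtype=float)

    def predict(self, records) -> np.ndarray:
        X = _as_feature_matrix(records)
        span = self.x_max - self.x_min
        center = 0.5 * (self.x_max + self.x_min)
        lim = 5.0 * np.where(span > 0, span, np.abs(center) + 1.0)
        if np.any(X < center - lim) or np.any(X > center + lim):
            warnings.warn(
                "predictor outside 10x the training range; network output is "
                "an extrapolation",
                stacklevel=2,
            )
        Xs = (X - self.x_mean) / self.x_std
        ys = np.tanh(Xs @ self.W1.T + self.b1) @ self.w2 + self.b2
        return ys * self.y_half + self.y_mid

    def summary(self) -> str:
        return "\n".join(
            [
                "Feedforward tansig network (BPNN)",
                f"architecture {self.W1.shape[1]}-{self.W1.shape[0]}-1, seed {self.seed}",
                f"n = {len(self.model.y) if self.model is not None else '?'}, "
                "final training cost = "
                f"{self.loss_history[-1]:.6g}, "
                f"{'converged' if self.converged else 'NOT converged'} "
                f"in {len(self.loss_history) - 1} accepted steps",
            ]
        )

    def to_dict(self) -> dict:
        return {
            "kind": self.kind,
            "seed": self.seed,
            "converged": self.converged,
            "hidden_weights": self.W1.tolist(),
            "hidden_bias": self.b1.tolist(),
            "output_weights": self.w2.tolist(),
            "output_bias": self.b2,
            "x_mean": self.x_mean.tolist(),
            "x_std": self.x_std.tolist(),
            "y_mid": self.y_mid,
            "y_half": self.y_half,
            "x_min": self.x_min.tolist(),
            "x_max": self.x_max.tolist(),
        }

    def save(self, path) -> None:
        Path(path).write_text(json.dumps(self.to_dict(), indent=2) + "\n")


def load_results(path):
    """Load a saved MPR4Results or BPNNResults from its JSON file."""
    d = json.loads(Path(path).read_text())
    if d["kind"] == "mpr4":
        params = np.concatenate([[d["intercept"]], d["coefficients"]])
        bse = None if d.get("bse") is None else np.asarray(d["bse"])
        return MPR4Results(model=None, params=params, bse=bse)
    if d["kind"] == "bpnn":
        return BPNNResults(
            model=None,
            W1=d["hidden_weights"], b1=d["hidden_bias"],
            w2=d["output_weights"], b2=d["output_bias"],
            x_mean=d["x_mean"], x_std=d["x_std"],
            y_mid=d["y_mid"], y_half=d["y_half"],
            x_min=d["x_min"], x_max=d["x_max"],
            seed=d["seed"], converged=d["converged"],
            loss_history=[np.nan],
        )
    raise ValueError(f"unknown model kind {d.get('kind')!r}")
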