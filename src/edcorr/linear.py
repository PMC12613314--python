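"""Linear correction models fitted by direct loss minimisation.

The model is ``y = X w + b + d_disp`` with six trainable weights on the
weighted descriptor columns, a trainable intercept and a fixed unit
weight on the dispersion delta.  Unlike ordinary least squares, the
coefficients are found by minimising a selectable loss — SSE, MAE or
MAPE — with scipy's BFGS or Nelder-Mead, optionally with an L2 (ridge)
penalty on the six weights.  Features are never normalised, so the
fitted coefficients keep their physical reading: a weight of 1 means
"take this energy component at face value".

MAPE is undefined at zero reference energy; fitting or scoring with MAPE
against near-zero references raises rather than silently flooring the
denominator, because flooring would distort the objective.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.optimize import minimize

from edcorr.features import FEATURE_COLUMNS, feature_matrix

LOSSES = ("SSE", "MAE", "MAPE")
OPTIMIZERS = ("BFGS", "NELDER_MEAD")

#: References with magnitude below this are rejected for MAPE.
MAPE_REF_FLOOR = 1e-10

_SCIPY_METHOD = {"BFGS": "BFGS", "NELDER_MEAD": "Nelder-Mead"}

SCHEMA_VERSION = 1


@dataclass
class LinearModel:
    """Six weights + intercept, with fit metadata.

    ``w`` is ordered as the weighted feature columns
    (d_te, d_vnn, d_ven, d_ex, d_ej, d_ec); ``b`` is in kcal/mol.
    """

    w: np.ndarray
    b: float
    loss_name: str = "SSE"
    l2_strength: float = 0.0
    optimizer_name: str = "BFGS"
    tag: dict = field(default_factory=dict)

    def __post_init__(self):
        self.w = np.asarray(self.w, dtype=float)
        if self.w.shape != (6,):
            raise ValueError("LinearModel requires exactly six weights")
        if not np.all(np.isfinite(self.w)) or not np.isfinite(self.b):
            raise ValueError("model coefficients must be finite")
        if self.l2_strength < 0:
            raise ValueError("l2_strength must be non-negative")

    def to_dict(self) -> dict:
        return {
            "schema_version": SCHEMA_VERSION,
            "w": [float(x) for x in self.w],
            "b": float(self.b),
            "loss_name": self.loss_name,
            "l2_strength": float(self.l2_strength),
            "optimizer_name": self.optimizer_name,
            "tag": dict(self.tag),
        }

    @classmethod
    def from_dict(cls, d: dict) -> "LinearModel":
        return cls(
            w=np.array(d["w"], dtype=float),
            b=float(d["b"]),
            loss_name=d.get("loss_name", "SSE"),
            l2_strength=float(d.get("l2_strength", 0.0)),
            optimizer_name=d.get("optimizer_name", "BFGS"),
            tag=dict(d.get("tag", {})),
        )

    def save(self, path) -> None:
        with open(path, "w") as fh:
            json.dump(self.to_dict(), fh, indent=2, sort_keys=True)
            fh.write("\n")

    @classmethod
    def load(cls, path) -> "LinearModel":
        with open(path) as fh:
            return cls.from_dict(json.load(fh))


def baseline_model(tag: dict | None = None) -> LinearModel:
    """The uncorrected-DFT identity model: w = 1, b = 0."""
    return LinearModel(w=np.ones(6), b=0.0, tag=tag or {})


@dataclass
class FitConfig:
    """Everything a fit needs besides the data."""

    loss_name: str = "SSE"
    optimizer_name: str = "BFGS"
    l2_strength: float = 0.0
    init_w: np.ndarray = field(default_factory=lambda: np.ones(6))
    init_b: float = 0.0
    max_iterations: int = 10_000
    convergence_tolerance: float = 1e-8
    seed: int = 0

    def __post_init__(self):
        self.init_w = np.asarray(self.init_w, dtype=float)
        if self.init_w.shape != (6,):
            raise ValueError("init_w must have length 6")
        if self.loss_name not in LOSSES:
            raise ValueError(f"loss_name must be one of {LOSSES}")
        if self.optimizer_name not in OPTIMIZERS:
            raise ValueError(f"optimizer_name must be one of {OPTIMIZERS}")
        if self.convergence_tolerance <= 0 or self.max_iterations < 1:
            raise ValueError("tolerances must be positive")
        if self.l2_strength < 0:
            raise ValueError("l2_strength must be non-negative")

    def replace(self, **kw) -> "FitConfig":
        d = {
            "loss_name": self.loss_name,
            "optimizer_name": self.optimizer_name,
            "l2_strength": self.l2_strength,
            "init_w": self.init_w.copy(),
            "init_b": self.init_b,
            "max_iterations": self.max_iterations,
            "convergence_tolerance": self.convergence_tolerance,
            "seed": self.seed,
        }
        d.update(kw)
        return FitConfig(**d)


def predict(model: LinearModel, table: pd.DataFrame) -> np.ndarray:
    """Predict corrected reaction energies (kcal/mol) for feature rows.

    Dispersion always enters with fixed unit weight.
    """
    X, d_disp = feature_matrix(table)
    if not np.all(np.isfinite(X)) or not np.all(np.isfinite(d_disp)):
        raise ValueError("non-finite feature value in table")
    # row-sum of the scaled columns, so that the w = 1, b = 0 baseline
    # reproduces the plain sum of the seven deltas bit-for-bit
    scaled = np.column_stack([X * model.w, d_disp])
    return scaled.sum(axis=1) + model.b


def _data_loss(loss_name: str, predictions: np.ndarray, references: np.ndarray) -> float:
    r = references - predictions
    if loss_name == "SSE":
        return float(np.sum(r * r))
    if loss_name == "MAE":
        return float(np.mean(np.abs(r)))
    if loss_name == "MAPE":
        if np.any(np.abs(references) < MAPE_REF_FLOOR):
            raise ValueError(
                "MAPE is undefined for (near-)zero reference energies; "
                "use MAE or SSE for this data"
            )
        return float(np.mean(np.abs(r / references)) * 100.0)
    raise ValueError(f"unknown loss {loss_name!r}")


def objective(
    loss_name: str,
    predictions,
    references,
    w=None,
    l2_strength: float = 0.0,
) -> float:
    """Loss value: data term per the metric plus ``L * sum(w_i^2)``.

    MAPE is returned on the percent scale.  The penalty covers the six
    weights only — never the intercept or the fixed dispersion term.
    """
    predictions = np.asarray(predictions, dtype=float)
    references = np.asarray(references, dtype=float)
    if predictions.shape != references.shape or predictions.size == 0:
        raise ValueError("predictions and references must be equal-length and non-empty")
    val = _data_loss(loss_name, predictions, references)
    if l2_strength:
        if w is None:
            raise ValueError("weights required when l2_strength > 0")
        w = np.asarray(w, dtype=float)
        val += float(l2_strength) * float(np.sum(w * w))
    return val


def _objective_and_grad(theta, X, d_disp, y, loss_name, L):
    """Value and (sub)gradient of the penalised loss at theta = (w, b)."""
    w, b = theta[:6], theta[6]
    pred = X @ w + d_disp + b
    r = y - pred  # residual; d pred/d theta = [X, 1]
    n = y.size
    if loss_name == "SSE":
        val = np.sum(r * r)
        gw = -2.0 * (X.T @ r)
        gb = -2.0 * np.sum(r)
    elif loss_name == "MAE":
        val = np.mean(np.abs(r))
        s = np.sign(r) / n
        gw = -(X.T @ s)
        gb = -np.sum(s)
    else:  # MAPE
        val = np.mean(np.abs(r / y)) * 100.0
        s = np.sign(r / y) / np.abs(y) * (100.0 / n)
        gw = -(X.T @ s)
        gb = -np.sum(s)
    if L:
        val += L * np.sum(w * w)
        gw = gw + 2.0 * L * w
    return float(val), np.concatenate([gw, [gb]])


def fit(table: pd.DataFrame, config: FitConfig) -> tuple[LinearModel, dict]:
    """Fit the model by direct minimisation of the configured loss.

    Deterministic given the config: BFGS and Nelder-Mead are run once
    from the configured start, with no hidden randomness.  Returns the
    fitted model and a report dict with the final loss, iteration count,
    convergence flag and the loss at the initial point.  The returned
    parameters never score worse than the start (monotone improvement).

    Requires at least 8 rows (more rows than free parameters) with
    reference energies present.
    """
    refs = table["ref_energy"]
    if refs.isna().any():
        raise ValueError("fit requires reference energies for every row")
    y = refs.to_numpy(dtype=float)
    if len(y) < 8:
        raise ValueError(f"fit requires >= 8 rows, got {len(y)}")
    X, d_disp = feature_matrix(table)
    if config.loss_name == "MAPE" and np.any(np.abs(y) < MAPE_REF_FLOOR):
        raise ValueError(
            "MAPE loss is undefined for (near-)zero references; use MAE or SSE"
        )

    rank = np.linalg.matrix_rank(np.column_stack([X, np.ones(len(y))]))
    rank_deficient = rank < 7

    L = float(config.l2_strength)
    x0 = np.concatenate([config.init_w, [config.init_b]])
    f0, _ = _objective_and_grad(x0, X, d_disp, y, config.loss_name, L)

    method = _SCIPY_METHOD[config.optimizer_name]
    if method == "BFGS":
        res = minimize(
            _objective_and_grad,
            x0,
            args=(X, d_disp, y, config.loss_name, L),
            jac=True,
            method="BFGS",
            options={"maxiter": config.max_iterations, "gtol": config.convergence_tolerance},
        )
    else:
        # Nelder-Mead with deterministic restarts: reinitialising the
        # simplex at the previous optimum escapes the degenerate-simplex
        # stalls the method is prone to on piecewise-linear objectives.
        fun = lambda t: _objective_and_grad(t, X, d_disp, y, config.loss_name, L)[0]
        opts = {
            "maxiter": config.max_iterations,
            "maxfev": 10 * config.max_iterations,
            "xatol": config.convergence_tolerance,
            "fatol": config.convergence_tolerance,
            "adaptive": True,  # needed for reliable convergence in 7 dims
        }
        res = minimize(fun, x0, method="Nelder-Mead", options=opts)
        for _ in range(20):
            prev = res.fun
            restarted = minimize(fun, res.x, method="Nelder-Mead", options=opts)
            if restarted.fun < res.fun:
                res = restarted
            if prev - res.fun <= config.convergence_tolerance * max(1.0, abs(prev)):
                break

    theta = np.asarray(res.x, dtype=float)
    f_final, _ = _objective_and_grad(theta, X, d_disp, y, config.loss_name, L)
    if f_final > f0:  # solver contract: never return a worse point than the start
        theta, f_final = x0, f0

    model = LinearModel(
        w=theta[:6],
        b=float(theta[6]),
        loss_name=config.loss_name,
        l2_strength=L,
        optimizer_name=config.optimizer_name,
    )
    report = {
        "final_loss": float(f_final),
        "initial_loss": float(f0),
        "iterations": int(getattr(res, "nit", 0) or 0),
        "converged": bool(res.success),
        "rank_deficient": bool(rank_deficient),
        "message": str(res.message),
    }
    return model, report


def least_squares_closed_form(table: pd.DataFrame) -> tuple[np.ndarray, float]:
    """Normal-equations SSE solution (L = 0) for cross-checking fits.

    Solves ``min ||y - d_disp - [X 1] theta||^2`` by ``lstsq``; returns
    ``(w, b)``.  This is the independent oracle for the SSE loss path.
    """
    X, d_disp = feature_matrix(table)
    y = table["ref_energy"].to_numpy(dtype=float) - d_disp
    A = np.column_stack([X, np.ones(len(y))])
    theta, *_ = np.linalg.lstsq(A, y, rcond=None)
    return theta[:6], float(theta[6])
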