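"""Error metrics and residual reports.

Residuals are reference minus prediction, in kcal/mol.  MAPE is on the
percent scale and is computed only over entries whose reference
magnitude is at least 1e-10; the count of excluded entries is reported.
RMSE and RMSD denote the same quantity (root mean squared residual).
Sigma is the population standard deviation of the residuals (divide by
N), which makes sigma ~ RMSE whenever the residual mean is near zero.
"""

from __future__ import annotations

import json
from dataclasses import dataclass

import numpy as np
import pandas as pd

from edcorr.linear import MAPE_REF_FLOOR


@dataclass
class EvaluationReport:
    n: int
    mae: float
    mape: float | None
    rmse: float
    sigma: float
    residuals: np.ndarray
    n_mape_excluded: int = 0

    def summary(self) -> dict:
        return {
            "n": self.n,
            "mae": self.mae,
            "mape": self.mape,
            "rmse": self.rmse,
            "sigma": self.sigma,
            "n_mape_excluded": self.n_mape_excluded,
        }

    def save(self, json_path=None, residuals_csv=None, reaction_ids=None) -> None:
        if json_path is not None:
            with open(json_path, "w") as fh:
                json.dump(self.summary(), fh, indent=2, sort_keys=True)
                fh.write("\n")
        if residuals_csv is not None:
            frame = pd.DataFrame({"residual": self.residuals})
            if reaction_ids is not None:
                frame.insert(0, "reaction_id", list(reaction_ids))
            frame.to_csv(residuals_csv, index=False, float_format="%.17g")


def evaluate(predictions, references) -> EvaluationReport:
    """Compute MAE, MAPE, RMSE and sigma for a prediction set."""
    p = np.asarray(predictions, dtype=float)
    r = np.asarray(references, dtype=float)
    if p.shape != r.shape or p.size == 0:
        raise ValueError("predictions and references must be equal-length and non-empty")
    resid = r - p
    mae = float(np.mean(np.abs(resid)))
    rmse = float(np.sqrt(np.mean(resid * resid)))
    sigma = float(np.std(resid))  # population (ddof=0)
    ok = np.abs(r) >= MAPE_REF_FLOOR
    n_excluded = int(np.sum(~ok))
    mape = float(np.mean(np.abs(resid[ok] / r[ok])) * 100.0) if ok.any() else None
    return EvaluationReport(
        n=p.size,
        mae=mae,
        mape=mape,
        rmse=rmse,
        sigma=sigma,
        residuals=resid,
        n_mape_excluded=n_excluded,
    )
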