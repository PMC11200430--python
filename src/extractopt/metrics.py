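"""Prediction-ability statistics and the RSM-vs-ANN comparison grid.

Four statistics quantify how well a surrogate reproduces the observations:

* AAD  — absolute average deviation, (100/n) * sum |yhat_i - y_i| / y_i (%),
  the mean relative absolute error; undefined when any observation is zero.
* RMSE — root mean square error, in response units.
* SEP  — standard error of prediction, 100 * RMSE / mean(y) (%).
* R²   — 1 - SSE/SST; can be negative for predictors worse than the mean.

AAD and SEP definitions vary across the literature; the relative-to-
observation AAD and mean-relative SEP used here are fixed and documented.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

__all__ = ["aad", "rmse", "sep", "r2", "compare_models"]


def _pair(observed, predicted) -> tuple[np.ndarray, np.ndarray]:
    y = np.asarray(observed, dtype=float)
    yhat = np.asarray(predicted, dtype=float)
    if y.shape != yhat.shape or y.ndim != 1 or len(y) < 1:
        raise ValueError("observed and predicted must be equal-length 1-D arrays")
    return y, yhat


def aad(observed, predicted) -> float:
    """Absolute average deviation in percent."""
    y, yhat = _pair(observed, predicted)
    zero = np.nonzero(y == 0)[0]
    if len(zero):
        raise ValueError(f"observed value is zero at index {zero[0]}; AAD undefined")
    return float(100.0 * np.mean(np.abs(yhat - y) / y))


def rmse(observed, predicted) -> float:
    """Root mean square error in response units."""
    y, yhat = _pair(observed, predicted)
    return float(np.sqrt(np.mean((yhat - y) ** 2)))


def sep(observed, predicted) -> float:
    """Standard error of prediction: RMSE as a percentage of the observed mean."""
    y, yhat = _pair(observed, predicted)
    m = y.mean()
    if m == 0:
        raise ValueError("mean of observed values is zero; SEP undefined")
    return float(100.0 * rmse(y, yhat) / m)


def r2(observed, predicted) -> float:
    """Coefficient of determination 1 - SSE/SST (may be negative)."""
    y, yhat = _pair(observed, predicted)
    sst = float(((y - y.mean()) ** 2).sum())
    if sst == 0:
        raise ValueError("observed values have zero variance; R^2 undefined")
    return float(1.0 - ((yhat - y) ** 2).sum() / sst)


#: metric name -> (function, True when larger values are better)
_METRICS = {
    "aad_percent": (aad, False),
    "sep_percent": (sep, False),
    "rmse": (rmse, False),
    "r2": (r2, True),
}


def compare_models(
    observed: pd.DataFrame,
    rsm_pred: pd.DataFrame,
    ann_pred: pd.DataFrame,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Full metric grid for two prediction sets plus per-response verdicts.

    All three frames must share an index (run ids) and response columns.
    Returns ``(grid, verdicts)``: the grid has a (model, response) row per
    combination; verdicts name the better model per response and metric,
    or ``"tie"`` on exact equality.
    """
    responses = list(observed.columns)
    for name, df in (("rsm", rsm_pred), ("ann", ann_pred)):
        missing = set(responses) - set(df.columns)
        if missing:
            raise ValueError(f"{name} predictions missing column(s): {sorted(missing)}")

    rows = []
    for model_name, pred in (("rsm", rsm_pred), ("ann", ann_pred)):
        aligned = pred.loc[observed.index]
        for resp in responses:
            y, yhat = observed[resp].values, aligned[resp].values
            rows.append(
                {
                    "model": model_name,
                    "response": resp,
                    **{m: fn(y, yhat) for m, (fn, _) in _METRICS.items()},
                    "n": len(y),
                }
            )
    grid = pd.DataFrame(rows).set_index(["model", "response"])

    verdict_rows = []
    for resp in responses:
        row = {"response": resp}
        for m, (_, higher_better) in _METRICS.items():
            a = grid.loc[("rsm", resp), m]
            b = grid.loc[("ann", resp), m]
            if a == b:
                row[m] = "tie"
            elif (b > a) == higher_better:
                row[m] = "ann"
            else:
                row[m] = "rsm"
        verdict_rows.append(row)
    verdicts = pd.DataFrame(verdict_rows).set_index("response")
    return grid, verdicts
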