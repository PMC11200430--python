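"""Second-order response-surface fitting, ANOVA and adequacy diagnostics.

The response surface is the full quadratic polynomial in the coded factors,

    Y = b0 + sum_i bi xi + sum_i bii xi^2 + sum_{i<j} bij xi xj,

fitted by ordinary least squares: 15 terms for four factors.  Significance of
each term uses partial (Type-III) sums of squares — the increase in residual
SS when the single term is dropped from the full model — tested against the
full-model residual mean square.  Replicated center runs partition the
residual into lack-of-fit and pure error, giving the model-adequacy F test.

Adequacy statistics follow the conventions of standard DOE software:
R², adjusted R², the coefficient of variation CV% = 100·√MSE / mean(Y), and
"adequate precision", the signal-to-noise ratio

    (max ŷ − min ŷ over the design points) / √(p · MSE / n)

with p the number of model terms; values above 4 indicate the surface rises
well clear of its average prediction noise.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .design import DesignTable, FactorSpec, code_value

__all__ = [
    "QuadraticModel",
    "AnovaReport",
    "term_names",
    "model_matrix",
    "fit_quadratic",
    "predict",
    "anova",
    "adequacy",
    "coef_confint",
    "surface_grid",
]


def term_names(factor_names: list[str]) -> list[str]:
    """Canonical term order: intercept, linear, pure quadratic, interactions."""
    k = len(factor_names)
    names = ["Intercept"] + list(factor_names)
    names += [f"{f}^2" for f in factor_names]
    for i in range(k):
        for j in range(i + 1, k):
            names.append(f"{factor_names[i]}:{factor_names[j]}")
    return names


def model_matrix(coded: pd.DataFrame) -> pd.DataFrame:
    """Full second-order model matrix from coded factor columns."""
    k = coded.shape[1]
    cols = {"Intercept": np.ones(len(coded))}
    for f in coded.columns:
        cols[f] = coded[f].values
    for f in coded.columns:
        cols[f"{f}^2"] = coded[f].values ** 2
    names = list(coded.columns)
    for i in range(k):
        for j in range(i + 1, k):
            cols[f"{names[i]}:{names[j]}"] = coded[names[i]].values * coded[names[j]].values
    return pd.DataFrame(cols, index=coded.index)


@dataclass
class QuadraticModel:
    """A fitted full second-order surface on the coded scale."""

    response_name: str
    factors: tuple[FactorSpec, ...]
    scheme: str
    coef: pd.Series  # indexed by term name
    residual_df: int
    residual_mse: float

    @property
    def n_terms(self) -> int:
        return len(self.coef)

    def coef_dict(self) -> dict[str, float]:
        return {t: float(b) for t, b in self.coef.items()}


def _align_response(design: DesignTable, response: pd.Series | np.ndarray) -> np.ndarray:
    if isinstance(response, pd.Series):
        missing = design.actual.index.difference(response.index)
        if len(missing):
            raise ValueError(f"response missing run_id(s): {list(missing)}")
        y = response.loc[design.actual.index].values.astype(float)
    else:
        y = np.asarray(response, dtype=float)
        if len(y) != design.n_runs:
            raise ValueError(
                f"response length {len(y)} != design runs {design.n_runs}"
            )
    if not np.all(np.isfinite(y)):
        raise ValueError("response contains missing/non-finite values")
    return y


def fit_quadratic(
    design: DesignTable,
    response: pd.Series | np.ndarray,
    response_name: str = "Y",
) -> QuadraticModel:
    """OLS fit of the full coded quadratic; deterministic given inputs."""
    y = _align_response(design, response)
    X = model_matrix(design.coded()).values
    p = X.shape[1]
    if design.n_runs < p + 1:
        raise ValueError(
            f"{design.n_runs} runs cannot support the {p}-term quadratic "
            "with a residual degree of freedom"
        )
    if np.linalg.matrix_rank(X) < p:
        raise np.linalg.LinAlgError("rank-deficient design for the full quadratic")
    beta, _, _, _ = np.linalg.lstsq(X, y, rcond=None)
    resid = y - X @ beta
    df_resid = design.n_runs - p
    mse = float(resid @ resid) / df_resid
    names = term_names(design.factor_names)
    return QuadraticModel(
        response_name=response_name,
        factors=design.factors,
        scheme=design.scheme,
        coef=pd.Series(beta, index=names),
        residual_df=df_resid,
        residual_mse=mse,
    )


def predict(model: QuadraticModel, points: pd.DataFrame | dict) -> np.ndarray:
    """Evaluate the surface at factor settings given in actual units."""
    if isinstance(points, dict):
        points = pd.DataFrame({k: np.atleast_1d(v) for k, v in points.items()})
    unknown = set(points.columns) - {f.name for f in model.factors}
    if unknown:
        raise KeyError(f"unknown factor name(s): {sorted(unknown)}")
    coded = pd.DataFrame(
        {
            f.name: code_value(f, points[f.name].values.astype(float), model.scheme)
            for f in model.factors
        },
        index=points.index,
    )
    X = model_matrix(coded)
    return X[model.coef.index].values @ model.coef.values


@dataclass
class AnovaReport:
    """Per-term ANOVA with lack-of-fit partition and adequacy statistics."""

    response_name: str
    table: pd.DataFrame  # index=source, columns SS, df, MS, F, p, significant
    r2: float
    adj_r2: float
    cv_percent: float
    adequate_precision: float
    alpha: float

    def significant_terms(self) -> list[str]:
        t = self.table
        mask = t["significant"].fillna(False).astype(bool)
        skip = {"Model", "Residual", "Lack of fit", "Pure error", "Total"}
        return [s for s in t.index[mask] if s not in skip]


def anova(
    model: QuadraticModel,
    design: DesignTable,
    response: pd.Series | np.ndarray,
    alpha: float = 0.05,
) -> AnovaReport:
    """Partial-SS ANOVA of the full quadratic with the lack-of-fit test.

    Each term's F statistic is MS_term / MS_residual of the full model.  When
    the design carries >= 2 center replicates, pure error is estimated from
    them and the lack-of-fit F = MS_LOF / MS_PE is reported; otherwise those
    rows are omitted.
    """
    y = _align_response(design, response)
    Xdf = model_matrix(design.coded())
    X = Xdf.values
    n, p = X.shape
    beta = model.coef.values
    fitted = X @ beta
    resid = y - fitted
    ss_resid = float(resid @ resid)
    ss_total = float(((y - y.mean()) ** 2).sum())
    ss_model = ss_total - ss_resid
    df_model, df_resid = p - 1, n - p
    ms_resid = ss_resid / df_resid

    rows: dict[str, list] = {}
    f_model = (ss_model / df_model) / ms_resid
    rows["Model"] = [
        ss_model, df_model, ss_model / df_model, f_model,
        stats.f.sf(f_model, df_model, df_resid),
    ]
    # partial (Type-III) SS: refit dropping one column at a time
    for term in Xdf.columns:
        if term == "Intercept":
            continue
        Xr = Xdf.drop(columns=term).values
        br, _, _, _ = np.linalg.lstsq(Xr, y, rcond=None)
        ss_term = float(((y - Xr @ br) ** 2).sum()) - ss_resid
        f_term = (ss_term / 1) / ms_resid
        rows[term] = [ss_term, 1, ss_term, f_term, stats.f.sf(f_term, 1, df_resid)]

    rows["Residual"] = [ss_resid, df_resid, ms_resid, np.nan, np.nan]

    n_center = int(design.is_center.sum())
    if n_center >= 2:
        yc = y[design.is_center.values]
        ss_pe = float(((yc - yc.mean()) ** 2).sum())
        df_pe = n_center - 1
        ss_lof = ss_resid - ss_pe
        df_lof = df_resid - df_pe
        if df_lof > 0 and ss_pe > 0:
            f_lof = (ss_lof / df_lof) / (ss_pe / df_pe)
            p_lof = stats.f.sf(f_lof, df_lof, df_pe)
        else:
            f_lof, p_lof = np.nan, np.nan
        rows["Lack of fit"] = [ss_lof, df_lof, ss_lof / max(df_lof, 1), f_lof, p_lof]
        rows["Pure error"] = [ss_pe, df_pe, ss_pe / df_pe, np.nan, np.nan]

    rows["Total"] = [ss_total, n - 1, np.nan, np.nan, np.nan]

    table = pd.DataFrame.from_dict(
        rows, orient="index", columns=["SS", "df", "MS", "F", "p"]
    )
    table.index.name = "source"
    table["significant"] = table["p"] < alpha

    r2, adj_r2, cv, ap = adequacy(model, design, response)
    return AnovaReport(
        response_name=model.response_name,
        table=table,
        r2=r2,
        adj_r2=adj_r2,
        cv_percent=cv,
        adequate_precision=ap,
        alpha=alpha,
    )


def adequacy(
    model: QuadraticModel,
    design: DesignTable,
    response: pd.Series | np.ndarray,
) -> tuple[float, float, float, float]:
    """(R², adjusted R², CV%, adequate precision) for a fitted surface."""
    y = _align_response(design, response)
    X = model_matrix(design.coded()).values
    n, p = X.shape
    fitted = X @ model.coef.values
    ss_resid = float(((y - fitted) ** 2).sum())
    ss_total = float(((y - y.mean()) ** 2).sum())
    r2 = 1.0 - ss_resid / ss_total
    adj_r2 = 1.0 - (ss_resid / (n - p)) / (ss_total / (n - 1))
    mse = ss_resid / (n - p)
    cv = 100.0 * np.sqrt(mse) / y.mean()
    # an exact interpolation leaves only rounding noise in the residual
    if ss_resid <= 1e-16 * max(ss_total, np.finfo(float).tiny):
        ap = float("inf")
    else:
        ap = (fitted.max() - fitted.min()) / np.sqrt(p * mse / n)
    return r2, adj_r2, float(cv), float(ap)


def coef_confint(
    model: QuadraticModel,
    design: DesignTable,
    alpha: float = 0.05,
) -> pd.DataFrame:
    """Per-term OLS confidence intervals: beta +- t(1-alpha/2, df) * SE.

    Standard errors come from the diagonal of MSE * (X'X)^-1.
    """
    X = model_matrix(design.coded()).values
    cov = model.residual_mse * np.linalg.inv(X.T @ X)
    se = np.sqrt(np.diag(cov))
    tcrit = stats.t.ppf(1 - alpha / 2, model.residual_df)
    return pd.DataFrame(
        {
            "coef": model.coef.values,
            "se": se,
            "lower": model.coef.values - tcrit * se,
            "upper": model.coef.values + tcrit * se,
        },
        index=model.coef.index,
    )


def surface_grid(
    model: QuadraticModel,
    vary: tuple[str, str],
    fixed: dict[str, float],
    resolution: int = 50,
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Predictions over the coded [-1, 1]² square of two factors.

    Returns (grid_a, grid_b, Z) where grid_a/grid_b are the actual-unit axis
    values of the varied factors and Z[i, j] is the prediction at
    (grid_a[j], grid_b[i]), all other factors held at ``fixed``.
    """
    fa, fb = vary
    if fa == fb:
        raise ValueError("the two varied factors must be distinct")
    if fa in fixed or fb in fixed:
        raise ValueError("a varied factor also appears in `fixed`")
    by_name = {f.name: f for f in model.factors}
    for name in (fa, fb):
        if name not in by_name:
            raise KeyError(f"unknown factor {name!r}")

    from .design import decode_value

    coded_axis = np.linspace(-1.0, 1.0, resolution)
    axis_a = decode_value(by_name[fa], coded_axis, "affine")
    axis_b = decode_value(by_name[fb], coded_axis, "affine")
    A, B = np.meshgrid(coded_axis, coded_axis)
    coded = pd.DataFrame({fa: A.ravel(), fb: B.ravel()})
    for f in model.factors:
        if f.name not in (fa, fb):
            coded[f.name] = code_value(f, float(fixed[f.name]), model.scheme)
    coded = coded[[f.name for f in model.factors]]
    X = model_matrix(coded)
    Z = (X[model.coef.index].values @ model.coef.values).reshape(resolution, resolution)
    return axis_a, axis_b, Z
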