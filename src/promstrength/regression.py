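"""Linear modelling of promoter strength from PWM scores.

The response is the natural log of promoter strength (normalized to a
reference promoter, so strength lies in (0, 1]; a floor of 1e-4 is
applied before the log to keep weak promoters finite).  The features are
the -35 and -10 PWM scores; the fitted model is

    ln(strength) = b0 + b35 * s35 + b10 * s10

Two fitting routes are provided: exact ordinary least squares and batch
gradient descent on the mean-squared-error cost (the two must agree on
any well-conditioned problem — their fitted values correlating at ~1 is
itself a check of the optimisation).  Classical OLS inference (t and F
statistics, confidence intervals) is computed from the residual variance
and the design-matrix inverse.
"""

from __future__ import annotations

import json
import math
import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .pwm import PWM, clean_sequence

#: floor applied to normalized strength before taking the natural log
STRENGTH_FLOOR = 1e-4

MAIN_FEATURES = ("s35", "s10")


def log_strength(strength, floor: float = STRENGTH_FLOOR):
    """Natural log of max(strength, floor); floor keeps ln finite at 0."""
    if floor <= 0:
        raise ValueError("floor must be positive")
    arr = np.asarray(strength, dtype=float)
    if np.any(arr < 0):
        raise ValueError("strength must be non-negative")
    out = np.log(np.maximum(arr, floor))
    return float(out) if np.isscalar(strength) or arr.ndim == 0 else out


@dataclass
class PromoterRecord:
    """One characterized promoter: its two hexamers and normalized strength."""

    id: str
    hex35: str
    hex10: str
    strength: float

    def __post_init__(self) -> None:
        self.hex35 = clean_sequence(self.hex35, label=f"{self.id} hex35")
        self.hex10 = clean_sequence(self.hex10, label=f"{self.id} hex10")
        if self.strength < 0:
            raise ValueError(f"{self.id}: strength must be non-negative")


def feature_table(
    ids: Sequence[str],
    s35: Sequence[float],
    s10: Sequence[float],
    y: Sequence[float],
) -> pd.DataFrame:
    """Assemble the (id, s35, s10, y) regression table, y = ln strength."""
    df = pd.DataFrame({"id": list(ids), "s35": s35, "s10": s10, "y": y})
    if df[["s35", "s10", "y"]].isna().any().any():
        raise ValueError("feature table contains missing values")
    return df


def featurize(
    records: Sequence[PromoterRecord],
    pwm35: PWM,
    pwm10: PWM,
    floor: float = STRENGTH_FLOOR,
) -> pd.DataFrame:
    """Score each record's hexamers and log-transform its strength."""
    rows = []
    for rec in records:
        try:
            rows.append(
                (rec.id, pwm35.score(rec.hex35), pwm10.score(rec.hex10),
                 log_strength(rec.strength, floor=floor))
            )
        except ValueError as exc:
            raise ValueError(f"record {rec.id}: {exc}") from exc
    if not rows:
        return pd.DataFrame(columns=["id", "s35", "s10", "y"])
    ids, a, b, y = zip(*rows)
    return feature_table(ids, a, b, y)


@dataclass
class RegressionFit:
    """Fitted linear model: intercept plus one slope per feature."""

    feature_names: tuple[str, ...]
    intercept: float
    slopes: np.ndarray
    fit_method: str = "ols"
    learning_rate: float | None = None
    iterations: int | None = None
    feature_scaling: bool = False
    final_cost: float | None = None
    cost_trajectory: np.ndarray | None = field(default=None, repr=False)

    def __post_init__(self) -> None:
        self.slopes = np.asarray(self.slopes, dtype=float)
        if not (math.isfinite(self.intercept) and np.all(np.isfinite(self.slopes))):
            raise ValueError("non-finite coefficients")

    def slope(self, name: str) -> float:
        return float(self.slopes[self.feature_names.index(name)])

    @property
    def beta35(self) -> float:
        return self.slope("s35")

    @property
    def beta10(self) -> float:
        return self.slope("s10")

    def coefficients(self) -> dict[str, float]:
        d = {"intercept": self.intercept}
        d.update({n: float(b) for n, b in zip(self.feature_names, self.slopes)})
        return d

    def predict_table(self, table: pd.DataFrame) -> np.ndarray:
        X = table[list(self.feature_names)].to_numpy(dtype=float)
        return self.intercept + X @ self.slopes

    def to_dict(self) -> dict:
        return {
            "feature_names": list(self.feature_names),
            "intercept": self.intercept,
            "slopes": self.slopes.tolist(),
            "fit_method": self.fit_method,
            "learning_rate": self.learning_rate,
            "iterations": self.iterations,
            "feature_scaling": self.feature_scaling,
        }

    @classmethod
    def from_dict(cls, d: dict) -> "RegressionFit":
        return cls(
            feature_names=tuple(d["feature_names"]),
            intercept=float(d["intercept"]),
            slopes=np.array(d["slopes"], dtype=float),
            fit_method=d.get("fit_method", "ols"),
            learning_rate=d.get("learning_rate"),
            iterations=d.get("iterations"),
            feature_scaling=bool(d.get("feature_scaling", False)),
        )


def _design(table: pd.DataFrame, features: Sequence[str], response: str):
    X = np.column_stack(
        [np.ones(len(table))] + [table[f].to_numpy(dtype=float) for f in features]
    )
    y = table[response].to_numpy(dtype=float)
    return X, y


def fit_ols(
    table: pd.DataFrame,
    features: Sequence[str] = MAIN_FEATURES,
    response: str = "y",
) -> RegressionFit:
    """Exact least-squares fit (with intercept) via a rank-revealing solve."""
    m = len(features)
    n = len(table)
    if n < m + 2:
        raise ValueError(f"need at least {m + 2} rows to fit {m} features, got {n}")
    X, y = _design(table, features, response)
    if np.linalg.matrix_rank(X) < X.shape[1]:
        raise ValueError("collinear features: design matrix is rank-deficient")
    beta, *_ = np.linalg.lstsq(X, y, rcond=None)
    return RegressionFit(
        feature_names=tuple(features),
        intercept=float(beta[0]),
        slopes=beta[1:],
        fit_method="ols",
    )


def fit_gradient_descent(
    table: pd.DataFrame,
    learning_rate: float = 0.015,
    iterations: int = 100_000,
    feature_scaling: bool = False,
    features: Sequence[str] = MAIN_FEATURES,
    response: str = "y",
    keep_cost_every: int = 100,
) -> RegressionFit:
    """Batch gradient descent on the mean-squared-error cost.

    Coefficients start at zero and follow ``beta -= lr * X'(X beta - y)/n``.
    With ``feature_scaling`` the features are standardized internally and
    the coefficients mapped back, which permits much larger learning
    rates.  The run is deterministic; the cost is recorded every
    ``keep_cost_every`` steps and a sustained cost increase over 100
    consecutive steps aborts with advice to reduce the rate or scale.
    """
    if learning_rate <= 0:
        raise ValueError("learning_rate must be positive")
    iterations = int(iterations)
    X, y = _design(table, features, response)
    n = len(y)
    mu = X[:, 1:].mean(axis=0)
    sd = X[:, 1:].std(axis=0)
    if feature_scaling:
        if np.any(sd == 0):
            raise ValueError("collinear features: constant column cannot be scaled")
        X = X.copy()
        X[:, 1:] = (X[:, 1:] - mu) / sd

    divergence = ValueError(
        "gradient descent is diverging; reduce learning_rate or enable feature_scaling"
    )
    beta = np.zeros(X.shape[1])
    costs = []
    prev_cost = math.inf
    rising = 0
    with np.errstate(over="ignore", invalid="ignore"):
        for it in range(iterations):
            resid = X @ beta - y
            cost = float(resid @ resid) / (2 * n)
            if not math.isfinite(cost):
                raise divergence
            if cost > prev_cost:
                rising += 1
                if rising >= 100:
                    raise divergence
            else:
                rising = 0
            prev_cost = cost
            if it % keep_cost_every == 0:
                costs.append(cost)
            beta -= learning_rate * (X.T @ resid) / n

    resid = X @ beta - y
    final_cost = float(resid @ resid) / (2 * n)
    costs.append(final_cost)
    if feature_scaling:
        slopes = beta[1:] / sd
        intercept = beta[0] - float(slopes @ mu)
    else:
        slopes = beta[1:]
        intercept = beta[0]
    return RegressionFit(
        feature_names=tuple(features),
        intercept=float(intercept),
        slopes=slopes,
        fit_method="gradient_descent",
        learning_rate=learning_rate,
        iterations=iterations,
        feature_scaling=feature_scaling,
        final_cost=final_cost,
        cost_trajectory=np.array(costs),
    )


def adjusted_r2(r2: float, n: int, m: int) -> float:
    """Complexity-penalized coefficient of determination,
    1 - (1 - R^2)(n - 1)/(n - m - 1)."""
    if n <= m + 1:
        raise ValueError(f"need n > m + 1 (got n={n}, m={m})")
    return 1.0 - (1.0 - r2) * (n - 1) / (n - m - 1)


@dataclass
class ModelStats:
    """Classical OLS inference for a fitted linear model."""

    n: int
    m: int
    r2: float
    adj_r2: float
    f_statistic: float
    f_pvalue: float
    level: float
    params: pd.DataFrame  # index: intercept + features; columns: coef, se, t, p, ci_low, ci_high

    def ci(self, name: str) -> tuple[float, float]:
        row = self.params.loc[name]
        return float(row["ci_low"]), float(row["ci_high"])


def model_stats(fit: RegressionFit, table: pd.DataFrame, level: float = 0.95,
                response: str = "y") -> ModelStats:
    """t/F statistics, p-values and confidence intervals for a fit.

    Standard errors come from the residual variance and the diagonal of
    (X'X)^-1 with n - m - 1 degrees of freedom; the F statistic tests all
    slopes jointly against the intercept-only model.
    """
    X, y = _design(table, fit.feature_names, response)
    n, p = X.shape
    m = p - 1
    df = n - m - 1
    if df <= 0:
        raise ValueError("not enough residual degrees of freedom")
    beta = np.concatenate([[fit.intercept], fit.slopes])
    resid = y - X @ beta
    rss = float(resid @ resid)
    tss = float(((y - y.mean()) ** 2).sum())
    r2 = 1.0 - rss / tss if tss > 0 else 1.0
    sigma2 = rss / df
    if sigma2 <= 1e-20 * max(1.0, float(y @ y) / n):  # numerically exact fit
        sigma2 = 0.0
        warnings.warn("zero residual variance: t statistics are infinite", RuntimeWarning)
    cov = sigma2 * np.linalg.inv(X.T @ X)
    se = np.sqrt(np.diag(cov))
    with np.errstate(divide="ignore", invalid="ignore"):
        tvals = np.where(se > 0, beta / se, np.sign(beta) * np.inf)
    pvals = 2 * stats.t.sf(np.abs(tvals), df)
    tcrit = stats.t.ppf(0.5 + level / 2, df)
    if sigma2 > 0:
        f_stat = (tss - rss) / m / sigma2
        f_p = float(stats.f.sf(f_stat, m, df))
    else:
        f_stat, f_p = math.inf, 0.0
    params = pd.DataFrame(
        {
            "coef": beta,
            "se": se,
            "t": tvals,
            "p": pvals,
            "ci_low": beta - tcrit * se,
            "ci_high": beta + tcrit * se,
        },
        index=["intercept", *fit.feature_names],
    )
    return ModelStats(
        n=n, m=m, r2=r2, adj_r2=adjusted_r2(r2, n, m),
        f_statistic=float(f_stat), f_pvalue=f_p, level=level, params=params,
    )


def predict_log_strength(fit: RegressionFit, s35: float, s10: float) -> float:
    """Linear predictor b0 + b35*s35 + b10*s10 on the ln(strength) scale."""
    return float(fit.intercept + fit.beta35 * s35 + fit.beta10 * s10)


def predict_strength(fit: RegressionFit, s35: float, s10: float) -> float:
    """exp of the linear predictor.  Values above 1 mean the query is
    predicted stronger than the reference promoter and are reported as-is."""
    return float(math.exp(predict_log_strength(fit, s35, s10)))


@dataclass
class VariantComparison:
    """Side-by-side fits of the main model and its variants."""

    fits: dict[str, RegressionFit]
    stats: dict[str, ModelStats]
    summary: pd.DataFrame  # index: model; columns: response, features, r2, adj_r2


def fit_variant_models(table: pd.DataFrame, strengths: Sequence[float] | None = None) -> VariantComparison:
    """Fit the main two-feature model plus three diagnostics variants.

    * ``interaction``  — ln(strength) ~ s35 + s10 + s35:s10
    * ``combined``     — ln(strength) ~ (s35 + s10), a single summed score
    * ``raw_strength`` — un-logged strength ~ s35 + s10

    ``strengths`` supplies the raw response for ``raw_strength``;
    by default it is recovered as exp(y).
    """
    work = table.copy()
    work["s35s10"] = work["s35"] * work["s10"]
    work["combined"] = work["s35"] + work["s10"]
    work["strength"] = (
        np.asarray(strengths, dtype=float) if strengths is not None else np.exp(work["y"])
    )
    specs = {
        "main": (("s35", "s10"), "y"),
        "interaction": (("s35", "s10", "s35s10"), "y"),
        "combined": (("combined",), "y"),
        "raw_strength": (("s35", "s10"), "strength"),
    }
    fits, allstats, rows = {}, {}, []
    for name, (features, response) in specs.items():
        fit = fit_ols(work, features=features, response=response)
        st = model_stats(fit, work, response=response)
        fits[name] = fit
        allstats[name] = st
        rows.append((name, response, "+".join(features), st.r2, st.adj_r2))
    summary = pd.DataFrame(
        rows, columns=["model", "response", "features", "r2", "adj_r2"]
    ).set_index("model")
    return VariantComparison(fits=fits, stats=allstats, summary=summary)


def save_model(fit: RegressionFit, path: str | Path, stats: ModelStats | None = None,
               provenance: str | None = None) -> None:
    doc = {"model": fit.to_dict()}
    if stats is not None:
        doc["stats"] = {
            "n": stats.n, "m": stats.m, "r2": stats.r2, "adj_r2": stats.adj_r2,
            "f_statistic": stats.f_statistic, "f_pvalue": stats.f_pvalue,
            "level": stats.level,
            "params": stats.params.reset_index().rename(columns={"index": "term"}).to_dict(
                orient="records"
            ),
        }
    if provenance:
        doc["provenance"] = provenance
    Path(path).write_text(json.dumps(doc, indent=1))


def load_model(path: str | Path) -> RegressionFit:
    doc = json.loads(Path(path).read_text())
    return RegressionFit.from_dict(doc["model"])
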