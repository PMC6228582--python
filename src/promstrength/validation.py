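"""Model validation: LOOCV, random-promoter baseline, correlations, diagnostics.

Leave-one-out cross-validation refits the regression once per held-out
promoter; the observed-vs-predicted correlation summarizes out-of-sample
skill.  The random baseline scores uniformly random hexamer pairs to
check that the model assigns near-zero strength to non-promoter
sequence.  Diagnostics emit the four standard linear-model plot datasets
(residuals vs fitted, scale-location, normal Q-Q, residuals vs
leverage) as plain tables.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .pwm import BASES, PWM
from .regression import (
    ModelStats,
    RegressionFit,
    _design,
    fit_ols,
    predict_strength,
)


@dataclass
class CVResult:
    """Per-fold LOOCV predictions and their summary correlation."""

    table: pd.DataFrame  # fold, s35, s10, combined, observed, cvpred, cvres
    correlation: float

    def write_tsv(self, path: str | Path) -> None:
        self.table.to_csv(path, sep="\t", index=False)


def loocv(
    table: pd.DataFrame,
    features: Sequence[str] = ("s35", "s10"),
    response: str = "y",
) -> CVResult:
    """Leave-one-out cross-validation by explicit refitting.

    Fold ``i`` (1-based, input order) trains on the other n-1 rows and
    predicts row ``i``; ``cvres = observed - cvpred``.
    """
    n = len(table)
    if n < 5:
        raise ValueError(f"need at least 5 rows for LOOCV, got {n}")
    rows = []
    for i in range(n):
        train = table.drop(table.index[i])
        try:
            fit = fit_ols(train, features=features, response=response)
        except ValueError as exc:
            raise ValueError(f"fold {i + 1}: {exc}") from exc
        held = table.iloc[[i]]
        cvpred = float(fit.predict_table(held)[0])
        obs = float(held[response].iloc[0])
        rows.append(
            (i + 1, *[float(held[f].iloc[0]) for f in features], obs, cvpred, obs - cvpred)
        )
    cols = ["fold", *features, "observed", "cvpred", "cvres"]
    df = pd.DataFrame(rows, columns=cols)
    if set(features) == {"s35", "s10"}:
        df.insert(3, "combined", df["s35"] + df["s10"])
    corr = float(np.corrcoef(df["observed"], df["cvpred"])[0, 1])
    return CVResult(table=df, correlation=corr)


def loocv_shortcut(table: pd.DataFrame, features: Sequence[str] = ("s35", "s10"),
                   response: str = "y") -> np.ndarray:
    """Closed-form LOOCV residuals, resid_i / (1 - leverage_i).

    Algebraically identical to refitting for OLS; kept as an independent
    route for cross-checking :func:`loocv`.
    """
    fit = fit_ols(table, features=features, response=response)
    X, y = _design(table, fit.feature_names, response)
    hat = X @ np.linalg.inv(X.T @ X) @ X.T
    resid = y - X @ np.concatenate([[fit.intercept], fit.slopes])
    return resid / (1.0 - np.diag(hat))


def random_hexamers(n: int, seed: int) -> list[tuple[str, str]]:
    """n random (-35, -10) hexamer pairs, bases i.i.d. uniform on {A,C,G,T}."""
    if n <= 0:
        raise ValueError("n must be positive")
    rng = np.random.default_rng(seed)
    letters = rng.integers(0, 4, size=(n, 2, 6))
    return [
        ("".join(BASES[k] for k in pair[0]), "".join(BASES[k] for k in pair[1]))
        for pair in letters
    ]


@dataclass
class BaselineSummary:
    """Sampling distribution of mean predicted strength of random promoters."""

    set_means: np.ndarray
    mean: float
    standard_error: float
    n_sets: int
    set_size: int
    seed: int

    def to_json(self, path: str | Path) -> None:
        Path(path).write_text(
            json.dumps(
                {
                    "mean": self.mean,
                    "standard_error": self.standard_error,
                    "n_sets": self.n_sets,
                    "set_size": self.set_size,
                    "seed": self.seed,
                    "set_means": self.set_means.tolist(),
                },
                indent=1,
            )
        )


def random_baseline(
    fit: RegressionFit,
    pwm35: PWM,
    pwm10: PWM,
    n_sets: int = 100,
    set_size: int = 100,
    seed: int = 0,
) -> BaselineSummary:
    """Predicted strength of random hexamer pairs, summarized over sets.

    Each of ``n_sets`` sets holds ``set_size`` uniformly random pairs;
    the grand mean of the per-set mean strengths estimates the expected
    strength of a non-promoter, with standard error
    sd(set means)/sqrt(n_sets).
    """
    pairs = random_hexamers(n_sets * set_size, seed=seed)
    preds = np.array(
        [predict_strength(fit, pwm35.score(h35), pwm10.score(h10)) for h35, h10 in pairs]
    )
    set_means = preds.reshape(n_sets, set_size).mean(axis=1)
    se = float(set_means.std(ddof=1) / math.sqrt(n_sets)) if n_sets > 1 else 0.0
    return BaselineSummary(
        set_means=set_means,
        mean=float(set_means.mean()),
        standard_error=se,
        n_sets=n_sets,
        set_size=set_size,
        seed=seed,
    )


def correlation_matrix(table: pd.DataFrame, strengths: Sequence[float] | None = None) -> pd.DataFrame:
    """Pearson correlations among the two PWM scores, their sum, the raw
    strength and the log strength (5x5, unit diagonal)."""
    if len(table) < 3:
        raise ValueError("need at least 3 rows")
    raw = np.asarray(strengths, dtype=float) if strengths is not None else np.exp(
        table["y"].to_numpy()
    )
    df = pd.DataFrame(
        {
            "PWM_35": table["s35"].to_numpy(dtype=float),
            "PWM_10": table["s10"].to_numpy(dtype=float),
            "combined": table["s35"].to_numpy(dtype=float) + table["s10"].to_numpy(dtype=float),
            "strength": raw,
            "log_strength": table["y"].to_numpy(dtype=float),
        }
    )
    return df.corr(method="pearson")


@dataclass
class DiagnosticsReport:
    """Datasets behind the four standard linear-model diagnostic plots."""

    table: pd.DataFrame  # id, fitted, residual, std_residual, sqrt_abs_std_residual, leverage
    qq: pd.DataFrame  # theoretical, sample (ordered standardized residuals)

    def write_tsv(self, prefix: str | Path) -> None:
        prefix = str(prefix)
        self.table.to_csv(prefix + ".diagnostics.tsv", sep="\t", index=False)
        self.qq.to_csv(prefix + ".qq.tsv", sep="\t", index=False)


def diagnostics(fit: RegressionFit, table: pd.DataFrame, response: str = "y") -> DiagnosticsReport:
    """Fitted values, residuals, internally studentized residuals, leverages,
    and normal Q-Q pairs using the (i - 0.5)/n plotting position."""
    X, y = _design(table, fit.feature_names, response)
    n, p = X.shape
    beta = np.concatenate([[fit.intercept], fit.slopes])
    fitted = X @ beta
    resid = y - fitted
    hat = X @ np.linalg.inv(X.T @ X) @ X.T
    lev = np.diag(hat)
    sigma2 = float(resid @ resid) / (n - p)
    denom = np.sqrt(sigma2 * (1.0 - lev))
    with np.errstate(divide="ignore", invalid="ignore"):
        std_resid = np.where(denom > 0, resid / denom, 0.0)
    ids = table["id"].to_numpy() if "id" in table.columns else np.arange(1, n + 1)
    report = pd.DataFrame(
        {
            "id": ids,
            "fitted": fitted,
            "residual": resid,
            "std_residual": std_resid,
            "sqrt_abs_std_residual": np.sqrt(np.abs(std_resid)),
            "leverage": lev,
        }
    )
    order = np.argsort(std_resid)
    qq = pd.DataFrame(
        {
            "theoretical": stats.norm.ppf((np.arange(1, n + 1) - 0.5) / n),
            "sample": std_resid[order],
        }
    )
    return DiagnosticsReport(table=report, qq=qq)
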