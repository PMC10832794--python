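"""GPP regression models, validation metrics, stratification and aggregation.

Half-hourly matched samples (09:00-15:00) pair eddy-covariance GPP with
the BRDF-hotspot and two-leaf total-canopy PRI/SIF of the same half hour.
Six ordinary-least-squares models are built — PRI-only, SIF-only and
PRI+SIF, each in a hotspot ('hs') and total-canopy ('tot') variant — on a
modeling/validation split by day of year. Validation reports carry R2,
RMSE = sqrt(mean((obs - pred)^2)) and the relative prediction deviation
RPD = SD(observations) / RMSE (RPD > 2: strong model). A stratified
analysis bins samples by LAI, air temperature and VPD and reports the
univariate R2 of GPP on each index per bin with F-test significance stars.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import statsmodels.api as sm

__all__ = [
    "GPPModelFit",
    "EvaluationReport",
    "SplitError",
    "EvaluationError",
    "split_dataset",
    "fit_gpp_model",
    "evaluate_model",
    "stratified_r2",
    "aggregate_daily",
    "rmse",
    "DEFAULT_BINS",
    "CLOUDY_PAR_THRESHOLD",
]

#: Daily-mean PAR (umol m-2 s-1) below which a day is classed cloudy.
CLOUDY_PAR_THRESHOLD = 1000.0

#: Default stratification bin edges (open-ended outer bins).
DEFAULT_BINS = {
    "lai": [6.0, 7.0],
    "t_air": [25.0, 30.0],
    "vpd": [2.0, 3.0],
}


class SplitError(ValueError):
    """Modeling/validation split is empty on one side."""


class EvaluationError(ValueError):
    """Validation set too small to evaluate."""


@dataclass
class GPPModelFit:
    """One fitted OLS GPP model (with intercept)."""

    predictors: tuple[str, ...]
    variant: str  # 'hs' or 'tot'
    coefficients: dict[str, float]
    intercept: float
    r2: float
    rmse: float
    f_stat: float
    f_pvalue: float
    n: int

    def predict(self, samples: pd.DataFrame) -> np.ndarray:
        cols = [f"{p}_{self.variant}" for p in self.predictors]
        x = samples[cols].to_numpy(dtype=float)
        beta = np.array([self.coefficients[c] for c in cols])
        return x @ beta + self.intercept


@dataclass
class EvaluationReport:
    """Out-of-sample metrics; rpd = sd_validation / rmse."""

    r2: float
    rmse: float
    rpd: float
    sd_validation: float
    n_validation: int


def rmse(observed, predicted) -> float:
    """Root-mean-square error with the 1/n convention."""
    o = np.asarray(observed, dtype=float)
    p = np.asarray(predicted, dtype=float)
    return float(np.sqrt(np.mean((o - p) ** 2)))


def split_dataset(
    samples: pd.DataFrame, validation_doys: list[int]
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Disjoint, exhaustive split by day of year.

    Rows whose ``doy`` is in ``validation_doys`` form the validation set.
    """
    if "doy" not in samples.columns:
        raise ValueError("samples must carry a 'doy' column")
    mask = samples["doy"].isin(validation_doys)
    validation = samples[mask]
    modeling = samples[~mask]
    if len(validation) == 0:
        raise SplitError("validation set is empty")
    if len(modeling) == 0:
        raise SplitError("modeling set is empty")
    return modeling, validation


def fit_gpp_model(
    modeling: pd.DataFrame,
    predictors: tuple[str, ...] = ("pri", "sif"),
    variant: str = "tot",
) -> GPPModelFit:
    """OLS of GPP on the chosen predictor set with intercept.

    ``predictors`` is a subset of {'pri', 'sif'}; ``variant`` selects the
    hotspot or total-canopy columns (e.g. 'sif_tot'). Reports in-sample
    R2, RMSE and the regression F statistic.
    """
    cols = [f"{p}_{variant}" for p in predictors]
    df = modeling.dropna(subset=["gpp", *cols])
    if len(df) < 3:
        raise ValueError("need >= 3 complete rows to fit a GPP model")
    x = sm.add_constant(df[cols].to_numpy(dtype=float), has_constant="add")
    y = df["gpp"].to_numpy(dtype=float)
    if np.linalg.matrix_rank(x) < x.shape[1]:
        raise np.linalg.LinAlgError("constant predictor: rank-deficient design")
    res = sm.OLS(y, x).fit()
    coefficients = {c: float(b) for c, b in zip(cols, res.params[1:])}
    r2 = float(res.rsquared) if np.var(y) > 0 else 0.0  # constant response
    return GPPModelFit(
        predictors=tuple(predictors),
        variant=variant,
        coefficients=coefficients,
        intercept=float(res.params[0]),
        r2=r2,
        rmse=rmse(y, res.fittedvalues),
        f_stat=float(res.fvalue),
        f_pvalue=float(res.f_pvalue),
        n=len(df),
    )


def evaluate_model(fit: GPPModelFit, validation: pd.DataFrame) -> EvaluationReport:
    """Out-of-sample R2, RMSE and RPD = SD(validation GPP)/RMSE.

    SD uses the sample (n-1) convention; a perfect fit (RMSE = 0) yields
    an infinite RPD.
    """
    cols = [f"{p}_{fit.variant}" for p in fit.predictors]
    df = validation.dropna(subset=["gpp", *cols])
    if len(df) < 2:
        raise EvaluationError("need >= 2 validation rows (SD undefined otherwise)")
    obs = df["gpp"].to_numpy(dtype=float)
    pred = fit.predict(df)
    err = rmse(obs, pred)
    sd = float(np.std(obs, ddof=1))
    ss_res = float(np.sum((obs - pred) ** 2))
    ss_tot = float(np.sum((obs - obs.mean()) ** 2))
    r2 = 1.0 - ss_res / ss_tot if ss_tot > 0 else np.nan
    rpd = sd / err if err > 0 else float("inf")
    return EvaluationReport(
        r2=r2, rmse=err, rpd=rpd, sd_validation=sd, n_validation=len(df)
    )


def _bin_labels(edges: list[float], unit: str = "") -> list[str]:
    labels = [f"<{edges[0]:g}"]
    labels += [f"{a:g}-{b:g}" for a, b in zip(edges[:-1], edges[1:])]
    labels += [f">{edges[-1]:g}"]
    return labels


def stratified_r2(
    samples: pd.DataFrame,
    index_name: str,
    bins: dict[str, list[float]] | None = None,
) -> pd.DataFrame:
    """Per-bin univariate R2 of GPP on one index, with significance stars.

    ``bins`` maps a stratifying column (e.g. 'lai', 't_air', 'vpd') to its
    interior edges; outer bins are open-ended. Stars come from the F test
    of the univariate regression: '*' p < 0.05, '**' p < 0.01. Bins with
    fewer than 3 samples report undefined R2 rather than raising.
    """
    if bins is None:
        bins = DEFAULT_BINS
    rows = []
    for factor, edges in bins.items():
        if list(edges) != sorted(edges) or len(set(edges)) != len(edges):
            raise ValueError(f"bin edges for {factor!r} must be strictly increasing")
        full_edges = [-np.inf, *edges, np.inf]
        labels = _bin_labels(list(edges))
        cat = pd.cut(samples[factor], bins=full_edges, labels=labels)
        for label in labels:
            sub = samples[cat == label].dropna(subset=["gpp", index_name])
            if len(sub) < 3 or sub[index_name].nunique() < 2:
                rows.append(
                    {"factor": factor, "interval": label, "index": index_name,
                     "n": len(sub), "r2": np.nan, "stars": ""}
                )
                continue
            x = sm.add_constant(sub[index_name].to_numpy(dtype=float))
            res = sm.OLS(sub["gpp"].to_numpy(dtype=float), x).fit()
            p = float(res.f_pvalue)
            stars = "**" if p < 0.01 else ("*" if p < 0.05 else "")
            rows.append(
                {"factor": factor, "interval": label, "index": index_name,
                 "n": len(sub), "r2": float(res.rsquared), "stars": stars}
            )
    return pd.DataFrame(rows)


def aggregate_daily(samples: pd.DataFrame) -> pd.DataFrame:
    """Per-day mean and standard error of GPP, indices and PAR.

    Adds a sky class: 'cloudy' when the daily mean PAR falls below
    1,000 umol m-2 s-1, else 'clear'.
    """
    value_cols = [
        c
        for c in ("gpp", "pri_hs", "pri_tot", "sif_hs", "sif_tot", "par")
        if c in samples.columns
    ]
    g = samples.groupby("doy")[value_cols]
    daily = g.mean().add_suffix("_mean")
    se = g.sem(ddof=1).add_suffix("_se")
    out = daily.join(se).reset_index()
    if "par_mean" in out.columns:
        out["sky"] = np.where(
            out["par_mean"] < CLOUDY_PAR_THRESHOLD, "cloudy", "clear"
        )
    return out
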