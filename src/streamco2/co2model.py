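"""Empirical streamwater CO2 regression.

Streamwater CO2 concentration (umol L^-1) is modelled as a log-linear
function of mean channel elevation (m a.s.l.), annual mean discharge
(m3 s^-1) and soil organic carbon content (g kg^-1):

    ln(CO2) = b_E ln(E) + b_Q ln(Q) + b_SOC ln(SOC) + b0

The default coefficients are the published fit to 323 direct
measurements from mountain streams (R^2 = 0.39); refitting is supported
on synthetic calibration sets. The response unit is taken as umol L^-1,
consistent with the groundwater mass balance and with predictions that
convert to pCO2 values in the few-hundred-uatm range typical of
turbulent mountain streams.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
import statsmodels.api as sm

#: Column schema for calibration tables (CSV header).
CALIBRATION_COLUMNS = ("elevation_m", "discharge_m3s", "soc_gkg", "co2_umol_l")

#: Published proportion of variance explained by the regression.
PUBLISHED_R2 = 0.39

#: Default log-uniform covariate ranges for synthetic calibration sets:
#: elevation spans the mountain-stream band, discharge the validity range
#: of the hydraulic geometry, SOC a typical alpine-soil span.
DEFAULT_COVARIATE_RANGES: Mapping[str, tuple[float, float]] = {
    "elevation_m": (500.0, 4938.0),
    "discharge_m3s": (0.001, 2.26),
    "soc_gkg": (10.0, 200.0),
}


@dataclass(frozen=True)
class CO2RegressionModel:
    """Coefficients (and standard errors) of the ln-scale CO2 regression."""

    beta_ln_elevation: float = -0.647
    beta_ln_discharge: float = -0.094
    beta_ln_soc: float = 0.099
    intercept: float = 7.287
    se_ln_elevation: float = 0.052
    se_ln_discharge: float = 0.014
    se_ln_soc: float = 0.029
    se_intercept: float = 0.427
    #: ln-scale residual standard deviation; None until set or fitted.
    residual_sd: float | None = None

    def with_residual_sd(self, sd: float) -> "CO2RegressionModel":
        if sd < 0:
            raise ValueError("residual_sd must be non-negative")
        return replace(self, residual_sd=sd)


@dataclass(frozen=True)
class FitReport:
    """Goodness-of-fit summary returned alongside a refitted model."""

    r_squared: float
    n: int
    residual_sd: float
    standard_errors: dict = field(default_factory=dict)


DEFAULT_CO2_MODEL = CO2RegressionModel()


def predict_co2(elevation, discharge, soc, model: CO2RegressionModel = DEFAULT_CO2_MODEL):
    """Predicted streamwater CO2 concentration, umol L^-1.

    Strictly decreasing in elevation and discharge, increasing in SOC
    (for the default coefficient signs). All covariates must be
    strictly positive.
    """
    e = np.asarray(elevation, dtype=float)
    q = np.asarray(discharge, dtype=float)
    s = np.asarray(soc, dtype=float)
    if np.any(e <= 0) or np.any(q <= 0) or np.any(s <= 0):
        raise ValueError("elevation, discharge and SOC must be strictly positive")
    ln_pred = (
        model.beta_ln_elevation * np.log(e)
        + model.beta_ln_discharge * np.log(q)
        + model.beta_ln_soc * np.log(s)
        + model.intercept
    )
    out = np.exp(ln_pred)
    if np.ndim(elevation) == 0 and np.ndim(discharge) == 0 and np.ndim(soc) == 0:
        return float(out)
    return out


def sample_co2(
    elevation,
    discharge,
    soc,
    model: CO2RegressionModel,
    rng: np.random.Generator,
    size: int | tuple | None = None,
):
    """Draw CO2 concentrations with lognormal residual noise.

    Multiplies the point prediction by ``exp(eps)`` with
    ``eps ~ Normal(0, residual_sd)`` on the ln scale. Deterministic for
    a fixed generator state.
    """
    if model.residual_sd is None:
        raise ValueError(
            "model.residual_sd is not set; use with_residual_sd() or "
            "residual_sd_for_r2()"
        )
    pred = predict_co2(elevation, discharge, soc, model)
    shape = np.shape(pred) if size is None else size
    eps = rng.normal(0.0, model.residual_sd, size=shape)
    return pred * np.exp(eps)


def fit_co2_model(
    observations: pd.DataFrame, min_n: int = 10
) -> tuple[CO2RegressionModel, FitReport]:
    """Refit the ln-linear CO2 regression by ordinary least squares.

    ``observations`` must carry the calibration columns
    (elevation_m, discharge_m3s, soc_gkg, co2_umol_l), all positive.
    Returns the fitted model (residual_sd set to the OLS residual
    standard deviation) and a report with R^2, n and coefficient
    standard errors.
    """
    missing = [c for c in CALIBRATION_COLUMNS if c not in observations.columns]
    if missing:
        raise ValueError(f"calibration table is missing columns: {missing}")
    n = len(observations)
    if n < min_n:
        raise ValueError(f"need at least {min_n} observations, got {n}")
    vals = observations[list(CALIBRATION_COLUMNS)].to_numpy(dtype=float)
    if np.any(vals <= 0):
        raise ValueError("all calibration values must be strictly positive")

    y = np.log(vals[:, 3])
    x = sm.add_constant(np.log(vals[:, :3]), has_constant="add")
    rank = np.linalg.matrix_rank(x)
    if rank < x.shape[1]:
        raise ValueError("rank-deficient design matrix; covariates are collinear")
    res = sm.OLS(y, x).fit()
    residual_sd = float(np.sqrt(res.scale)) if res.df_resid > 0 else 0.0
    model = CO2RegressionModel(
        intercept=float(res.params[0]),
        beta_ln_elevation=float(res.params[1]),
        beta_ln_discharge=float(res.params[2]),
        beta_ln_soc=float(res.params[3]),
        se_intercept=float(res.bse[0]),
        se_ln_elevation=float(res.bse[1]),
        se_ln_discharge=float(res.bse[2]),
        se_ln_soc=float(res.bse[3]),
        residual_sd=residual_sd,
    )
    report = FitReport(
        r_squared=float(res.rsquared),
        n=n,
        residual_sd=residual_sd,
        standard_errors={
            "intercept": float(res.bse[0]),
            "beta_ln_elevation": float(res.bse[1]),
            "beta_ln_discharge": float(res.bse[2]),
            "beta_ln_soc": float(res.bse[3]),
        },
    )
    return model, report


def residual_sd_for_r2(
    target_r2: float = PUBLISHED_R2,
    covariate_ranges: Mapping[str, tuple[float, float]] = DEFAULT_COVARIATE_RANGES,
    model: CO2RegressionModel = DEFAULT_CO2_MODEL,
) -> float:
    """ln-scale residual sd implied by a target R^2 under log-uniform covariates.

    With independent covariates log-uniform over ``covariate_ranges``,
    each ln-covariate is uniform with variance (ln(hi) - ln(lo))^2 / 12,
    so the variance of the linear predictor is the coefficient-weighted
    sum, and R^2 = var_model / (var_model + sd^2) gives
    ``sd = sqrt(var_model * (1 - R^2) / R^2)``.
    """
    if not 0 < target_r2 < 1:
        raise ValueError("target_r2 must lie in (0, 1)")
    betas = {
        "elevation_m": model.beta_ln_elevation,
        "discharge_m3s": model.beta_ln_discharge,
        "soc_gkg": model.beta_ln_soc,
    }
    var_model = 0.0
    for name, beta in betas.items():
        lo, hi = covariate_ranges[name]
        if not 0 < lo < hi:
            raise ValueError(f"invalid range for {name}: ({lo}, {hi})")
        var_ln = (math.log(hi) - math.log(lo)) ** 2 / 12.0
        var_model += beta**2 * var_ln
    return math.sqrt(var_model * (1.0 - target_r2) / target_r2)
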