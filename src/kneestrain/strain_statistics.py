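"""Statistical pipeline relating landing kinematics to peak ACL strain.

The pipeline mirrors a standard biomechanics workflow:

1. z-normalize peak strains across the cohort,
2. screen candidate sagittal-plane predictors with bivariate Pearson
   correlations (two-sided p from the t distribution, n-2 df),
3. Box--Cox transform the (positive) strain response,
4. fit a multivariate ordinary-least-squares model and report coefficients,
   p-values, R-squared and sequential (type-I) variance contributions that,
   together with the error term, total 100%.

:func:`predict_peak_strain` evaluates the published empirical model

    ln(peak ACL strain %) = 9.09 + 0.0701 * knee_max
                                 - 0.2661 * ankle@maxGRF
                                 - 0.1362 * hip@maxGRF
                                 - 0.1649 * trunk@maxGRF

with angles in degrees. Strain is in percent: with angle magnitudes of
tens of degrees and strains of a few percent, the 9.09 constant is only
consistent on the percent scale. The log branch is used for prediction
because the published model is stated on the ln scale; the fitting
pipeline keeps its estimated Box--Cox lambda and callers can compare.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import scipy.optimize
import scipy.special
import scipy.stats
import statsmodels.api as sm

from .errors import InsufficientDataError, ParameterError

#: canonical predictor order of the empirical model (entry order for the
#: sequential variance decomposition)
EQ_PREDICTORS = ("trunk_flexion_at_maxgrf", "max_knee_flexion",
                 "ankle_flexion_at_maxgrf", "hip_flexion_at_maxgrf")


@dataclass
class RegressionModel:
    """Fitted (or published) empirical peak-strain model on the ln(%) scale."""

    coefficients: dict[str, float]          # const + per-predictor, 1/deg
    boxcox_lambda: float
    r_squared: float
    p_values: dict[str, float] = field(default_factory=dict)
    contributions: dict[str, float] = field(default_factory=dict)  # % of variance

    def __post_init__(self):
        if not 0.0 <= self.r_squared <= 1.0 + 1e-12:
            raise ParameterError(f"r_squared must be in [0, 1], got {self.r_squared}")
        if self.contributions:
            total = sum(self.contributions.values())
            if abs(total - 100.0) > 0.1:
                raise ParameterError(
                    f"variance contributions + error must total 100% (got {total:.3f})")

    def linear_predictor(self, predictors: dict[str, float]) -> float:
        lp = self.coefficients["const"]
        for name, coef in self.coefficients.items():
            if name != "const":
                lp += coef * predictors[name]
        return lp


#: Eq.-style published model: full-precision coefficients, percent strain scale
PUBLISHED_MODEL = RegressionModel(
    coefficients={
        "const": 9.09,
        "max_knee_flexion": 0.0701,
        "ankle_flexion_at_maxgrf": -0.2661,
        "hip_flexion_at_maxgrf": -0.1362,
        "trunk_flexion_at_maxgrf": -0.1649,
    },
    boxcox_lambda=0.0,
    r_squared=0.9004,
    p_values={"model": 0.01, "const": 0.001, "trunk_flexion_at_maxgrf": 0.002,
              "max_knee_flexion": 0.011, "ankle_flexion_at_maxgrf": 0.003,
              "hip_flexion_at_maxgrf": 0.002},
    contributions={"trunk_flexion_at_maxgrf": 43.43, "max_knee_flexion": 31.55,
                   "ankle_flexion_at_maxgrf": 8.44, "hip_flexion_at_maxgrf": 6.62,
                   "error": 9.96})


# ---------------------------------------------------------------------------
# elementary operations
# ---------------------------------------------------------------------------

def znormalize(values) -> np.ndarray:
    """Center and scale to unit sample (n-1) standard deviation."""
    x = np.asarray(values, dtype=float)
    if x.size < 2:
        raise InsufficientDataError("z-normalization needs at least 2 values")
    sd = np.std(x, ddof=1)
    if sd == 0.0:
        raise ParameterError("z-normalization undefined for constant input")
    return (x - np.mean(x)) / sd


def bivariate_screen(table: pd.DataFrame, response: str = "peak_strain_pct",
                     predictors: list[str] | None = None) -> pd.DataFrame:
    """Pearson r and two-sided p of each predictor against the response.

    Constant predictors are flagged (r and p reported as NaN) rather than
    raising, since screening tables routinely contain degenerate columns.
    """
    if len(table) < 3:
        raise InsufficientDataError("bivariate screening needs n >= 3")
    if predictors is None:
        predictors = [c for c in table.columns
                      if c not in (response, "id") and
                      np.issubdtype(table[c].dtype, np.number)]
    y = table[response].to_numpy(dtype=float)
    rows = []
    for name in predictors:
        x = table[name].to_numpy(dtype=float)
        if np.std(x) == 0.0 or np.std(y) == 0.0:
            rows.append({"predictor": name, "pearson_r": np.nan,
                         "p_value": np.nan, "constant": True})
            continue
        res = scipy.stats.pearsonr(x, y)
        rows.append({"predictor": name, "pearson_r": float(res.statistic),
                     "p_value": float(res.pvalue), "constant": False})
    return pd.DataFrame(rows)


def boxcox_transform(values, grid=(-2.0, 2.0, 401)) -> tuple[float, np.ndarray]:
    """Box--Cox transform with lambda chosen by profile log-likelihood.

    The likelihood is profiled on a uniform grid over [-2, 2] (401 points by
    default) and polished with a bounded scalar minimizer; lambda = 0 is the
    natural-log branch. Only defined for strictly positive data.
    """
    x = np.asarray(values, dtype=float)
    if np.any(x <= 0):
        raise ParameterError("Box-Cox transform requires strictly positive values")
    lo, hi, npts = grid
    lams = np.linspace(lo, hi, int(npts))
    llf = np.array([scipy.stats.boxcox_llf(l, x) for l in lams])
    best = lams[int(np.argmax(llf))]
    span = lams[1] - lams[0]
    res = scipy.optimize.minimize_scalar(
        lambda l: -scipy.stats.boxcox_llf(l, x),
        bounds=(max(lo, best - 2 * span), min(hi, best + 2 * span)),
        method="bounded")
    lam = float(res.x)
    return lam, scipy.special.boxcox(x, lam)


# ---------------------------------------------------------------------------
# model fitting and prediction
# ---------------------------------------------------------------------------

def fit_empirical_model(table: pd.DataFrame,
                        predictors: list[str] = list(EQ_PREDICTORS),
                        response: str = "peak_strain_pct",
                        transform: str = "boxcox") -> RegressionModel:
    """OLS fit of the transformed peak strain on the given predictors.

    ``transform`` is ``"boxcox"`` (estimated lambda), ``"log"`` (natural log,
    the published model's branch) or ``"none"``. Contributions are sequential
    type-I shares of variance in the predictors' entry order and sum with the
    error share to 100%.
    """
    n = len(table)
    if n <= len(predictors) + 1:
        raise InsufficientDataError(
            f"need more observations ({n}) than predictors + 1 ({len(predictors) + 1})")
    y_raw = table[response].to_numpy(dtype=float)
    if transform == "boxcox":
        lam, y = boxcox_transform(y_raw)
    elif transform == "log":
        if np.any(y_raw <= 0):
            raise ParameterError("log transform requires positive response")
        lam, y = 0.0, np.log(y_raw)
    elif transform == "none":
        lam, y = 1.0, y_raw
    else:
        raise ParameterError(f"unknown transform {transform!r}")

    X = table[list(predictors)].to_numpy(dtype=float)
    if np.linalg.matrix_rank(np.column_stack([np.ones(n), X])) < len(predictors) + 1:
        corr = np.corrcoef(X, rowvar=False)
        worst = np.unravel_index(
            np.argmax(np.abs(corr - np.eye(len(predictors)))), corr.shape)
        raise ParameterError(
            "rank-deficient design; most collinear columns: "
            f"{predictors[worst[0]]}, {predictors[worst[1]]}")

    Xc = sm.add_constant(pd.DataFrame(X, columns=list(predictors)))
    fit = sm.OLS(y, Xc).fit()

    # sequential (type-I) variance shares in entry order
    sst = float(np.sum((y - y.mean()) ** 2))
    contributions: dict[str, float] = {}
    prev_ssr = 0.0
    for k in range(1, len(predictors) + 1):
        sub = sm.OLS(y, sm.add_constant(
            pd.DataFrame(X[:, :k], columns=list(predictors[:k])))).fit()
        ssr = float(sub.ess)
        contributions[predictors[k - 1]] = 100.0 * (ssr - prev_ssr) / sst
        prev_ssr = ssr
    contributions["error"] = 100.0 * float(fit.ssr) / sst

    coefs = {"const": float(fit.params["const"])}
    pvals = {"const": float(fit.pvalues["const"]), "model": float(fit.f_pvalue)}
    for name in predictors:
        coefs[name] = float(fit.params[name])
        pvals[name] = float(fit.pvalues[name])
    return RegressionModel(coefficients=coefs, boxcox_lambda=lam,
                           r_squared=float(fit.rsquared), p_values=pvals,
                           contributions=contributions)


#: envelope of landing postures the empirical model was built over (degrees);
#: predictions outside it are extrapolations and draw a warning
ANGLE_ENVELOPE = {"trunk": (-5.0, 60.0), "hip": (0.0, 90.0),
                  "knee": (10.0, 110.0), "ankle": (-10.0, 50.0)}


def predict_peak_strain(trunk: float, hip: float, knee: float, ankle: float,
                        model: RegressionModel | None = None) -> float:
    """Peak ACL strain (percent) for one landing posture.

    ``trunk``, ``hip``, ``ankle`` are the flexion angles at the instant of
    peak GRF; ``knee`` is the maximum knee flexion. Uses the published model
    unless a fitted one is passed; evaluation is ``exp`` of the linear
    predictor (the ln branch).
    """
    model = PUBLISHED_MODEL if model is None else model
    for name, val in (("trunk", trunk), ("hip", hip), ("knee", knee), ("ankle", ankle)):
        lo, hi = ANGLE_ENVELOPE[name]
        if not lo <= val <= hi:
            warnings.warn(f"{name} angle {val:g} deg outside the documented "
                          f"envelope [{lo:g}, {hi:g}]; extrapolating", stacklevel=2)
    lp = model.linear_predictor({
        "trunk_flexion_at_maxgrf": trunk, "hip_flexion_at_maxgrf": hip,
        "max_knee_flexion": knee, "ankle_flexion_at_maxgrf": ankle})
    return float(np.exp(lp))
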