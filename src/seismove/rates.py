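"""Fine-scale movement rates near seismic lines.

Assembles the within-100-m rate dataset, fits Gaussian random-intercept
mixed models of ln(movement rate) on ln(Veght+1) x season x forest
(candidate set M6-M8, compared by AICc on maximum-likelihood fits),
reports marginal/conditional R^2, and locates the vegetation height at
which the rate-height slope changes via grid-search hinge regression with
a case-resampling percentile bootstrap for the confidence interval.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
import statsmodels.api as sm
import statsmodels.formula.api as smf

from .lines import FOREST_CLASSES, SegmentIndex

log = logging.getLogger(__name__)

#: Fixed-effect formulas of the movement-rate candidate set.
RATE_MODELS: dict[str, str] = {
    "M6": "log_rate ~ C(season)",
    "M7": "log_rate ~ log_veght * C(season)",
    "M8": "log_rate ~ log_veght * C(season) * forest",
}

MAX_DISTANCE = 100.0   # m: zone of influence around lines
MIN_PER_SEASON = 20    # qualifying locations per animal-season


# ---------------------------------------------------------------------------
# Dataset assembly
# ---------------------------------------------------------------------------

def build_rate_dataset(steps: pd.DataFrame, seg_index: SegmentIndex,
                       max_distance: float = MAX_DISTANCE,
                       min_per_season: int = MIN_PER_SEASON) -> pd.DataFrame:
    """Movement-rate observations within `max_distance` of a line.

    Keeps movement steps whose end fix lies within `max_distance` metres of
    any segment, attaches the nearest segment's covariates, log-transforms
    rate and Veght (ln, with +1 on Veght), and drops animal-seasons with
    fewer than `min_per_season` qualifying locations.
    """
    if len(steps) == 0:
        raise ValueError("no steps supplied")
    idx, dist = seg_index.nearest(steps["x1"].to_numpy(),
                                  steps["y1"].to_numpy())
    segs = seg_index.segments
    tab = steps.reset_index(drop=True).copy()
    tab["distance_to_line"] = dist
    tab["veght"] = segs["veght"].to_numpy()[idx]
    tab["landcover"] = segs["landcover"].to_numpy()[idx]
    tab = tab[tab["distance_to_line"] <= max_distance].copy()
    counts = (tab.groupby(["animal_id", "season"], observed=True)
              .size().rename("n").reset_index())
    if len(tab) == 0:
        raise ValueError("no steps within the line buffer; per-animal "
                         "report:\n" + counts.to_string(index=False))
    keep = set(map(tuple, counts.loc[counts["n"] >= min_per_season,
                                     ["animal_id", "season"]].to_numpy()))
    tab = tab[[(a, s) in keep for a, s in
               zip(tab["animal_id"], tab["season"])]].copy()
    if len(tab) == 0:
        raise ValueError("all animal-seasons below the minimum; report:\n"
                         + counts.to_string(index=False))
    tab["forest"] = tab["landcover"].isin(FOREST_CLASSES).astype(int)
    tab["log_rate"] = np.log(tab["rate"])
    tab["log_veght"] = np.log1p(tab["veght"])
    return tab.reset_index(drop=True)


# ---------------------------------------------------------------------------
# Mixed models
# ---------------------------------------------------------------------------

@dataclass
class LMMFit:
    """A Gaussian random-intercept mixed-model fit."""

    model: str
    fixed: pd.DataFrame            # term, beta, ci_halfwidth, significant
    random_variances: dict[str, float]
    residual_variance: float
    loglik_ml: float
    n_obs: int
    n_params: int
    aicc: float
    r2_marginal: float
    r2_conditional: float
    fitted_fixed: np.ndarray = None

    def __post_init__(self):
        for v in self.random_variances.values():
            if v < -1e-9:
                raise ValueError("negative random variance")


def fit_lmm(table: pd.DataFrame, formula: str,
            random: str = "individual") -> LMMFit:
    """REML random-intercept fit with an ML log-likelihood for AICc.

    `random` is ``"individual"`` (intercept per animal) or
    ``"individual_in_group"`` (intercepts for pack and for animal within
    pack). Variance components are REML; the AICc log-likelihood comes from
    a matching ML fit, the standard convention when comparing fixed-effect
    structures. A singular random structure pins the variance at ~0 with a
    warning rather than failing.
    """
    if random == "individual":
        groups = table["animal_id"]
        vc = None
        re_formula = None
    elif random == "individual_in_group":
        groups = table["group"]
        vc = {"individual": "0 + C(animal_id)"}
        re_formula = "1"
    else:
        raise ValueError(f"unknown random structure {random!r}")
    if groups.nunique() < 2:
        raise ValueError("need >= 2 levels of the random factor")
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        md = smf.mixedlm(formula, table, groups=groups, vc_formula=vc,
                         re_formula=re_formula)
        res = md.fit(reml=True)
        res_ml = smf.mixedlm(formula, table, groups=groups, vc_formula=vc,
                             re_formula=re_formula).fit(reml=False)
        fe = res.fe_params
        se = res.bse_fe  # NaN where the design cell is empty/collinear
    if not res.converged:
        log.warning("REML fit did not fully converge; variance may be "
                    "pinned near zero")
    ci_half = 1.96 * se
    fixed = pd.DataFrame({
        "term": fe.index,
        "beta": fe.to_numpy(),
        "ci_halfwidth": ci_half.to_numpy(),
    })
    fixed["significant"] = fixed["ci_halfwidth"] < np.abs(fixed["beta"])

    # cov_re and vcomp are reported in response units already
    rand_var = {"group" if random == "individual_in_group" else "individual":
                float(res.cov_re.iloc[0, 0]) if res.cov_re.size else 0.0}
    if vc is not None:
        for name, v in zip(md.exog_vc.names, res.vcomp):
            rand_var[name] = float(v)
    resid_var = float(res.scale)

    n = len(table)
    # parameters: fixed effects + variance components + residual variance
    p = len(fe) + len(rand_var) + 1
    aicc_val = aicc(float(res_ml.llf), n, p)

    X = md.exog
    fitted_fixed = X @ fe.to_numpy()
    var_f = float(np.var(fitted_fixed, ddof=0))
    var_r = float(sum(rand_var.values()))
    r2m, r2c = r2_from_variances(var_f, var_r, resid_var)

    return LMMFit(model=formula, fixed=fixed, random_variances=rand_var,
                  residual_variance=resid_var, loglik_ml=float(res_ml.llf),
                  n_obs=n, n_params=p, aicc=aicc_val,
                  r2_marginal=r2m, r2_conditional=r2c,
                  fitted_fixed=fitted_fixed)


def aicc(loglik: float, n: int, p: int) -> float:
    """AICc = -2 loglik + 2p + 2p(p+1)/(n-p-1); requires n > p + 1."""
    if n <= p + 1:
        raise ValueError("AICc undefined for n <= p + 1")
    return -2.0 * loglik + 2.0 * p + 2.0 * p * (p + 1) / (n - p - 1)


def r2_from_variances(var_fixed: float, var_random: float,
                      var_residual: float) -> tuple[float, float]:
    """Marginal and conditional R^2 for a Gaussian identity-link mixed model.

    r2m = fixed / (fixed + random + residual); r2c adds the random
    component to the numerator. This is the variance-partitioning R^2
    standard for mixed models.
    """
    total = var_fixed + var_random + var_residual
    if total <= 0:
        raise ValueError("zero total variance")
    return var_fixed / total, (var_fixed + var_random) / total


def r2_nakagawa(fit: LMMFit) -> tuple[float, float]:
    """(marginal, conditional) R^2 of a fitted mixed model."""
    return fit.r2_marginal, fit.r2_conditional


def compete_rate_models(table: pd.DataFrame,
                        models: dict[str, str] = None,
                        random: str = "individual") -> pd.DataFrame:
    """AICc table over the candidate fixed-effect structures."""
    models = models or RATE_MODELS
    rows = []
    for name, formula in models.items():
        fit = fit_lmm(table, formula, random=random)
        rows.append({"model": name, "formula": formula, "aicc": fit.aicc,
                     "loglik_ml": fit.loglik_ml, "n_params": fit.n_params,
                     "r2_marginal": fit.r2_marginal,
                     "r2_conditional": fit.r2_conditional})
    tab = pd.DataFrame(rows)
    tab["delta"] = tab["aicc"] - tab["aicc"].min()
    raw = np.exp(-tab["delta"] / 2)
    tab["weight"] = raw / raw.sum()
    return tab.sort_values("aicc", kind="stable").reset_index(drop=True)


# ---------------------------------------------------------------------------
# Piecewise (hinge) regression
# ---------------------------------------------------------------------------

@dataclass
class PiecewiseFit:
    """A two-segment continuous hinge fit."""

    breakpoint: float
    slope_left: float
    slope_right: float
    intercept: float          # fitted value at the breakpoint
    sse: float
    n: int
    ci_halfwidth: float | None = None
    n_boot: int = 0

    def predict(self, x) -> np.ndarray:
        x = np.asarray(x, dtype=float)
        return self.intercept + np.where(
            x <= self.breakpoint,
            self.slope_left * (x - self.breakpoint),
            self.slope_right * (x - self.breakpoint))


def _hinge_sse_batch(x: np.ndarray, y: np.ndarray,
                     candidates: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """SSE and parameters of the hinge OLS at each candidate breakpoint.

    The design per candidate bp is [1, min(x-bp, 0), max(x-bp, 0)], whose
    normal equations involve only left/right partial sums of x, x^2, y and
    xy — so all candidates are evaluated from prefix sums in one batched
    3x3 solve instead of per-candidate least squares.
    """
    order = np.argsort(x, kind="stable")
    xs, ys = x[order], y[order]
    n = len(xs)
    cx = np.concatenate([[0.0], np.cumsum(xs)])
    cx2 = np.concatenate([[0.0], np.cumsum(xs * xs)])
    cy = np.concatenate([[0.0], np.cumsum(ys)])
    cxy = np.concatenate([[0.0], np.cumsum(xs * ys)])
    yty = float(ys @ ys)
    sum_y = cy[-1]
    # points with x <= bp go left
    k = np.searchsorted(xs, candidates, side="right")   # left counts
    bp = candidates
    sl = (cx[k] - k * bp)                               # sum of min(x-bp,0)
    sl2 = cx2[k] - 2 * bp * cx[k] + k * bp * bp
    sly = cxy[k] - bp * cy[k]
    kr = n - k
    sr = (cx[-1] - cx[k]) - kr * bp
    sr2 = (cx2[-1] - cx2[k]) - 2 * bp * (cx[-1] - cx[k]) + kr * bp * bp
    sry = (cxy[-1] - cxy[k]) - bp * (sum_y - cy[k])
    K = len(candidates)
    XtX = np.empty((K, 3, 3))
    XtX[:, 0, 0] = n
    XtX[:, 0, 1] = XtX[:, 1, 0] = sl
    XtX[:, 0, 2] = XtX[:, 2, 0] = sr
    XtX[:, 1, 1] = sl2
    XtX[:, 2, 2] = sr2
    XtX[:, 1, 2] = XtX[:, 2, 1] = 0.0                   # min*max == 0
    Xty = np.stack([np.full(K, sum_y), sly, sry], axis=1)
    # tiny ridge guards candidates with an empty/degenerate side
    XtX += 1e-10 * np.eye(3)
    params = np.linalg.solve(XtX, Xty[..., None])[..., 0]
    sses = yty - np.einsum("ki,ki->k", params, 2 * Xty) \
        + np.einsum("ki,kij,kj->k", params, XtX, params)
    return sses, params


def piecewise_fit(x, y, central_frac: float = 0.9) -> PiecewiseFit:
    """Least-squares hinge fit with the breakpoint on a grid of observed x.

    Candidate breakpoints are the observed x values within the central
    `central_frac` of the range; for each, a continuous two-segment OLS is
    fit, and the SSE-minimising candidate wins (ties to the smallest x).
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if len(x) < 20:
        raise ValueError("need >= 20 points for piecewise regression")
    lo, hi = x.min(), x.max()
    if hi <= lo:
        raise ValueError("x must span an interval")
    pad = (1.0 - central_frac) / 2 * (hi - lo)
    candidates = np.unique(x[(x >= lo + pad) & (x <= hi - pad)])
    if len(candidates) == 0:
        raise ValueError("no interior candidate breakpoints")
    sses, params = _hinge_sse_batch(x, y, candidates)
    best = int(np.argmin(sses))
    inter, sl, sr = params[best]
    return PiecewiseFit(breakpoint=float(candidates[best]),
                        slope_left=float(sl), slope_right=float(sr),
                        intercept=float(inter), sse=float(sses[best]),
                        n=len(x))


def bootstrap_breakpoint_ci(x, y, n_boot: int = 1000, alpha: float = 0.05,
                            seed: int = 0,
                            central_frac: float = 0.9) -> PiecewiseFit:
    """Percentile bootstrap CI for the hinge breakpoint.

    Case-resampling: rows are resampled with replacement `n_boot` times and
    the hinge refit on each; the interval is the (alpha/2, 1-alpha/2)
    percentile range of replicate breakpoints, reported as a half-width
    around the full-data point estimate. Replicates whose resample cannot
    support a fit are skipped; more than 20% failures aborts.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    fit = piecewise_fit(x, y, central_frac=central_frac)
    rng = np.random.default_rng(seed)
    n = len(x)
    boots = []
    failures = 0
    for _ in range(n_boot):
        idx = rng.integers(n, size=n)
        try:
            bfit = piecewise_fit(x[idx], y[idx], central_frac=central_frac)
        except (ValueError, np.linalg.LinAlgError):
            failures += 1
            continue
        boots.append(bfit.breakpoint)
    if failures > 0.2 * n_boot:
        raise ValueError(f"{failures}/{n_boot} bootstrap replicates failed")
    lo_q, hi_q = np.quantile(boots, [alpha / 2, 1 - alpha / 2])
    fit.ci_halfwidth = float((hi_q - lo_q) / 2)
    fit.n_boot = len(boots)
    fit.ci_bounds = (float(lo_q), float(hi_q))
    return fit


def estimate_breakpoint_m(table: pd.DataFrame, n_boot: int = 1000,
                          alpha: float = 0.05, seed: int = 0) -> dict:
    """Breakpoint of log-rate vs vegetation height, reported in metres.

    Fits the hinge on u = ln(Veght+1) (the scale the mixed models use) and
    maps the estimate and percentile bounds back to the Veght metre scale.
    """
    u = table["log_veght"].to_numpy(dtype=float)
    y = table["log_rate"].to_numpy(dtype=float)
    fit = bootstrap_breakpoint_ci(u, y, n_boot=n_boot, alpha=alpha, seed=seed)
    bp_m = float(np.expm1(fit.breakpoint))
    lo_m, hi_m = (float(np.expm1(b)) for b in fit.ci_bounds)
    return {
        "breakpoint_m": bp_m,
        "ci_halfwidth_m": (hi_m - lo_m) / 2,
        "ci_bounds_m": (lo_m, hi_m),
        "slope_left": fit.slope_left,
        "slope_right": fit.slope_right,
        "n_boot": fit.n_boot,
        "n": fit.n,
    }
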