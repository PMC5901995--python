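"""Step selection functions: strata, conditional logistic fits, validation.

The unit of analysis is the stratum: one observed (used) step plus K random
(available) steps sharing its start point, with available step lengths and
turn angles drawn from the observed movement distributions. Selection
coefficients come from conditional logistic regression maximising

    sum_s w_s [ beta' x_used(s) - log sum_{j in s} exp(beta' x_j) ]

by Newton iterations with step-halving. Standard errors are cluster-robust
(sandwich over independent step clusters), model competition uses QIC_U
with Akaike-style weights, population inference pools per-individual fits
by inverse-variance weighting, and predictive skill is assessed by k-fold
cross-validation on Spearman rank frequencies (r_s1 used, r_s0 available).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.special import expit, logsumexp
from scipy.stats import rankdata, spearmanr

from .lines import (LANDCOVER_CLASSES, SegmentIndex, edist_transform,
                    reflect_into)

log = logging.getLogger(__name__)

#: Default available steps per used step.
K_AVAILABLE = 10

#: Spearman length-angle correlation gate before independent sampling.
LT_TA_RHO_GATE = 0.115


# ---------------------------------------------------------------------------
# Model specifications (broad-scale candidate set)
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class ModelSpec:
    """A named candidate model: a list of ':'-joined interaction terms.

    Factors are ``eDist``, ``Veght``, ``eWAM``, ``Density`` and the
    categorical ``fLand`` (reference cell: NF, dummies Con and Mix).
    Interaction terms always appear with their main effects.
    """

    name: str
    terms: tuple[str, ...]


def _factorial(*factors: str) -> tuple[str, ...]:
    """All non-empty subsets of `factors`, preserving hierarchy order."""
    out: list[str] = []
    n = len(factors)
    for size in range(1, n + 1):
        from itertools import combinations
        for combo in combinations(range(n), size):
            out.append(":".join(factors[i] for i in combo))
    return tuple(out)


SSF_MODELS: dict[str, ModelSpec] = {
    "M1": ModelSpec("M1", ("eDist",)),
    "M2": ModelSpec("M2", _factorial("eDist", "Veght")),
    "M3": ModelSpec("M3", _factorial("eDist", "Veght", "eWAM")),
    "M4": ModelSpec("M4", _factorial("eDist", "Veght", "Density")),
    "M5": ModelSpec("M5", _factorial("eDist", "Veght", "fLand")),
}

_NUMERIC_FACTORS = {"eDist": "edist", "Veght": "veght",
                    "eWAM": "ewam", "Density": "density"}


def build_design(cov, terms) -> tuple[np.ndarray, list[str]]:
    """Design matrix for the given terms from an endpoint covariate table.

    `cov` is a DataFrame or a mapping of arrays with keys ``edist``,
    ``veght``, ``ewam``, ``density``, ``landcover`` as applicable.
    ``fLand`` expands to dummies for Con and Mix against the NF reference;
    an interaction containing fLand expands to one column per dummy.
    """
    columns: list[np.ndarray] = []
    names: list[str] = []
    for term in terms:
        factors = term.split(":")
        expanded: list[tuple[str, np.ndarray]] = [("", np.float64(1.0))]
        for factor in factors:
            if factor in _NUMERIC_FACTORS:
                vals = np.asarray(cov[_NUMERIC_FACTORS[factor]], dtype=float)
                expanded = [(f"{nm}:{factor}" if nm else factor, col * vals)
                            for nm, col in expanded]
            elif factor == "fLand":
                land = np.asarray(cov["landcover"])
                new = []
                for cls in LANDCOVER_CLASSES[:-1]:  # NF is the reference
                    dummy = (land == cls).astype(float)
                    label = f"fLand[{cls}]"
                    new.extend(
                        (f"{nm}:{label}" if nm else label, col * dummy)
                        for nm, col in expanded)
                expanded = new
            else:
                raise ValueError(f"unknown model factor {factor!r}")
        for nm, col in expanded:
            names.append(nm)
            columns.append(col)
    if not columns:
        raise ValueError("model has no terms")
    X = np.column_stack(columns)
    return X, names


# ---------------------------------------------------------------------------
# Endpoint covariates
# ---------------------------------------------------------------------------

def covariate_arrays(x, y, seg_index: SegmentIndex) -> dict[str, np.ndarray]:
    """Endpoint covariates as plain arrays (fast path, no DataFrame)."""
    idx, dist = seg_index.nearest(x, y)
    a = seg_index.attrs
    return {
        "segment_id": a["segment_id"][idx],
        "dist": dist,
        "edist": edist_transform(dist),
        "veght": a["veght"][idx],
        "ewam": a["ewam"][idx],
        "density": a["density"][idx],
        "landcover": a["landcover"][idx],
    }


def endpoint_covariates(x, y, seg_index: SegmentIndex) -> pd.DataFrame:
    """Seismic-line covariates at step endpoints.

    eDist is the decayed distance to the nearest ~100-m line segment;
    Veght, eWAM, Density and landcover are that segment's attributes.
    """
    return pd.DataFrame(covariate_arrays(x, y, seg_index))


# ---------------------------------------------------------------------------
# Pre-fit screens
# ---------------------------------------------------------------------------

def check_lt_ta_correlation(steps: pd.DataFrame,
                            threshold: float = LT_TA_RHO_GATE) -> float:
    """Spearman correlation between step length and |turn angle|.

    Independent sampling of available lengths and angles assumes the two
    are uncorrelated; a |rho| above `threshold` is logged as a warning.
    """
    ok = steps.dropna(subset=["turn_angle"])
    if len(ok) < 10:
        raise ValueError("need >= 10 steps with defined turn angles")
    rho = spearmanr(ok["length"], ok["turn_angle"].abs()).statistic
    if abs(rho) > threshold:
        log.warning("step length vs |turn angle| Spearman rho = %.3f "
                    "exceeds gate %.3f", rho, threshold)
    return float(rho)


def screen_collinearity(cov: pd.DataFrame, r_threshold: float = 0.6,
                        vif_threshold: float = 3.0):
    """Flag |r| > 0.6 pairs and VIF > 3 columns; drop the later-listed one.

    Returns ``(retained column names, report DataFrame)``. Decisions are
    deterministic: for each offending pair the column that appears later in
    the table is dropped; VIFs are then recomputed until all pass.
    """
    cols = list(cov.columns)
    report = []
    # pairwise correlation pass
    corr = cov.corr().to_numpy()
    dropped: set[str] = set()
    for i in range(len(cols)):
        for j in range(i + 1, len(cols)):
            if cols[i] in dropped or cols[j] in dropped:
                continue
            if abs(corr[i, j]) > r_threshold:
                dropped.add(cols[j])
                report.append({"column": cols[j], "reason": "correlation",
                               "partner": cols[i], "value": corr[i, j]})
    retained = [c for c in cols if c not in dropped]
    # VIF pass (iterative)
    while len(retained) > 1:
        X = cov[retained].to_numpy(dtype=float)
        X = (X - X.mean(axis=0)) / X.std(axis=0, ddof=0)
        vifs = []
        for k in range(X.shape[1]):
            others = np.delete(X, k, axis=1)
            beta, *_ = np.linalg.lstsq(others, X[:, k], rcond=None)
            resid = X[:, k] - others @ beta
            r2 = 1.0 - resid.var() / X[:, k].var()
            vifs.append(1.0 / max(1.0 - r2, 1e-12))
        worst = int(np.argmax(vifs))
        if vifs[worst] <= vif_threshold:
            break
        # among all offenders, drop the later-listed one
        offenders = [k for k, v in enumerate(vifs) if v > vif_threshold]
        drop_k = max(offenders)
        report.append({"column": retained[drop_k], "reason": "vif",
                       "partner": "", "value": vifs[drop_k]})
        retained.pop(drop_k)
    return retained, pd.DataFrame(report,
                                  columns=["column", "reason", "partner",
                                           "value"])


# ---------------------------------------------------------------------------
# Stratum construction
# ---------------------------------------------------------------------------

def sample_available(used: pd.Series, length_pool, angle_pool,
                     K: int, rng: np.random.Generator) -> np.ndarray:
    """K available endpoints for one used step.

    Lengths and turn angles are drawn independently with replacement from
    the pooled observed distributions; each available bearing is the used
    step's previous bearing plus a sampled turn angle. Returns (K, 2)
    endpoint coordinates.
    """
    length_pool = np.asarray(length_pool, dtype=float)
    angle_pool = np.asarray(angle_pool, dtype=float)
    if len(length_pool) < 1 or len(angle_pool) < 1:
        raise ValueError("empty sampling pool")
    prev_bearing = used["bearing"] - used["turn_angle"]
    if np.isnan(prev_bearing):
        raise ValueError("used step has no previous bearing")
    lengths = rng.choice(length_pool, size=K, replace=True)
    turns = rng.choice(angle_pool, size=K, replace=True)
    bearings = prev_bearing + turns
    return np.column_stack([used["x0"] + lengths * np.cos(bearings),
                            used["y0"] + lengths * np.sin(bearings)])


def build_strata(steps: pd.DataFrame, seg_index: SegmentIndex,
                 K: int = K_AVAILABLE, seed: int = 0,
                 pool_by=("species", "sex", "season"),
                 extent: tuple | None = None) -> pd.DataFrame:
    """Long-format used/available table, one stratum per eligible used step.

    Steps without a previous bearing cannot seed available angles and are
    skipped (logged). Pools of lengths and turn angles are built per
    `pool_by` group (species-sex-season by default). When a study `extent`
    (x_min, y_min, x_max, y_max) is given, available endpoints falling
    outside it are reflected at the boundary — the same treatment the
    observed movement received, so availability is not biased outward near
    edges. Output columns: ``stratum_id``, ``animal_id``, ``group``,
    ``season``, ``t0``, ``case`` (1 used / 0 available), endpoint
    ``x``/``y``, the endpoint covariates, and ``weight``.
    """
    rng = np.random.default_rng(seed)
    ok = steps.dropna(subset=["turn_angle"]).reset_index(drop=True)
    n_skipped = len(steps) - len(ok)
    if n_skipped:
        log.info("skipped %d steps without a previous bearing", n_skipped)
    if len(ok) == 0:
        raise ValueError("no steps with defined turn angles")
    blocks = []
    for _, grp in ok.groupby(list(pool_by), sort=True, observed=True):
        length_pool = grp["length"].to_numpy(dtype=float)
        angle_pool = grp["turn_angle"].to_numpy(dtype=float)
        n = len(grp)
        # vectorised draw: (n, K) lengths and turns for the whole group
        lengths = rng.choice(length_pool, size=(n, K), replace=True)
        turns = rng.choice(angle_pool, size=(n, K), replace=True)
        prev_bearing = (grp["bearing"] - grp["turn_angle"]).to_numpy()
        bearings = prev_bearing[:, None] + turns
        ax = grp["x0"].to_numpy()[:, None] + lengths * np.cos(bearings)
        ay = grp["y0"].to_numpy()[:, None] + lengths * np.sin(bearings)
        xs = np.column_stack([grp["x1"].to_numpy(), ax]).ravel()
        ys = np.column_stack([grp["y1"].to_numpy(), ay]).ravel()
        blocks.append((xs, ys, grp))
    x = np.concatenate([b[0] for b in blocks])
    y = np.concatenate([b[1] for b in blocks])
    meta = pd.concat([b[2] for b in blocks])
    if extent is not None:
        x_min, y_min, x_max, y_max = extent
        x = reflect_into(x, x_min, x_max)
        y = reflect_into(y, y_min, y_max)
    cov = endpoint_covariates(x, y, seg_index)
    S = len(meta)
    out = cov
    out["stratum_id"] = np.repeat(np.arange(S), K + 1)
    out["case"] = np.tile(np.r_[1, np.zeros(K, dtype=int)], S)
    for col in ("animal_id", "group", "season", "t0", "weight"):
        out[col] = np.repeat(meta[col].to_numpy(), K + 1)
    out["x"] = x
    out["y"] = y
    return out


def filter_pack_correlated(steps: pd.DataFrame, radius: float = 200.0,
                           seed: int = 0) -> pd.DataFrame:
    """Retain one step among contemporaneous same-pack steps within 200 m.

    Steps of the same group at the same nominal timestamp whose start
    points fall in one connected within-`radius` component are reduced to a
    single uniformly chosen representative.
    """
    rng = np.random.default_rng(seed)
    keep_idx = []
    for _, grp in steps.groupby(["group", "t0"], sort=True, observed=True):
        if len(grp) == 1:
            keep_idx.extend(grp.index)
            continue
        pts = grp[["x0", "y0"]].to_numpy(dtype=float)
        n = len(grp)
        # connected components of the within-radius graph (transitive)
        parent = list(range(n))

        def find(a):
            while parent[a] != a:
                parent[a] = parent[parent[a]]
                a = parent[a]
            return a

        for i in range(n):
            for j in range(i + 1, n):
                if np.hypot(*(pts[i] - pts[j])) <= radius:
                    parent[find(i)] = find(j)
        comps: dict[int, list[int]] = {}
        for i in range(n):
            comps.setdefault(find(i), []).append(i)
        for members in comps.values():
            chosen = members[rng.integers(len(members))]
            keep_idx.append(grp.index[chosen])
    return steps.loc[sorted(keep_idx)].reset_index(drop=True)


def assign_clusters(steps: pd.DataFrame, gap_hours: float) -> np.ndarray:
    """Independence-cluster ids for one animal's time-ordered steps.

    A new cluster starts when the time since the previous step exceeds
    `gap_hours` or when the cumulative span since the cluster began exceeds
    `gap_hours` (the rolling rule that bounds bear clusters to 24 h even
    under continuous hourly sampling).
    """
    t = pd.to_datetime(steps["t0"]).to_numpy()
    order = np.argsort(t, kind="stable")
    gap = np.timedelta64(int(gap_hours * 3600), "s")
    ids = np.zeros(len(steps), dtype=int)
    current = 0
    cluster_start = t[order[0]] if len(order) else None
    for prev, cur in zip(order[:-1], order[1:]):
        if (t[cur] - t[prev] > gap) or (t[cur] - cluster_start > gap):
            current += 1
            cluster_start = t[cur]
        ids[cur] = current
    return ids


# ---------------------------------------------------------------------------
# Conditional logistic regression
# ---------------------------------------------------------------------------

@dataclass
class CLogitFit:
    """A converged conditional-logistic fit on stratified used/available data."""

    beta: pd.Series
    naive_cov: np.ndarray
    loglik: float
    qicu: float
    n_strata: int
    converged: bool
    robust_cov: np.ndarray | None = None
    info: np.ndarray = field(default=None, repr=False)
    scores: np.ndarray = field(default=None, repr=False)  # (S, p) per stratum
    stratum_ids: np.ndarray = field(default=None, repr=False)

    @property
    def names(self) -> list[str]:
        return list(self.beta.index)

    def se(self, robust: bool = True) -> pd.Series:
        cov = self.robust_cov if (robust and self.robust_cov is not None) \
            else self.naive_cov
        return pd.Series(np.sqrt(np.diag(cov)), index=self.beta.index)


def _stratum_tensors(strata: pd.DataFrame, terms):
    """Reshape a long stratum table into (S, m, p) design tensors."""
    df = strata.sort_values(["stratum_id", "case"],
                            ascending=[True, False], kind="stable")
    sizes = df.groupby("stratum_id", sort=True).size()
    if sizes.nunique() != 1:
        raise ValueError("strata must all have the same size")
    m = int(sizes.iloc[0])
    S = len(sizes)
    X_flat, names = build_design(df, terms)
    X = X_flat.reshape(S, m, len(names))
    w = df.groupby("stratum_id", sort=True)["weight"].first().to_numpy(float)
    sid = sizes.index.to_numpy()
    return X, w, names, sid


def _clogit_parts(X: np.ndarray, w: np.ndarray, beta: np.ndarray):
    """Log-likelihood, per-stratum scores, and information at `beta`.

    Row 0 of each stratum is the used step.
    """
    eta = X @ beta                                 # (S, m)
    lse = logsumexp(eta, axis=1)                   # (S,)
    ll = float(np.sum(w * (eta[:, 0] - lse)))
    p = np.exp(eta - lse[:, None])                 # conditional probabilities
    xbar = np.einsum("sm,smk->sk", p, X)           # E[x | stratum]
    scores = w[:, None] * (X[:, 0, :] - xbar)      # (S, p)
    exx = np.einsum("sm,smk,sml->kl", w[:, None].repeat(X.shape[1], 1) * p,
                    X, X)
    info = exx - np.einsum("s,sk,sl->kl", w, xbar, xbar)
    return ll, scores, info


def fit_clogit(strata: pd.DataFrame, spec: ModelSpec | tuple,
               tol: float = 1e-8, max_iter: int = 50) -> CLogitFit:
    """Fit a conditional logistic regression by Newton with step-halving.

    `strata` is the long table from :func:`build_strata` (PFix-derived
    weights multiply stratum contributions). Starts at beta = 0, declares
    convergence when the gradient max-norm drops below `tol`, and raises on
    rank deficiency or separation (a coefficient diverging because a
    covariate perfectly ranks the used steps).
    """
    terms = spec.terms if isinstance(spec, ModelSpec) else tuple(spec)
    X, w, names, sid = _stratum_tensors(strata, terms)
    S, m, p = X.shape
    if S < 1:
        raise ValueError("need at least one stratum")
    # within-stratum centred design must be full rank
    Xc = (X - X.mean(axis=1, keepdims=True)).reshape(S * m, p)
    if np.linalg.matrix_rank(Xc) < p:
        raise ValueError("design is rank deficient within strata")

    beta = np.zeros(p)
    ll, scores, info = _clogit_parts(X, w, beta)
    converged = False
    for _ in range(max_iter):
        grad = scores.sum(axis=0)
        if np.max(np.abs(grad)) < tol:
            converged = True
            break
        try:
            step = np.linalg.solve(info, grad)
        except np.linalg.LinAlgError as err:
            raise ValueError("singular information matrix") from err
        # step-halving line search
        factor = 1.0
        for _ in range(30):
            ll_new, scores_new, info_new = _clogit_parts(X, w,
                                                         beta + factor * step)
            if ll_new >= ll - 1e-12:
                break
            factor /= 2
        beta = beta + factor * step
        ll, scores, info = ll_new, scores_new, info_new
    else:
        grad = scores.sum(axis=0)
        converged = bool(np.max(np.abs(grad)) < tol)
    # a gradient can vanish numerically while beta runs off to a flat
    # plateau of the likelihood: that is separation, not convergence
    if np.max(np.abs(beta)) > 30:
        worst = names[int(np.argmax(np.abs(beta)))]
        raise ValueError(f"separation: coefficient for {worst!r} diverges")
    naive_cov = np.linalg.inv(info)
    fit = CLogitFit(beta=pd.Series(beta, index=names),
                    naive_cov=naive_cov, loglik=ll,
                    qicu=-2.0 * ll + 2.0 * p, n_strata=S,
                    converged=converged, info=info, scores=scores,
                    stratum_ids=sid)
    return fit


def robust_cov(fit: CLogitFit, cluster_ids) -> np.ndarray:
    """Cluster-robust sandwich covariance A^-1 B A^-1.

    A is the observed information; B sums, over independence clusters, the
    outer products of cluster-summed per-stratum scores. `cluster_ids`
    aligns with the fit's strata (one label per stratum, in stratum-id
    order). The result is stored on the fit and returned.
    """
    if not fit.converged:
        raise ValueError("fit did not converge")
    cluster_ids = np.asarray(cluster_ids)
    if cluster_ids.shape[0] != fit.scores.shape[0]:
        raise ValueError("one cluster id per stratum required")
    uniq = pd.unique(cluster_ids)
    if len(uniq) < 2:
        raise ValueError("need >= 2 independence clusters")
    p = fit.scores.shape[1]
    B = np.zeros((p, p))
    for c in uniq:
        g = fit.scores[cluster_ids == c].sum(axis=0)
        B += np.outer(g, g)
    A_inv = np.linalg.inv(fit.info)
    cov = A_inv @ B @ A_inv
    cov = (cov + cov.T) / 2  # enforce symmetry against round-off
    fit.robust_cov = cov
    return cov


# ---------------------------------------------------------------------------
# Model competition and population inference
# ---------------------------------------------------------------------------

def qicu_select(fits: dict[str, CLogitFit]) -> pd.DataFrame:
    """Rank candidate fits by QIC_U with Akaike-style model weights.

    QIC_U = -2 loglik + 2p; Delta = QIC_U - min; weight
    omega = exp(-Delta/2) normalised to 1. All fits must be on the same
    strata.
    """
    counts = {name: f.n_strata for name, f in fits.items()}
    if len(set(counts.values())) != 1:
        raise ValueError(f"fits use differing strata counts: {counts}")
    tab = pd.DataFrame({
        "model": list(fits),
        "qicu": [f.qicu for f in fits.values()],
        "loglik": [f.loglik for f in fits.values()],
        "n_params": [len(f.beta) for f in fits.values()],
    })
    tab["delta"] = tab["qicu"] - tab["qicu"].min()
    raw = np.exp(-tab["delta"] / 2)
    tab["weight"] = raw / raw.sum()
    return tab.sort_values("qicu", kind="stable").reset_index(drop=True)


def population_average(individual_fits: list[CLogitFit]) -> pd.DataFrame:
    """Inverse-variance pooled coefficients across individuals.

    pooled beta_k = sum_i (beta_ik / v_ik) / sum_i (1 / v_ik) with v_ik the
    robust variance of individual i's coefficient k; the 95% CI half-width
    is 1.96 / sqrt(sum_i 1/v_ik). Non-converged fits are excluded (logged).
    """
    fits = []
    for i, f in enumerate(individual_fits):
        if f.converged:
            fits.append(f)
        else:
            log.info("excluding non-converged individual fit %d", i)
    if len(fits) == 0:
        raise ValueError("no converged individual fits to pool")
    if len(fits) < 2:
        raise ValueError("need >= 2 individual fits to pool")
    names = fits[0].names
    rows = []
    for k, name in enumerate(names):
        betas = np.array([f.beta.iloc[k] for f in fits])
        variances = np.array([
            (f.robust_cov if f.robust_cov is not None else f.naive_cov)[k, k]
            for f in fits])
        wts = 1.0 / variances
        pooled = float(np.sum(betas * wts) / np.sum(wts))
        half = float(1.96 / np.sqrt(np.sum(wts)))
        rows.append({"term": name, "beta": pooled, "ci_halfwidth": half,
                     "n_individuals": len(fits)})
    return pd.DataFrame(rows)


def predict_relative_prob(beta: pd.Series, cov: pd.DataFrame) -> np.ndarray:
    """Relative selection probability: inverse logit of beta' x.

    This is the reporting scale for selection curves (not the conditional
    likelihood used for fitting).
    """
    X, names = build_design(cov, _terms_for_beta(beta))
    missing = [n for n in beta.index if n not in names]
    if missing:
        raise ValueError(f"coefficients without covariates: {missing}")
    order = [names.index(n) for n in beta.index]
    return expit(X[:, order] @ beta.to_numpy())


def _terms_for_beta(beta: pd.Series) -> tuple[str, ...]:
    """Recover model terms from coefficient names (collapse fLand dummies)."""
    terms = []
    for name in beta.index:
        term = ":".join("fLand" if f.startswith("fLand[") else f
                        for f in name.split(":"))
        if term not in terms:
            terms.append(term)
    return tuple(terms)


# ---------------------------------------------------------------------------
# k-fold cross-validation
# ---------------------------------------------------------------------------

def kfold_cv(strata: pd.DataFrame, spec: ModelSpec | tuple, reps: int = 100,
             train_frac: float = 0.8, seed: int = 0,
             forced_beta: pd.Series | None = None) -> dict:
    """Rank-frequency cross-validation of an SSF.

    Per repetition: strata are split 80/20; the model is fit on the
    training strata; in each test stratum the K+1 member scores are ranked
    (average ranks on ties, rank K+1 = most preferred); the frequency of
    each rank among used steps is tallied across test strata and
    Spearman-correlated with the rank index (r_s1). For r_s0 one randomly
    chosen available step per stratum plays the used role and is ranked
    among the available steps only, so its rank is uniform by construction
    under any model and r_s0 centres on zero unless ranking is degenerate.
    Returns means and min-max ranges over `reps`.
    """
    terms = spec.terms if isinstance(spec, ModelSpec) else tuple(spec)
    X, w, names, sid = _stratum_tensors(strata, terms)
    S, m, p = X.shape
    if S < 25:
        raise ValueError("need >= 25 strata for cross-validation")
    rng = np.random.default_rng(seed)
    n_train = int(round(train_frac * S))
    rs1, rs0 = [], []
    sub = strata.set_index("stratum_id")
    for _ in range(reps):
        perm = rng.permutation(S)
        train, test = perm[:n_train], perm[n_train:]
        if len(test) == 0 or len(train) == 0:
            log.info("degenerate fold skipped")
            continue
        if forced_beta is not None:
            beta = forced_beta.to_numpy(dtype=float)
        else:
            train_tab = sub.loc[sid[train]].reset_index()
            beta = fit_clogit(train_tab, terms).beta.to_numpy()
        eta = X[test] @ beta                      # (T, m)
        ranks = rankdata(eta, axis=1)
        freq1 = np.zeros(m)
        used_bins = np.clip(np.round(ranks[:, 0]).astype(int) - 1, 0, m - 1)
        np.add.at(freq1, used_bins, 1)
        # pseudo-used: a random available, ranked among availables only
        avail_ranks = rankdata(eta[:, 1:], axis=1)     # (T, m-1)
        pseudo = rng.integers(0, m - 1, size=len(test))
        freq0 = np.zeros(m - 1)
        pseudo_bins = np.clip(
            np.round(avail_ranks[np.arange(len(test)), pseudo]).astype(int)
            - 1, 0, m - 2)
        np.add.at(freq0, pseudo_bins, 1)
        rs1.append(spearmanr(np.arange(1, m + 1), freq1).statistic)
        rs0.append(spearmanr(np.arange(1, m), freq0).statistic)
    rs1, rs0 = np.asarray(rs1), np.asarray(rs0)
    return {
        "rs1_mean": float(np.mean(rs1)),
        "rs1_range": (float(np.min(rs1)), float(np.max(rs1))),
        "rs0_mean": float(np.mean(rs0)),
        "rs0_range": (float(np.min(rs0)), float(np.max(rs0))),
        "n_reps": int(len(rs1)),
    }
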