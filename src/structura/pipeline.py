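"""Association pipeline: grain selection by rank correlation,
collinearity filtering, random-forest importance with leave-one-out
cross-validation, linear/polynomial models, and distance-based group
tests (Bray-Curtis, ANOSIM, PERMANOVA).

Permutation tests enumerate all distinct relabelings exhaustively when
there are at most 10,000 of them; otherwise they use random
permutations with the add-one p-value convention
p = (1 + #{permuted statistic >= observed}) / (1 + n_perm).
"""

from __future__ import annotations

import itertools
import logging
import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats as sps
from scipy.spatial.distance import squareform
from sklearn.ensemble import RandomForestRegressor
from sklearn.inspection import permutation_importance
import statsmodels.api as sm
from statsmodels.stats.multitest import multipletests

logger = logging.getLogger("structura.pipeline")

EXHAUSTIVE_LIMIT = 10_000


# ---------------------------------------------------------------- spearman

def spearman(x, y) -> tuple[float, float]:
    """Spearman rank correlation with its p-value.

    rho is the Pearson correlation of mid-ranks (average ranks on
    ties). The p-value uses the t approximation (df = n - 2) for
    n >= 10 and exact permutation enumeration below that.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    n = x.size
    if n < 3 or y.size != n:
        raise ValueError("need at least 3 paired values")
    if not (np.isfinite(x).all() and np.isfinite(y).all()):
        raise ValueError("non-finite values")
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        raise ValueError("constant input; Spearman rho undefined")
    rx = sps.rankdata(x)
    ry = sps.rankdata(y)
    rho = float(np.corrcoef(rx, ry)[0, 1])
    if n >= 10:
        r = min(max(rho, -1.0), 1.0)
        if abs(r) == 1.0:
            return rho, 0.0
        t = r * math.sqrt((n - 2) / (1.0 - r * r))
        p = 2.0 * sps.t.sf(abs(t), df=n - 2)
        return rho, float(p)
    # exact two-sided permutation distribution of rho
    perms = np.array(list(itertools.permutations(ry)))
    mx, my = rx.mean(), ry.mean()
    sx = rx - mx
    sy = perms - my
    num = sy @ sx
    den = math.sqrt(float(sx @ sx)) * np.sqrt(np.sum(sy**2, axis=1))
    rho_perm = num / den
    p = float(np.mean(np.abs(rho_perm) >= abs(rho) - 1e-12))
    return rho, p


# ------------------------------------------------------- variable selection

def select_grain(correlations: pd.DataFrame, alpha: float = 0.05) -> pd.DataFrame:
    """Pick, per metric, the grain with the largest |rho| among
    significant (p <= alpha) correlations.

    ``correlations`` has columns metric, grain, r_s, p. Ties on |rho|
    go to the smaller grain. Metrics with no significant grain are
    returned with ``selected=False`` and should be excluded downstream.
    A Benjamini-Hochberg adjusted p column is attached for transparency
    but plays no role in selection.
    """
    df = correlations.copy()
    df["p_adj"] = multipletests(df["p"].to_numpy(), method="fdr_bh")[1]
    rows = []
    for metric, grp in df.groupby("metric", sort=True):
        sig = grp[grp["p"] <= alpha]
        if len(sig) == 0:
            logger.info("metric %s: no significant grain; excluded", metric)
            best = grp.sort_values(["grain"]).iloc[0]
            rows.append({**best.to_dict(), "selected": False})
            continue
        sig = sig.assign(abs_r=sig["r_s"].abs()).sort_values(["abs_r", "grain"], ascending=[False, True])
        best = sig.iloc[0]
        logger.info("metric %s: grain %s selected (r_s=%.3f, p=%.4f)", metric, best["grain"], best["r_s"], best["p"])
        rows.append({k: best[k] for k in ("metric", "grain", "r_s", "p", "p_adj")} | {"selected": True})
    return pd.DataFrame(rows)


def collinearity_filter(metric_table: pd.DataFrame, response, threshold: float = 0.7) -> tuple[list[str], pd.DataFrame]:
    """Greedy collinearity filter.

    Metrics (columns of ``metric_table``, one row per site) are ranked
    by |Spearman rho| with the response; walking down that ranking, a
    candidate is kept only if its |rho| with every already-kept metric
    stays below ``threshold``. Returns the kept column names and a log
    of each decision.
    """
    y = np.asarray(response, dtype=float)
    strength = {}
    for col in metric_table.columns:
        rho, _ = spearman(metric_table[col].to_numpy(), y)
        strength[col] = abs(rho)
    order = sorted(metric_table.columns, key=lambda c: (-strength[c], c))
    kept: list[str] = []
    log = []
    for col in order:
        clash = None
        for k in kept:
            rho_k, _ = spearman(metric_table[col].to_numpy(), metric_table[k].to_numpy())
            if abs(rho_k) >= threshold:
                clash = (k, rho_k)
                break
        if clash is None:
            kept.append(col)
            log.append({"metric": col, "abs_r_response": strength[col], "kept": True, "reason": ""})
            logger.info("keep %s (|r_s| with response %.3f)", col, strength[col])
        else:
            log.append(
                {
                    "metric": col,
                    "abs_r_response": strength[col],
                    "kept": False,
                    "reason": f"|r_s|={abs(clash[1]):.3f} with {clash[0]}",
                }
            )
            logger.info("drop %s: collinear with %s (r_s=%.3f)", col, clash[0], clash[1])
    return kept, pd.DataFrame(log)


# ------------------------------------------------------------ random forest

@dataclass
class RFResult:
    importances: pd.Series  # permutation importance, descending
    ranking: list[str]
    loocv_rmse: float | None
    predictions: np.ndarray | None = None
    impurity_importances: pd.Series | None = field(default=None)


def rf_importance(
    features: pd.DataFrame,
    response,
    ntree: int = 600,
    mtry: int = 2,
    seed: int = 0,
    importance: str = "permutation",
    loocv: bool = True,
) -> RFResult:
    """Random-forest predictor ranking with optional LOOCV RMSE.

    A regression forest of ``ntree`` trees drawing ``mtry`` candidate
    predictors per split is fit to the site table; predictors are
    ranked by permutation importance (impurity importance is also
    recorded). With ``loocv`` each site is held out in turn, the forest
    refit on the rest, and the RMSE of the holdout predictions
    reported. Deterministic for a fixed seed.
    """
    X = features.to_numpy(dtype=float)
    if not np.isfinite(X).all():
        raise ValueError("non-numeric or non-finite feature values")
    y = np.asarray(response, dtype=float)
    rf_kwargs = dict(n_estimators=ntree, max_features=mtry, random_state=seed)
    model = RandomForestRegressor(**rf_kwargs)
    model.fit(X, y)
    impurity = pd.Series(model.feature_importances_, index=features.columns)
    perm = permutation_importance(model, X, y, n_repeats=5, random_state=seed)
    pi = pd.Series(perm.importances_mean, index=features.columns)
    scores = pi if importance == "permutation" else impurity
    scores = scores.sort_values(ascending=False)
    preds = None
    rmse = None
    if loocv:
        preds = np.empty_like(y)
        for i in range(len(y)):
            idx = np.arange(len(y)) != i
            m = RandomForestRegressor(**rf_kwargs)
            m.fit(X[idx], y[idx])
            preds[i] = m.predict(X[i : i + 1])[0]
        rmse = float(np.sqrt(np.mean((preds - y) ** 2)))
    return RFResult(
        importances=scores,
        ranking=list(scores.index),
        loocv_rmse=rmse,
        predictions=preds,
        impurity_importances=impurity.sort_values(ascending=False),
    )


# ------------------------------------------------------------- model fits

@dataclass
class ModelFitSummary:
    predictors: list[str]
    deviance_explained: float  # percent
    adj_r2: float
    rmse: float
    p_values: dict
    params: dict
    nobs: int


def _summarize(fit, predictors) -> ModelFitSummary:
    resid = fit.resid
    return ModelFitSummary(
        predictors=list(predictors),
        deviance_explained=float(fit.rsquared * 100.0),
        adj_r2=float(fit.rsquared_adj),
        rmse=float(np.sqrt(np.mean(resid**2))),
        p_values={k: float(v) for k, v in fit.pvalues.items()},
        params={k: float(v) for k, v in fit.params.items()},
        nobs=int(fit.nobs),
    )


def linear_fit(response, predictor, name: str = "x") -> ModelFitSummary:
    """Ordinary least squares of the response on one predictor."""
    x = np.asarray(predictor, dtype=float)
    y = np.asarray(response, dtype=float)
    if x.size < 3:
        raise ValueError("need at least 3 observations")
    if np.ptp(x) == 0:
        raise ValueError("zero-variance predictor")
    X = pd.DataFrame({name: x})
    fit = sm.OLS(y, sm.add_constant(X)).fit()
    return _summarize(fit, [name])


def polynomial_fit(
    table: pd.DataFrame,
    response: str = "mdi",
    complexity: str = "ruc",
    pure_quadratic: bool = False,
) -> tuple[ModelFitSummary, ModelFitSummary, float]:
    """Polynomial model of MDI on geography and climate, with and
    without the complexity term.

    The base model regresses the response on longitude and mean annual
    precipitation with linear + quadratic terms and mean annual
    temperature linearly (``pure_quadratic`` drops the linear lon/MAP
    terms); the second model adds the complexity column linearly.
    Returns both summaries and the R-squared gained by adding
    complexity.
    """
    for col in ("lon", "map", "mat", response, complexity):
        if col not in table.columns:
            raise ValueError(f"missing column {col!r}")
    y = table[response].to_numpy(dtype=float)
    base = pd.DataFrame(index=table.index)
    if not pure_quadratic:
        base["lon"] = table["lon"]
        base["map"] = table["map"]
    base["lon2"] = table["lon"] ** 2
    base["map2"] = table["map"] ** 2
    base["mat"] = table["mat"]
    X1 = sm.add_constant(base)
    if np.linalg.matrix_rank(X1.to_numpy()) < X1.shape[1]:
        raise ValueError("rank-deficient design")
    fit1 = sm.OLS(y, X1).fit()
    X2 = sm.add_constant(base.assign(**{complexity: table[complexity]}))
    fit2 = sm.OLS(y, X2).fit()
    s1 = _summarize(fit1, list(base.columns))
    s2 = _summarize(fit2, list(base.columns) + [complexity])
    return s1, s2, float(fit2.rsquared - fit1.rsquared)


# ---------------------------------------------------- distance-based tests

def bray_curtis(counts: pd.DataFrame) -> pd.DataFrame:
    """Site-by-site Bray-Curtis dissimilarity matrix.

    ``counts`` is a wide site x taxon table of non-negative counts, or
    a long table with site/taxon/count columns. d(a, b) =
    1 - 2 sum_t min(a_t, b_t) / (sum a + sum b); in [0, 1], 0 on the
    diagonal, 1 for disjoint communities.
    """
    if {"site", "taxon", "count"}.issubset(counts.columns):
        counts = counts.pivot_table(index="site", columns="taxon", values="count", aggfunc="sum", fill_value=0)
    X = counts.to_numpy(dtype=float)
    if (X < 0).any():
        raise ValueError("negative counts")
    totals = X.sum(axis=1)
    if (totals == 0).any():
        bad = list(counts.index[totals == 0])
        raise ValueError(f"all-zero sites: {bad}")
    n = X.shape[0]
    if n < 2:
        raise ValueError("need at least 2 sites")
    D = np.zeros((n, n))
    for i in range(n):
        shared = np.minimum(X[i], X[i + 1 :]).sum(axis=1)
        d = 1.0 - 2.0 * shared / (totals[i] + totals[i + 1 :])
        D[i, i + 1 :] = d
        D[i + 1 :, i] = d
    return pd.DataFrame(D, index=counts.index, columns=counts.index)


def _distinct_permutations(labels: np.ndarray):
    """Yield every distinct ordering of a label multiset."""
    items = sorted(labels.tolist())
    n = len(items)

    def rec(remaining):
        if not remaining:
            yield []
            return
        seen = set()
        for i, v in enumerate(remaining):
            if v in seen:
                continue
            seen.add(v)
            for tail in rec(remaining[:i] + remaining[i + 1 :]):
                yield [v] + tail

    for perm in rec(items):
        yield np.array(perm)


def _n_distinct_permutations(labels: np.ndarray) -> int:
    _, counts = np.unique(labels, return_counts=True)
    total = math.factorial(len(labels))
    for c in counts:
        total //= math.factorial(int(c))
    return total


def _check_groups(groups: np.ndarray):
    uniq, counts = np.unique(groups, return_counts=True)
    if len(uniq) < 2:
        raise ValueError("need at least 2 groups")
    if (counts < 2).any():
        small = [str(u) for u, c in zip(uniq, counts) if c < 2]
        raise ValueError(f"groups of size 1: {small}")


def _permutation_p(stat_fn, groups: np.ndarray, observed: float, n_perm: int, seed) -> tuple[float, int]:
    """Exhaustive p when distinct relabelings <= EXHAUSTIVE_LIMIT, else
    random permutations with the add-one convention."""
    n_distinct = _n_distinct_permutations(groups)
    if n_distinct <= EXHAUSTIVE_LIMIT:
        ge = sum(1 for perm in _distinct_permutations(groups) if stat_fn(perm) >= observed - 1e-12)
        return ge / n_distinct, n_distinct
    rng = np.random.default_rng(seed)
    ge = 0
    for _ in range(n_perm):
        if stat_fn(rng.permutation(groups)) >= observed - 1e-12:
            ge += 1
    return (1 + ge) / (1 + n_perm), n_perm


def anosim(dist, groups, n_perm: int = 999, seed: int = 0) -> tuple[float, float]:
    """Analysis of similarities on a distance matrix.

    R = (mean between-group rank - mean within-group rank) / (M / 2),
    with ranks taken over the M = n(n-1)/2 pairwise distances
    (mid-ranks on ties). R near 1 means groups are well separated;
    near 0, no separation. The p-value is the fraction of (distinct)
    relabelings whose R meets or exceeds the observed one.
    """
    D = np.asarray(dist, dtype=float)
    groups = np.asarray(groups)
    _check_groups(groups)
    n = D.shape[0]
    condensed = squareform(D, checks=False)
    ranks = sps.rankdata(condensed)
    M = n * (n - 1) // 2
    iu, ju = np.triu_indices(n, k=1)

    def stat(g):
        within = g[iu] == g[ju]
        return (ranks[~within].mean() - ranks[within].mean()) / (M / 2.0)

    R = float(stat(groups))
    p, _ = _permutation_p(stat, groups, R, n_perm, seed)
    return R, float(p)


def permanova(dist, groups, n_perm: int = 999, seed: int = 0) -> tuple[float, float, float]:
    """Permutational multivariate ANOVA on a distance matrix.

    Squared distances are partitioned into between- and within-group
    sums of squares (the Gower-centered inner-product decomposition
    evaluated directly from the distances): SST = sum d^2 / N,
    SSW = sum over groups of within-group d^2 / n_g, SSB = SST - SSW.
    pseudo-F = (SSB / (a - 1)) / (SSW / (N - a)); returns
    (pseudo-F, R^2, p). With SSW = 0 the pseudo-F is infinite and p
    still comes from the permutations.
    """
    D = np.asarray(dist, dtype=float)
    groups = np.asarray(groups)
    _check_groups(groups)
    n = D.shape[0]
    D2 = D**2
    iu, ju = np.triu_indices(n, k=1)
    d2 = D2[iu, ju]
    sst = d2.sum() / n
    uniq = np.unique(groups)
    a = len(uniq)

    def ssw_of(g):
        ssw = 0.0
        for u in uniq:
            members = g == u
            ng = members.sum()
            within = members[iu] & members[ju]
            ssw += d2[within].sum() / ng
        return ssw

    def stat(g):
        ssw = ssw_of(g)
        ssb = sst - ssw
        if ssw <= 0:
            return math.inf
        return (ssb / (a - 1)) / (ssw / (n - a))

    ssw = ssw_of(groups)
    ssb = sst - ssw
    F = stat(groups)
    r2 = ssb / sst if sst > 0 else 0.0
    p, _ = _permutation_p(stat, groups, F, n_perm, seed)
    return float(F), float(r2), float(p)
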