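"""Zero-inflation-aware differential expression.

Single-cell UMI counts carry excess zeros ("dropout").  Fitting each
gene with a zero-inflated negative binomial (ZINB) — a point mass at
zero with probability pi, otherwise NB(mu, theta) — yields a posterior
probability that each observed zero came from the NB component.  That
posterior is used as an observational weight which downweights
technical zeros in a weighted negative-binomial likelihood-ratio test
between two conditions.  Genes with |log2FC| > 1 and BH-adjusted
p < 0.05 in a cluster constitute a DE event.

The model is an independent per-gene ZINB: no shared latent factors or
cell-level covariates.  The weight for a zero is

    w0 = (1 - pi) * f_NB(0) / (pi + (1 - pi) * f_NB(0)),
    f_NB(0) = (theta / (theta + mu)) ** theta,

and nonzero observations have weight exactly 1.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import sparse
from scipy.optimize import minimize_scalar
from scipy.special import digamma, gammaln, polygamma
from scipy.stats import chi2
from statsmodels.stats.multitest import multipletests

from .errors import DataError, InsufficientDataError

__all__ = [
    "ZinbFit",
    "fit_zinb",
    "observational_weights",
    "weighted_nb_test",
    "run_de",
    "summarize_de",
    "union_de",
]

_LOG2 = np.log(2.0)
_THETA_LOG_BOUNDS = (-7.0, 14.0)


@dataclass
class ZinbFit:
    mu: float
    theta: float
    pi: float
    converged: bool
    loglik: float
    n_iter: int
    degenerate: bool = False


def _nb_logpmf(y, mu, theta):
    mu = np.maximum(mu, 1e-12)
    return (
        gammaln(y + theta)
        - gammaln(theta)
        - gammaln(y + 1.0)
        + theta * np.log(theta / (theta + mu))
        + y * np.log(mu / (theta + mu))
    )


def _theta_newton_step(y, w, mu, lt, n_steps=2):
    """Damped Newton update of log-theta for the weighted NB likelihood.

    Each step backtracks until the weighted log-likelihood does not
    decrease, so using it as the M-step keeps EM ascent monotone."""

    def wll(lt_):
        return (w * _nb_logpmf(y, mu, np.exp(lt_))).sum()

    cur = wll(lt)
    for _ in range(n_steps):
        th = np.exp(lt)
        fp = (
            w
            * (digamma(y + th) - digamma(th) + np.log(th / (th + mu)) + (mu - y) / (th + mu))
        ).sum()
        fpp = (
            w
            * (
                polygamma(1, y + th)
                - polygamma(1, th)
                + 1.0 / th
                - 1.0 / (th + mu)
                - (mu - y) / (th + mu) ** 2
            )
        ).sum()
        g = th * fp  # dL/d(log theta)
        h = th * th * fpp + g
        step = -g / h if h < 0 else np.sign(g)
        step = float(np.clip(step, -2.0, 2.0))
        new_lt = float(np.clip(lt + step, *_THETA_LOG_BOUNDS))
        new = wll(new_lt)
        for _ in range(12):
            if new >= cur - 1e-12:
                break
            new_lt = lt + 0.5 * (new_lt - lt)
            new = wll(new_lt)
        if new < cur - 1e-12:
            break  # keep the incumbent theta
        if abs(new_lt - lt) < 1e-10:
            lt = new_lt
            cur = new
            break
        lt, cur = new_lt, new
    return lt


def _zinb_loglik(y, mu, theta, pi):
    zero = y == 0
    nb0 = np.exp(theta * np.log(theta / (theta + mu)))
    ll = np.empty_like(y, dtype=float)
    ll[zero] = np.log(pi + (1.0 - pi) * nb0 + 1e-300)
    ll[~zero] = np.log(1.0 - pi + 1e-300) + _nb_logpmf(y[~zero], mu, theta)
    return float(ll.sum())


def fit_zinb(y, max_iter: int = 200, tol: float = 1e-6, min_n: int = 50) -> ZinbFit:
    """EM fit of a per-gene ZINB to a vector of non-negative counts.

    E-step: posterior source of each zero.  M-step: closed-form updates
    for pi and mu (the weighted-ML mean of an NB is the weighted sample
    mean, independent of theta) and a 1-D profile maximization for
    theta.  The likelihood is monotone non-decreasing; iteration stops
    when its change falls below ``tol``.

    All-zero genes are flagged degenerate and must not be tested.
    """
    y = np.asarray(y)
    if y.size < min_n:
        raise InsufficientDataError(f"need >= {min_n} cells to fit ZINB, got {y.size}")
    if np.any(y < 0) or np.any(y != np.floor(y)):
        raise DataError("ZINB requires non-negative integer counts")
    y = y.astype(float)
    if not np.any(y > 0):
        return ZinbFit(0.0, 1.0, 0.0, False, -np.inf, 0, degenerate=True)

    zero = y == 0
    zero_frac = zero.mean()
    pi = 0.5 * zero_frac
    mu = y.mean() / max(1.0 - pi, 1e-6)
    v = y.var()
    theta = mu**2 / max(v - mu, 1e-3) if v > mu else 100.0
    theta = float(np.clip(theta, 1e-3, 1e6))

    ll_prev = -np.inf
    converged = False
    for it in range(1, max_iter + 1):
        # E-step
        nb0 = np.exp(theta * np.log(theta / (theta + mu)))
        z = np.zeros_like(y)
        z[zero] = pi / (pi + (1.0 - pi) * nb0 + 1e-300)
        w = 1.0 - z
        # M-step
        pi = float(z.mean())
        mu = float((w * y).sum() / max(w.sum(), 1e-12))
        mu = max(mu, 1e-8)

        if pi < 1e-5:
            # boundary solution: no zero inflation; finish with a plain
            # NB maximum-likelihood fit instead of letting pi creep
            pi = 0.0
            w = np.ones_like(y)
            mu = float(y.mean())
            res = minimize_scalar(
                lambda lt: -(_nb_logpmf(y, mu, np.exp(lt))).sum(),
                bounds=_THETA_LOG_BOUNDS, method="bounded",
                options={"xatol": 1e-7},
            )
            theta = float(np.exp(res.x))
            ll_prev = _zinb_loglik(y, mu, theta, pi)
            converged = True
            break

        if it == 1:  # global profile search once, then cheap local updates
            def nll_theta(lt):
                return -(w * _nb_logpmf(y, mu, np.exp(lt))).sum()

            res = minimize_scalar(
                nll_theta, bounds=_THETA_LOG_BOUNDS, method="bounded",
                options={"xatol": 1e-7},
            )
            theta = float(np.exp(res.x))
        elif it % 3 == 0:  # theta moves slowly; refresh every few iterations
            theta = float(np.exp(_theta_newton_step(y, w, mu, np.log(theta))))

        ll = _zinb_loglik(y, mu, theta, pi)
        if ll < ll_prev - 1e-6:  # EM guarantees monotone ascent
            raise RuntimeError("ZINB EM log-likelihood decreased")
        d_ll = abs(ll - ll_prev)
        ll_prev = ll
        if d_ll < tol:
            converged = True
            break
    # at the iteration cap, a fit whose likelihood has effectively
    # plateaued (e.g. pi creeping toward the zero boundary) still counts
    # as converged; only genuinely unstable fits are flagged
    if not converged and d_ll < 1e-3:
        converged = True
    return ZinbFit(mu, theta, max(pi, 0.0), converged, ll_prev, it)


def observational_weights(y, fit: ZinbFit) -> np.ndarray:
    """Posterior probability that each count arose from the NB component.

    Nonzero counts have weight exactly 1; zeros get the closed-form
    posterior.  Requires a converged, non-degenerate fit.
    """
    if fit.degenerate or not fit.converged:
        raise DataError("observational weights require a converged ZINB fit")
    y = np.asarray(y, float)
    w = np.ones_like(y)
    nb0 = (fit.theta / (fit.theta + fit.mu)) ** fit.theta
    w[y == 0] = (1.0 - fit.pi) * nb0 / (fit.pi + (1.0 - fit.pi) * nb0)
    return w


# ---------------------------------------------------------------------------
# weighted NB likelihood-ratio test
# ---------------------------------------------------------------------------

def _wnb_nll(y, w, L, s_per_obs, theta):
    mu = np.exp(s_per_obs) * L
    return -(w * _nb_logpmf(y, mu, theta)).sum()


def _newton_mean(y, w, L, theta, s0, n_steps=25):
    """Solve the weighted NB score equation for a single log-mean."""
    s = s0
    for _ in range(n_steps):
        mu = np.exp(s) * L
        f = (w * (y - (y + theta) * mu / (mu + theta))).sum()
        fp = -(w * (y + theta) * theta * mu / (mu + theta) ** 2).sum()
        if fp == 0:
            break
        step = np.clip(f / fp, -5.0, 5.0)
        s -= step
        if abs(step) < 1e-10:
            break
    return s


def _fit_wnb(y, w, L, group_indices, max_outer=50, tol=1e-8):
    """Weighted NB ML with one log-mean per group and a shared dispersion.

    Alternates closed-ish mean updates (Newton per group) with a 1-D
    profile maximization of log-theta.  The effective sample size in the
    dispersion estimate is the sum of the observational weights.
    """
    s = []
    for idx in group_indices:
        m = (w[idx] * y[idx]).sum() / max((w[idx] * L[idx]).sum(), 1e-12)
        s.append(np.log(max(m, 1e-8)))
    s = np.array(s)
    theta = 10.0
    ll_prev = np.inf
    for _ in range(max_outer):
        s_obs = np.empty_like(y, dtype=float)
        for g, idx in enumerate(group_indices):
            s_obs[idx] = s[g]

        def nll_theta(lt):
            return _wnb_nll(y, w, L, s_obs, np.exp(lt))

        res = minimize_scalar(
            nll_theta, bounds=_THETA_LOG_BOUNDS, method="bounded",
            options={"xatol": 1e-7},
        )
        theta = float(np.exp(res.x))
        for g, idx in enumerate(group_indices):
            s[g] = _newton_mean(y[idx], w[idx], L[idx], theta, s[g])
            s_obs[idx] = s[g]
        ll = -_wnb_nll(y, w, L, s_obs, theta)
        if np.isfinite(ll_prev) and abs(ll - ll_prev) < tol:
            break
        ll_prev = ll
    return ll, s, theta


def weighted_nb_test(y, groups, weights=None, offsets=None, ref=None) -> dict:
    """Weighted two-group NB likelihood-ratio test.

    ``groups`` is a two-level label vector; ``ref`` names the reference
    level (default: first of the sorted levels).  ``offsets`` are log
    library sizes (default 0).  The statistic 2*(llik_alt - llik_null)
    is referred to chi-square with 1 df; the log2 fold change is the
    difference of the fitted log-means (non-reference vs reference) in
    base 2.

    Returns a dict with keys ``log2fc, p, stat, mean_weight, skipped``.
    A group whose weights sum to zero makes the test unidentifiable; the
    row is returned with ``skipped=True`` and NaN statistics.
    """
    y = np.asarray(y, float)
    groups = np.asarray(groups)
    levels = sorted(pd.unique(groups).tolist())
    if len(levels) != 2:
        raise DataError(f"weighted_nb_test needs exactly 2 groups, got {levels}")
    if ref is None:
        ref = levels[0]
    elif ref not in levels:
        raise DataError(f"reference level {ref!r} not among groups {levels}")
    other = levels[1] if ref == levels[0] else levels[0]
    ia = np.flatnonzero(groups == ref)
    ib = np.flatnonzero(groups == other)
    if min(ia.size, ib.size) < 3:
        raise InsufficientDataError("each group needs >= 3 cells")

    w = np.ones_like(y) if weights is None else np.asarray(weights, float)
    L = np.ones_like(y) if offsets is None else np.exp(np.asarray(offsets, float))
    if w[ia].sum() <= 0 or w[ib].sum() <= 0:
        return dict(log2fc=np.nan, p=np.nan, stat=np.nan,
                    mean_weight=float(w.mean()), skipped=True)

    ll_alt, s_alt, _ = _fit_wnb(y, w, L, [ia, ib])
    ll_null, _, _ = _fit_wnb(y, w, L, [np.arange(y.size)])
    stat = max(0.0, 2.0 * (ll_alt - ll_null))
    p = float(chi2.sf(stat, df=1))
    return dict(
        log2fc=float((s_alt[1] - s_alt[0]) / _LOG2),
        p=p,
        stat=float(stat),
        mean_weight=float(w.mean()),
        skipped=False,
    )


# ---------------------------------------------------------------------------
# per-cluster driver and DE-event summaries
# ---------------------------------------------------------------------------

def run_de(
    adata,
    condition_key: str = "condition",
    contrast=None,
    cluster_key=None,
    class_key=None,
    min_cells: int = 50,
    min_nonzero_cells: int = 1,
) -> pd.DataFrame:
    """Per-cluster, per-gene weighted NB test between two conditions.

    For each cluster: ZINB is fitted per gene on the cluster's raw
    counts (pooled conditions), observational weights derived, and the
    weighted test run with log-total-UMI offsets.  BH adjustment is
    applied within each cluster's tested gene set.  ``contrast`` is
    ``(condition, reference)``; default uses the two observed levels in
    sorted order with the first as reference.
    """
    X = adata.X
    dense = X.toarray() if sparse.issparse(X) else np.asarray(X, float)
    obs = adata.obs
    if condition_key not in obs:
        raise DataError(f"missing obs column: {condition_key}")
    cond = obs[condition_key].to_numpy()
    if contrast is None:
        levels = sorted(pd.unique(cond).tolist())
        if len(levels) != 2:
            raise DataError("condition column must have exactly two levels")
        contrast = (levels[1], levels[0])
    target, refname = contrast

    clusters = (
        obs[cluster_key].to_numpy() if cluster_key else np.full(len(obs), "all")
    )
    classes = obs[class_key].to_numpy() if class_key else clusters
    lib = dense.sum(axis=1)
    offsets = np.log(np.where(lib > 0, lib, 1.0))
    offsets -= offsets.mean()

    rows = []
    for cl in pd.unique(clusters):
        sel = clusters == cl
        in_contrast = sel & np.isin(cond, [target, refname])
        if in_contrast.sum() < min_cells:
            continue
        sub = dense[in_contrast]
        g = cond[in_contrast]
        off = offsets[in_contrast]
        klass = pd.unique(classes[sel])[0]
        nz = (sub > 0).sum(axis=0)
        for j in np.flatnonzero(nz >= min_nonzero_cells):
            yj = sub[:, j]
            fit = fit_zinb(yj)
            if fit.degenerate or not fit.converged:
                continue
            w = observational_weights(yj, fit)
            res = weighted_nb_test(yj, g, weights=w, offsets=off, ref=refname)
            if res["skipped"]:
                continue
            rows.append(
                dict(cluster=cl, cell_class=klass, gene=adata.var_names[j],
                     log2fc=res["log2fc"], p=res["p"],
                     mean_weight=res["mean_weight"])
            )
    out = pd.DataFrame(rows, columns=["cluster", "cell_class", "gene", "log2fc", "p", "mean_weight"])
    if len(out):
        out["padj"] = np.nan
        for cl in out["cluster"].unique():
            m = out["cluster"] == cl
            out.loc[m, "padj"] = multipletests(out.loc[m, "p"], method="fdr_bh")[1]
    else:
        out["padj"] = pd.Series(dtype=float)
    return out


def summarize_de(results: pd.DataFrame, fc_cut: float = 1.0, alpha: float = 0.05):
    """DE-event table: a DE event is a (gene, cluster) pair with
    |log2FC| > fc_cut and padj < alpha.

    Returns ``(events, per_class, genes_any)`` — the passing rows, the
    per-class up/down event counts, and the sorted set of genes DE in at
    least one cluster.
    """
    if len(results) == 0:
        empty = results.copy()
        per_class = pd.DataFrame(columns=["cell_class", "direction", "n_events"])
        return empty, per_class, []
    passing = results[
        (results["log2fc"].abs() > fc_cut) & (results["padj"] < alpha)
    ].copy()
    passing["direction"] = np.where(passing["log2fc"] > 0, "up", "down")
    key = "cell_class" if "cell_class" in passing.columns else "cluster"
    per_class = (
        passing.groupby([key, "direction"], observed=True)
        .size()
        .reset_index(name="n_events")
        .rename(columns={key: "cell_class"})
    )
    genes_any = sorted(passing["gene"].unique().tolist())
    return passing, per_class, genes_any


def union_de(results_a: pd.DataFrame, results_b: pd.DataFrame,
             fc_cut: float = 1.0, alpha: float = 0.05):
    """Genes passing the DE criteria in either of two result sets (e.g.
    two different testing tools); each gene counts once."""
    _, _, ga = summarize_de(results_a, fc_cut, alpha)
    _, _, gb = summarize_de(results_b, fc_cut, alpha)
    return sorted(set(ga) | set(gb))
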