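"""Regression models comparing genotypes at the whole-lung and lesion level.

Three models:

* tumor fraction — logistic regression of each cell's tumor/non-tumor
  indicator on genotype, with the sample (mouse) grouping handled by a
  random intercept (adaptive Gauss-Hermite maximum likelihood), sample
  fixed effects, or cluster-robust standard errors;
* lesion size — zero-truncated negative binomial (NB2, variance
  mu + mu^2/theta, conditioned on Y >= 1) regression of lesion size on
  genotype with a log link, fitted by direct maximum likelihood;
* niche PC1 — Gaussian linear model of each lesion's PC1 score on lesion
  size, genotype, and their interaction.

The ZTNB likelihood is implemented directly (log-gamma / log1p forms) so
its behavior is fully specified and testable.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field as dc_field

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy import optimize, special
from statsmodels.tools.numdiff import approx_fprime, approx_hess

GROUPING_MODES = ("random_intercept", "fixed_sample", "cluster_robust", "none")


@dataclass
class ModelFit:
    """Tidy fit result: coefficient table plus model-level quantities."""

    name: str
    params: pd.DataFrame          # index: term; columns: coef, se, z, p
    loglik: float
    converged: bool
    grouping: str
    dispersion: float | None = None   # NB2 theta
    re_sd: float | None = None        # random-intercept SD, if any
    metadata: dict = dc_field(default_factory=dict)

    def coef(self, term: str) -> float:
        return float(self.params.loc[term, "coef"])

    def pvalue(self, term: str) -> float:
        return float(self.params.loc[term, "p"])

    def to_frame(self) -> pd.DataFrame:
        out = self.params.copy()
        out.insert(0, "model", self.name)
        return out.reset_index(names="term")


def _param_table(names, coefs, ses) -> pd.DataFrame:
    coefs = np.asarray(coefs, dtype=float)
    ses = np.asarray(ses, dtype=float)
    with np.errstate(divide="ignore", invalid="ignore"):
        z = coefs / ses
    p = 2.0 * special.ndtr(-np.abs(z))
    return pd.DataFrame({"coef": coefs, "se": ses, "z": z, "p": p}, index=list(names))


# ---------------------------------------------------------------------------
# design matrices
# ---------------------------------------------------------------------------

def _genotype_indicator(genotype: pd.Series, reference: str = "control") -> np.ndarray:
    levels = sorted(genotype.unique())
    if len(levels) == 1:
        warnings.warn(f"single genotype {levels[0]!r}; genotype effect dropped")
        return None
    other = [g for g in levels if g != reference]
    if reference not in levels or len(other) != 1:
        raise ValueError(f"expected two genotypes incl. {reference!r}, got {levels}")
    return (genotype == other[0]).to_numpy(dtype=float)


def _design(df: pd.DataFrame, grouping: str, extra: dict[str, np.ndarray] | None = None,
            reference: str = "control"):
    """Intercept + genotype (+ extras) + full-rank sample dummies if fixed.

    Sample IDs are nested in genotype, so sample dummies are added greedily,
    only while they increase the column rank — this keeps the genotype
    contrast identified (one reference sample per genotype).
    """
    cols = {"intercept": np.ones(len(df))}
    geno = _genotype_indicator(df["genotype"], reference)
    if geno is not None:
        cols["genotype_ko"] = geno
    for name, v in (extra or {}).items():
        cols[name] = v
    if grouping == "fixed_sample":
        X = np.column_stack(list(cols.values()))
        rank = np.linalg.matrix_rank(X)
        for s in sorted(df["sample_id"].unique()):
            d = (df["sample_id"] == s).to_numpy(dtype=float)
            cand = np.column_stack([X, d])
            r = np.linalg.matrix_rank(cand)
            if r > rank:
                cols[f"sample[{s}]"] = d
                X, rank = cand, r
    names = list(cols)
    return np.column_stack([cols[n] for n in names]), names


# ---------------------------------------------------------------------------
# zero-truncated negative binomial likelihood
# ---------------------------------------------------------------------------

def nb2_logpmf(y, mu, theta) -> np.ndarray:
    """log NB2 pmf with mean mu and dispersion theta (var = mu + mu^2/theta)."""
    y = np.asarray(y, dtype=float)
    mu = np.asarray(mu, dtype=float)
    return (special.gammaln(y + theta) - special.gammaln(theta)
            - special.gammaln(y + 1.0)
            + theta * (np.log(theta) - np.log(theta + mu))
            + y * (np.log(mu) - np.log(theta + mu)))


def ztnb_loglik(y, mu, theta: float) -> float:
    """Zero-truncated NB2 log-likelihood, summed over observations.

    Sum_i [ log NB(y_i; mu_i, theta) - log(1 - NB(0; mu_i, theta)) ] with
    NB(0; mu, theta) = (theta/(theta+mu))^theta, evaluated via log-gamma
    and expm1 so small and large mu are both stable.
    """
    y = np.asarray(y, dtype=float)
    if np.any(y < 1):
        raise ValueError("zero-truncated support requires all y >= 1")
    if theta <= 0:
        raise ValueError("theta must be positive")
    mu = np.broadcast_to(np.asarray(mu, dtype=float), y.shape)
    if np.any(mu <= 0):
        raise ValueError("mu must be positive")
    log_p0 = theta * (np.log(theta) - np.log(theta + mu))
    log_trunc = np.log(-np.expm1(log_p0))
    return float(np.sum(nb2_logpmf(y, mu, theta) - log_trunc))


def ztpoisson_loglik(y, mu) -> float:
    """Zero-truncated Poisson log-likelihood (the theta -> inf limit)."""
    y = np.asarray(y, dtype=float)
    mu = np.broadcast_to(np.asarray(mu, dtype=float), y.shape)
    return float(np.sum(y * np.log(mu) - mu - special.gammaln(y + 1.0)
                        - np.log(-np.expm1(-mu))))


def ztnb_rvs_check(*args, **kwargs):  # pragma: no cover - convenience alias
    from .synthdata import ztnb_rvs
    return ztnb_rvs(*args, **kwargs)


def _fit_ztnb_ml(y: np.ndarray, X: np.ndarray, seed: int = 0, n_starts: int = 5,
                 gtol: float = 1e-8):
    """Maximize the ZTNB log-likelihood over (beta, log theta)."""
    n, p = X.shape

    def nll(params):
        beta, log_theta = params[:p], params[p]
        if abs(log_theta) > 30:
            return 1e12
        eta = X @ beta
        if np.any(np.abs(eta) > 30):
            return 1e12
        return -ztnb_loglik(y, np.exp(eta), np.exp(log_theta))

    # start from the log-mean intercept; extra starts perturb it
    rng = np.random.default_rng(seed)
    base = np.zeros(p + 1)
    base[0] = np.log(max(y.mean(), 1.01))
    starts = [base]
    for _ in range(n_starts - 1):
        starts.append(base + rng.normal(0, 0.5, p + 1))
    best = None
    for x0 in starts:
        res = optimize.minimize(nll, x0, method="L-BFGS-B",
                                options={"gtol": gtol, "maxiter": 500})
        if best is None or res.fun < best.fun:
            best = res
    if best is None or not np.isfinite(best.fun):
        raise RuntimeError("ZTNB optimization failed from all starts")
    return best


def fit_lesion_size(
    lesion_df: pd.DataFrame,
    grouping_mode: str = "fixed_sample",
    seed: int = 0,
    n_starts: int = 5,
    reference: str = "control",
) -> ModelFit:
    """ZTNB regression of lesion size on genotype (log link).

    ``grouping_mode``: ``fixed_sample`` (sample as fixed covariate, the
    documented default), ``cluster_robust`` (pooled fit with sample-cluster
    sandwich SEs), or ``none`` (pooled). Standard errors otherwise come
    from the inverse observed information.
    """
    y = lesion_df["size"].to_numpy(dtype=float)
    if len(y) < 10:
        raise ValueError("need >= 10 lesions")
    if np.any(y < 1):
        raise ValueError("lesion sizes must be >= 1")
    if grouping_mode not in ("fixed_sample", "cluster_robust", "none"):
        raise NotImplementedError(
            f"grouping_mode {grouping_mode!r} is not available for the ZTNB "
            "size model; use fixed_sample, cluster_robust, or none"
        )
    X, names = _design(lesion_df, grouping_mode, reference=reference)
    best = _fit_ztnb_ml(y, X, seed=seed, n_starts=n_starts)
    p = X.shape[1]

    def nll(params):
        return -ztnb_loglik(y, np.exp(X @ params[:p]), np.exp(params[p]))

    H = approx_hess(best.x, nll)
    cov = np.linalg.pinv(H)
    if grouping_mode == "cluster_robust":
        groups = lesion_df["sample_id"].to_numpy()
        scores = np.zeros((len(np.unique(groups)), p + 1))
        for gi, g in enumerate(np.unique(groups)):
            sel = groups == g

            def nll_g(params, sel=sel):
                return -ztnb_loglik(y[sel], np.exp(X[sel] @ params[:p]),
                                    np.exp(params[p]))

            scores[gi] = -approx_fprime(best.x, nll_g)
        meat = scores.T @ scores
        cov = cov @ meat @ cov
    ses = np.sqrt(np.clip(np.diag(cov), 0, None))
    theta = float(np.exp(best.x[p]))
    table = _param_table(names + ["log_theta"], best.x, ses)
    return ModelFit(
        name="lesion_size_ztnb",
        params=table,
        loglik=-float(best.fun),
        converged=bool(best.success),
        grouping=grouping_mode,
        dispersion=theta,
        metadata={"link": "log", "family": "truncated_nbinom2",
                  "genotype_reference": reference},
    )


# ---------------------------------------------------------------------------
# logistic tumor-fraction model
# ---------------------------------------------------------------------------

def _agh_logistic_loglik(beta, log_sigma, clusters, nodes, weights):
    """Marginal log-likelihood of a random-intercept logistic model.

    ``clusters`` is a list of (X_g, y_sum_or_y, n) reduced per cluster:
    here each cluster shares a single fixed-effect row x_g (genotype is
    constant within sample), so the cluster log-likelihood given u is
    s_g*(eta+u) - n_g*log(1+exp(eta+u)) with s_g the success count.
    Integration over u is adaptive Gauss-Hermite per cluster.
    """
    sigma = np.exp(log_sigma)
    total = 0.0
    for x_g, s_g, n_g in clusters:
        eta = float(x_g @ beta)

        def f(u):  # integrand exponent: cluster loglik + log N(u; 0, sigma)
            a = eta + u
            return (s_g * a - n_g * np.logaddexp(0.0, a)
                    - 0.5 * (u / sigma) ** 2 - np.log(sigma)
                    - 0.5 * np.log(2 * np.pi))

        # Newton for the mode: f'(u) = s - n*expit(eta+u) - u/sigma^2
        u = 0.0
        for _ in range(50):
            p_ = special.expit(eta + u)
            g1 = s_g - n_g * p_ - u / sigma**2
            g2 = -n_g * p_ * (1 - p_) - 1.0 / sigma**2
            step = g1 / g2
            u -= step
            if abs(step) < 1e-10:
                break
        p_ = special.expit(eta + u)
        h = 1.0 / np.sqrt(n_g * p_ * (1 - p_) + 1.0 / sigma**2)
        z = u + np.sqrt(2.0) * h * nodes
        vals = np.array([f(zi) for zi in z]) + nodes**2
        m = vals.max()
        total += m + np.log(np.sum(weights * np.exp(vals - m))) \
            + 0.5 * np.log(2.0) + np.log(h)
    return total


def fit_tumor_fraction(
    cells: pd.DataFrame,
    grouping_mode: str = "random_intercept",
    n_quad: int = 25,
    reference: str = "control",
) -> ModelFit:
    """Logistic regression of tumor-cell status on genotype.

    ``cells`` needs columns ``is_tumor``, ``genotype``, ``sample_id`` with
    at least two samples per genotype. Modes: ``random_intercept``
    (sample random effect integrated by adaptive Gauss-Hermite),
    ``fixed_sample``, ``cluster_robust``, or ``none``.
    """
    y = cells["is_tumor"].to_numpy(dtype=float)
    for geno, grp in cells.groupby("genotype"):
        if grp["sample_id"].nunique() < 2:
            raise ValueError(f"genotype {geno!r} has < 2 samples")
        rate = grp["is_tumor"].mean()
        if rate in (0.0, 1.0):
            raise ValueError(
                f"complete separation: genotype {geno!r} is all "
                f"{'tumor' if rate else 'non-tumor'}"
            )

    if grouping_mode == "random_intercept":
        # collapse to per-sample sufficient statistics
        agg = cells.groupby(["sample_id", "genotype"])["is_tumor"].agg(["sum", "size"])
        agg = agg.reset_index()
        geno = _genotype_indicator(agg["genotype"], reference)
        Xg = np.column_stack([np.ones(len(agg)), geno])
        names = ["intercept", "genotype_ko"]
        clusters = [(Xg[i], float(agg["sum"][i]), float(agg["size"][i]))
                    for i in range(len(agg))]
        nodes, weights = np.polynomial.hermite.hermgauss(n_quad)

        def nll(params):
            return -_agh_logistic_loglik(params[:-1], params[-1], clusters,
                                         nodes, weights)

        glm = sm.GLM(y, sm.add_constant(_genotype_indicator(cells["genotype"],
                                                            reference)),
                     family=sm.families.Binomial()).fit()
        x0 = np.concatenate([glm.params, [np.log(0.25)]])
        res = optimize.minimize(nll, x0, method="L-BFGS-B",
                                options={"gtol": 1e-9, "maxiter": 300})
        H = approx_hess(res.x, nll)
        cov = np.linalg.pinv(H)
        ses = np.sqrt(np.clip(np.diag(cov), 0, None))
        table = _param_table(names, res.x[:-1], ses[:-1])
        return ModelFit(
            name="tumor_fraction_logistic", params=table,
            loglik=-float(res.fun), converged=bool(res.success),
            grouping=grouping_mode, re_sd=float(np.exp(res.x[-1])),
            metadata={"quadrature_nodes": n_quad,
                      "genotype_reference": reference},
        )

    if grouping_mode not in ("fixed_sample", "cluster_robust", "none"):
        raise ValueError(f"unknown grouping_mode {grouping_mode!r}")
    X, names = _design(cells, "fixed_sample" if grouping_mode == "fixed_sample"
                       else "none", reference=reference)
    model = sm.GLM(y, X, family=sm.families.Binomial())
    if grouping_mode == "cluster_robust":
        fit = model.fit(cov_type="cluster",
                        cov_kwds={"groups": cells["sample_id"].to_numpy()})
    else:
        fit = model.fit()
    table = _param_table(names, fit.params, fit.bse)
    return ModelFit(
        name="tumor_fraction_logistic", params=table,
        loglik=float(fit.llf), converged=True, grouping=grouping_mode,
        metadata={"genotype_reference": reference},
    )


# ---------------------------------------------------------------------------
# Gaussian PC1 model
# ---------------------------------------------------------------------------

def _fit_lmm_random_intercept(y: np.ndarray, X: np.ndarray, groups: np.ndarray):
    """Gaussian random-intercept ML by profiling the variance ratio.

    With lambda = sigma_u^2 / sigma_e^2, GLS reduces to OLS on
    within-cluster shrunken data (y_ij - theta_i * ybar_i with
    theta_i = 1 - 1/sqrt(1 + n_i lambda)); sigma_e^2 and beta have closed
    forms given lambda, so only lambda is optimized. Well behaved at the
    lambda = 0 boundary, where the model collapses to OLS.
    """
    n = len(y)
    uniq, inv = np.unique(groups, return_inverse=True)
    n_i = np.bincount(inv).astype(float)

    def profile_nll(lam):
        theta = 1.0 - 1.0 / np.sqrt(1.0 + n_i * lam)
        ybar = np.bincount(inv, weights=y) / n_i
        Xbar = np.vstack([np.bincount(inv, weights=X[:, j]) / n_i
                          for j in range(X.shape[1])]).T
        ys = y - theta[inv] * ybar[inv]
        Xs = X - theta[inv, None] * Xbar[inv]
        beta, *_ = np.linalg.lstsq(Xs, ys, rcond=None)
        rss = float(np.sum((ys - Xs @ beta) ** 2))
        sigma2 = rss / n
        ll = -0.5 * (n * (np.log(2 * np.pi * sigma2) + 1.0)
                     + np.sum(np.log1p(n_i * lam)))
        return -ll, beta, sigma2, Xs

    res = optimize.minimize_scalar(
        lambda t: profile_nll(np.expm1(t))[0] if t > 0 else profile_nll(0.0)[0],
        bounds=(0.0, 10.0), method="bounded",
        options={"xatol": 1e-10},
    )
    lam = float(np.expm1(res.x)) if res.x > 0 else 0.0
    nll0 = profile_nll(0.0)[0]
    if nll0 <= res.fun:     # boundary solution: no sample variance
        lam = 0.0
    nll, beta, sigma2, Xs = profile_nll(lam)
    cov = sigma2 * np.linalg.pinv(Xs.T @ Xs)
    ses = np.sqrt(np.clip(np.diag(cov), 0, None))
    re_sd = float(np.sqrt(lam * sigma2))
    return beta, ses, -float(nll), re_sd

def fit_pc1(
    scores: pd.DataFrame,
    grouping_mode: str = "random_intercept",
    size_scale: str = "log",
    reference: str = "control",
) -> ModelFit:
    """Gaussian model of lesion PC1 on size, genotype, and interaction.

    ``scores`` needs columns ``PC1``, ``size``, ``genotype``, ``sample_id``.
    Size enters logged by default (sizes span orders of magnitude);
    ``size_scale='raw'`` uses the raw count. ``random_intercept`` uses a
    linear mixed model (REML off) with a sample intercept.
    """
    if size_scale not in ("log", "raw"):
        raise ValueError("size_scale must be 'log' or 'raw'")
    y = scores["PC1"].to_numpy(dtype=float)
    size = scores["size"].to_numpy(dtype=float)
    s = np.log(size) if size_scale == "log" else size
    # center the size covariate so the genotype main effect is evaluated at
    # the typical lesion size rather than extrapolated to size = 1, and the
    # interaction term is decorrelated from the main effects
    center = float(s.mean())
    s = s - center
    geno = _genotype_indicator(scores["genotype"], reference)
    extra = {"size": s}
    if geno is not None:
        extra["size:genotype_ko"] = s * geno

    if grouping_mode == "random_intercept":
        cols = {"intercept": np.ones(len(y))}
        if geno is not None:
            cols["genotype_ko"] = geno
        cols.update(extra)
        names = list(cols)
        X = np.column_stack([cols[c] for c in names])
        beta, ses, llf, re_sd = _fit_lmm_random_intercept(
            y, X, scores["sample_id"].to_numpy())
        table = _param_table(names, beta, ses)
        return ModelFit(
            name="pc1_gaussian", params=table, loglik=llf,
            converged=True, grouping=grouping_mode, re_sd=re_sd,
            metadata={"size_scale": size_scale, "size_center": center,
                      "genotype_reference": reference},
        )

    X, names = _design(scores, "fixed_sample" if grouping_mode == "fixed_sample"
                       else "none", extra=extra, reference=reference)
    model = sm.OLS(y, X)
    if grouping_mode == "cluster_robust":
        fit = model.fit(cov_type="cluster",
                        cov_kwds={"groups": scores["sample_id"].to_numpy()})
    else:
        fit = model.fit()
    table = _param_table(names, fit.params, fit.bse)
    return ModelFit(
        name="pc1_gaussian", params=table, loglik=float(fit.llf),
        converged=True, grouping=grouping_mode,
        metadata={"size_scale": size_scale, "size_center": center,
                  "genotype_reference": reference},
    )
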