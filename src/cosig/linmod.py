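"""Genewise linear models with precision weights and empirical-Bayes moderation.

Implements the standard RNA-seq differential-expression stack: mean-variance
trend estimation producing per-observation precision weights ("voom"),
genewise weighted least squares, empirical-Bayes shrinkage of residual
variances toward a common prior (yielding moderated t-statistics with
augmented degrees of freedom), fold-change-threshold tests (TREAT), and
Benjamini-Hochberg FDR control.

The moderation prior is fitted by moment matching on the log residual
variances: with ``e_g = log s_g^2 - psi(d_g/2) + log(d_g/2)``, the prior
degrees of freedom d0 solve ``trigamma(d0/2) = 2 * excess variance of e`` and
the prior variance is recovered from the mean of e.  Posterior variances are
``(d0 s0^2 + d_g s_g^2) / (d0 + d_g)``.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import special, stats
from statsmodels.nonparametric.smoothers_lowess import lowess as sm_lowess

from .expression import CountMatrix, LogExpression, NormFactors

__all__ = [
    "Design",
    "GenewiseFit",
    "ModerationPrior",
    "DEResult",
    "group_means_design",
    "voom_weights",
    "fit_genewise_lm",
    "moderate_variances",
    "treat_test",
    "moderated_t_test",
    "bh_fdr",
]


@dataclass
class Design:
    """Sample-by-coefficient design matrix with named contrasts.

    ``matrix`` must have full column rank.  Contrast vectors have one entry
    per coefficient; for a contrast "P-Q" a positive estimate means up in P.
    """

    matrix: pd.DataFrame
    contrasts: dict[str, np.ndarray] = field(default_factory=dict)

    def __post_init__(self) -> None:
        X = self.matrix.to_numpy(dtype=float)
        if np.linalg.matrix_rank(X) < X.shape[1]:
            _, r = np.linalg.qr(X)
            diag = np.abs(np.diag(r))
            aliased = [self.matrix.columns[i] for i in range(len(diag))
                       if diag[i] < 1e-10 * diag.max()]
            raise ValueError(f"design matrix is rank deficient; aliased coefficients: {aliased}")
        for name, c in self.contrasts.items():
            if len(c) != X.shape[1]:
                raise ValueError(f"contrast {name!r} has wrong length")

    @property
    def n_samples(self) -> int:
        return self.matrix.shape[0]

    @property
    def n_coef(self) -> int:
        return self.matrix.shape[1]

    @property
    def coef_names(self) -> list[str]:
        return list(self.matrix.columns)

    def contrast_vector(self, contrast) -> np.ndarray:
        if isinstance(contrast, str):
            contrast = self.contrasts[contrast]
        c = np.asarray(contrast, dtype=float)
        if len(c) != self.n_coef:
            raise ValueError("contrast length must equal the coefficient count")
        return c


def group_means_design(groups: pd.Series, pairwise: bool = True) -> Design:
    """Group-means (cell-means) design with pairwise difference contrasts.

    Each population gets one indicator coefficient; the contrast ``"P-Q"``
    estimates mean(P) - mean(Q), so a positive log-fold change means up in P.
    """
    groups = pd.Series(groups)
    levels = list(pd.unique(groups))
    mat = pd.DataFrame(
        {lev: (groups == lev).astype(float).to_numpy() for lev in levels},
        index=groups.index,
    )
    contrasts: dict[str, np.ndarray] = {}
    if pairwise:
        for i, a in enumerate(levels):
            for b in levels[i + 1:]:
                c = np.zeros(len(levels))
                c[i] = 1.0
                c[levels.index(b)] = -1.0
                contrasts[f"{a}-{b}"] = c
                contrasts[f"{b}-{a}"] = -c
    return Design(mat, contrasts)


@dataclass
class GenewiseFit:
    """Per-gene least-squares results.

    ``coef`` holds estimates; ``cov_unscaled`` the per-gene unscaled
    coefficient covariance (X'WX)^-1 (shape G x p x p, or 1 x p x p when all
    genes share it); ``sigma2`` the residual variances; ``df_residual`` the
    residual degrees of freedom; ``amean`` the average log expression.  The
    fitted expression object is retained so downstream resampling tests can
    recompute orthogonal effect coordinates.
    """

    coef: pd.DataFrame
    cov_unscaled: np.ndarray
    sigma2: pd.Series
    df_residual: float
    amean: pd.Series
    design: Design
    expr: LogExpression | None = None

    @property
    def stdev_unscaled(self) -> pd.DataFrame:
        u = np.sqrt(np.diagonal(self.cov_unscaled, axis1=1, axis2=2))
        if u.shape[0] == 1:
            u = np.broadcast_to(u, (len(self.coef), u.shape[1]))
        return pd.DataFrame(u, index=self.coef.index, columns=self.coef.columns)

    def contrast_fit(self, contrast) -> tuple[pd.Series, pd.Series]:
        """Estimate and unscaled standard error of c'beta for every gene."""
        c = self.design.contrast_vector(contrast)
        beta = self.coef.to_numpy() @ c
        u2 = np.einsum("i,gij,j->g", c, self.cov_unscaled, c)
        u = np.sqrt(u2)
        if len(u) == 1:
            u = np.repeat(u, len(beta))
        return (
            pd.Series(beta, index=self.coef.index),
            pd.Series(u, index=self.coef.index),
        )


@dataclass
class ModerationPrior:
    """Empirical-Bayes variance prior and per-gene posterior variances."""

    df_prior: float  # may be inf
    var_prior: float
    var_post: pd.Series
    df_total: float

    def __post_init__(self) -> None:
        if not self.df_prior > 0:
            raise ValueError("prior df must be > 0")


def fit_genewise_lm(expr: LogExpression, design: Design) -> GenewiseFit:
    """Weighted least squares per gene.

    Uses per-observation precision weights when the expression object carries
    them; otherwise ordinary least squares (vectorized over genes).  Residual
    df is samples - rank(design) for every gene (complete data).
    """
    X = design.matrix.to_numpy(dtype=float)
    n, p = X.shape
    if n - p < 1:
        raise ValueError("design leaves no residual degrees of freedom")
    Y = expr.values.to_numpy()
    W = expr.weights.to_numpy() if expr.weights is not None else None
    G = Y.shape[0]
    if W is None:
        cov = np.linalg.inv(X.T @ X)[None, :, :]
        coefs = (cov[0] @ X.T @ Y.T).T
        resid = Y - coefs @ X.T
        s2 = np.sum(resid**2, axis=1) / (n - p)
    else:
        coefs = np.empty((G, p))
        cov = np.empty((G, p, p))
        s2 = np.empty(G)
        for g in range(G):
            sw = np.sqrt(W[g])
            Xw = X * sw[:, None]
            yw = Y[g] * sw
            cov[g] = np.linalg.inv(Xw.T @ Xw)
            coefs[g] = cov[g] @ (Xw.T @ yw)
            r = yw - Xw @ coefs[g]
            s2[g] = float(r @ r) / (n - p)
    return GenewiseFit(
        coef=pd.DataFrame(coefs, index=expr.genes, columns=design.coef_names),
        cov_unscaled=cov,
        sigma2=pd.Series(s2, index=expr.genes),
        df_residual=float(n - p),
        amean=expr.values.mean(axis=1),
        design=design,
        expr=expr,
    )


# ---------------------------------------------------------------------------
# voom


def voom_weights(
    cm: CountMatrix,
    design: Design,
    norm: NormFactors | None = None,
    span: float = 0.5,
) -> LogExpression:
    """log2-CPM values with mean-variance precision weights.

    Fits genewise OLS on log-CPM, smooths sqrt(residual sd) against average
    log2 count with lowess (span 0.5, 3 robustness iterations), predicts the
    sqrt-sd at every fitted observation and sets the weight to the predicted
    value to the power -4.  The trend is extrapolated flat beyond the data
    range.
    """
    lib = cm.lib_sizes.to_numpy()
    if norm is not None:
        lib = lib * norm.factors.reindex(cm.samples).to_numpy()
    n, p = len(lib), design.n_coef
    if n - p < 2:
        raise ValueError("need at least 2 residual df to estimate the mean-variance trend")
    y = np.log2((cm.counts.to_numpy() + 0.5) / (lib + 1.0) * 1e6)
    expr = LogExpression(pd.DataFrame(y, index=cm.genes, columns=cm.samples))
    fit = fit_genewise_lm(expr, design)
    sx = fit.amean.to_numpy() + np.mean(np.log2(lib + 1.0)) - np.log2(1e6)
    sy = np.sqrt(np.sqrt(fit.sigma2.to_numpy()))  # quarter-root variance
    trend = sm_lowess(sy, sx, frac=span, it=3, return_sorted=True)
    tx, ty = trend[:, 0], trend[:, 1]
    fitted = fit.coef.to_numpy() @ design.matrix.to_numpy(dtype=float).T
    fitted_logcount = fitted + np.log2(lib + 1.0)[None, :] - np.log2(1e6)
    pred = np.interp(fitted_logcount, tx, ty)  # flat beyond range
    w = pred**-4.0
    return LogExpression(
        pd.DataFrame(y, index=cm.genes, columns=cm.samples),
        weights=pd.DataFrame(w, index=cm.genes, columns=cm.samples),
        provenance={"transform": "voom", "span": span, "normalized": norm is not None,
                    "trend_x": tx, "trend_y": ty},
    )


# ---------------------------------------------------------------------------
# empirical Bayes


def _trigamma_inverse(x: float) -> float:
    """Solve trigamma(y) = x by Newton iteration."""
    if x <= 0:
        return np.inf
    if x > 1e7:
        return 1.0 / np.sqrt(x)
    if x < 1e-6:
        return 1.0 / x
    y = 0.5 + 1.0 / x
    for _ in range(50):
        tri = special.polygamma(1, y)
        dif = tri * (1.0 - tri / x) / special.polygamma(2, y)
        y += dif
        if -dif / y < 1e-10:
            break
    return float(y)


def moderate_variances(fit: GenewiseFit, df_cap_factor: float = 10.0) -> ModerationPrior:
    """Estimate the variance prior and squeeze genewise variances toward it.

    If the spread of log variances does not exceed its expected sampling
    variance -- or the fitted prior df exceeds ``df_cap_factor`` times the
    residual df -- the prior df is declared infinite and every posterior
    variance equals the prior variance.
    """
    s2 = fit.sigma2.to_numpy()
    d = fit.df_residual
    if len(s2) < 2:
        raise ValueError("need at least 2 genes to moderate variances")
    if np.all(s2 == 0):
        raise ValueError("all residual variances are zero")
    z = np.log(np.maximum(s2, 1e-300))
    if np.ptp(z) == 0:  # degenerate: no spread at all, prior is the common value
        common = float(s2[0])
        return ModerationPrior(df_prior=np.inf, var_prior=common,
                               var_post=pd.Series(np.full_like(s2, common),
                                                  index=fit.sigma2.index),
                               df_total=np.inf)
    e = z - special.digamma(d / 2.0) + np.log(d / 2.0)
    emean = e.mean()
    evar = e.var(ddof=1) - special.polygamma(1, d / 2.0)
    if evar > 0:
        df_prior = 2.0 * _trigamma_inverse(evar)
        if df_prior > df_cap_factor * d:
            df_prior = np.inf
    else:
        df_prior = np.inf
    if np.isinf(df_prior):
        var_prior = float(np.exp(emean))
        var_post = np.full_like(s2, var_prior)
    else:
        var_prior = float(np.exp(emean + special.digamma(df_prior / 2.0) - np.log(df_prior / 2.0)))
        var_post = (df_prior * var_prior + d * s2) / (df_prior + d)
    return ModerationPrior(
        df_prior=df_prior,
        var_prior=var_prior,
        var_post=pd.Series(var_post, index=fit.sigma2.index),
        df_total=float(df_prior + d) if np.isfinite(df_prior) else np.inf,
    )


# ---------------------------------------------------------------------------
# tests


@dataclass
class DEResult:
    """Per-gene test results for one contrast.

    ``table`` has columns logFC, t, p, adj_p indexed by gene.
    """

    table: pd.DataFrame
    contrast: str
    test: str  # "moderated_t" or "treat"
    tau: float = 1.0

    def write(self, path) -> None:
        out = self.table.copy()
        out["test"] = self.test
        out["tau"] = self.tau
        out.to_csv(path, sep="\t", index_label="gene")


def _t_sf(x, df):
    return stats.t.sf(x, df) if np.isfinite(df) else stats.norm.sf(x)


def moderated_t_test(fit: GenewiseFit, prior: ModerationPrior, contrast) -> DEResult:
    """Two-sided moderated t-test for a contrast."""
    return treat_test(fit, prior, contrast, tau_fc=1.0)


def treat_test(fit: GenewiseFit, prior: ModerationPrior, contrast, tau_fc: float = 1.0) -> DEResult:
    """Test whether the log fold change exceeds a threshold of log2(tau_fc).

    With moderated standard error se = s-tilde * u and total df d0 + d, the
    p-value is ``P(T >= (|b| - delta)/se) + P(T >= (|b| + delta)/se)`` where
    ``delta = log2(tau_fc)``.  At tau_fc = 1 this reduces exactly to the
    two-sided moderated t-test.
    """
    if tau_fc < 1:
        raise ValueError("tau_fc must be >= 1")
    delta = np.log2(tau_fc)
    beta, u = fit.contrast_fit(contrast)
    se = np.sqrt(prior.var_post.to_numpy()) * u.to_numpy()
    df = prior.df_total
    absb = np.abs(beta.to_numpy())
    p = _t_sf((absb - delta) / se, df) + _t_sf((absb + delta) / se, df)
    p = np.minimum(p, 1.0)
    tstat = np.sign(beta.to_numpy()) * (absb - delta) / se
    name = contrast if isinstance(contrast, str) else "custom"
    table = pd.DataFrame(
        {"logFC": beta, "t": tstat, "p": p, "adj_p": bh_fdr(p)}, index=fit.coef.index
    )
    return DEResult(table=table, contrast=name,
                    test="moderated_t" if tau_fc == 1 else "treat", tau=tau_fc)


def bh_fdr(pvalues) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values, order-preserving.

    NaN inputs propagate as NaN and are excluded from the number of tests.
    """
    p = np.asarray(pvalues, dtype=float)
    out = np.full(p.shape, np.nan)
    ok = ~np.isnan(p)
    pv = p[ok]
    if (pv < 0).any() or (pv > 1).any():
        raise ValueError("p-values must lie in [0, 1]")
    m = len(pv)
    if m == 0:
        return out
    order = np.argsort(pv, kind="stable")
    ranked = pv[order] * m / np.arange(1, m + 1)
    ranked = np.minimum.accumulate(ranked[::-1])[::-1]
    adj = np.empty(m)
    adj[order] = np.minimum(ranked, 1.0)
    out[ok] = adj
    return out
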