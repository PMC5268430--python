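"""Weighted rotation gene-set tests and barcode-plot enrichment data.

A rotation test builds the null distribution of a gene-set statistic by
randomly rotating, in residual space, the orthogonal effect coordinates of
the tested contrast.  Each gene is reduced to a (d+1)-vector: the contrast
effect plus d independent residual effects (nuisance coefficients projected
out).  One random unit vector per iteration is applied to *all* set genes,
preserving the inter-gene correlation that makes the test exact for
correlated sets.

The set statistic is the weighted mean of moderated-t z-scores,
``T = sum(w_g z_g) / sum(|w_g|)``; signed weights let down-regulated
signature genes count toward the same direction as up-regulated ones.
Directional p-values are ``(b + 1) / (B + 1)`` where b counts rotations at
least as extreme as the observed statistic.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import scipy.linalg
from scipy import stats

from .linmod import GenewiseFit, ModerationPrior
from .signatures import SignatureSet

__all__ = ["RotationResult", "BarcodeData", "t_to_z", "rotation_gene_set_test", "barcode_data"]


def t_to_z(t, df):
    """Convert t-statistics to standard-normal equivalents.

    ``z = Phi^-1(F_t(t; df))``, evaluated through the survival function so
    that far tails keep full floating-point precision; strictly increasing
    in t with z(0) = 0.
    """
    t = np.asarray(t, dtype=float)
    if not np.all(np.isfinite(t)):
        raise ValueError("t statistics must be finite")
    if not df > 0:
        raise ValueError("df must be > 0")
    if np.isinf(df):
        return t.copy() if t.ndim else float(t)
    sf = stats.t.sf(np.abs(t), df)
    z = -np.sign(t) * stats.norm.ppf(sf)
    return z if z.ndim else float(z)


@dataclass
class RotationResult:
    """Outcome of one rotation gene-set test."""

    statistic: float
    p_up: float
    p_down: float
    p_mixed: float
    n_rotations: int
    seed: int
    n_genes: int
    exceed_up: int
    exceed_down: int
    exceed_mixed: int

    def as_series(self) -> pd.Series:
        return pd.Series({
            "statistic": self.statistic, "p_up": self.p_up, "p_down": self.p_down,
            "p_mixed": self.p_mixed, "n_rotations": self.n_rotations,
            "n_genes": self.n_genes, "seed": self.seed,
        })


def _contrast_effects(fit: GenewiseFit, contrast, genes: pd.Index):
    """Orthogonal (effect, residual) coordinates for the tested contrast.

    Reparameterizes the design so the contrast is the last coefficient,
    takes a full QR decomposition, and returns per gene the contrast effect
    (oriented so positive means positive contrast) and the d residual
    effects.  Per-observation precision weights, when present, are absorbed
    by scaling each gene's response and design by sqrt(weight).
    """
    c = fit.design.contrast_vector(contrast)
    X = fit.design.matrix.to_numpy(dtype=float)
    n, p = X.shape
    d = n - p
    if d < 1:
        raise ValueError("rotation test needs at least 1 residual df")
    # reparameterize so the contrast is the last coefficient: rows of P are an
    # orthonormal complement of c followed by c itself
    cn = c / np.linalg.norm(c)
    Qc, _ = scipy.linalg.qr(cn.reshape(-1, 1), mode="full")
    P = np.vstack([Qc[:, 1:].T, c])
    Xp = X @ np.linalg.inv(P)

    Y = fit.expr.values.loc[genes].to_numpy()
    W = fit.expr.weights.loc[genes].to_numpy() if fit.expr.weights is not None else None
    G = len(genes)
    V = np.empty((G, d + 1))
    if W is None:
        Q, R = scipy.linalg.qr(Xp, mode="full")
        sign = 1.0 if R[p - 1, p - 1] >= 0 else -1.0
        U = Y @ Q  # gene x n effects
        V[:, 0] = sign * U[:, p - 1]
        V[:, 1:] = U[:, p:]
    else:
        for g in range(G):
            sw = np.sqrt(W[g])
            Q, R = scipy.linalg.qr(Xp * sw[:, None], mode="full")
            sign = 1.0 if R[p - 1, p - 1] >= 0 else -1.0
            u = Q.T @ (Y[g] * sw)
            V[g, 0] = sign * u[p - 1]
            V[g, 1:] = u[p:]
    return V, d


def _moderated_z(effect, s2, prior: ModerationPrior, d: float):
    if np.isinf(prior.df_prior):
        s2_post = prior.var_prior
        df_total = np.inf
    else:
        s2_post = (prior.df_prior * prior.var_prior + d * s2) / (prior.df_prior + d)
        df_total = prior.df_prior + d
    t = effect / np.sqrt(s2_post)
    return t_to_z(t, df_total)


def rotation_gene_set_test(
    fit: GenewiseFit,
    prior: ModerationPrior,
    contrast,
    set_genes,
    weights=None,
    B: int = 9999,
    seed: int = 0,
) -> RotationResult:
    """Weighted rotation gene-set test for one contrast.

    ``set_genes`` are intersected with the fitted genes; ``weights`` (signed,
    defaulting to 1) are aligned to the set genes.  Each of the B rotations
    draws a single random unit vector of dimension d+1 (normalized Gaussian),
    applies it to every set gene's effect coordinates, recomputes residual
    variances as ``(|v|^2 - effect^2)/d``, re-moderates them with the fixed
    prior, and recomputes the weighted-mean z statistic.  ``p_up`` counts
    rotations with a statistic >= the observed one, ``p_down`` <=, and
    ``p_mixed`` uses the |z| version of the statistic with the same
    rotations.
    """
    set_genes = pd.Index(set_genes)
    genes = set_genes[set_genes.isin(fit.coef.index)]
    if len(genes) == 0:
        raise ValueError("no gene of the set is present in the fit")
    if weights is None:
        w = np.ones(len(genes))
    else:
        w = pd.Series(weights).reindex(genes)
        if w.isna().any():
            raise ValueError("weights must cover every set gene present in the fit")
        w = w.to_numpy(dtype=float)
    if np.sum(np.abs(w)) == 0:
        raise ValueError("weights must not all be zero")

    V, d = _contrast_effects(fit, contrast, genes)
    norms2 = np.sum(V**2, axis=1)
    wsum = np.sum(np.abs(w))

    def set_stats(effect, s2):
        z = _moderated_z(effect, s2, prior, d)
        return float(np.sum(w * z) / wsum), float(np.sum(np.abs(w) * np.abs(z)) / wsum)

    s2_obs = (norms2 - V[:, 0] ** 2) / d
    T_obs, M_obs = set_stats(V[:, 0], s2_obs)

    rng = np.random.Generator(np.random.PCG64(np.random.SeedSequence(seed)))
    R = rng.standard_normal((B, d + 1))
    R /= np.linalg.norm(R, axis=1, keepdims=True)
    E = V @ R.T  # genes x B rotated effects
    S2 = np.maximum(norms2[:, None] - E**2, 0.0) / d
    Z = _moderated_z(E, S2, prior, d)
    T_rot = (w @ Z) / wsum
    M_rot = (np.abs(w) @ np.abs(Z)) / wsum

    b_up = int(np.sum(T_rot >= T_obs))
    b_down = int(np.sum(T_rot <= T_obs))
    b_mixed = int(np.sum(M_rot >= M_obs))
    return RotationResult(
        statistic=T_obs,
        p_up=(b_up + 1) / (B + 1),
        p_down=(b_down + 1) / (B + 1),
        p_mixed=(b_mixed + 1) / (B + 1),
        n_rotations=B,
        seed=seed,
        n_genes=len(genes),
        exceed_up=b_up,
        exceed_down=b_down,
        exceed_mixed=b_mixed,
    )


@dataclass
class BarcodeData:
    """Data behind a barcode enrichment plot.

    Genes are ranked 1..G from most up- to most down-regulated.  ``pos_ranks``
    and ``neg_ranks`` are the positions of positive- and negative-weight set
    genes; the worms are smoothed local densities of those positions divided
    by the uniform expectation (1 means no enrichment).
    """

    ranked_stats: pd.Series
    pos_ranks: np.ndarray
    neg_ranks: np.ndarray
    worm_pos: np.ndarray
    worm_neg: np.ndarray
    bandwidth: float
    set_weights: pd.Series = field(default=None)  # type: ignore[assignment]

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({
            "gene": self.ranked_stats.index,
            "stat": self.ranked_stats.to_numpy(),
            "rank": np.arange(1, len(self.ranked_stats) + 1),
            "worm_pos": self.worm_pos,
            "worm_neg": self.worm_neg,
        })


def _worm(set_ranks: np.ndarray, G: int, h: float) -> np.ndarray:
    """Triangular-kernel relative enrichment of set ranks along 1..G."""
    if len(set_ranks) == 0:
        return np.full(G, np.nan)
    half = int(np.floor(h))
    u = np.arange(-half, half + 1)
    kernel = np.maximum(0.0, 1.0 - np.abs(u) / h)
    ind = np.zeros(G)
    ind[set_ranks - 1] = 1.0
    num = np.convolve(ind, kernel, mode="same")
    den = np.convolve(np.ones(G), kernel, mode="same") * (len(set_ranks) / G)
    return num / den


def barcode_data(gene_stats: pd.Series, signature: SignatureSet,
                 smoothing_bandwidth: float | None = None) -> BarcodeData:
    """Ranked-statistic positions of signature genes with enrichment worms.

    ``gene_stats`` holds one statistic per gene for the tumour contrast;
    genes are sorted descending (most up-regulated first, stable in input
    order for ties).  The default bandwidth is G/20 ranks.
    """
    stats_sorted = gene_stats.sort_values(ascending=False, kind="stable")
    G = len(stats_sorted)
    present = signature.genes[signature.genes.isin(stats_sorted.index)]
    if len(present) == 0:
        raise ValueError("no signature gene appears in the ranked statistics")
    h = smoothing_bandwidth if smoothing_bandwidth is not None else G / 20.0
    rank_of = pd.Series(np.arange(1, G + 1), index=stats_sorted.index)
    w = signature.weights.loc[present]
    pos_ranks = np.sort(rank_of.loc[w.index[w > 0]].to_numpy())
    neg_ranks = np.sort(rank_of.loc[w.index[w < 0]].to_numpy())
    return BarcodeData(
        ranked_stats=stats_sorted,
        pos_ranks=pos_ranks,
        neg_ranks=neg_ranks,
        worm_pos=_worm(pos_ranks, G, h),
        worm_neg=_worm(neg_ranks, G, h),
        bandwidth=h,
        set_weights=w,
    )
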