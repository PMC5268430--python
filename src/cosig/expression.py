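"""Count-matrix containers, I/O, filtering, TMM normalization and log transforms.

The central objects are :class:`CountMatrix` (non-negative integer read counts,
genes x samples, with library sizes and group labels) and
:class:`LogExpression` (log2-scale values, optionally carrying per-observation
precision weights).  Normalization follows the trimmed-mean-of-M-values (TMM)
scheme: pairwise log-ratios against a reference library are doubly trimmed and
averaged with precision weights, and the resulting per-sample factors are
rescaled to have product one.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import scipy.io
import scipy.sparse
from scipy.stats import rankdata

__all__ = [
    "CountMatrix",
    "NormFactors",
    "LogExpression",
    "read_count_matrix",
    "write_count_matrix",
    "filter_genes",
    "tmm_factors",
    "log_cpm",
    "rpkm",
    "leading_logfc_mds",
    "zscore_rows",
]


@dataclass
class CountMatrix:
    """Gene-by-sample matrix of non-negative integer read counts.

    Parameters
    ----------
    counts:
        DataFrame indexed by gene identifier with sample identifiers as
        columns.  Values must be non-negative integers.
    groups:
        Optional mapping of sample identifier to population/group label.
    lib_sizes:
        Per-sample library sizes.  Defaults to the column sums.
    """

    counts: pd.DataFrame
    groups: pd.Series | None = None
    lib_sizes: pd.Series = field(default=None)  # type: ignore[assignment]

    def __post_init__(self) -> None:
        if self.counts.index.has_duplicates:
            dups = self.counts.index[self.counts.index.duplicated()].unique()
            raise ValueError(f"duplicate gene identifiers: {list(dups[:5])}")
        if self.counts.columns.has_duplicates:
            dups = self.counts.columns[self.counts.columns.duplicated()].unique()
            raise ValueError(f"duplicate sample identifiers: {list(dups[:5])}")
        arr = self.counts.to_numpy()
        if np.any(arr < 0) or not np.allclose(arr, np.round(arr)):
            bad = np.argwhere((arr < 0) | ~np.isclose(arr, np.round(arr)))[0]
            raise ValueError(
                "counts must be non-negative integers; offending entry at "
                f"gene {self.counts.index[bad[0]]!r}, sample {self.counts.columns[bad[1]]!r}"
            )
        self.counts = self.counts.astype(np.int64)
        if self.lib_sizes is None:
            self.lib_sizes = self.counts.sum(axis=0).astype(float)
        else:
            self.lib_sizes = pd.Series(self.lib_sizes, dtype=float).reindex(self.counts.columns)
            if self.lib_sizes.isna().any() or (self.lib_sizes <= 0).any():
                raise ValueError("library sizes must be positive and cover every sample")
        if self.groups is not None:
            self.groups = pd.Series(self.groups).reindex(self.counts.columns)

    @property
    def genes(self) -> pd.Index:
        return self.counts.index

    @property
    def samples(self) -> pd.Index:
        return self.counts.columns

    @property
    def shape(self) -> tuple[int, int]:
        return self.counts.shape

    def cpm(self) -> pd.DataFrame:
        """Counts per million on raw (pre-normalization) library sizes."""
        return self.counts / self.lib_sizes.to_numpy() * 1e6

    def subset_genes(self, genes) -> "CountMatrix":
        return CountMatrix(self.counts.loc[genes], groups=self.groups, lib_sizes=self.lib_sizes)


@dataclass
class NormFactors:
    """Per-sample TMM scaling factors; the product of factors is one."""

    factors: pd.Series
    reference: str

    def __post_init__(self) -> None:
        self.factors = pd.Series(self.factors, dtype=float)
        if (self.factors <= 0).any():
            raise ValueError("normalization factors must be positive")
        logprod = np.log(self.factors.to_numpy()).sum()
        if abs(logprod) > 1e-10 * max(1, len(self.factors)):
            raise ValueError("normalization factors must multiply to 1")

    @classmethod
    def unit(cls, samples) -> "NormFactors":
        return cls(pd.Series(1.0, index=pd.Index(samples)), reference=list(samples)[0])


@dataclass
class LogExpression:
    """log2-scale expression values with optional per-observation weights.

    ``values`` is genes x samples; ``weights``, when present, has the same
    shape and holds strictly positive finite precision weights (inverse
    variances).  ``provenance`` records how the values were produced
    (prior count, normalization, transform name).
    """

    values: pd.DataFrame
    weights: pd.DataFrame | None = None
    provenance: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.weights is not None:
            if self.weights.shape != self.values.shape:
                raise ValueError("weights must have the same shape as values")
            w = self.weights.to_numpy()
            if not np.all(np.isfinite(w)) or np.any(w <= 0):
                raise ValueError("weights must be finite and > 0")

    @property
    def genes(self) -> pd.Index:
        return self.values.index

    @property
    def samples(self) -> pd.Index:
        return self.values.columns


# ---------------------------------------------------------------------------
# I/O


def write_count_matrix(cm: CountMatrix, path, fmt: str = "tsv") -> None:
    """Write counts as TSV (genes x samples) or MatrixMarket triplet + sidecars."""
    path = Path(path)
    if fmt == "tsv":
        cm.counts.to_csv(path, sep="\t", index_label="gene")
    elif fmt == "mtx":
        scipy.io.mmwrite(str(path), scipy.sparse.coo_matrix(cm.counts.to_numpy()))
        path.with_suffix(".rownames.txt").write_text("\n".join(map(str, cm.genes)) + "\n")
        path.with_suffix(".colnames.txt").write_text("\n".join(map(str, cm.samples)) + "\n")
    else:
        raise ValueError(f"unknown format {fmt!r}; expected 'tsv' or 'mtx'")


def read_count_matrix(path, fmt: str = "tsv", groups: pd.Series | None = None) -> CountMatrix:
    """Read a validated count matrix from TSV or MatrixMarket triplet format.

    MatrixMarket input expects ``<stem>.rownames.txt`` / ``<stem>.colnames.txt``
    sidecar files next to the matrix listing gene and sample identifiers.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    if fmt == "tsv":
        df = pd.read_csv(path, sep="\t", index_col=0, comment="#")
    elif fmt == "mtx":
        mat = scipy.io.mmread(str(path))  # raises on out-of-range indices
        genes = path.with_suffix(".rownames.txt").read_text().splitlines()
        samples = path.with_suffix(".colnames.txt").read_text().splitlines()
        dense = np.asarray(mat.todense() if scipy.sparse.issparse(mat) else mat)
        if dense.shape != (len(genes), len(samples)):
            raise ValueError(
                f"matrix shape {dense.shape} does not match sidecars "
                f"({len(genes)} genes, {len(samples)} samples)"
            )
        df = pd.DataFrame(dense, index=genes, columns=samples)
    else:
        raise ValueError(f"unknown format {fmt!r}; expected 'tsv' or 'mtx'")
    return CountMatrix(df, groups=groups)


# ---------------------------------------------------------------------------
# Filtering


def filter_genes(cm: CountMatrix, min_cpm: float = 1.0, min_samples: int = 3) -> CountMatrix:
    """Keep genes whose CPM exceeds ``min_cpm`` in at least ``min_samples`` samples.

    CPM is computed on raw library sizes (the filter runs before
    normalization).  The comparison is strict (> min_cpm).  The operation is
    idempotent: filtering preserves the original library sizes.
    """
    if min_cpm <= 0:
        raise ValueError("min_cpm must be > 0")
    if not 1 <= min_samples <= cm.shape[1]:
        raise ValueError(f"min_samples must be in [1, {cm.shape[1]}]")
    keep = (cm.cpm() > min_cpm).sum(axis=1) >= min_samples
    if not keep.any():
        warnings.warn("no genes pass the expression filter", UserWarning, stacklevel=2)
    return CountMatrix(cm.counts.loc[keep], groups=cm.groups, lib_sizes=cm.lib_sizes)


# ---------------------------------------------------------------------------
# TMM


def _tmm_pair(obs, ref, n_obs, n_ref, trim_M, trim_A):
    """Trimmed, precision-weighted mean of M-values for one sample pair."""
    p_obs = obs / n_obs
    p_ref = ref / n_ref
    ok = (obs > 0) & (ref > 0)
    if not ok.any():
        return np.nan
    M = np.log2(p_obs[ok] / p_ref[ok])
    A = 0.5 * np.log2(p_obs[ok] * p_ref[ok])
    # asymptotic (delta-method) variance of M
    v = (n_obs - obs[ok]) / (n_obs * obs[ok]) + (n_ref - ref[ok]) / (n_ref * ref[ok])
    if np.max(np.abs(M)) < 1e-6:
        return 0.0
    n = len(M)
    loM = np.floor(n * trim_M) + 1
    hiM = n + 1 - loM
    loA = np.floor(n * trim_A) + 1
    hiA = n + 1 - loA
    rM = rankdata(M)
    rA = rankdata(A)
    keep = (rM >= loM) & (rM <= hiM) & (rA >= loA) & (rA <= hiA)
    if not keep.any():
        return np.nan
    return np.sum(M[keep] / v[keep]) / np.sum(1.0 / v[keep])


def tmm_factors(cm: CountMatrix, trim_M: float = 0.30, trim_A: float = 0.05) -> NormFactors:
    """Trimmed-mean-of-M-values scaling factors.

    The reference sample is the one whose 75th-percentile CPM is closest to
    the mean 75th percentile over samples.  For every other sample, genewise
    log2 abundance ratios (M) and average log abundances (A) against the
    reference are computed over genes expressed in both; 30% of M-values and
    5% of A-values are trimmed from each tail and the factor is 2 to the
    precision-weighted mean of the retained M-values.  Factors are rescaled
    to multiply to one.
    """
    if cm.shape[1] < 2:
        raise ValueError("TMM requires at least two samples")
    counts = cm.counts.to_numpy(dtype=float)
    lib = cm.lib_sizes.to_numpy()
    if np.any(counts.sum(axis=0) == 0):
        raise ValueError("every sample must contain at least one nonzero count")
    q75 = np.quantile(counts, 0.75, axis=0) / lib
    ref_idx = int(np.argmin(np.abs(q75 - q75.mean())))
    logf = np.zeros(cm.shape[1])
    for j in range(cm.shape[1]):
        if j == ref_idx:
            continue
        f = _tmm_pair(counts[:, j], counts[:, ref_idx], lib[j], lib[ref_idx], trim_M, trim_A)
        if np.isnan(f):
            warnings.warn(
                f"sample {cm.samples[j]!r} shares no co-expressed genes with the "
                "reference; factor set to 1",
                UserWarning,
                stacklevel=2,
            )
            f = 0.0
        logf[j] = f
    logf -= logf.mean()  # geometric-mean rescale -> product of factors is 1
    return NormFactors(pd.Series(2.0**logf, index=cm.samples), reference=str(cm.samples[ref_idx]))


# ---------------------------------------------------------------------------
# Transforms


def _effective_lib(cm: CountMatrix, norm: NormFactors | None) -> np.ndarray:
    lib = cm.lib_sizes.to_numpy()
    if norm is not None:
        lib = lib * norm.factors.reindex(cm.samples).to_numpy()
    return lib


def log_cpm(cm: CountMatrix, norm: NormFactors | None = None, prior_count: float = 0.5) -> LogExpression:
    """log2 counts per million with a library-size-scaled prior count.

    With effective library sizes ``L_i`` (library size times normalization
    factor) and ``p_i = prior_count * L_i / mean(L)``, the value is
    ``log2((count + p_i) / (L_i + 2 p_i) * 1e6)``.  The prior scaling makes
    the transform invariant to a uniform change of sequencing depth.
    """
    if prior_count < 0:
        raise ValueError("prior_count must be >= 0")
    if prior_count == 0 and (cm.counts.to_numpy() == 0).any():
        raise ValueError("prior_count must be > 0 when zero counts are present")
    lib = _effective_lib(cm, norm)
    prior = prior_count * lib / lib.mean()
    vals = np.log2((cm.counts.to_numpy() + prior) / (lib + 2 * prior) * 1e6)
    return LogExpression(
        pd.DataFrame(vals, index=cm.genes, columns=cm.samples),
        provenance={"transform": "log_cpm", "prior_count": prior_count,
                    "normalized": norm is not None},
    )


def rpkm(
    cm: CountMatrix,
    gene_lengths: pd.Series,
    norm: NormFactors | None = None,
    prior_count: float = 0.5,
    log: bool = False,
) -> LogExpression | pd.DataFrame:
    """Reads per kilobase per million mapped reads.

    Genes without a length are dropped with a warning.  The log2 variant
    applies the same library-scaled prior convention as :func:`log_cpm`
    before dividing by gene length in kb.
    """
    gene_lengths = pd.Series(gene_lengths, dtype=float)
    if (gene_lengths.dropna() <= 0).any():
        raise ValueError("gene lengths must be > 0")
    lengths = gene_lengths.reindex(cm.genes)
    missing = lengths.index[lengths.isna()]
    if len(missing) > 0:
        warnings.warn(f"dropping {len(missing)} genes without length", UserWarning, stacklevel=2)
    keep = lengths.dropna().index
    sub = cm.subset_genes(keep)
    kb = (lengths.loc[keep] / 1000.0).to_numpy()[:, None]
    if log:
        lc = log_cpm(sub, norm=norm, prior_count=prior_count)
        vals = lc.values - np.log2(kb)
        return LogExpression(
            pd.DataFrame(vals, index=keep, columns=cm.samples),
            provenance={"transform": "log_rpkm", "prior_count": prior_count},
        )
    lib = _effective_lib(sub, norm)
    cpm = sub.counts.to_numpy() / lib * 1e6
    return pd.DataFrame(cpm / kb, index=keep, columns=cm.samples)


def zscore_rows(expr: LogExpression) -> pd.DataFrame:
    """Standardize each gene to mean 0 and standard deviation 1 across samples."""
    v = expr.values
    sd = v.std(axis=1, ddof=1).replace(0, np.nan)
    return v.sub(v.mean(axis=1), axis=0).div(sd, axis=0)


# ---------------------------------------------------------------------------
# Multidimensional scaling


def leading_logfc_mds(expr: LogExpression, top: int = 500, dims: int = 2):
    """Leading log-fold-change distances and classical MDS coordinates.

    The distance between two samples is the root-mean-square log2 difference
    over the ``min(top, G)`` genes with the largest absolute difference for
    that pair ("the genes that best distinguish each pair").  Coordinates come
    from classical (Torgerson) scaling of the squared distances, components
    ordered by descending eigenvalue.
    """
    if top < 1:
        raise ValueError("top must be >= 1")
    y = expr.values.to_numpy()
    n = y.shape[1]
    if dims > n - 1:
        raise ValueError(f"dims must be <= samples - 1 = {n - 1}")
    k = min(top, y.shape[0])
    dist = np.zeros((n, n))
    for i in range(n):
        for j in range(i + 1, n):
            diff2 = (y[:, i] - y[:, j]) ** 2
            topk = np.partition(diff2, len(diff2) - k)[len(diff2) - k:]
            dist[i, j] = dist[j, i] = np.sqrt(topk.mean())
    # Torgerson double centering
    d2 = dist**2
    J = np.eye(n) - np.ones((n, n)) / n
    B = -0.5 * J @ d2 @ J
    evals, evecs = np.linalg.eigh(B)
    order = np.argsort(-evals, kind="stable")
    evals, evecs = evals[order], evecs[:, order]
    coords = evecs[:, :dims] * np.sqrt(np.clip(evals[:dims], 0, None))
    dist_df = pd.DataFrame(dist, index=expr.samples, columns=expr.samples)
    coord_df = pd.DataFrame(
        coords, index=expr.samples, columns=[f"dim{i + 1}" for i in range(dims)]
    )
    return dist_df, coord_df
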