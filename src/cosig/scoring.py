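"""Tumour signature scoring and genomic-instability association.

The signature score of a tumour for a normal-cell population is the
weighted mean ``sum(w_g y_g) / sum(|w_g|)`` over the population's signature
genes, where ``y_g`` is the tumour's log expression and ``w_g`` the signed
signature weight.  Scores are then scaled to [0, 1] within each population
across tumours, so subtypes can be compared on a common footing.

Array preprocessing follows the usual probe-level conventions: drop probes
whose average log expression sits in the bottom half, drop unmapped probes,
and collapse multiple probes per gene to the one with the highest average
expression.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .expression import LogExpression
from .signatures import SignatureSet

__all__ = [
    "ScoreTable",
    "InstabilityTable",
    "prepare_array_matrix",
    "signature_scores",
    "scale_scores",
    "quartile_association",
]


@dataclass
class ScoreTable:
    """Tumour x population signature scores.

    ``raw`` and ``scaled`` are DataFrames indexed by tumour with one column
    per population; ``genes_used`` counts the signature genes found in the
    tumour matrix for each population.
    """

    raw: pd.DataFrame
    scaled: pd.DataFrame | None
    genes_used: pd.Series

    def write(self, path) -> None:
        out = self.raw.add_suffix("_raw")
        if self.scaled is not None:
            out = out.join(self.scaled.add_suffix("_scaled"))
        out.to_csv(path, sep="\t", index_label="tumor")


@dataclass
class InstabilityTable:
    """Per-tumour gene expression with proportion of genome altered."""

    gene: str
    expression: pd.Series
    proportion_altered: pd.Series

    def __post_init__(self) -> None:
        self.proportion_altered = self.proportion_altered.reindex(self.expression.index)
        ok = self.proportion_altered.dropna()
        if ((ok < 0) | (ok > 1)).any():
            raise ValueError("proportion of genome altered must lie in [0, 1]")


def prepare_array_matrix(probe_matrix: pd.DataFrame, probe_map: pd.Series) -> LogExpression:
    """Filter and collapse a probe-level log-intensity matrix to gene level.

    Probes whose average log expression is at or below the median of probe
    averages are dropped, as are probes without a mapped gene symbol.  When
    several surviving probes map to one gene, the probe with the highest
    average expression is kept.
    """
    avg = probe_matrix.mean(axis=1)
    keep = probe_matrix.index[avg > avg.median()]
    probe_map = pd.Series(probe_map)
    mapped = keep[keep.isin(probe_map.index)]
    mapped = mapped[probe_map.loc[mapped].notna()]
    if len(mapped) == 0:
        raise ValueError("no probe survives filtering and symbol mapping")
    sub = probe_matrix.loc[mapped]
    symbols = probe_map.loc[mapped]
    order = avg.loc[mapped].sort_values(ascending=False).index
    best = pd.Series(order).groupby(symbols.loc[order].to_numpy(), sort=False).first()
    out = sub.loc[best.to_numpy()]
    out.index = pd.Index(best.index, name="gene")
    return LogExpression(out.sort_index(), provenance={"transform": "probe_collapse"})


def signature_scores(tumors: LogExpression, signatures) -> ScoreTable:
    """Raw weighted-mean signature scores for every tumour and population.

    Signature genes absent from the tumour matrix are excluded from both the
    numerator and the denominator, keeping the score a weighted mean of the
    genes actually measured.
    """
    if isinstance(signatures, SignatureSet):
        signatures = [signatures]
    cols, used = {}, {}
    Y = tumors.values
    for sig in signatures:
        present = sig.genes[sig.genes.isin(Y.index)]
        if len(present) == 0:
            raise ValueError(f"no signature gene of population {sig.population!r} "
                             "is present in the tumour matrix")
        w = sig.weights.loc[present].to_numpy()
        y = Y.loc[present].to_numpy()
        cols[sig.population] = (w @ y) / np.sum(np.abs(w))
        used[sig.population] = len(present)
    raw = pd.DataFrame(cols, index=Y.columns)
    return ScoreTable(raw=raw, scaled=None, genes_used=pd.Series(used))


def scale_scores(table: ScoreTable) -> ScoreTable:
    """Scale raw scores to [0, 1] within each population across tumours.

    A degenerate population (all tumours equal) maps to 0.5 everywhere with
    a warning.
    """
    if len(table.raw) < 2:
        raise ValueError("scaling needs at least 2 tumours")
    lo = table.raw.min(axis=0)
    hi = table.raw.max(axis=0)
    span = hi - lo
    degenerate = span == 0
    if degenerate.any():
        warnings.warn(
            f"constant raw scores for populations {list(span.index[degenerate])}; "
            "scaled scores set to 0.5",
            UserWarning,
            stacklevel=2,
        )
    span = span.replace(0, np.nan)
    scaled = (table.raw - lo) / span
    scaled = scaled.fillna(0.5)
    return ScoreTable(raw=table.raw, scaled=scaled, genes_used=table.genes_used)


def quartile_association(table: InstabilityTable, welch: bool = False) -> pd.DataFrame:
    """Compare genomic instability between expression quartiles.

    Tumours are split into quartiles Q1..Q4 of the gene's expression (by
    rank, ties broken by tumour identifier order), and the proportion of
    genome altered is compared between Q1 and Q4 and between each adjacent
    pair with two-sample t-tests (pooled variance by default).  Tumours
    lacking the proportion are excluded; their count is reported in the
    ``n_missing`` attribute of the returned frame.
    """
    expr = table.expression
    prop = table.proportion_altered
    ok = prop.notna() & expr.notna()
    n_missing = int((~ok).sum())
    expr, prop = expr[ok], prop[ok]
    n = len(expr)
    if n < 8:
        raise ValueError("need at least 8 tumours with complete data")
    order = np.argsort(expr.to_numpy(), kind="stable")
    ranks = np.empty(n, dtype=int)
    ranks[order] = np.arange(n)
    quart = np.minimum(ranks * 4 // n, 3) + 1  # sizes differ by <= 1
    groups = {q: prop.to_numpy()[quart == q] for q in (1, 2, 3, 4)}
    rows = []
    for a, b in [(1, 4), (1, 2), (2, 3), (3, 4)]:
        t, p = stats.ttest_ind(groups[a], groups[b], equal_var=not welch)
        rows.append({
            "comparison": f"Q{a}-vs-Q{b}", "t": float(t), "p": float(p),
            "mean_a": groups[a].mean(), "mean_b": groups[b].mean(),
            "n_a": len(groups[a]), "n_b": len(groups[b]),
        })
    out = pd.DataFrame(rows)
    out.attrs["n_missing"] = n_missing
    out.attrs["quartiles"] = pd.Series(quart, index=expr.index)
    return out
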