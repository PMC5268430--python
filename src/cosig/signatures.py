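"""Population signature genes with signed per-gene weights.

A signature gene for population P is one that is consistently up- or
down-regulated in P versus *every* other population in the panel, judged by
fold-change-threshold (TREAT) tests at FDR 0.05 within each pairwise
contrast.  The fold-change threshold is adaptive: the smallest value on a
grid (1.0 to 1.2) that keeps the signature at or below a size cap, so
populations with many candidate genes get a stricter threshold.

Each signature gene carries a signed weight: the log2 fold change against
the "next closest" population, read per gene as the pairwise contrast with
the smallest absolute fold change — the most conservative choice.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .linmod import DEResult, GenewiseFit, ModerationPrior, treat_test

__all__ = [
    "SignatureSet",
    "OrthologMap",
    "select_signature_genes",
    "assign_signature_weights",
    "derive_signatures",
    "map_orthologs",
    "DEFAULT_TAU_GRID",
]

DEFAULT_TAU_GRID = (1.00, 1.05, 1.10, 1.15, 1.20)


@dataclass
class SignatureSet:
    """Signed signature weights for one population.

    ``table`` is indexed by gene with columns ``direction`` (+1/-1),
    ``weight`` (signed log2 fold change vs the next closest population) and
    one ``logFC_vs_<Q>`` column per other population.
    """

    population: str
    table: pd.DataFrame
    tau: float
    fdr: float = 0.05
    provenance: dict = field(default_factory=dict)

    @property
    def genes(self) -> pd.Index:
        return self.table.index

    @property
    def weights(self) -> pd.Series:
        return self.table["weight"]

    def __len__(self) -> int:
        return len(self.table)

    def write(self, path) -> None:
        self.table.to_csv(path, sep="\t", index_label="gene")

    @classmethod
    def read(cls, path, population: str, tau: float = np.nan) -> "SignatureSet":
        return cls(population, pd.read_csv(path, sep="\t", index_col="gene"), tau=tau)


@dataclass
class OrthologMap:
    """Cross-species gene pairs with mapping class (1:1, 1:many, many:many)."""

    pairs: pd.DataFrame  # columns: source, target, class

    def __post_init__(self) -> None:
        p = self.pairs
        if "class" not in p.columns:
            src_counts = p["source"].value_counts()
            tgt_counts = p["target"].value_counts()
            cls = np.where(
                (p["source"].map(src_counts) == 1) & (p["target"].map(tgt_counts) == 1),
                "1:1",
                np.where(p["source"].map(src_counts) == 1, "1:many", "many:many"),
            )
            self.pairs = p.assign(**{"class": cls})
        one2one = self.pairs[self.pairs["class"] == "1:1"]
        if one2one["source"].duplicated().any() or one2one["target"].duplicated().any():
            raise ValueError("declared 1:1 ortholog pairs must be unique on both sides")

    @classmethod
    def read(cls, path) -> "OrthologMap":
        df = pd.read_csv(path, sep="\t")
        df.columns = ["source", "target"] + list(df.columns[2:])
        return cls(df)


def _contrast_sign_and_name(contrast_name: str, population: str) -> int | None:
    """Orientation of a 'A-B' contrast relative to ``population`` (+1 if A)."""
    a, _, b = contrast_name.partition("-")
    if a == population:
        return 1
    if b == population:
        return -1
    return None


def select_signature_genes(
    de_results: dict[float, dict[str, DEResult]],
    population: str,
    tau_grid=DEFAULT_TAU_GRID,
    fdr: float = 0.05,
    size_cap: int = 1000,
) -> SignatureSet:
    """Pick the population's signature genes at an adaptive fold-change threshold.

    ``de_results`` maps each threshold tau to the per-contrast TREAT results
    (BH-adjusted within contrast).  At a given tau a gene qualifies if its
    adjusted p is below ``fdr`` in every contrast involving the population
    and all its fold changes (oriented toward the population) share one
    sign.  The chosen tau is the smallest grid value whose signature size is
    at most ``size_cap``; if none qualifies, the largest grid value is used.
    """
    tau_grid = sorted(tau_grid)
    chosen_tau, chosen = None, None
    for tau in tau_grid:
        contrasts = de_results[tau]
        oriented: dict[str, tuple[pd.DataFrame, int]] = {}
        for name, res in contrasts.items():
            sign = _contrast_sign_and_name(name, population)
            if sign is not None:
                other = name.partition("-")[2] if sign == 1 else name.partition("-")[0]
                oriented[other] = (res.table, sign)
        if len(oriented) < 1:
            raise ValueError(
                f"signature selection needs at least 2 populations; no contrast "
                f"involves population {population!r}"
            )
        lfc_cols = {}
        pos_all, neg_all = None, None
        for other, (tab, sign) in oriented.items():
            lfc = sign * tab["logFC"]
            ok = tab["adj_p"] < fdr
            lfc_cols[other] = lfc
            pos = ok & (lfc > 0)
            neg = ok & (lfc < 0)
            pos_all = pos if pos_all is None else (pos_all & pos)
            neg_all = neg if neg_all is None else (neg_all & neg)
        selected = pos_all | neg_all
        idx = selected[selected].index
        table = pd.DataFrame(index=idx)
        table["direction"] = np.where(pos_all.loc[idx], 1, -1)
        for other, lfc in lfc_cols.items():
            table[f"logFC_vs_{other}"] = lfc.loc[idx]
        sig = SignatureSet(population, table, tau=tau, fdr=fdr,
                           provenance={"size_cap": size_cap, "tau_grid": list(tau_grid)})
        chosen_tau, chosen = tau, sig
        if len(sig) <= size_cap:
            break
    assert chosen is not None and chosen.tau == chosen_tau
    return assign_signature_weights(chosen)


def assign_signature_weights(signature: SignatureSet) -> SignatureSet:
    """Weight each gene by its fold change against the next closest population.

    The next closest population is read per gene: among the pairwise log2
    fold changes of the signature's population versus every other
    population, the one with the smallest absolute value.  The weight keeps
    the gene's direction as its sign.
    """
    lfc_cols = [c for c in signature.table.columns if c.startswith("logFC_vs_")]
    if not lfc_cols:
        raise ValueError("per-gene pairwise logFC table is missing")
    lfc = signature.table[lfc_cols]
    if lfc.isna().any().any():
        bad = lfc.index[lfc.isna().any(axis=1)]
        raise ValueError(f"missing contrast fold changes for genes: {list(bad[:5])}")
    table = signature.table.copy()
    if len(table):
        amin = lfc.abs().to_numpy().argmin(axis=1)
        w = lfc.to_numpy()[np.arange(len(lfc)), amin]
        table["weight"] = np.abs(w) * table["direction"]
        table["next_closest"] = [lfc_cols[i].removeprefix("logFC_vs_") for i in amin]
    else:
        table["weight"] = pd.Series(dtype=float)
        table["next_closest"] = pd.Series(dtype=object)
    return SignatureSet(signature.population, table, tau=signature.tau,
                        fdr=signature.fdr, provenance=signature.provenance)


def derive_signatures(
    fit: GenewiseFit,
    prior: ModerationPrior,
    populations,
    tau_grid=DEFAULT_TAU_GRID,
    fdr: float = 0.05,
    size_cap: int = 1000,
) -> dict[str, SignatureSet]:
    """Run TREAT on every pairwise contrast and derive all population signatures.

    Convenience wrapper around :func:`select_signature_genes`: TREAT is run
    once per (tau, contrast) on the shared fit, BH-adjusted within contrast.
    """
    populations = list(populations)
    if len(populations) < 2:
        raise ValueError("need at least 2 populations")
    names, seen = [], set()
    for n in fit.design.contrasts:
        if not _contrast_involves_only(n, populations):
            continue
        pair = frozenset(n.partition("-")[::2])
        if pair not in seen:  # one orientation per population pair
            seen.add(pair)
            names.append(n)
    de: dict[float, dict[str, DEResult]] = {}
    for tau in tau_grid:
        de[tau] = {n: treat_test(fit, prior, n, tau_fc=tau) for n in names}
    return {
        pop: select_signature_genes(de, pop, tau_grid=tau_grid, fdr=fdr, size_cap=size_cap)
        for pop in populations
    }


def _contrast_involves_only(name: str, populations) -> bool:
    a, _, b = name.partition("-")
    return a in populations and b in populations


def map_orthologs(signature: SignatureSet, omap: OrthologMap) -> tuple[SignatureSet, pd.DataFrame]:
    """Translate a signature across species through declared 1:1 orthologs.

    Genes without a 1:1 ortholog are dropped and listed in the returned
    report; weights are carried over unchanged (no cross-species rescaling).
    """
    one2one = omap.pairs[omap.pairs["class"] == "1:1"].set_index("source")["target"]
    keep = signature.genes[signature.genes.isin(one2one.index)]
    dropped = signature.genes.difference(keep)
    report = pd.DataFrame({
        "gene": list(dropped),
        "reason": ["no 1:1 ortholog"] * len(dropped),
    })
    if len(keep) == 0:
        raise ValueError("no signature gene has a declared 1:1 ortholog")
    if len(dropped):
        warnings.warn(f"{len(dropped)} signature genes lack a 1:1 ortholog and were dropped",
                      UserWarning, stacklevel=2)
    table = signature.table.loc[keep].copy()
    table.index = pd.Index(one2one.loc[keep].to_numpy(), name="gene")
    mapped = SignatureSet(signature.population, table, tau=signature.tau,
                          fdr=signature.fdr,
                          provenance={**signature.provenance, "ortholog_mapped": True})
    return mapped, report
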