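"""Relative telomere length from qPCR standard curves.

Telomere abundance (T) and a single-copy gene's abundance (S, albumin) are
each quantified against a four-point standard curve of quantification cycle
(Cq) versus log2 DNA input; the T/S ratio, reported relative to a reference
sample, is proportional to average telomere length.  A slope of -1 per
doubling corresponds to 100% amplification efficiency.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

__all__ = ["StandardCurve", "fit_standard_curve", "relative_ts_ratio", "analyze_plate"]


@dataclass
class StandardCurve:
    """Linear fit of Cq on log2(input ng) for one assay."""

    assay: str
    slope: float
    intercept: float
    r_squared: float
    points: pd.DataFrame  # columns ng, Cq

    def __post_init__(self) -> None:
        if self.slope >= 0:
            raise ValueError(f"standard curve for {self.assay!r} has non-negative "
                             "slope; curve unusable")

    def quantity(self, cq: float) -> float:
        """Invert the curve: DNA input (ng equivalents) at a given Cq."""
        return float(2.0 ** ((cq - self.intercept) / self.slope))

    def in_range(self, cq: float, slack_log2: float = 2.0) -> bool:
        lo = self.points["ng"].min()
        hi = self.points["ng"].max()
        q = np.log2(self.quantity(cq))
        return np.log2(lo) - slack_log2 <= q <= np.log2(hi) + slack_log2


def fit_standard_curve(points, assay: str = "assay") -> StandardCurve:
    """Least-squares standard curve from (ng, Cq) pairs.

    Requires at least 3 distinct DNA inputs; duplicate inputs are all fitted
    (no pre-averaging).  Accepts log2 input scale natively; callers using
    log10 dilutions can pass raw ng values, which is the common case.
    """
    pts = pd.DataFrame(points, columns=["ng", "Cq"])
    if (pts["ng"] <= 0).any():
        raise ValueError("DNA inputs must be > 0 ng")
    if pts["ng"].nunique() < 3:
        raise ValueError("need at least 3 distinct DNA inputs")
    res = stats.linregress(np.log2(pts["ng"]), pts["Cq"])
    return StandardCurve(
        assay=assay,
        slope=float(res.slope),
        intercept=float(res.intercept),
        r_squared=float(res.rvalue**2),
        points=pts,
    )


def _mean_cq(cqs, outlier_cycles: float | None = None) -> float:
    """Average triplicate Cqs, optionally dropping >0.5-cycle outliers."""
    c = np.asarray(cqs, dtype=float)
    if outlier_cycles is not None:
        med = np.median(c)
        keep = np.abs(c - med) <= outlier_cycles
        if keep.any():
            c = c[keep]
    return float(c.mean())


def relative_ts_ratio(
    sample_cqs: dict[str, dict[str, list[float]]],
    telomere_curve: StandardCurve,
    single_copy_curve: StandardCurve,
    reference: str,
    outlier_cycles: float | None = None,
) -> pd.DataFrame:
    """T/S ratios relative to a reference sample.

    ``sample_cqs`` maps sample name to ``{"telomere": [...], "single_copy":
    [...]}`` replicate Cqs.  Replicates are averaged on the Cq scale before
    curve inversion.  Samples whose averaged Cq falls more than 2 log2 units
    outside a curve's input range are flagged (``out_of_range``), not
    rejected.  The reference sample maps to ratio 1 exactly.
    """
    if reference not in sample_cqs:
        raise ValueError(f"reference sample {reference!r} not present")
    rows = {}
    for name, assays in sample_cqs.items():
        cq_t = _mean_cq(assays["telomere"], outlier_cycles)
        cq_s = _mean_cq(assays["single_copy"], outlier_cycles)
        t = telomere_curve.quantity(cq_t)
        s = single_copy_curve.quantity(cq_s)
        flag = not (telomere_curve.in_range(cq_t) and single_copy_curve.in_range(cq_s))
        if flag:
            warnings.warn(f"sample {name!r}: Cq outside standard-curve range",
                          UserWarning, stacklevel=2)
        rows[name] = {"ts_ratio": t / s, "out_of_range": flag}
    out = pd.DataFrame.from_dict(rows, orient="index")
    out["relative_ratio"] = out["ts_ratio"] / out.loc[reference, "ts_ratio"]
    return out


def analyze_plate(plate: pd.DataFrame, reference: str,
                  outlier_cycles: float | None = None) -> pd.DataFrame:
    """End-to-end analysis of a plate table as written by the generator.

    Expects columns sample/assay/replicate/Cq/ng; wells with a non-null ng
    are standard-curve wells.  Fits both curves, averages sample triplicates
    and returns relative T/S ratios.
    """
    std = plate[plate["ng"].notna()]
    if std.empty:
        raise ValueError("plate contains no standard-curve wells")
    curves = {}
    for assay, grp in std.groupby("assay"):
        curves[assay] = fit_standard_curve(grp[["ng", "Cq"]].to_numpy(), assay=assay)
    samples = plate[plate["ng"].isna()]
    cqs: dict[str, dict[str, list[float]]] = {}
    for (name, assay), grp in samples.groupby(["sample", "assay"], sort=False):
        cqs.setdefault(name, {})[assay] = grp["Cq"].tolist()
    return relative_ts_ratio(cqs, curves["telomere"], curves["single_copy"],
                             reference=reference, outlier_cycles=outlier_cycles)
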