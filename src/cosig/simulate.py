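"""Synthetic data with planted ground truth for the signature pipeline.

Three generators mirror the shapes of the real inputs: a negative-binomial
count matrix of sorted normal-cell populations (bulk RNA-seq replicates), a
microarray-like tumour log-expression matrix in which each tumour carries an
attenuated, noisy copy of one population's planted signature, and a qPCR
plate with standard-curve wells for the telomere module.

All randomness flows from a single integer seed through a splittable
generator: the seed is expanded with ``numpy.random.SeedSequence`` into
independent child streams, in this fixed order: (0) gene baselines,
(1) planted signature genes and effects, (2) library sizes, (3) counts,
(4) tumour noise, (5) qPCR noise.  Adding more genes therefore changes the
count draws but never the tumour-noise stream pairing, and the same seed
reproduces every output bit for bit.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .expression import CountMatrix, LogExpression

__all__ = [
    "SimConfig",
    "SimTruth",
    "gen_population_counts",
    "gen_tumor_matrix",
    "gen_telomere_plate",
    "STANDARD_CURVE_NG",
]

#: four-point standard-curve DNA inputs in ng (three successive 3-fold dilutions of 50 ng)
STANDARD_CURVE_NG = (50.0, 16.7, 5.56, 1.85)


@dataclass
class SimConfig:
    """Parameters of the synthetic study.

    Defaults describe the emulated study design: a panel of 4 sorted airway
    epithelial populations with 3 biological replicates each, ~2,000
    expressed genes, negative-binomial counts with biological dispersion 0.1,
    60 planted signature genes per population with |log2 effect| = 3, and
    tumour cohorts of 50 profiles per origin subtype carrying the origin's
    signature at attenuation 0.5 under unit Gaussian noise.  Library sizes
    are uniform on a range chosen so that per-gene depth matches bulk
    libraries of 16-26 million reads scaled to the simulated gene count.
    """

    n_genes: int = 2000
    populations: tuple[str, ...] = ("BSC", "secretory", "ciliated", "AT2")
    reps_per_pop: int = 3
    dispersion: float = 0.1
    lib_size_range: tuple[float, float] = (1.6e6, 2.6e6)
    genes_per_signature: int = 60
    effect_size: float = 3.0
    baseline_mean_log2cpm: float = 5.0
    baseline_sd_log2cpm: float = 2.0
    tumors_per_subtype: int = 50
    attenuation: float = 0.5
    tumor_noise_sd: float = 1.0
    seed: int = 0

    def validate(self) -> None:
        if self.n_genes < 1:
            raise ValueError("n_genes must be >= 1")
        if len(self.populations) < 1 or len(set(self.populations)) != len(self.populations):
            raise ValueError("populations must be non-empty and unique")
        if self.reps_per_pop < 1:
            raise ValueError("reps_per_pop must be >= 1")
        if self.dispersion <= 0:
            raise ValueError("dispersion must be > 0")
        lo, hi = self.lib_size_range
        if lo <= 0 or hi < lo:
            raise ValueError("lib_size_range must satisfy 0 < low <= high")
        if self.genes_per_signature < 0:
            raise ValueError("genes_per_signature must be >= 0")
        if self.genes_per_signature * len(self.populations) > self.n_genes:
            raise ValueError("genes_per_signature: planted genes exceed n_genes")
        if self.tumors_per_subtype < 1:
            raise ValueError("tumors_per_subtype must be >= 1")
        if self.attenuation < 0:
            raise ValueError("attenuation must be >= 0")
        if self.tumor_noise_sd < 0:
            raise ValueError("tumor_noise_sd must be >= 0")

    def to_yaml(self, path) -> None:
        d = asdict(self)
        d["populations"] = list(self.populations)
        d["lib_size_range"] = list(self.lib_size_range)
        Path(path).write_text(yaml.safe_dump(d, sort_keys=False))

    @classmethod
    def from_yaml(cls, path) -> "SimConfig":
        d = yaml.safe_load(Path(path).read_text())
        d["populations"] = tuple(d["populations"])
        d["lib_size_range"] = tuple(d["lib_size_range"])
        return cls(**d)


@dataclass
class SimTruth:
    """Planted ground truth of one simulated study.

    ``effects`` maps population name to a gene-indexed Series of signed log2
    effect sizes for that population's planted signature.  ``baseline`` is
    the per-gene baseline log2 CPM shared by all populations and tumours.
    Tumour fields are filled by :func:`gen_tumor_matrix`.
    """

    populations: tuple[str, ...]
    effects: dict[str, pd.Series]
    baseline: pd.Series
    seed: int
    tumor_origin: pd.Series | None = None
    tumor_attenuation: pd.Series | None = None

    def signature_genes(self, population: str) -> pd.Index:
        return self.effects[population].index

    def write(self, path) -> None:
        rows = []
        for pop, eff in self.effects.items():
            for gene, e in eff.items():
                rows.append((pop, gene, e))
        pd.DataFrame(rows, columns=["population", "gene", "effect"]).to_csv(
            path, sep="\t", index=False
        )


def _streams(seed: int) -> list[np.random.Generator]:
    children = np.random.SeedSequence(seed).spawn(6)
    return [np.random.Generator(np.random.PCG64(c)) for c in children]


def _truth_from_config(config: SimConfig) -> tuple[SimTruth, pd.Index]:
    """Draw baselines and planted effects (streams 0 and 1)."""
    rng_base, rng_plant = _streams(config.seed)[:2]
    genes = pd.Index([f"G{i + 1:05d}" for i in range(config.n_genes)])
    baseline = pd.Series(
        rng_base.normal(config.baseline_mean_log2cpm, config.baseline_sd_log2cpm,
                        config.n_genes),
        index=genes,
    )
    k = config.genes_per_signature
    chosen = rng_plant.choice(config.n_genes, size=k * len(config.populations),
                              replace=False)
    effects: dict[str, pd.Series] = {}
    for i, pop in enumerate(config.populations):
        idx = genes[np.sort(chosen[i * k:(i + 1) * k])]
        signs = rng_plant.choice([-1.0, 1.0], size=k)
        effects[pop] = pd.Series(signs * config.effect_size, index=idx)
    return SimTruth(populations=tuple(config.populations), effects=effects,
                    baseline=baseline, seed=config.seed), genes


def gen_population_counts(config: SimConfig) -> tuple[CountMatrix, SimTruth]:
    """Negative-binomial count matrix for the normal-population panel.

    Per-gene mean in sample s of population P is
    ``lib_s * p_g * 2^effect_gP`` where ``p_g`` are baseline CPM proportions
    and ``effect_gP`` is nonzero only for P's planted signature genes.
    Counts are Gamma-Poisson draws with variance ``mu + dispersion * mu^2``.
    """
    config.validate()
    truth, genes = _truth_from_config(config)
    streams = _streams(config.seed)
    rng_lib, rng_counts = streams[2], streams[3]

    pops = list(config.populations)
    n_samples = len(pops) * config.reps_per_pop
    lib = rng_lib.uniform(*config.lib_size_range, size=n_samples)
    prop = 2.0 ** truth.baseline.to_numpy()
    prop = prop / prop.sum()

    sample_names, groups = [], []
    for pop in pops:
        for r in range(config.reps_per_pop):
            sample_names.append(f"{pop}_{r + 1}")
            groups.append(pop)

    fc = np.ones((config.n_genes, n_samples))
    for j, pop in enumerate(groups):
        eff = truth.effects[pop]
        if len(eff):
            rows = genes.get_indexer(eff.index)
            fc[rows, j] = 2.0 ** eff.to_numpy()
    mu = prop[:, None] * lib[None, :] * fc
    shape = 1.0 / config.dispersion
    lam = rng_counts.gamma(shape, mu * config.dispersion)
    counts = rng_counts.poisson(lam)
    cm = CountMatrix(
        pd.DataFrame(counts, index=genes, columns=sample_names),
        groups=pd.Series(groups, index=sample_names),
    )
    return cm, truth


def gen_tumor_matrix(
    truth: SimTruth,
    config: SimConfig,
    origins: tuple[str, ...] | None = None,
) -> tuple[LogExpression, pd.Series]:
    """Microarray-like tumour log-expression profiles with known origins.

    Each tumour of origin P has log2 expression
    ``baseline_g + attenuation * effect_gP + N(0, noise_sd)``; a tumour
    subtype is simulated for every population (or for the requested subset).
    Returns the log-expression matrix and the per-tumour origin labels, and
    records both on ``truth``.
    """
    config.validate()
    if len(truth.populations) < 1:
        raise ValueError("truth must contain at least one population")
    if origins is None:
        origins = truth.populations
    for o in origins:
        if o not in truth.populations:
            raise ValueError(f"unknown origin label {o!r}; known: {list(truth.populations)}")
    rng = _streams(truth.seed)[4]
    genes = truth.baseline.index
    cols, labels, blocks = [], [], []
    for origin in origins:
        shift = np.zeros(len(genes))
        eff = truth.effects[origin]
        if len(eff):
            shift[genes.get_indexer(eff.index)] = config.attenuation * eff.to_numpy()
        base = truth.baseline.to_numpy()[:, None] + shift[:, None]
        noise = rng.normal(0.0, config.tumor_noise_sd,
                           size=(len(genes), config.tumors_per_subtype))
        blocks.append(base + noise)
        for t in range(config.tumors_per_subtype):
            cols.append(f"{origin}_T{t + 1:03d}")
            labels.append(origin)
    values = pd.DataFrame(np.hstack(blocks), index=genes, columns=cols)
    label_s = pd.Series(labels, index=cols, name="origin")
    truth.tumor_origin = label_s
    truth.tumor_attenuation = pd.Series(config.attenuation, index=cols)
    expr = LogExpression(values, provenance={"transform": "simulated_tumor",
                                             "attenuation": config.attenuation,
                                             "noise_sd": config.tumor_noise_sd})
    return expr, label_s


def gen_telomere_plate(
    ratios,
    telomere_curve: tuple[float, float] = (14.0, -1.0),
    single_copy_curve: tuple[float, float] = (22.0, -1.0),
    cq_noise_sd: float = 0.0,
    sample_ng: float = 20.0,
    seed: int = 0,
    n_replicates: int = 3,
) -> pd.DataFrame:
    """qPCR plate table for relative telomere-length quantification.

    ``ratios`` maps sample name to its true T/S ratio (a list is labelled
    S1..Sn).  Curves are (intercept, slope) of Cq versus log2(input ng); a
    slope of -1 is 100% amplification efficiency.  The plate holds triplicate
    telomere and single-copy (albumin) wells for every sample at ``sample_ng``
    input plus four-point standard curves at 50, 16.7, 5.56 and 1.85 ng.
    """
    if isinstance(ratios, dict):
        items = list(ratios.items())
    else:
        items = [(f"S{i + 1}", r) for i, r in enumerate(ratios)]
    for name, r in items:
        if not r > 0:
            raise ValueError(f"T/S ratio for sample {name!r} must be > 0")
    for label, (_, slope) in (("telomere", telomere_curve),
                              ("single_copy", single_copy_curve)):
        if slope >= 0:
            raise ValueError(f"{label} standard-curve slope must be < 0")
    rng = _streams(seed)[5]
    rows = []

    def cq(curve, ng):
        a, b = curve
        return a + b * np.log2(ng)

    for std_i, ng in enumerate(STANDARD_CURVE_NG):
        for assay, curve in (("telomere", telomere_curve), ("single_copy", single_copy_curve)):
            for rep in range(n_replicates):
                rows.append((f"STD{std_i + 1}", assay, rep + 1,
                             cq(curve, ng) + rng.normal(0, cq_noise_sd), ng))
    for name, ratio in items:
        for assay, curve, q in (("telomere", telomere_curve, sample_ng * ratio),
                                ("single_copy", single_copy_curve, sample_ng)):
            for rep in range(n_replicates):
                rows.append((name, assay, rep + 1,
                             cq(curve, q) + rng.normal(0, cq_noise_sd), np.nan))
    return pd.DataFrame(rows, columns=["sample", "assay", "replicate", "Cq", "ng"])
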