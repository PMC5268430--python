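"""End-to-end orchestration: simulate, normalize, model, sign, score, test.

``run_pipeline`` drives the whole analysis from a single config: generate (or
load) a normal-population count matrix, filter and TMM-normalize it, fit
precision-weighted genewise models, derive per-population signatures with
signed weights, score a tumour cohort, and test each signature against its
matching tumour-subtype contrast with weighted rotation tests.  Every stage
writes its table to the output directory with a provenance header, and a
summary report collects signature sizes, score ranges, rotation p-values and
(when ground truth is available) origin-recovery accuracy.
"""

from __future__ import annotations

import json
import logging
import sys
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .expression import filter_genes, read_count_matrix, tmm_factors, write_count_matrix
from .linmod import fit_genewise_lm, group_means_design, moderate_variances, voom_weights
from .rotation import rotation_gene_set_test
from .scoring import scale_scores, signature_scores
from .signatures import DEFAULT_TAU_GRID, derive_signatures
from .simulate import SimConfig, gen_population_counts, gen_tumor_matrix

__all__ = ["PipelineConfig", "run_pipeline"]

log = logging.getLogger("cosig")


@dataclass
class PipelineConfig:
    """Configuration of a full pipeline run.

    Either ``simulate`` holds a :class:`SimConfig` (ground truth available)
    or ``counts_path``/``tumor_path`` point at input tables.  ``seed`` is
    mandatory when simulating and also seeds the rotation tests.
    """

    out_dir: str = "cosig_run"
    simulate: SimConfig | None = None
    counts_path: str | None = None
    counts_format: str = "tsv"
    groups_path: str | None = None
    tumor_path: str | None = None
    min_cpm: float = 1.0
    min_samples: int = 3
    tau_grid: tuple[float, ...] = DEFAULT_TAU_GRID
    fdr: float = 0.05
    size_cap: int = 1000
    rotations: int = 9999
    seed: int | None = None

    def validate(self) -> None:
        if self.simulate is None and self.counts_path is None:
            raise ValueError("either a simulation config or counts_path is required")
        if self.simulate is not None and self.seed is None:
            raise ValueError("seed is mandatory when simulation is requested")
        for p in (self.counts_path, self.groups_path, self.tumor_path):
            if p is not None and not Path(p).exists():
                raise ValueError(f"input path does not exist: {p}")
        if self.simulate is not None:
            self.simulate.validate()

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        d = yaml.safe_load(Path(path).read_text())
        if "simulate" in d and d["simulate"] is not None:
            sim = d["simulate"]
            if "populations" in sim:
                sim["populations"] = tuple(sim["populations"])
            if "lib_size_range" in sim:
                sim["lib_size_range"] = tuple(sim["lib_size_range"])
            d["simulate"] = SimConfig(**sim)
        if "tau_grid" in d:
            d["tau_grid"] = tuple(d["tau_grid"])
        return cls(**d)


def _write_table(df: pd.DataFrame, path: Path, provenance: str, index_label="id") -> None:
    with open(path, "w") as fh:
        fh.write(f"# cosig {__version__} | {provenance}\n")
        df.to_csv(fh, sep="\t", index_label=index_label)


def run_pipeline(config: PipelineConfig) -> dict:
    """Execute all stages in order and return the summary report (also
    written to ``<out_dir>/report.json``)."""
    config.validate()
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    handler = logging.FileHandler(out / "run.log")
    stderr_handler = logging.StreamHandler(sys.stderr)
    log.setLevel(logging.INFO)
    log.addHandler(handler)
    log.addHandler(stderr_handler)
    report: dict = {"version": __version__, "seed": config.seed, "stages": []}
    stage = "setup"
    try:
        truth = None
        if config.simulate is not None:
            stage = "simulate"
            log.info("simulating counts (seed=%d)", config.simulate.seed)
            cm, truth = gen_population_counts(config.simulate)
            tumors, origins = gen_tumor_matrix(truth, config.simulate)
            write_count_matrix(cm, out / "counts.tsv")
            truth.write(out / "truth.tsv")
            _write_table(tumors.values, out / "tumors.tsv", "simulated tumour log expression",
                         index_label="gene")
        else:
            stage = "load"
            groups = None
            if config.groups_path:
                groups = pd.read_csv(config.groups_path, sep="\t", index_col=0).iloc[:, 0]
            cm = read_count_matrix(config.counts_path, fmt=config.counts_format, groups=groups)
            tumors = None
            origins = None
            if config.tumor_path:
                from .expression import LogExpression

                tumors = LogExpression(pd.read_csv(config.tumor_path, sep="\t",
                                                   index_col=0, comment="#"))
        report["stages"].append(stage)

        stage = "normalize"
        filtered = filter_genes(cm, min_cpm=config.min_cpm, min_samples=config.min_samples)
        log.info("filter: %d of %d genes kept", filtered.shape[0], cm.shape[0])
        norm = tmm_factors(filtered)
        _write_table(norm.factors.to_frame("tmm_factor"), out / "norm_factors.tsv",
                     f"TMM, reference={norm.reference}", index_label="sample")
        report["stages"].append(stage)
        report["n_genes_kept"] = int(filtered.shape[0])

        stage = "de"
        design = group_means_design(filtered.groups)
        vexpr = voom_weights(filtered, design, norm=norm)
        fit = fit_genewise_lm(vexpr, design)
        prior = moderate_variances(fit)
        report["stages"].append(stage)
        report["df_prior"] = None if np.isinf(prior.df_prior) else prior.df_prior
        report["var_prior"] = prior.var_prior

        stage = "signatures"
        pops = list(pd.unique(filtered.groups))
        sigs = derive_signatures(fit, prior, pops, tau_grid=config.tau_grid,
                                 fdr=config.fdr, size_cap=config.size_cap)
        for pop, sig in sigs.items():
            sig.write(out / f"signature_{pop}.tsv")
        report["stages"].append(stage)
        report["signature_sizes"] = {p: len(s) for p, s in sigs.items()}
        report["signature_tau"] = {p: s.tau for p, s in sigs.items()}

        rotation_p: dict[str, float] = {}
        accuracy = None
        if tumors is not None:
            stage = "score"
            table = scale_scores(signature_scores(tumors, list(sigs.values())))
            table.write(out / "scores.tsv")
            report["stages"].append(stage)
            report["score_range"] = {
                p: [float(table.scaled[p].min()), float(table.scaled[p].max())]
                for p in table.scaled.columns
            }
            if origins is not None:
                predicted = table.scaled.idxmax(axis=1)
                accuracy = float((predicted == origins).mean())
                report["origin_recovery_accuracy"] = accuracy
                log.info("origin recovery accuracy: %.3f", accuracy)

            stage = "roast"
            if origins is not None:
                tumor_design = group_means_design(origins)
                tfit = fit_genewise_lm(tumors, tumor_design)
                tprior = moderate_variances(tfit)
                levels = list(pd.unique(origins))
                for pop, sig in sigs.items():
                    if pop not in levels or len(sig) == 0:
                        continue
                    c = np.full(len(levels), -1.0 / (len(levels) - 1))
                    c[levels.index(pop)] = 1.0
                    res = rotation_gene_set_test(
                        tfit, tprior, c, sig.genes, weights=sig.weights,
                        B=config.rotations, seed=config.seed or 0,
                    )
                    rotation_p[pop] = res.p_up
                report["rotation_p_up"] = rotation_p
                report["stages"].append(stage)
    except Exception as exc:  # persist partial progress, then re-raise
        report["failed_stage"] = stage
        report["error"] = str(exc)
        (out / "report.json").write_text(json.dumps(report, indent=2))
        log.error("stage %s failed: %s", stage, exc)
        raise
    finally:
        log.removeHandler(handler)
        log.removeHandler(stderr_handler)
        handler.close()
    (out / "report.json").write_text(json.dumps(report, indent=2))
    return report
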