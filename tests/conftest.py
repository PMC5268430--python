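import numpy as np
import pandas as pd
import pytest

import cosig


@pytest.fixture(scope="session")
def study():
    """One simulated study, run once through the full modelling stack.

    Default design: 4 populations x 3 replicates, 2,000 genes, 60 planted
    signature genes per population at |log2 effect| 3, tumours at
    attenuation 0.5 under unit noise.
    """
    cfg = cosig.SimConfig(seed=11)
    counts, truth = cosig.gen_population_counts(cfg)
    tumors, origins = cosig.gen_tumor_matrix(truth, cfg)
    filtered = cosig.filter_genes(counts)
    norm = cosig.tmm_factors(filtered)
    design = cosig.group_means_design(filtered.groups)
    vexpr = cosig.voom_weights(filtered, design, norm=norm)
    fit = cosig.fit_genewise_lm(vexpr, design)
    prior = cosig.moderate_variances(fit)
    sigs = cosig.derive_signatures(fit, prior, list(cfg.populations))
    return {
        "config": cfg,
        "counts": counts,
        "truth": truth,
        "tumors": tumors,
        "origins": origins,
        "filtered": filtered,
        "norm": norm,
        "design": design,
        "vexpr": vexpr,
        "fit": fit,
        "prior": prior,
        "signatures": sigs,
    }


@pytest.fixture
def toy_signature():
    table = pd.DataFrame(
        {
            "direction": [1, 1, -1, 1, -1],
            "weight": [2.0, 0.5, -1.5, 3.0, -0.5],
            "logFC_vs_Q": [2.0, 0.5, -1.5, 3.0, -0.5],
            "logFC_vs_R": [2.5, 1.0, -2.0, 4.0, -1.0],
        },
        index=[f"g{i}" for i in range(5)],
    )
    return cosig.SignatureSet("P", table, tau=1.0)


@pytest.fixture
def rng():
    return np.random.Generator(np.random.PCG64(20240917))
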