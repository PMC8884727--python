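import numpy as np
import pandas as pd
import pytest

from clonotrace.sc_responder import ScParams, log_normalize, qc_filter
from clonotrace.synthdata import ExperimentDesign, gen_clonal_experiment, gen_expression_experiment


@pytest.fixture(scope="session")
def noise_free_cohort():
    """Deterministic cohort: exact class weights, equal clone sizes, expected counts."""
    design = ExperimentDesign(
        groups=("control",),
        n_mice_per_group=2,
        n_clones_per_mouse=30,
        class_mixture={"MBE": 0.6, "ME": 0.4},
        class_profiles={"MBE": (1 / 3, 1 / 3, 1 / 3), "ME": (0.5, 0.0, 0.5)},
        depth_per_sample=60_000,
        contamination_rate=0.0,
        sampling="expected",
        seed=7,
    )
    return design, gen_clonal_experiment(design)


@pytest.fixture(scope="session")
def noisy_cohort():
    design = ExperimentDesign(
        groups=("control", "EPO"),
        n_mice_per_group=2,
        n_clones_per_mouse=40,
        depth_per_sample=30_000,
        contamination_rate=0.0,
        seed=11,
    )
    return design, gen_clonal_experiment(design)


@pytest.fixture(scope="session")
def sc_params():
    # synthetic matrices carry ~1000 genes, so the cell filter is scaled down
    return ScParams(min_genes_per_cell=150)


@pytest.fixture(scope="session")
def responder_dataset(sc_params):
    """Strong planted responder experiment, QC'd and normalized."""
    adata, truth = gen_expression_experiment(
        responder_fraction=0.10,
        n_cells_per_group=400,
        n_genes=1000,
        fold_up=3.0,
        fold_down=3.0,
        seed=2,
    )
    filtered, _ = qc_filter(adata, sc_params)
    return log_normalize(filtered, sc_params), truth


@pytest.fixture(scope="session")
def null_expression(sc_params):
    """No planted effect: control and EPO cells exchangeable."""
    adata, truth = gen_expression_experiment(
        responder_fraction=0.0,
        n_cells_per_group=200,
        n_genes=600,
        seed=5,
    )
    filtered, _ = qc_filter(adata, sc_params)
    return log_normalize(filtered, sc_params), truth


@pytest.fixture()
def rng():
    return np.random.default_rng(0)


def make_series(values, index=None):
    return pd.Series(
        np.asarray(values, dtype=float),
        index=index or [f"BC{i}" for i in range(len(values))],
    )
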