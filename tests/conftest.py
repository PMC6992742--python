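import numpy as np
import pandas as pd
import pytest

from brainage import SimulationParams, generate_cohort, generate_dataset


@pytest.fixture(scope="session")
def default_small_params() -> SimulationParams:
    """Reduced-panel study conditions reused across tests: default effect
    sizes and noise, 60 features of which 40 informative."""
    return SimulationParams(
        n_subjects=2000,
        n_features=60,
        n_informative_features=40,
        n_snps=300,
        seed=7,
    )


@pytest.fixture(scope="session")
def small_dataset(default_small_params):
    return generate_dataset(default_small_params)


@pytest.fixture(scope="session")
def rba_pipeline_small(default_small_params, small_dataset):
    """One fitted brain-age pipeline on the reduced panel.

    Returns a dict with the evaluation-set phenotype frame, aligned
    PBA/RBA series and the genotype matrix.
    """
    from brainage import (
        compute_rba,
        fit_brain_age_model,
        fit_epba,
        predict_brain_age,
        split_cohort,
    )

    cohort, features, geno = small_dataset
    train, ev = split_cohort(cohort["subject_id"], 0.30, default_small_params.seed)
    c = cohort.set_index("subject_id")
    model = fit_brain_age_model(
        features.loc[train], c.loc[train, "ca"], seed=default_small_params.seed
    )
    epba = fit_epba(
        predict_brain_age(model, features.loc[train]), c.loc[train, "ca"]
    )
    pba = predict_brain_age(model, features.loc[ev])
    rba = compute_rba(pba, c.loc[ev, "ca"], epba)
    return {
        "eval": c.loc[ev],
        "pba": pd.Series(pba, index=ev),
        "rba": pd.Series(rba, index=ev),
        "geno": geno,
        "train_ids": train,
    }
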