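"""Shared fixtures: small synthetic cohorts reused across test modules."""

from __future__ import annotations

import numpy as np
import pandas as pd
import pytest

import orthoimmune as oi
from orthoimmune.features import derive_feature_table, impute_missing
from orthoimmune.gating import apply_gating, default_gating_scheme
from orthoimmune.synthetic import simulation_cohort_config

#: Reduced hyperparameter grid used by simulation-heavy tests.
EN_SIM_KW = dict(l1_ratios=(0.1, 0.5, 0.9), n_alphas=20, alpha_min_ratio=1e-2)


@pytest.fixture(scope="session")
def panel():
    return oi.PanelConfig()


@pytest.fixture(scope="session")
def scheme():
    return default_gating_scheme()


@pytest.fixture(scope="session")
def small_cohort(panel):
    """One seeded cohort at reduced scale, with gating labels and truth."""
    config = oi.CohortConfig(events_per_sample=500, seed=7)
    events, truth = oi.generate_cohort(config, panel)
    return config, events, truth


@pytest.fixture(scope="session")
def small_feature_table(small_cohort, scheme):
    _, events, _ = small_cohort
    labels = apply_gating(events, scheme)
    table = derive_feature_table(events, labels, scheme)
    imputed, _ = impute_missing(table)
    return imputed


@pytest.fixture(scope="session")
def sim_setup():
    """Reduced-population simulation scheme shared by EN simulation tests."""
    config = simulation_cohort_config(seed=0)
    pops = [p.name for p in config.populations]
    return default_gating_scheme(populations=pops)


def make_feature_table(values: pd.DataFrame, sexes, timepoint="12h") -> oi.FeatureTable:
    """Wrap a plain matrix as a FeatureTable with minimal annotations."""
    meta = pd.DataFrame(
        {"animal_id": list(values.index), "sex": list(sexes),
         "timepoint": timepoint},
        index=values.index,
    )
    ann = pd.DataFrame(
        {
            "feature": list(values.columns),
            "population": [str(c).split("|")[0] for c in values.columns],
            "marker": [str(c).split("|")[-1] for c in values.columns],
            "feature_class": "functional",
            "compartment": "innate",
        }
    ).set_index("feature")
    return oi.FeatureTable(values=values, meta=meta, annotations=ann)
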