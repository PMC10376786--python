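import numpy as np
import pandas as pd
import pytest

import seropanel as sp


@pytest.fixture(scope="session")
def default_cohort():
    """One default synthetic cohort (25+25, 87 proteins + 295 lipids)."""
    return sp.generate_cohort(sp.CohortConfig(seed=1))


@pytest.fixture(scope="session")
def protein_expansion(default_cohort):
    ft, ct, truth = default_cohort
    exp = sp.expand_products(ft, whitelist=ft.features_of_class("protein"))
    return exp, ct.binary_labels()


@pytest.fixture
def small_feature_table():
    values = np.array([[1.0, 10.0], [2.0, 20.0], [3.0, 30.0]])
    meta = pd.DataFrame(
        {
            "analyte_class": ["protein", "lipid"],
            "units": ["fmol_per_uL", "intensity_au"],
            "ion_mode": ["na", "positive"],
        },
        index=pd.Index(["F1", "F2"]),
    )
    return sp.FeatureTable(
        sample_ids=["S1", "S2", "S3"],
        feature_ids=["F1", "F2"],
        values=values,
        feature_meta=meta,
    )


def make_clinical(groups, n_metastases=None, **extra):
    n = len(groups)
    if n_metastases is None:
        n_metastases = [0 if g == "non_metastatic" else 1 for g in groups]
    data = {"group": groups, "n_metastases": n_metastases}
    data.update(extra)
    df = pd.DataFrame(data, index=pd.Index([f"S{i+1}" for i in range(n)]))
    return sp.ClinicalTable(df)
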