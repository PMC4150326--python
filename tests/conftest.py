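"""Shared fixtures: small synthetic worlds generated at test time."""

import numpy as np
import pandas as pd
import pytest

from ecohurdle.synth import GeneratorConfig, generate_dataset


def small_config(seed: int = 11, **kw) -> GeneratorConfig:
    """A quick 8-study network for unit-level checks."""
    defaults = dict(
        n_studies=8,
        sites_per_study=(8, 14),
        taxa_pool_size=120,
        taxa_per_study=(6, 12),
        seed=seed,
    )
    defaults.update(kw)
    return GeneratorConfig(**defaults)


def model_frame(ds, stage: str = "occurrence") -> pd.DataFrame:
    """Model-ready frame using the latent (true) iNDVI as the pressure.

    Bypasses the NDVI-recovery pipeline so model tests isolate the
    estimator from pressure measurement error.
    """
    from ecohurdle.prep import correct_effort, derive_occurrence

    sites = ds.sites.copy()
    sites["indvi"] = [ds.truth.true_indvi[s] for s in sites["site_id"]]
    covar = sites[["study_id", "site_id", "land_use", "hpd", "forest_cover", "indvi"]]
    groups = ds.taxa[["taxon_id", "group"]]
    if stage == "occurrence":
        base = derive_occurrence(ds.records)
    else:
        corrected = correct_effort(ds.records)
        base = corrected[corrected["value"] > 0]
    return (
        base.merge(covar, on=["study_id", "site_id"])
        .merge(groups, on="taxon_id")
        .reset_index(drop=True)
    )


@pytest.fixture(scope="session")
def small_dataset():
    return generate_dataset(small_config())


@pytest.fixture(scope="session")
def small_occ_frame(small_dataset):
    return model_frame(small_dataset, "occurrence")


@pytest.fixture(scope="session")
def small_ab_frame(small_dataset):
    return model_frame(small_dataset, "abundance")


@pytest.fixture()
def rng():
    return np.random.default_rng(20260925)
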