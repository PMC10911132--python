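import numpy as np
import pandas as pd
import pytest

from sbrkit import Cohort, RunConfig, SynthConfig, generate_cohort
from sbrkit.config import ScannerParams, SiteParams


def make_cohort(values, batch=None, diagnosis=None, *, site=None, age=65.0,
                sex="F", stage="age_sex_corrected", feature_prefix="f"):
    """Build a cohort from a (n, G) value matrix and per-record labels."""
    values = np.atleast_2d(np.asarray(values, dtype=float))
    n, g = values.shape
    batch = list(batch) if batch is not None else ["S1"] * n
    site = list(site) if site is not None else batch
    diagnosis = list(diagnosis) if diagnosis is not None else ["HC"] * n
    age = np.broadcast_to(np.asarray(age, dtype=float), (n,))
    sex = np.broadcast_to(np.asarray(sex, dtype=object), (n,))
    df = pd.DataFrame({
        "id": [f"r{i:04d}" for i in range(n)],
        "site": site, "scanner": batch, "diagnosis": diagnosis,
        "age": age, "sex": sex,
    })
    for j in range(g):
        df[f"sbr_{feature_prefix}{j + 1}"] = values[:, j]
    return Cohort(df, stage=stage)


def single_site_config(n_hc=100, n_pd=100, *, gain=1.0, offset=0.0, bias=0.0,
                       sigma_eps=0.0, **kwargs) -> SynthConfig:
    """A one-site, one-scanner generator config for focused recovery tests."""
    params = dict(
        sites={"S": SiteParams(n_hc=n_hc, n_pd=n_pd,
                               age_hc=(67.0, 8.0) if n_hc else None,
                               age_pd=(70.0, 8.0) if n_pd else None,
                               male_hc=n_hc // 2, male_pd=n_pd // 2,
                               procedure_bias=bias, pd_shift=0.0)},
        scanners={"S_A": ScannerParams(site="S", gain=gain, offset=offset)},
        sigma_eps=sigma_eps,
    )
    params.update(kwargs)
    return SynthConfig(**params)


@pytest.fixture(scope="session")
def default_cohort():
    """One default-config synthetic cohort with its latent truth."""
    return generate_cohort(SynthConfig(), seed=7)


@pytest.fixture()
def run_config():
    return RunConfig(seed=11)
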