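import numpy as np
import pytest

from twosample_mr.datasets import (
    EXPOSURE_N,
    OUTCOME_N,
    load_example_exposure,
    load_example_instruments,
    load_example_outcome,
)
from twosample_mr.harmonize import HarmonizedInstrument


@pytest.fixture(scope="session")
def example_exposure():
    return load_example_exposure()


@pytest.fixture(scope="session")
def example_outcome():
    return load_example_outcome()


@pytest.fixture(scope="session")
def example_instruments():
    return load_example_instruments()


@pytest.fixture(scope="session")
def example_arrays(example_instruments):
    """Raw (beta_exp, se_exp, beta_out, se_out) arrays for oracle arithmetic."""
    return (
        np.array([i.beta_exp for i in example_instruments]),
        np.array([i.se_exp for i in example_instruments]),
        np.array([i.beta_out for i in example_instruments]),
        np.array([i.se_out for i in example_instruments]),
    )


def make_instrument(
    rsid="rs1",
    beta_exp=0.05,
    se_exp=0.005,
    beta_out=0.005,
    se_out=0.004,
    eaf_exp=0.3,
    eaf_out=0.3,
    **kwargs,
) -> HarmonizedInstrument:
    """Hand-built instrument with sensible defaults for estimator tests."""
    defaults = dict(
        effect_allele="A",
        other_allele="G",
        pval_exp=1e-10,
        pval_out=0.1,
        n_exp=EXPOSURE_N,
        n_out=OUTCOME_N,
        r2_exp=1e-4,
        f_stat=50.0,
    )
    defaults.update(kwargs)
    return HarmonizedInstrument(
        rsid=rsid,
        beta_exp=beta_exp,
        se_exp=se_exp,
        beta_out=beta_out,
        se_out=se_out,
        eaf_exp=eaf_exp,
        eaf_out=eaf_out,
        **defaults,
    )
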