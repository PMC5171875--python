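import numpy as np
import pytest

from tsmr import (
    GwasAssociation,
    HarmonizedInstrument,
    InstrumentSet,
    make_liver_enzyme_fixture,
)


def make_assoc(snp_id="rs1", ea="A", oa="G", beta=0.1, se=0.01, p=1e-10, trait="x", **kw):
    return GwasAssociation(
        snp_id=snp_id,
        effect_allele=ea,
        other_allele=oa,
        beta=beta,
        se=se,
        p_value=p,
        trait_id=trait,
        **kw,
    )


def make_inst(snp_id="rs1", gamma=0.2, se_gamma=0.02, big_gamma=0.1, se_big_gamma=0.02, **kw):
    return HarmonizedInstrument(
        snp_id=snp_id,
        gamma_hat=gamma,
        se_gamma=se_gamma,
        big_gamma_hat=big_gamma,
        se_big_gamma=se_big_gamma,
        effect_allele="A",
        **kw,
    )


def random_instruments(rng, n, beta=0.3):
    """Instrument list with heterogeneous strengths and noise, no pleiotropy."""
    out = []
    for j in range(n):
        gamma = rng.uniform(0.1, 0.5)
        se_g = rng.uniform(0.005, 0.02)
        se_G = rng.uniform(0.01, 0.05)
        out.append(
            make_inst(
                snp_id=f"rs{j}",
                gamma=rng.normal(gamma, se_g),
                se_gamma=se_g,
                big_gamma=rng.normal(beta * gamma, se_G),
                se_big_gamma=se_G,
            )
        )
    return out


@pytest.fixture
def rng():
    return np.random.default_rng(20161220)


@pytest.fixture(scope="session")
def fixture_bundle():
    return make_liver_enzyme_fixture(seed=38813)


@pytest.fixture
def instrument_set(rng):
    return InstrumentSet(
        exposure_id="exp",
        outcome_id="out",
        instruments=random_instruments(rng, 8),
    )
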