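import numpy as np
import pandas as pd
import pytest

from trophomr.harmonize import HarmonizedInstrument
from trophomr.sumstats import VariantAssociation
from trophomr.instrument_table import (packaged_annotations, packaged_exposure_records,
                             packaged_instrument_table, packaged_ld_table)


@pytest.fixture(scope="session")
def packaged_table():
    tab, exclusions = packaged_instrument_table()
    return tab, exclusions


@pytest.fixture(scope="session")
def packaged_records():
    return packaged_exposure_records()


@pytest.fixture(scope="session")
def packaged_annot():
    return packaged_annotations()


@pytest.fixture(scope="session")
def packaged_ld():
    return packaged_ld_table()


def make_harmonized(gamma, se_gamma, Gamma, se_Gamma, ids=None):
    ids = ids or [f"rs{i}" for i in range(len(gamma))]
    return [
        HarmonizedInstrument(snp_id=i, gamma=g, se_gamma=sg, Gamma=G,
                             se_Gamma=sG)
        for i, g, sg, G, sG in zip(ids, gamma, se_gamma, Gamma, se_Gamma)
    ]


@pytest.fixture
def simple_instruments():
    """Five strong instruments lying nearly on the line Gamma = 0.2 gamma."""
    gamma = np.array([0.02, 0.025, 0.03, 0.018, 0.027])
    Gamma = 0.2 * gamma + np.array([1e-4, -2e-4, 5e-5, -5e-5, 1.5e-4])
    return make_harmonized(gamma, [0.002] * 5, Gamma, [0.004] * 5)


def variant(snp_id="rs1", ea="A", oa="G", eaf=0.3, beta=0.1, se=0.01,
            pval=1e-10, chrom="1", pos=1000, **kw):
    return VariantAssociation(snp_id=snp_id, effect_allele=ea,
                              other_allele=oa, eaf=eaf, beta=beta, se=se,
                              pval=pval, chrom=chrom, pos=pos, **kw)
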