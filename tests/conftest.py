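import numpy as np
import pandas as pd
import pytest

from teqtl.datatypes import CohortDesign, TruthTable
from teqtl import synthetic as syn


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture(scope="session")
def small_variants():
    """80 variants x 120 patients, common MAFs for stable power."""
    return syn.generate_genotypes(120, 80, maf_low=0.2, maf_high=0.5, seed=11)


@pytest.fixture
def paired_cohort():
    """Paired 80-patient cohort with one shared and one tumor-only eQTL."""
    design = CohortDesign.simple(80)
    variants = syn.generate_genotypes(80, 40, maf_low=0.2, maf_high=0.5, seed=5)
    truth = TruthTable(
        effects=pd.DataFrame(
            {
                "phenotype_id": ["te00000", "te00001"],
                "variant_id": ["var000005", "var000020"],
                "scope": ["shared", "tumor_only"],
                "slope": [0.8, 0.8],
            }
        )
    )
    normal, tumor, truth = syn.generate_paired_cohort(
        design, variants, n_te=6, n_gene=6, truth=truth, seed=17
    )
    return design, variants, normal, tumor, truth
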