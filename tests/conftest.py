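import numpy as np
import pandas as pd
import pytest

from nrf2screen import CnvMatrix, CohortBundle, CountMatrix, VariantTable
from nrf2screen.simulate import SimulationSpec, simulate_cohort


def make_bundle(
    samples,
    variants=(),
    cnv_events=(),
    genes=("KEAP1", "NFE2L2", "CUL3", "ARID1A", "ARID1B", "ARID2", "PBRM1"),
    counts=None,
    name="toy",
):
    """Hand-built cohort: variants as (gene, sample, class) triples, CNV
    events as (gene, sample, score)."""
    genes = list(genes)
    if counts is None:
        counts = pd.DataFrame(10, index=genes, columns=list(samples))
    var_df = pd.DataFrame(
        list(variants) or np.empty((0, 3), dtype=object),
        columns=["gene", "sample", "variant_class"],
    )
    cnv = pd.DataFrame(0, index=genes, columns=list(samples), dtype=np.int64)
    for g, s, score in cnv_events:
        cnv.loc[g, s] = score
    return CohortBundle(
        cohort_name=name,
        count_matrix=CountMatrix(counts),
        variants=VariantTable(var_df),
        cnv=CnvMatrix(cnv),
        shared_samples=list(samples),
    )


@pytest.fixture
def toy_bundle():
    """Six-sample cohort exercising every group-assignment rule:

    S1 ARID1A missense only           -> mutant
    S2 ARID1A + KEAP1 missense        -> excluded (confounded)
    S3 clean                          -> control
    S4 PBRM1 missense only            -> excluded (other subunit)
    S5 NFE2L2 missense only           -> excluded (NRF2 pathway)
    S6 clean                          -> control
    """
    return make_bundle(
        samples=[f"S{i}" for i in range(1, 7)],
        variants=[
            ("ARID1A", "S1", "Missense_Mutation"),
            ("ARID1A", "S2", "Missense_Mutation"),
            ("KEAP1", "S2", "Missense_Mutation"),
            ("PBRM1", "S4", "Missense_Mutation"),
            ("NFE2L2", "S5", "Missense_Mutation"),
            ("CUL3", "S3", "Silent"),
            ("CUL3", "S6", "Silent"),
        ],
    )


@pytest.fixture(scope="session")
def small_cohort():
    """One mid-size simulated cohort with planted NRF2 activity (seed 1)."""
    spec = SimulationSpec(
        n_genes=600, n_samples=100, n_signature_genes=60, seed=1
    )
    return simulate_cohort(spec)


@pytest.fixture(scope="session")
def reference_cohort():
    """The reference study-condition cohort: 2,000 genes x 120 samples,
    30% NRF2-active, 100 planted up-genes at mean log2FC 2, seed 1."""
    return simulate_cohort(SimulationSpec(seed=1))
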