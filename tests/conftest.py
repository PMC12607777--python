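import numpy as np
import pytest

import spectratype as st


@pytest.fixture(scope="session")
def tiny_expression() -> st.ExpressionMatrix:
    """3 genes × 2 samples with distinct values."""
    return st.ExpressionMatrix(
        gene_ids=["G1", "G2", "G3"],
        sample_ids=["s1", "s2"],
        values=np.array([[5.0, 1.0], [1.0, 2.0], [3.0, 4.0]]),
    )


@pytest.fixture(scope="session")
def small_study() -> st.SimulatedStudy:
    """A compact 3-class cohort used across modules (fast to enrich)."""
    cfg = st.SimulationConfig(
        n_genes=400,
        n_sets=20,
        set_size_range=(6, 10),
        n_classes=3,
        samples_per_class=(12, 12, 12),
        informative_sets_per_class=2,
        effect_size=3.0,
        seed=11,
    )
    return st.simulate(cfg)


@pytest.fixture(scope="session")
def small_spectra(small_study) -> st.EnrichmentMatrix:
    return st.functional_spectra(
        small_study.expression, small_study.gene_sets, st.EnrichmentParams()
    )
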