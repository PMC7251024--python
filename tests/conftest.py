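import numpy as np
import pandas as pd
import pytest

import vivoseq as v


@pytest.fixture(scope="session")
def qc_fixture():
    """Canonical 63-cell sequencing cohort with designed QC failures."""
    return v.gen_qc_fixture(1)


@pytest.fixture(scope="session")
def calcium_fixture():
    """Canonical 83-trace calcium cohort (41 LS / 22 NS / 20 excluded designs)."""
    return v.gen_calcium_fixture(3)


@pytest.fixture(scope="session")
def planted_de_cohort():
    """Expression cohort with 100 planted DE genes and no modules (41 LS / 12 NS)."""
    matrix, records, truth = v.gen_expression_cohort(
        v.ExprSimParams(seed=11, n_modules=0)
    )
    return v.compute_fpkm(matrix), records, truth


@pytest.fixture(scope="session")
def planted_module_cohort():
    """Expression cohort with 5 planted modules, the first trait-correlated."""
    matrix, records, truth = v.gen_expression_cohort(v.ExprSimParams(seed=5))
    return v.compute_fpkm(matrix), records, truth


@pytest.fixture
def simple_protocol():
    """Standard 5-repetition protocol with a 15-s lead-in."""
    return v.StimulusProtocol(onsets_s=(15.0, 35.0, 55.0, 75.0, 95.0))


def labels_of(records) -> pd.Series:
    return pd.Series({r.cell_id: r.label for r in records})


@pytest.fixture
def rng():
    return np.random.default_rng(0)
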