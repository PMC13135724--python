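import numpy as np
import pandas as pd
import pytest

from loyscan import simulate as sim


@pytest.fixture(scope="session")
def cohort():
    """One mid-sized synthetic cohort shared by read-only tests."""
    return sim.simulate_cohort(n_donors=40, n_cells_per_donor=150, seed=11)


@pytest.fixture(scope="session")
def called_cells(cohort):
    """Cohort cells with LOY called from the dual-source MSY matrices."""
    from loyscan import call_loy

    ann = cohort["cells"].drop(columns=["loy"])
    return call_loy(cohort["msy_a"], cohort["msy_b"], ann)


@pytest.fixture(scope="session")
def normalized(cohort):
    from loyscan import log_normalize

    return log_normalize(cohort["expression"])


@pytest.fixture
def rng():
    return np.random.default_rng(2026)


def make_annotation(barcodes, donors=None, sex="M", **cols):
    """Small helper: build a per-cell annotation table."""
    n = len(barcodes)
    table = pd.DataFrame({
        "barcode": list(barcodes),
        "donor": donors if donors is not None else ["d0"] * n,
        "sex": [sex] * n if isinstance(sex, str) else list(sex),
    })
    for k, v in cols.items():
        table[k] = v
    return table
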