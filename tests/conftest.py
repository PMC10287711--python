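import numpy as np
import pandas as pd
import pytest

import hypoxsig as hx


@pytest.fixture(scope="session")
def secretome_default():
    """Default-seed secretome bundle: planted hypoxia response, MNAR dropout."""
    return hx.simulate_secretome(hx.SecretomeSimConfig(seed=0))


@pytest.fixture(scope="session")
def tissue_default():
    return hx.simulate_tissue(hx.TissueSimConfig(seed=0))


@pytest.fixture(scope="session")
def prognostic_cohort():
    """n=500 cohort whose hazard doubles per signature-score sd."""
    return hx.simulate_cohort(
        hx.CohortSimConfig(n_patients=500, n_genes=200, beta=float(np.log(2)), seed=0)
    )


@pytest.fixture(scope="session")
def null_cohort():
    """Cohort whose survival is independent of expression."""
    return hx.simulate_cohort(
        hx.CohortSimConfig(n_patients=200, n_genes=100, beta=0.0, seed=0)
    )


@pytest.fixture
def tiny_matrix():
    data = pd.DataFrame(
        [[1.0, 2.0, np.nan, 4.0],
         [5.0, np.nan, 7.0, 8.0],
         [9.0, 10.0, 11.0, 12.0]],
        index=["P1", "P2", "P3"],
        columns=["s1", "s2", "s3", "s4"],
    )
    return hx.IntensityMatrix(data)


HYPOXIA_WITHIN = {
    "luminal": hx.Contrast("oxygen", ("normoxia", "hypoxia"), {"subtype": "luminal"}),
    "basal": hx.Contrast("oxygen", ("normoxia", "hypoxia"), {"subtype": "basal"}),
}
SUBTYPE_WITHIN = {
    "stroma": hx.Contrast("subtype", ("luminal", "basal"), {"compartment": "stroma"}),
    "epithelium": hx.Contrast("subtype", ("luminal", "basal"),
                              {"compartment": "epithelium"}),
}


@pytest.fixture(scope="session")
def derive_pipeline():
    return derive_from_bundles


def derive_from_bundles(secretome, tissue, alpha=0.05):
    """Full derivation: hypoxome union ∩ stroma-exclusive differences."""
    m, d, _ = secretome
    mt, dt, _ = tissue
    tab_lum = hx.differential_test(m, d, HYPOXIA_WITHIN["luminal"])
    tab_bas = hx.differential_test(m, d, HYPOXIA_WITHIN["basal"])
    _, _, hypoxome = hx.derive_hypoxome(tab_lum, tab_bas, alpha)
    stroma_excl = hx.derive_stroma_exclusive(
        hx.differential_test(mt, dt, SUBTYPE_WITHIN["stroma"]),
        hx.differential_test(mt, dt, SUBTYPE_WITHIN["epithelium"]),
        alpha,
    )
    return hx.intersect_signature(hypoxome, stroma_excl)
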