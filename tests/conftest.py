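import numpy as np
import pandas as pd
import pytest

from dbpmr import SummaryAssoc, generate_cohort
from dbpmr.cohort import camos_params


@pytest.fixture(scope="session")
def camos():
    return camos_params()


@pytest.fixture(scope="session")
def camos_noconf():
    return camos_params(confounding=False)


@pytest.fixture(scope="session")
def big_cohort(camos):
    """One large calibrated cohort for marginal/recovery checks."""
    cohort, params = generate_cohort(camos, 100_000, seed=20_240)
    return cohort, params


@pytest.fixture(scope="session")
def small_cohort(camos):
    """A cohort at the study's actual sample size."""
    cohort, params = generate_cohort(camos, 2254, seed=7)
    return cohort, params


def _se_from_ci(lo: float, hi: float) -> float:
    return (hi - lo) / (2 * 1.959963984540054)


@pytest.fixture(scope="session")
def gwas_lookup_table():
    """Published single-SNP per-allele association summaries (effect, SE
    back-computed from the printed 95% CI; log scale for diseases).  The
    insulin effect is carried at the higher precision implied by its
    published p-value (0.22); it rounds to the printed -0.01."""
    rows = [
        # phenotype, source, beta, ci_lo, ci_hi, n, unit, binary
        ("t25ohd", "cohort", -4.48, -6.00, -2.97, 2254, "nmol/l", False),
        ("glucose", "MAGIC", 0.00, -0.01, 0.01, 46186, "mmol/l", False),
        ("insulin", "MAGIC", -0.004, -0.01, 0.003, 46186, "log pmol/l", False),
        ("bmi", "GIANT", 0.00, -0.01, 0.01, 127587, "kg/m^2", False),
        ("bmd", "GEFOS", 0.01, -0.01, 0.03, 32961, "g/cm^2", False),
        ("stroke", "METASTROKE", np.log(1.00), np.log(0.97), np.log(1.04),
         74393, "OR", True),
        ("cad", "CARDIoGRAM", np.log(1.02), np.log(0.99), np.log(1.05),
         86995, "OR", True),
        ("diabetes", "DIAGRAM", np.log(1.01), np.log(0.97), np.log(1.05),
         63390, "OR", True),
    ]
    return [
        SummaryAssoc(phenotype=p, source=s, beta=b, se=_se_from_ci(lo, hi),
                     n=n, unit=u, binary=bin_)
        for p, s, b, lo, hi, n, u, bin_ in rows
    ]


@pytest.fixture(scope="session")
def dbp_exposure_assoc():
    """Instrument -> exposure association: -27.6 (95% CI -30.4, -24.8) mg/l."""
    return SummaryAssoc(phenotype="dbp", source="cohort", beta=-27.6,
                        se=_se_from_ci(-30.4, -24.8), n=2248, unit="mg/l")


@pytest.fixture()
def tiny_cohort_frame():
    """Hand-written 3-row cohort table for I/O round-trip checks."""
    return pd.DataFrame({
        "id": [1, 2, 3],
        "genotype": [0.0, 1.0, 2.0],
        "age": [45.5, 60.25, 72.0],
        "sex": ["female", "male", "female"],
        "ethnicity": ["european", "european", "non_european"],
        "season": ["cold", "warm", "cold"],
        "dbp": [401.125, 355.5, 322.0],
        "t25ohd": [70.5, 65.0, np.nan],
        "bmi": [24.0, 31.5, 27.25],
        "hypertension": [0, 1, 0],
    })
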