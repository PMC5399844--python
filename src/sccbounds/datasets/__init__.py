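"""Bundled example datasets.

Two published contingency tables commonly used to illustrate
sufficient-cause interaction bounds:

* a hypertension cohort cross-classified by body-mass index (BMI < 25 vs
  >= 25 kg/m^2) and age (< 40 vs >= 40 years), 4,897 subjects;
* a lung-cancer case-control study cross-classified by the ADPRT Val762Ala
  and XRCC1 Arg399Gln genotypes (3 x 3), 1,000 cases and 1,018 controls.
"""

from importlib.resources import files

from ..io import read_casecontrol_csv, read_cohort_csv
from ..types import CaseControlTable, CohortTable

__all__ = [
    "load_hypertension_cohort",
    "load_lung_cancer_casecontrol",
    "dataset_path",
]


def dataset_path(name: str):
    """Filesystem path of a bundled CSV (``hypertension_cohort`` or
    ``lung_cancer_casecontrol``)."""
    return files(__name__).joinpath(f"{name}.csv")


def load_hypertension_cohort() -> CohortTable:
    """The 2x2 hypertension cohort (BMI x age)."""
    return read_cohort_csv(dataset_path("hypertension_cohort"))


def load_lung_cancer_casecontrol() -> CaseControlTable:
    """The 3x3 lung-cancer case-control table (ADPRT x XRCC1 genotypes)."""
    return read_casecontrol_csv(dataset_path("lung_cancer_casecontrol"))
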