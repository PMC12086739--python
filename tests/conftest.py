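import numpy as np
import pandas as pd
import pytest
from hypothesis import settings

settings.register_profile("ci", derandomize=True, deadline=None)
settings.load_profile("ci")

from dwscreen.datamodel import AnalyteCatalog, Dataset
from dwscreen.synthetic import generate_dataset, paper_like_scenario


@pytest.fixture(scope="session")
def paper_like():
    """One generated instance of the packaged three-supply scenario."""
    return generate_dataset(paper_like_scenario(seed=7))


@pytest.fixture
def small_catalog():
    return AnalyteCatalog(pd.DataFrame({
        "analyte_id": ["as", "pfoa", "chcl3", "caff"],
        "analyte_name": ["arsenic", "PFOA", "trichloromethane", "caffeine"],
        "analyte_class": ["inorganic", "PFAS", "DBP", "pharmaceutical"],
        "core_flag": [True, True, True, False],
        "molecular_weight": [np.nan, 414.07, 119.38, 194.19],
    }))


def make_dataset(catalog, rows):
    """rows: (sample_id, supply, analyte_id, conc-or-None, rl)."""
    det = pd.DataFrame(rows, columns=["sample_id", "supply_class", "analyte_id",
                                      "concentration", "reporting_limit"])
    cat = catalog.table.set_index("analyte_id")
    det["analyte_name"] = det["analyte_id"].map(cat["analyte_name"])
    det["analyte_class"] = det["analyte_id"].map(cat["analyte_class"])
    det["study_id"] = "study-t"
    det["detected"] = det["concentration"].notna()
    samples = det[["sample_id", "supply_class", "study_id"]].drop_duplicates("sample_id")
    cols = ["study_id", "sample_id", "supply_class", "analyte_id", "analyte_name",
            "analyte_class", "concentration", "reporting_limit", "detected"]
    return Dataset(detections=det[cols], catalog=catalog,
                   samples=samples.reset_index(drop=True))


@pytest.fixture
def small_dataset(small_catalog):
    return make_dataset(small_catalog, [
        ("s1", "private_tw", "as", 1.0, 0.05),
        ("s1", "private_tw", "pfoa", 0.004, 0.004),
        ("s1", "private_tw", "chcl3", None, 0.02),
        ("s2", "public_tw", "chcl3", 20.0, 0.02),
        ("s2", "public_tw", "caff", 0.1, 0.005),
        ("s3", "bottled", "as", None, 0.05),
    ])
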