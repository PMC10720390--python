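import logging

import numpy as np
import pandas as pd
import pytest

from polyrisk.io_cohort import PhenotypeRecord, RateSchedule

logging.getLogger("polyrisk").setLevel(logging.ERROR)


@pytest.fixture
def scoring_frame():
    return pd.DataFrame(
        {
            "variant_id": ["rs1", "rs2", "rs3"],
            "chr": [1, 2, 3],
            "pos": [100, 200, 300],
            "effect_allele": ["A", "C", "G"],
            "other_allele": ["G", "T", "A"],
            "weight": [0.1, -0.2, 0.3],
        }
    )


@pytest.fixture
def scoring_file(tmp_path, scoring_frame):
    p = tmp_path / "scoring.tsv"
    scoring_frame.to_csv(p, sep="\t", index=False)
    return p


@pytest.fixture
def rates_file(tmp_path):
    p = tmp_path / "rates.csv"
    pd.DataFrame(
        {
            "age_start": [60, 65, 70],
            "age_end": [64, 69, 74],
            "incidence_per_100k": [500.0, 800.0, 1200.0],
            "mortality_per_100k": [1000.0, 1600.0, 2500.0],
        }
    ).to_csv(p, index=False)
    return p


@pytest.fixture
def flat_rates():
    ages = np.arange(40, 86)
    return RateSchedule(ages, np.full(len(ages), 0.002), np.full(len(ages), 0.01))


def make_case(ind="c1", country="US", gleason=None, stage=None, psa=None, died=False, age=65):
    return PhenotypeRecord(
        individual_id=ind, status="case", age=age, country=country,
        study="UGPCS" if country == "Uganda" else "MEC",
        gleason=gleason, stage=stage, psa=psa, died_of_disease=died,
    )


@pytest.fixture
def small_cohort():
    """Unadjusted two-group cohort builder for oracle comparisons."""

    def build(cells):
        # cells: {category: (n_cases, n_controls)}
        rows = []
        k = 0
        for cat, (ncase, nctrl) in cells.items():
            for _ in range(ncase):
                rows.append({"individual_id": f"i{k}", "status": "case", "outcome": "nonaggressive",
                             "joint_category": cat, "prs_category": "intermediate", "carrier": False,
                             "age": 60, "study": "MEC", "prs_score": 0.0})
                k += 1
            for _ in range(nctrl):
                rows.append({"individual_id": f"i{k}", "status": "control", "outcome": "control",
                             "joint_category": cat, "prs_category": "intermediate", "carrier": False,
                             "age": 60, "study": "MEC", "prs_score": 0.0})
                k += 1
        return pd.DataFrame(rows).set_index("individual_id")

    return build
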