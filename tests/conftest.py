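import logging

import numpy as np
import pandas as pd
import pytest

from sembiome.data_model import CountTable, MetadataTable
from sembiome.synthetic_data import generate_community, published_female_scenario

logging.getLogger("sembiome").setLevel(logging.ERROR)


@pytest.fixture
def tiny_counts() -> CountTable:
    return CountTable(
        ["g1", "g2", "g3"],
        ["s1", "s2", "s3", "s4"],
        np.array([[3, 0, 10, 4], [1, 5, 2, 2], [6, 7, 1, 9]]),
    )


def nc_metadata_row(**overrides) -> dict:
    """Questionnaire answers satisfying every normal-control condition."""
    row = {
        "sample_id": "s1",
        "sex": "female",
        "atopic_dermatitis": "no",
        "other_disease": "no",
        "medication": "no",
        "bmi": 22.0,
        "cesd": 5,
        "age": 35,
        "hospitalization_or_surgery": "no",
        "helicobacter_treatment": "no",
        "insomnia_consultation": "no",
        "defecation_frequency": "1-2_per_day",
        "alcohol": "none",
        "smoking_history": "no",
        "menstrual_status": "regular",
        "menstruating_now": "no",
        "pregnant_or_breastfeeding": "no",
        "colorectal_surgery_history": "no",
    }
    row.update(overrides)
    return row


def metadata_from_rows(rows: list[dict]) -> MetadataTable:
    import sembiome.data_model as dm

    df = pd.DataFrame(rows).set_index("sample_id")
    for col in dm._BOOL_FIELDS:
        df[col] = df[col].map(
            lambda v: pd.NA if pd.isna(v) else str(v).lower() in {"yes", "true", "1"}
        ).astype("boolean")
    return MetadataTable(df)


@pytest.fixture(scope="session")
def small_cohort():
    """A small synthetic cohort shared by read-only tests."""
    cfg = published_female_scenario(n_scale=0.15, seed=7)
    counts, meta, truth = generate_community(cfg)
    return cfg, counts, meta, truth
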