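import numpy as np
import pytest

from osteorisk import classifier as clf
from osteorisk import cohort as coh


@pytest.fixture(scope="session")
def default_cohort():
    """The published-calibration synthetic cohort, seed 1 (463 records)."""
    return coh.generate_cohort(coh.default_config(seed=1))


@pytest.fixture(scope="session")
def wear_age_spec():
    return clf.FeatureSpec.of("annual_wear", "age_at_surgery")


@pytest.fixture(scope="session")
def wear_spec():
    return clf.FeatureSpec.of("annual_wear")


def make_record(
    id="S0001",
    sex="female",
    age_at_surgery=60.0,
    height=1.65,
    bmi=28.0,
    total_wear=1.0,
    survival_time=10.0,
    label="control",
    annual_wear=None,
):
    """A valid SubjectRecord with overridable fields (weight derived)."""
    if annual_wear is not None:
        total_wear = annual_wear * survival_time
    return coh.SubjectRecord(
        id=id,
        sex=sex,
        age_at_surgery=age_at_surgery,
        height=height,
        weight=bmi * height * height,
        bmi=bmi,
        total_wear=total_wear,
        survival_time=survival_time,
        annual_wear=total_wear / survival_time,
        label=label,
    )


def two_class_records(control_wear, osteo_wear, **kwargs):
    """1-D cohorts from explicit annual-wear values per class."""
    recs = [
        make_record(id=f"C{i:04d}", annual_wear=w, label="control", **kwargs)
        for i, w in enumerate(control_wear)
    ]
    recs += [
        make_record(id=f"O{i:04d}", annual_wear=w, label="osteolysis", **kwargs)
        for i, w in enumerate(osteo_wear)
    ]
    return recs
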