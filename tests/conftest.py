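"""Shared fixtures: seeded synthetic cohorts and analysis configuration."""
import warnings

import numpy as np
import pytest

from ardsrec import (AnalysisConfig, Cohort, CohortConfig, PatientRecord,
                     Gender, generate_cohort)
from ardsrec.pipeline import split_subgroups


@pytest.fixture(scope="session")
def analysis_config():
    return AnalysisConfig()


@pytest.fixture(scope="session")
def default_cohort():
    """Paper-scale cohort under the default study conditions."""
    return generate_cohort(CohortConfig(seed=2024))


@pytest.fixture(scope="session")
def subgroups(default_cohort):
    return split_subgroups(default_cohort)


@pytest.fixture(scope="session")
def large_cohort():
    """2000-per-cohort population for structural-fidelity checks."""
    return generate_cohort(CohortConfig(n_ards=2000, n_control=2000, seed=7))


def make_record(patient_id="P0", cohort=Cohort.ARDS, gender=Gender.MALE,
                height_in=68.0, vt_ml=450.0, pf_lowest=150.0, pf_first=None,
                documented=False, latent=None, duration=24.0, pplat=25.0,
                **kw):
    from ardsrec import compute_pbw

    pbw = compute_pbw(height_in, gender)
    return PatientRecord(
        patient_id=patient_id, cohort=cohort, gender=gender,
        height_in=height_in, pbw_kg=pbw, admit_weight_kg=pbw * 1.1,
        pf_first=pf_lowest if pf_first is None else pf_first,
        pf_lowest=pf_lowest, pplat_highest=pplat, vt_lowest_ml=vt_ml,
        vt_std=vt_ml / pbw, documented=documented,
        study_duration_h=duration, latent_recognized=latent, **kw)


@pytest.fixture()
def record_factory():
    return make_record
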