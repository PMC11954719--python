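import numpy as np
import pytest

from ritopk.dataset_io import (
    DEFAULT_ANALYTES,
    ConcentrationProfile,
    ConcentrationRecord,
)
from ritopk.ddi_model import DDIModelParams
from ritopk.synthetic_trial import TrialGeneratorConfig, generate_trial


def make_profile(times, concs, dose_ng=1e7, analyte="atorvastatin",
                 subject_id="S01", occasion="baseline", blq=None):
    """Build a profile from parallel arrays; blq is an optional bool mask."""
    blq = [False] * len(times) if blq is None else blq
    records = tuple(
        ConcentrationRecord(float(t), None if b else float(c), bool(b))
        for t, c, b in zip(times, concs, blq)
    )
    return ConcentrationProfile(
        subject_id=subject_id,
        analyte=DEFAULT_ANALYTES[analyte],
        occasion=occasion,
        dose_ng=dose_ng,
        records=records,
    )


@pytest.fixture
def profile_factory():
    return make_profile


@pytest.fixture
def default_params():
    return DDIModelParams()


@pytest.fixture(scope="session")
def default_trial():
    """One default virtual trial (seed 1), shared across tests."""
    return generate_trial(TrialGeneratorConfig(seed=1))


@pytest.fixture(scope="session")
def noisefree_trial():
    """Deterministic trial: no IIV, no residual error, no censoring."""
    cfg = TrialGeneratorConfig(
        seed=1,
        sigma_prop=0.0,
        omega={"f_rel": 0.0, "cl_f": 0.0, "vc_f": 0.0},
        lloq_censor=False,
    )
    return generate_trial(cfg)
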