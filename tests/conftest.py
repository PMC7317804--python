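import warnings

import numpy as np
import pytest

import jointtraj as jt
from jointtraj.jointmodel import JointModelSpec

# statsmodels MixedLM emits benign convergence chatter on tiny fixtures
warnings.filterwarnings("ignore", module="statsmodels")


@pytest.fixture(scope="session")
def paper_cohort():
    """One study-sized cohort (167 subjects) from the default generator."""
    params = jt.paper_like_params(seed=42)
    patients, visits = jt.simulate_cohort(params)
    return params, patients, visits


@pytest.fixture(scope="session")
def dataset_months(paper_cohort):
    _, patients, visits = paper_cohort
    return jt.build_dataset(visits, patients, time_unit="months")


@pytest.fixture(scope="session")
def joint_fit_medium():
    """A converged joint fit on a 250-subject cohort, shared by tests that
    only need *some* realistic fitted model (predictions, comparisons)."""
    params = jt.paper_like_params(seed=7).with_(n_subjects=250)
    patients, visits = jt.simulate_cohort(params)
    data = jt.build_dataset(visits, patients, time_unit="months")
    fit = jt.fit_joint_model(data, JointModelSpec(scale="log2"))
    return params, data, fit
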