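import numpy as np
import pytest
from hypothesis import HealthCheck, settings

import megmapper as mm

settings.register_profile(
    "deterministic",
    derandomize=True,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("deterministic")


def make_matrix(data, boundary=None, labels=None, channel_ids=None, subject_id="sub-test"):
    """Build an AnalysisMatrix directly from an array for unit tests."""
    data = np.asarray(data, dtype=float)
    n = data.shape[0]
    if boundary is None:
        boundary = n // 2
    if labels is None:
        labels = np.array(["A"] * boundary + ["B"] * (n - boundary), dtype=object)
    if channel_ids is None:
        channel_ids = [f"ch{i:03d}" for i in range(data.shape[1])]
    return mm.AnalysisMatrix(
        data=data,
        paradigm=np.asarray(labels, dtype=object),
        boundary=boundary,
        channel_ids=channel_ids,
        subject_id=subject_id,
    )


def make_series(data, paradigm="A", phase="stimulus", rate=256.0, subject_id="sub-test"):
    """Build a LabeledTimeSeries with uniform labels unless overridden."""
    data = np.asarray(data, dtype=float)
    n = data.shape[0]
    paradigm = np.full(n, paradigm, dtype=object) if isinstance(paradigm, str) else np.asarray(paradigm, dtype=object)
    phase = np.full(n, phase, dtype=object) if isinstance(phase, str) else np.asarray(phase, dtype=object)
    return mm.LabeledTimeSeries(
        data=data,
        channel_ids=[f"ch{i:03d}" for i in range(data.shape[1])],
        sampling_rate=rate,
        paradigm=paradigm,
        phase=phase,
        subject_id=subject_id,
    )


@pytest.fixture(scope="session")
def table1():
    return mm.load_table1_fixture()


@pytest.fixture(scope="session")
def small_cohort():
    """4 subjects, 2 x 150 time points, 16 channels; demanding vs relaxed."""
    dem, rel = mm.synthetic.default_cohort_configs(n_channels=16, n_timepoints=150)
    return mm.generate_cohort(4, dem, rel, seed=11)


@pytest.fixture(scope="session")
def small_sweep(small_cohort):
    spec = mm.SweepSpec(
        intervals=(4,),
        overlaps=(50,),
        clusters=(3,),
        filter_method="pca",
        comparison=("demanding", "relaxed"),
        hypothesis="a_greater",
        keep_graphs=True,
    )
    return mm.run_sweep(small_cohort, spec), spec
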