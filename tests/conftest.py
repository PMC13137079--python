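import pytest
from hypothesis import HealthCheck, settings

from kasphi.pipeline import run_calibration, run_estimation
from kasphi.simulate import simulate_experiment

settings.register_profile(
    "deterministic",
    deadline=None,
    derandomize=True,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("deterministic")


@pytest.fixture(scope="session")
def study_experiment():
    """One simulated run of the default (study-layout) experiment."""
    return simulate_experiment(seed=11)


@pytest.fixture(scope="session")
def study_pipeline(study_experiment):
    """The default experiment pushed through calibration and estimation."""
    exp = study_experiment
    cal, qc = run_calibration(exp.fluorescence, exp.design)
    est = run_estimation(
        exp.fluorescence, cal.calibrations, exp.design, mismatch=cal.mismatch, qc_res=qc
    )
    return exp, cal, qc, est
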