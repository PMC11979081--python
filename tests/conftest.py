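import numpy as np
import pytest
from hypothesis import HealthCheck, settings

import stumpwave as sw

settings.register_profile(
    "suite",
    derandomize=True,
    max_examples=25,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("suite")

FS = 100.0


def clean_params(**kw):
    """Noise-free, drift-free, artifact-free beat parameters."""
    base = dict(noise_sd=0.0, drift_amplitude=0.0, artifact_rate=0.0)
    base.update(kw)
    return sw.BeatModelParams(**base)


@pytest.fixture(scope="session")
def clean_trace():
    """60-s noise-free trace at 100 Hz, HR 60, tau 1.5 s, with truth."""
    params = clean_params(tau=1.5)
    trace, truth = sw.generate_trace(params, duration=60.0, sampling_rate=FS)
    return params, trace, truth


@pytest.fixture(scope="session")
def clean_fit(clean_trace):
    """Fitted pipeline results on the clean 60-s trace."""
    params, trace, _ = clean_trace
    model = sw.PulseWaveAnalysis(
        trace, tau_asymptote=sw.simulate.derived_asymptote(params)
    )
    return params, model.fit()


def template_beat(params, fs=FS):
    """Noise-free single-cycle samples (the clean beat template)."""
    from stumpwave.simulate import _beat_template

    return _beat_template(params, fs)


def ensemble_from_samples(samples, fs=FS, heart_rate=np.nan, fiducial_offset=0):
    """Wrap raw samples as a single-beat ensemble for metric-level tests."""
    return sw.EnsembleBeat(
        representative=np.asarray(samples, dtype=float),
        sampling_rate=fs,
        n_detected=1,
        n_retained=1,
        correlations=np.array([1.0]),
        retained_flags=np.array([True]),
        heart_rate=heart_rate,
        fiducial_offset=fiducial_offset,
    )
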