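import numpy as np
import pytest

import fnpag
from fnpag.core import AnalysisConfig, BinnedSeries, MotorState


@pytest.fixture(scope="session")
def small_session():
    """A short synthetic conditioning session reused by IO/pipeline tests."""
    cfg = fnpag.SimConfig(
        duration_s=60.0,
        n_source_cells=2,
        n_target_cells=2,
        mean_dwell_active_s=5.0,
        mean_dwell_immobile_s=5.0,
        seed=7,
    )
    protocol = fnpag.ProtocolSpec(
        acclimation_s=10.0, n_cs=2, cs_duration_s=5.0, iti_s=10.0
    )
    return fnpag.simulate_session(cfg, protocol)


def binned(values, label="x", kind="spikes", bin_s=0.01, start_s=0.0):
    return BinnedSeries(bin_s=bin_s, start_s=start_s, values=np.asarray(values),
                        kind=kind, label=label)


def motor_state_from_path(path, sample_rate_hz=100.0):
    path = np.asarray(path)
    return MotorState(
        times=np.arange(path.size) / sample_rate_hz,
        state=path,
        smoothing_sd_ms=64.0,
        threshold_deg_s=12.0,
    )


@pytest.fixture
def analysis_cfg():
    return AnalysisConfig()
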