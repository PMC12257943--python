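import numpy as np
import pytest

from irapkit.io_units import PO2Trace, RespirometerConfig
from irapkit.mo2 import MO2Series, MO2Window
from irapkit.synthetic import TrialTruth, default_config


@pytest.fixture(scope="session")
def config() -> RespirometerConfig:
    """Default 50 g fish in a 50:1 chamber at 18 degC (V_r - V_f = 2.45 L)."""
    return default_config()


@pytest.fixture()
def truth() -> TrialTruth:
    return TrialTruth(seed=0)


def make_linear_trace(
    slope: float,
    duration_s: int = 300,
    p0: float = 100.0,
    chamber_id: str = "ch1",
    phase: str = "measurement",
) -> PO2Trace:
    """A single-phase trace with an exactly linear PO2 decline."""
    t = np.arange(duration_s, dtype=float)
    return PO2Trace(
        chamber_id=chamber_id,
        time_s=t,
        po2=p0 + slope * t,
        temp_c=np.full(duration_s, 18.0),
        phase=np.full(duration_s, phase, dtype=object),
    )


def make_series(
    mo2_values,
    mid_times_s,
    config: RespirometerConfig,
    mean_po2=None,
    excluded=None,
    fish_id: str = "fish1",
) -> MO2Series:
    """Hand-built MO2Series for estimator unit tests."""
    n = len(mo2_values)
    mean_po2 = mean_po2 if mean_po2 is not None else [100.0] * n
    excluded = excluded if excluded is not None else [False] * n
    windows = [
        MO2Window(
            start_index=i,
            duration_s=60.0,
            slope=-v / 1000.0,
            r_squared=0.99,
            mo2=float(v),
            mid_time_s=float(t),
            phase_id=i,
            mean_po2=float(p),
            excluded=bool(e),
        )
        for i, (v, t, p, e) in enumerate(zip(mo2_values, mid_times_s, mean_po2, excluded))
    ]
    return MO2Series(fish_id=fish_id, windows=windows, config=config)
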