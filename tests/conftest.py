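import numpy as np
import pandas as pd
import pytest

from ridemix.containers import EpochSet
from ridemix.synthetic import EEGSimSpec, simulate_epochs


def error_frame(errors_deg, participant=0):
    """Minimal error table around an explicit list of angular errors."""
    errors_deg = np.asarray(errors_deg, dtype=float)
    return pd.DataFrame(
        {
            "participant": participant,
            "trial": np.arange(errors_deg.size),
            "error_deg": errors_deg,
            "rt_ms": 1000.0,
        }
    )


@pytest.fixture
def high_trials():
    """60 perfectly recollected trials (error 0), used as C-carrying epochs."""
    return error_frame(np.zeros(60))


@pytest.fixture
def toy_epochs():
    """Tiny deterministic EpochSet: 4 trials, 2 channels, 0..1996 ms at 250 Hz."""
    data = np.zeros((4, 2, 500))
    data[0] += 7.0  # constant trial
    data[1, 0, 100] = 3.0  # impulse
    return EpochSet(
        data=data,
        sfreq=250.0,
        tmin_ms=0.0,
        channel_names=["CP1", "P1"],
        trial_meta=pd.DataFrame(
            {"participant": 0, "trial": range(4), "error_deg": [5.0, 20.0, 50.0, 120.0]}
        ),
    )


def simulate_bin_epochs(noise_sd=0.0, seed=0, n=60, **overrides):
    """Epochs for n all-High trials with the default S/C construction."""
    spec = EEGSimSpec(noise_sd=noise_sd, seed=seed, **overrides)
    return simulate_epochs(spec, error_frame(np.zeros(n)))
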