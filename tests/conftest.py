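import numpy as np
import pytest

from ctgforesee import CTGRecord, SynthParams, acidotic_regime, non_acidotic_regime
from ctgforesee.io import SAMPLE_RATE_HZ


def noise_free(regime_fn, seed: int, duration_s: float = 1200.0) -> SynthParams:
    """A regime with every stochastic nuisance disabled, so planted events
    are the only structure in the trace."""
    return regime_fn(
        duration_s=duration_s,
        noise_sd_bpm=0.0,
        baseline_drift_sd=0.0,
        variability_bpm=0.0,
        dropout_rate_per_hr=0.0,
        seed=seed,
    )


def hump(n_samples: int) -> np.ndarray:
    """Raised-cosine 0->1->0 test shape."""
    t = np.arange(n_samples)
    return 0.5 * (1.0 - np.cos(2.0 * np.pi * (t + 0.5) / n_samples))


def make_record(
    fhr: np.ndarray, uc: np.ndarray | None = None, ph: float | None = None, rid="t"
) -> CTGRecord:
    if uc is None:
        uc = np.full(len(fhr), 8.0)
    return CTGRecord(record_id=rid, fhr=fhr, uc=uc, ph=ph)


def seconds(s: float) -> int:
    return int(s * SAMPLE_RATE_HZ)


@pytest.fixture
def rng():
    return np.random.default_rng(12345)
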