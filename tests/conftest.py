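import numpy as np
import pytest

from kneeae.types import GenerativeParams, HitTiming, StudyDesign, Waveform


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture
def timing():
    return HitTiming()


def make_burst_waveform(peaks_db, onsets_s, fs=50_000.0, noise_db=20.0,
                        tau=1.5e-3, seed=0, duration=None):
    """Waveform with decaying-cosine bursts at known onsets/peaks."""
    rng = np.random.default_rng(seed)
    if duration is None:
        duration = (max(onsets_s) if onsets_s else 0.5) + 0.1
    n = int(duration * fs)
    w = rng.normal(0.0, 10 ** (noise_db / 20.0), n)
    n_tail = int(8 * tau * fs)
    tt = np.arange(n_tail) / fs
    kernel = np.exp(-tt / tau) * np.cos(2 * np.pi * (fs / 20.0) * tt)
    for a_db, t0 in zip(peaks_db, onsets_s):
        i0 = int(round(t0 * fs))
        seg = kernel[: n - i0]
        w[i0:i0 + seg.size] += 10 ** (a_db / 20.0) * seg
    return Waveform(samples=w, sampling_rate=fs)


def day1_design(n_participants):
    return StudyDesign(n_participants=n_participants, n_days=1, n_weeks=1,
                       day1_multi_rp=True)


def repeated_design(n_participants, n_days):
    return StudyDesign(n_participants=n_participants, n_days=n_days,
                       n_weeks=1, day1_multi_rp=False)


def table2a_params(**over):
    base = dict(sd_patient=82.06, sd_session_in_patient=46.02,
                sd_day_in_patient=0.0, sd_rp=6.05, sd_residual=18.74)
    base.update(over)
    return GenerativeParams.variance_only(**base)


def table2b_params(**over):
    base = dict(sd_patient=79.15, sd_session_in_patient=0.0,
                sd_day_in_patient=55.75, sd_rp=47.22, sd_residual=19.42)
    base.update(over)
    return GenerativeParams.variance_only(**base)


def table3_params():
    """Final association model as generating truth (no nuisance REs)."""
    return GenerativeParams(
        intercept=160.13, kl_contrasts=(-81.77, 22.54, 38.39),
        weight_coef=2.06, contralateral_pain_coef=57.05,
        sd_patient=93.17, sd_session_in_patient=0.0, sd_day_in_patient=0.0,
        sd_rp=0.0, sd_residual=22.51, machine_offsets=(0.0, 0.0, 0.0))
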