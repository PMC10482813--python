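import numpy as np
import pytest

from pao2osc import synthetic as syn
from pao2osc import preprocess as pp
from pao2osc.core import DT, SignalTrace


@pytest.fixture(scope="session")
def clean_spec():
    return syn.ConditionSpec(
        condition_id="fix-1",
        animal_id="A1",
        peep=8.0,
        vt_per_kg=10.0,
        injured=False,
        morphology=syn.ARCHETYPES[0],
        snr_db=30.0,
    )


@pytest.fixture(scope="session")
def clean_trace(clean_spec):
    trace, truth = syn.simulate_condition(clean_spec, seed=42)
    return trace


@pytest.fixture(scope="session")
def preset_results():
    """84-condition exclusions-preset cohort, preprocessed once."""
    specs, traces, truth = syn.pilot_exclusions_preset(seed=1)
    results = [pp.preprocess_condition(tr) for tr in traces]
    return specs, results, truth


def make_periodic_trace(n_breaths=12, amp=20.0, mean=300.0, phase_fn=None,
                        hold_s=20.0, noise_sd=0.0, seed=0):
    """Hand-built trace: periodic PaO2 before a breath hold, linear decline,
    linear recovery. Used for segmentation/alignment unit tests."""
    period = 60.0
    rng = np.random.default_rng(seed)
    hold_start = n_breaths * period
    restart = hold_start + hold_s
    total = restart + 2 * period
    t = np.arange(int(round(total / DT))) * DT
    if phase_fn is None:
        phase_fn = lambda ph: np.sin(2 * np.pi * ph)  # noqa: E731
    pao2 = np.where(
        t < hold_start,
        mean + amp * phase_fn(np.mod(t, period) / period),
        0.0,
    )
    hold = (t >= hold_start) & (t < restart)
    v0 = mean + amp * phase_fn(0.0)
    pao2[hold] = v0 - 2.0 * (t[hold] - hold_start)
    v_low = v0 - 2.0 * hold_s
    post = t >= restart
    pao2[post] = v_low + 8.0 * (t[post] - restart)
    pao2 = np.minimum(pao2, mean) if phase_fn is None else pao2
    if noise_sd > 0:
        pao2 = pao2 + rng.normal(0, noise_sd, len(t))
    paw = np.where(np.mod(t, 60.0) < 20.0, 18.0, 5.0)
    paw[hold] = 5.0
    return SignalTrace(
        t=t, pao2=pao2, paw=paw,
        breath_hold_window=(hold_start, restart),
        ventilation_restart_s=restart,
        condition_id="periodic",
    )
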