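"""Shared constants and the raw-signal container.

The canonical analysis grid is one aggregate breath of 600 samples at 10 Hz
(0.1 s spacing), with an inspiratory:expiratory ratio of 1:2 so the first
third of the grid ([0, 20) s) is inspiration. All PaO2 values are carried
internally in mmHg; kPa inputs are converted on read.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Any

import numpy as np

#: sampling interval of the fast intra-arterial sensor, seconds
DT = 0.1
#: samples per aggregate breath on the canonical grid
BREATH_SAMPLES = 600
#: duration of one canonical breath, seconds
BREATH_PERIOD_S = BREATH_SAMPLES * DT
#: inspiratory fraction of the breath (I:E = 1:2)
INSP_FRACTION = 1.0 / 3.0
#: nominal respiratory rate that yields the canonical 600-sample grid
NOMINAL_RR = 10.0
#: unit conversion for arterial oxygen tension
MMHG_PER_KPA = 7.50062


def breath_grid(n_samples: int = BREATH_SAMPLES, dt: float = DT) -> np.ndarray:
    """Half-open canonical breath time grid t_j = j*dt, j = 0..n-1."""
    return np.arange(n_samples) * dt


def samples_per_breath(rr: float = NOMINAL_RR, fs: float = 1.0 / DT) -> int:
    """Breath grid length for a configured respiratory rate.

    rr=10 at fs=10 Hz gives the canonical 600-sample grid; other rates
    rescale it proportionally.
    """
    if rr <= 0:
        raise ValueError("respiratory rate must be positive")
    return int(round(BREATH_SAMPLES * (NOMINAL_RR / rr) * (fs * DT)))


@dataclass
class SignalTrace:
    """One ventilatory condition's raw 10 Hz recording.

    Layout: tidal ventilation, then an end-expiratory breath hold (airway
    pressure parked at PEEP), then resumed ventilation. ``breath_hold_window``
    is (start_s, end_s) and ``ventilation_restart_s`` equals the window end.
    """

    t: np.ndarray
    pao2: np.ndarray
    paw: np.ndarray
    breath_hold_window: tuple[float, float]
    ventilation_restart_s: float
    condition_id: str = ""
    meta: dict[str, Any] = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.t = np.asarray(self.t, dtype=float)
        self.pao2 = np.asarray(self.pao2, dtype=float)
        self.paw = np.asarray(self.paw, dtype=float)
        if not (self.t.shape == self.pao2.shape == self.paw.shape):
            raise ValueError("t, pao2 and paw must have identical shapes")
        if len(self.t) > 1:
            dev = np.abs(np.diff(self.t) - DT)
            if dev.max() > 1e-6:
                raise ValueError("time grid is not uniform at 0.1 s")

    @property
    def dt(self) -> float:
        return DT

    @property
    def fs(self) -> float:
        return 1.0 / DT

    def index_of(self, time_s: float) -> int:
        """Nearest sample index for a time on this trace's grid."""
        return int(round((time_s - self.t[0]) / DT))
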