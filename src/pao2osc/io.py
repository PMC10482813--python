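"""Plain-text signal and artifact I/O.

Signal CSV dialect: header ``t_s,pao2_mmHg,paw_cmH2O`` (or ``pao2_kPa``,
converted at 7.50062 mmHg/kPa on read), one row per 0.1 s sample. The
breath-hold window and restart time are not stored in the CSV; they are
re-inferred from the airway-pressure channel (the hold is the one
between-breath gap longer than a breath period, the restart its end).
"""

from __future__ import annotations

from pathlib import Path

import numpy as np
import pandas as pd

from .core import BREATH_PERIOD_S, DT, MMHG_PER_KPA, SignalTrace

__all__ = ["read_signal_csv", "write_signal_csv", "infer_ventilation_landmarks"]

_FLOAT_FMT = "%.12g"  # lossless to well below 1e-9 for mmHg/cmH2O magnitudes


def write_signal_csv(trace: SignalTrace, path: str | Path) -> Path:
    path = Path(path)
    df = pd.DataFrame(
        {"t_s": trace.t, "pao2_mmHg": trace.pao2, "paw_cmH2O": trace.paw}
    )
    df.to_csv(path, index=False, float_format=_FLOAT_FMT)
    return path


def read_signal_csv(path: str | Path, condition_id: str | None = None) -> SignalTrace:
    """Read a signal CSV, validate the grid, infer ventilation landmarks."""
    path = Path(path)
    df = pd.read_csv(path)
    cols = {c.lower(): c for c in df.columns}
    if "t_s" not in cols or "paw_cmh2o" not in cols:
        raise ValueError(f"{path.name}: missing required columns (t_s, paw_cmH2O)")
    if "pao2_mmhg" in cols:
        pao2 = df[cols["pao2_mmhg"]].to_numpy(dtype=float)
    elif "pao2_kpa" in cols:
        pao2 = df[cols["pao2_kpa"]].to_numpy(dtype=float) * MMHG_PER_KPA
    else:
        raise ValueError(f"{path.name}: missing pao2_mmHg / pao2_kPa column")
    t = df[cols["t_s"]].to_numpy(dtype=float)
    if len(t) > 1:
        dev = np.abs(np.diff(t) - DT)
        if dev.max() > 1e-6:
            bad = int(np.argmax(dev > 1e-6)) + 2  # header is line 1
            raise ValueError(f"{path.name}: non-uniform time grid at line {bad}")
    paw = df[cols["paw_cmh2o"]].to_numpy(dtype=float)
    hold, restart = infer_ventilation_landmarks(t, paw)
    return SignalTrace(
        t=t,
        pao2=pao2,
        paw=paw,
        breath_hold_window=hold,
        ventilation_restart_s=restart,
        condition_id=condition_id or path.stem,
    )


def infer_ventilation_landmarks(
    t: np.ndarray, paw: np.ndarray, period_s: float = BREATH_PERIOD_S
) -> tuple[tuple[float, float], float]:
    """Locate the breath hold from the airway-pressure channel.

    Inspiration onsets are the rising edges of the pressure-control square
    wave; the hold is the single onset-to-onset gap exceeding one breath
    period, running from the end of the last pre-hold breath to the first
    post-restart onset.
    """
    paw = np.asarray(paw, dtype=float)
    lo, hi = paw.min(), paw.max()
    if hi - lo < 1e-9:
        raise ValueError("airway pressure is constant; cannot locate breaths")
    high = paw > (lo + hi) / 2.0
    onsets = np.flatnonzero(high[1:] & ~high[:-1]) + 1
    if high[0]:
        onsets = np.concatenate(([0], onsets))
    if len(onsets) < 3:
        raise ValueError("too few breaths to locate a breath hold")
    gaps = np.diff(onsets) * DT
    long_gaps = np.flatnonzero(gaps > period_s + DT)
    if len(long_gaps) != 1:
        raise ValueError(
            f"expected exactly one breath-hold gap, found {len(long_gaps)}"
        )
    g = int(long_gaps[0])
    hold_start = t[onsets[g]] + period_s  # end of the last complete pre-hold breath
    restart = t[onsets[g + 1]]
    return (float(hold_start), float(restart)), float(restart)
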