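"""Raw trace -> aligned, aggregated, normalized single breath.

Stages, in the order they are applied per condition:

1. alignment — the ventilation-to-PaO2 lag (offset) is estimated from the
   PaO2 rise after the post-breath-hold restart of ventilation;
2. segmentation — the last ten complete breaths of tidal ventilation
   before the hold are extracted on the canonical 600-sample grid, with
   the offset applied retrospectively to the PaO2 time axis;
3. linear detrend of the concatenated ten-breath series;
4. per-timepoint median aggregation into a single breath (suppresses
   cardiac-frequency ripple and other non-respiratory-locked content);
5. normalization to zero mean and unit SD;
6. exclusion filtering (PaO2 trough < 100 mmHg, SNR < 20 dB, unalignable).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable

import numpy as np
import pandas as pd
import scipy.signal

from .core import BREATH_SAMPLES, DT, NOMINAL_RR, SignalTrace, breath_grid, samples_per_breath

__all__ = [
    "AlignmentConfig",
    "AlignmentResult",
    "BreathMatrix",
    "NormalizedBreath",
    "detect_alignment_offset",
    "segment_breaths",
    "detrend_linear",
    "aggregate_median_breath",
    "normalize_breath",
    "estimate_snr_db",
    "apply_exclusion_filters",
    "preprocess_condition",
    "SNR_CAP_DB",
    "TROUGH_THRESHOLD_MMHG",
    "SNR_THRESHOLD_DB",
]

SNR_CAP_DB = 60.0
TROUGH_THRESHOLD_MMHG = 100.0
SNR_THRESHOLD_DB = 20.0


# --------------------------------------------------------------------------
# alignment
# --------------------------------------------------------------------------

@dataclass(frozen=True)
class AlignmentConfig:
    """Tunables of the offset detector.

    The primary detector extrapolates the fitted breath-hold decline line
    and looks for ``consecutive`` post-restart samples exceeding it by
    ``k_sigma`` residual SDs; the reported offset is then refined by
    intersecting the decline line with a line fitted to the early rise.
    When the decline fit is noise-free the threshold test is degenerate
    and the two-line intersection is used directly.
    """

    decline_fit_window_s: float = 5.0
    k_sigma: float = 3.0
    consecutive: int = 5
    rise_fit_window_s: float = 5.0
    scan_window_s: float = 12.0
    min_offset_s: float = 0.2
    max_offset_s: float = 5.0
    min_rise_slope: float = 1.0  # mmHg/s; below this the recovery is "flat"
    smooth_samples: int = 5  # pre-smoothing of the noisy recovery (0.5 s)


@dataclass
class AlignmentResult:
    offset: float | None
    method: str  # "change_point" | "two_line_intersection" | "none"
    alignable: bool
    decline_resid_sd: float


def _fit_line(t: np.ndarray, y: np.ndarray) -> tuple[float, float, float]:
    """OLS line y = a + b t; returns (a, b, residual SD)."""
    b, a = np.polyfit(t, y, 1)
    resid = y - (a + b * t)
    dof = max(len(y) - 2, 1)
    return a, b, float(np.sqrt(np.sum(resid**2) / dof))


def detect_alignment_offset(
    trace: SignalTrace, config: AlignmentConfig | None = None
) -> AlignmentResult:
    """Estimate the lag between ventilation restart and the PaO2 rise."""
    cfg = config or AlignmentConfig()
    if trace.breath_hold_window is None:
        raise ValueError("trace has no breath-hold window")
    hold_start, hold_end = trace.breath_hold_window
    restart = trace.ventilation_restart_s

    i_decl0 = trace.index_of(hold_end - cfg.decline_fit_window_s)
    i_decl1 = trace.index_of(hold_end)
    t_d = trace.t[i_decl0:i_decl1]
    y_d = trace.pao2[i_decl0:i_decl1]
    if len(t_d) < 4:
        raise ValueError("breath-hold decline window too short to fit")
    a_d, b_d, sigma = _fit_line(t_d - restart, y_d)  # decline line in t-restart coords

    i_r0 = trace.index_of(restart)
    i_r1 = min(trace.index_of(restart + cfg.scan_window_s), len(trace.t))
    t_s = trace.t[i_r0:i_r1] - restart
    y_s = trace.pao2[i_r0:i_r1]
    pred = a_d + b_d * t_s

    offset = _piecewise_kink(t_s, y_s, a_d, b_d, sigma, cfg)
    method = "none"
    if offset is not None:
        method = "two_line_intersection"
        if sigma > 1e-9:
            above = y_s > pred + cfg.k_sigma * sigma
            if _first_run(above, cfg.consecutive) is not None:
                method = "change_point"

    alignable = offset is not None and cfg.min_offset_s <= offset <= cfg.max_offset_s
    return AlignmentResult(
        offset=float(offset) if alignable else None,
        method=method if alignable else "none",
        alignable=alignable,
        decline_resid_sd=sigma,
    )


def _first_run(mask: np.ndarray, length: int) -> int | None:
    """Index of the first run of ``length`` consecutive True values."""
    if length <= 1:
        idx = np.flatnonzero(mask)
        return int(idx[0]) if len(idx) else None
    conv = np.convolve(mask.astype(int), np.ones(length, dtype=int), mode="valid")
    hits = np.flatnonzero(conv == length)
    return int(hits[0]) if len(hits) else None


def _piecewise_kink(
    t_s: np.ndarray,
    y_s: np.ndarray,
    a_d: float,
    b_d: float,
    sigma: float,
    cfg: AlignmentConfig,
) -> float | None:
    """Kink time of a piecewise model of the recovery.

    For each candidate kink on the sample grid, samples before it are
    scored against the (fixed, extrapolated) breath-hold decline line and
    the following ``rise_fit_window_s`` against a rise segment anchored on
    the decline line at the kink (the recovery is continuous) with free
    slope and curvature; the candidate minimizing the mean squared error
    wins. Noisy recoveries are lightly smoothed first; noise-free input
    (sigma = 0) is scored raw, so an exact piecewise-linear kink is
    recovered exactly. Candidates whose rise slope falls below
    ``min_rise_slope`` are invalid, so a recovery that never rises yields
    no kink at all.
    """
    w = max(int(round(cfg.rise_fit_window_s / DT)), 3)
    i_max = min(int(round(cfg.max_offset_s / DT)) + 1, len(t_s) - w)
    if i_max < 1:
        return None

    ys = y_s
    if cfg.smooth_samples > 1 and sigma > 1e-9:
        kern = np.ones(cfg.smooth_samples) / cfg.smooth_samples
        ys = np.convolve(y_s, kern, mode="same")
        h = cfg.smooth_samples // 2
        if h:
            ys[:h] = y_s[:h]
            ys[-h:] = y_s[-h:]

    best_t0, best_mse = None, np.inf
    for i0 in range(i_max):
        t0 = t_s[i0]
        seg_t = t_s[i0 : i0 + w] - t0
        seg_y = ys[i0 : i0 + w] - (a_d + b_d * t0)
        basis = np.column_stack([seg_t, seg_t * seg_t])
        beta, *_ = np.linalg.lstsq(basis, seg_y, rcond=None)
        # gate on the unconstrained slope too: a flat recovery shifted off
        # the decline line would fool the anchored fit into a spurious rise
        b_free = np.polyfit(seg_t, seg_y, 1)[0]
        if b_free < cfg.min_rise_slope or beta[0] < cfg.min_rise_slope:
            continue
        sse_rise = float(np.sum((seg_y - basis @ beta) ** 2))
        pre = ys[:i0] - (a_d + b_d * t_s[:i0])
        # mean squared error: candidates span different sample counts
        mse = (float(np.sum(pre**2)) + sse_rise) / (i0 + w)
        if mse < best_mse:
            best_mse, best_t0 = mse, float(t0)
    return best_t0


# --------------------------------------------------------------------------
# segmentation, detrend, aggregation, normalization
# --------------------------------------------------------------------------

@dataclass
class BreathMatrix:
    """n_breaths x n_samples of PaO2 on the canonical breath grid, rows in
    temporal order, grid origin at (offset-corrected) inspiration onset."""

    values: np.ndarray
    condition_id: str = ""
    detrended: bool = False

    def __post_init__(self) -> None:
        self.values = np.atleast_2d(np.asarray(self.values, dtype=float))

    @property
    def n_breaths(self) -> int:
        return self.values.shape[0]

    @property
    def grid(self) -> np.ndarray:
        return breath_grid(self.values.shape[1])

    @property
    def trough(self) -> float:
        return float(self.values.min())


@dataclass
class NormalizedBreath:
    """The aggregate breath in SD units (zero mean, unit SD)."""

    values: np.ndarray
    raw_mean: float
    raw_sd: float
    condition_id: str = ""


def segment_breaths(
    trace: SignalTrace,
    offset: float,
    rr: float = NOMINAL_RR,
    n_breaths: int = 10,
) -> BreathMatrix:
    """Extract the last ``n_breaths`` complete breaths of tidal ventilation
    before the breath hold, offset applied retrospectively to PaO2.

    The offset is rounded to the nearest sample. Breath k's window is
    [onset_k + offset, onset_k + offset + period).
    """
    period_n = samples_per_breath(rr)
    hold_start = trace.breath_hold_window[0]
    offset_n = int(round(offset / DT))
    i_hold = trace.index_of(hold_start)
    rows = []
    for k in range(n_breaths, 0, -1):
        i0 = i_hold - k * period_n + offset_n
        i1 = i0 + period_n
        if i0 < 0 or i1 > len(trace.pao2):
            raise ValueError(
                f"trace too short for {n_breaths} breaths before the hold "
                f"(condition {trace.condition_id or '?'})"
            )
        rows.append(trace.pao2[i0:i1])
    return BreathMatrix(np.vstack(rows), condition_id=trace.condition_id)


def detrend_linear(series: np.ndarray) -> np.ndarray:
    """Remove the OLS line from a series (zero mean, zero slope out)."""
    series = np.asarray(series, dtype=float)
    if series.size < 2:
        raise ValueError("need at least 2 samples to detrend")
    if np.ptp(series) == 0.0:
        return np.zeros_like(series)
    return scipy.signal.detrend(series, type="linear")


def detrend_matrix(matrix: BreathMatrix) -> BreathMatrix:
    """Detrend the concatenated breath series and reshape back to rows."""
    flat = detrend_linear(matrix.values.reshape(-1))
    return BreathMatrix(
        flat.reshape(matrix.values.shape),
        condition_id=matrix.condition_id,
        detrended=True,
    )


def aggregate_median_breath(matrix: BreathMatrix) -> np.ndarray:
    """Per-timepoint median across breaths (standard sample median)."""
    if matrix.n_breaths < 3:
        raise ValueError("median aggregation needs at least 3 breaths")
    return np.median(matrix.values, axis=0)


def normalize_breath(breath: np.ndarray, condition_id: str = "") -> NormalizedBreath:
    """Convert a breath to multiples of its own SD (zero mean)."""
    breath = np.asarray(breath, dtype=float)
    mu = float(breath.mean())
    sd = float(breath.std())
    if sd < 1e-12:
        raise ValueError("zero-SD breath cannot be normalized")
    return NormalizedBreath(
        values=(breath - mu) / sd, raw_mean=mu, raw_sd=sd, condition_id=condition_id
    )


def estimate_snr_db(matrix: BreathMatrix) -> float:
    """SNR of the respiratory-locked signal, in dB.

    Signal power is the temporal variance of the per-timepoint median
    breath; noise power is the variance of the residuals of each
    (detrended) breath about that median, pooled over all breaths and
    samples. Each breath's residual mean is removed before pooling:
    breath-to-breath baseline offsets (residual drift the global linear
    detrend cannot represent) are low-frequency content, not noise that
    impairs detection of the respiratory rate. Capped at +60 dB for
    effectively noise-free input.
    """
    if matrix.n_breaths < 3:
        raise ValueError("SNR estimation needs at least 3 breaths")
    values = matrix.values
    if not matrix.detrended:
        values = detrend_matrix(matrix).values
    med = np.median(values, axis=0)
    signal_var = float(med.var())
    resid = values - med
    resid = resid - resid.mean(axis=1, keepdims=True)
    resid_var = float(np.mean(resid**2))
    if resid_var < 1e-12:
        return SNR_CAP_DB
    return min(10.0 * np.log10(signal_var / resid_var), SNR_CAP_DB)


# --------------------------------------------------------------------------
# per-condition driver and exclusion filtering
# --------------------------------------------------------------------------

@dataclass
class ConditionResult:
    """Everything the inclusion filter and downstream stages need."""

    condition_id: str
    alignment: AlignmentResult
    trough: float | None = None
    snr_db: float | None = None
    normalized: NormalizedBreath | None = None


def preprocess_condition(
    trace: SignalTrace,
    config: AlignmentConfig | None = None,
    n_breaths: int = 10,
) -> ConditionResult:
    """Run alignment, segmentation, detrend, aggregation and normalization
    for one condition. Unalignable traces are still segmented at offset 0
    so the trough and SNR metrics can be reported."""
    alignment = detect_alignment_offset(trace, config)
    offset = alignment.offset if alignment.alignable else 0.0
    raw = segment_breaths(trace, offset, n_breaths=n_breaths)
    trough = raw.trough
    det = detrend_matrix(raw)
    snr = estimate_snr_db(det)
    normalized = None
    if det.values.std() > 1e-12:
        normalized = normalize_breath(aggregate_median_breath(det), trace.condition_id)
    return ConditionResult(
        condition_id=trace.condition_id,
        alignment=alignment,
        trough=trough,
        snr_db=snr,
        normalized=normalized,
    )


def apply_exclusion_filters(
    results: Iterable[ConditionResult],
    trough_mmhg: float = TROUGH_THRESHOLD_MMHG,
    snr_db: float = SNR_THRESHOLD_DB,
) -> pd.DataFrame:
    """Inclusion report: one row per condition.

    A condition is excluded iff trough < trough_mmhg (strict) OR
    SNR < snr_db OR it is unalignable; reasons are evaluated in the fixed
    order trough -> snr -> alignment and the first failure is recorded.
    """
    rows = []
    for r in results:
        if r.trough is not None and r.trough < trough_mmhg:
            reason = "trough_below_100mmHg"
        elif r.snr_db is not None and r.snr_db < snr_db:
            reason = "snr_below_20dB"
        elif not r.alignment.alignable:
            reason = "unalignable"
        else:
            reason = "none"
        rows.append(
            {
                "condition_id": r.condition_id,
                "included": reason == "none",
                "reason": reason,
                "trough_mmHg": r.trough,
                "snr_db": r.snr_db,
                "offset_s": r.alignment.offset,
            }
        )
    return pd.DataFrame(rows)
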