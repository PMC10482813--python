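"""Synthetic cohorts of PaO2 / airway-pressure traces with known ground truth.

The generator is phenomenological: each condition's within-breath PaO2
morphology is a unit-variance template built from the respiratory
fundamental plus second and third harmonics. A progression coordinate
``theta`` in [0, 1] interpolates the fundamental from the ventilation-
dependent shape (peak at end-inspiration, theta=0) to its inversion
(theta=1); the harmonic terms create the intermediate biphasic shapes
with two peaks per breath. Five fixed archetypes along this continuum
define the morphology clusters a recovery experiment should find.

Every public generator is a pure function of its spec and an explicit
seed; omitting the seed is an error.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd

from .core import (
    BREATH_PERIOD_S,
    BREATH_SAMPLES,
    DT,
    INSP_FRACTION,
    SignalTrace,
    breath_grid,
)

__all__ = [
    "MorphologyParams",
    "ConditionSpec",
    "ARCHETYPES",
    "breath_template",
    "morphology_from_coeffs",
    "morphology_to_coeffs",
    "simulate_condition",
    "generate_cohort",
    "pilot_exclusions_preset",
    "recovery_cohort_design",
    "simulate_covariates",
    "simulate_progression_outcomes",
]


# --------------------------------------------------------------------------
# morphology templates
# --------------------------------------------------------------------------

@dataclass(frozen=True)
class MorphologyParams:
    """Shape parameters of one within-breath PaO2 oscillation.

    theta
        Progression coordinate in [0, 1]: 0 = ventilation-dependent
        (PaO2 peaks at the inspiration->expiration transition), 1 = the
        inverted, perfusion-dependent shape (trough there).
    biphasic_weight, harmonic_phase
        Amplitude (fraction of the fundamental's scale) and phase
        (radians) of the second harmonic; a nonzero weight at
        intermediate theta produces two local maxima per breath.
    third_weight, third_phase
        Amplitude and phase of a third-harmonic term carrying the finer
        late-breath structure that distinguishes the archetypes.
    """

    theta: float
    biphasic_weight: float = 0.0
    harmonic_phase: float = 0.0
    third_weight: float = 0.0
    third_phase: float = 0.0

    def __post_init__(self) -> None:
        if not 0.0 <= self.theta <= 1.0:
            raise ValueError(f"theta must be in [0, 1], got {self.theta}")
        if not 0.0 <= self.biphasic_weight <= 1.0:
            raise ValueError(
                f"biphasic_weight must be in [0, 1], got {self.biphasic_weight}"
            )
        if self.third_weight < 0.0:
            raise ValueError("third_weight must be nonnegative")


def breath_template(
    morphology: MorphologyParams,
    n_samples: int = BREATH_SAMPLES,
    insp_fraction: float = INSP_FRACTION,
) -> np.ndarray:
    """Unit-variance morphology template on the half-open breath grid.

    The fundamental is phased so that at theta=0 its maximum falls exactly
    at the inspiration->expiration transition (sample index
    n_samples*insp_fraction); theta=1 yields the pointwise negation.
    """
    if n_samples < 4:
        raise ValueError("n_samples must be >= 4")
    if not 0.0 < insp_fraction < 1.0:
        raise ValueError("insp_fraction must be in (0, 1)")
    m = morphology
    phase = np.arange(n_samples) / n_samples - insp_fraction
    raw = (
        (1.0 - 2.0 * m.theta) * np.cos(2.0 * np.pi * phase)
        + m.biphasic_weight * np.cos(4.0 * np.pi * phase + m.harmonic_phase)
        + m.third_weight * np.cos(6.0 * np.pi * phase + m.third_phase)
    )
    sd = raw.std()
    if sd < 1e-12:
        raise ValueError("degenerate morphology: template has zero variance")
    return (raw - raw.mean()) / sd


def morphology_to_coeffs(m: MorphologyParams) -> np.ndarray:
    """Coefficients (a, b2, g2, b3, g3) of the template in the cos/sin
    harmonic basis: a*cos1 + b2*cos2 + g2*sin2 + b3*cos3 + g3*sin3,
    all phased relative to end-inspiration."""
    return np.array(
        [
            1.0 - 2.0 * m.theta,
            m.biphasic_weight * math.cos(m.harmonic_phase),
            -m.biphasic_weight * math.sin(m.harmonic_phase),
            m.third_weight * math.cos(m.third_phase),
            -m.third_weight * math.sin(m.third_phase),
        ]
    )


def morphology_from_coeffs(coeffs: Sequence[float]) -> MorphologyParams:
    """Inverse of :func:`morphology_to_coeffs` (a clipped to [-1, 1])."""
    a, b2, g2, b3, g3 = (float(c) for c in coeffs)
    a = min(1.0, max(-1.0, a))
    return MorphologyParams(
        theta=(1.0 - a) / 2.0,
        biphasic_weight=min(1.0, math.hypot(b2, g2)),
        harmonic_phase=math.atan2(-g2, b2) if (b2, g2) != (0.0, 0.0) else 0.0,
        third_weight=math.hypot(b3, g3),
        third_phase=math.atan2(-g3, b3) if (b3, g3) != (0.0, 0.0) else 0.0,
    )


# Five archetypes ordered by progression rank 1 (ventilation-dependent,
# non-inverted) to 5 (perfusion-dependent, inverted), as unit vectors in
# the harmonic-coefficient basis. The across-rank patterns of the five
# basis coefficients follow linear / quadratic / cubic / quartic
# contrasts, so the five mean shapes span four between-archetype
# directions; together with the within-archetype third-harmonic
# variability this yields a five-dimensional score space whose leading
# component carries ~55% of the variance and whose fifth still carries
# >5% — the morphology continuum a five-component analysis resolves.
_ARCHETYPE_COEFFS = np.array(
    [
        #    a       b2       g2       b3       g3
        [0.9644, 0.0423, -0.1543, 0.2043, 0.0516],
        [0.5960, 0.5412, 0.4941, -0.3271, -0.0275],
        [0.0000, 0.8348, 0.0000, 0.5505, 0.0000],
        [-0.5960, 0.5412, -0.4941, -0.3271, 0.0275],
        [-0.9644, 0.0423, 0.1543, 0.2043, -0.0516],
    ]
)

#: archetypes indexed by progression rank - 1
ARCHETYPES: tuple[MorphologyParams, ...] = tuple(
    morphology_from_coeffs(c) for c in _ARCHETYPE_COEFFS
)

#: within-archetype jitter SDs in the harmonic-coefficient basis; the
#: third-harmonic sine direction carries the bulk of the within-cluster
#: shape variability (condition-level late-breath fine structure).
_JITTER_SD = np.array([0.04, 0.04, 0.04, 0.04, 0.37])


def _jittered_morphology(rank: int, rng: np.random.Generator) -> MorphologyParams:
    base = _ARCHETYPE_COEFFS[rank - 1]
    return morphology_from_coeffs(base + rng.normal(0.0, _JITTER_SD))


# --------------------------------------------------------------------------
# condition specification
# --------------------------------------------------------------------------

@dataclass(frozen=True)
class ConditionSpec:
    """Everything needed to simulate one ventilatory condition."""

    condition_id: str
    animal_id: str
    peep: float  # cmH2O
    vt_per_kg: float  # mL/kg
    injured: bool
    morphology: MorphologyParams
    mean_pao2: float = 300.0  # mmHg
    osc_amplitude: float = 20.0  # mmHg, half peak-to-trough
    drift_slope: float = 0.0  # mmHg/s
    snr_db: float = 30.0
    cardiac_rate: float = 116.5  # beats/min
    cardiac_amp: float | None = None  # mmHg; default 5% of osc_amplitude
    force_exclusion: str = "none"  # none | trough | snr | unalignable
    true_offset: float = 1.2  # s, ventilation-to-PaO2 lag
    progression_rank: int | None = None  # archetype index 1..5 if applicable
    weight_kg: float = 31.0

    def __post_init__(self) -> None:
        if self.mean_pao2 - self.osc_amplitude <= 0:
            raise ValueError("mean_pao2 - osc_amplitude must be positive")
        if self.cardiac_rate <= 60.0 / BREATH_PERIOD_S:
            raise ValueError("cardiac_rate must exceed the respiratory rate")
        if self.true_offset < 0:
            raise ValueError("true_offset must be nonnegative")
        if self.force_exclusion not in {"none", "trough", "snr", "unalignable"}:
            raise ValueError(f"unknown force_exclusion {self.force_exclusion!r}")


# simulation layout constants
_N_BREATHS_PRE = 10
_N_BREATHS_POST = 10
_HOLD_DURATION_S = 20.0
_DECLINE_RATE = 2.5  # mmHg/s during the breath hold (~50 mmHg over 20 s apnoea)
_RECOVERY_TAU = 4.0  # s, exponential PaO2 recovery after restart
_SNR_FORCED_DB = 15.0
_TROUGH_TARGET_FRACTION = 0.6  # forced-trough mean = 100 + 0.6*amplitude


def _driving_pressure(spec: ConditionSpec) -> float:
    """Pressure-control driving pressure, cmH2O (stiffer if injured)."""
    dp = 1.4 * spec.vt_per_kg
    return dp * 1.25 if spec.injured else dp


def simulate_condition(
    spec: ConditionSpec, seed: int | np.random.SeedSequence
) -> tuple[SignalTrace, dict]:
    """Simulate one condition's 10 Hz trace plus its ground-truth record.

    Layout: ``_N_BREATHS_PRE`` tidal breaths, a 20 s end-expiratory breath
    hold, then ``_N_BREATHS_POST`` breaths after the restart. The PaO2
    channel follows the ventilation phase at ``t - true_offset``, so the
    hold decline and the post-restart recovery both begin ``true_offset``
    after the corresponding airway-pressure event.
    """
    if seed is None:
        raise ValueError("simulate_condition requires an explicit seed")
    rng = np.random.default_rng(seed)

    period = BREATH_PERIOD_S
    hold_start = _N_BREATHS_PRE * period
    restart = hold_start + _HOLD_DURATION_S
    total_s = restart + _N_BREATHS_POST * period
    n = int(round(total_s / DT))
    t = np.arange(n) * DT

    mean_pao2 = spec.mean_pao2
    amp = spec.osc_amplitude
    if spec.force_exclusion == "trough":
        # park the mean just above threshold so the oscillation trough dips below
        mean_pao2 = 100.0 + _TROUGH_TARGET_FRACTION * amp
    snr_db = _SNR_FORCED_DB if spec.force_exclusion == "snr" else spec.snr_db

    template = breath_template(spec.morphology)
    lag = spec.true_offset

    # --- oscillatory PaO2, lagged behind the ventilator phase ------------
    t_vent = t - lag  # ventilation phase driving the PaO2 sample at t
    phase_idx = np.mod(np.round(t_vent / DT).astype(int), BREATH_SAMPLES)
    osc = amp * template[phase_idx]

    pao2 = np.empty(n)
    pre = t_vent < hold_start
    pao2[pre] = mean_pao2 + osc[pre]

    # --- breath-hold decline ---------------------------------------------
    decline_start_v = mean_pao2 + amp * template[0]  # phase 0 at hold onset
    in_hold = (t_vent >= hold_start) & (t_vent < restart)
    pao2[in_hold] = decline_start_v - _DECLINE_RATE * (t_vent[in_hold] - hold_start)
    v_low = decline_start_v - _DECLINE_RATE * _HOLD_DURATION_S

    # --- recovery and resumed oscillation --------------------------------
    post = t_vent >= restart
    if spec.force_exclusion == "unalignable":
        # the signal never picks back up: flat at the hold-end value
        pao2[post] = v_low
    else:
        dt_post = t_vent[post] - restart
        recovery = v_low + (mean_pao2 - v_low) * (1.0 - np.exp(-dt_post / _RECOVERY_TAU))
        ramp = np.clip(dt_post / (2.0 * period), 0.0, 1.0)
        post_phase = np.mod(np.round(dt_post / DT).astype(int), BREATH_SAMPLES)
        pao2[post] = recovery + ramp * amp * template[post_phase]

    # --- drift, cardiac ripple, white noise -------------------------------
    pao2 += spec.drift_slope * t

    residual_budget = amp**2 * 10.0 ** (-snr_db / 10.0)
    cardiac_amp = 0.05 * amp if spec.cardiac_amp is None else spec.cardiac_amp
    cardiac_var = min(cardiac_amp**2 / 2.0, 0.25 * residual_budget)
    cardiac_amp_eff = math.sqrt(2.0 * cardiac_var)
    white_var = residual_budget - cardiac_var
    cardiac_phase = rng.uniform(0.0, 2.0 * np.pi)
    pao2 += cardiac_amp_eff * np.sin(
        2.0 * np.pi * spec.cardiac_rate / 60.0 * t + cardiac_phase
    )
    pao2 += rng.normal(0.0, math.sqrt(white_var), n)

    # --- airway pressure ---------------------------------------------------
    dp = _driving_pressure(spec)
    breath_phase = np.mod(t, period)
    paw = np.where(breath_phase < INSP_FRACTION * period, spec.peep + dp, spec.peep)
    paw[(t >= hold_start) & (t < restart)] = spec.peep
    # re-phase the post-restart cycles to start at the restart
    post_paw = t >= restart
    paw[post_paw] = np.where(
        np.mod(t[post_paw] - restart, period) < INSP_FRACTION * period,
        spec.peep + dp,
        spec.peep,
    )

    trace = SignalTrace(
        t=t,
        pao2=pao2,
        paw=paw,
        breath_hold_window=(hold_start, restart),
        ventilation_restart_s=restart,
        condition_id=spec.condition_id,
        meta={"animal_id": spec.animal_id, "peep": spec.peep, "vt_per_kg": spec.vt_per_kg},
    )
    truth = {
        "condition_id": spec.condition_id,
        "animal_id": spec.animal_id,
        "peep_cmh2o": spec.peep,
        "vt_ml_per_kg": spec.vt_per_kg,
        "injured": spec.injured,
        "progression_rank": spec.progression_rank,
        "theta": spec.morphology.theta,
        "true_offset_s": spec.true_offset,
        "snr_db": snr_db,
        "force_exclusion": spec.force_exclusion,
        "mean_pao2_mmhg": mean_pao2,
        "osc_amplitude_mmhg": amp,
        "driving_pressure_cmh2o": dp,
        "plateau_pressure_cmh2o": spec.peep + dp,
    }
    return trace, truth


# --------------------------------------------------------------------------
# cohort designs
# --------------------------------------------------------------------------

_DEFAULT_ANIMALS = tuple(f"A{i}" for i in range(1, 8))
_DEFAULT_PEEP = (5.0, 8.0, 10.0, 12.0)
_DEFAULT_VT = (7.0, 10.0, 15.0)


def _spawn_seeds(seed: int | np.random.SeedSequence, n: int) -> list[int]:
    ss = seed if isinstance(seed, np.random.SeedSequence) else np.random.SeedSequence(seed)
    return [int(s.generate_state(1)[0] % 2**31) for s in ss.spawn(n)]


def generate_cohort(
    seed: int | np.random.SeedSequence,
    animals: Sequence[str] = _DEFAULT_ANIMALS,
    peep_levels: Sequence[float] = _DEFAULT_PEEP,
    vt_levels: Sequence[float] = _DEFAULT_VT,
    injured_animals: Sequence[str] | None = None,
    exclusion_flags: dict[str, str] | None = None,
    snr_db: float = 30.0,
    simulate: bool = True,
) -> tuple[list[ConditionSpec], list[SignalTrace], pd.DataFrame]:
    """Full-factorial cohort (animals x PEEP x VT), morphology archetypes
    assigned in balanced rotation over a seeded shuffle of the cells.

    Returns (specs, traces, truth table); ``simulate=False`` skips trace
    synthesis and returns an empty trace list (design only). Condition
    order is randomized per animal under the seed; the same seed
    reproduces the cohort exactly.
    """
    if not (len(animals) and len(peep_levels) and len(vt_levels)):
        raise ValueError("animals, peep_levels and vt_levels must be nonempty")
    if len(set(animals)) != len(animals):
        raise ValueError("duplicate animal ids")

    ss = seed if isinstance(seed, np.random.SeedSequence) else np.random.SeedSequence(seed)
    order_ss, morph_ss, cond_ss = ss.spawn(3)
    rng_order = np.random.default_rng(order_ss)
    rng_morph = np.random.default_rng(morph_ss)

    if injured_animals is None:
        # three of seven in the lavage-injury arm by default
        k = max(1, round(len(animals) * 3 / 7))
        injured_animals = tuple(animals[:k])
    injured_set = set(injured_animals)

    cells: list[tuple[str, float, float]] = []
    for animal in animals:
        combos = [(animal, p, v) for p in peep_levels for v in vt_levels]
        rng_order.shuffle(combos)
        cells.extend(combos)

    # balanced archetype rotation over a global shuffle of cell indices
    perm = rng_morph.permutation(len(cells))
    ranks = np.empty(len(cells), dtype=int)
    ranks[perm] = np.arange(len(cells)) % len(ARCHETYPES) + 1

    exclusion_flags = exclusion_flags or {}
    specs: list[ConditionSpec] = []
    seen: set[str] = set()
    for i, (animal, p, v) in enumerate(cells):
        cid = f"{animal}-P{p:g}-V{v:g}"
        if cid in seen:
            raise ValueError(f"duplicate condition_id {cid}")
        seen.add(cid)
        rank = int(ranks[i])
        specs.append(
            ConditionSpec(
                condition_id=cid,
                animal_id=animal,
                peep=p,
                vt_per_kg=v,
                injured=animal in injured_set,
                morphology=_jittered_morphology(rank, rng_morph),
                mean_pao2=float(rng_morph.uniform(200.0, 400.0)),
                osc_amplitude=float(rng_morph.uniform(15.0, 30.0)),
                drift_slope=float(rng_morph.normal(0.0, 0.01)),
                snr_db=snr_db,
                cardiac_rate=float(rng_morph.uniform(110.0, 146.0)),
                force_exclusion=exclusion_flags.get(cid, "none"),
                true_offset=float(np.clip(rng_morph.normal(1.23, 0.23), 0.4, 3.0)),
                progression_rank=rank,
            )
        )

    traces: list[SignalTrace] = []
    truths: list[dict] = []
    cond_seeds = _spawn_seeds(cond_ss, len(specs))
    for spec, s in zip(specs, cond_seeds):
        if simulate:
            trace, truth = simulate_condition(spec, s)
            traces.append(trace)
        else:
            _, truth = _truth_only(spec)
        truths.append(truth)
    return specs, traces, pd.DataFrame(truths)


def _truth_only(spec: ConditionSpec) -> tuple[None, dict]:
    dp = _driving_pressure(spec)
    mean_pao2 = spec.mean_pao2
    if spec.force_exclusion == "trough":
        mean_pao2 = 100.0 + _TROUGH_TARGET_FRACTION * spec.osc_amplitude
    truth = {
        "condition_id": spec.condition_id,
        "animal_id": spec.animal_id,
        "peep_cmh2o": spec.peep,
        "vt_ml_per_kg": spec.vt_per_kg,
        "injured": spec.injured,
        "progression_rank": spec.progression_rank,
        "theta": spec.morphology.theta,
        "true_offset_s": spec.true_offset,
        "snr_db": _SNR_FORCED_DB if spec.force_exclusion == "snr" else spec.snr_db,
        "force_exclusion": spec.force_exclusion,
        "mean_pao2_mmhg": mean_pao2,
        "osc_amplitude_mmhg": spec.osc_amplitude,
        "driving_pressure_cmh2o": dp,
        "plateau_pressure_cmh2o": spec.peep + dp,
    }
    return None, truth


def pilot_exclusions_preset(
    seed: int | np.random.SeedSequence, simulate: bool = True
) -> tuple[list[ConditionSpec], list[SignalTrace], pd.DataFrame]:
    """The 84-condition factorial (7 animals x PEEP {5,8,10,12} x VT
    {7,10,15}) with 3 conditions forced to violate the trough criterion,
    3 the SNR criterion and 5 the alignability criterion, in distinct
    cells — the design whose inclusion report should retain 73 conditions.
    """
    ss = seed if isinstance(seed, np.random.SeedSequence) else np.random.SeedSequence(seed)
    flag_ss, cohort_ss = ss.spawn(2)
    rng = np.random.default_rng(flag_ss)

    cell_ids = [
        f"{a}-P{p:g}-V{v:g}"
        for a in _DEFAULT_ANIMALS
        for p in _DEFAULT_PEEP
        for v in _DEFAULT_VT
    ]
    flagged = rng.choice(len(cell_ids), size=11, replace=False)
    flags = {cell_ids[i]: "trough" for i in flagged[:3]}
    flags.update({cell_ids[i]: "snr" for i in flagged[3:6]})
    flags.update({cell_ids[i]: "unalignable" for i in flagged[6:]})
    return generate_cohort(cohort_ss, exclusion_flags=flags, simulate=simulate)


def recovery_cohort_design(
    seed: int | np.random.SeedSequence, snr_db: float = 30.0, simulate: bool = True
) -> tuple[list[ConditionSpec], list[SignalTrace], pd.DataFrame]:
    """75-condition cohort (5 animals x PEEP {4,6,8,10,12} x VT {7,10,15})
    with the five archetypes balanced 15-a-piece, used for end-to-end
    morphology-recovery experiments."""
    return generate_cohort(
        seed,
        animals=tuple(f"A{i}" for i in range(1, 6)),
        peep_levels=(4.0, 6.0, 8.0, 10.0, 12.0),
        vt_levels=(7.0, 10.0, 15.0),
        snr_db=snr_db,
        simulate=simulate,
    )


# --------------------------------------------------------------------------
# covariates
# --------------------------------------------------------------------------

@dataclass(frozen=True)
class CovariateEffects:
    """Generating model for per-condition cardiorespiratory covariates:
    linear in theta plus a per-animal random intercept plus noise."""

    pf_kpa_intercept: float = 44.0
    pf_kpa_slope: float = -19.0  # kPa per unit theta
    ppv_intercept: float = 12.0
    ppv_slope: float = 8.0  # % per unit theta
    co_intercept: float = 4.7
    co_slope: float = 0.3  # L/min per unit theta
    animal_sd: float = 3.0  # random-intercept SD, in each covariate's units
    noise_sd: float = 3.0

    def scaled(self) -> dict[str, tuple[float, float, float, float]]:
        """covariate -> (intercept, slope, animal_sd, noise_sd), with the
        animal/noise SDs scaled to each covariate's natural spread."""
        return {
            "pf_kpa": (self.pf_kpa_intercept, self.pf_kpa_slope, self.animal_sd, self.noise_sd),
            "ppv_pct": (self.ppv_intercept, self.ppv_slope, self.animal_sd, self.noise_sd),
            "cardiac_output_l_min": (
                self.co_intercept,
                self.co_slope,
                self.animal_sd * 0.15,
                self.noise_sd * 0.2,
            ),
        }


def simulate_covariates(
    truth: pd.DataFrame,
    effects: CovariateEffects | None = None,
    seed: int | np.random.SeedSequence | None = None,
) -> pd.DataFrame:
    """Per-condition covariate table generated from the truth record.

    Each covariate is intercept + slope*theta + animal intercept + noise.
    The generating parameters are attached as ``df.attrs['effects']`` so
    recovery experiments can compare fitted against generating values.
    """
    if truth.empty:
        raise ValueError("truth table is empty")
    if seed is None:
        raise ValueError("simulate_covariates requires an explicit seed")
    effects = effects or CovariateEffects()
    rng = np.random.default_rng(
        seed if not isinstance(seed, np.random.SeedSequence) else seed
    )

    out = truth[["condition_id", "animal_id", "injured", "theta"]].copy()
    animals = sorted(truth["animal_id"].unique())
    theta = truth["theta"].to_numpy(dtype=float)
    for name, (b0, b1, a_sd, e_sd) in effects.scaled().items():
        intercepts = dict(zip(animals, rng.normal(0.0, a_sd, len(animals))))
        u = truth["animal_id"].map(intercepts).to_numpy(dtype=float)
        out[name] = b0 + b1 * theta + u + rng.normal(0.0, e_sd, len(truth))
    out["pf_mmhg"] = out["pf_kpa"] * 7.50062
    for col in ("peep_cmh2o", "vt_ml_per_kg", "plateau_pressure_cmh2o",
                "driving_pressure_cmh2o", "mean_pao2_mmhg", "osc_amplitude_mmhg"):
        if col in truth:
            out[col] = truth[col].to_numpy()
    out.attrs["effects"] = effects
    return out


def simulate_progression_outcomes(
    n_animals: int = 7,
    n_conditions: int = 84,
    slopes: dict[str, float] | None = None,
    animal_sd: float = 0.75,
    noise_sd: float = 0.8,
    seed: int | np.random.SeedSequence | None = None,
) -> pd.DataFrame:
    """Direct generator for mixed-model recovery experiments.

    Produces a table with exogenous covariates (pf_kpa, ppv_pct), an
    animal id, and a continuous progression outcome
    rank = 3 + sum(slope*covariate) + u_animal + eps with
    u_animal ~ N(0, animal_sd^2). Used to check that the mixed model
    recovers the generating random-intercept SD.
    """
    if seed is None:
        raise ValueError("simulate_progression_outcomes requires an explicit seed")
    slopes = slopes if slopes is not None else {"pf_kpa": -0.06, "ppv_pct": 0.065}
    rng = np.random.default_rng(seed)
    animal_ids = np.array([f"A{i % n_animals + 1}" for i in range(n_conditions)])
    u = rng.normal(0.0, animal_sd, n_animals)
    df = pd.DataFrame({"animal_id": animal_ids})
    df["pf_kpa"] = rng.uniform(20.0, 55.0, n_conditions)
    df["ppv_pct"] = rng.uniform(5.0, 25.0, n_conditions)
    rank = np.full(n_conditions, 3.0)
    for name, b in slopes.items():
        rank += b * (df[name] - df[name].mean()).to_numpy()
    rank += u[[int(a[1:]) - 1 for a in animal_ids]]
    rank += rng.normal(0.0, noise_sd, n_conditions)
    df["progression_rank"] = rank
    df.attrs["generating"] = {"slopes": slopes, "animal_sd": animal_sd, "noise_sd": noise_sd}
    return df
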