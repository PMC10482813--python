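"""End-to-end orchestration: simulate -> preprocess -> FPCA -> cluster -> stats.

A run is fully determined by its :class:`RunConfig`; the master seed is
expanded into fixed per-stage streams (cohort simulation, covariates,
Monte-Carlo clustering, finalization) so no stage's randomness leaks into
another. Artifacts are plain CSV/JSON stamped with a hash of the config.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from . import cluster as cl
from . import fpca as fp
from . import preprocess as pp
from . import stats as st
from . import synthetic as syn
from .core import SignalTrace
from .io import read_signal_csv, write_signal_csv

__all__ = ["RunConfig", "run_pipeline", "PipelineError"]

SCHEMA_VERSION = "pao2osc-run-1"


class PipelineError(RuntimeError):
    """A stage failure, carrying the stage and condition it occurred in."""

    def __init__(self, stage: str, condition_id: str | None, message: str):
        self.stage = stage
        self.condition_id = condition_id
        where = f"stage={stage}" + (f", condition={condition_id}" if condition_id else "")
        super().__init__(f"[{where}] {message}")


@dataclass(frozen=True)
class RunConfig:
    """Configuration of one reproducible pipeline run."""

    out_dir: str
    seed: int
    preset: str = "pilot-exclusions"  # pilot-exclusions | recovery | from-files
    signals_dir: str | None = None
    manifest: str | None = None
    trough_mmhg: float = 100.0
    snr_db: float = 20.0
    variance_threshold: float = 0.95
    k_range: tuple[int, ...] | None = None  # default 1..K_retained
    n_iterations: int = 10_000
    n_starts: int = 100
    tie_rule: str = "band"
    units: str = "mmHg"
    write_signals: bool = False

    def __post_init__(self) -> None:
        if self.seed is None:
            raise ValueError("a master seed is mandatory")
        if min(self.trough_mmhg, self.snr_db, self.variance_threshold) <= 0:
            raise ValueError("all thresholds must be positive")

    def config_hash(self) -> str:
        payload = json.dumps(dataclasses.asdict(self), sort_keys=True, default=str)
        return hashlib.sha256(payload.encode()).hexdigest()[:16]


def _stage_seed(master: int, stage: str) -> int:
    digest = hashlib.sha256(f"{master}:{stage}".encode()).digest()
    return int.from_bytes(digest[:4], "big") % 2**31


def _load_cohort(config: RunConfig):
    seed = _stage_seed(config.seed, "simulate")
    if config.preset == "pilot-exclusions":
        return syn.pilot_exclusions_preset(seed)
    if config.preset == "recovery":
        return syn.recovery_cohort_design(seed)
    if config.preset == "from-files":
        if not (config.signals_dir and config.manifest):
            raise PipelineError("load", None, "from-files needs signals_dir and manifest")
        manifest = pd.read_csv(config.manifest)
        traces: list[SignalTrace] = []
        for cid in manifest["condition_id"]:
            path = Path(config.signals_dir) / f"{cid}.csv"
            if not path.exists():
                raise PipelineError("load", str(cid), f"signal file missing: {path}")
            traces.append(read_signal_csv(path, condition_id=str(cid)))
        return None, traces, manifest
    raise PipelineError("load", None, f"unknown preset {config.preset!r}")


def run_pipeline(config: RunConfig) -> dict:
    """Execute every stage and write artifacts to ``config.out_dir``.

    Returns the summary dict (also written as summary.json). Reruns with
    the same config are bit-identical.
    """
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    stamp = {"schema": SCHEMA_VERSION, "config_hash": config.config_hash(), "seed": config.seed}

    # --- simulate / load ---------------------------------------------------
    specs, traces, truth = _load_cohort(config)
    if config.write_signals and traces:
        sig_dir = out / "signals"
        sig_dir.mkdir(exist_ok=True)
        for tr in traces:
            write_signal_csv(tr, sig_dir / f"{tr.condition_id}.csv")
    if truth is not None:
        truth.to_csv(out / "manifest.csv", index=False)

    # --- preprocess --------------------------------------------------------
    results = []
    for tr in traces:
        try:
            results.append(pp.preprocess_condition(tr))
        except Exception as exc:  # noqa: BLE001 - reported with context
            raise PipelineError("preprocess", tr.condition_id, str(exc)) from exc
    report = pp.apply_exclusion_filters(
        results, trough_mmhg=config.trough_mmhg, snr_db=config.snr_db
    )
    report.to_csv(out / "inclusion_report.csv", index=False, float_format="%.6g")
    included = report[report["included"]]["condition_id"].tolist()
    by_id = {r.condition_id: r for r in results}
    curves = np.vstack([by_id[cid].normalized.values for cid in included])

    # --- FPCA ---------------------------------------------------------------
    try:
        model = fp.fit_fpca(curves)
    except Exception as exc:  # noqa: BLE001
        raise PipelineError("fpca", None, str(exc)) from exc
    k_retained = fp.n_components_for_threshold(model, config.variance_threshold)
    scores = model.scores[:, :k_retained]
    model.to_json(out / "fpca_model.json")
    score_df = pd.DataFrame(
        scores, columns=[f"pc{i+1}" for i in range(k_retained)]
    )
    score_df.insert(0, "condition_id", included)
    score_df.to_csv(out / "scores.csv", index=False, float_format="%.10g")

    # --- cluster ------------------------------------------------------------
    k_range = config.k_range or tuple(range(1, k_retained + 1))
    try:
        selection = cl.select_k_monte_carlo(
            scores,
            k_range,
            n_iterations=config.n_iterations,
            seed=_stage_seed(config.seed, "cluster-mc"),
            tie_rule=config.tie_rule,
        )
        ordered = cl.finalize_clustering(
            scores,
            selection.chosen_k,
            seed=_stage_seed(config.seed, "cluster-final"),
            n_starts=config.n_starts,
            curves=curves,
        )
    except Exception as exc:  # noqa: BLE001
        raise PipelineError("cluster", None, str(exc)) from exc
    selection.table.to_csv(out / "aic_table.csv", index=False, float_format="%.10g")
    assign_df = score_df.copy()
    assign_df.insert(1, "cluster", ordered.solution.assignments)
    assign_df.insert(2, "progression_rank", ordered.progression_rank)
    assign_df.to_csv(out / "assignments.csv", index=False, float_format="%.10g")
    if ordered.cluster_mean_curves is not None:
        pd.DataFrame(
            ordered.cluster_mean_curves.T,
            columns=[f"rank_{r+1}" for r in range(ordered.cluster_mean_curves.shape[0])],
        ).to_csv(out / "cluster_means.csv", index=False, float_format="%.10g")

    # --- stats --------------------------------------------------------------
    summary_stats: dict = {}
    reg = st.progression_regression(scores[:, 0], ordered.progression_rank)
    (out / "progression_regression.json").write_text(
        json.dumps({**stamp, **dataclasses.asdict(reg)}, sort_keys=True)
    )
    summary_stats["pc1_rank_r_squared"] = reg.r_squared
    if truth is not None and "theta" in truth.columns:
        cov = syn.simulate_covariates(
            truth, seed=_stage_seed(config.seed, "covariates")
        )
        cov = cov[cov["condition_id"].isin(included)].reset_index(drop=True)
        cov["progression_rank"] = [
            int(ordered.progression_rank[included.index(c)]) for c in cov["condition_id"]
        ]
        try:
            table = st.cluster_comparison_table(
                cov,
                numeric=("pf_kpa", "ppv_pct", "cardiac_output_l_min"),
                categorical=("injured",),
            )
            table.to_csv(out / "cluster_comparison.csv", index=False, float_format="%.6g")
            mixed = st.fit_mixed_progression(cov)
            (out / "mixed_model.json").write_text(
                json.dumps({**stamp, **dataclasses.asdict(mixed)}, sort_keys=True)
            )
            summary_stats["mixed_random_intercept_sd"] = mixed.random_intercept_sd
        except ValueError as exc:
            summary_stats["stats_note"] = str(exc)

    # --- summary ------------------------------------------------------------
    reasons = report["reason"].value_counts().to_dict()
    summary = {
        **stamp,
        "n_conditions": int(len(report)),
        "n_included": int(report["included"].sum()),
        "exclusions": {
            k: int(v) for k, v in sorted(reasons.items()) if k != "none"
        },
        "k_retained": int(k_retained),
        "chosen_k": int(selection.chosen_k),
        "cluster_sizes": {
            str(r): int((ordered.progression_rank == r).sum())
            for r in sorted(set(ordered.progression_rank))
        },
        **summary_stats,
    }
    (out / "summary.json").write_text(json.dumps(summary, sort_keys=True, indent=1))
    return summary
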