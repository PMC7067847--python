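"""High-level calibration and recovery experiments on synthetic cohorts.

These runners wire the full pipeline together — simulate a cohort, build
the paired case-crossover structure, featurize the windows, and either fit
the forecasting models or run the differential-expression analysis — and
are used both by the test suite and by the reproduction script.

The injected effect always targets the ``health`` dictionary category of
the default synthetic vocabulary, calibrated through the analytic
effect-size oracle in :mod:`langshift.synthetic`.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .corpus_io import PipelineConfig
from .design import CaseControlCohort, assemble_cohort
from .features import FeatureResources, featurize_cohort
from .forecasting import (
    EvaluationReport,
    build_model_matrix,
    grouped_cv_evaluate,
    ridge_logistic_control,
)
from .inference import change_matrix, diff_of_diff_matrix, differential_table
from .synthetic import (
    SimulationConfig,
    SyntheticCohort,
    default_resources,
    generate_cohort,
    multiplier_for_effect,
)

__all__ = [
    "EFFECT_CATEGORY",
    "child_seeds",
    "make_sim_config",
    "cohort_change_matrix",
    "run_differential",
    "run_forecast",
    "null_auc_experiment",
    "null_fdp_experiment",
    "parameter_recovery_experiment",
    "signal_grid_experiment",
]

#: Dictionary category carrying the injected effect in every experiment.
EFFECT_CATEGORY = "health"


def child_seeds(seed: int, n: int) -> np.ndarray:
    """n reproducible sub-seeds (< 2^31) derived from one master seed."""
    rng = np.random.default_rng(seed)
    return rng.integers(0, 2**31 - 1, size=n)


def make_sim_config(n_patients: int, seed: int, target_d: float = 0.0,
                    history_days: int = 365) -> SimulationConfig:
    """Study-condition config with the effect calibrated to ``target_d``."""
    base = SimulationConfig(n_patients=n_patients, history_days=history_days,
                            rng_seed=int(seed))
    if target_d == 0.0:
        return base
    mult = multiplier_for_effect(base, EFFECT_CATEGORY, target_d)
    return base.with_(effect_specs=((EFFECT_CATEGORY, mult),))


def cohort_change_matrix(
    cohort: SyntheticCohort,
    pipe: PipelineConfig | None = None,
    resources: FeatureResources | None = None,
    cohort_seed: int | None = None,
) -> tuple[pd.DataFrame, CaseControlCohort]:
    """Simulated posts -> paired cohort -> featurized windows -> changes."""
    pipe = pipe or PipelineConfig(rng_seed=cohort.config.rng_seed)
    resources = resources or default_resources()
    cc = assemble_cohort(cohort.posts, cohort.events, cohort.config.visit_type,
                         pipe, rng=cohort_seed)
    panel = featurize_cohort(cohort.posts, cc, resources)
    return change_matrix(panel), cc


def run_differential(sim: SimulationConfig,
                     pipe: PipelineConfig | None = None) -> pd.DataFrame:
    """End-to-end differential-expression table for one synthetic cohort."""
    pipe = pipe or PipelineConfig(rng_seed=sim.rng_seed)
    cohort = generate_cohort(sim)
    changes, _ = cohort_change_matrix(cohort, pipe)
    dod = diff_of_diff_matrix(changes)
    return differential_table(dod, alpha=pipe.alpha)


def run_forecast(sim: SimulationConfig, pipe: PipelineConfig | None = None,
                 model: str = "ensemble") -> EvaluationReport:
    """End-to-end grouped-CV evaluation for one synthetic cohort."""
    pipe = pipe or PipelineConfig(rng_seed=sim.rng_seed)
    cohort = generate_cohort(sim)
    changes, _ = cohort_change_matrix(cohort, pipe)
    matrix = build_model_matrix(changes)
    evaluate = grouped_cv_evaluate if model == "ensemble" \
        else ridge_logistic_control
    return evaluate(matrix, k=pipe.cv_folds, seed=pipe.rng_seed,
                    variance_retained=pipe.pca_variance_retained)


def null_auc_experiment(seed: int, n_patients: int = 400) -> EvaluationReport:
    """Pooled 5-fold ensemble AUC on a no-effect cohort (expected ~ 0.5)."""
    sim = make_sim_config(n_patients, seed, target_d=0.0)
    return run_forecast(sim)


def null_fdp_experiment(seed: int, n_runs: int = 200, n_patients: int = 100,
                        history_days: int = 160,
                        alpha: float = 0.05) -> np.ndarray:
    """False-discovery proportion per seeded differential run, global null.

    Under the global null every BH discovery is false, so the per-run FDP is
    1 when any feature is called significant and 0 otherwise; the mean over
    runs estimates the realized FDR, which BH bounds at alpha.
    """
    fdps = np.empty(n_runs)
    for i, sub in enumerate(child_seeds(seed, n_runs)):
        sim = make_sim_config(n_patients, int(sub), target_d=0.0,
                              history_days=history_days)
        pipe = PipelineConfig(rng_seed=int(sub), alpha=alpha)
        table = run_differential(sim, pipe)
        n_disc = int(table["significant"].sum())
        fdps[i] = 1.0 if n_disc > 0 else 0.0
    return fdps


@dataclass
class RecoveryResult:
    target_d: float
    estimated_d: list[float]
    significant: list[bool]

    @property
    def mean_d(self) -> float:
        return float(np.mean(self.estimated_d))

    @property
    def significance_rate(self) -> float:
        return float(np.mean(self.significant))


def parameter_recovery_experiment(seed: int, target_d: float = 0.3,
                                  n_seeds: int = 20,
                                  n_patients: int = 200) -> RecoveryResult:
    """Recover an injected effect: estimated d_z vs the analytic target.

    Per seed, one cohort is generated with the effect multiplier calibrated
    to ``target_d`` on the injected category; the differential table's d and
    BH significance for that category's feature are collected.
    """
    estimated, significant = [], []
    feature = f"dict:{EFFECT_CATEGORY}"
    for sub in child_seeds(seed, n_seeds):
        sim = make_sim_config(n_patients, int(sub), target_d=target_d)
        table = run_differential(sim)
        row = table.set_index("feature").loc[feature]
        estimated.append(float(row["cohens_d"]))
        significant.append(bool(row["significant"]))
    return RecoveryResult(target_d=target_d, estimated_d=estimated,
                          significant=significant)


def signal_grid_experiment(seed: int,
                           d_values: tuple[float, ...] = (0.0, 0.25, 0.5, 1.0),
                           n_patients: int = 400,
                           seeds_per_level: int = 3) -> dict[float, float]:
    """Mean pooled-CV AUC at each injected effect size."""
    out: dict[float, float] = {}
    seeds = child_seeds(seed, len(d_values) * seeds_per_level)
    for i, d in enumerate(d_values):
        aucs = []
        for sub in seeds[i * seeds_per_level:(i + 1) * seeds_per_level]:
            sim = make_sim_config(n_patients, int(sub), target_d=d)
            aucs.append(run_forecast(sim).auc)
        out[d] = float(np.mean(aucs))
    return out
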