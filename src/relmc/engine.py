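"""Condition grids and the replication engine.

Four study designs are supported:

* ``tn``       — true-negative study: null populations, RMSE and %bias.
* ``fpm``      — modified false positives: null populations, share of
                 replications at or above the 0.7 cut-off.
* ``fnm``      — modified false negatives: tau-equivalent and congeneric
                 populations at acceptable reliability (0.731 for 6
                 items, 0.845 for 12), share of replications at or
                 below 0.
* ``fpm_weak`` — false positives under *unacceptable* reliability
                 (tau-equivalent 0.3 with 6 items; congeneric 0.5 with
                 12 items).

Seeding is hierarchical and collision-free: every replication's
generator is derived from ``SeedSequence(master_seed, spawn_key=(study,
k, n, model, replication))``, so results are byte-identical regardless
of execution order and conditions never share a stream.
"""

from __future__ import annotations

import time
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from . import criteria, indices, populations

__all__ = [
    "Condition",
    "RunResult",
    "EstimatorConfig",
    "STUDIES",
    "default_grid",
    "run_condition",
    "run_grid",
]

STUDIES = ("tn", "fpm", "fnm", "fpm_weak")
_STUDY_CODE = {s: i for i, s in enumerate(STUDIES)}
_MODEL_CODE = {"null": 0, "TE": 1, "CG": 2}

#: acceptable-level true reliabilities of the reference design, by item count
ACCEPTABLE_RELIABILITY = {6: 0.731, 12: 0.845}
#: unacceptable-level blocks of the weak-reliability extension
WEAK_BLOCKS = ((6, "TE", 0.3), (12, "CG", 0.5))

_SMALL_N = (20, 25, 30, 35, 40, 45, 50)
_LARGE_N = (250, 500, 1000)
DEFAULT_REPS = 10_000


@dataclass(frozen=True)
class Condition:
    """One cell of a study grid."""

    study: str
    k: int
    n: int
    model: str  # "null" | "TE" | "CG"
    true_reliability: float
    reps: int = DEFAULT_REPS

    def __post_init__(self) -> None:
        if self.study not in STUDIES:
            raise ValueError(f"unknown study {self.study!r}")
        if self.model not in _MODEL_CODE:
            raise ValueError(f"unknown model {self.model!r}")
        if self.study in ("tn", "fpm") and (
            self.model != "null" or self.true_reliability != 0.0
        ):
            raise ValueError(f"{self.study} conditions must be null populations")
        if self.study == "fnm" and self.model not in ("TE", "CG"):
            raise ValueError("fnm conditions need a TE or CG population")
        if self.study == "fpm_weak" and self.true_reliability not in (0.3, 0.5):
            raise ValueError("fpm_weak conditions use reliability 0.3 or 0.5")


@dataclass(frozen=True)
class EstimatorConfig:
    """Settings for the index estimators used inside a run.

    ``reverse_key`` routes alpha and omega through the reference
    routine's reverse-keying pipeline (items with negative
    general-factor loadings are flipped before the indices are
    computed), which is how the published evaluation behaves; set it to
    False for the keying-free estimators.
    """

    omega_factors: int = 3
    glb_factors: int | None = None  # None -> per-k default (floor(k/2))
    reverse_key: bool = True
    fpm_cutoff: float = 0.7
    fnm_floor: float = 0.0
    bias_modes: tuple[str, ...] = (
        "absolute",
        "signed_est_minus_true",
        "signed_true_minus_est",
    )


@dataclass
class RunResult:
    """Aggregated criteria for one condition."""

    condition: Condition
    replication_sets: Mapping[str, criteria.ReplicationSet]
    criterion_values: Mapping[str, Mapping[str, criteria.CriterionValue]]
    master_seed: int
    wall_time: float

    def n_failed(self, estimator: str) -> int:
        return self.replication_sets[estimator].n_failed


def _population_for(cond: Condition) -> populations.PopulationSpec:
    if cond.model == "null":
        return populations.build_null(cond.k)
    if cond.model == "TE":
        return populations.build_tau_equivalent(cond.k, cond.true_reliability)
    return populations.build_congeneric(cond.k, cond.true_reliability)


def default_grid(study: str, reps: int = DEFAULT_REPS) -> list[Condition]:
    """The default condition grid for a study.

    tn: {6,12} x {250,500,1000}; fpm: {6,12} x the full small+large
    sample grid; fnm: the fpm grid crossed with {TE, CG} at the
    acceptable reliability for each length; fpm_weak: the two weak
    blocks (6-item TE at 0.3; 12-item CG at 0.5) across all sizes.
    """
    if study == "tn":
        return [
            Condition("tn", k, n, "null", 0.0, reps)
            for k in (6, 12)
            for n in _LARGE_N
        ]
    if study == "fpm":
        return [
            Condition("fpm", k, n, "null", 0.0, reps)
            for k in (6, 12)
            for n in (*_SMALL_N, *_LARGE_N)
        ]
    if study == "fnm":
        return [
            Condition("fnm", k, n, model, ACCEPTABLE_RELIABILITY[k], reps)
            for k in (6, 12)
            for n in (*_SMALL_N, *_LARGE_N)
            for model in ("TE", "CG")
        ]
    if study == "fpm_weak":
        return [
            Condition("fpm_weak", k, n, model, rel, reps)
            for (k, model, rel) in WEAK_BLOCKS
            for n in (*_SMALL_N, *_LARGE_N)
        ]
    raise ValueError(f"unknown study {study!r}")


def replication_rng(
    master_seed: int, cond: Condition, rep: int
) -> np.random.Generator:
    """Deterministic generator for one (condition, replication) pair."""
    ss = np.random.SeedSequence(
        entropy=master_seed,
        spawn_key=(
            _STUDY_CODE[cond.study],
            cond.k,
            cond.n,
            _MODEL_CODE[cond.model],
            rep,
        ),
    )
    return np.random.default_rng(ss)


def run_condition(
    cond: Condition,
    estimators: Sequence[str] = indices.ESTIMATOR_NAMES,
    master_seed: int = 0,
    config: EstimatorConfig | None = None,
) -> RunResult:
    """Run all replications of one condition and aggregate its criteria.

    Every estimator is computed on the same sample within a replication
    (paired design).  Estimator failures are recorded and excluded from
    that estimator's aggregation only.
    """
    if not estimators:
        raise ValueError("need at least one estimator")
    config = config or EstimatorConfig()
    spec = _population_for(cond)
    t0 = time.perf_counter()

    values: dict[str, list[float]] = {e: [] for e in estimators}
    failures: dict[str, int] = {e: 0 for e in estimators}
    for rep in range(cond.reps):
        rng = replication_rng(master_seed, cond, rep)
        sample = populations.draw_sample(spec, cond.n, rng)
        R = indices.sample_correlation(sample)
        results = indices.compute_all(
            R,
            estimators=estimators,
            omega_factors=config.omega_factors,
            glb_factors=config.glb_factors,
            reverse_key=config.reverse_key,
        )
        for name, iv in results.items():
            if iv.ok and np.isfinite(iv.value):
                values[name].append(iv.value)
            else:
                failures[name] += 1

    rep_sets = {
        e: criteria.ReplicationSet(
            estimator=e,
            estimates=np.asarray(values[e]),
            true_p=cond.true_reliability,
            n_failed=failures[e],
        )
        for e in estimators
    }
    crit: dict[str, dict[str, criteria.CriterionValue]] = {}
    for e, reps_e in rep_sets.items():
        crit[e] = _aggregate(cond.study, reps_e, config)
    return RunResult(
        condition=cond,
        replication_sets=rep_sets,
        criterion_values=crit,
        master_seed=master_seed,
        wall_time=time.perf_counter() - t0,
    )


def _aggregate(
    study: str, reps: criteria.ReplicationSet, config: EstimatorConfig
) -> dict[str, criteria.CriterionValue]:
    out: dict[str, criteria.CriterionValue] = {}
    if study == "tn":
        out["rmse"] = criteria.rmse(reps)
        for mode in config.bias_modes:
            cv = criteria.pct_bias(reps, mode=mode)
            out[cv.criterion] = cv
    elif study == "fpm":
        out["fpm"] = criteria.fpm(reps, cutoff=config.fpm_cutoff)
    elif study == "fpm_weak":
        # the population is weak but non-null; the question asked is still
        # "how often does the estimate clear the acceptability cut-off"
        cv = criteria.fpm(criteria.as_null(reps), cutoff=config.fpm_cutoff)
        out["fpm"] = criteria.CriterionValue("fpm", cv.value, cv.n_used)
    elif study == "fnm":
        out["fnm"] = criteria.fnm(reps, floor=config.fnm_floor)
    return out


def run_grid(
    study: str,
    estimators: Sequence[str] = indices.ESTIMATOR_NAMES,
    master_seed: int = 0,
    reps_override: int | None = None,
    conditions: Sequence[Condition] | None = None,
    config: EstimatorConfig | None = None,
) -> pd.DataFrame:
    """Run a study grid and return a tidy criterion table.

    One row per condition x estimator x criterion, with columns
    ``study, k, n, model, true_reliability, reps, estimator, criterion,
    value, n_used, n_failed``.  Values are on the raw scale (rates as
    fractions, bias as percent as defined by the criterion itself).
    """
    if conditions is None:
        conditions = default_grid(study, reps=reps_override or DEFAULT_REPS)
    elif reps_override is not None:
        conditions = [
            Condition(c.study, c.k, c.n, c.model, c.true_reliability, reps_override)
            for c in conditions
        ]
    rows = []
    for cond in conditions:
        result = run_condition(cond, estimators, master_seed, config)
        for est, crits in result.criterion_values.items():
            for crit_name, cv in crits.items():
                rows.append(
                    {
                        "study": cond.study,
                        "k": cond.k,
                        "n": cond.n,
                        "model": cond.model,
                        "true_reliability": cond.true_reliability,
                        "reps": cond.reps,
                        "estimator": est,
                        "criterion": crit_name,
                        "value": cv.value,
                        "n_used": cv.n_used,
                        "n_failed": result.n_failed(est),
                    }
                )
    return pd.DataFrame(rows)
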