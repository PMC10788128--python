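"""Evaluation criteria for replicated estimates, and the dummy indices.

Given a set of replication estimates of a statistic with known true
population value p, four criteria are computed:

* RMSE        — sqrt(mean((est - p)^2))
* %bias       — mean deviation x 100, under one of three sign
                conventions (estimate-minus-true, true-minus-estimate,
                or absolute deviation)
* FPm         — P(estimate >= cutoff) under a null population (p = 0):
                the modified false-positive rate at the field's
                acceptability cut-off (0.7 for internal consistency)
* FNm         — P(estimate <= floor) under a population whose parameter
                is at an acceptable level: the modified false-negative
                rate (floor 0.0)

The two dummy indices encode the argument that RMSE/%bias alone cannot
separate a valid estimator from a constant: C ≡ 0.78 and C-dot drawn
uniformly on [0.711, 0.751] both show small RMSE/%bias against
p ≈ 0.731 yet trigger FPm = 100% under any null relabeling.
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from typing import Literal, Sequence

import numpy as np

__all__ = [
    "ReplicationSet",
    "CriterionValue",
    "AggregationError",
    "rmse",
    "pct_bias",
    "fpm",
    "fnm",
    "exceedance_rate",
    "dummy_constant",
    "dummy_uniform",
    "as_null",
]

BiasMode = Literal["signed_est_minus_true", "signed_true_minus_est", "absolute"]


class AggregationError(ValueError):
    """Raised when a criterion is aggregated over no successful replications."""


@dataclass(frozen=True)
class ReplicationSet:
    """Estimates of one statistic across replications of one condition."""

    estimator: str
    estimates: np.ndarray
    true_p: float
    n_failed: int = 0

    def __post_init__(self) -> None:
        est = np.atleast_1d(np.asarray(self.estimates, dtype=float))
        object.__setattr__(self, "estimates", est)
        if self.n_failed < 0:
            raise ValueError("n_failed must be non-negative")

    @property
    def n_used(self) -> int:
        return self.estimates.size

    def _require_nonempty(self) -> None:
        if self.estimates.size == 0:
            raise AggregationError(
                f"no successful replications for {self.estimator!r}"
            )


@dataclass(frozen=True)
class CriterionValue:
    criterion: str
    value: float
    n_used: int


def rmse(reps: ReplicationSet) -> CriterionValue:
    """Root mean squared deviation of the estimates from the true value."""
    reps._require_nonempty()
    dev = reps.estimates - reps.true_p
    return CriterionValue("rmse", float(np.sqrt(np.mean(dev**2))), reps.n_used)


def pct_bias(
    reps: ReplicationSet, mode: BiasMode = "signed_est_minus_true"
) -> CriterionValue:
    """Mean deviation x 100 under the chosen sign convention."""
    reps._require_nonempty()
    dev = reps.estimates - reps.true_p
    if mode == "signed_est_minus_true":
        value = float(np.mean(dev))
    elif mode == "signed_true_minus_est":
        value = float(np.mean(-dev))
    elif mode == "absolute":
        value = float(np.mean(np.abs(dev)))
    else:
        raise ValueError(f"unknown %bias mode {mode!r}")
    return CriterionValue(f"pct_bias_{mode}", value * 100.0, reps.n_used)


def exceedance_rate(estimates: np.ndarray, cutoff: float) -> float:
    """Fraction of estimates at or above the cut-off (inclusive)."""
    est = np.asarray(estimates, dtype=float)
    if est.size == 0:
        raise AggregationError("no estimates to threshold")
    return float(np.mean(est >= cutoff))


def fpm(reps: ReplicationSet, cutoff: float = 0.7) -> CriterionValue:
    """Modified false-positive rate: P(estimate >= cutoff | null population).

    Only meaningful when the replications were generated under a null
    population; a non-zero ``true_p`` is a misuse error (relabel with
    :func:`as_null` to apply the threshold to other sets deliberately).
    """
    if reps.true_p != 0.0:
        raise ValueError(
            "FPm is defined conditional on a null population (true_p = 0); "
            f"got true_p={reps.true_p}"
        )
    return CriterionValue("fpm", exceedance_rate(reps.estimates, cutoff), reps.n_used)


def fnm(reps: ReplicationSet, floor: float = 0.0) -> CriterionValue:
    """Modified false-negative rate: P(estimate <= floor | acceptable parameter)."""
    if reps.true_p == 0.0:
        raise ValueError(
            "FNm is defined conditional on a non-null population; got true_p=0"
        )
    reps._require_nonempty()
    value = float(np.mean(reps.estimates <= floor))
    return CriterionValue("fnm", value, reps.n_used)


def as_null(reps: ReplicationSet) -> ReplicationSet:
    """Relabel a replication set as if drawn under a null population.

    Used to ask the counterfactual question behind the dummy-index
    demonstration: what FPm would these estimates produce had the
    population carried no effect?
    """
    return replace(reps, true_p=0.0)


def dummy_constant(Nr: int, true_p: float = 0.731, value: float = 0.78) -> ReplicationSet:
    """The constant dummy index C: the same number in every replication."""
    if Nr < 1:
        raise ValueError("need at least one replication")
    return ReplicationSet("dummy_c", np.full(Nr, value), true_p)


def dummy_uniform(
    Nr: int,
    rng: np.random.Generator,
    true_p: float = 0.731,
    bounds: Sequence[float] = (0.711, 0.751),
) -> ReplicationSet:
    """The varying dummy index C-dot: uniform draws on [0.711, 0.751]."""
    if Nr < 1:
        raise ValueError("need at least one replication")
    lo, hi = bounds
    return ReplicationSet("dummy_c_uniform", rng.uniform(lo, hi, Nr), true_p)
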