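"""Population covariance structures with known true reliability.

Three population models are supported, all with unit item variances so
that population covariance and correlation matrices coincide:

* ``null`` — k mutually independent standard-normal items.  The true
  internal consistency is exactly zero; this is the null distribution
  against which false-positive behaviour of an index is judged.
* ``tau_equivalent`` — a single common factor with equal loadings, which
  for unit variances is an equicorrelated matrix.  Cronbach's alpha on
  the population matrix equals the true reliability.
* ``congeneric`` — a single common factor with unequal loadings; the
  one-factor composite reliability (omega) equals the true reliability
  while alpha underestimates it.

Samples are multivariate normal, drawn through a Cholesky factor of the
population matrix (eigen factor as fallback for semidefinite corner
cases).
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from typing import Mapping

import numpy as np
from scipy.optimize import brentq

__all__ = [
    "PopulationSpec",
    "SampleMatrix",
    "InvalidDimensionError",
    "InfeasibleTargetError",
    "build_null",
    "build_tau_equivalent",
    "build_congeneric",
    "equicorrelation_for_alpha",
    "composite_omega",
    "draw_sample",
    "verify_null_large_sample",
]

#: smallest eigenvalue tolerated before a constructed matrix is rejected
_PSD_TOL = 1e-10


class InvalidDimensionError(ValueError):
    """Raised when an item count or sample size is too small."""


class InfeasibleTargetError(ValueError):
    """Raised when no admissible parameterization reaches the target reliability."""


@dataclass(frozen=True)
class PopulationSpec:
    """A population correlation structure with known true reliability.

    Attributes
    ----------
    kind : str
        One of ``"null"``, ``"tau_equivalent"``, ``"congeneric"``.
    k : int
        Number of items.
    sigma : numpy.ndarray
        k x k unit-diagonal covariance (= correlation) matrix.
    true_reliability : float
        The population value of the internal-consistency parameter:
        0 for the null model, alpha for tau-equivalence, one-factor
        omega for the congeneric model.
    loadings : numpy.ndarray or None
        Factor loadings (congeneric model only).
    """

    kind: str
    k: int
    sigma: np.ndarray
    true_reliability: float
    loadings: np.ndarray | None = None

    def __post_init__(self) -> None:
        sigma = np.asarray(self.sigma, dtype=float)
        object.__setattr__(self, "sigma", sigma)
        if self.kind not in ("null", "tau_equivalent", "congeneric"):
            raise ValueError(f"unknown population kind {self.kind!r}")
        if sigma.shape != (self.k, self.k):
            raise InvalidDimensionError(
                f"sigma has shape {sigma.shape}, expected ({self.k}, {self.k})"
            )
        if not np.allclose(sigma, sigma.T, atol=1e-12):
            raise ValueError("sigma must be symmetric")
        if not np.allclose(np.diag(sigma), 1.0, atol=1e-12):
            raise ValueError("sigma must have a unit diagonal")
        if np.linalg.eigvalsh(sigma)[0] < -_PSD_TOL:
            raise ValueError("sigma is not positive semidefinite")
        if not (0.0 <= self.true_reliability < 1.0):
            raise ValueError("true_reliability must lie in [0, 1)")
        if self.loadings is not None:
            object.__setattr__(
                self, "loadings", np.asarray(self.loadings, dtype=float)
            )

    # -- serialization -------------------------------------------------
    def to_json(self) -> str:
        """Serialize to a plain JSON document (archivable alongside results)."""
        doc: dict = {
            "kind": self.kind,
            "k": self.k,
            "true_reliability": self.true_reliability,
            "sigma": self.sigma.tolist(),
        }
        if self.loadings is not None:
            doc["loadings"] = self.loadings.tolist()
        return json.dumps(doc)

    @classmethod
    def from_json(cls, doc: str) -> "PopulationSpec":
        d = json.loads(doc)
        loadings = d.get("loadings")
        return cls(
            kind=d["kind"],
            k=int(d["k"]),
            sigma=np.asarray(d["sigma"], dtype=float),
            true_reliability=float(d["true_reliability"]),
            loadings=None if loadings is None else np.asarray(loadings, dtype=float),
        )


@dataclass(frozen=True)
class SampleMatrix:
    """An n x k draw from a population (rows = simulated respondents)."""

    values: np.ndarray
    population: PopulationSpec | None = None

    def __post_init__(self) -> None:
        values = np.asarray(self.values, dtype=float)
        object.__setattr__(self, "values", values)
        if values.ndim != 2:
            raise InvalidDimensionError("sample must be a 2-d matrix")
        n, k = values.shape
        if n < 3 or k < 2:
            raise InvalidDimensionError(f"need n >= 3 and k >= 2, got n={n}, k={k}")
        if not np.all(np.isfinite(values)):
            raise ValueError("sample contains non-finite values")

    @property
    def n(self) -> int:
        return self.values.shape[0]

    @property
    def k(self) -> int:
        return self.values.shape[1]


def _check_k(k: int) -> None:
    if k < 2:
        raise InvalidDimensionError(
            f"internal consistency is undefined for k={k}; need at least 2 items"
        )


def build_null(k: int) -> PopulationSpec:
    """Population of k mutually independent N(0, 1) items (true reliability 0)."""
    _check_k(k)
    return PopulationSpec(kind="null", k=k, sigma=np.eye(k), true_reliability=0.0)


def equicorrelation_for_alpha(k: int, alpha: float) -> float:
    """Off-diagonal correlation r for which a k-item equicorrelated matrix has
    Cronbach alpha equal to ``alpha``.

    Inverts alpha = k*r / (1 + (k-1)*r), giving r = alpha / (k - (k-1)*alpha).
    """
    return alpha / (k - (k - 1) * alpha)


def build_tau_equivalent(k: int, target_alpha: float) -> PopulationSpec:
    """Equicorrelated (tau-equivalent, unit-variance) population with
    population Cronbach alpha exactly ``target_alpha``."""
    _check_k(k)
    if not (0.0 <= target_alpha < 1.0):
        raise InfeasibleTargetError(
            f"target alpha must lie in [0, 1), got {target_alpha}"
        )
    r = equicorrelation_for_alpha(k, target_alpha)
    if r <= -1.0 / (k - 1):
        raise InfeasibleTargetError(
            f"equicorrelation r={r:.4f} is not positive semidefinite for k={k}"
        )
    sigma = np.full((k, k), r)
    np.fill_diagonal(sigma, 1.0)
    return PopulationSpec(
        kind="tau_equivalent", k=k, sigma=sigma, true_reliability=target_alpha
    )


def composite_omega(loadings: np.ndarray) -> float:
    """One-factor composite reliability (sum lam)^2 / ((sum lam)^2 + sum(1 - lam^2))."""
    lam = np.asarray(loadings, dtype=float)
    s = lam.sum() ** 2
    return s / (s + np.sum(1.0 - lam**2))


def build_congeneric(
    k: int,
    target_reliability: float,
    loading_pattern: np.ndarray | None = None,
) -> PopulationSpec:
    """One-factor population with unequal loadings scaled to a target
    composite reliability.

    The loading pattern fixes the *shape* of the loadings; a scalar
    multiplier is solved numerically so that the one-factor omega of the
    resulting matrix equals ``target_reliability`` (to ~1e-12).  The
    default pattern is an arithmetic sequence from 0.3 to 0.8 across the
    k items.
    """
    _check_k(k)
    if not (0.0 < target_reliability < 1.0):
        raise InfeasibleTargetError(
            f"target reliability must lie in (0, 1), got {target_reliability}"
        )
    if loading_pattern is None:
        pattern = np.linspace(0.3, 0.8, k)
    else:
        pattern = np.asarray(loading_pattern, dtype=float)
    if pattern.shape != (k,):
        raise InvalidDimensionError(
            f"loading pattern has length {pattern.size}, expected {k}"
        )
    if np.any(pattern <= 0.0) or np.any(pattern >= 1.0):
        raise ValueError("loading pattern entries must lie in (0, 1)")
    if np.ptp(pattern) < 1e-12:
        raise ValueError(
            "all loadings equal is the tau-equivalent model; "
            "use build_tau_equivalent instead"
        )

    c_max = 1.0 / pattern.max()

    def gap(c: float) -> float:
        return composite_omega(c * pattern) - target_reliability

    hi = c_max * (1.0 - 1e-9)
    if gap(hi) < 0.0:
        raise InfeasibleTargetError(
            f"no loading scale in (0, {c_max:.3f}) reaches reliability "
            f"{target_reliability} with the given pattern"
        )
    c = brentq(gap, 1e-12, hi, xtol=1e-14, rtol=8.9e-16)
    loadings = c * pattern
    sigma = np.outer(loadings, loadings)
    np.fill_diagonal(sigma, 1.0)
    return PopulationSpec(
        kind="congeneric",
        k=k,
        sigma=sigma,
        true_reliability=target_reliability,
        loadings=loadings,
    )


def _factor(sigma: np.ndarray) -> np.ndarray:
    """Lower-triangular-ish factor L with L @ L.T = sigma."""
    try:
        return np.linalg.cholesky(sigma)
    except np.linalg.LinAlgError:
        w, v = np.linalg.eigh(sigma)
        w = np.clip(w, 0.0, None)
        return v * np.sqrt(w)


def draw_sample(
    spec: PopulationSpec, n: int, rng: np.random.Generator
) -> SampleMatrix:
    """Draw n independent multivariate-normal respondents from ``spec``."""
    if n < 3:
        raise InvalidDimensionError(f"need n >= 3, got n={n}")
    L = _factor(spec.sigma)
    values = rng.standard_normal((n, spec.k)) @ L.T
    return SampleMatrix(values=values, population=spec)


def verify_null_large_sample(
    k: int, n: int, rng: np.random.Generator
) -> Mapping[str, float]:
    """Large-sample check that the null design carries no internal consistency.

    Draws one big sample from the null population and computes all four
    indices on it; by consistency every index should be near zero.
    Returns a mapping from estimator name to value.
    """
    if n < 10000:
        raise InvalidDimensionError(
            f"large-sample verification needs n >= 10000, got n={n}"
        )
    from . import indices  # deferred: indices does not import populations

    sample = draw_sample(build_null(k), n, rng)
    R = indices.sample_correlation(sample)
    out: dict[str, float] = {}
    for name in ("alpha", "omega", "glb", "glba"):
        try:
            out[name] = indices.compute_index(name, R).value
        except Exception as exc:  # estimator failure propagates with its name
            raise RuntimeError(f"estimator {name!r} failed: {exc}") from exc
    return out
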