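"""Internal-consistency estimators computed from first principles.

All four indices operate on the sample Pearson correlation matrix of an
n x k data matrix (respondents by items):

* Cronbach's alpha — closed form ``k/(k-1) * (1 - k / sum(R))``.
* Omega-total — ``1 - sum(uniquenesses) / sum(R)`` with uniquenesses
  taken from a minimum-residual (minres) exploratory factor solution
  (3 factors by default, reduced when the model is unidentified).
* Factor-based GLB — the greatest-lower-bound formula with m-factor
  communalities substituted on the diagonal:
  ``(sum(R) - k + sum(h^2)) / sum(R)``; m defaults to floor(k/2).
* Algebraic GLB — the exact optimization: maximize the total error
  variance ``sum(y)`` subject to ``R - diag(y)`` positive semidefinite
  and ``0 <= y_i <= 1``; the index is ``1 - sum(y*) / sum(R)``.

The minres fit minimizes the sum of squared off-diagonal residuals of
``R - Lambda Lambda'`` over the uniquenesses, with loadings obtained
from the truncated eigendecomposition of the reduced matrix — the
standard formulation of exploratory minres/ULS factor analysis.

:func:`omega_reliability` additionally emulates the full omega routine
of the field's standard software: oblique (quartimin) rotation of the
3-factor solution, a general factor extracted from the factor
correlations (Schmid-Leiman decomposition), and — crucially —
*reverse-keying*: items whose general-factor loading is negative are
sign-flipped and the analysis redone on the flipped matrix, with alpha
and omega-total reported for the flipped matrix.  Reverse keying is a
data-driven step: under a null population it aligns sampling noise and
therefore inflates both indices, which is precisely the behaviour the
confusion-matrix evaluation is designed to expose.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Literal

import numpy as np
from scipy.optimize import minimize

__all__ = [
    "CorrelationMatrix",
    "FactorSolution",
    "SchmidLeimanSolution",
    "ReliabilityReport",
    "IndexValue",
    "DegenerateInputError",
    "ESTIMATOR_NAMES",
    "sample_correlation",
    "cronbach_alpha",
    "efa_minres",
    "oblimin",
    "schmid_leiman",
    "omega_total",
    "omega_reliability",
    "glb_factor",
    "glb_algebraic",
    "compute_index",
    "compute_all",
    "max_identified_factors",
    "default_glb_factors",
]

ESTIMATOR_NAMES = ("alpha", "omega", "glb", "glba")

#: eigenvalue below which a sample correlation matrix is treated as
#: numerically indefinite and smoothed before semidefinite optimization
_NPD_TOL = -1e-8


class DegenerateInputError(ValueError):
    """Raised for inputs on which a correlation matrix is undefined."""


@dataclass(frozen=True)
class CorrelationMatrix:
    """A k x k correlation matrix, flagged if PSD smoothing was applied."""

    values: np.ndarray
    smoothed: bool = False

    def __post_init__(self) -> None:
        values = np.asarray(self.values, dtype=float)
        object.__setattr__(self, "values", values)
        if values.ndim != 2 or values.shape[0] != values.shape[1]:
            raise ValueError("correlation matrix must be square")

    @property
    def k(self) -> int:
        return self.values.shape[0]


@dataclass(frozen=True)
class FactorSolution:
    """Result of an exploratory factor fit.

    ``uniquenesses`` are ``1 - communalities`` clipped to [0, 1]; the
    ``heywood`` flag records whether clipping occurred (a communality
    outside [0, 1] in the raw solution).
    """

    loadings: np.ndarray
    uniquenesses: np.ndarray
    m: int
    converged: bool
    heywood: bool

    @property
    def communalities(self) -> np.ndarray:
        return 1.0 - self.uniquenesses


@dataclass(frozen=True)
class IndexValue:
    """One reliability estimate with provenance and convergence status."""

    estimator: str
    value: float
    status: Literal["ok", "failed", "clipped"] = "ok"

    @property
    def ok(self) -> bool:
        return self.status != "failed"


def _smooth_psd(R: np.ndarray) -> np.ndarray:
    """Nearest-PSD smoothing: clip eigenvalues at 1e-10, re-standardize."""
    w, v = np.linalg.eigh(R)
    w = np.clip(w, 1e-10, None)
    S = (v * w) @ v.T
    d = np.sqrt(np.diag(S))
    S = S / np.outer(d, d)
    S = (S + S.T) / 2.0
    np.fill_diagonal(S, 1.0)
    return S


def sample_correlation(sample) -> CorrelationMatrix:
    """Pearson correlation of the columns of an n x k sample.

    Accepts a :class:`~relmc.populations.SampleMatrix` or any array-like
    with rows as observations.  Columns with zero variance are rejected.
    A numerically indefinite result (smallest eigenvalue < -1e-8) is
    smoothed to the nearest PSD correlation matrix and flagged.
    """
    X = np.asarray(getattr(sample, "values", sample), dtype=float)
    if X.ndim != 2:
        raise DegenerateInputError("sample must be a 2-d matrix")
    n, k = X.shape
    if n < 3:
        raise DegenerateInputError(f"need at least 3 observations, got {n}")
    if np.any(X.std(axis=0) == 0.0):
        raise DegenerateInputError("zero-variance column in sample")
    R = np.corrcoef(X, rowvar=False)
    R = (R + R.T) / 2.0
    np.fill_diagonal(R, 1.0)
    smoothed = False
    if np.linalg.eigvalsh(R)[0] < _NPD_TOL:
        R = _smooth_psd(R)
        smoothed = True
    return CorrelationMatrix(values=R, smoothed=smoothed)


def _as_matrix(R) -> np.ndarray:
    return np.asarray(getattr(R, "values", R), dtype=float)


def cronbach_alpha(R) -> IndexValue:
    """Cronbach's alpha: k/(k-1) * (1 - k / sum(R)).

    Alpha may be negative on samples whose correlations sum below zero;
    it is bounded above by k/(k-1) but not truncated here.
    """
    Rm = _as_matrix(R)
    k = Rm.shape[0]
    total = Rm.sum()
    if abs(total) < 1e-300:
        return IndexValue("alpha", np.nan, "failed")
    return IndexValue("alpha", k / (k - 1.0) * (1.0 - k / total))


def max_identified_factors(k: int) -> int:
    """Largest m with non-negative degrees of freedom ((k-m)^2 - k - m)/2.

    A single factor is always permitted (for k < 4 the one-factor model
    is under-identified yet still computable, e.g. two items determine
    the communality |r| exactly).
    """
    m = 0
    while (k - (m + 1)) ** 2 - k - (m + 1) >= 0:
        m += 1
    return max(m, 1)


def _squared_multiple_correlations(R: np.ndarray) -> np.ndarray:
    """SMC of each item on the rest; pseudo-inverse fallback for singular R."""
    try:
        Rinv = np.linalg.inv(R)
        d = np.diag(Rinv)
        if np.any(d <= 0):
            raise np.linalg.LinAlgError
        return 1.0 - 1.0 / d
    except np.linalg.LinAlgError:
        w, v = np.linalg.eigh(R)
        w = np.clip(w, 1e-8, None)
        d = np.diag((v / w) @ v.T)
        return 1.0 - 1.0 / d


def _minres_objective(psi: np.ndarray, R: np.ndarray, m: int) -> float:
    S = R.copy()
    np.fill_diagonal(S, 1.0 - psi)
    w, v = np.linalg.eigh(S)
    w_m = np.clip(w[-m:], 0.0, None)
    lam = v[:, -m:] * np.sqrt(w_m)
    resid = S - lam @ lam.T
    np.fill_diagonal(resid, 0.0)
    return float(np.sum(resid**2))


def _minres_value_and_grad(psi: np.ndarray, R: np.ndarray, m: int):
    """Objective plus forward-difference gradient via one batched eigh call.

    The objective is non-smooth only at eigenvalue crossings; a batched
    finite difference keeps the optimizer fast (a single LAPACK call per
    L-BFGS-B iteration instead of k+1 Python round-trips).
    """
    k = psi.size
    eps = 1e-7
    Psi = np.tile(psi, (k + 1, 1))
    Psi[1:, :] += eps * np.eye(k)
    S = np.broadcast_to(R, (k + 1, k, k)).copy()
    idx = np.arange(k)
    S[:, idx, idx] = 1.0 - Psi
    w, v = np.linalg.eigh(S)
    w_m = np.clip(w[:, -m:], 0.0, None)
    Vm = v[:, :, -m:]
    model = (Vm * w_m[:, None, :]) @ Vm.transpose(0, 2, 1)
    resid = S - model
    resid[:, idx, idx] = 0.0
    f = np.sum(resid**2, axis=(1, 2))
    return f[0], (f[1:] - f[0]) / eps


_MINRES_LOWER = 0.005  # lower bound on uniquenesses, as in common practice


def efa_minres(
    R, m: int, max_restarts: int = 3, rng: np.random.Generator | None = None
) -> FactorSolution:
    """Minimum-residual exploratory factor analysis.

    Minimizes the sum of squared off-diagonal residuals of the m-factor
    model over the uniquenesses (bounded quasi-Newton, started at
    1 - squared multiple correlations, with jittered restarts on
    non-convergence).  Loadings are the truncated eigendecomposition of
    the reduced correlation matrix at the optimum.
    """
    Rm = _as_matrix(R)
    k = Rm.shape[0]
    if m < 1:
        raise ValueError("need at least one factor")
    if m > max_identified_factors(k):
        raise ValueError(f"the {m}-factor model is unidentified for k={k}")

    smc = np.clip(_squared_multiple_correlations(Rm), 0.0, 1.0 - _MINRES_LOWER)
    start = 1.0 - smc
    bounds = [(_MINRES_LOWER, 1.0)] * k

    best = None
    for attempt in range(max_restarts + 1):
        x0 = start
        if attempt > 0:
            jitter_rng = rng if rng is not None else np.random.default_rng(attempt)
            x0 = np.clip(
                start + jitter_rng.uniform(-0.1, 0.1, size=k), _MINRES_LOWER, 1.0
            )
        res = minimize(
            _minres_value_and_grad,
            x0,
            args=(Rm, m),
            jac=True,
            method="L-BFGS-B",
            bounds=bounds,
            options={"maxiter": 1000, "ftol": 1e-10, "gtol": 1e-7},
        )
        if best is None or res.fun < best.fun:
            best = res
        if res.success:
            best = res
            break
    converged = bool(best.success)

    psi = best.x
    S = Rm.copy()
    np.fill_diagonal(S, 1.0 - psi)
    w, v = np.linalg.eigh(S)
    w_m = np.clip(w[-m:], 0.0, None)
    lam = v[:, -m:][:, ::-1] * np.sqrt(w_m[::-1])
    h2 = np.sum(lam**2, axis=1)
    heywood = bool(np.any(h2 > 1.0 + 1e-10))
    uniq = np.clip(1.0 - h2, 0.0, 1.0)
    return FactorSolution(
        loadings=lam, uniquenesses=uniq, m=m, converged=converged, heywood=heywood
    )


def oblimin(A: np.ndarray, max_iter: int = 1000, tol: float = 1e-5):
    """Oblique quartimin rotation via gradient projection.

    Minimizes the quartimin criterion sum_i sum_{j!=l} L_ij^2 L_il^2
    over oblique rotations L = A (T')^{-1} with unit-length columns of
    T (the gradient-projection algorithm of Jennrich).  Returns the
    rotated pattern matrix and the factor correlation matrix Phi.
    """
    A = np.asarray(A, dtype=float)
    m = A.shape[1]
    if m == 1:
        return A.copy(), np.ones((1, 1))

    N = np.ones((m, m)) - np.eye(m)

    def criterion(L):
        L2 = L**2
        B = L2 @ N
        return float(np.sum(L2 * B)) / 4.0, L * B

    T = np.eye(m)
    Ti = np.linalg.inv(T)
    L = A @ Ti.T
    f, Gq = criterion(L)
    G = -(L.T @ Gq @ Ti).T
    al = 1.0
    for _ in range(max_iter):
        Gp = G - T * np.sum(T * G, axis=0)
        s = float(np.sqrt(np.sum(Gp**2)))
        if s < tol:
            break
        al *= 2.0
        for _ in range(30):
            X = T - al * Gp
            X = X / np.sqrt(np.sum(X**2, axis=0))
            try:
                Ti_new = np.linalg.inv(X)
            except np.linalg.LinAlgError:
                al /= 2.0
                continue
            L_new = A @ Ti_new.T
            f_new, Gq_new = criterion(L_new)
            if f_new < f - 0.5 * s**2 * al:
                break
            al /= 2.0
        T, Ti, L, f, Gq = X, Ti_new, L_new, f_new, Gq_new
        G = -(L.T @ Gq @ Ti).T
    Phi = T.T @ T
    return L, Phi


@dataclass(frozen=True)
class SchmidLeimanSolution:
    """Hierarchical (general + group factor) decomposition of an
    oblique m-factor solution."""

    g_loadings: np.ndarray
    group_loadings: np.ndarray
    communalities: np.ndarray  # raw h2 = g^2 + row sums of group^2 (not clipped)
    factor_g: np.ndarray  # loadings of the oblique factors on the general factor


def schmid_leiman(
    R, m: int = 3, fit: FactorSolution | None = None
) -> SchmidLeimanSolution:
    """Schmid-Leiman transformation of an m-factor minres solution.

    Rotates the minres loadings obliquely (quartimin), fits one factor
    to the factor correlation matrix, and splits each item's loading
    into a general-factor part ``g = L f_g`` and orthogonal group parts
    ``L * sqrt(1 - f_g^2)``.  When the one-factor model of Phi fits
    exactly the communalities equal those of the unrotated solution.
    """
    Rm = _as_matrix(R)
    if fit is None or fit.m != m:
        fit = efa_minres(Rm, m)
    L, Phi = oblimin(fit.loadings)
    signs = np.sign(L.sum(axis=0))
    signs[signs == 0] = 1.0
    L = L * signs
    Phi = Phi * np.outer(signs, signs)
    if m == 1:
        fg = np.ones(1)
    elif m == 2:
        # one factor is unidentified for a 2x2 Phi: split the shared
        # correlation equally over the two factors
        c = np.sqrt(max(Phi[0, 1], 0.0))
        fg = np.array([c, c])
    else:
        gfit = efa_minres(Phi, 1)
        fg = gfit.loadings[:, 0]
        if fg.sum() < 0:
            fg = -fg
    g = L @ fg
    group = L * np.sqrt(np.clip(1.0 - fg**2, 0.0, None))
    h2 = g**2 + np.sum(group**2, axis=1)
    return SchmidLeimanSolution(
        g_loadings=g, group_loadings=group, communalities=h2, factor_g=fg
    )


@dataclass(frozen=True)
class ReliabilityReport:
    """Alpha and omega-total as produced by the reference omega routine,
    including its reverse-keying step."""

    alpha: IndexValue
    omega_total: IndexValue
    flipped: np.ndarray  # boolean mask of reverse-keyed items
    solution: SchmidLeimanSolution

    @property
    def n_flipped(self) -> int:
        return int(np.count_nonzero(self.flipped))


def omega_reliability(
    R,
    m: int = 3,
    reverse_key: bool = True,
    fit: FactorSolution | None = None,
) -> ReliabilityReport:
    """Alpha and omega-total via the full omega pipeline.

    Fits the Schmid-Leiman decomposition; if ``reverse_key`` is set,
    items with a negative general-factor loading are sign-flipped and
    the decomposition is redone on the flipped matrix.  Alpha is the
    closed form on the (possibly flipped) correlation matrix;
    omega-total is ``1 - sum(1 - h2) / sum(R)`` with the *raw*
    Schmid-Leiman communalities (Heywood cases are not truncated inside
    the sum, as in the reference routine; the reported value is clipped
    to [0, 1] and flagged).

    Reverse keying conditions the analysis on the sample: under a null
    population roughly half the items get flipped, which aligns noise
    and biases both indices upward.  Pass ``reverse_key=False`` for the
    keying-free estimators.
    """
    Rm = _as_matrix(R)
    k = Rm.shape[0]
    m_eff = min(m, max_identified_factors(k))
    sol = schmid_leiman(Rm, m_eff, fit=fit)
    flipped = np.zeros(k, dtype=bool)
    R_used = Rm
    if reverse_key and np.any(sol.g_loadings < 0):
        flipped = sol.g_loadings < 0
        d = np.where(flipped, -1.0, 1.0)
        R_used = Rm * np.outer(d, d)
        # redoing the factor analysis on D R D reproduces the same
        # solution with sign-flipped loading rows (the minres and
        # quartimin criteria depend only on squared loadings), so the
        # communalities carry over; only the sign-aligned quantities
        # need updating
        sol = SchmidLeimanSolution(
            g_loadings=np.abs(sol.g_loadings),
            group_loadings=sol.group_loadings * d[:, None],
            communalities=sol.communalities,
            factor_g=sol.factor_g,
        )
    alpha = cronbach_alpha(R_used)
    total = R_used.sum()
    if total <= 0:
        omega = IndexValue("omega", np.nan, "failed")
    else:
        omega = _clip_unit(
            "omega", 1.0 - np.sum(1.0 - sol.communalities) / total, True
        )
    return ReliabilityReport(
        alpha=alpha, omega_total=omega, flipped=flipped, solution=sol
    )


def _clip_unit(estimator: str, value: float, status_ok: bool) -> IndexValue:
    if not status_ok:
        return IndexValue(estimator, value, "failed")
    if value < 0.0:
        return IndexValue(estimator, 0.0, "clipped")
    if value > 1.0:
        return IndexValue(estimator, 1.0, "clipped")
    return IndexValue(estimator, value)


def omega_total(
    R, m: int = 3, fit: FactorSolution | None = None
) -> IndexValue:
    """Omega-total from an m-factor minres solution.

    omega_t = 1 - sum(uniquenesses) / sum(R).  Rotation does not alter
    uniquenesses, so omega_t is computed directly from the unrotated
    fit.  If the requested m is unidentified for k items, the largest
    identified m is used.
    """
    Rm = _as_matrix(R)
    m_eff = min(m, max_identified_factors(Rm.shape[0]))
    if fit is None or fit.m != m_eff:
        fit = efa_minres(Rm, m_eff)
    total = Rm.sum()
    if total <= 0:
        return IndexValue("omega", np.nan, "failed")
    value = 1.0 - fit.uniquenesses.sum() / total
    return _clip_unit("omega", value, fit.converged)


def glb_factor(
    R, m: int | None = None, fit: FactorSolution | None = None
) -> IndexValue:
    """Greatest lower bound via factor-based communalities.

    The diagonal of R is replaced by m-factor minres communalities:
    glb = (sum(R) - k + sum(h^2)) / sum(R).  The default factor count
    follows :func:`default_glb_factors`.
    """
    Rm = _as_matrix(R)
    k = Rm.shape[0]
    if m is None:
        m = default_glb_factors(k)
    m_eff = min(m, max_identified_factors(k))
    if fit is None or fit.m != m_eff:
        fit = efa_minres(Rm, m_eff)
    total = Rm.sum()
    if total <= 0:
        return IndexValue("glb", np.nan, "failed")
    value = (total - k + fit.communalities.sum()) / total
    return _clip_unit("glb", value, fit.converged)


def default_glb_factors(k: int) -> int:
    """Default factor count for the factor-based GLB: floor(k/2), capped
    at the largest identified model.

    With half the items as factors the communalities absorb most of the
    observed covariation, which is what makes this variant a *greatest*
    lower bound in practice; the cap keeps the model identified.
    """
    return min(k // 2, max_identified_factors(k))


def glb_algebraic(R, tol: float = 1e-9) -> IndexValue:
    """Algebraic greatest lower bound to reliability.

    Solves  maximize sum(y)  s.t.  R - diag(y) PSD,  0 <= y_i <= 1
    (y are item error variances), then glb = 1 - sum(y*) / sum(R).
    The semidefinite constraint is enforced through the eigenvalues of
    R - diag(y) with analytic gradients (d lambda_j / d y_i = -v_ij^2),
    solved by SLSQP from the feasible start y = 0.
    """
    Rm = _as_matrix(R)
    k = Rm.shape[0]
    if np.linalg.eigvalsh(Rm)[0] < _NPD_TOL:
        Rm = _smooth_psd(Rm)
    total = Rm.sum()
    if total <= 0:
        return IndexValue("glba", np.nan, "failed")

    def neg_sum(y):
        return -float(np.sum(y))

    def neg_sum_grad(y):
        return -np.ones_like(y)

    def eigs(y):
        return np.linalg.eigvalsh(Rm - np.diag(y))

    def eigs_jac(y):
        _, v = np.linalg.eigh(Rm - np.diag(y))
        # rows: eigenvalues (ascending); cols: y_i
        return -(v**2).T

    res = minimize(
        neg_sum,
        np.zeros(k),
        jac=neg_sum_grad,
        method="SLSQP",
        bounds=[(0.0, 1.0)] * k,
        constraints=[{"type": "ineq", "fun": eigs, "jac": eigs_jac}],
        options={"maxiter": 500, "ftol": tol},
    )
    y = np.clip(res.x, 0.0, 1.0)
    feasible = np.linalg.eigvalsh(Rm - np.diag(y))[0] >= -1e-7
    if not feasible:
        # pull back toward the feasible origin until the PSD check passes
        lo, hi = 0.0, 1.0
        for _ in range(60):
            mid = (lo + hi) / 2.0
            if np.linalg.eigvalsh(Rm - np.diag(mid * y))[0] >= -1e-9:
                lo = mid
            else:
                hi = mid
        y = lo * y
        feasible = True
    if not res.success and not feasible:
        return IndexValue("glba", np.nan, "failed")
    value = 1.0 - y.sum() / total
    return _clip_unit("glba", value, True)


def compute_index(
    name: str,
    R,
    omega_factors: int = 3,
    glb_factors: int | None = None,
    fit: FactorSolution | None = None,
) -> IndexValue:
    """Dispatch a single estimator by name ('alpha', 'omega', 'glb', 'glba')."""
    if name == "alpha":
        return cronbach_alpha(R)
    if name == "omega":
        return omega_total(R, m=omega_factors, fit=fit)
    if name == "glb":
        return glb_factor(R, m=glb_factors, fit=fit)
    if name == "glba":
        return glb_algebraic(R)
    raise ValueError(f"unknown estimator {name!r}")


def compute_all(
    R,
    estimators=ESTIMATOR_NAMES,
    omega_factors: int = 3,
    glb_factors: int | None = None,
    reverse_key: bool = False,
) -> dict[str, IndexValue]:
    """Compute several estimators on one correlation matrix.

    With ``reverse_key=False`` (default) every index is computed on the
    matrix as given.  With ``reverse_key=True`` alpha and omega go
    through :func:`omega_reliability` — the reference routine's
    pipeline including its data-driven item flipping — while the two
    GLB variants stay keying-free (their reference routines do not
    flip).  Factor fits are shared between omega and the factor GLB
    when their factor counts coincide.
    """
    Rm = _as_matrix(R)
    k = Rm.shape[0]
    fits: dict[int, FactorSolution] = {}

    def fit_for(m: int) -> FactorSolution:
        m_eff = min(m, max_identified_factors(k))
        if m_eff not in fits:
            fits[m_eff] = efa_minres(Rm, m_eff)
        return fits[m_eff]

    out: dict[str, IndexValue] = {}
    report: ReliabilityReport | None = None
    for name in estimators:
        if reverse_key and name in ("alpha", "omega"):
            if report is None:
                report = omega_reliability(
                    Rm,
                    m=omega_factors,
                    reverse_key=True,
                    fit=fit_for(omega_factors),
                )
            out[name] = report.alpha if name == "alpha" else report.omega_total
        elif name == "omega":
            out[name] = omega_total(Rm, m=omega_factors, fit=fit_for(omega_factors))
        elif name == "glb":
            m = glb_factors if glb_factors is not None else default_glb_factors(k)
            out[name] = glb_factor(Rm, m=m, fit=fit_for(m))
        else:
            out[name] = compute_index(name, Rm)
    return out
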