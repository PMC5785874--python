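"""Generic FOCE-I machinery for nonlinear mixed-effects models.

The marginal likelihood of each subject's data is approximated by the
first-order conditional method with interaction: the random-effect vector
``b`` is set to its conditional mode ``b_hat`` (the empirical Bayes
estimate), the structural model is linearised there, and the resulting
Gaussian marginal is evaluated exactly::

    f(b) ~= f(b_hat) + G (b - b_hat),        G = df/db at b_hat
    y ~ N(f(b_hat) - G b_hat + G b,  V),     b ~ N(0, S)
    =>  y ~ N(f(b_hat) - G b_hat + ... ,  C),  C = G S G' + V

    OFV_i = r' C^-1 r + log det C + n_i log 2pi,
    r = y - f(b_hat) + G b_hat

with the residual variance ``V`` evaluated at the conditional predictions
("interaction").  For a linear structural model with additive error this
is the exact marginal -2 log likelihood, which the tests exploit.

The engine is model-agnostic: a subject is a vector of observations plus a
callable mapping ``b`` to predictions (optionally with an analytic or
structured Jacobian).  Random effects are independent with per-component
prior SDs; components with SD 0 are treated as structurally absent.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Callable, Sequence

import numpy as np

__all__ = [
    "SubjectProblem",
    "InnerResult",
    "EstimationError",
    "conditional_mode",
    "subject_ofv",
    "total_ofv",
    "Transform",
    "LOG",
    "SHIFTED_LOG",
    "IDENTITY",
    "interval",
]

_LOG2PI = math.log(2.0 * math.pi)
_VAR_FLOOR = 1e-30


class EstimationError(RuntimeError):
    pass


@dataclass
class SubjectProblem:
    """One subject's data and structural model.

    ``predict(b)`` returns the prediction vector; ``predict_jac(b)``
    (optional) returns ``(f, G)`` with ``G[j, k] = df_j / db_k``; when
    absent a forward-difference Jacobian is used.  ``sd_b`` holds the
    prior SDs of the random-effect components; ``error`` is
    ``"proportional"`` (``var = sigma^2 f^2``) or ``"additive"``
    (``var = sigma^2``).
    """

    label: str | int
    y: np.ndarray
    predict: Callable[[np.ndarray], np.ndarray]
    sd_b: np.ndarray
    sigma: float
    error: str = "proportional"
    predict_jac: Callable[[np.ndarray], tuple[np.ndarray, np.ndarray]] | None = None

    def __post_init__(self) -> None:
        self.y = np.asarray(self.y, dtype=float)
        self.sd_b = np.asarray(self.sd_b, dtype=float)
        if self.error not in ("proportional", "additive"):
            raise ValueError(f"unknown error model {self.error!r}")
        if np.any(self.sd_b < 0):
            raise ValueError("random-effect SDs must be non-negative")
        if self.sigma <= 0:
            raise ValueError("sigma must be positive")

    # Jacobian fallback ------------------------------------------------
    def jac(self, b: np.ndarray, f0: np.ndarray | None = None,
            step: float = 1e-5) -> tuple[np.ndarray, np.ndarray]:
        if self.predict_jac is not None:
            return self.predict_jac(b)
        if f0 is None:
            f0 = self.predict(b)
        G = np.empty((len(f0), len(b)))
        for k in range(len(b)):
            bp = b.copy()
            bp[k] += step
            G[:, k] = (self.predict(bp) - f0) / step
        return f0, G


def _variance(f: np.ndarray, sigma: float, error: str) -> np.ndarray:
    if error == "proportional":
        return np.maximum(sigma * sigma * f * f, _VAR_FLOOR)
    return np.full_like(f, sigma * sigma)


def _dvar_df(f: np.ndarray, sigma: float, error: str) -> np.ndarray:
    if error == "proportional":
        return 2.0 * sigma * sigma * f
    return np.zeros_like(f)


def _penalized_objective(prob: SubjectProblem, b: np.ndarray,
                         f: np.ndarray, inv_s2: np.ndarray) -> float:
    """-2 log of the joint density p(y | b) p(b), up to the prior constant."""
    with np.errstate(over="ignore", invalid="ignore", divide="ignore"):
        v = _variance(f, prob.sigma, prob.error)
        r = prob.y - f
        return float(np.sum(r * r / v + np.log(v) + _LOG2PI)
                     + np.sum(b * b * inv_s2))


@dataclass
class InnerResult:
    b: np.ndarray            # conditional mode over active components
    f: np.ndarray            # predictions at the mode
    G: np.ndarray            # Jacobian at the mode (active columns)
    hessian: np.ndarray      # Fisher-type curvature of the penalized -2 log
    active: np.ndarray       # boolean mask of components with sd > 0
    objective: float
    converged: bool
    n_iter: int

    def full_b(self) -> np.ndarray:
        out = np.zeros(len(self.active))
        out[self.active] = self.b
        return out


def conditional_mode(
    prob: SubjectProblem,
    b0: np.ndarray | None = None,
    gtol: float = 1e-6,
    max_iter: int = 100,
    rescue: bool = True,
) -> InnerResult:
    """Penalized-likelihood mode of the random effects (EBE) with curvature.

    Newton iterations from ``b0`` (zero by default).  The subject-level
    surface can have spurious modes with absurd deviates (flip-flop-type
    compensations); when the converged mode has any deviate beyond 5
    prior SDs, or the iteration stalled, a deterministic battery of
    restarts (+/-1 on each of the leading components) is tried and the
    lowest penalized objective kept (``rescue=False`` disables this).
    """
    res = _newton_mode(prob, b0, gtol, max_iter)
    d = len(res.b)
    if rescue and d:
        s = np.maximum(prob.sd_b[res.active], 1e-12)
        if ((not res.converged and res.n_iter >= max_iter)
                or np.max(np.abs(res.b) / s) > 5.0):
            d_full = len(prob.sd_b)
            axes = np.flatnonzero(res.active)[:3]
            best = res
            for ax in axes:
                for v in (1.0, -1.0):
                    b_try = np.zeros(d_full)
                    b_try[ax] = v
                    try:
                        cand = _newton_mode(prob, b_try, gtol,
                                            min(max_iter, 40))
                    except EstimationError:
                        continue
                    if cand.objective < best.objective - 1e-9:
                        best = cand
            res = best
    return res


def _newton_mode(
    prob: SubjectProblem,
    b0: np.ndarray | None,
    gtol: float,
    max_iter: int,
) -> InnerResult:
    """Single Newton run with Fisher curvature and backtracking.

    Restarts from zero if the objective is non-finite at the warm start;
    components with prior SD zero are fixed at zero and excluded.
    """
    if len(prob.y) == 0:
        act = prob.sd_b > 0
        z = np.zeros(int(act.sum()))
        return InnerResult(z, np.empty(0), np.empty((0, len(z))),
                           np.diag(1.0 / np.maximum(prob.sd_b[act], 1e-12) ** 2),
                           act, 0.0, True, 0)
    active = prob.sd_b > 0
    d_full = len(prob.sd_b)
    d = int(active.sum())
    inv_s2 = 1.0 / prob.sd_b[active] ** 2 if d else np.empty(0)

    def expand(ba: np.ndarray) -> np.ndarray:
        out = np.zeros(d_full)
        out[active] = ba
        return out

    b = np.zeros(d) if b0 is None else np.asarray(b0, dtype=float)[active]
    f = prob.predict(expand(b))
    if prob.error == "proportional" and np.max(np.abs(f)) < 1e-300 \
            and np.max(np.abs(prob.y)) > 0:
        raise EstimationError(
            f"subject {prob.label}: all predictions are zero with "
            f"non-zero observations")
    obj = _penalized_objective(prob, b, f, inv_s2)
    if not np.isfinite(obj) and b0 is not None:
        b = np.zeros(d)
        f = prob.predict(expand(b))
        obj = _penalized_objective(prob, b, f, inv_s2)
    if not np.isfinite(obj):
        raise EstimationError(
            f"subject {prob.label}: non-finite objective at zero")

    if d == 0:
        _, G = prob.jac(expand(b), f)
        return InnerResult(b, f, G[:, active], np.empty((0, 0)), active,
                           obj, True, 0)

    converged = False
    it = 0
    G_act = None
    for it in range(1, max_iter + 1):
        f, G = prob.jac(expand(b), f)
        G_act = G[:, active] if G.shape[1] == d_full else G
        with np.errstate(over="ignore", invalid="ignore", divide="ignore"):
            v = _variance(f, prob.sigma, prob.error)
            dv = _dvar_df(f, prob.sigma, prob.error)
            r = prob.y - f
            dobj_df = -2.0 * r / v + dv * (1.0 / v - r * r / (v * v))
            grad = G_act.T @ dobj_df + 2.0 * b * inv_s2
            fisher_w = 1.0 / v + dv * dv / (2.0 * v * v)
            H = 2.0 * (G_act.T * fisher_w) @ G_act + 2.0 * np.diag(inv_s2)
        if not np.all(np.isfinite(grad)):
            raise EstimationError(
                f"subject {prob.label}: non-finite gradient")
        if np.max(np.abs(grad)) < gtol:
            converged = True
            break
        try:
            step = np.linalg.solve(H, -grad)
        except np.linalg.LinAlgError:
            step = -grad / np.max(np.abs(np.diag(H)))
        big = np.max(np.abs(step))
        if big > 5.0:   # trust region: deviates live on the log scale
            step *= 5.0 / big
        # backtracking line search
        alpha = 1.0
        improved = False
        for _ in range(30):
            b_new = b + alpha * step
            f_new = prob.predict(expand(b_new))
            obj_new = _penalized_objective(prob, b_new, f_new, inv_s2)
            if np.isfinite(obj_new) and obj_new < obj:
                decrease = obj - obj_new
                b, f, obj = b_new, f_new, obj_new
                improved = True
                break
            alpha *= 0.5
        if not improved or decrease < 1e-10 * (1.0 + abs(obj)):
            # stalled at the resolution of the finite-difference Jacobian:
            # treat as converged when the gradient is already small
            converged = np.max(np.abs(grad)) < 1e-3
            break
    if G_act is None:  # max_iter == 0 defensive path
        f, G = prob.jac(expand(b), f)
        G_act = G[:, active] if G.shape[1] == d_full else G
    with np.errstate(over="ignore", invalid="ignore", divide="ignore"):
        v = _variance(f, prob.sigma, prob.error)
        dv = _dvar_df(f, prob.sigma, prob.error)
        fisher_w = 1.0 / v + dv * dv / (2.0 * v * v)
        H = 2.0 * (G_act.T * fisher_w) @ G_act + 2.0 * np.diag(inv_s2)
    return InnerResult(b, f, G_act, H, active, obj, converged, it)


def subject_ofv(prob: SubjectProblem, inner: InnerResult) -> float:
    """-2 log marginal likelihood contribution via the FOCE-I linearisation."""
    n = len(prob.y)
    if n == 0:
        return 0.0
    f, G, b = inner.f, inner.G, inner.b
    v = _variance(f, prob.sigma, prob.error)
    s2 = prob.sd_b[inner.active] ** 2
    C = np.diag(v)
    if len(b):
        C = C + (G * s2) @ G.T
    r = prob.y - f + (G @ b if len(b) else 0.0)
    try:
        L = np.linalg.cholesky(C)
    except np.linalg.LinAlgError as exc:
        raise EstimationError(
            f"subject {prob.label}: singular marginal covariance") from exc
    z = np.linalg.solve(L, r)
    logdet = 2.0 * float(np.sum(np.log(np.diag(L))))
    return float(z @ z) + logdet + n * _LOG2PI


def linearized_residuals(prob: SubjectProblem, inner: InnerResult
                         ) -> np.ndarray:
    """Conditional weighted residuals under the FOCE linearisation.

    The marginal residual ``y - (f(b_hat) - G b_hat)`` decorrelated by the
    inverse Cholesky factor of ``C = G S G' + V``; approximately standard
    normal when the model is correct.
    """
    f, G, b = inner.f, inner.G, inner.b
    v = _variance(f, prob.sigma, prob.error)
    s2 = prob.sd_b[inner.active] ** 2
    C = np.diag(v)
    if len(b):
        C = C + (G * s2) @ G.T
    r = prob.y - f + (G @ b if len(b) else 0.0)
    try:
        L = np.linalg.cholesky(C)
    except np.linalg.LinAlgError as exc:
        raise EstimationError(
            f"subject {prob.label}: singular marginal covariance") from exc
    return np.linalg.solve(L, r)


def total_ofv(problems: Sequence[SubjectProblem],
              warm: dict | None = None) -> float:
    """Sum of subject OFVs; inner modes cold-started unless ``warm`` given."""
    out = 0.0
    for i, prob in enumerate(problems):
        b0 = warm.get(i) if warm is not None else None
        inner = conditional_mode(prob, b0=b0)
        if warm is not None:
            warm[i] = inner.full_b()
        out += subject_ofv(prob, inner)
    return out


# ---------------------------------------------------------------------------
# parameter transforms for the outer problem
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class Transform:
    """Bijection between a constrained natural scale and the real line."""

    name: str
    to_unconstrained: Callable[[float], float]
    to_natural: Callable[[float], float]

    def dnat(self, t: float, eps: float = 1e-6) -> float:
        """Derivative of the natural value w.r.t. the unconstrained one."""
        return (self.to_natural(t + eps) - self.to_natural(t - eps)) / (2 * eps)


LOG = Transform("log", math.log, math.exp)
SHIFTED_LOG = Transform("shifted_log",
                        lambda x: math.log1p(x), lambda t: math.expm1(t))
IDENTITY = Transform("identity", lambda x: x, lambda t: t)


def interval(lo: float, hi: float) -> Transform:
    """Generalised-logit transform onto the open interval (lo, hi)."""
    width = hi - lo

    def fwd(x: float) -> float:
        if not lo < x < hi:
            raise ValueError(f"value {x} outside ({lo}, {hi})")
        return math.log((x - lo) / (hi - x))

    def inv(t: float) -> float:
        pad = 1e-12 * width   # keep the image strictly inside (lo, hi)
        return min(max(lo + width / (1.0 + math.exp(-t)), lo + pad),
                   hi - pad)

    return Transform(f"interval({lo},{hi})", fwd, inv)
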