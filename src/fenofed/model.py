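"""Model / Results objects for fitting the food-effect PK model.

:class:`MBPKModel` binds a :class:`~fenofed.io.PKDataset` to the structural
model and exposes ``fit()`` (FOCE-I estimation), ``ofv()`` (the objective
at given parameters) and ``conditional_estimates()`` (per-subject
empirical Bayes modes).  ``fit()`` returns an :class:`MBPKResults` with
estimates, OFV, EBEs, optional standard errors, and diagnostics
(``residual_table``, ``vpc``, ``bootstrap``) hanging off the results
object, in the spirit of statsmodels.

Random-effect layout per subject (P = number of occasions)::

    b = [eta_kg, eta_kel, eta_vc, kappa_kel_1..P, kappa_vc_1..P]

``eta_kg`` is shared between the drug and calorie gastric-emptying rates.
The Jacobian of the predictions w.r.t. ``b`` is assembled from one finite
difference per ODE-coupled component (``eta_kg``, ``eta_kel``) plus exact
columns: occasion-`p` kappa columns equal the corresponding eta column
restricted to that occasion's rows, and volume columns are ``-f``.
"""

from __future__ import annotations

import time
from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd
from scipy.optimize import minimize

from .core import RandomEffects
from .fastsolve import CompiledSchedule
from .foce import (LOG, SHIFTED_LOG, EstimationError, InnerResult,
                   SubjectProblem, Transform, conditional_mode, interval,
                   subject_ofv)
from .io import OccasionData, PKDataset
from .params import ModelParameters

__all__ = ["MBPKModel", "MBPKResults", "DEFAULT_FREE", "TRANSFORMS"]

#: default free-parameter set; gastric emptying of calories (kg', k_out),
#: the food-window times, and the physiological volumes stay fixed.
DEFAULT_FREE: tuple[str, ...] = (
    "tv_kg", "k_ma", "k_el", "vc_over_f",
    "e_bile", "e_food", "e_vc1", "e_vc2",
    "omega_kg", "omega_kel", "omega_vc", "pi_kel", "pi_vc",
    "sigma_prop",
)

TRANSFORMS: dict[str, Transform] = {
    "tv_kg": LOG, "k_ma": LOG, "k_el": LOG, "vc_over_f": LOG,
    "kg_prime": LOG, "k_out": LOG, "mtime2": LOG, "sigma_prop": LOG,
    "omega_kg": LOG, "omega_kel": LOG, "omega_vc": LOG,
    "pi_kel": LOG, "pi_vc": LOG,
    "e_food": SHIFTED_LOG, "e_bile": SHIFTED_LOG,
    "e_vc1": interval(-1.0, 10.0), "e_vc2": interval(-1.0, 10.0),
}

_FD_STEP = 1e-4   # finite-difference step on eta for the Jacobian


class _SubjectContext:
    """Precompiled schedules and observation bookkeeping for one subject."""

    def __init__(self, sid: int, occasions: list[OccasionData],
                 params: ModelParameters):
        self.sid = sid
        self.occasions = occasions
        self.P = len(occasions)
        self._compiled_cache: dict[tuple, list[CompiledSchedule]] = {}
        self.compiled = self._compiled(params)
        self.n_obs = [len(occ.y) for occ in occasions]
        self.y = np.concatenate([occ.y for occ in occasions]) \
            if occasions else np.empty(0)
        # row slices per occasion in the concatenated vector
        edges = np.cumsum([0] + self.n_obs)
        self.slices = [slice(edges[p], edges[p + 1]) for p in range(self.P)]
        self.d = 3 + 2 * self.P

    def _compiled(self, params: ModelParameters) -> list[CompiledSchedule]:
        # the node grid depends on the food-window edges, so schedules are
        # re-compiled when mtime1/mtime2 change (e.g. mtime2 estimated)
        key = (params.mtime1, params.mtime2, params.calorie_unit_kcal)
        if key not in self._compiled_cache:
            self._compiled_cache[key] = [
                CompiledSchedule.build(
                    occ.schedule, occ.t_obs, params.mtime1, params.mtime2,
                    params.calorie_unit_kcal)
                for occ in self.occasions
            ]
        return self._compiled_cache[key]

    def _re(self, b: np.ndarray, p: int) -> RandomEffects:
        # clip to keep exp() finite during line-search excursions
        bc = np.clip(b, -40.0, 40.0)
        return RandomEffects(bc[0], bc[1], bc[2], bc[3 + p],
                             bc[3 + self.P + p])

    def predict(self, params: ModelParameters, b: np.ndarray) -> np.ndarray:
        out = np.empty(len(self.y))
        for p, cs in enumerate(self._compiled(params)):
            out[self.slices[p]] = cs.solve_conc(params, self._re(b, p))
        return out

    def predict_jac(self, params: ModelParameters, b: np.ndarray
                    ) -> tuple[np.ndarray, np.ndarray]:
        f = self.predict(params, b)
        G = np.zeros((len(f), self.d))
        for col, idx in ((0, 0), (1, 1)):      # eta_kg, eta_kel
            bp = b.copy()
            bp[idx] += _FD_STEP
            G[:, col] = (self.predict(params, bp) - f) / _FD_STEP
        G[:, 2] = -f                            # eta_vc (exact)
        for p in range(self.P):
            sl = self.slices[p]
            # kel enters only as k_el*exp(eta_kel + kappa_p): same column
            G[sl, 3 + p] = G[sl, 1]
            G[sl, 3 + self.P + p] = -f[sl]
        return f, G

    def sd_b(self, params: ModelParameters) -> np.ndarray:
        return np.concatenate([
            [params.omega_kg, params.omega_kel, params.omega_vc],
            np.full(self.P, params.pi_kel),
            np.full(self.P, params.pi_vc),
        ])

    def problem(self, params: ModelParameters) -> SubjectProblem:
        return SubjectProblem(
            label=self.sid, y=self.y,
            predict=lambda b: self.predict(params, b),
            predict_jac=lambda b: self.predict_jac(params, b),
            sd_b=self.sd_b(params), sigma=params.sigma_prop,
            error="proportional",
        )


class MBPKModel:
    """The food-effect PK model bound to a dataset, ready to fit."""

    def __init__(self, dataset: PKDataset,
                 params: ModelParameters | None = None):
        self.dataset = dataset
        self.base_params = params or ModelParameters()
        self._contexts = [
            _SubjectContext(sid, occs, self.base_params)
            for sid, occs in dataset.iter_subjects()
        ]

    @classmethod
    def from_dataframe(cls, frame: pd.DataFrame,
                       params: ModelParameters | None = None) -> "MBPKModel":
        return cls(PKDataset(frame), params)

    # ------------------------------------------------------------------
    def problems(self, params: ModelParameters | None = None
                 ) -> list[SubjectProblem]:
        params = params or self.base_params
        return [ctx.problem(params) for ctx in self._contexts]

    def ofv(self, params: ModelParameters | None = None) -> float:
        """FOCE-I objective at the given parameters (cold inner starts)."""
        params = params or self.base_params
        total = 0.0
        for ctx in self._contexts:
            prob = ctx.problem(params)
            total += subject_ofv(prob, conditional_mode(prob))
        return total

    def conditional_estimates(self, subject: int,
                              params: ModelParameters | None = None
                              ) -> InnerResult:
        """EBE mode and curvature for one subject."""
        params = params or self.base_params
        for ctx in self._contexts:
            if ctx.sid == subject:
                return conditional_mode(ctx.problem(params))
        raise KeyError(f"no subject {subject} in the dataset")

    # ------------------------------------------------------------------
    def fit(
        self,
        free: Sequence[str] = DEFAULT_FREE,
        start: ModelParameters | None = None,
        se: bool = False,
        maxiter: int = 200,
        gtol: float = 1e-5,
        verbose: bool = False,
    ) -> "MBPKResults":
        """Maximise the FOCE-I approximate marginal likelihood.

        Parameters are optimised on transformed scales (log for rates,
        volumes and variabilities; shifted log for the food/bile effects;
        a bounded logit for the volume food effects).  ``start`` defaults
        to the model's base parameters.  ``se=True`` adds a
        finite-difference Hessian for asymptotic standard errors (roughly
        doubles the cost).
        """
        start = start or self.base_params
        free = tuple(free)
        for name in free:
            if name not in TRANSFORMS:
                raise ValueError(f"parameter {name!r} cannot be estimated")
            if name in ("omega_kg", "omega_kel", "omega_vc",
                        "pi_kel", "pi_vc") and getattr(start, name) <= 0:
                raise ValueError(
                    f"{name} must start positive to be estimated")
        theta0 = np.array([
            TRANSFORMS[n].to_unconstrained(getattr(start, n)) for n in free
        ])
        warm: dict[int, np.ndarray] = {}
        n_eval = [0]

        def natural(theta: np.ndarray) -> ModelParameters:
            changes = {n: TRANSFORMS[n].to_natural(t)
                       for n, t in zip(free, theta)}
            return start.replace(**changes)

        def objective(theta: np.ndarray) -> float:
            n_eval[0] += 1
            try:
                params = natural(theta)
            except (ValueError, OverflowError):
                return 1e12
            total = 0.0
            for i, ctx in enumerate(self._contexts):
                prob = ctx.problem(params)
                try:
                    inner = conditional_mode(prob, b0=warm.get(i))
                except EstimationError:
                    return 1e12
                warm[i] = inner.full_b()
                contrib = subject_ofv(prob, inner)
                if not np.isfinite(contrib):
                    return 1e12
                total += contrib
            return total

        history: list[float] = []

        # track accepted-iterate values without extra objective calls
        def tracked(theta: np.ndarray) -> float:
            val = objective(theta)
            tracked.last = val
            return val
        tracked.last = np.inf

        def cb(theta: np.ndarray) -> None:
            # re-evaluate at the accepted iterate: tracked.last may belong
            # to a line-search or finite-difference probe
            history.append(objective(theta))
            if verbose:
                print(f"iter {len(history):3d}  OFV {history[-1]:.4f}")

        t0 = time.time()
        res = minimize(
            tracked, theta0, method="L-BFGS-B", callback=cb,
            options={"maxiter": maxiter, "eps": 1e-4, "ftol": 1e-10,
                     "gtol": gtol},
        )
        elapsed = time.time() - t0

        params_hat = natural(res.x)
        ofv_hat = objective(res.x)
        estimates = {n: getattr(params_hat, n) for n in free}

        bse = rse = cov = None
        if se:
            H = _central_hessian(objective, res.x, step=1e-2)
            try:
                cov_t = 2.0 * np.linalg.inv(H)
                se_t = np.sqrt(np.clip(np.diag(cov_t), 0.0, None))
                bse = {}
                for i, n in enumerate(free):
                    bse[n] = se_t[i] * abs(TRANSFORMS[n].dnat(res.x[i]))
                rse = {n: (100.0 * bse[n] / abs(estimates[n])
                           if estimates[n] != 0 else np.nan)
                       for n in free}
                cov = cov_t
            except np.linalg.LinAlgError:
                bse = rse = cov = None

        ebes = {}
        for ctx in self._contexts:
            inner = conditional_mode(ctx.problem(params_hat))
            ebes[ctx.sid] = inner.full_b()

        return MBPKResults(
            model=self, params=params_hat, free=free, estimates=estimates,
            ofv=ofv_hat, converged=bool(res.success), message=str(res.message),
            n_iter=int(res.nit), n_eval=n_eval[0], history=history,
            ebes=ebes, bse=bse, rse=rse, cov_unconstrained=cov,
            start=start, elapsed=elapsed,
        )


def _central_hessian(fun, x: np.ndarray, step: float = 1e-2) -> np.ndarray:
    """Central-difference Hessian (no external differentiation package)."""
    d = len(x)
    H = np.empty((d, d))
    f0 = fun(x)
    for i in range(d):
        ei = np.zeros(d)
        ei[i] = step
        fpp = fun(x + 2 * ei)
        fmm = fun(x - 2 * ei)
        H[i, i] = (fpp - 2 * f0 + fmm) / (4 * step * step)
        for j in range(i + 1, d):
            ej = np.zeros(d)
            ej[j] = step
            fpq = fun(x + ei + ej)
            fpm = fun(x + ei - ej)
            fmp = fun(x - ei + ej)
            fmq = fun(x - ei - ej)
            H[i, j] = H[j, i] = (fpq - fpm - fmp + fmq) / (4 * step * step)
    return H


@dataclass
class MBPKResults:
    """Estimation output: estimates, OFV, EBEs, uncertainty, diagnostics."""

    model: MBPKModel
    params: ModelParameters
    free: tuple[str, ...]
    estimates: dict[str, float]
    ofv: float
    converged: bool
    message: str
    n_iter: int
    n_eval: int
    history: list[float]
    ebes: dict[int, np.ndarray]
    bse: dict[str, float] | None
    rse: dict[str, float] | None
    cov_unconstrained: np.ndarray | None
    start: ModelParameters
    elapsed: float

    # ------------------------------------------------------------------
    def ebes_frame(self) -> pd.DataFrame:
        rows = []
        for ctx in self.model._contexts:
            b = self.ebes[ctx.sid]
            row = {"ID": ctx.sid, "eta_kg": b[0], "eta_kel": b[1],
                   "eta_vc": b[2]}
            for p in range(ctx.P):
                row[f"kappa_kel_occ{p + 1}"] = b[3 + p]
                row[f"kappa_vc_occ{p + 1}"] = b[3 + ctx.P + p]
            rows.append(row)
        return pd.DataFrame(rows)

    def summary(self) -> str:
        lines = [
            "FOCE-I fit of the mechanism-based food-effect PK model",
            f"  subjects: {self.model.dataset.n_subjects}   "
            f"observations: {self.model.dataset.n_observations}",
            f"  OFV: {self.ofv:.3f}   converged: {self.converged}   "
            f"iterations: {self.n_iter} ({self.n_eval} evaluations, "
            f"{self.elapsed:.1f} s)",
            "",
            f"  {'parameter':<12} {'estimate':>12} {'SE':>10} {'RSE%':>8}",
        ]
        for n in self.free:
            est = self.estimates[n]
            if self.bse is not None:
                lines.append(f"  {n:<12} {est:>12.5g} {self.bse[n]:>10.3g} "
                             f"{self.rse[n]:>8.1f}")
            else:
                lines.append(f"  {n:<12} {est:>12.5g} {'-':>10} {'-':>8}")
        return "\n".join(lines)

    def to_frame(self) -> pd.DataFrame:
        rows = []
        for n in self.free:
            rows.append({
                "parameter": n,
                "estimate": self.estimates[n],
                "se": self.bse[n] if self.bse else np.nan,
                "rse_pct": self.rse[n] if self.rse else np.nan,
            })
        return pd.DataFrame(rows)

    # diagnostics --------------------------------------------------------
    def residual_table(self) -> pd.DataFrame:
        from .diagnostics import residual_table
        return residual_table(self.model, self.params)

    def vpc(self, n_replicates: int = 1000, seed: int = 0, **kw):
        from .diagnostics import vpc
        return vpc(self.model.dataset, self.params,
                   n_replicates=n_replicates, seed=seed, **kw)

    def bootstrap(self, n_replicates: int = 1000, fraction: float = 0.9,
                  seed: int = 0, **kw):
        from .diagnostics import bootstrap
        return bootstrap(self.model.dataset, params=self.start,
                         free=self.free, n_replicates=n_replicates,
                         fraction=fraction, seed=seed, **kw)
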