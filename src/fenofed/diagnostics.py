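"""Model evaluation: residual tables, visual predictive check, bootstrap.

* ``residual_table`` computes population predictions (PRED, random effects
  at zero), individual predictions (IPRED, at the empirical Bayes modes)
  and conditional weighted residuals (CWRES): the marginal residuals under
  the FOCE linearisation decorrelated by the inverse Cholesky factor of
  the linearised marginal covariance.
* ``vpc`` simulates replicate datasets at the design of the input
  (same subjects, times, meals, doses; residual error included), computes
  the requested observed percentiles per time bin, and brackets each with
  its simulation-based 95% confidence band, stratified by food type.
* ``bootstrap`` re-estimates the model on random 90% subject subsets
  (sampling without replacement, as used for the original model's internal
  validation; classical resampling with replacement is available as an
  option) and reports per-parameter medians and percentile intervals.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .core import RandomEffects
from .fastsolve import CompiledSchedule
from .foce import EstimationError, conditional_mode, linearized_residuals
from .io import PKDataset
from .params import ModelParameters

__all__ = ["residual_table", "vpc", "VPCResult", "bootstrap",
           "BootstrapResult"]


# ---------------------------------------------------------------------------
# residuals
# ---------------------------------------------------------------------------

def residual_table(model, params: ModelParameters | None = None
                   ) -> pd.DataFrame:
    """Per-observation PRED, IPRED and CWRES for a fitted or given model.

    ``model`` is an :class:`~fenofed.model.MBPKModel`; the table is
    invariant to observation order within subjects (rows come back in
    dataset order).
    """
    params = params or model.base_params
    rows = []
    for ctx in model._contexts:
        prob = ctx.problem(params)
        inner = conditional_mode(prob)
        zeros = np.zeros(ctx.d)
        pred = ctx.predict(params, zeros)
        f = inner.f
        cwres = linearized_residuals(prob, inner)
        i = 0
        for p, occ in enumerate(ctx.occasions):
            for t, dv in zip(occ.t_obs, occ.y):
                rows.append({
                    "ID": ctx.sid, "OCC": occ.occasion, "TIME": t, "DV": dv,
                    "PRED": pred[i], "IPRED": f[i], "CWRES": cwres[i],
                })
                i += 1
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# visual predictive check
# ---------------------------------------------------------------------------

@dataclass
class VPCResult:
    """Percentile bands per food-type stratum.

    Each stratum table has one row per time bin with the observed
    percentiles and, for each, the lower/upper edge of its simulated
    confidence band.
    """

    n_replicates: int
    percentiles: tuple[float, ...]
    ci: float
    strata: dict[str, pd.DataFrame]

    def coverage(self) -> float:
        """Fraction of (bin, percentile) cells whose observed value lies
        inside its simulated band."""
        inside = total = 0
        for tab in self.strata.values():
            for q in self.percentiles:
                obs = tab[f"obs_p{q:g}"]
                lo = tab[f"lo_p{q:g}"]
                hi = tab[f"hi_p{q:g}"]
                inside += int(((obs >= lo) & (obs <= hi)).sum())
                total += len(tab)
        return inside / total if total else float("nan")

    def to_frame(self) -> pd.DataFrame:
        out = []
        for name, tab in self.strata.items():
            t = tab.copy()
            t.insert(0, "stratum", name)
            out.append(t)
        return pd.concat(out, ignore_index=True)

    def plot(self, path=None):
        """Concentration-time percentile bands, one panel per stratum."""
        import matplotlib
        matplotlib.use("Agg")
        import matplotlib.pyplot as plt

        n = len(self.strata)
        fig, axes = plt.subplots(1, n, figsize=(4 * n, 3.2), squeeze=False)
        for ax, (name, tab) in zip(axes[0], self.strata.items()):
            for q in self.percentiles:
                ax.fill_between(tab["time"], tab[f"lo_p{q:g}"],
                                tab[f"hi_p{q:g}"], alpha=0.25)
                ax.plot(tab["time"], tab[f"obs_p{q:g}"], "o-", ms=3, lw=1)
            ax.set_title(name)
            ax.set_xlabel("time (h)")
            ax.set_ylabel("concentration (ug/mL)")
        fig.tight_layout()
        if path is not None:
            fig.savefig(path, dpi=120)
            plt.close(fig)
        return fig


def vpc(
    dataset: PKDataset,
    params: ModelParameters,
    n_replicates: int = 1000,
    percentiles: tuple[float, ...] = (5.0, 50.0, 95.0),
    seed: int | np.random.Generator = 0,
    bins=None,
    ci: float = 95.0,
) -> VPCResult:
    """Visual predictive check at the dataset's own design.

    ``bins=None`` bins at the nominal sampling times (the design is a
    fixed schedule); alternatively pass explicit bin edges, in which case
    every bin must contain observations (empty bins raise, listing the
    offenders).
    """
    if n_replicates < 2:
        raise ValueError("n_replicates must be >= 2")
    rng = (seed if isinstance(seed, np.random.Generator)
           else np.random.default_rng(seed))
    percentiles = tuple(float(q) for q in sorted(percentiles))

    # compile every subject-occasion once; group occasions by stratum
    occasions = []   # (stratum, cs, t_obs, y)
    for sid, occs in dataset.iter_subjects():
        for occ in occs:
            if len(occ.t_obs) == 0:
                continue
            occasions.append((occ.food_type.name, CompiledSchedule.build(
                occ.schedule, occ.t_obs, params.mtime1, params.mtime2,
                params.calorie_unit_kcal), occ))
    strata_names = sorted({s for s, _, _ in occasions})

    def bin_index(stratum: str):
        times = np.concatenate([o.t_obs for s, _, o in occasions
                                if s == stratum])
        if bins is None:
            centers = np.unique(times)
            idx_of = {t: i for i, t in enumerate(centers)}
            return centers, lambda t: np.array([idx_of[x] for x in t])
        edges = np.asarray(bins, dtype=float)
        which = np.clip(np.searchsorted(edges, times, side="right") - 1,
                        0, len(edges) - 2)
        counts = np.bincount(which, minlength=len(edges) - 1)
        empty = [f"[{edges[i]}, {edges[i + 1]})"
                 for i in range(len(edges) - 1) if counts[i] == 0]
        if empty:
            raise ValueError(
                f"empty VPC bins in stratum {stratum}: {', '.join(empty)}")
        centers = 0.5 * (edges[:-1] + edges[1:])
        return centers, lambda t: np.clip(
            np.searchsorted(edges, t, side="right") - 1, 0, len(edges) - 2)

    result: dict[str, pd.DataFrame] = {}
    # per-subject eta must be shared across that subject's occasions
    subj_ids = sorted({o.subject for _, _, o in occasions})
    subj_pos = {s: i for i, s in enumerate(subj_ids)}

    for stratum in strata_names:
        centers, to_bin = bin_index(stratum)
        occ_here = [(cs, o) for s, cs, o in occasions if s == stratum]
        bin_of = [to_bin(o.t_obs) for _, o in occ_here]
        n_bins = len(centers)

        obs_vals: list[list[float]] = [[] for _ in range(n_bins)]
        for (cs, o), bidx in zip(occ_here, bin_of):
            for bi, dv in zip(bidx, o.y):
                obs_vals[bi].append(dv)

        sim_pcts = np.empty((n_replicates, n_bins, len(percentiles)))
        for rep in range(n_replicates):
            etas = rng.normal(
                0.0, [params.omega_kg, params.omega_kel, params.omega_vc],
                size=(len(subj_ids), 3))
            vals: list[list[float]] = [[] for _ in range(n_bins)]
            for (cs, o), bidx in zip(occ_here, bin_of):
                eta = etas[subj_pos[o.subject]]
                kap = rng.normal(0.0, [params.pi_kel, params.pi_vc])
                re = RandomEffects(eta[0], eta[1], eta[2], kap[0], kap[1])
                f = cs.solve_conc(params, re)
                y = f * (1.0 + rng.normal(0.0, params.sigma_prop,
                                          size=f.shape))
                bad = y < 0
                while bad.any():
                    y[bad] = f[bad] * (1.0 + rng.normal(
                        0.0, params.sigma_prop, size=int(bad.sum())))
                    bad = y < 0
                for bi, v in zip(bidx, y):
                    vals[bi].append(v)
            for bi in range(n_bins):
                sim_pcts[rep, bi] = np.percentile(vals[bi], percentiles)

        alpha = (100.0 - ci) / 2.0
        tab = {"time": centers,
               "n_obs": [len(v) for v in obs_vals]}
        for qi, q in enumerate(percentiles):
            tab[f"obs_p{q:g}"] = [float(np.percentile(v, q))
                                  for v in obs_vals]
            tab[f"lo_p{q:g}"] = np.percentile(sim_pcts[:, :, qi], alpha,
                                              axis=0)
            tab[f"hi_p{q:g}"] = np.percentile(sim_pcts[:, :, qi],
                                              100.0 - alpha, axis=0)
        result[stratum] = pd.DataFrame(tab)

    return VPCResult(n_replicates=n_replicates, percentiles=percentiles,
                     ci=ci, strata=result)


# ---------------------------------------------------------------------------
# bootstrap
# ---------------------------------------------------------------------------

@dataclass
class BootstrapResult:
    replicates: pd.DataFrame        # columns: replicate, parameter, value
    n_replicates: int
    n_success: int
    fraction: float
    method: str

    def summary_frame(self, ci: float = 95.0) -> pd.DataFrame:
        alpha = (100.0 - ci) / 2.0
        ok = self.replicates[self.replicates["converged"]]
        rows = []
        for name, g in ok.groupby("parameter", sort=False):
            v = g["value"].to_numpy()
            rows.append({
                "parameter": name,
                "median": float(np.median(v)),
                "ci_lo": float(np.percentile(v, alpha)),
                "ci_hi": float(np.percentile(v, 100.0 - alpha)),
                "n": len(v),
            })
        return pd.DataFrame(rows)


def bootstrap(
    dataset: PKDataset,
    params: ModelParameters,
    free,
    n_replicates: int = 1000,
    fraction: float = 0.9,
    seed: int | np.random.Generator = 0,
    method: str = "subsample",
    fit_kwargs: dict | None = None,
) -> BootstrapResult:
    """Subject-level bootstrap of the FOCE-I fit.

    ``method="subsample"`` draws ``floor(fraction * N)`` subjects without
    replacement per replicate (the internal-validation procedure the model
    was published with); ``method="resample"`` is the classical bootstrap
    with replacement at ``fraction=1.0``.  Replicates that fail to
    converge are recorded, not fatal; more than 50% failures raise.
    """
    from .model import MBPKModel

    if not 0.0 < fraction <= 1.0:
        raise ValueError("fraction must be in (0, 1]")
    if method not in ("subsample", "resample"):
        raise ValueError(f"unknown bootstrap method {method!r}")
    subjects = dataset.subjects
    if len(subjects) < 5:
        raise ValueError("bootstrap needs at least 5 subjects")
    rng = (seed if isinstance(seed, np.random.Generator)
           else np.random.default_rng(seed))
    fit_kwargs = dict(fit_kwargs or {})
    m = int(math.floor(fraction * len(subjects)))

    rows = []
    n_success = 0
    for rep in range(1, n_replicates + 1):
        if method == "subsample":
            # sort: subject order is irrelevant without replacement, and a
            # canonical order keeps fraction=1.0 replicates bit-identical
            chosen = sorted(rng.choice(subjects, size=m, replace=False))
        else:
            chosen = list(rng.choice(subjects, size=m, replace=True))
        sub = _renumbered_subset(dataset, chosen)
        converged = False
        est = {name: np.nan for name in free}
        try:
            fit = MBPKModel(sub, params).fit(free=free, **fit_kwargs)
            est = fit.estimates
            converged = fit.converged
        except (EstimationError, np.linalg.LinAlgError):
            pass
        n_success += int(converged)
        for name in free:
            rows.append({"replicate": rep, "parameter": name,
                         "value": est[name], "converged": converged})
    if n_success < 0.5 * n_replicates:
        raise EstimationError(
            f"bootstrap: only {n_success}/{n_replicates} replicates "
            f"converged")
    return BootstrapResult(
        replicates=pd.DataFrame(rows), n_replicates=n_replicates,
        n_success=n_success, fraction=fraction, method=method,
    )


def _renumbered_subset(dataset: PKDataset, chosen) -> PKDataset:
    """Subset that keeps duplicated subjects distinct (for resampling)."""
    frames = []
    for new_id, sid in enumerate(chosen, start=1):
        g = dataset.frame[dataset.frame["ID"] == sid].copy()
        g["ID"] = new_id
        frames.append(g)
    return PKDataset(pd.concat(frames, ignore_index=True))
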