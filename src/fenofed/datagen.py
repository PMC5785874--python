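"""Synthetic crossover-trial generator.

Emulates the study design behind the model: a randomized three-way
crossover in 24 healthy subjects, each receiving a single 250 mg
sustained-release fenofibrate capsule fasted, after a 686.3 kcal standard
breakfast, and after a high-fat breakfast, with plasma fenofibric acid
sampled at 1, 2, 3, 4, 5, 6, 8, 10, 12, 24, 48 and 72 h.  Periods are
separated by a washout long enough that they are simulated independently
(single-dose crossover practice); IIV is drawn per subject, IOV per
period, and proportional residual error per sample.

The generator returns both the observable dataset and the hidden true
random effects, so estimation code can be tested for parameter recovery.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .core import RandomEffects, effective_vc
from .events import EventSchedule, FoodType
from .fastsolve import CompiledSchedule
from .io import PKDataset
from .params import ModelParameters
from .population import IndividualRealization

__all__ = ["TrialDesign", "GeneratedTrial", "generate_trial",
           "FIXTURE_SEEDS", "fixture_dataset", "regenerate_fixture"]

DEFAULT_SAMPLING = (1., 2., 3., 4., 5., 6., 8., 10., 12., 24., 48., 72.)

#: shipped frozen fixtures: name -> (n_subjects, seed)
FIXTURE_SEEDS = {"small": (6, 101), "full": (24, 202)}


@dataclass(frozen=True)
class TrialDesign:
    """Crossover study design (defaults reproduce the source study)."""

    n_subjects: int = 24
    periods: tuple[tuple[FoodType, float], ...] = (
        (FoodType.FASTED, 0.0),
        (FoodType.STANDARD, 686.3),
        (FoodType.HIGH_FAT, 1280.0),
    )
    dose_mg: float = 250.0
    sampling_times: tuple[float, ...] = DEFAULT_SAMPLING
    washout_h: float = 168.0   # between periods; periods run independently
    include_predose: bool = True

    def __post_init__(self) -> None:
        if self.n_subjects < 1:
            raise ValueError("n_subjects must be >= 1")
        if not self.periods:
            raise ValueError("at least one period required")
        t = np.asarray(self.sampling_times)
        if np.any(np.diff(t) <= 0) or np.any(t <= 0):
            raise ValueError("sampling times must be positive and increasing")
        for ft, cal in self.periods:
            if FoodType(ft) == FoodType.FASTED and cal != 0:
                raise ValueError("fasted periods must have zero calories")
            if cal < 0:
                raise ValueError("calories must be non-negative")


@dataclass
class GeneratedTrial:
    dataset: PKDataset
    realizations: list[IndividualRealization]
    design: TrialDesign
    seed: int | None
    n_redrawn: int      # residual-error draws rejected for negativity

    def truth_frame(self) -> pd.DataFrame:
        return pd.DataFrame([r.__dict__ for r in self.realizations])


def generate_trial(
    design: TrialDesign,
    params: ModelParameters,
    seed: int | np.random.Generator = 0,
) -> GeneratedTrial:
    """Simulate one crossover trial: dataset plus ground-truth deviates."""
    rng = (seed if isinstance(seed, np.random.Generator)
           else np.random.default_rng(seed))
    seed_val = seed if isinstance(seed, int) else None
    t_obs = np.asarray(design.sampling_times)

    compiled = []
    for ft, cal in design.periods:
        sch = EventSchedule.single_dose(design.dose_mg, FoodType(ft), cal)
        compiled.append(CompiledSchedule.build(
            sch, t_obs, params.mtime1, params.mtime2,
            params.calorie_unit_kcal))

    rows = []
    reals: list[IndividualRealization] = []
    n_redrawn = 0
    for i in range(1, design.n_subjects + 1):
        eta = rng.normal(0.0, [params.omega_kg, params.omega_kel,
                               params.omega_vc])
        for p, (ft, cal) in enumerate(design.periods, start=1):
            ft = FoodType(ft)
            kap = rng.normal(0.0, [params.pi_kel, params.pi_vc])
            re = RandomEffects(eta[0], eta[1], eta[2], kap[0], kap[1])
            reals.append(IndividualRealization(
                subject=i, occasion=p,
                eta_kg=eta[0], eta_kel=eta[1], eta_vc=eta[2],
                kappa_kel=kap[0], kappa_vc=kap[1],
                kg=params.tv_kg * float(np.exp(eta[0])),
                k_el=params.k_el * float(np.exp(eta[1] + kap[0])),
                vc_eff=effective_vc(params.vc_over_f, ft, params.e_vc1,
                                    params.e_vc2)
                * float(np.exp(eta[2] + kap[1])),
            ))
            pred = compiled[p - 1].solve_conc(params, re)
            y = pred * (1.0 + rng.normal(0.0, params.sigma_prop,
                                         size=pred.shape))
            bad = y < 0
            while bad.any():
                n_redrawn += int(bad.sum())
                y[bad] = pred[bad] * (
                    1.0 + rng.normal(0.0, params.sigma_prop,
                                     size=int(bad.sum())))
                bad = y < 0
            food_code = int(ft)
            # dose row (carries the meal), then pre-dose zero, then samples
            rows.append((i, 0.0, design.dose_mg, 0.0, 1, 1, p, food_code,
                         cal))
            if design.include_predose:
                rows.append((i, 0.0, 0.0, 0.0, 0, 1, p, food_code, 0.0))
            for t, obs in zip(t_obs, y):
                rows.append((i, t, 0.0, obs, 0, 0, p, food_code, 0.0))

    frame = pd.DataFrame(
        rows, columns=["ID", "TIME", "AMT", "DV", "EVID", "MDV", "OCC",
                       "FOOD", "CAL"])
    return GeneratedTrial(
        dataset=PKDataset(frame), realizations=reals, design=design,
        seed=seed_val, n_redrawn=n_redrawn,
    )


def regenerate_fixture(name: str) -> GeneratedTrial:
    """Rebuild a shipped fixture trial from its recorded seed."""
    try:
        n, seed = FIXTURE_SEEDS[name]
    except KeyError:
        raise ValueError(f"unknown fixture {name!r}; "
                         f"choose from {sorted(FIXTURE_SEEDS)}") from None
    return generate_trial(TrialDesign(n_subjects=n), ModelParameters(),
                          seed=seed)


def fixture_dataset(name: str) -> PKDataset:
    """Load a shipped frozen fixture dataset ("small" or "full")."""
    from importlib.resources import files

    from .io import read_dataset

    if name not in FIXTURE_SEEDS:
        raise ValueError(f"unknown fixture {name!r}; "
                         f"choose from {sorted(FIXTURE_SEEDS)}")
    return read_dataset(files("fenofed") / "data" / f"trial_{name}.csv")
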