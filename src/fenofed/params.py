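"""Model parameters for the mechanism-based food-effect PK model.

The model describes fenofibric acid kinetics after oral fenofibrate with a
five-compartment system: drug in stomach (X1), drug in duodenum (X2),
fenofibric acid in the central compartment (X3), plus meal calories in
stomach (X4) and duodenum (X5).  Food acts on three parameters:

* gastric emptying of drug is boosted by a factor ``1 + e_food`` during a
  time window ``[mtime1, mtime2)`` after each meal,
* the combined metabolism/absorption rate is scaled by
  ``1 + e_bile * X5`` (bile secretion driven by duodenal calories),
* the apparent central volume shrinks by ``1 + e_vc1`` (standard meal) or
  ``1 + e_vc2`` (high-fat meal), encoding the bioavailability gain.

Calories are carried in units of ``calorie_unit_kcal`` (100 kcal by
default); only this scaling makes the bile coefficient consistent with the
derived fed-state absorption rates it is reported with.
"""

from __future__ import annotations

import dataclasses
import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable

import yaml

__all__ = [
    "ModelParameters",
    "omega_from_cv",
    "cv_from_omega",
    "default_parameters",
]


def omega_from_cv(cv_percent: float, convention: str = "direct") -> float:
    """Convert a printed %CV of a log-normal random effect to a log-scale SD.

    Parameters
    ----------
    cv_percent : float
        Coefficient of variation in percent.
    convention : {"direct", "lognormal"}
        ``"direct"`` treats the printed %CV as ``100 * omega`` (the common
        reporting convention for moderate variabilities); ``"lognormal"``
        uses the exact relation ``omega = sqrt(ln(1 + CV^2))``.
    """
    cv = cv_percent / 100.0
    if cv < 0:
        raise ValueError("cv_percent must be non-negative")
    if convention == "direct":
        return cv
    if convention == "lognormal":
        return math.sqrt(math.log1p(cv * cv))
    raise ValueError(f"unknown %CV convention: {convention!r}")


def cv_from_omega(omega: float, convention: str = "direct") -> float:
    """Inverse of :func:`omega_from_cv`, returning percent."""
    if convention == "direct":
        return 100.0 * omega
    if convention == "lognormal":
        return 100.0 * math.sqrt(math.expm1(omega * omega))
    raise ValueError(f"unknown %CV convention: {convention!r}")


_POSITIVE = (
    "tv_kg",
    "k_ma",
    "k_el",
    "vc_over_f",
    "kg_prime",
    "k_out",
    "sigma_prop",
)


@dataclass
class ModelParameters:
    """Fixed effects, random-effect magnitudes and residual error.

    Rate constants are in 1/h, volumes in litres, times in hours.  Random
    effect magnitudes (``omega_*``, ``pi_*``) are standard deviations on the
    log scale; defaults derive from printed %CV values with the "direct"
    convention.  ``v_stomach_fasted``, ``v_stomach_fed`` and ``v_duodenum``
    are physiological metadata: they appear in no model equation (all food
    effects act on amounts) and are carried for reporting only.
    """

    # fixed effects
    tv_kg: float = 0.0412        # typical fasted gastric emptying of drug
    k_ma: float = 0.198          # combined metabolism + absorption
    k_el: float = 0.27           # fenofibric acid elimination
    vc_over_f: float = 12.9      # apparent central volume (fasted)
    kg_prime: float = 0.00971    # gastric emptying of calories
    k_out: float = 0.00972       # calorie elimination from duodenum
    e_bile: float = 0.0239       # bile effect per calorie unit in duodenum
    e_food: float = 0.617        # fractional kg increase inside food window
    e_vc1: float = -0.394        # Vc/F fractional change, standard meal
    e_vc2: float = -0.461        # Vc/F fractional change, high-fat meal
    mtime1: float = 0.0          # food window start after meal (fixed)
    mtime2: float = 6.94         # food window end after meal

    # physiological metadata (not used in the equations)
    v_stomach_fasted: float = 0.049
    v_stomach_fed: float = 1.0
    v_duodenum: float = 0.045

    # inter-individual variability (log-scale SD)
    omega_kg: float = omega_from_cv(31.7)
    omega_kel: float = omega_from_cv(86.3)
    omega_vc: float = omega_from_cv(93.0)

    # inter-occasion variability (log-scale SD)
    pi_kel: float = omega_from_cv(44.9)
    pi_vc: float = omega_from_cv(50.9)

    # residual proportional error (SD of the relative error)
    sigma_prop: float = 0.608

    # unit of the calorie compartments, kcal per calorie-unit
    calorie_unit_kcal: float = 100.0

    def __post_init__(self) -> None:
        self.validate()

    def validate(self) -> None:
        for name in _POSITIVE:
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be strictly positive")
        for name in ("v_stomach_fasted", "v_stomach_fed", "v_duodenum",
                     "calorie_unit_kcal"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be strictly positive")
        if self.e_vc1 <= -1 or self.e_vc2 <= -1:
            raise ValueError("e_vc1/e_vc2 must be > -1 (Vc stays positive)")
        if self.e_food <= -1:
            raise ValueError("e_food must be > -1")
        if not (self.mtime2 > self.mtime1 >= 0):
            raise ValueError("food window requires mtime2 > mtime1 >= 0")
        for name in ("omega_kg", "omega_kel", "omega_vc", "pi_kel", "pi_vc"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be non-negative")

    # ------------------------------------------------------------------
    def replace(self, **changes: float) -> "ModelParameters":
        """Return a copy with the given fields replaced (validated)."""
        return dataclasses.replace(self, **changes)

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)

    @classmethod
    def from_dict(cls, d: dict) -> "ModelParameters":
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(d) - known
        if unknown:
            raise ValueError(f"unknown parameter keys: {sorted(unknown)}")
        return cls(**d)

    # flat YAML round trip -------------------------------------------------
    def to_yaml(self, path: str | Path) -> None:
        Path(path).write_text(
            yaml.safe_dump(self.to_dict(), sort_keys=False), encoding="utf-8"
        )

    @classmethod
    def from_yaml(cls, path: str | Path) -> "ModelParameters":
        data = yaml.safe_load(Path(path).read_text(encoding="utf-8"))
        if not isinstance(data, dict):
            raise ValueError(f"{path}: expected a flat key/value mapping")
        return cls.from_dict(data)

    def zero_random_effects(self) -> "ModelParameters":
        """Copy with all IIV/IOV magnitudes and residual error set to ~0."""
        return self.replace(
            omega_kg=0.0, omega_kel=0.0, omega_vc=0.0,
            pi_kel=0.0, pi_vc=0.0, sigma_prop=1e-12,
        )


def default_parameters() -> ModelParameters:
    """The published final-model estimates as a parameter set."""
    return ModelParameters()


def free_parameter_names() -> Iterable[str]:
    """Names of parameters that are structurally estimable."""
    return (
        "tv_kg", "k_ma", "k_el", "vc_over_f", "kg_prime", "k_out",
        "e_bile", "e_food", "e_vc1", "e_vc2", "mtime2",
        "omega_kg", "omega_kel", "omega_vc", "pi_kel", "pi_vc",
        "sigma_prop",
    )
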