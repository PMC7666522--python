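"""Propofol pharmacokinetics: Schnider three-compartment model with an effect site.

The induction protocol studied here is a zero-order infusion of 1% propofol
(10 mg/mL) at 3.3 mL/kg/h, run until loss of responsiveness.  Plasma and
effect-site concentrations are obtained by integrating the covariate-adjusted
Schnider model

    dA1/dt = R(t) - (k10 + k12 + k13) A1 + k21 A2 + k31 A3
    dA2/dt = k12 A1 - k21 A2
    dA3/dt = k13 A1 - k31 A3
    Cp     = A1 / V1
    dCe/dt = ke0 (Cp - Ce)

with micro-rate constants derived from the published clearances
(k10 = Cl1/V1, k12 = Cl2/V1, k21 = Cl2/V2, k13 = Cl3/V1, k31 = Cl3/V3).
Amounts are in mg, volumes in L, clearances in L/min, concentrations in
µg/mL (= mg/L), and the public time axis is in seconds.

Remifentanil is a constant covariate of the study (effect-site target
2.5 ng/mL, assumed equilibrated) and is never simulated.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np

__all__ = [
    "Demographics",
    "CompartmentModel",
    "InfusionSchedule",
    "ConcentrationTrajectory",
    "SCHNIDER_CONSTANTS",
    "james_lbm",
    "schnider_parameters",
    "protocol_infusion",
    "simulate_infusion",
]

# ---------------------------------------------------------------------------
# Model constants
# ---------------------------------------------------------------------------

#: Published Schnider propofol parameter set (single documented table).
#: Volumes in L, clearances in L/min, ages in years, weights in kg,
#: heights in cm, LBM in kg, ke0 in 1/min.
SCHNIDER_CONSTANTS = {
    "V1_l": 4.27,
    "V2_l": lambda age: 18.9 - 0.391 * (age - 53.0),
    "V3_l": 238.0,
    "Cl1_l_min": lambda weight, lbm, height: (
        1.89
        + 0.0456 * (weight - 77.0)
        - 0.0681 * (lbm - 59.0)
        + 0.0264 * (height - 177.0)
    ),
    "Cl2_l_min": lambda age: 1.29 - 0.024 * (age - 53.0),
    "Cl3_l_min": 0.836,
    "ke0_per_min": 0.456,
}

#: Default protocol settings: 3.3 mL/kg/h of 1% (10 mg/mL) propofol.
DEFAULT_INFUSION_ML_KG_H = 3.3
DEFAULT_PROPOFOL_MG_PER_ML = 10.0
DEFAULT_REMIFENTANIL_CE_NG_ML = 2.5
DEFAULT_DT_S = 0.1


# ---------------------------------------------------------------------------
# Domain types
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class Demographics:
    """Patient covariates entering the Schnider model.

    Parameters
    ----------
    age : float
        Years; must be >= 18 (adult study population).
    weight : float
        Total body weight, kg.
    height : float
        cm.
    sex : str
        ``"female"`` or ``"male"`` (selects the James lean-body-mass equation).
    """

    age: float
    weight: float
    height: float
    sex: str

    def __post_init__(self) -> None:
        if self.sex not in ("female", "male"):
            raise ValueError(f"sex must be 'female' or 'male', got {self.sex!r}")
        if self.age < 18:
            raise ValueError(f"age must be >= 18 y, got {self.age}")
        if self.weight <= 0 or self.height <= 0:
            raise ValueError("weight and height must be positive")


@dataclass(frozen=True)
class CompartmentModel:
    """Three-compartment mammillary model plus effect-site rate constant."""

    V1: float  # L
    V2: float  # L
    V3: float  # L
    Cl1: float  # L/min
    Cl2: float  # L/min
    Cl3: float  # L/min
    ke0: float  # 1/min

    def __post_init__(self) -> None:
        for name in ("V1", "V2", "V3", "Cl1", "Cl2", "Cl3", "ke0"):
            if getattr(self, name) <= 0:
                raise ValueError(f"compartment parameter {name} must be > 0")

    @property
    def rate_constants_per_min(self) -> dict[str, float]:
        """Micro rate constants k10, k12, k21, k13, k31 in 1/min."""
        return {
            "k10": self.Cl1 / self.V1,
            "k12": self.Cl2 / self.V1,
            "k21": self.Cl2 / self.V2,
            "k13": self.Cl3 / self.V1,
            "k31": self.Cl3 / self.V3,
        }


@dataclass(frozen=True)
class InfusionSchedule:
    """Piecewise-constant infusion: segments of (t_start_s, t_end_s, rate_mg_min)."""

    segments: tuple[tuple[float, float, float], ...]

    def __post_init__(self) -> None:
        prev_end = -math.inf
        for t0, t1, rate in self.segments:
            if not t0 < t1:
                raise ValueError(f"segment must have t_start < t_end, got ({t0}, {t1})")
            if rate < 0:
                raise ValueError("infusion rate must be >= 0")
            if t0 < prev_end:
                raise ValueError("infusion segments overlap")
            prev_end = t1

    def rate_at(self, t_s: float) -> float:
        """Infusion rate in mg/min at time ``t_s`` (half-open segments)."""
        for t0, t1, rate in self.segments:
            if t0 <= t_s < t1:
                return rate
        return 0.0

    @property
    def end_s(self) -> float:
        return max((t1 for _, t1, _ in self.segments), default=0.0)

    def total_drug_mg(self) -> float:
        return sum(rate * (t1 - t0) / 60.0 for t0, t1, rate in self.segments)


@dataclass(frozen=True)
class ConcentrationTrajectory:
    """Plasma and effect-site concentrations on a uniform time grid (seconds)."""

    times: np.ndarray  # s
    cp: np.ndarray  # µg/mL
    ce: np.ndarray  # µg/mL
    amounts: np.ndarray | None = None  # (n, 3) compartment amounts, mg (optional)

    def ce_at(self, t_s: float) -> float:
        """Effect-site concentration linearly interpolated at ``t_s``."""
        return float(np.interp(t_s, self.times, self.ce))

    def first_crossing(self, threshold: float) -> float | None:
        """Earliest time at which Ce reaches ``threshold`` (linear interpolation).

        Returns None if the trajectory never reaches the threshold.
        """
        above = np.nonzero(self.ce >= threshold)[0]
        if above.size == 0:
            return None
        i = int(above[0])
        if i == 0:
            return float(self.times[0])
        t0, t1 = self.times[i - 1], self.times[i]
        c0, c1 = self.ce[i - 1], self.ce[i]
        if c1 == c0:
            return float(t1)
        return float(t0 + (threshold - c0) * (t1 - t0) / (c1 - c0))

    def to_frame(self):
        import pandas as pd

        return pd.DataFrame(
            {"time_s": self.times, "cp_ug_ml": self.cp, "ce_ug_ml": self.ce}
        )


# ---------------------------------------------------------------------------
# Operations
# ---------------------------------------------------------------------------

def james_lbm(sex: str, weight: float, height: float) -> float:
    """Lean body mass (kg) by the James equations (weight kg, height cm)."""
    if sex == "male":
        return 1.1 * weight - 128.0 * (weight / height) ** 2
    if sex == "female":
        return 1.07 * weight - 148.0 * (weight / height) ** 2
    raise ValueError(f"unknown sex {sex!r}")


def schnider_parameters(
    demographics: Demographics, ke0_per_min: float = SCHNIDER_CONSTANTS["ke0_per_min"]
) -> CompartmentModel:
    """Covariate-adjusted Schnider propofol parameters for one patient.

    ``ke0`` defaults to 0.456 1/min, the plasma/effect-site equilibration
    constant of the published effect-site model.

    Raises
    ------
    ValueError
        If the age-adjusted V2 is not positive (implausible age).
    """
    d = demographics
    lbm = james_lbm(d.sex, d.weight, d.height)
    v2 = SCHNIDER_CONSTANTS["V2_l"](d.age)
    if v2 <= 0:
        raise ValueError(
            f"Schnider V2 = 18.9 - 0.391*(age-53) is non-positive for age {d.age} y; "
            "model undefined for this demographic"
        )
    return CompartmentModel(
        V1=SCHNIDER_CONSTANTS["V1_l"],
        V2=v2,
        V3=SCHNIDER_CONSTANTS["V3_l"],
        Cl1=SCHNIDER_CONSTANTS["Cl1_l_min"](d.weight, lbm, d.height),
        Cl2=SCHNIDER_CONSTANTS["Cl2_l_min"](d.age),
        Cl3=SCHNIDER_CONSTANTS["Cl3_l_min"],
        ke0=ke0_per_min,
    )


def protocol_infusion(
    demographics: Demographics,
    stop_time_s: float,
    infusion_ml_kg_h: float = DEFAULT_INFUSION_ML_KG_H,
    propofol_mg_per_ml: float = DEFAULT_PROPOFOL_MG_PER_ML,
) -> InfusionSchedule:
    """Study infusion: constant 3.3 mL/kg/h of 1% propofol from t=0 to stop.

    The rate in mg/min is ``ml_kg_h * mg_per_ml * weight / 60``; at the
    defaults and 72 kg this is 39.6 mg/min.
    """
    if stop_time_s <= 0:
        raise ValueError(f"stop_time_s must be > 0, got {stop_time_s}")
    rate_mg_min = infusion_ml_kg_h * propofol_mg_per_ml * demographics.weight / 60.0
    return InfusionSchedule(segments=((0.0, float(stop_time_s), rate_mg_min),))


def simulate_infusion(
    model: CompartmentModel,
    schedule: InfusionSchedule,
    dt_s: float = DEFAULT_DT_S,
    t_end_s: float | None = None,
    t_start_s: float = 0.0,
    keep_amounts: bool = False,
) -> ConcentrationTrajectory:
    """Integrate the compartment ODEs with fixed-step classical Runge-Kutta.

    A fixed step (default 0.1 s) keeps runs bit-reproducible; the system is
    only mildly stiff at these rates, and halving the step changes Ce at the
    end of a typical induction by well under 0.1%.

    Parameters
    ----------
    t_end_s : float, optional
        End of the grid; defaults to the end of the schedule.
    t_start_s : float
        Grid start (may be negative to include a drug-naive baseline).
    """
    if dt_s <= 0:
        raise ValueError("dt_s must be > 0")
    if t_end_s is None:
        t_end_s = schedule.end_s
    if t_end_s < schedule.end_s:
        raise ValueError("t_end_s must cover the infusion schedule (or extend it)")
    n = int(round((t_end_s - t_start_s) / dt_s))
    k = model.rate_constants_per_min
    # per-second rates; python floats in the inner loop for speed
    k10 = k["k10"] / 60.0
    k12 = k["k12"] / 60.0
    k21 = k["k21"] / 60.0
    k13 = k["k13"] / 60.0
    k31 = k["k31"] / 60.0
    ke0 = model.ke0 / 60.0
    v1 = model.V1

    times = t_start_s + dt_s * np.arange(n + 1)
    cp_out = np.empty(n + 1)
    ce_out = np.empty(n + 1)
    amounts = np.zeros((n + 1, 3)) if keep_amounts else None

    a1 = a2 = a3 = ce = 0.0
    cp_out[0] = 0.0
    ce_out[0] = 0.0
    half = dt_s / 2.0
    sixth = dt_s / 6.0
    for i in range(n):
        t = times[i]
        # infusion rate is piecewise constant on [t0, t1); sample once per
        # substage so segment edges that fall mid-step are still honoured
        r0 = schedule.rate_at(t) / 60.0
        rh = schedule.rate_at(t + half) / 60.0
        r1 = schedule.rate_at(t + dt_s) / 60.0

        def deriv(a1_, a2_, a3_, ce_, r_):
            cp_ = a1_ / v1
            return (
                r_ - (k10 + k12 + k13) * a1_ + k21 * a2_ + k31 * a3_,
                k12 * a1_ - k21 * a2_,
                k13 * a1_ - k31 * a3_,
                ke0 * (cp_ - ce_),
            )

        d1 = deriv(a1, a2, a3, ce, r0)
        d2 = deriv(a1 + half * d1[0], a2 + half * d1[1], a3 + half * d1[2],
                   ce + half * d1[3], rh)
        d3 = deriv(a1 + half * d2[0], a2 + half * d2[1], a3 + half * d2[2],
                   ce + half * d2[3], rh)
        d4 = deriv(a1 + dt_s * d3[0], a2 + dt_s * d3[1], a3 + dt_s * d3[2],
                   ce + dt_s * d3[3], r1)
        a1 += sixth * (d1[0] + 2 * d2[0] + 2 * d3[0] + d4[0])
        a2 += sixth * (d1[1] + 2 * d2[1] + 2 * d3[1] + d4[1])
        a3 += sixth * (d1[2] + 2 * d2[2] + 2 * d3[2] + d4[2])
        ce += sixth * (d1[3] + 2 * d2[3] + 2 * d3[3] + d4[3])
        if not (math.isfinite(a1) and math.isfinite(ce)):
            raise ArithmeticError(
                f"non-finite compartment state at t={times[i + 1]:.3f} s; "
                "check dt and model parameters"
            )
        # clip tiny negative round-off; amounts are physically nonnegative
        a1 = max(a1, 0.0)
        a2 = max(a2, 0.0)
        a3 = max(a3, 0.0)
        ce = max(ce, 0.0)
        cp_out[i + 1] = a1 / v1
        ce_out[i + 1] = ce
        if amounts is not None:
            amounts[i + 1] = (a1, a2, a3)
    return ConcentrationTrajectory(times=times, cp=cp_out, ce=ce_out,
                                   amounts=amounts)
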