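"""Derived time-varying pharmacokinetic quantities.

Total volume of distribution ``V1 + V2*f(t)``, first-order half-life,
spleen sequestration fractions (cumulative and per dose interval), and
pointwise consensus summaries across a set of models.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Callable, Sequence

import numpy as np
import pandas as pd

from .exceptions import DomainError, ValidationError
from .model_core import (
    DoseSchedule,
    StructuralModel,
    cumulative_dose,
    simulate_profile,
)

__all__ = [
    "DerivedTrajectory",
    "ConsensusSummary",
    "vd_total",
    "half_life",
    "cumulative_fraction_sequestered",
    "per_dose_fraction_sequestered",
    "derive_trajectory",
    "consensus",
]

#: quantities carried by a DerivedTrajectory and summarized by consensus()
QUANTITIES = (
    "vd_serum",
    "vd_spleen",
    "vd_total",
    "half_life",
    "spleen_mass",
    "cumulative_fraction",
    "per_dose_fraction",
)


def vd_total(model: StructuralModel, t):
    """Total volume of distribution ``V1 + V2*f(t)`` (L/kg)."""
    t_arr = np.asarray(t, dtype=float)
    if np.any(t_arr < 0):
        raise DomainError("t must be >= 0")
    p = model.parameters
    out = p.v1 + p.v2 * np.asarray(model.expansion.evaluate(t_arr))
    if np.ndim(t) == 0:
        return float(out)
    return out


def half_life(model: StructuralModel, t, convention: str = "first_order"):
    """Elimination half-life (days) at time t.

    ``first_order`` (default): ``ln2 * (V1 + V2*f(t)) / (K(t) * V1)`` with
    ``K(t)`` following the model's scaling convention.  ``eigen``: ``ln2``
    over the slowest nonzero eigenvalue of the rate matrix with its
    coefficients frozen at time t.
    """
    if model.parameters.k <= 0:
        raise DomainError("half-life undefined for K <= 0")
    if convention not in ("first_order", "eigen"):
        raise ValidationError("convention must be 'first_order' or 'eigen'")
    t_arr = np.atleast_1d(np.asarray(t, dtype=float))
    if np.any(t_arr < 0):
        raise DomainError("t must be >= 0")
    p = model.parameters
    if convention == "first_order":
        f = np.asarray(model.expansion.evaluate(t_arr))
        k_t = p.k / f if model.scaling.scale_k == "inverse_f" else np.full_like(f, p.k)
        out = math.log(2.0) * (p.v1 + p.v2 * f) / (k_t * p.v1)
    else:
        out = np.empty_like(t_arr)
        for i, ti in enumerate(t_arr):
            rc = model.rate_constants_at(float(ti))
            m = np.array([
                [-(rc["k"] + rc["k12"]), rc["k21"]],
                [rc["k12"], -rc["k21"]],
            ])
            if model.n_compartments == 3:
                m = np.array([
                    [-(rc["k"] + rc["k12"] + rc["k13"]), rc["k21"], rc["k31"]],
                    [rc["k12"], -rc["k21"], 0.0],
                    [rc["k13"], 0.0, -rc["k31"]],
                ])
            ev = np.linalg.eigvals(m)
            mags = np.abs(ev.real)
            nz = mags[mags > 1e-12]
            out[i] = math.log(2.0) / float(np.min(nz))
    if np.ndim(t) == 0:
        return float(out[0])
    return out


def _spleen_mass_per_kg(
    model: StructuralModel,
    schedule: DoseSchedule,
    spleen_volume_fn: Callable[[float], float],
    times: np.ndarray,
    dt_max: float = 0.05,
) -> np.ndarray:
    """Drug mass in the spleen (mg per kg body weight) at each time."""
    sim = simulate_profile(model, schedule, times, dt_max=dt_max)
    w = np.asarray([spleen_volume_fn(float(ti)) for ti in times])
    return sim.spleen * w


def cumulative_fraction_sequestered(
    model: StructuralModel,
    schedule: DoseSchedule,
    spleen_volume_fn: Callable[[float], float],
    t,
    dt_max: float = 0.05,
):
    """Fraction of all administered drug residing in the spleen at time t.

    ``spleen_volume_fn`` maps time (days) to spleen volume in L per kg body
    weight (organ mass at density 1 g/mL divided by body weight).  The
    fraction is ``C2(t) * W(t) / cumulative_dose(t)`` and requires at least
    one dose at or before t.
    """
    scalar = np.ndim(t) == 0
    t_arr = np.atleast_1d(np.asarray(t, dtype=float))
    doses = np.array([cumulative_dose(schedule, ti) for ti in t_arr])
    if np.any(doses <= 0):
        raise DomainError("cumulative fraction undefined before the first dose")
    mass = _spleen_mass_per_kg(model, schedule, spleen_volume_fn, t_arr, dt_max)
    out = mass / doses
    return float(out[0]) if scalar else out


def per_dose_fraction_sequestered(
    model: StructuralModel,
    schedule: DoseSchedule,
    spleen_volume_fn: Callable[[float], float],
    t_prev: float,
    t_now: float,
    dt_max: float = 0.05,
) -> float:
    """Fraction of the dose given in (t_prev, t_now] that ends up in the spleen.

    ``[M(t_now) - M(t_prev)] / [D(t_now) - D(t_prev)]`` with
    ``M = C2 * W_spleen``; errors if no dose falls in the interval.
    """
    if not t_prev < t_now:
        raise DomainError("t_prev must be < t_now")
    d = cumulative_dose(schedule, t_now) - cumulative_dose(schedule, t_prev)
    if d <= 0:
        raise DomainError(f"no dose administered in ({t_prev}, {t_now}]")
    mass = _spleen_mass_per_kg(
        model, schedule, spleen_volume_fn, np.array([t_prev, t_now]), dt_max
    )
    return float((mass[1] - mass[0]) / d)


@dataclass
class DerivedTrajectory:
    """Derived quantities on a shared time grid.

    Sequestration fractions are NaN at times before the first dose.
    """

    model_name: str
    times: np.ndarray
    vd_serum: np.ndarray
    vd_spleen: np.ndarray
    vd_total: np.ndarray
    half_life: np.ndarray
    spleen_mass: np.ndarray
    cumulative_fraction: np.ndarray
    per_dose_fraction: np.ndarray

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({
            "time": self.times,
            "vd_serum": self.vd_serum,
            "vd_spleen": self.vd_spleen,
            "vd_total": self.vd_total,
            "half_life": self.half_life,
            "spleen_mass": self.spleen_mass,
            "cumulative_fraction": self.cumulative_fraction,
            "per_dose_fraction": self.per_dose_fraction,
        })

    def quantity(self, name: str) -> np.ndarray:
        if name == "cumulative_fraction":
            return self.cumulative_fraction
        if name == "per_dose_fraction":
            return self.per_dose_fraction
        return getattr(self, name)


def derive_trajectory(
    model: StructuralModel,
    schedule: DoseSchedule,
    spleen_volume_fn: Callable[[float], float],
    times: Sequence[float],
    name: str = "",
    half_life_convention: str = "first_order",
    dt_max: float = 0.05,
) -> DerivedTrajectory:
    """Compute every derived quantity on a time grid in one pass."""
    t = np.asarray(times, dtype=float)
    if t.ndim != 1 or t.size == 0 or np.any(np.diff(t) <= 0):
        raise ValidationError("times must be strictly increasing and non-empty")
    p = model.parameters
    f = np.asarray(model.expansion.evaluate(t))
    vd_spl = p.v2 * f
    vd_tot = p.v1 + vd_spl
    hl = half_life(model, t, convention=half_life_convention)
    mass = _spleen_mass_per_kg(model, schedule, spleen_volume_fn, t, dt_max)
    doses = np.array([cumulative_dose(schedule, ti) for ti in t])
    with np.errstate(invalid="ignore", divide="ignore"):
        cum_frac = np.where(doses > 0, mass / np.where(doses > 0, doses, 1.0), np.nan)
    per_frac = np.full_like(t, np.nan)
    prev_mass = 0.0
    prev_dose = 0.0
    for i, ti in enumerate(t):
        d = doses[i] - prev_dose
        if d > 0:
            per_frac[i] = (mass[i] - prev_mass) / d
            prev_mass = mass[i]
            prev_dose = doses[i]
    return DerivedTrajectory(
        model_name=name,
        times=t,
        vd_serum=np.full_like(t, p.v1),
        vd_spleen=vd_spl,
        vd_total=vd_tot,
        half_life=hl,
        spleen_mass=mass,
        cumulative_fraction=cum_frac,
        per_dose_fraction=per_frac,
    )


@dataclass
class ConsensusSummary:
    """Pointwise mean and sample SD of derived quantities across models."""

    times: np.ndarray
    mean: pd.DataFrame  # columns = QUANTITIES
    sd: pd.DataFrame
    n_models: int

    def to_frame(self) -> pd.DataFrame:
        out = pd.DataFrame({"time": self.times})
        for q in QUANTITIES:
            out[f"{q}_mean"] = self.mean[q].to_numpy()
            out[f"{q}_sd"] = self.sd[q].to_numpy()
        return out


def consensus(trajectories: Sequence[DerivedTrajectory]) -> ConsensusSummary:
    """Combine derived trajectories on a shared grid into mean +/- SD."""
    if not trajectories:
        raise ValidationError("need at least one trajectory")
    t0 = trajectories[0].times
    for tr in trajectories[1:]:
        if not np.array_equal(tr.times, t0):
            raise ValidationError("trajectories must share one time grid")
    mean = {}
    sd = {}
    for q in QUANTITIES:
        stack = np.stack([tr.quantity(q) for tr in trajectories])
        mean[q] = stack.mean(axis=0)
        sd[q] = stack.std(axis=0, ddof=1) if len(trajectories) > 1 else np.zeros_like(t0)
    return ConsensusSummary(
        times=t0,
        mean=pd.DataFrame(mean),
        sd=pd.DataFrame(sd),
        n_models=len(trajectories),
    )
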