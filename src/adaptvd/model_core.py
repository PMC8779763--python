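"""Compartmental model structure, dosing schedules and simulation.

Serum is compartment 1 (drug enters and is eliminated there); the tissue
compartment 2 has baseline volume ``V2`` multiplied by the expansion
function ``f(t)``; an optional static peripheral compartment 3 exchanges
with serum.  State is tracked as amounts per kg body weight; concentrations
are formed at output time only, so the time-varying volume never enters the
ODE state.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from scipy.linalg import expm

from ._kernel import integrate_mesh
from .exceptions import DomainError, SolverError, ValidationError
from .expansion import ExpansionFunction

__all__ = [
    "PKParameters",
    "ScalingConvention",
    "StructuralModel",
    "DoseEvent",
    "DoseSchedule",
    "build_schedule",
    "cumulative_dose",
    "rhs",
    "simulate_profile",
    "SimulationResult",
    "analytic_two_compartment",
]

STRUCTURAL_NAMES_2 = ("v1", "v2", "k", "k12", "k21")
STRUCTURAL_NAMES_3 = STRUCTURAL_NAMES_2 + ("v3", "k13", "k31")


@dataclass(frozen=True)
class PKParameters:
    """Rate constants (1/day) and compartment volumes (L/kg body weight)."""

    v1: float
    v2: float
    k: float
    k12: float
    k21: float
    v3: float | None = None
    k13: float | None = None
    k31: float | None = None
    fixed: frozenset = field(default_factory=frozenset)

    def __post_init__(self) -> None:
        # volumes strictly positive; rate constants may be zero so the
        # degenerate one-compartment limits stay expressible
        for name in STRUCTURAL_NAMES_2:
            v = getattr(self, name)
            lo_ok = v > 0 if name in ("v1", "v2") else v >= 0
            if not np.isfinite(v) or not lo_ok:
                raise ValidationError(f"parameter {name!r} out of range (got {v})")
        third = [self.v3, self.k13, self.k31]
        present = [x is not None for x in third]
        if any(present) and not all(present):
            raise ValidationError("v3, k13, k31 must be given together")
        if all(present):
            for name in ("v3", "k13", "k31"):
                v = getattr(self, name)
                lo_ok = v > 0 if name == "v3" else v >= 0
                if not np.isfinite(v) or not lo_ok:
                    raise ValidationError(f"parameter {name!r} out of range")
        object.__setattr__(self, "fixed", frozenset(self.fixed))
        names = self.names
        unknown = self.fixed - set(names)
        if unknown:
            raise ValidationError(f"fixed mask names unknown parameters: {sorted(unknown)}")

    @property
    def has_peripheral(self) -> bool:
        return self.v3 is not None

    @property
    def names(self) -> tuple[str, ...]:
        return STRUCTURAL_NAMES_3 if self.has_peripheral else STRUCTURAL_NAMES_2

    def to_dict(self) -> dict:
        return {n: getattr(self, n) for n in self.names}

    def replace_values(self, **updates: float) -> "PKParameters":
        unknown = set(updates) - set(self.names)
        if unknown:
            raise ValidationError(f"unknown parameters: {sorted(unknown)}")
        return replace(self, **updates)


@dataclass(frozen=True)
class ScalingConvention:
    """Which rate constants are divided by ``f(t)`` as the volume expands."""

    scale_k21: str = "inverse_f"
    scale_k: str = "inverse_f"

    def __post_init__(self) -> None:
        for name in ("scale_k21", "scale_k"):
            v = getattr(self, name)
            if v not in ("inverse_f", "none"):
                raise ValidationError(f"{name} must be 'inverse_f' or 'none'")


@dataclass(frozen=True)
class StructuralModel:
    """A compartmental model plus its expansion function and scaling."""

    parameters: PKParameters
    expansion: ExpansionFunction = field(default_factory=ExpansionFunction.constant)
    scaling: ScalingConvention = field(default_factory=ScalingConvention)

    def __post_init__(self) -> None:
        if self.n_compartments == 3 and not self.parameters.has_peripheral:
            raise ValidationError("three-compartment model requires v3/k13/k31")

    @property
    def n_compartments(self) -> int:
        return 3 if self.parameters.has_peripheral else 2

    def with_parameters(self, **updates: float) -> "StructuralModel":
        """Copy with structural and/or expansion parameters replaced."""
        struct = {k: v for k, v in updates.items() if k in self.parameters.names}
        expans = {k: v for k, v in updates.items() if k not in struct}
        params = self.parameters.replace_values(**struct) if struct else self.parameters
        exp = self.expansion.replace(**expans) if expans else self.expansion
        return replace(self, parameters=params, expansion=exp)

    def to_dict(self) -> dict:
        d = {
            "n_compartments": self.n_compartments,
            "parameters": self.parameters.to_dict(),
            "fixed": sorted(self.parameters.fixed),
            "expansion": self.expansion.to_dict(),
            "scaling": {
                "scale_k21": self.scaling.scale_k21,
                "scale_k": self.scaling.scale_k,
            },
        }
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "StructuralModel":
        params = PKParameters(
            **d["parameters"], fixed=frozenset(d.get("fixed", ()))
        )
        exp = ExpansionFunction.from_dict(d["expansion"])
        scaling = ScalingConvention(**d.get("scaling", {}))
        return cls(params, exp, scaling)

    def rate_constants_at(self, t: float) -> dict:
        """Effective rate constants after applying the scaling convention."""
        f = self.expansion.evaluate(t)
        p = self.parameters
        k = p.k / f if self.scaling.scale_k == "inverse_f" else p.k
        k21 = p.k21 / f if self.scaling.scale_k21 == "inverse_f" else p.k21
        out = {"k": k, "k12": p.k12, "k21": k21}
        if p.has_peripheral:
            out.update(k13=p.k13, k31=p.k31)
        return out


@dataclass(frozen=True)
class DoseEvent:
    time: float
    amount: float
    compartment: int = 1

    def __post_init__(self) -> None:
        if self.time < 0:
            raise ValidationError("dose time must be >= 0")
        if self.amount <= 0:
            raise ValidationError("dose amount must be > 0")
        if self.compartment != 1:
            raise ValidationError("doses enter compartment 1 only")


@dataclass(frozen=True)
class DoseSchedule:
    """Ordered bolus dose events with optional regimen metadata."""

    times: np.ndarray
    amounts: np.ndarray
    regimen: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        times = np.asarray(self.times, dtype=float)
        amounts = np.asarray(self.amounts, dtype=float)
        if times.shape != amounts.shape or times.ndim != 1:
            raise ValidationError("times and amounts must be 1-D and congruent")
        if times.size and (np.any(np.diff(times) <= 0)):
            raise ValidationError("dose times must be strictly increasing")
        if np.any(times < 0) or np.any(amounts <= 0):
            raise ValidationError("dose times must be >= 0 and amounts > 0")
        object.__setattr__(self, "times", times)
        object.__setattr__(self, "amounts", amounts)

    def __len__(self) -> int:
        return int(self.times.size)

    @property
    def events(self) -> list[DoseEvent]:
        return [DoseEvent(t, a) for t, a in zip(self.times, self.amounts)]

    @property
    def total_dose(self) -> float:
        return float(self.amounts.sum())

    def truncate(self, t_max: float) -> "DoseSchedule":
        keep = self.times <= t_max
        return DoseSchedule(self.times[keep], self.amounts[keep], dict(self.regimen))


def build_schedule(
    dose_mg_per_kg: float,
    weeks: int,
    pattern: Iterable[int] = (1, 2, 3, 4, 5),
) -> DoseSchedule:
    """Weekly bolus regimen: doses at days ``7*w + d`` for in-week days ``d``.

    The default pattern (1..5) is once daily Monday through Friday with the
    first dose on day 1.
    """
    if dose_mg_per_kg <= 0:
        raise ValidationError("dose must be > 0")
    if weeks < 1:
        raise ValidationError("weeks must be >= 1")
    days = sorted(set(int(d) for d in pattern))
    if not days:
        raise ValidationError("weekday pattern must be non-empty")
    if any(d < 1 or d > 7 for d in days):
        raise ValidationError("weekday pattern entries must lie in 1..7")
    times = np.array(
        [7.0 * w + d for w in range(int(weeks)) for d in days], dtype=float
    )
    amounts = np.full(times.shape, float(dose_mg_per_kg))
    meta = {"dose_mg_per_kg": float(dose_mg_per_kg), "weeks": int(weeks), "pattern": days}
    return DoseSchedule(times, amounts, meta)


def cumulative_dose(schedule: DoseSchedule, t: float) -> float:
    """Total administered amount (mg/kg) from events with time <= t."""
    if t < 0:
        raise DomainError("t must be >= 0")
    return float(schedule.amounts[schedule.times <= t].sum())


def rhs(amounts: Sequence[float], t: float, model: StructuralModel) -> np.ndarray:
    """Time derivative of compartment amounts (reference implementation).

    ``amounts`` has length ``n_compartments``; elimination is from
    compartment 1 at the (possibly expansion-scaled) rate ``K(t)``.
    """
    a = np.asarray(amounts, dtype=float)
    if not np.all(np.isfinite(a)):
        raise SolverError(f"non-finite state at t={t}")
    rc = model.rate_constants_at(t)
    k13 = rc.get("k13", 0.0)
    k31 = rc.get("k31", 0.0)
    a3 = a[2] if a.size > 2 else 0.0
    d1 = -(rc["k"] + rc["k12"] + k13) * a[0] + rc["k21"] * a[1] + k31 * a3
    d2 = rc["k12"] * a[0] - rc["k21"] * a[1]
    if model.n_compartments == 3:
        d3 = k13 * a[0] - k31 * a3
        return np.array([d1, d2, d3])
    return np.array([d1, d2])


@dataclass
class SimulationResult:
    """Trajectories from :func:`simulate_profile` on the requested grid."""

    times: np.ndarray
    amounts: np.ndarray          # (n_times, n_compartments)
    eliminated: np.ndarray       # cumulative eliminated amount
    concentrations: np.ndarray   # (n_times, n_compartments)
    model: StructuralModel
    schedule: DoseSchedule

    @property
    def serum(self) -> np.ndarray:
        return self.concentrations[:, 0]

    @property
    def spleen(self) -> np.ndarray:
        return self.concentrations[:, 1]

    @property
    def administered(self) -> np.ndarray:
        """Cumulative administered dose at each output time (trough side)."""
        return np.array(
            [self.schedule.amounts[self.schedule.times < t].sum()
             if t in self.schedule.times else cumulative_dose(self.schedule, t)
             for t in self.times]
        )

    def mass_balance_error(self) -> float:
        """Max relative |administered - (in body + eliminated)| after first dose."""
        in_body = self.amounts.sum(axis=1) + self.eliminated
        admin = self.administered
        mask = admin > 0
        if not mask.any():
            return 0.0
        return float(np.max(np.abs(in_body[mask] - admin[mask]) / admin[mask]))

    def to_frame(self) -> pd.DataFrame:
        rows = []
        labels = ["serum", "spleen", "peripheral"][: self.amounts.shape[1]]
        for j, lab in enumerate(labels):
            rows.append(pd.DataFrame({
                "time": self.times,
                "compartment": lab,
                "amount": self.amounts[:, j],
                "concentration": self.concentrations[:, j],
            }))
        return pd.concat(rows, ignore_index=True)


def _volumes_at(model: StructuralModel, times: np.ndarray) -> np.ndarray:
    p = model.parameters
    f = np.asarray(model.expansion.evaluate(times), dtype=float)
    vols = [np.full_like(f, p.v1), p.v2 * f]
    if p.has_peripheral:
        vols.append(np.full_like(f, p.v3))
    return np.stack(vols, axis=1)


def simulate_profile(
    model: StructuralModel,
    schedule: DoseSchedule,
    times: Sequence[float],
    dt_max: float = 0.02,
) -> SimulationResult:
    """Integrate the model under a dose schedule and report trajectories.

    Doses are instantaneous boluses into compartment 1.  An output time
    that coincides with a dose time is evaluated *before* the dose
    (trough convention).  ``dt_max`` bounds the RK4 step length.
    """
    t_out = np.asarray(times, dtype=float)
    if t_out.ndim != 1 or t_out.size == 0:
        raise ValidationError("times must be a non-empty 1-D sequence")
    if np.any(np.diff(t_out) < 0):
        raise ValidationError("times must be sorted ascending")
    if np.any(t_out < 0):
        raise DomainError("times must be >= 0")

    # bound the RK4 step by the fastest unscaled rate so the fixed-step
    # scheme stays stable even for extreme parameter proposals
    p = model.parameters
    rate = p.k + p.k12 + p.k21 + (p.k13 or 0.0) + (p.k31 or 0.0)
    if rate > 0:
        dt_max = min(dt_max, 1.0 / rate)
    if t_out[-1] / dt_max > 1e5:
        raise SolverError(
            f"rate constants too fast for the step budget (sum {rate:.3g}/day "
            f"over [0, {t_out[-1]}])"
        )

    t_end = t_out[-1]
    d_times = schedule.times[schedule.times <= t_end]
    d_amts = schedule.amounts[schedule.times <= t_end]

    mesh = np.unique(np.concatenate([[0.0], d_times, t_out]))
    bolus = np.zeros_like(mesh)
    idx = np.searchsorted(mesh, d_times)
    bolus[idx] = d_amts
    rec = np.full(mesh.shape, -1, dtype=np.int64)
    out_idx = np.searchsorted(mesh, np.unique(t_out))
    rec[out_idx] = np.arange(out_idx.size)

    out = np.empty((out_idx.size, 4), dtype=float)
    status = integrate_mesh(
        mesh, bolus, rec,
        model.expansion.kind_code, *model.expansion.kernel_params,
        model.parameters.k, model.parameters.k12, model.parameters.k21,
        model.parameters.k13 or 0.0, model.parameters.k31 or 0.0,
        1 if model.scaling.scale_k == "inverse_f" else 0,
        1 if model.scaling.scale_k21 == "inverse_f" else 0,
        float(dt_max), out,
    )
    if status != 0:
        raise SolverError(
            f"integration produced non-finite state for model with expansion "
            f"{model.expansion.kind!r} on [0, {t_end}]"
        )

    # map unique output rows back to the (possibly duplicated) request grid
    uniq = np.unique(t_out)
    row_of = {t: i for i, t in enumerate(uniq)}
    rows = np.array([row_of[t] for t in t_out])
    n_cmt = model.n_compartments
    amounts = out[rows, :n_cmt]
    eliminated = out[rows, 3]
    conc = amounts / _volumes_at(model, t_out)
    return SimulationResult(t_out, amounts, eliminated, conc, model, schedule)


def analytic_two_compartment(
    params: PKParameters,
    bolus: float,
    times: Sequence[float],
    dose_times: Sequence[float] | None = None,
) -> np.ndarray:
    """Closed-form concentrations for the constant-volume two-compartment model.

    Bi-exponential solution via the eigenvalues of the 2x2 rate matrix
    (``lambda^2 + (K+K12+K21)*lambda + K*K21 = 0``).  With ``dose_times``
    given, identical boluses are superposed (the system is linear) using
    the trough convention of :func:`simulate_profile`: an output time equal
    to a dose time excludes that dose.  Without ``dose_times`` a single
    bolus at t=0 is included at t=0 (``C1(0) = bolus/V1``).
    Returns an array of shape ``(n_times, 2)`` with columns C1, C2.
    """
    t = np.asarray(times, dtype=float)
    if np.any(t < 0):
        raise DomainError("times must be >= 0")
    k, k12, k21 = params.k, params.k12, params.k21
    tr = -(k + k12 + k21)
    det = k * k21
    disc = tr * tr - 4.0 * det
    d_times = np.asarray([0.0] if dose_times is None else dose_times, dtype=float)

    dt = t[:, None] - d_times[None, :]
    active = dt >= 0 if dose_times is None else dt > 0
    dtc = np.where(active, dt, 0.0)

    if disc > 1e-12 * max(tr * tr, 1.0):
        s = np.sqrt(disc)
        l1, l2 = (tr + s) / 2.0, (tr - s) / 2.0
        e1, e2 = np.exp(l1 * dtc), np.exp(l2 * dtc)
        a1 = ((l1 + k21) * e1 - (l2 + k21) * e2) / (l1 - l2)
        a2 = k12 * (e1 - e2) / (l1 - l2)
    else:
        # (near-)repeated eigenvalues: fall back to the matrix exponential
        m = np.array([[-(k + k12), k21], [k12, -k21]])
        a1 = np.zeros_like(dtc)
        a2 = np.zeros_like(dtc)
        for val in np.unique(dtc):
            ph = expm(m * val)
            sel = dtc == val
            a1[sel] = ph[0, 0]
            a2[sel] = ph[1, 0]
    a1 = np.where(active, a1, 0.0).sum(axis=1) * bolus
    a2 = np.where(active, a2, 0.0).sum(axis=1) * bolus
    return np.stack([a1 / params.v1, a2 / params.v2], axis=1)
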