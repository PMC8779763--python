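"""Synthetic study generation.

Emulates the statistical structure of the destructive-sampling mouse
experiment: animals dosed 25 mg/kg on weekdays for 20 weeks, small cohorts
euthanized at a handful of sampling days, serum and tissue concentrations
read at trough with multiplicative noise, and a per-animal spleen weight
tied to the expansion function.  Everything is seed-reproducible so the
whole pipeline is testable without any external data.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Mapping

import numpy as np
import pandas as pd

from .exceptions import EmptyDatasetError, ValidationError
from .expansion import ETA_PARAMS, ExpansionFunction
from .model_core import DoseSchedule, StructuralModel, build_schedule, simulate_profile

__all__ = [
    "StudyDesign",
    "Observation",
    "StudyDataset",
    "generate_study",
    "spleen_weight",
    "truncate_study",
    "default_schedule",
    "reference_model",
    "transition_model",
]

STREAMS = ("serum", "spleen")


def default_schedule() -> DoseSchedule:
    """The study regimen: 25 mg/kg, Monday-Friday, 20 weeks."""
    return build_schedule(25.0, 20)


def reference_model() -> StructuralModel:
    """Study-like generating truth with a moderate expansion ceiling.

    Rate constants follow the published two-compartment estimates; the
    expansion ceiling is reduced (e^2.5 ~ 12-fold) so that trough tissue
    concentrations rise strictly across the 20 dosing weeks under the
    default scaling convention.  Used as the default demo/test truth.
    """
    from .model_core import PKParameters

    return StructuralModel(
        PKParameters(
            v1=2.43, v2=0.00708, k=0.229, k12=0.183, k21=3.36,
            fixed=frozenset({"v1", "k12"}),
        ),
        ExpansionFunction.hill_exp(emax=2.5, t50=49.0, hill=3.71),
    )


def transition_model() -> StructuralModel:
    """Generating truth with the full published expansion ceiling.

    Uses the complete exponentiated-Hill estimates (e^6.99 ~ 1086-fold
    plateau) with serum-side elimination left unscaled, producing a
    pronounced rise-then-dilution pattern in tissue concentration that a
    constant-volume model cannot track.  Used for model-selection and
    misfit-pattern studies.
    """
    from .model_core import PKParameters, ScalingConvention

    return StructuralModel(
        PKParameters(
            v1=2.43, v2=0.00708, k=0.229, k12=0.183, k21=3.36,
            fixed=frozenset({"v1", "k12"}),
        ),
        ExpansionFunction.hill_exp(emax=6.99, t50=49.0, hill=3.71),
        ScalingConvention(scale_k="none"),
    )


@dataclass(frozen=True)
class StudyDesign:
    """Destructive-sampling design parameters.

    ``animals_per_day`` applies to every sampling day except those listed
    in ``cohort_overrides`` (the default drops day 14 to two animals).
    Spleen weight follows the expansion curve between ``spleen_w0_g`` and
    ``spleen_wmax_g`` unless ``fixed_spleen_weight`` is set.
    """

    sampling_days: tuple = (7.0, 14.0, 28.0, 56.0, 84.0, 114.0, 140.0)
    animals_per_day: int = 3
    # None -> the study default (two animals at day 14, when sampled)
    cohort_overrides: Mapping[float, int] | None = None
    streams: tuple = STREAMS
    trough: bool = True
    body_weight_kg: float = 0.02
    spleen_w0_g: float = 0.1
    spleen_wmax_g: float = 0.5
    fixed_spleen_weight: bool = False

    def __post_init__(self) -> None:
        if not self.sampling_days:
            raise ValidationError("design needs at least one sampling day")
        days = tuple(float(d) for d in sorted(self.sampling_days))
        if any(d <= 0 for d in days):
            raise ValidationError("sampling days must be > 0")
        object.__setattr__(self, "sampling_days", days)
        if self.animals_per_day < 1:
            raise ValidationError("animals_per_day must be >= 1")
        if self.cohort_overrides is None:
            object.__setattr__(
                self, "cohort_overrides", {14.0: 2} if 14.0 in days else {}
            )
        for d, n in self.cohort_overrides.items():
            if float(d) not in days:
                raise ValidationError(f"override day {d} not a sampling day")
            if n < 1:
                raise ValidationError("cohort sizes must be >= 1")
        unknown = set(self.streams) - set(STREAMS)
        if unknown:
            raise ValidationError(f"unknown streams: {sorted(unknown)}")
        if self.body_weight_kg <= 0:
            raise ValidationError("body weight must be > 0")
        if self.spleen_wmax_g < self.spleen_w0_g:
            raise ValidationError("spleen_wmax_g must be >= spleen_w0_g")

    def n_animals_at(self, day: float) -> int:
        return int(self.cohort_overrides.get(float(day), self.animals_per_day))

    @property
    def n_animals(self) -> int:
        return sum(self.n_animals_at(d) for d in self.sampling_days)


@dataclass(frozen=True)
class Observation:
    """One concentration record from one animal at its sampling time."""

    animal: str
    time: float
    stream: str
    conc: float  # ug/mL == mg/L

    def __post_init__(self) -> None:
        if self.stream not in STREAMS:
            raise ValidationError(f"unknown stream {self.stream!r}")
        if self.conc <= 0:
            raise ValidationError("concentration must be > 0")
        if self.time < 0:
            raise ValidationError("time must be >= 0")


_OBS_COLUMNS = ["animal", "time", "stream", "conc"]


@dataclass
class StudyDataset:
    """Observations + dose schedule + per-animal spleen weights.

    ``observations`` columns: animal, time, stream, conc.
    ``weights`` columns: animal, time, weight_g (one row per animal).
    """

    observations: pd.DataFrame
    schedule: DoseSchedule
    weights: pd.DataFrame | None = None
    design: StudyDesign | None = None
    provenance: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        obs = self.observations
        missing = set(_OBS_COLUMNS) - set(obs.columns)
        if missing:
            raise ValidationError(f"observations missing columns {sorted(missing)}")
        if len(obs) == 0:
            raise EmptyDatasetError("dataset has no observations")
        if (obs["conc"] <= 0).any():
            raise ValidationError("all concentrations must be > 0")
        bad = set(obs["stream"]) - set(STREAMS)
        if bad:
            raise ValidationError(f"unknown streams {sorted(bad)}")
        # destructive design: each animal appears at exactly one time
        per_animal = obs.groupby("animal")["time"].nunique()
        if (per_animal > 1).any():
            offenders = per_animal[per_animal > 1].index.tolist()
            raise ValidationError(
                f"animals observed at multiple times: {offenders}"
            )
        self.observations = obs.reset_index(drop=True)

    @property
    def n_obs(self) -> int:
        return len(self.observations)

    @property
    def animals(self) -> list[str]:
        return list(dict.fromkeys(self.observations["animal"]))

    @property
    def sampling_times(self) -> np.ndarray:
        return np.unique(self.observations["time"].to_numpy(dtype=float))

    def animal_day(self) -> pd.Series:
        """Map animal id -> its (single) sampling time."""
        return self.observations.groupby("animal", sort=False)["time"].first()

    def equals(self, other: "StudyDataset") -> bool:
        """Exact equality of observations, schedule and weights."""
        a = self.observations[_OBS_COLUMNS].reset_index(drop=True)
        b = other.observations[_OBS_COLUMNS].reset_index(drop=True)
        if not a.equals(b):
            return False
        if not (
            np.array_equal(self.schedule.times, other.schedule.times)
            and np.array_equal(self.schedule.amounts, other.schedule.amounts)
        ):
            return False
        if (self.weights is None) != (other.weights is None):
            return False
        if self.weights is not None:
            wa = self.weights.reset_index(drop=True)
            wb = other.weights.reset_index(drop=True)
            if not wa.equals(wb):
                return False
        return True


def spleen_weight(
    t,
    w0_g: float,
    wmax_g: float,
    expansion: ExpansionFunction,
):
    """Spleen mass (g) at time t, tied to the expansion curve.

    For a sigmoid expansion, ``W(t) = W0 + (Wmax - W0)*(f(t)-1)/(f(inf)-1)``
    so the organ grows along the same sigmoid; non-sigmoid kinds return the
    constant baseline weight.
    """
    if wmax_g < w0_g:
        raise ValidationError("wmax_g must be >= w0_g")
    t_arr = np.asarray(t, dtype=float)
    if not expansion.is_sigmoid:
        out = np.full_like(t_arr, float(w0_g))
    else:
        plateau = expansion.plateau
        frac = (np.asarray(expansion.evaluate(t_arr)) - 1.0) / (plateau - 1.0)
        out = w0_g + (wmax_g - w0_g) * frac
    if np.ndim(t) == 0:
        return float(out)
    return out


def _apply_etas(
    expansion: ExpansionFunction,
    omega2: Mapping[str, float],
    rng: np.random.Generator,
) -> ExpansionFunction:
    """Log-normal per-animal perturbation of designated expansion parameters."""
    updates = {}
    for name in ETA_PARAMS[expansion.kind]:
        var = float(omega2.get(name, 0.0))
        eta = rng.normal(0.0, np.sqrt(var)) if var > 0 else 0.0
        if eta != 0.0:
            updates[name] = expansion.params[name] * np.exp(eta)
    return expansion.replace(**updates) if updates else expansion


def generate_study(
    model: StructuralModel,
    design: StudyDesign | None = None,
    sigma_serum: float = 0.1,
    sigma_spleen: float = 0.1,
    omega2: Mapping[str, float] | None = None,
    seed: int = 0,
    schedule: DoseSchedule | None = None,
    dt_max: float = 0.05,
) -> StudyDataset:
    """Simulate a destructive-sampling study from a structural model.

    Each animal gets log-normal random effects on the designated expansion
    parameters (``omega2`` maps parameter name to variance), its trajectory
    is read at trough on its single sampling day, and multiplicative noise
    ``obs = pred*(1+eps)``, ``eps ~ N(0, sigma^2)``, is applied per stream;
    non-positive draws are rejected and resampled so observations stay
    positive without clipping bias.
    """
    design = design or StudyDesign()
    schedule = schedule or default_schedule()
    omega2 = dict(omega2 or {})
    if sigma_serum < 0 or sigma_spleen < 0:
        raise ValidationError("noise SDs must be >= 0")
    horizon = 7.0 * schedule.regimen.get("weeks", 0) or float(schedule.times[-1]) + 7.0
    for d in design.sampling_days:
        if d > horizon:
            raise ValidationError(
                f"sampling day {d} outside the dosing horizon {horizon}"
            )

    rng = np.random.default_rng(seed)
    sigma = {"serum": float(sigma_serum), "spleen": float(sigma_spleen)}
    has_eta = any(v > 0 for v in omega2.values())

    shared = None
    if not has_eta:
        days = np.asarray(design.sampling_days, dtype=float)
        sim = simulate_profile(model, schedule, days, dt_max=dt_max)
        shared = {d: (sim.serum[i], sim.spleen[i]) for i, d in enumerate(days)}

    obs_rows = []
    weight_rows = []
    counter = 0
    for day in design.sampling_days:
        for rep in range(design.n_animals_at(day)):
            counter += 1
            animal = f"M{counter:03d}"
            if has_eta:
                exp_i = _apply_etas(model.expansion, omega2, rng)
                model_i = replace(model, expansion=exp_i)
                sim = simulate_profile(model_i, schedule, [day], dt_max=dt_max)
                preds = {"serum": sim.serum[0], "spleen": sim.spleen[0]}
                exp_for_weight = exp_i
            else:
                preds = dict(zip(("serum", "spleen"), shared[day]))
                exp_for_weight = model.expansion
            for stream in design.streams:
                pred = preds[stream]
                s = sigma[stream]
                if s == 0:
                    conc = pred
                else:
                    conc = -1.0
                    while conc <= 0:
                        conc = pred * (1.0 + rng.normal(0.0, s))
                obs_rows.append((animal, float(day), stream, float(conc)))
            if design.fixed_spleen_weight:
                w = design.spleen_w0_g
            else:
                w = spleen_weight(
                    day, design.spleen_w0_g, design.spleen_wmax_g, exp_for_weight
                )
            weight_rows.append((animal, float(day), float(w)))

    observations = pd.DataFrame(obs_rows, columns=_OBS_COLUMNS)
    weights = pd.DataFrame(weight_rows, columns=["animal", "time", "weight_g"])
    provenance = {
        "generator": "adaptvd.synthetic_data.generate_study",
        "seed": int(seed),
        "sigma_serum": sigma["serum"],
        "sigma_spleen": sigma["spleen"],
        "omega2": omega2,
        "model": model.to_dict(),
        "body_weight_kg": design.body_weight_kg,
    }
    return StudyDataset(observations, schedule, weights, design, provenance)


def truncate_study(dataset: StudyDataset, t_max: float) -> StudyDataset:
    """Restrict a study to observations and doses at or before ``t_max``."""
    if t_max <= 0:
        raise ValidationError("t_max must be > 0")
    obs = dataset.observations[dataset.observations["time"] <= t_max]
    if len(obs) == 0:
        raise EmptyDatasetError(f"no observations at or before t={t_max}")
    weights = None
    if dataset.weights is not None:
        weights = dataset.weights[dataset.weights["time"] <= t_max].reset_index(
            drop=True
        )
    prov = dict(dataset.provenance)
    prov["truncated_at"] = float(t_max)
    return StudyDataset(
        obs.reset_index(drop=True),
        dataset.schedule.truncate(t_max),
        weights,
        dataset.design,
        prov,
    )
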