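"""Volume-expansion functions.

An :class:`ExpansionFunction` is a dimensionless, non-decreasing multiplier
``f(t)`` applied to the baseline volume of the tissue compartment.  Five
families are provided:

``constant``
    ``f(t) = 1`` — the fixed-volume base model.
``linear``
    ``f(t) = 1 + X*t`` with expansion rate ``X`` (1/day).
``hill_exp``
    Exponentiated Hill curve ``f(t) = exp(Emax * t^H / (T50^H + t^H))``
    with log-fold ceiling ``Emax``, half-time ``T50`` (days) and Hill
    coefficient ``H``.  Plateau ``exp(Emax)``.
``logistic``
    Baseline-normalized logistic with fold ceiling ``M1``, steepness ``M2``
    (1/day) and inflection time ``M3`` (days).  With
    ``L(t) = 1/(1+exp(-M2*(t-M3)))``,
    ``f(t) = 1 + (M1-1)*(L(t)-L(0))/(1-L(0))``.  Plateau ``M1``.
``sqrt_sigmoid``
    Baseline-normalized rational square-root sigmoid with fold ceiling
    ``B1``, inflection time ``B2`` (days) and squared width ``B3`` (days^2).
    With ``S(t) = (1 + (t-B2)/sqrt((t-B2)^2+B3))/2``,
    ``f(t) = 1 + (B1-1)*(S(t)-S(0))/(1-S(0))``.  Plateau ``B1``.

All forms are normalized so that ``f(0) = 1`` exactly, and every family is
non-decreasing on ``t >= 0`` for admissible parameters.  Times are in days
throughout.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Mapping

import numpy as np
from scipy.optimize import brentq, minimize_scalar

from .exceptions import DomainError, UnsupportedKindError, ValidationError

__all__ = [
    "ExpansionFunction",
    "KINDS",
    "SIGMOID_KINDS",
]

KINDS = ("constant", "linear", "hill_exp", "logistic", "sqrt_sigmoid")
SIGMOID_KINDS = ("hill_exp", "logistic", "sqrt_sigmoid")

#: parameter names per kind, in kernel order
PARAM_NAMES: dict[str, tuple[str, ...]] = {
    "constant": (),
    "linear": ("x",),
    "hill_exp": ("emax", "t50", "hill"),
    "logistic": ("m1", "m2", "m3"),
    "sqrt_sigmoid": ("b1", "b2", "b3"),
}

#: integer codes used by the compiled ODE kernel
KIND_CODES = {k: i for i, k in enumerate(KINDS)}

# parameters that must be strictly positive (others only non-negative)
_STRICTLY_POSITIVE = {"t50", "hill", "b3"}
# fold-ceiling parameters that must be >= 1 for monotonicity
_CEILINGS = {"m1", "b1"}

# designated (ceiling, rate) parameters that receive between-subject
# variability in the synthetic generator
ETA_PARAMS: dict[str, tuple[str, ...]] = {
    "constant": (),
    "linear": ("x",),
    "hill_exp": ("emax", "t50"),
    "logistic": ("m1", "m2"),
    "sqrt_sigmoid": ("b1", "b2"),
}


def _logistic_L(t, m2, m3):
    return 1.0 / (1.0 + np.exp(-m2 * (t - m3)))


def _sqrt_S(t, b2, b3):
    u = t - b2
    return 0.5 * (1.0 + u / np.sqrt(u * u + b3))


@dataclass(frozen=True)
class ExpansionFunction:
    """A parameterized fold-expansion curve ``f(t)``.

    Parameters
    ----------
    kind : str
        One of ``constant``, ``linear``, ``hill_exp``, ``logistic``,
        ``sqrt_sigmoid``.
    params : mapping
        Named scalar parameters for the kind (see module docstring).
    """

    kind: str
    params: Mapping[str, float] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.kind not in KINDS:
            raise ValidationError(f"unknown expansion kind {self.kind!r}")
        names = PARAM_NAMES[self.kind]
        given = dict(self.params)
        extra = set(given) - set(names)
        if extra:
            raise ValidationError(
                f"unexpected parameters for kind {self.kind!r}: {sorted(extra)}"
            )
        missing = set(names) - set(given)
        if missing:
            raise ValidationError(
                f"missing parameters for kind {self.kind!r}: {sorted(missing)}"
            )
        for name in names:
            v = float(given[name])
            if not math.isfinite(v):
                raise ValidationError(f"parameter {name!r} must be finite")
            if v < 0:
                raise ValidationError(f"parameter {name!r} must be non-negative")
            if name in _STRICTLY_POSITIVE and v == 0:
                raise ValidationError(f"parameter {name!r} must be > 0")
            if name in _CEILINGS and v < 1:
                raise ValidationError(
                    f"fold ceiling {name!r} must be >= 1 (got {v})"
                )
            given[name] = v
        object.__setattr__(self, "params", given)

    # -- constructors -------------------------------------------------

    @classmethod
    def constant(cls) -> "ExpansionFunction":
        return cls("constant")

    @classmethod
    def linear(cls, x: float) -> "ExpansionFunction":
        return cls("linear", {"x": x})

    @classmethod
    def hill_exp(cls, emax: float, t50: float, hill: float) -> "ExpansionFunction":
        return cls("hill_exp", {"emax": emax, "t50": t50, "hill": hill})

    @classmethod
    def logistic(cls, m1: float, m2: float, m3: float) -> "ExpansionFunction":
        return cls("logistic", {"m1": m1, "m2": m2, "m3": m3})

    @classmethod
    def sqrt_sigmoid(cls, b1: float, b2: float, b3: float) -> "ExpansionFunction":
        return cls("sqrt_sigmoid", {"b1": b1, "b2": b2, "b3": b3})

    # -- serialization ------------------------------------------------

    def to_dict(self) -> dict:
        return {"kind": self.kind, **self.params}

    @classmethod
    def from_dict(cls, d: Mapping) -> "ExpansionFunction":
        d = dict(d)
        kind = d.pop("kind")
        return cls(kind, d)

    def replace(self, **updates: float) -> "ExpansionFunction":
        """Return a copy with some parameters replaced."""
        p = dict(self.params)
        for k, v in updates.items():
            if k not in p:
                raise ValidationError(f"{self.kind!r} has no parameter {k!r}")
            p[k] = v
        return ExpansionFunction(self.kind, p)

    # -- kernel plumbing ----------------------------------------------

    @property
    def kind_code(self) -> int:
        return KIND_CODES[self.kind]

    @property
    def kernel_params(self) -> tuple[float, float, float]:
        """Parameters padded to three scalars, in kernel order."""
        vals = [self.params[n] for n in PARAM_NAMES[self.kind]]
        while len(vals) < 3:
            vals.append(0.0)
        return tuple(vals)

    # -- properties ---------------------------------------------------

    @property
    def is_sigmoid(self) -> bool:
        return self.kind in SIGMOID_KINDS

    @property
    def plateau(self) -> float:
        """Limit of ``f(t)`` as ``t -> inf`` (inf for linear with X>0)."""
        p = self.params
        if self.kind == "constant":
            return 1.0
        if self.kind == "linear":
            return math.inf if p["x"] > 0 else 1.0
        if self.kind == "hill_exp":
            return math.exp(p["emax"])
        if self.kind == "logistic":
            return p["m1"]
        return p["b1"]

    def _time_scale(self) -> float:
        p = self.params
        if self.kind == "hill_exp":
            return p["t50"]
        if self.kind == "logistic":
            return max(p["m3"], 1.0 / max(p["m2"], 1e-6))
        if self.kind == "sqrt_sigmoid":
            return max(p["b2"], math.sqrt(p["b3"]))
        return 1.0

    # -- evaluation ---------------------------------------------------

    def __call__(self, t):
        return self.evaluate(t)

    def evaluate(self, t):
        """Evaluate ``f(t)``; accepts scalars or arrays, ``t >= 0``."""
        t_arr = np.asarray(t, dtype=float)
        if np.any(t_arr < 0):
            raise DomainError("expansion functions are defined on t >= 0")
        p = self.params
        if self.kind == "constant":
            out = np.ones_like(t_arr)
        elif self.kind == "linear":
            out = 1.0 + p["x"] * t_arr
        elif self.kind == "hill_exp":
            th = t_arr ** p["hill"]
            out = np.exp(p["emax"] * th / (p["t50"] ** p["hill"] + th))
        elif self.kind == "logistic":
            L0 = _logistic_L(0.0, p["m2"], p["m3"])
            L = _logistic_L(t_arr, p["m2"], p["m3"])
            if L0 >= 1.0:  # degenerate: curve already saturated at t=0
                out = np.ones_like(t_arr)
            else:
                out = 1.0 + (p["m1"] - 1.0) * (L - L0) / (1.0 - L0)
        else:  # sqrt_sigmoid
            S0 = _sqrt_S(0.0, p["b2"], p["b3"])
            S = _sqrt_S(t_arr, p["b2"], p["b3"])
            out = 1.0 + (p["b1"] - 1.0) * (S - S0) / (1.0 - S0)
        if np.ndim(t) == 0:
            return float(out)
        return out

    def derivative(self, t):
        """Analytic ``df/dt`` (1/day); scalar or array input, ``t >= 0``."""
        t_arr = np.asarray(t, dtype=float)
        if np.any(t_arr < 0):
            raise DomainError("expansion functions are defined on t >= 0")
        p = self.params
        if self.kind == "constant":
            out = np.zeros_like(t_arr)
        elif self.kind == "linear":
            out = np.full_like(t_arr, p["x"])
        elif self.kind == "hill_exp":
            h, t50, emax = p["hill"], p["t50"], p["emax"]
            th = t_arr ** h
            denom = (t50 ** h + th) ** 2
            with np.errstate(divide="ignore", invalid="ignore"):
                g = emax * h * t50 ** h * t_arr ** (h - 1.0) / denom
            f = np.exp(emax * th / (t50 ** h + th))
            out = f * g
        elif self.kind == "logistic":
            m1, m2, m3 = p["m1"], p["m2"], p["m3"]
            L0 = _logistic_L(0.0, m2, m3)
            if L0 >= 1.0:
                out = np.zeros_like(t_arr)
            else:
                L = _logistic_L(t_arr, m2, m3)
                out = (m1 - 1.0) / (1.0 - L0) * m2 * L * (1.0 - L)
        else:  # sqrt_sigmoid
            b1, b2, b3 = p["b1"], p["b2"], p["b3"]
            S0 = _sqrt_S(0.0, b2, b3)
            u = t_arr - b2
            dS = 0.5 * b3 / (u * u + b3) ** 1.5
            out = (b1 - 1.0) / (1.0 - S0) * dS
        if np.ndim(t) == 0:
            return float(out)
        return out

    # -- landmark times -----------------------------------------------

    def inflection_time(self, horizon: float | None = None) -> float:
        """Time of maximum expansion rate (argmax of the derivative).

        Only defined for the sigmoid kinds.  The symmetric families
        return their inflection parameter exactly; ``hill_exp`` is
        located numerically (coarse grid + bounded refinement).
        """
        if not self.is_sigmoid:
            raise UnsupportedKindError(
                f"inflection_time is undefined for kind {self.kind!r}"
            )
        p = self.params
        if self.kind == "sqrt_sigmoid":
            return p["b2"]
        if self.kind == "logistic":
            return p["m3"]
        if horizon is None:
            horizon = 10.0 * self._time_scale()
        grid = np.linspace(0.0, horizon, 20001)
        d = self.derivative(grid)
        d = np.where(np.isfinite(d), d, -np.inf)
        i = int(np.argmax(d))
        lo = grid[max(i - 1, 0)]
        hi = grid[min(i + 1, grid.size - 1)]
        res = minimize_scalar(
            lambda t: -self.derivative(float(t)),
            bounds=(lo, hi),
            method="bounded",
            options={"xatol": 1e-8},
        )
        return float(res.x)

    def time_to_fraction_of_plateau(self, q: float) -> float:
        """Smallest t with ``f(t) - 1 = q * (plateau - 1)``.

        Only defined for sigmoid kinds and ``0 < q < 1``; solved by
        bracketed root finding to 1e-6-day tolerance.
        """
        if not self.is_sigmoid:
            raise UnsupportedKindError(
                f"time_to_fraction_of_plateau is undefined for kind {self.kind!r}"
            )
        if not 0.0 < q < 1.0:
            raise DomainError("q must lie strictly in (0, 1)")
        target = q * (self.plateau - 1.0)

        def g(t: float) -> float:
            return self.evaluate(t) - 1.0 - target

        hi = 10.0 * self._time_scale()
        while g(hi) < 0:
            hi *= 2.0
            if hi > 1e12:
                raise DomainError("plateau fraction not reached numerically")
        return float(brentq(g, 0.0, hi, xtol=1e-6))
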