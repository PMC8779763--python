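"""Maximum-likelihood estimation, model comparison and bootstrap.

The objective is an extended-least-squares normal likelihood with
proportional (multiplicative) error, pooled naively across animals:

    OFV = sum_i [ log(2*pi) + log(sigma_s^2 * pred_i^2)
                  + (obs_i - pred_i)^2 / (sigma_s^2 * pred_i^2) ]

with a separate ``sigma`` per observation stream (serum, spleen).  By
default the stream SDs are profiled out analytically at each objective
evaluation; they still count toward the AIC parameter total.  Structural
and expansion parameters are optimized in log space (enforcing positivity)
by multistart Nelder-Mead.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import optimize

from .exceptions import (
    FitFailureError,
    PredictionError,
    SolverError,
    UndefinedStatisticError,
    ValidationError,
)
from .expansion import PARAM_NAMES
from .model_core import StructuralModel, simulate_profile
from .synthetic_data import StudyDataset

__all__ = [
    "ErrorModel",
    "RandomEffects",
    "FitResult",
    "BootstrapSummary",
    "neg2loglik",
    "fit_model",
    "aic",
    "r_squared",
    "weighted_residuals",
    "bootstrap",
    "compare_models",
]

_LOG_2PI = math.log(2.0 * math.pi)
_SIGMA2_FLOOR = 1e-12
_PENALTY = 1e12


@dataclass(frozen=True)
class ErrorModel:
    """Proportional error SDs per observation stream (dimensionless)."""

    sigma_serum: float
    sigma_spleen: float

    def __post_init__(self) -> None:
        if self.sigma_serum <= 0 or self.sigma_spleen <= 0:
            raise ValidationError("error SDs must be > 0")

    def sigma_for(self, stream: str) -> float:
        return self.sigma_serum if stream == "serum" else self.sigma_spleen


@dataclass(frozen=True)
class RandomEffects:
    """Variances of log-normal between-subject effects on expansion parameters."""

    omega2: Mapping[str, float] = field(default_factory=dict)

    def __post_init__(self) -> None:
        for k, v in self.omega2.items():
            if v < 0:
                raise ValidationError(f"omega2[{k!r}] must be >= 0")


@dataclass
class BootstrapSummary:
    """Percentile CIs / SD / CV% of estimates over bootstrap resamples."""

    table: pd.DataFrame  # index: parameter; columns: mean, sd, cv_percent, ci_lo, ci_hi
    n_reps: int
    n_failed: int
    seed: int
    warning: bool = False  # set when >20% of refits failed

    @property
    def samples(self) -> pd.DataFrame:
        return self._samples

    def to_dict(self) -> dict:
        return {
            "n_reps": self.n_reps,
            "n_failed": self.n_failed,
            "seed": self.seed,
            "warning": self.warning,
            "table": self.table.to_dict(orient="index"),
        }


@dataclass
class FitResult:
    """Outcome of a maximum-likelihood fit."""

    model: StructuralModel
    estimates: dict
    cv_percent: dict
    fixed: dict
    sigma: dict
    ofv: float
    aic: float
    r_squared: float
    residuals: pd.DataFrame
    n_obs: int
    p: int
    converged: bool
    n_starts: int
    start_ofvs: list
    cv_source: str = "hessian"
    bootstrap: BootstrapSummary | None = None

    def to_dict(self) -> dict:
        d = {
            "estimates": self.estimates,
            "cv_percent": self.cv_percent,
            "fixed": self.fixed,
            "sigma": self.sigma,
            "ofv": self.ofv,
            "aic": self.aic,
            "r_squared": self.r_squared,
            "n_obs": self.n_obs,
            "p": self.p,
            "converged": self.converged,
            "n_starts": self.n_starts,
            "start_ofvs": self.start_ofvs,
            "cv_source": self.cv_source,
            "model": self.model.to_dict(),
        }
        if self.bootstrap is not None:
            d["bootstrap"] = self.bootstrap.to_dict()
        return d


# ---------------------------------------------------------------------------
# predictions and likelihood


def predict(
    dataset: StudyDataset, model: StructuralModel, dt_max: float = 0.05
) -> np.ndarray:
    """Model prediction aligned with each observation row."""
    obs = dataset.observations
    times = np.unique(obs["time"].to_numpy(dtype=float))
    sim = simulate_profile(model, dataset.schedule, times, dt_max=dt_max)
    lut = {
        ("serum", t): sim.serum[i] for i, t in enumerate(times)
    }
    lut.update({("spleen", t): sim.spleen[i] for i, t in enumerate(times)})
    return np.array(
        [lut[(s, t)] for s, t in zip(obs["stream"], obs["time"].astype(float))]
    )


def neg2loglik(
    dataset: StudyDataset,
    model: StructuralModel,
    error: ErrorModel,
    dt_max: float = 0.05,
) -> float:
    """-2 log-likelihood (OFV) under the proportional error model."""
    obs = dataset.observations
    pred = predict(dataset, model, dt_max=dt_max)
    if np.any(pred <= 0):
        i = int(np.argmax(pred <= 0))
        row = obs.iloc[i]
        raise PredictionError(
            f"non-positive prediction for animal {row['animal']} "
            f"({row['stream']}, t={row['time']})"
        )
    y = obs["conc"].to_numpy(dtype=float)
    sig = np.array([error.sigma_for(s) for s in obs["stream"]])
    var = sig**2 * pred**2
    return float(np.sum(_LOG_2PI + np.log(var) + (y - pred) ** 2 / var))


def _profiled_ofv(y, pred, stream_mask):
    """ELS objective with stream sigmas profiled out analytically.

    Returns (ofv, sigma_serum, sigma_spleen).  For each stream the
    optimal ``sigma^2`` is the mean squared relative residual.
    """
    ofv = 2.0 * float(np.sum(np.log(pred))) + len(y) * _LOG_2PI
    sigmas = []
    for mask in stream_mask:
        n = int(mask.sum())
        if n == 0:
            sigmas.append(float("nan"))
            continue
        r = (y[mask] - pred[mask]) / pred[mask]
        s2 = max(float(np.mean(r * r)), _SIGMA2_FLOOR)
        ofv += n * (math.log(s2) + 1.0)
        sigmas.append(math.sqrt(s2))
    return ofv, sigmas


def aic(ofv: float, p: int) -> float:
    """Akaike information criterion: ``OFV + 2*p``."""
    if p < 0:
        raise ValidationError("p must be >= 0")
    return float(ofv) + 2.0 * int(p)


def r_squared(observed: Sequence[float], predicted: Sequence[float]) -> float:
    """Squared Pearson correlation of observed vs predicted values."""
    y = np.asarray(observed, dtype=float)
    yhat = np.asarray(predicted, dtype=float)
    if y.size < 2 or y.size != yhat.size:
        raise UndefinedStatisticError("need >= 2 paired observations")
    if np.std(y) == 0 or np.std(yhat) == 0:
        raise UndefinedStatisticError("zero variance in observed or predicted")
    r = np.corrcoef(y, yhat)[0, 1]
    return float(r * r)


def weighted_residuals(
    dataset: StudyDataset,
    model: StructuralModel,
    error: ErrorModel,
    dt_max: float = 0.05,
) -> pd.DataFrame:
    """Population-prediction weighted residuals ``(obs-pred)/(sigma*pred)``."""
    obs = dataset.observations
    pred = predict(dataset, model, dt_max=dt_max)
    if np.any(pred <= 0):
        i = int(np.argmax(pred <= 0))
        row = obs.iloc[i]
        raise PredictionError(
            f"non-positive prediction for animal {row['animal']} "
            f"({row['stream']}, t={row['time']})"
        )
    sig = np.array([error.sigma_for(s) for s in obs["stream"]])
    y = obs["conc"].to_numpy(dtype=float)
    out = obs[["animal", "time", "stream"]].copy()
    out["observed"] = y
    out["predicted"] = pred
    out["wres"] = (y - pred) / (sig * pred)
    return out


# ---------------------------------------------------------------------------
# estimation


def _estimated_names(model: StructuralModel, fixed: frozenset) -> list[str]:
    names = [n for n in model.parameters.names if n not in fixed]
    names += [n for n in PARAM_NAMES[model.expansion.kind] if n not in fixed]
    return names


def count_estimated(
    model: StructuralModel,
    fixed: Sequence[str] | None = None,
    include_sigma: bool = True,
) -> int:
    """Number of estimated parameters (for AIC), including the stream SDs."""
    fixed_all = frozenset(model.parameters.fixed) | frozenset(fixed or ())
    p = len(_estimated_names(model, fixed_all))
    return p + (2 if include_sigma else 0)


def _current_values(model: StructuralModel) -> dict:
    vals = model.parameters.to_dict()
    vals.update(model.expansion.params)
    return vals


def fit_model(
    dataset: StudyDataset,
    model: StructuralModel,
    init: Mapping[str, float] | None = None,
    fixed: Sequence[str] | None = None,
    error: ErrorModel | None = None,
    n_multistart: int = 8,
    seed: int = 0,
    dt_max: float = 0.05,
    maxfev: int | None = None,
    compute_cv: bool = True,
) -> FitResult:
    """Fit a structural model by multistart maximum likelihood.

    ``fixed`` extends the model's own fixed mask; fixed parameters keep
    their (init) values and are excluded from the AIC parameter count.
    When ``error`` is None (default) the stream SDs are profiled out of the
    likelihood and reported as estimates (counting 2 toward AIC); an
    explicit :class:`ErrorModel` holds them fixed instead.
    """
    fixed_all = frozenset(model.parameters.fixed) | frozenset(fixed or ())
    names = _estimated_names(model, fixed_all)
    values = _current_values(model)
    if init:
        unknown = set(init) - set(values)
        if unknown:
            raise ValidationError(f"init names unknown parameters: {sorted(unknown)}")
        values.update(init)
    model = model.with_parameters(**values)

    obs = dataset.observations
    y = obs["conc"].to_numpy(dtype=float)
    stream_mask = (
        (obs["stream"] == "serum").to_numpy(),
        (obs["stream"] == "spleen").to_numpy(),
    )
    # fast prediction path: simulate on the unique-time grid once per
    # objective evaluation and scatter back to observation rows
    uniq_times = np.unique(obs["time"].to_numpy(dtype=float))
    t_idx = np.searchsorted(uniq_times, obs["time"].to_numpy(dtype=float))
    serum_rows = stream_mask[0]

    def _fast_predict(m: StructuralModel) -> np.ndarray:
        sim = simulate_profile(m, dataset.schedule, uniq_times, dt_max=dt_max)
        return np.where(serum_rows, sim.serum[t_idx], sim.spleen[t_idx])

    def ofv_at(vals: Mapping[str, float]) -> tuple[float, list[float]]:
        m = model.with_parameters(**dict(vals))
        pred = _fast_predict(m)
        if np.any(pred <= 0) or not np.all(np.isfinite(pred)):
            return _PENALTY, [float("nan")] * 2
        if error is not None:
            sig = [error.sigma_serum, error.sigma_spleen]
            var_parts = 0.0
            for mask, s in zip(stream_mask, sig):
                r = (y[mask] - pred[mask]) / pred[mask]
                var_parts += float(
                    np.sum(_LOG_2PI + np.log(s * s * pred[mask] ** 2) + r * r / (s * s))
                )
            return var_parts, sig
        return _profiled_ofv(y, pred, stream_mask)

    n_sigma = 0 if error is not None else 2
    p = len(names) + (2 if error is None else 0)

    if not names:
        ofv0, sigmas = ofv_at(values)
        if error is None:
            raise ValidationError(
                "no estimated parameters: pass an explicit ErrorModel"
            )
        pred = predict(dataset, model, dt_max=dt_max)
        res = weighted_residuals(dataset, model, error, dt_max=dt_max)
        return FitResult(
            model=model,
            estimates={},
            cv_percent={},
            fixed={k: values[k] for k in sorted(fixed_all) if k in values},
            sigma={"serum": error.sigma_serum, "spleen": error.sigma_spleen},
            ofv=ofv0,
            aic=aic(ofv0, 0),
            r_squared=r_squared(y, pred),
            residuals=res,
            n_obs=len(y),
            p=0,
            converged=True,
            n_starts=0,
            start_ofvs=[ofv0],
        )

    x0 = np.log([values[n] for n in names])

    def objective(x: np.ndarray) -> float:
        try:
            vals = dict(zip(names, np.exp(x)))
            return ofv_at(vals)[0]
        except (ValidationError, PredictionError, SolverError,
                FloatingPointError, OverflowError):
            return _PENALTY

    rng = np.random.default_rng(seed)
    jitter = math.log(1.5)  # +/-50% multiplicative jitter
    starts = [x0]
    for _ in range(max(int(n_multistart), 1) - 1):
        starts.append(x0 + rng.uniform(-jitter, jitter, size=x0.size))

    best = None
    start_ofvs = []
    any_success = False
    for x_start in starts:
        res = optimize.minimize(
            objective,
            x_start,
            method="Nelder-Mead",
            options={
                "xatol": 1e-6,
                "fatol": 1e-8,
                "maxfev": maxfev or 400 * len(names),
                "adaptive": len(names) > 4,
            },
        )
        start_ofvs.append(float(res.fun))
        any_success = any_success or bool(res.success)
        if best is None or res.fun < best.fun:
            best = res
    if best is None or best.fun >= _PENALTY:
        raise FitFailureError(
            f"all {len(starts)} starts failed; per-start OFVs: {start_ofvs}"
        )

    x_hat = best.x
    est = dict(zip(names, np.exp(x_hat)))
    ofv_hat, sigmas = ofv_at(est)
    fitted = model.with_parameters(**est)
    if error is not None:
        err_hat = error
    else:
        err_hat = ErrorModel(max(sigmas[0], 1e-8), max(sigmas[1], 1e-8))

    cv = {n: float("nan") for n in names}
    cv_source = "hessian"
    if compute_cv:
        try:
            H = _fd_hessian(objective, x_hat)
            cov = 2.0 * np.linalg.inv(H)
            se = np.sqrt(np.maximum(np.diag(cov), 0.0))
            if np.all(np.isfinite(se)):
                cv = {n: float(100.0 * s) for n, s in zip(names, se)}
            else:
                cv_source = "unavailable"
        except np.linalg.LinAlgError:
            cv_source = "unavailable"

    resid = weighted_residuals(dataset, fitted, err_hat, dt_max=dt_max)
    pred = resid["predicted"].to_numpy()
    return FitResult(
        model=fitted,
        estimates=est,
        cv_percent=cv,
        fixed={k: values[k] for k in sorted(fixed_all) if k in values},
        sigma={"serum": err_hat.sigma_serum, "spleen": err_hat.sigma_spleen},
        ofv=float(ofv_hat),
        aic=aic(ofv_hat, p),
        r_squared=r_squared(y, pred),
        residuals=resid,
        n_obs=len(y),
        p=p,
        converged=any_success,
        n_starts=len(starts),
        start_ofvs=start_ofvs,
        cv_source=cv_source,
    )


def _fd_hessian(fun, x: np.ndarray, step: float = 1e-4) -> np.ndarray:
    """Central finite-difference Hessian."""
    n = x.size
    H = np.empty((n, n))
    f0 = fun(x)
    for i in range(n):
        for j in range(i, n):
            ei = np.zeros(n)
            ej = np.zeros(n)
            ei[i] = step
            ej[j] = step
            if i == j:
                H[i, i] = (fun(x + ei) - 2 * f0 + fun(x - ei)) / step**2
            else:
                H[i, j] = H[j, i] = (
                    fun(x + ei + ej) - fun(x + ei - ej)
                    - fun(x - ei + ej) + fun(x - ei - ej)
                ) / (4 * step**2)
    return H


# ---------------------------------------------------------------------------
# bootstrap and model comparison


def bootstrap(
    dataset: StudyDataset,
    model: StructuralModel,
    n_reps: int,
    seed: int = 0,
    init: Mapping[str, float] | None = None,
    fixed: Sequence[str] | None = None,
    error: ErrorModel | None = None,
    n_multistart: int = 1,
    dt_max: float = 0.05,
    maxfev: int | None = None,
) -> BootstrapSummary:
    """Nonparametric bootstrap preserving the destructive design.

    Animals are resampled with replacement within each sampling-day
    stratum, the model is refit on each resample, and per-parameter
    percentile 95% CIs, SD and CV% are reported.  Fully deterministic for
    a given seed.
    """
    if n_reps < 10:
        raise ValidationError("n_reps must be >= 10")
    rng = np.random.default_rng(seed)
    obs = dataset.observations
    day_of = dataset.animal_day()
    strata = {
        day: list(ids.index)
        for day, ids in day_of.groupby(day_of)
    }
    weights = dataset.weights

    samples = []
    n_failed = 0
    for rep in range(int(n_reps)):
        frames = []
        wframes = []
        tag = 0
        for day in sorted(strata):
            ids = strata[day]
            draw = rng.choice(len(ids), size=len(ids), replace=True)
            for d in draw:
                tag += 1
                orig = ids[d]
                sub = obs[obs["animal"] == orig].copy()
                sub["animal"] = f"B{tag:03d}"
                frames.append(sub)
                if weights is not None:
                    wsub = weights[weights["animal"] == orig].copy()
                    wsub["animal"] = f"B{tag:03d}"
                    wframes.append(wsub)
        boot = StudyDataset(
            pd.concat(frames, ignore_index=True),
            dataset.schedule,
            pd.concat(wframes, ignore_index=True) if wframes else None,
            dataset.design,
            {"bootstrap_rep": rep},
        )
        try:
            fit = fit_model(
                boot, model, init=init, fixed=fixed, error=error,
                n_multistart=n_multistart, seed=seed + rep + 1,
                dt_max=dt_max, maxfev=maxfev, compute_cv=False,
            )
            row = dict(fit.estimates)
            row.update({f"sigma_{k}": v for k, v in fit.sigma.items()})
            samples.append(row)
        except (FitFailureError, UndefinedStatisticError, PredictionError,
                SolverError):
            n_failed += 1

    if not samples:
        raise FitFailureError("every bootstrap refit failed")
    df = pd.DataFrame(samples)
    mean = df.mean()
    sd = df.std(ddof=1)
    table = pd.DataFrame({
        "mean": mean,
        "sd": sd,
        "cv_percent": 100.0 * sd / mean.abs(),
        "ci_lo": df.quantile(0.025),
        "ci_hi": df.quantile(0.975),
    })
    summary = BootstrapSummary(
        table=table,
        n_reps=int(n_reps),
        n_failed=n_failed,
        seed=int(seed),
        warning=n_failed > 0.2 * n_reps,
    )
    summary._samples = df
    return summary


def compare_models(
    dataset: StudyDataset,
    models: Mapping[str, StructuralModel],
    inits: Mapping[str, Mapping[str, float]] | None = None,
    fixed: Sequence[str] | None = None,
    fixed_per_model: Mapping[str, Sequence[str]] | None = None,
    **fit_kwargs,
) -> pd.DataFrame:
    """Fit every model and tabulate (p, OFV, AIC, R^2), sorted by AIC.

    Single-model failures are recorded in the ``error`` column rather
    than aborting; ties and failures preserve input order (stable sort).
    The fitted :class:`FitResult` objects are attached as
    ``result.attrs['fits']``.
    """
    if len(models) < 2:
        raise ValidationError("compare_models needs at least 2 models")
    rows = []
    fits = {}
    for name, model in models.items():
        init = (inits or {}).get(name)
        fix = tuple(fixed or ()) + tuple((fixed_per_model or {}).get(name, ()))
        try:
            fit = fit_model(dataset, model, init=init, fixed=fix, **fit_kwargs)
            fits[name] = fit
            cv = {f"cv_{k}": v for k, v in fit.cv_percent.items()}
            rows.append({
                "name": name, "p": fit.p, "ofv": fit.ofv, "aic": fit.aic,
                "r_squared": fit.r_squared, "converged": fit.converged,
                "error": "", **cv,
            })
        except (FitFailureError, PredictionError, UndefinedStatisticError,
                ValidationError) as exc:
            rows.append({
                "name": name, "p": np.nan, "ofv": np.nan, "aic": np.nan,
                "r_squared": np.nan, "converged": False, "error": str(exc),
            })
    out = pd.DataFrame(rows)
    out = out.sort_values("aic", kind="stable", na_position="last")
    out = out.reset_index(drop=True)
    out.attrs["fits"] = fits
    return out
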