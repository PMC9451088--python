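"""Isotemporal substitution: outcome differences for user-defined time
reallocations.

A reallocation is a vector of signed per-part minute deltas netting to zero.
For an identity-scale outcome the difference between the reallocated and
initial compositions is a linear contrast of the fitted coefficients, with a
t-based CI from the contrast variance. For a log-modelled outcome the
difference of the exponentiated predictions gets a MOVER (method of variance
estimates recovery) interval in the style of Zou, combining the raw-scale
limits of the two lognormal estimates with their correlation.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
from scipy import stats

from .coda import (
    Composition,
    CompositionError,
    PART_NAMES,
    close,
    ilr,
    replace_zeros_fixed,
)
from .model import CovariateProfile, FittedModel, ModelError, build_design_row

DEFAULT_CAP_MINUTES = 60.0


class ReallocationError(ValueError):
    """A reallocation request violates the zero-net-sum, cap, or
    non-negativity constraints."""


@dataclass(frozen=True)
class Reallocation:
    """Signed per-part deltas (minutes) with zero net sum, each bounded by
    ``cap`` in absolute value."""

    deltas: np.ndarray
    cap: float = DEFAULT_CAP_MINUTES

    def __post_init__(self):
        if isinstance(self.deltas, Mapping):
            unknown = set(self.deltas) - set(PART_NAMES)
            if unknown:
                raise ReallocationError(f"unknown parts: {sorted(unknown)}")
            vec = np.array([float(self.deltas.get(p, 0.0)) for p in PART_NAMES])
        else:
            vec = np.asarray(self.deltas, dtype=float)
            if vec.shape != (len(PART_NAMES),):
                raise ReallocationError(
                    f"expected {len(PART_NAMES)} deltas, got shape {vec.shape}")
        object.__setattr__(self, "deltas", vec)
        net = vec.sum()
        if abs(net) > 1e-9:
            raise ReallocationError(
                f"reallocation deltas must net to zero; they sum to {net:+.6f} min")
        over = np.abs(vec) > self.cap + 1e-9
        if over.any():
            worst = [PART_NAMES[i] for i in np.where(over)[0]]
            raise ReallocationError(
                f"deltas exceed the {self.cap:g}-min cap for: {worst}")

    @property
    def is_null(self) -> bool:
        return bool(np.all(self.deltas == 0))


def apply_reallocation(initial: Composition, realloc: Reallocation) -> Composition:
    """Shift time between parts: new = initial + deltas, total preserved.

    Raises (naming the part and the shortfall) if any part would go negative —
    the user cannot reallocate more time than they have available.
    """
    if not isinstance(initial, Composition):
        initial = close(initial)
    new = initial.values + realloc.deltas
    neg = new < 0
    if neg.any():
        i = int(np.argmin(new))
        raise ReallocationError(
            f"reallocating {abs(realloc.deltas[i]):g} min from "
            f"'{PART_NAMES[i]}' would result in a negative value "
            f"(only {initial.values[i]:g} min available, short by {-new[i]:g} min)"
        )
    return Composition(new, total=initial.total)


@dataclass(frozen=True)
class Prediction:
    """Point prediction for one composition/profile: linear-scale estimate and
    SE, plus the raw-scale estimate with its 95% CI (exponentiated when the
    model is on the log scale)."""

    estimate: float       # on the modelling (possibly log) scale
    se: float
    raw_estimate: float
    raw_ci: tuple[float, float]
    df: int


def _design_row_for(model: FittedModel, comp, cov: CovariateProfile) -> np.ndarray:
    if not isinstance(comp, Composition):
        comp = close(comp)
    comp = replace_zeros_fixed(comp)
    return build_design_row(ilr(comp, model.sbp), cov)


def predict_outcome(model: FittedModel, comp, cov: CovariateProfile,
                    alpha: float = 0.05) -> Prediction:
    """Predict the outcome at a composition and covariate profile using only
    the stored regression parameters. Zero parts are imputed with the fixed
    3.25-min rule before taking log ratios."""
    x = _design_row_for(model, comp, cov)
    yhat = float(x @ model.coefficients)
    se = float(np.sqrt(max(x @ model.covariance @ x, 0.0)))
    t = stats.t.ppf(1 - alpha / 2, model.residual_df)
    lo, hi = yhat - t * se, yhat + t * se
    if model.transform == "log":
        return Prediction(yhat, se, float(np.exp(yhat)),
                          (float(np.exp(lo)), float(np.exp(hi))), model.residual_df)
    return Prediction(yhat, se, yhat, (float(lo), float(hi)), model.residual_df)


@dataclass(frozen=True)
class SubstitutionEstimate:
    """Estimated outcome difference (new minus initial) for one reallocation,
    with 95% CI, percent difference relative to the initial prediction, and a
    favourable-direction flag (None for no change)."""

    outcome_name: str
    estimate_initial: float
    ci_initial: tuple[float, float]
    estimate_new: float
    ci_new: tuple[float, float]
    difference: float
    ci_low: float
    ci_high: float
    percent_difference: float
    favourable: bool | None
    alpha: float = 0.05

    def as_dict(self) -> dict:
        return {
            "outcome": self.outcome_name,
            "estimate_initial": self.estimate_initial,
            "ci_initial": list(self.ci_initial),
            "estimate_new": self.estimate_new,
            "ci_new": list(self.ci_new),
            "difference": self.difference,
            "ci_low": self.ci_low,
            "ci_high": self.ci_high,
            "percent_difference": self.percent_difference,
            "favourable": self.favourable,
            "alpha": self.alpha,
        }


def _favourable_flag(model: FittedModel, difference: float) -> bool | None:
    if difference == 0:
        return None
    return (difference > 0) == (model.favourable == "higher")


def percent_difference(est: SubstitutionEstimate) -> float:
    """Difference as a percentage of the raw-scale prediction at the initial
    composition."""
    if est.estimate_initial == 0:
        raise ZeroDivisionError(
            "percent difference is undefined for a zero baseline estimate")
    return 100.0 * est.difference / est.estimate_initial


def estimate_difference_linear(model: FittedModel, comp0, comp1,
                               cov: CovariateProfile,
                               alpha: float = 0.05) -> SubstitutionEstimate:
    """Difference for an identity-scale outcome: d = (x1-x0)'b with
    Var(d) = (x1-x0)'V(x1-x0) and a t(residual_df) interval."""
    if model.transform != "identity":
        raise ModelError(
            "model is log-transformed; use estimate_difference_lognormal")
    x0 = _design_row_for(model, comp0, cov)
    x1 = _design_row_for(model, comp1, cov)
    p0 = predict_outcome(model, comp0, cov, alpha)
    p1 = predict_outcome(model, comp1, cov, alpha)
    dx = x1 - x0
    d = float(dx @ model.coefficients)
    var = float(max(dx @ model.covariance @ dx, 0.0))
    t = stats.t.ppf(1 - alpha / 2, model.residual_df)
    half = t * np.sqrt(var)
    est = SubstitutionEstimate(
        outcome_name=model.outcome_name,
        estimate_initial=p0.raw_estimate, ci_initial=p0.raw_ci,
        estimate_new=p1.raw_estimate, ci_new=p1.raw_ci,
        difference=d, ci_low=float(d - half), ci_high=float(d + half),
        percent_difference=0.0, favourable=_favourable_flag(model, d),
        alpha=alpha,
    )
    return _with_percent(est)


def mover_lognormal_difference(y0: float, se0: float, y1: float, se1: float,
                               r: float, df: int,
                               alpha: float = 0.05) -> tuple[float, float, float]:
    """MOVER interval for exp(y1) - exp(y0) given correlated normal estimates
    on the log scale.

    Individual raw-scale limits (l_i, u_i) = exp(y_i -/+ t*se_i) are combined
    with the correlation r of the two estimates:

        L = t1 - t0 - sqrt((t1-l1)^2 + (u0-t0)^2 - 2r(t1-l1)(u0-t0))
        U = t1 - t0 + sqrt((u1-t1)^2 + (t0-l0)^2 - 2r(u1-t1)(t0-l0))

    with t_i = exp(y_i). Returns (difference, L, U).
    """
    t = stats.t.ppf(1 - alpha / 2, df)
    th0, th1 = np.exp(y0), np.exp(y1)
    l0, u0 = np.exp(y0 - t * se0), np.exp(y0 + t * se0)
    l1, u1 = np.exp(y1 - t * se1), np.exp(y1 + t * se1)
    d = th1 - th0
    lo = d - np.sqrt(max(
        (th1 - l1) ** 2 + (u0 - th0) ** 2 - 2 * r * (th1 - l1) * (u0 - th0), 0.0))
    hi = d + np.sqrt(max(
        (u1 - th1) ** 2 + (th0 - l0) ** 2 - 2 * r * (u1 - th1) * (th0 - l0), 0.0))
    return float(d), float(lo), float(hi)


def estimate_difference_lognormal(model: FittedModel, comp0, comp1,
                                  cov: CovariateProfile,
                                  alpha: float = 0.05) -> SubstitutionEstimate:
    """Difference for a log-modelled outcome: exp(y1) - exp(y0) with a MOVER
    interval accounting for the covariance of the two predictions.

    A null reallocation (identical design rows) returns an exact zero
    difference with a zero-width interval.
    """
    if model.transform != "log":
        raise ModelError(
            "model is on the identity scale; use estimate_difference_linear")
    x0 = _design_row_for(model, comp0, cov)
    x1 = _design_row_for(model, comp1, cov)
    p0 = predict_outcome(model, comp0, cov, alpha)
    p1 = predict_outcome(model, comp1, cov, alpha)
    if np.array_equal(x0, x1):
        est = SubstitutionEstimate(
            outcome_name=model.outcome_name,
            estimate_initial=p0.raw_estimate, ci_initial=p0.raw_ci,
            estimate_new=p1.raw_estimate, ci_new=p1.raw_ci,
            difference=0.0, ci_low=0.0, ci_high=0.0,
            percent_difference=0.0, favourable=None, alpha=alpha,
        )
        return est
    cov01 = float(x0 @ model.covariance @ x1)
    if p0.se > 0 and p1.se > 0:
        r = cov01 / (p0.se * p1.se)
        r = float(np.clip(r, -1.0, 1.0))
    else:
        r = 0.0
    d, lo, hi = mover_lognormal_difference(
        p0.estimate, p0.se, p1.estimate, p1.se, r, model.residual_df, alpha)
    est = SubstitutionEstimate(
        outcome_name=model.outcome_name,
        estimate_initial=p0.raw_estimate, ci_initial=p0.raw_ci,
        estimate_new=p1.raw_estimate, ci_new=p1.raw_ci,
        difference=d, ci_low=lo, ci_high=hi,
        percent_difference=0.0, favourable=_favourable_flag(model, d),
        alpha=alpha,
    )
    return _with_percent(est)


def _with_percent(est: SubstitutionEstimate) -> SubstitutionEstimate:
    from dataclasses import replace
    return replace(est, percent_difference=percent_difference(est))


def estimate_difference(model: FittedModel, comp0, comp1, cov: CovariateProfile,
                        alpha: float = 0.05) -> SubstitutionEstimate:
    """Dispatch to the linear or lognormal difference by the model transform."""
    if model.transform == "log":
        return estimate_difference_lognormal(model, comp0, comp1, cov, alpha)
    return estimate_difference_linear(model, comp0, comp1, cov, alpha)


def substitution_report(models: Sequence[FittedModel], initial,
                        realloc: Reallocation, cov: CovariateProfile,
                        alpha: float = 0.05) -> dict[str, SubstitutionEstimate]:
    """Apply one reallocation and estimate the difference under every model.

    Returns a dict keyed by outcome name.
    """
    if not isinstance(initial, Composition):
        initial = close(initial)
    new = apply_reallocation(initial, realloc)
    return {
        m.outcome_name: estimate_difference(m, initial, new, cov, alpha)
        for m in models
    }
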