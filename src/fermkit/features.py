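"""Physiological feature extraction, organised as a four-level ladder.

* **analyte** features need one time course: numerical rates (gradients) and
  growth-model fits (exponential, generalised logistic, 5-parameter
  Richards).
* **trial** features need several analytes from one fermentation volume:
  product yield, biomass normalisation, specific productivity
  (mmol/gDW/h; the biomass-specific growth rate mu, 1/h, is the special case
  applied to biomass itself).
* **replicate** features need several single trials: missing-value-aware
  mean/standard-deviation courses and leave-one-out outlier flagging.
* **experiment** features span trials: blank assignment/subtraction and
  stage slicing.

Missing observations (NaN) are dropped pairwise inside each computation,
never imputed; statistics simply see fewer observations at the affected
time points.

Growth-model closed forms (Zwietering-style biological parameterisation —
asymptote ``A``, maximum specific rate ``mu_max``, lag ``lam``)::

    exponential:  X(t) = X0 * exp(mu * t)
    gen_logistic: X(t) = A / (1 + exp(4*mu_max/A*(lam - t) + 2))
    richards5:    X(t) = X0 + (A - X0) * [1 + nu*exp(1+nu)
                          * exp((mu_max/A)*(1+nu)**(1+1/nu)*(lam - t))]**(-1/nu)
"""

from __future__ import annotations

import copy
import logging
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
from scipy.optimize import least_squares

from .errors import FeatureError, FitError
from .identifiers import serialize_identifier
from .schema import AnalyteCourse, Experiment, ReplicateTrial, SingleTrial

logger = logging.getLogger(__name__)

OUTLIER_EPS = 1e-6
DEFAULT_TAU = 0.5
YIELD_TOL = 1e-9


# ---------------------------------------------------------------------------
# result containers


@dataclass
class RateSeries:
    """A rate vector aligned to the finite-valued points of its parent course."""

    times: np.ndarray
    rates: np.ndarray
    kind: str  # gradient | specific | normalized
    unit: str = ""


@dataclass
class GrowthFit:
    """Parameters of a growth-model least-squares fit."""

    model: str
    params: dict[str, float]
    rss: float
    n_points: int

    def predict(self, times) -> np.ndarray:
        return _MODEL_FORMS[self.model](np.asarray(times, dtype=float), self.params)


@dataclass
class YieldResult:
    """Endpoint and cumulative product-per-substrate yields (same units as inputs)."""

    endpoint_yield: float
    times: np.ndarray
    cumulative: np.ndarray  # NaN where substrate consumption <= tolerance


@dataclass
class ReplicateStats:
    """Mean/std courses over replicates on the union time grid.

    The sample standard deviation uses the n-1 denominator and is NaN
    wherever fewer than two finite observations remain.
    """

    times: np.ndarray
    mean: np.ndarray
    std: np.ndarray
    n_obs: np.ndarray
    unit: str = ""


# ---------------------------------------------------------------------------
# feature registry

FEATURE_LEVELS = ("analyte", "trial", "replicate", "experiment")
_REGISTRY: dict[str, tuple[str, object]] = {}


def register_feature(name: str, level: str):
    """Decorator: register a feature under (name, hierarchy level)."""
    if level not in FEATURE_LEVELS:
        raise ValueError(f"unknown feature level {level!r}")

    def deco(func):
        _REGISTRY[name] = (level, func)
        return func

    return deco


def registered_features() -> dict[str, str]:
    """Name -> level for every registered feature."""
    return {name: level for name, (level, _) in sorted(_REGISTRY.items())}


def get_feature(name: str):
    if name not in _REGISTRY:
        raise FeatureError(
            f"unknown feature {name!r}; available: {sorted(_REGISTRY)}"
        )
    return _REGISTRY[name]


# ---------------------------------------------------------------------------
# analyte features


@register_feature("gradient", "analyte")
def gradient(course: AnalyteCourse) -> RateSeries:
    """Numerical rate d(value)/dt at each finite point of the course.

    Second-order central differences on the (possibly non-uniform) interior
    grid, first-order one-sided differences at the endpoints. Exact for
    affine series everywhere and for quadratics at interior points.
    """
    t, y = course.finite()
    if t.size < 2:
        raise FeatureError(
            f"insufficient data: gradient needs >= 2 finite points, got {t.size}"
        )
    rates = np.gradient(y, t)
    return RateSeries(times=t, rates=rates, kind="gradient", unit=f"{course.unit}/h")


def _exp_form(t, p):
    return p["X0"] * np.exp(p["mu"] * t)


def _logistic_form(t, p):
    return p["A"] / (1.0 + np.exp(4.0 * p["mu_max"] / p["A"] * (p["lam"] - t) + 2.0))


def _richards5_form(t, p):
    A, mu, lam, nu, X0 = p["A"], p["mu_max"], p["lam"], p["nu"], p["X0"]
    inner = 1.0 + nu * np.exp(1.0 + nu) * np.exp(
        (mu / A) * (1.0 + nu) ** (1.0 + 1.0 / nu) * (lam - t)
    )
    return X0 + (A - X0) * inner ** (-1.0 / nu)


_MODEL_FORMS = {
    "exponential": _exp_form,
    "gen_logistic": _logistic_form,
    "richards5": _richards5_form,
}
_MIN_POINTS = {"exponential": 3, "gen_logistic": 5, "richards5": 6}


def _sigmoid_init(t, y):
    """Deterministic initial guess: asymptote from max(y), rate and lag from
    the steepest finite-difference chord."""
    A0 = float(np.max(y))
    slopes = np.diff(y) / np.diff(t)
    k = int(np.argmax(slopes))
    slope = max(float(slopes[k]), 1e-6)
    t_steep = 0.5 * (t[k] + t[k + 1])
    lam0 = t_steep - A0 / (2.0 * slope)
    return A0, slope, lam0


def fit_growth_model(
    course: AnalyteCourse, model: str = "exponential", window: tuple[float, float] | None = None
) -> GrowthFit:
    """Least-squares fit of a growth model to one course.

    The exponential model is solved exactly by ordinary least squares on
    log-transformed values (requires strictly positive values); the sigmoid
    models use bounded nonlinear least squares with a deterministic
    initialisation, so repeated fits of the same data are identical.
    ``window`` restricts the fit to a closed time interval.
    """
    if model not in _MODEL_FORMS:
        raise FeatureError(f"unknown growth model {model!r}; expected {sorted(_MODEL_FORMS)}")
    t, y = course.finite()
    if window is not None:
        mask = (t >= window[0]) & (t <= window[1])
        t, y = t[mask], y[mask]
    if t.size < _MIN_POINTS[model]:
        raise FeatureError(
            f"insufficient data: {model} needs >= {_MIN_POINTS[model]} finite points, got {t.size}"
        )

    if model == "exponential":
        if np.any(y <= 0):
            raise FeatureError("exponential fit requires strictly positive values")
        # log X = log X0 + mu t  -> linear OLS, exact
        mu, logx0 = np.polyfit(t, np.log(y), 1)
        params = {"X0": float(np.exp(logx0)), "mu": float(mu)}
    else:
        A0, slope, lam0 = _sigmoid_init(t, y)
        if model == "gen_logistic":
            names = ["A", "mu_max", "lam"]
            x0 = [A0, slope, lam0]
            lo = [1e-12, 1e-9, -np.inf]
            hi = [np.inf, np.inf, np.inf]
        else:  # richards5
            names = ["A", "mu_max", "lam", "nu", "X0"]
            x0 = [A0, slope, lam0, 1.0, float(np.min(y))]
            lo = [1e-12, 1e-9, -np.inf, 1e-6, -np.inf]
            hi = [np.inf, np.inf, np.inf, np.inf, np.inf]
        x0 = np.clip(x0, lo, hi)

        def resid(x):
            return _MODEL_FORMS[model](t, dict(zip(names, x))) - y

        res = least_squares(
            resid, x0, bounds=(lo, hi), xtol=1e-15, ftol=1e-15, gtol=1e-15, max_nfev=20000
        )
        if not res.success:
            raise FitError(
                f"{model} fit did not converge: {res.message}",
                last_iterate=dict(zip(names, res.x)),
            )
        params = {n: float(v) for n, v in zip(names, res.x)}

    pred = _MODEL_FORMS[model](t, params)
    rss = float(np.sum((pred - y) ** 2))
    return GrowthFit(model=model, params=params, rss=rss, n_points=int(t.size))


register_feature("growth_fit", "analyte")(fit_growth_model)


# ---------------------------------------------------------------------------
# trial features


def _interp_onto(course: AnalyteCourse, target_times: np.ndarray):
    """Linearly interpolate a course's finite values onto target times.

    No extrapolation: targets outside the course's finite span are masked out
    (with a warning). Returns (values, in-span mask).
    """
    t, y = course.finite()
    if t.size == 0:
        raise FeatureError(f"course {course.analyte_name!r} has no finite values")
    in_span = (target_times >= t[0]) & (target_times <= t[-1])
    if not np.all(in_span):
        logger.warning(
            "%d/%d target times outside the span of %r dropped (no extrapolation)",
            int(np.sum(~in_span)), target_times.size, course.analyte_name,
        )
    values = np.interp(target_times, t, y)
    return values, in_span


@register_feature("yield", "trial")
def compute_yield(
    product: AnalyteCourse, substrate: AnalyteCourse, tol: float = YIELD_TOL
) -> YieldResult:
    """Product yield Y_P/S: product formed per substrate consumed.

    Substrate values are interpolated onto the product's finite time grid.
    The endpoint yield is (P_end - P_0)/(S_0 - S_end); the cumulative series
    is defined only where net substrate consumption exceeds ``tol``.
    """
    pt, pv = product.finite()
    if pt.size < 2:
        raise FeatureError("yield needs >= 2 finite product points")
    sv, in_span = _interp_onto(substrate, pt)
    pt, pv, sv = pt[in_span], pv[in_span], sv[in_span]
    if pt.size < 2:
        raise FeatureError("yield: product and substrate grids do not overlap")
    consumed = sv[0] - sv
    if consumed[-1] <= tol:
        raise FeatureError("no substrate consumed")
    endpoint = float((pv[-1] - pv[0]) / consumed[-1])
    cumulative = np.full(pt.size, np.nan)
    ok = consumed > tol
    cumulative[ok] = (pv[ok] - pv[0]) / consumed[ok]
    return YieldResult(endpoint_yield=endpoint, times=pt, cumulative=cumulative)


@register_feature("specific_rate", "trial")
def specific_rate(
    analyte: AnalyteCourse, biomass: AnalyteCourse, molar_mass: float | None = None
) -> RateSeries:
    """Biomass-specific rate q = (d[analyte]/dt) / X, evaluated at the
    analyte's finite time points (biomass linearly interpolated).

    With ``molar_mass`` (g/mol) and a mass-concentration course (g/L), the
    result is converted to the canonical mmol/gDW/h. Applied to the biomass
    course itself this yields the instantaneous specific growth rate mu (1/h).
    """
    grad = gradient(analyte)
    x, in_span = _interp_onto(biomass, grad.times)
    t = grad.times[in_span]
    rates = grad.rates[in_span]
    x = x[in_span]
    if np.any(x <= 0):
        raise FeatureError("specific rate undefined: biomass <= 0 at an evaluation time")
    q = rates / x
    unit = f"{analyte.unit}/gDW/h" if analyte.unit else "1/h"
    if molar_mass is not None:
        q = q * 1000.0 / molar_mass
        unit = "mmol/gDW/h"
    return RateSeries(times=t, rates=q, kind="specific", unit=unit)


@register_feature("normalize_to_biomass", "trial")
def normalize_to_biomass(analyte: AnalyteCourse, biomass: AnalyteCourse) -> AnalyteCourse:
    """Divide an analyte course pointwise by (interpolated) biomass.

    Missing analyte values stay missing; the unit is annotated accordingly.
    """
    x, in_span = _interp_onto(biomass, analyte.times)
    if np.any(x[in_span] <= 0):
        raise FeatureError("normalization undefined: biomass <= 0 at an analyte time")
    times = analyte.times[in_span]
    values = analyte.values[in_span] / x[in_span]
    unit = f"{analyte.unit}/{biomass.unit}" if biomass.unit else f"{analyte.unit}/biomass"
    return AnalyteCourse(
        identifier=analyte.identifier,
        analyte_type=analyte.analyte_type,
        times=times,
        values=values,
        unit=unit,
    )


# ---------------------------------------------------------------------------
# replicate features


def _aligned_frame(r: ReplicateTrial, analyte: str) -> pd.DataFrame:
    """Replicates aligned on the union time grid (columns = single trials)."""
    series = {}
    for i, single in enumerate(r.singles):
        if analyte not in single.courses:
            continue
        course = single.courses[analyte]
        idx = single.identifier.replicate_index
        series[idx if idx is not None else i + 1] = pd.Series(
            course.values, index=course.times
        )
    if not series:
        raise FeatureError(f"analyte {analyte!r} not present in any single trial")
    return pd.DataFrame(series).sort_index()


@register_feature("replicate_statistics", "replicate")
def replicate_statistics(r: ReplicateTrial) -> dict[str, ReplicateStats]:
    """Mean and sample standard deviation per analyte on the union time grid.

    NaN observations are excluded pointwise; the mean is defined wherever at
    least one observation remains (so a lone replicate still yields a mean
    course), the std wherever at least two remain. Results are cached on
    ``r.statistics``.
    """
    if not r.singles:
        raise FeatureError("replicate trial has no single trials")
    stats: dict[str, ReplicateStats] = {}
    for analyte in r.analyte_names:
        df = _aligned_frame(r, analyte)
        n_obs = df.notna().sum(axis=1).to_numpy(dtype=int)
        mean = df.mean(axis=1, skipna=True).to_numpy(dtype=float)
        std = df.std(axis=1, ddof=1, skipna=True).to_numpy(dtype=float)
        std[n_obs < 2] = np.nan
        unit = ""
        for s in r.singles:
            if analyte in s.courses:
                unit = s.courses[analyte].unit
                break
        stats[analyte] = ReplicateStats(
            times=df.index.to_numpy(dtype=float), mean=mean, std=std, n_obs=n_obs, unit=unit
        )
    r.statistics = stats
    return stats


@register_feature("outliers", "replicate")
def detect_outlier_replicates(
    r: ReplicateTrial, analyte: str, tau: float = DEFAULT_TAU, eps: float = OUTLIER_EPS
) -> set[int]:
    """Flag replicates deviating strongly from their peers (leave-one-out).

    For each replicate the deviation score is the median, over the time
    points it shares with at least one other finite observation, of the
    relative distance to the leave-one-out mean. Replicates scoring above
    ``tau`` are flagged, but never more than n-2 of them (the two most
    consistent replicates always survive). ``tau`` controls aggressiveness:
    smaller flags more. Deterministic and invariant to replicate order.
    """
    if tau <= 0:
        raise FeatureError("tau must be positive")
    df = _aligned_frame(r, analyte)
    n = df.shape[1]
    if n < 3:
        return set()
    scores: dict[int, float] = {}
    for col in df.columns:
        others = df.drop(columns=[col])
        loo_mean = others.mean(axis=1, skipna=True)
        mask = df[col].notna() & loo_mean.notna()
        if not mask.any():
            continue
        dev = (df[col][mask] - loo_mean[mask]).abs() / np.maximum(loo_mean[mask].abs(), eps)
        scores[int(col)] = float(dev.median())
    flagged = sorted(
        (idx for idx, rho in scores.items() if rho > tau),
        key=lambda idx: (-scores[idx], idx),
    )
    return set(flagged[: n - 2])


# ---------------------------------------------------------------------------
# experiment features


@register_feature("subtract_blank", "experiment")
def subtract_blank(r: ReplicateTrial, blank: ReplicateTrial) -> ReplicateTrial:
    """Subtract the blank's mean course (linearly interpolated, edge-held)
    from every matching analyte of every single trial.

    Analytes absent from the blank are left uncorrected with a warning;
    corrected values may go negative (no clipping). Returns a new trial
    marked ``blank_corrected``.
    """
    blank_stats = replicate_statistics(blank)
    corrected = copy.deepcopy(r)
    corrected.blank_corrected = True
    corrected.statistics = {}
    for single in corrected.singles:
        for name, course in single.courses.items():
            if name not in blank_stats:
                logger.warning(
                    "analyte %r missing from blank %s; left uncorrected",
                    name, serialize_identifier(blank.identifier),
                )
                continue
            bs = blank_stats[name]
            finite = np.isfinite(bs.mean)
            if not finite.any():
                logger.warning("blank mean for %r is all-missing; left uncorrected", name)
                continue
            background = np.interp(course.times, bs.times[finite], bs.mean[finite])
            course.values = course.values - background
    return corrected


@register_feature("assign_blanks", "experiment")
def assign_blanks(e: Experiment) -> dict[str, str]:
    """Map each non-blank replicate to the blank sharing its media and
    environment (serialized identifier -> serialized blank identifier).

    Ties pick the lexicographically first blank with a warning; unmatched
    replicates are left unmapped with a warning. The map is also stored on
    ``e.blank_map``.
    """
    blanks = [r for r in e.replicates if r.identifier.is_blank]
    mapping: dict[str, str] = {}
    if not blanks:
        logger.warning("experiment %r contains no blank trials", e.label)
        e.blank_map = mapping
        return mapping
    for rep in e.replicates:
        if rep.identifier.is_blank:
            continue
        matches = [
            b for b in blanks
            if b.identifier.media == rep.identifier.media
            and b.identifier.environment == rep.identifier.environment
        ]
        key = serialize_identifier(rep.identifier)
        if not matches:
            logger.warning("no blank matches %s (media/environment)", key)
            continue
        matches.sort(key=lambda b: serialize_identifier(b.identifier))
        if len(matches) > 1:
            logger.warning(
                "%d blanks match %s; choosing lexicographically first", len(matches), key
            )
        mapping[key] = serialize_identifier(matches[0].identifier)
    e.blank_map = mapping
    return mapping


@register_feature("slice_stages", "experiment")
def slice_stages(e: Experiment, boundaries: list[float]) -> list[Experiment]:
    """Split every course into fermentation stages for per-stage analysis.

    Stage k covers the half-open interval [b_k, b_{k+1}); the final stage is
    closed on the right at the last sample time, so no trailing sample is
    lost. Returns one experiment per stage, labelled ``<label>/stage<k>``.
    Empty stages yield experiments with no courses (warning).
    """
    b = list(boundaries)
    if len(b) < 2 or any(x >= y for x, y in zip(b, b[1:])):
        raise FeatureError("stage boundaries must be strictly increasing (>= 2 values)")
    stages: list[Experiment] = []
    for k in range(len(b) - 1):
        lo, hi = b[k], b[k + 1]
        final = k == len(b) - 2
        stage = Experiment(label=f"{e.label}/stage{k + 1}")
        for rep in e.replicates:
            new_rep = ReplicateTrial(identifier=rep.identifier, blank_corrected=rep.blank_corrected)
            for single in rep.singles:
                new_single = SingleTrial(identifier=single.identifier)
                for name, course in single.courses.items():
                    mask = (course.times >= lo) & (
                        (course.times <= hi) if final else (course.times < hi)
                    )
                    if not mask.any():
                        continue
                    new_single.courses[name] = AnalyteCourse(
                        identifier=course.identifier,
                        analyte_type=course.analyte_type,
                        times=course.times[mask],
                        values=course.values[mask],
                        unit=course.unit,
                    )
                if new_single.courses:
                    new_rep.singles.append(new_single)
            if new_rep.singles:
                stage.replicates.append(new_rep)
        if not stage.replicates:
            logger.warning("stage %d [%g, %g%s is empty", k + 1, lo, hi, "]" if final else ")")
        stages.append(stage)
    e.stage_definitions = [(b[k], b[k + 1]) for k in range(len(b) - 1)]
    return stages
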