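"""Background density model and the clustering threshold.

The bulk of the normalized cell densities on a map comes from
non-clustered points. That background sample — by convention the lowest
80% of the f~ values (nearest-rank quantile) — is fitted with a
three-parameter chi-square family,

    F(t) = ChiSquareCDF(c * t**b; df = a),

by least squares against the empirical CDF at the sorted sample values.
The clustering threshold is the significance-level quantile of the
fitted law, F(t*) = significance (default 0.90); cells denser than t*
are cluster candidates. Because the threshold comes from the fitted
model, it can lie below the empirical background cutoff.

By default the density exponent ``b`` is profiled over the integers
1..6 and (a, c) are optimised per value of b. The continuous-``b`` fit
is available but the least-squares surface then has a long ridge along
which (a, b, c) trade off with nearly equal objective, so individual
parameter estimates are poorly identified even when the fitted CDF —
and hence the threshold — is essentially unchanged.
"""

from __future__ import annotations

import json
import math
from dataclasses import asdict, dataclass
from pathlib import Path
from typing import Optional, Sequence

import numpy as np
from scipy.optimize import least_squares
from scipy.stats import chi2

from .exceptions import DegenerateInputError, FitError, InputError

__all__ = [
    "BackgroundFit", "model_cdf", "select_background", "fit_background",
    "threshold_at", "fit_threshold", "sample_model",
]

# parameter box constraints for the fit
A_BOUNDS = (0.01, 50.0)
B_BOUNDS = (0.2, 10.0)
C_BOUNDS = (1e-6, 10.0)
INTEGER_B_RANGE = range(1, 7)

_A_STARTS = (0.3, 1.0, 3.0)
_B_STARTS = (0.5, 1.0, 2.0, 4.0)

#: root-finding tolerance on F(threshold) = significance
THRESHOLD_FTOL = 1e-8


def model_cdf(t, a: float, b: float, c: float):
    """CDF of the background law: chi-square (df=a) at the point c*t**b."""
    t = np.asarray(t, dtype=float)
    return chi2.cdf(c * np.power(np.clip(t, 0.0, None), b), df=a)


def model_pdf(t, a: float, b: float, c: float):
    """Density of the background law (change of variables from chi-square)."""
    t = np.asarray(t, dtype=float)
    u = c * np.power(t, b)
    return chi2.pdf(u, df=a) * c * b * np.power(t, b - 1.0)


def sample_model(a: float, b: float, c: float, n: int,
                 rng: np.random.Generator) -> np.ndarray:
    """Inverse-CDF sample: t = (y / c)**(1/b) with y ~ chi-square(a)."""
    y = chi2.rvs(a, size=n, random_state=rng)
    return np.power(y / c, 1.0 / b)


@dataclass
class BackgroundFit:
    """Fitted background law plus the derived clustering threshold."""

    a: float
    b: float
    c: float
    background_fraction: float
    background_cutoff: float
    significance: float
    threshold: float
    objective: float
    n_background: int
    integer_b: bool = True

    def cdf(self, t):
        return model_cdf(t, self.a, self.b, self.c)

    def to_dict(self) -> dict:
        return asdict(self)

    def to_json(self, path: str | Path) -> None:
        Path(path).write_text(json.dumps(self.to_dict(), indent=2) + "\n")

    @classmethod
    def from_json(cls, path: str | Path) -> "BackgroundFit":
        return cls(**json.loads(Path(path).read_text()))


def select_background(densities: Sequence[float],
                      fraction: float = 0.8) -> tuple[np.ndarray, float]:
    """Lowest-``fraction`` background sample by the nearest-rank quantile.

    The cutoff is the ceil(fraction * n)-th order statistic; every value
    <= cutoff is returned (so ties at the cutoff are all included).
    """
    x = np.asarray(densities, dtype=float)
    if x.size == 0:
        raise InputError("empty density list")
    if not (0.0 < fraction <= 1.0):
        raise InputError(f"fraction {fraction} outside (0, 1]")
    x = np.sort(x)
    rank = math.ceil(fraction * x.size)
    cutoff = float(x[rank - 1])
    return x[x <= cutoff], cutoff


def _fit_ab_lc(x: np.ndarray, ecdf: np.ndarray, b: float,
               fit_b: bool) -> Optional[object]:
    """Least-squares solve from multiple starts; b free or held fixed."""
    best = None
    lc_lo, lc_hi = np.log(C_BOUNDS[0]), np.log(C_BOUNDS[1])
    med = float(np.median(x))

    if fit_b:
        def resid(p):
            a, bb, lc = p
            return model_cdf(x, a, bb, np.exp(lc)) - ecdf
        b_starts = _B_STARTS
        lo = [A_BOUNDS[0], B_BOUNDS[0], lc_lo]
        hi = [A_BOUNDS[1], B_BOUNDS[1], lc_hi]
    else:
        def resid(p):
            a, lc = p
            return model_cdf(x, a, b, np.exp(lc)) - ecdf
        b_starts = (b,)
        lo = [A_BOUNDS[0], lc_lo]
        hi = [A_BOUNDS[1], lc_hi]

    for a0 in _A_STARTS:
        for b0 in b_starts:
            # initialise c so the model median matches the sample median
            c0 = float(np.clip(chi2.ppf(0.5, a0) / med ** b0,
                               C_BOUNDS[0], C_BOUNDS[1]))
            x0 = [a0, b0, np.log(c0)] if fit_b else [a0, np.log(c0)]
            try:
                res = least_squares(resid, x0, bounds=(lo, hi),
                                    xtol=1e-12, ftol=1e-12, gtol=1e-12)
            except Exception:
                continue
            if res.success and (best is None or res.cost < best.cost):
                best = res
    return best


def fit_background(background: Sequence[float],
                   integer_b: bool = True) -> tuple[float, float, float, float]:
    """Fit (a, b, c) of the chi-square family to the background sample.

    Minimises the sum of squared differences between the model CDF and
    the empirical CDF evaluated at the sorted background values. With
    ``integer_b`` (default) b is profiled over 1..6; otherwise b is a
    free parameter in [0.2, 10]. Returns (a, b, c, objective).
    """
    x = np.sort(np.asarray(background, dtype=float))
    if np.unique(x).size < 10:
        raise DegenerateInputError(
            f"background has {np.unique(x).size} distinct values; "
            "at least 10 are required for the fit")
    if x[0] < 0:
        raise InputError("negative density in background sample")
    n = x.size
    ecdf = (np.arange(1, n + 1) - 0.5) / n

    if integer_b:
        best, best_b = None, None
        for b in INTEGER_B_RANGE:
            res = _fit_ab_lc(x, ecdf, float(b), fit_b=False)
            if res is not None and (best is None or res.cost < best.cost):
                best, best_b = res, float(b)
        if best is None:
            raise FitError("background fit failed at every start point")
        a, lc = best.x
        return float(a), best_b, float(np.exp(lc)), float(2.0 * best.cost)

    res = _fit_ab_lc(x, ecdf, 0.0, fit_b=True)
    if res is None:
        raise FitError("background fit failed at every start point")
    a, b, lc = res.x
    return float(a), float(b), float(np.exp(lc)), float(2.0 * res.cost)


def threshold_at(a: float, b: float, c: float, significance: float) -> float:
    """Quantile t* of the fitted law: ChiSquareCDF(c * t*^b; a) = significance.

    Inverted in closed form through the chi-square quantile function,
    t* = (ppf(significance, a) / c)**(1/b), which satisfies the
    F(t*) = significance condition to well below 1e-8.
    """
    if not (0.0 < significance < 1.0):
        raise InputError(f"significance {significance} outside (0, 1)")
    for name, v in (("a", a), ("b", b), ("c", c)):
        if not (v > 0 and math.isfinite(v)):
            raise InputError(f"parameter {name} = {v} must be positive finite")
    t = float((chi2.ppf(significance, a) / c) ** (1.0 / b))
    achieved = float(model_cdf(t, a, b, c))
    if abs(achieved - significance) > THRESHOLD_FTOL:
        raise FitError(
            f"threshold inversion off target: F(t*) = {achieved}")
    return t


def fit_threshold(densities: Sequence[float],
                  fraction: float = 0.8,
                  significance: float = 0.9,
                  integer_b: bool = True) -> BackgroundFit:
    """Background selection, chi-square fit and threshold in one call."""
    bg, cutoff = select_background(densities, fraction)
    a, b, c, objective = fit_background(bg, integer_b=integer_b)
    thr = threshold_at(a, b, c, significance)
    return BackgroundFit(a=a, b=b, c=c, background_fraction=fraction,
                         background_cutoff=cutoff, significance=significance,
                         threshold=thr, objective=objective,
                         n_background=int(len(bg)), integer_b=integer_b)
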