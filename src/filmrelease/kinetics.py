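"""Manifest-release kinetics for drug-loaded hydrogel films.

The measurable ("manifest") part of drug release from a thin hydrogel film
is modelled at two time scales:

* **Burst phase** (roughly the first 30 min): the cumulative release
  fraction follows the Higuchi law ``f(t) = k_H * sqrt(t)``, with the
  Higuchi constant ``k_H`` in 1/sqrt(min).
* **Long times** (out to thousands of minutes): the slab-diffusion series
  solution ``f(t) = 2*sqrt(sigma*t/d^2) * [pi^{-1/2} +
  sum_{n=1}^{N} (-1)^n erfc(n*d / (2*sqrt(sigma*t)))]``
  where ``sigma`` is the diffusion coefficient (mm^2/min) and ``d`` the
  film thickness (mm).

The two are tied together by the film-thickness relation
``k_H = 2*sqrt(sigma)/d``, which turns the empirical Higuchi constant into
a diffusion coefficient.  Note the two laws are *not* mutually consistent:
the series solution truncated at N=0 carries a ``pi^{-1/2}`` prefactor that
the Higuchi form omits, so converting a Higuchi slope fitted on N=0 data
through the thickness relation recovers ``sigma/pi``, not ``sigma``.  This
module implements both forms exactly as defined above and exposes the
discrepancy rather than hiding it (see :mod:`filmrelease` tests and the
methods note).

Descriptive film metrics (synthesis yield, swelling degree, release
efficiency) live here too, as they share the film bookkeeping.
"""

from __future__ import annotations

import dataclasses
import math
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
from scipy import optimize, special, stats

__all__ = [
    "ReleaseCurve",
    "FilmRecord",
    "HiguchiResult",
    "DiffusionEstimate",
    "SeriesModel",
    "SeriesFit",
    "film_yield",
    "swelling_ratio",
    "release_efficiency",
    "higuchi_predict",
    "fit_higuchi",
    "diffusion_from_higuchi",
    "series_release",
    "fit_series",
    "InsufficientDataError",
    "FitFailureError",
    "DEFAULT_BURST_WINDOW",
]

#: Default burst-phase fit window in minutes (initial rapid-release phase).
DEFAULT_BURST_WINDOW: tuple[float, float] = (0.0, 30.0)

# Fractions may exceed 1 slightly (normalisation by a noisy/rounded M_inf).
_FRACTION_TOL = 0.05


class InsufficientDataError(ValueError):
    """Raised when a fit window contains too few usable points."""


class FitFailureError(RuntimeError):
    """Raised when an iterative fit fails to converge.

    Carries the last iterate and residual for diagnosis.
    """

    def __init__(self, message: str, last_sigma: float, last_residual: float):
        super().__init__(message)
        self.last_sigma = last_sigma
        self.last_residual = last_residual


@dataclass(frozen=True)
class ReleaseCurve:
    """One film's cumulative release versus time.

    Parameters
    ----------
    sample_id : str
        Film label (e.g. ``"F1"``).
    times : array-like of float
        Sampling times in minutes, strictly increasing, all >= 0.
    values : array-like of float
        Cumulative released amount.  Interpreted in mg/mL when
        ``value_kind="amount"`` or as a dimensionless fraction of the
        asymptotic amount when ``value_kind="fraction"``.
    value_kind : {"amount", "fraction"}
    m_inf : float, optional
        Asymptotic / loaded reference amount ``M_inf`` used to normalise
        amounts to fractions.  Required when ``value_kind="amount"``.
    """

    sample_id: str
    times: np.ndarray
    values: np.ndarray
    value_kind: str = "amount"
    m_inf: float | None = None

    def __post_init__(self) -> None:
        t = np.asarray(self.times, dtype=float)
        v = np.asarray(self.values, dtype=float)
        object.__setattr__(self, "times", t)
        object.__setattr__(self, "values", v)
        if t.ndim != 1 or v.shape != t.shape:
            raise ValueError("times and values must be 1-D and equal length")
        if t.size and (np.any(t < 0) or np.any(np.diff(t) <= 0)):
            raise ValueError("times must be strictly increasing and >= 0")
        if np.any(v < 0):
            raise ValueError("released values must be >= 0")
        if self.value_kind not in ("amount", "fraction"):
            raise ValueError(f"unknown value_kind {self.value_kind!r}")
        if self.value_kind == "fraction":
            if np.any(v > 1.0 + _FRACTION_TOL):
                raise ValueError("fractions exceed 1 beyond tolerance")
        else:
            if self.m_inf is None:
                raise ValueError("m_inf is required when value_kind='amount'")
        if self.m_inf is not None and not self.m_inf > 0:
            raise ValueError("m_inf must be > 0")

    def fractions(self) -> np.ndarray:
        """Release fractions ``M_t / M_inf`` (values already fractions pass through)."""
        if self.value_kind == "fraction":
            return self.values.copy()
        return self.values / self.m_inf


@dataclass(frozen=True)
class FilmRecord:
    """Per-film metadata: geometry, loading and descriptive metrics."""

    sample_id: str
    thickness_d: float  # mm
    loaded_mt: float = math.nan  # mg
    released_max: float = math.nan  # mg/mL
    swelling_degree: float = math.nan  # percent
    yield_pct: float = math.nan  # percent

    def __post_init__(self) -> None:
        if not self.thickness_d > 0:
            raise ValueError("thickness_d must be > 0")
        for name in ("loaded_mt", "released_max", "swelling_degree", "yield_pct"):
            val = getattr(self, name)
            if not math.isnan(val) and val < 0:
                raise ValueError(f"{name} must be >= 0")
        if not math.isnan(self.loaded_mt) and not math.isnan(self.released_max):
            eff = release_efficiency(self.released_max, self.loaded_mt)
            # Source tables mix mg and mg/mL; allow slight overshoot.
            if not 0.0 <= eff <= 110.0:
                raise ValueError(
                    f"release efficiency {eff:.1f}% outside [0, 110] for "
                    f"{self.sample_id}: unit mismatch likely"
                )


@dataclass(frozen=True)
class HiguchiResult:
    """Fitted Higuchi constant with its window and fit quality.

    ``corr`` is the Pearson correlation between observed fractions and the
    fitted ``k_h*sqrt(t)`` over the window (NaN when degenerate).
    """

    k_h: float  # 1/sqrt(min)
    window: tuple[float, float]  # minutes
    n_points: int
    corr: float
    degenerate: bool = False

    def __post_init__(self) -> None:
        if self.k_h < 0:
            raise ValueError("k_h must be >= 0")
        if not self.window[0] < self.window[1]:
            raise ValueError("window must satisfy t_lo < t_hi")
        if self.n_points < 2:
            raise ValueError("n_points must be >= 2")


@dataclass(frozen=True)
class DiffusionEstimate:
    """Diffusion coefficient derived from a Higuchi constant and thickness."""

    sigma_mm2_per_min: float
    sigma_mm2_per_s: float
    thickness_d: float  # mm
    source_k_h: float  # 1/sqrt(min)


@dataclass(frozen=True)
class SeriesModel:
    """Parameters of the truncated erfc-series slab-diffusion solution."""

    sigma: float  # mm^2/min
    thickness_d: float  # mm
    truncation_n: int = 2

    def __post_init__(self) -> None:
        if not self.sigma > 0:
            raise ValueError("sigma must be > 0")
        if not self.thickness_d > 0:
            raise ValueError("thickness_d must be > 0")
        if self.truncation_n < 0:
            raise ValueError("truncation_n must be >= 0")


@dataclass(frozen=True)
class SeriesFit:
    """Result of fitting the series model to a release curve."""

    model: SeriesModel | None
    corr: float
    rss: float
    n_points: int
    degenerate: bool = False


def film_yield(dry_weight: float, total_reactant_weight: float) -> float:
    """Synthesis yield of a film in percent: 100 * dry / total reactants.

    Both weights in grams.
    """
    if not total_reactant_weight > 0:
        raise ValueError("total_reactant_weight must be > 0")
    if dry_weight < 0:
        raise ValueError("dry_weight must be >= 0")
    return 100.0 * dry_weight / total_reactant_weight


def swelling_ratio(w_swollen: float, w_dry: float) -> float:
    """Swelling degree Q in percent: 100 * (w_s - w_0) / w_0.

    Negative results (deswelling) are allowed; ``w_dry`` must be positive.
    """
    if not w_dry > 0:
        raise ValueError("w_dry must be > 0")
    return 100.0 * (w_swollen - w_dry) / w_dry


def release_efficiency(released: float, loaded: float) -> float:
    """Release efficiency in percent: 100 * released / loaded."""
    if not loaded > 0:
        raise ValueError("loaded must be > 0")
    return 100.0 * released / loaded


def higuchi_predict(t, k_h: float):
    """Higuchi release fraction ``k_h * sqrt(t)``; vectorised over ``t`` (min)."""
    t = np.asarray(t, dtype=float)
    if np.any(t < 0):
        raise ValueError("t must be >= 0")
    if k_h < 0:
        raise ValueError("k_h must be >= 0")
    out = k_h * np.sqrt(t)
    return float(out) if out.ndim == 0 else out


def fit_higuchi(
    curve: ReleaseCurve,
    window: tuple[float, float] = DEFAULT_BURST_WINDOW,
) -> HiguchiResult:
    """Fit the Higuchi constant on the burst phase of a release curve.

    The slope of fraction versus sqrt(t) is fitted by least squares
    constrained through the origin over points with ``t_lo <= t <= t_hi``
    and ``t > 0``:

        k_h = sum(f_i * sqrt(t_i)) / sum(t_i)

    ``corr`` is the Pearson correlation between observed and predicted
    fractions on the window.  All-zero fractions give a degenerate result
    with ``k_h = 0`` rather than an exception.
    """
    t_lo, t_hi = window
    if not t_lo < t_hi:
        raise ValueError("window must satisfy t_lo < t_hi")
    t = curve.times
    f = curve.fractions()
    mask = (t >= t_lo) & (t <= t_hi) & (t > 0)
    t_w, f_w = t[mask], f[mask]
    if t_w.size < 2:
        raise InsufficientDataError(
            f"only {t_w.size} usable point(s) in window [{t_lo}, {t_hi}] min"
        )
    if np.all(f_w == 0):
        return HiguchiResult(
            k_h=0.0, window=(t_lo, t_hi), n_points=int(t_w.size),
            corr=math.nan, degenerate=True,
        )
    sqrt_t = np.sqrt(t_w)
    k_h = float(np.dot(f_w, sqrt_t) / np.sum(t_w))
    pred = k_h * sqrt_t
    if np.ptp(pred) == 0 or np.ptp(f_w) == 0:
        corr = math.nan
    else:
        corr = float(stats.pearsonr(f_w, pred).statistic)
    return HiguchiResult(
        k_h=max(k_h, 0.0), window=(t_lo, t_hi), n_points=int(t_w.size), corr=corr
    )


def diffusion_from_higuchi(k_h: float, thickness_d: float) -> DiffusionEstimate:
    """Convert a Higuchi constant to a diffusion coefficient.

    Inverts the film-thickness relation ``k_H = 2*sqrt(sigma)/d``:

        sigma = (k_H * d / 2)^2    [mm^2/min]

    and also reports sigma in mm^2/s (divide by 60).
    """
    if k_h < 0:
        raise ValueError("k_h must be >= 0")
    if not thickness_d > 0:
        raise ValueError("thickness_d must be > 0")
    sigma_min = (k_h * thickness_d / 2.0) ** 2
    return DiffusionEstimate(
        sigma_mm2_per_min=sigma_min,
        sigma_mm2_per_s=sigma_min / 60.0,
        thickness_d=thickness_d,
        source_k_h=k_h,
    )


def series_release(t, model: SeriesModel):
    """Truncated erfc-series release fraction for a slab of thickness d.

    f(t) = 2*sqrt(sigma*t/d^2) * [ pi^{-1/2}
           + sum_{n=1}^{N} (-1)^n * erfc( n*d / (2*sqrt(sigma*t)) ) ]

    with N = ``model.truncation_n``.  f(0) = 0 by continuity.  The erfc
    terms underflow harmlessly to 0 for large arguments, so the early-time
    limit is exact.  Vectorised over ``t`` (minutes).
    """
    t = np.asarray(t, dtype=float)
    if np.any(t < 0):
        raise ValueError("t must be >= 0")
    scalar = t.ndim == 0
    t = np.atleast_1d(t)
    f = np.zeros_like(t)
    pos = t > 0
    if np.any(pos):
        tau = np.sqrt(model.sigma * t[pos]) / model.thickness_d  # sqrt(sigma t)/d
        bracket = np.full_like(tau, 1.0 / math.sqrt(math.pi))
        for n in range(1, model.truncation_n + 1):
            bracket += (-1.0) ** n * special.erfc(n / (2.0 * tau))
        f[pos] = 2.0 * tau * bracket
    return float(f[0]) if scalar else f


def fit_series(
    curve: ReleaseCurve,
    thickness_d: float,
    truncation_n: int = 2,
    sigma_init: float | None = None,
) -> SeriesFit:
    """Fit the series-model diffusion coefficient to a release curve.

    Minimises the sum of squared residuals between observed fractions and
    :func:`series_release` over all curve points, optimising log10(sigma)
    (sigma spans orders of magnitude across films).  ``sigma_init`` in
    mm^2/min seeds the optimiser; when omitted it is derived from a
    burst-phase Higuchi fit via the thickness relation.

    Returns a :class:`SeriesFit`; an all-zero curve yields a degenerate
    result (``model=None``), and non-convergence raises
    :class:`FitFailureError` with the last iterate.
    """
    if not thickness_d > 0:
        raise ValueError("thickness_d must be > 0")
    t = curve.times
    f = curve.fractions()
    usable = t > 0
    t_u, f_u = t[usable], f[usable]
    if t_u.size < 3:
        raise InsufficientDataError("need >= 3 points with t > 0")
    if np.all(f_u == 0):
        return SeriesFit(model=None, corr=math.nan, rss=0.0,
                         n_points=int(t_u.size), degenerate=True)

    if sigma_init is None:
        try:
            kh = fit_higuchi(curve).k_h
        except InsufficientDataError:
            kh = 0.0
        sigma_init = diffusion_from_higuchi(kh, thickness_d).sigma_mm2_per_min
        if sigma_init <= 0:
            sigma_init = (thickness_d / 2.0) ** 2 / np.median(t_u)
    if not sigma_init > 0:
        raise ValueError("sigma_init must be > 0")

    def residuals(log10_sigma: np.ndarray) -> np.ndarray:
        model = SeriesModel(10.0 ** log10_sigma[0], thickness_d, truncation_n)
        return series_release(t_u, model) - f_u

    x0 = np.array([math.log10(sigma_init)])
    sol = optimize.least_squares(residuals, x0, method="lm", xtol=1e-14, ftol=1e-14)
    sigma_hat = float(10.0 ** sol.x[0])
    rss = float(2.0 * sol.cost)
    if not sol.success:
        raise FitFailureError(
            f"series fit did not converge: {sol.message}", sigma_hat, rss
        )
    model = SeriesModel(sigma_hat, thickness_d, truncation_n)
    pred = series_release(t_u, model)
    if np.ptp(pred) == 0 or np.ptp(f_u) == 0:
        corr = math.nan
    else:
        corr = float(stats.pearsonr(f_u, pred).statistic)
    return SeriesFit(model=model, corr=corr, rss=rss, n_points=int(t_u.size))
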