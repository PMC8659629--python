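"""Non-manifest release patterns: complex-amplitude dynamics on hydrogel films.

Beneath the measurable release curve the model posits an oscillatory
background.  In a constant-potential regime the density obeys the harmonic
equation ``rho'' + k^2 rho = 0`` whose solution is labelled by a complex
amplitude z and a phase; the hidden SL(2,R) symmetry acts on z by Möbius
(fractional-linear) maps, synchronising structural units in amplitude as
well as phase.  Non-stationary states come from a harmonic-map principle on
the Poincaré half-plane, giving

    z(chi, alpha) = i (cosh chi - e^{-i alpha} sinh chi)
                    / (cosh chi + e^{-i alpha} sinh chi)

and, after the substitution r = coth(chi) and alpha = 2*omega*t,

    Re z = 2 r sin(2 w t) / Delta,   Im z = (1 - r^2) / Delta,
    Delta = 1 + r^2 + 2 r cos(2 w t).

Note on conventions: the fractional-linear algebra above fixes the two
components of z only up to overall sign; this module adopts the signs shown
(so that ``z_pattern(coth chi, w, t) == -z_harmonic(chi, 2 w t)`` exactly).
The *as-typeset* variant of the pattern amplitude — both components summed
on the imaginary axis, whose modulus is ``|Re z + Im z|`` — is exposed as
:func:`signed_amplitude`; its rectification cusp is what produces the
period-doubling signature for r > sqrt(2) - 1 (see docs/methods.md).

The time scale of the dynamics is set by omega (the interaction-scale
factor); |z| is exactly periodic in t with period pi/omega.  Attractors are
reconstructed from scalar traces by standard delay embedding.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
from scipy.signal import find_peaks

__all__ = [
    "StationaryDensityParams",
    "MobiusParams",
    "PatternParams",
    "EmbeddedTrajectory",
    "stationary_density",
    "mobius_apply",
    "mobius_compose",
    "z_harmonic",
    "z_pattern",
    "amplitude_map",
    "time_traces",
    "signed_amplitude",
    "peak_count",
    "delay_embed",
    "PoleError",
    "DELTA_EPS",
]

#: Mask tolerance on the modulus of the denominator 1 + r^2 + 2 r cos(2wt).
DELTA_EPS = 1e-9


class PoleError(ZeroDivisionError):
    """Raised when a fractional-linear map is evaluated at its pole."""


@dataclass(frozen=True)
class StationaryDensityParams:
    """Parameters of the stationary density rho(x) = 2 Re(z0 e^{i(kx+phi)})."""

    k: float  # wavenumber, 1/mm
    amp: complex  # complex amplitude z0
    phase: float = 0.0  # radians


@dataclass(frozen=True)
class MobiusParams:
    """Real parameters (a, b, c, d) of the SL(2,R) action z -> (az+b)/(cz+d)."""

    a: float
    b: float
    c: float
    d: float

    def __post_init__(self) -> None:
        if self.det == 0:
            raise ValueError("ad - bc must be nonzero")

    @property
    def det(self) -> float:
        return self.a * self.d - self.b * self.c

    def normalized(self) -> "MobiusParams":
        """Rescale so that ad - bc = 1 (requires positive determinant)."""
        det = self.det
        if det <= 0:
            raise ValueError("normalisation requires ad - bc > 0")
        s = math.sqrt(det)
        return MobiusParams(self.a / s, self.b / s, self.c / s, self.d / s)

    def as_matrix(self) -> np.ndarray:
        return np.array([[self.a, self.b], [self.c, self.d]], dtype=float)


@dataclass(frozen=True)
class PatternParams:
    """Grids for a 2-D amplitude map: |z(r, t)| at fixed omega."""

    omega: float  # rad / time unit
    r_grid: np.ndarray
    t_grid: np.ndarray

    def __post_init__(self) -> None:
        if not self.omega > 0:
            raise ValueError("omega must be > 0")
        r = np.asarray(self.r_grid, dtype=float)
        t = np.asarray(self.t_grid, dtype=float)
        if r.size == 0 or t.size == 0:
            raise ValueError("grids must be non-empty")
        object.__setattr__(self, "r_grid", r)
        object.__setattr__(self, "t_grid", t)

    @classmethod
    def default(cls, omega: float) -> "PatternParams":
        """Default map grid: r in [0, 0.99] (400 pts), t over 4 periods (800 pts)."""
        period = math.pi / omega
        return cls(
            omega=omega,
            r_grid=np.linspace(0.0, 0.99, 400),
            t_grid=np.linspace(0.0, 4 * period, 800),
        )


@dataclass(frozen=True)
class EmbeddedTrajectory:
    """Delay-embedded trajectory: point k = (s[k], s[k+lag], ..., s[k+(dim-1)lag])."""

    lag: int
    dim: int
    points: np.ndarray  # shape (n_points, dim)

    def __post_init__(self) -> None:
        if self.dim < 2:
            raise ValueError("dim must be >= 2")
        if self.lag < 1:
            raise ValueError("lag must be >= 1")


def stationary_density(x, params: StationaryDensityParams):
    """Real stationary density rho(x) = z e^{i(kx+phi)} + conj, i.e. 2 Re(...).

    Solves rho'' + k^2 rho = 0 for any complex amplitude; vectorised in x (mm).
    """
    x = np.asarray(x, dtype=float)
    rho = 2.0 * np.real(params.amp * np.exp(1j * (params.k * x + params.phase)))
    return float(rho) if rho.ndim == 0 else rho


def mobius_apply(z: complex, g: MobiusParams) -> complex:
    """Apply the fractional-linear map z -> (az + b)/(cz + d)."""
    den = g.c * z + g.d
    if abs(den) < DELTA_EPS:
        raise PoleError(f"z = {z} is at (or near) the pole of {g}")
    return (g.a * z + g.b) / den

def mobius_compose(g2: MobiusParams, g1: MobiusParams) -> MobiusParams:
    """Parameters of "g1 then g2", i.e. the matrix product g2 @ g1."""
    m = g2.as_matrix() @ g1.as_matrix()
    return MobiusParams(m[0, 0], m[0, 1], m[1, 0], m[1, 1])


def z_harmonic(chi: float, alpha: float) -> complex:
    """Harmonic-map complex amplitude.

    z = i (cosh chi - e^{-i alpha} sinh chi) / (cosh chi + e^{-i alpha} sinh chi)

    chi parameterises the amplitude coordinate (r = coth chi), alpha the
    phase of the non-stationary rotation.
    """
    ch, sh = math.cosh(chi), math.sinh(chi)
    e = complex(math.cos(alpha), -math.sin(alpha))  # e^{-i alpha}
    den = ch + e * sh
    if abs(den) < DELTA_EPS:
        raise PoleError(f"(chi={chi}, alpha={alpha}) is at the map's pole")
    return 1j * (ch - e * sh) / den


def _delta(r, theta):
    return 1.0 + r * r + 2.0 * r * np.cos(theta)


def z_pattern(r, omega: float, t):
    """Pattern amplitude z(r, omega, t).

    Re z = 2 r sin(2 w t) / Delta,  Im z = (1 - r^2) / Delta,
    Delta = 1 + r^2 + 2 r cos(2 w t).

    Vectorised over broadcastable ``r`` and ``t``.  Points with
    ``|Delta| < DELTA_EPS`` (the singular ring r = 1, 2wt = pi mod 2pi) are
    returned as NaN + NaN j so maps can mask them.
    """
    r = np.asarray(r, dtype=float)
    t = np.asarray(t, dtype=float)
    theta = 2.0 * omega * t
    delta = _delta(r, theta)
    scalar = delta.ndim == 0
    delta = np.atleast_1d(delta)
    theta = np.broadcast_to(np.atleast_1d(theta), delta.shape)
    r_b = np.broadcast_to(np.atleast_1d(r), delta.shape)
    ok = np.abs(delta) >= DELTA_EPS
    z = np.full(delta.shape, np.nan + 1j * np.nan, dtype=complex)
    z[ok] = (2.0 * r_b[ok] * np.sin(theta[ok]) + 1j * (1.0 - r_b[ok] ** 2)) / delta[ok]
    return complex(z[0]) if scalar else z


def amplitude_map(params: PatternParams) -> np.ndarray:
    """2-D map M[i, j] = |z(r_grid[i], omega, t_grid[j])| (NaN at singularities)."""
    r = params.r_grid[:, None]
    t = params.t_grid[None, :]
    return np.abs(z_pattern(r, params.omega, t))


def time_traces(r: float, omega: float, t_grid) -> dict[str, np.ndarray]:
    """Aligned time traces of the pattern amplitude at fixed r.

    Returns a dict with keys ``"t"``, ``"abs_z"``, ``"re_z"``, ``"im_z"``
    and ``"signed_abs_z"`` (the as-typeset amplitude |Re z + Im z|, the
    trace carrying the period-doubling signature).  ``|z|^2 = Re^2 + Im^2``
    holds at every sample.
    """
    t = np.asarray(t_grid, dtype=float)
    z = z_pattern(r, omega, t)
    return {
        "t": t,
        "abs_z": np.abs(z),
        "re_z": z.real,
        "im_z": z.imag,
        "signed_abs_z": np.abs(z.real + z.imag),
    }


def signed_amplitude(r, omega: float, t):
    """Amplitude of the single-axis (as-typeset) pattern form, |Re z + Im z|.

    Equals |2 r sin(2wt) + 1 - r^2| / Delta.  For r > sqrt(2) - 1 the
    numerator changes sign within a period and the rectified trace has two
    local maxima per period instead of one (period-doubling indicator).
    """
    z = z_pattern(r, omega, t)
    return np.abs(np.real(z) + np.imag(z))


def peak_count(series, per_period_samples: int | None = None) -> int:
    """Count local maxima of a (periodic) sampled series.

    When ``per_period_samples`` is given the series is assumed to cover
    exactly one period; the count is then wrap-aware (the series is tiled
    so maxima at the period boundary are not missed or double-counted).
    """
    s = np.asarray(series, dtype=float)
    if per_period_samples is not None:
        if s.size != per_period_samples:
            raise ValueError("series length must equal per_period_samples")
        tiled = np.tile(s, 3)
        pk, _ = find_peaks(tiled)
        return int(np.sum((pk >= s.size) & (pk < 2 * s.size)))
    pk, _ = find_peaks(s)
    return int(pk.size)


def delay_embed(series, lag: int, dim: int) -> EmbeddedTrajectory:
    """Reconstruct a trajectory from a scalar series by delay embedding.

    Point k is (s[k], s[k+lag], ..., s[k+(dim-1)*lag]); the trajectory has
    ``len(series) - (dim-1)*lag`` points.
    """
    s = np.asarray(series, dtype=float)
    if s.ndim != 1:
        raise ValueError("series must be 1-D")
    if lag < 1 or dim < 2:
        raise ValueError("need lag >= 1 and dim >= 2")
    n_pts = s.size - (dim - 1) * lag
    if n_pts < 1:
        raise ValueError(
            f"series of length {s.size} too short for dim={dim}, lag={lag}"
        )
    idx = np.arange(n_pts)[:, None] + lag * np.arange(dim)[None, :]
    return EmbeddedTrajectory(lag=lag, dim=dim, points=s[idx])
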