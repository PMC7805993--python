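"""Two-state Galam majority model with contrarians, composed with a
noisy-perception line, plus fixed-point analysis and profile fitting.

The update map for odd group size ``m`` is

    g(s, a) = (1 - a) * P_m(s) + a * P_m(1 - s),

where ``P_m(s) = Σ_{k > m/2} C(m, k) s^k (1-s)^{m-k}`` is the
probability that a random group of ``m`` agents has an A majority, and
``a`` is the contrarian fraction — agents adopting the group *minority*.
For ``m = 5`` the majority polynomial is ``10 s³(1-s)² + 5 s⁴(1-s) +
s⁵``, written out explicitly in :func:`galam_update`.

Perception noise enters by composing ``g`` with the local-perception
line ``s ↦ c1·s + c2``; under well mixing ``c1 = 1 - 2γ`` and
``c2 = γ``.  The composed drift, scaled by an amplitude ``d``, is the
model's prediction for the measured ``Δs(s)`` profile.  Contrarians are
used here as an effective parameter: a fitted ``a > 0`` absorbs the bias
that spatially correlated neighbourhoods exert against the global
majority.  As ``a`` grows the two outer stable fixed points of the
composed map move inwards and annihilate with the unstable midpoint at a
critical density ``a_c`` — for ``γ = 0.2`` at ``a_c = 1/18 ≈ 0.0555`` —
leaving a single stable state at ``s = 1/2``.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from math import comb
from typing import Sequence

import numpy as np
from scipy import optimize

from .observables import DeltaProfile

__all__ = [
    "GalamParams",
    "FixedPoint",
    "FixedPointSet",
    "galam_update",
    "galam_update_general",
    "majority_prob",
    "wellmixed_local",
    "corrected_delta",
    "fixed_points",
    "critical_contrarian_density",
    "critical_contrarian_density_closed_form",
    "fit_contrarian",
    "GalamFit",
]


def _check_unit(x, name: str) -> None:
    arr = np.asarray(x, dtype=float)
    if np.any(arr < -1e-12) or np.any(arr > 1.0 + 1e-12):
        raise ValueError(f"{name} must lie in [0, 1]")


def majority_prob(s, m: int = 5):
    """Probability that a group of ``m`` i.i.d. Bernoulli(``s``) opinions
    has an A majority (``m`` odd, so ties cannot occur)."""
    if m < 3 or m % 2 == 0:
        raise ValueError("group size m must be odd and >= 3")
    s = np.asarray(s, dtype=float)
    out = np.zeros_like(s)
    for k in range((m + 1) // 2, m + 1):
        out = out + comb(m, k) * s**k * (1.0 - s) ** (m - k)
    return out


def galam_update(s, a):
    """Galam update for group size 5, as an explicit polynomial.

    ``g(s, a) = (1-a)(10 s³(1-s)² + 5 s⁴(1-s) + s⁵) + a(10 (1-s)³ s² +
    5 (1-s)⁴ s + (1-s)⁵)``.  The binomial-sum route
    :func:`galam_update_general` is the independent cross-check.
    """
    _check_unit(s, "s")
    _check_unit(a, "a")
    s = np.asarray(s, dtype=float)
    q = 1.0 - s
    maj = 10.0 * s**3 * q**2 + 5.0 * s**4 * q + s**5
    maj_flip = 10.0 * q**3 * s**2 + 5.0 * q**4 * s + q**5
    out = (1.0 - np.asarray(a)) * maj + np.asarray(a) * maj_flip
    return out if out.ndim else float(out)


def galam_update_general(s, a, m: int = 5):
    """Galam update for any odd group size via the binomial majority sum.

    A contrarian fraction ``a`` adopts the group minority, equivalent to
    applying the majority rule to the mirrored state:
    ``(1-a)·P_m(s) + a·P_m(1-s)``.  Values of ``a`` outside ``[0, 1]``
    are accepted for bifurcation scans (an ``a < 0`` is an effective
    conformist excess); ``s`` must be a valid fraction.
    """
    _check_unit(s, "s")
    s = np.asarray(s, dtype=float)
    a = np.asarray(a, dtype=float)
    out = (1.0 - a) * majority_prob(s, m) + a * majority_prob(1.0 - s, m)
    return out if out.ndim else float(out)


def wellmixed_local(s, gamma):
    """Asymptotic local perception under the well-mixed assumption.

    With misperception probability ``γ`` and opinions independent of
    position, an agent's memory samples A with probability
    ``(1 - 2γ)·s + γ``: at ``s = 0`` it still perceives ``γ``, at
    ``s = 1`` only ``1 - γ``.
    """
    _check_unit(s, "s")
    _check_unit(gamma, "gamma")
    out = (1.0 - 2.0 * np.asarray(gamma)) * np.asarray(s, dtype=float) + np.asarray(gamma)
    return out if out.ndim else float(out)


@dataclass(frozen=True)
class GalamParams:
    """Parameters of the perception-composed contrarian model.

    ``c1``/``c2`` default to the well-mixed line coefficients
    ``1 - 2γ`` / ``γ``; supply both to override with an empirically
    fitted perception line.
    """

    a: float
    d: float = 1.0
    gamma: float = 0.2
    m: int = 5
    c1: float | None = None
    c2: float | None = None

    def __post_init__(self) -> None:
        if self.m < 3 or self.m % 2 == 0:
            raise ValueError("m must be odd and >= 3")
        if not -1.0 < self.a < 1.0:
            raise ValueError("contrarian density a must lie in (-1, 1)")
        if self.d <= 0:
            raise ValueError("amplitude d must be positive")
        if not 0.0 <= self.gamma <= 1.0:
            raise ValueError("gamma must lie in [0, 1]")
        if (self.c1 is None) != (self.c2 is None):
            raise ValueError("c1 and c2 must be overridden together")
        if self.c1 is not None:
            if self.c2 < 0 or self.c1 + self.c2 > 1:
                raise ValueError("perception line must map [0,1] into [0,1]")

    @property
    def line(self) -> tuple[float, float]:
        if self.c1 is not None:
            return self.c1, self.c2
        return 1.0 - 2.0 * self.gamma, self.gamma


def corrected_delta(s, params: GalamParams, scale_whole_map: bool = False):
    """Model drift ``Δs(s)`` of the perception-composed contrarian map.

    Default placement of the amplitude: ``d · (g(c1·s + c2, a) - s)`` —
    ``d`` scales the drift magnitudes without moving its zeros, so the
    fixed-point structure depends on ``a`` and ``γ`` alone.  With
    ``scale_whole_map=True`` the alternative reading ``d·g(...) - s`` is
    used instead.
    """
    c1, c2 = params.line
    s = np.asarray(s, dtype=float)
    g = galam_update_general(c1 * s + c2, params.a, params.m)
    if scale_whole_map:
        out = params.d * g - s
    else:
        out = params.d * (g - s)
    return out if out.ndim else float(out)


@dataclass(frozen=True)
class FixedPoint:
    location: float
    stable: bool


@dataclass
class FixedPointSet:
    """Roots of the model drift on [0, 1], sorted ascending."""

    points: list[FixedPoint]

    @property
    def locations(self) -> np.ndarray:
        return np.array([p.location for p in self.points])

    @property
    def stable(self) -> list[FixedPoint]:
        return [p for p in self.points if p.stable]

    @property
    def unstable(self) -> list[FixedPoint]:
        return [p for p in self.points if not p.stable]

    def __len__(self) -> int:
        return len(self.points)


_STABILITY_STEP = 1e-4  # drift-derivative probe; see docs/methods.md


def fixed_points(
    params: GalamParams,
    grid: float = 1e-4,
    xtol: float = 1e-10,
    scale_whole_map: bool = False,
) -> FixedPointSet:
    """All fixed points of the composed map, with stability flags.

    Roots of the drift are located by a uniform sign-change scan (step
    ``grid``) refined by Brent's method to ``xtol``; exact zeros at grid
    nodes are kept directly.  A root is stable when the drift slope
    there is negative (probed by a central difference wide enough to
    stay above floating-point noise near a degenerate root).
    """
    f = lambda x: corrected_delta(x, params, scale_whole_map)
    xs = np.linspace(0.0, 1.0, round(1.0 / grid) + 1)
    fs = np.asarray(f(xs))

    roots: list[float] = []
    zero = np.abs(fs) < 1e-14
    for x in xs[zero]:
        roots.append(float(x))
    sign = np.sign(fs)
    flip = (sign[:-1] * sign[1:]) < 0
    for i in np.nonzero(flip)[0]:
        r = optimize.brentq(f, xs[i], xs[i + 1], xtol=xtol)
        roots.append(float(r))
    roots = sorted(roots)
    # Merge duplicates (a grid-node zero re-found by Brent in the next
    # cell); genuinely distinct roots can sit one cell apart near a
    # saddle-node, so the tolerance stays far below ``grid``.
    merged: list[float] = []
    for r in roots:
        if not merged or r - merged[-1] > 1e-6:
            merged.append(r)

    pts = []
    h = _STABILITY_STEP
    for r in merged:
        lo, hi = max(0.0, r - h), min(1.0, r + h)
        slope = (f(hi) - f(lo)) / (hi - lo)
        pts.append(FixedPoint(location=r, stable=bool(slope < 0)))
    return FixedPointSet(pts)


def _majority_slope_at_half(m: int) -> float:
    # P_m'(1/2) = m * C(m-1, (m-1)/2) / 2^(m-1); equals 30/16 for m = 5.
    return m * comb(m - 1, (m - 1) // 2) / 2 ** (m - 1)


def critical_contrarian_density_closed_form(gamma: float, m: int = 5) -> float:
    """Closed-form critical contrarian density.

    The outer fixed points merge with the midpoint when the composed-map
    slope at ``s = 1/2`` equals one: ``(1 - 2a)·(1 - 2γ)·P_m'(1/2) = 1``,
    giving ``a_c = (1 - 1/((1 - 2γ)·P_m'(1/2))) / 2``.  For ``γ = 0.2``,
    ``m = 5`` this is exactly ``1/18``.
    """
    if not 0.0 <= gamma < 0.5:
        raise ValueError("gamma must lie in [0, 0.5): beyond that the map is monostable")
    slope = (1.0 - 2.0 * gamma) * _majority_slope_at_half(m)
    return 0.5 * (1.0 - 1.0 / slope)


def critical_contrarian_density(
    gamma: float, m: int = 5, tol: float = 1e-8
) -> float:
    """Critical contrarian density by bisection on the stable-point count.

    Searches for the smallest ``a`` at which the number of stable fixed
    points of the composed map drops to one.  Negative values indicate
    that perception noise alone already leaves the map monostable and an
    effective conformist excess would be needed for bistability.  Agrees
    with :func:`critical_contrarian_density_closed_form` to ``tol``.
    """
    if not 0.0 <= gamma < 0.5:
        raise ValueError("gamma must lie in [0, 0.5): beyond that the map is monostable")

    def bistable(a: float) -> bool:
        fps = fixed_points(GalamParams(a=a, gamma=gamma, m=m))
        return len(fps.stable) >= 2

    # For gamma large enough that perception noise alone is monostable the
    # transition sits at negative a (an effective conformist excess), and
    # the bistable window below it can be narrow — search in small steps.
    hi = 0.5
    lo = 0.0
    while not bistable(lo):
        lo -= 0.05
        if lo <= -1.0:
            raise RuntimeError("no bistable regime found for this gamma")
    if bistable(hi):  # pragma: no cover - cannot happen for valid gamma
        raise RuntimeError("map still bistable at a = 0.5")
    while hi - lo > tol:
        mid = 0.5 * (lo + hi)
        if bistable(mid):
            lo = mid
        else:
            hi = mid
    return 0.5 * (lo + hi)


@dataclass
class GalamFit:
    """Result of calibrating (a, d) against a measured drift profile."""

    a: float
    d: float
    residual_rms: float
    rms_inside: float
    rms_outside: float
    residuals: np.ndarray  # per populated bin, model - measured
    bin_centers: np.ndarray
    counts: np.ndarray
    diagnostic_interval: tuple[float, float]


def fit_contrarian(
    profile: DeltaProfile,
    gamma: float,
    fit_interval: tuple[float, float] | None = None,
    m: int = 5,
    c1: float | None = None,
    c2: float | None = None,
    diagnostic_interval: tuple[float, float] = (0.17, 0.83),
    scale_whole_map: bool = False,
) -> GalamFit:
    """Count-weighted least squares of the model drift against ``Δs(s)``.

    Optimises ``a ∈ [0, 0.5)`` and ``d ∈ (0, 10]`` over the populated
    bins inside ``fit_interval`` (default: all of ``[0, 1]``), starting
    from a coarse multi-start grid to dodge local minima.  The returned
    diagnostics split the residual RMS into the central interval and the
    tails, where the contrarian correction is known to degrade.
    """
    mask = profile.populated & np.isfinite(profile.mean_delta)
    if fit_interval is not None:
        lo, hi = fit_interval
        mask &= (profile.centers >= lo) & (profile.centers <= hi)
    if mask.sum() < 5:
        raise ValueError("need at least five populated bins in the fit interval")
    x = profile.centers[mask]
    y = profile.mean_delta[mask]
    w = profile.counts[mask].astype(float)
    if np.max(np.abs(y)) < 1e-12:
        raise ValueError("profile is identically zero: (a, d) not identifiable")
    sw = np.sqrt(w / w.sum())

    def make_params(a: float, d: float) -> GalamParams:
        return GalamParams(a=a, d=d, gamma=gamma, m=m, c1=c1, c2=c2)

    def resid(theta: np.ndarray) -> np.ndarray:
        a, d = theta
        return sw * (corrected_delta(x, make_params(a, d), scale_whole_map) - y)

    best = None
    for a0 in (0.0, 0.02, 0.05, 0.1, 0.2, 0.3):
        for d0 in (0.05, 0.25, 1.0, 4.0):
            sol = optimize.least_squares(
                resid,
                x0=[a0, d0],
                bounds=([0.0, 1e-8], [0.5 - 1e-9, 10.0]),
                xtol=1e-14,
                ftol=1e-14,
                gtol=1e-14,
            )
            if best is None or sol.cost < best.cost:
                best = sol
    a_hat, d_hat = float(best.x[0]), float(best.x[1])

    # Diagnostics over every populated bin, not just the fitted interval.
    full = profile.populated & np.isfinite(profile.mean_delta)
    xs, ys = profile.centers[full], profile.mean_delta[full]
    ws = profile.counts[full].astype(float)
    res = corrected_delta(xs, make_params(a_hat, d_hat), scale_whole_map) - ys
    lo, hi = diagnostic_interval
    inside = (xs > lo) & (xs < hi)

    def _rms(r: np.ndarray, wt: np.ndarray) -> float:
        if r.size == 0 or wt.sum() == 0:
            return float("nan")
        return float(np.sqrt(np.average(r**2, weights=wt)))

    return GalamFit(
        a=a_hat,
        d=d_hat,
        residual_rms=_rms(res, ws),
        rms_inside=_rms(res[inside], ws[inside]),
        rms_outside=_rms(res[~inside], ws[~inside]),
        residuals=res,
        bin_centers=xs,
        counts=profile.counts[full],
        diagnostic_interval=diagnostic_interval,
    )
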