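"""Urn model of collective decision-making with state-dependent feedback.

The urn holds ``N`` agents of opinion A or B.  Each turn an agent is
drawn with replacement and its opinion noted; with probability
``P_fb(s)`` the interaction is *positive* feedback (an agent of the
opposite opinion switches to the noted one, amplifying it) and otherwise
*negative* (an agent of the noted opinion switches away).  The majority
spreads when ``P_fb(s) > 1/2`` and erodes otherwise, giving the
macroscopic drift

    Δs = 4·e·(P_fb(s) - 1/2)·(s - 1/2),

for a time-scale constant ``e``.  The model has no notion of space or
group size, yet ``P_fb(s)`` measured from an agent-based simulation
absorbs the average effect of spatial correlation, which is what makes
the calibrated urn model an accurate one-dimensional surrogate.

``P_fb`` is estimated from directional revision counts.  Writing
``ρ(s)`` for the fraction of revisions that move *toward* the majority
bookkeeping convention chosen below, the mechanics give

    ρ_a(s) = r_a/(r_a + r_b) = s·P + (1-s)·(1-P),

which inverts to ``P = (ρ_a - 1 + s)/(2s - 1)`` for ``s ≠ 1/2``, with
``ρ`` constrained to ``[min(s, 1-s), max(s, 1-s)]``.  With ``r_b`` in
the numerator the same transform returns ``1 - P``; both conventions
are exposed and the default is the one under which feedback
probabilities used to *generate* revisions are recovered.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, replace
from typing import Literal

import numpy as np

from .observables import DeltaProfile, RevisionCounts, bin_centers, bin_index

__all__ = [
    "FeedbackProfile",
    "PfbSamples",
    "UrnRun",
    "estimate_pfb",
    "fit_pfb",
    "urn_delta",
    "fit_e",
    "simulate_urn",
]


@dataclass(frozen=True)
class FeedbackProfile:
    """Mirror-symmetric quartic feedback probability plus time scale.

    ``P_fb(s) = b0 + b1·u² + b2·u⁴`` with ``u = s - 1/2``; the even basis
    makes ``P_fb(s) = P_fb(1-s)`` hold by construction.  ``e`` is the
    drift time-scale constant (``None`` until fitted).
    """

    b0: float
    b1: float = 0.0
    b2: float = 0.0
    e: float | None = None

    def pfb(self, s):
        """Evaluate the feedback probability, clamped to [0, 1].

        The polynomial fit is unconstrained, so extrapolation may leave
        the unit interval; evaluation clamps (with a warning) because a
        probability is required downstream.
        """
        u = np.asarray(s, dtype=float) - 0.5
        raw = self.b0 + self.b1 * u**2 + self.b2 * u**4
        if np.any(raw < -1e-9) or np.any(raw > 1.0 + 1e-9):
            warnings.warn(
                "fitted P_fb leaves [0, 1]; clamping", RuntimeWarning, stacklevel=2
            )
        out = np.clip(raw, 0.0, 1.0)
        return out if out.ndim else float(out)

    def with_e(self, e: float) -> "FeedbackProfile":
        return replace(self, e=e)


@dataclass
class PfbSamples:
    """Per-bin feedback-probability estimates with their sample sizes.

    Bins at ``s = 1/2`` (where the transform is singular) or with no
    revisions are flagged invalid and excluded from fitting.
    """

    centers: np.ndarray
    estimate: np.ndarray  # NaN where invalid
    weight: np.ndarray  # r_a + r_b per bin
    valid: np.ndarray  # bool


def estimate_pfb(
    counts: RevisionCounts,
    numerator: Literal["r_a", "r_b"] = "r_a",
) -> PfbSamples:
    """Invert directional revision counts into feedback probabilities.

    Per valid bin the revision ratio is clipped into
    ``[min(s, 1-s), max(s, 1-s)]`` (finite counts can violate the bound)
    and transformed by ``(ratio - 1 + s)/(2s - 1)``, which lands in
    ``[0, 1]`` exactly.  ``numerator`` selects which direction sits in
    the ratio; the default ``"r_a"`` is the convention under which
    feedback probabilities generating the counts are recovered, while
    ``"r_b"`` reproduces the mirrored estimate ``1 - P_fb``.
    """
    s = counts.centers
    total = counts.r_a + counts.r_b
    num = counts.r_a if numerator == "r_a" else counts.r_b
    valid = (total > 0) & (np.abs(s - 0.5) > 1e-12)
    if not valid.any():
        raise ValueError("no estimable bins: all empty or at s = 1/2")

    est = np.full(len(s), np.nan)
    with np.errstate(invalid="ignore", divide="ignore"):
        ratio = np.where(total > 0, num / np.maximum(total, 1), np.nan)
    lo = np.minimum(s, 1.0 - s)
    hi = np.maximum(s, 1.0 - s)
    ratio = np.clip(ratio, lo, hi)
    est[valid] = (ratio[valid] - 1.0 + s[valid]) / (2.0 * s[valid] - 1.0)
    est[valid] = np.clip(est[valid], 0.0, 1.0)
    return PfbSamples(centers=s, estimate=est, weight=total, valid=valid)


def fit_pfb(samples: PfbSamples) -> FeedbackProfile:
    """Weighted least squares of the estimates in the even quartic basis.

    The basis ``{1, u², u⁴}`` enforces mirror symmetry about ``s = 1/2``
    structurally.  Weights are the per-bin revision totals, which also
    down-weights the low-leverage bins next to ``s = 1/2``.
    """
    mask = samples.valid & (samples.weight > 0) & np.isfinite(samples.estimate)
    u = samples.centers[mask] - 0.5
    y = samples.estimate[mask]
    w = samples.weight[mask].astype(float)
    if mask.sum() < 3 or len(np.unique(np.round(np.abs(u), 12))) < 3:
        raise ValueError("need >= 3 valid bins with distinct |s - 1/2| to fit")
    design = np.column_stack([np.ones_like(u), u**2, u**4])
    sw = np.sqrt(w)
    coef, *_ = np.linalg.lstsq(design * sw[:, None], y * sw, rcond=None)
    return FeedbackProfile(b0=float(coef[0]), b1=float(coef[1]), b2=float(coef[2]))


def urn_delta(s, profile: FeedbackProfile):
    """Macroscopic drift ``4·e·(P_fb(s) - 1/2)·(s - 1/2)``."""
    if profile.e is None:
        raise ValueError("profile has no time-scale constant e; fit or set it first")
    s = np.asarray(s, dtype=float)
    out = 4.0 * profile.e * (profile.pfb(s) - 0.5) * (s - 0.5)
    return out if out.ndim else float(out)


def fit_e(profile_emp: DeltaProfile, feedback: FeedbackProfile) -> float:
    """Closed-form weighted least squares for the time-scale constant.

    With predictor ``x(s) = 4·(P_fb(s) - 1/2)·(s - 1/2)`` the optimum is
    the ratio of weighted inner products ``Σw·y·x / Σw·x²``.
    """
    mask = profile_emp.populated & np.isfinite(profile_emp.mean_delta)
    s = profile_emp.centers[mask]
    y = profile_emp.mean_delta[mask]
    w = profile_emp.counts[mask].astype(float)
    x = 4.0 * (feedback.pfb(s) - 0.5) * (s - 0.5)
    denom = float(np.sum(w * x * x))
    if denom < 1e-30:
        if np.all(np.abs(y) < 1e-12):
            warnings.warn("degenerate fit: zero profile, returning e = 0", RuntimeWarning)
            return 0.0
        raise ValueError("all predictors zero: e not identifiable")
    return float(np.sum(w * y * x) / denom)


@dataclass
class UrnRun:
    """Trajectory and revision log of one urn-game simulation."""

    n_agents: int
    s: np.ndarray  # (n_turns + 1,) state after each turn
    rev_s: np.ndarray  # state before each executed switch
    rev_to_a: np.ndarray  # bool, True for a B->A switch

    def revision_counts(self, bin_width: float | None = None) -> RevisionCounts:
        if bin_width is None:
            bin_width = 1.0 / self.n_agents
        centers = bin_centers(bin_width)
        k = len(centers)
        r_a = np.zeros(k, dtype=np.int64)
        r_b = np.zeros(k, dtype=np.int64)
        if self.rev_s.size:
            idx = bin_index(self.rev_s, bin_width)
            r_a += np.bincount(idx[self.rev_to_a], minlength=k)
            r_b += np.bincount(idx[~self.rev_to_a], minlength=k)
        return RevisionCounts(bin_width, centers, r_a, r_b)


def simulate_urn(
    n_agents: int,
    feedback: FeedbackProfile,
    n_turns: int,
    seed: int | None = None,
    s0: float = 0.5,
    pin_state: float | None = None,
) -> UrnRun:
    """Play the two-draw urn game.

    Each turn at state ``s``: note the opinion of an agent drawn with
    replacement (A with probability ``s``); with probability
    ``P_fb(s)`` an agent of the *opposite* opinion switches to the noted
    one (positive feedback), otherwise an agent of the noted opinion
    switches away (negative feedback).  Every executed switch is logged
    at its pre-switch state.  A switch with no eligible agent (at
    ``s = 0`` or ``1``) is a no-op.

    With ``pin_state`` set the drawing state is held fixed and the urn
    content never changes — useful for measuring revision statistics
    conditioned on an exact state.
    """
    if n_agents < 2:
        raise ValueError("n_agents must be >= 2")
    rng = np.random.default_rng(seed)
    k = round((pin_state if pin_state is not None else s0) * n_agents)
    traj = np.empty(n_turns + 1)
    traj[0] = k / n_agents
    rev_s: list[float] = []
    rev_to_a: list[bool] = []

    for t in range(1, n_turns + 1):
        s = (pin_state if pin_state is not None else k / n_agents)
        drew_a = rng.random() < s
        positive = rng.random() < feedback.pfb(s)
        # Positive feedback pushes toward the drawn opinion, negative away.
        to_a = drew_a == positive
        if pin_state is not None:
            rev_s.append(s)
            rev_to_a.append(to_a)
        elif to_a and k < n_agents:
            rev_s.append(k / n_agents)
            rev_to_a.append(True)
            k += 1
        elif not to_a and k > 0:
            rev_s.append(k / n_agents)
            rev_to_a.append(False)
            k -= 1
        traj[t] = k / n_agents

    return UrnRun(
        n_agents=n_agents,
        s=traj,
        rev_s=np.array(rev_s),
        rev_to_a=np.array(rev_to_a, dtype=bool),
    )
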