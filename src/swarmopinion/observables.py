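"""Macroscopic measurements extracted from simulation event logs.

The comparison surface shared by every model in this package is the
binned one-step drift of the global opinion state: ``Δs(s) = s_{t+1} -
s_t`` averaged over all samples observed at state ``s``.  Alongside it,
the local perception state — the fraction of A entries in an agent's
memory — is averaged per global-state bin, overall and conditioned on
the observer's opinion, and opinion-changing revisions are counted per
bin and direction.  Under the well-mixed assumption the mean local state
is the line ``(1 - 2γ)·s + γ``; deviations from it, and the dependence
on the observer's own opinion, quantify spatial correlation.

The global state is intrinsically discrete (multiples of ``1/N``), so
the natural bin width is ``1/N``; coarser widths are available for small
ensembles.  A bin with no samples is reported as missing (``NaN`` mean
with ``n = 0``), never imputed as zero.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from .simulate import A, B, EventLog, Particle, RunSummary, SwarmState, summarize_log

__all__ = [
    "global_state",
    "local_state",
    "DeltaProfile",
    "LocalStateProfile",
    "RevisionCounts",
    "LineFit",
    "delta_profile",
    "local_state_profile",
    "revision_counts",
    "fit_local_line",
]


def global_state(state: SwarmState) -> float:
    """Fraction of agents holding opinion A: ``s = A_count / N``."""
    return state.n_a / state.n_agents


def local_state(particle: Particle) -> float | None:
    """Fraction of A entries in the particle's memory; ``None`` if empty.

    An empty memory carries no perception sample, so the local state is
    undefined and must be excluded from averages.
    """
    if not particle.memory:
        return None
    return sum(1 for o in particle.memory if o == A) / len(particle.memory)


def bin_centers(bin_width: float) -> np.ndarray:
    """Bin centres ``0, w, 2w, …, 1`` covering the unit interval."""
    n_bins = round(1.0 / bin_width)
    if abs(n_bins * bin_width - 1.0) > 1e-9:
        raise ValueError(f"bin_width {bin_width} does not divide [0, 1] evenly")
    return np.arange(n_bins + 1) * bin_width


def bin_index(s: np.ndarray | float, bin_width: float) -> np.ndarray:
    """Nearest-centre bin assignment (exact for states on the s-grid)."""
    return np.rint(np.asarray(s) / bin_width).astype(np.int64)


def _as_summaries(
    logs: Iterable[EventLog | RunSummary], window: tuple[int, int] | None
) -> list[RunSummary]:
    out: list[RunSummary] = []
    for log in logs:
        if isinstance(log, RunSummary):
            if window is not None and tuple(log.window) != tuple(window):
                raise ValueError(
                    f"summary window {log.window} does not match requested {window}"
                )
            out.append(log)
        else:
            out.append(summarize_log(log, window))
    if not out:
        raise ValueError("no logs supplied")
    return out


@dataclass
class DeltaProfile:
    """Binned mean one-step change of the global state.

    ``mean_delta[k]`` averages ``s_{t+1} - s_t`` over all samples whose
    pre-step state fell in bin ``k``; ``se`` is the standard error of
    that mean.  Empty bins hold ``NaN`` means and ``n = 0``.
    """

    bin_width: float
    centers: np.ndarray
    mean_delta: np.ndarray
    counts: np.ndarray
    se: np.ndarray
    window: tuple[int, int] | None = None

    @property
    def populated(self) -> np.ndarray:
        return self.counts > 0

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "s_bin": self.centers,
                "mean_delta": self.mean_delta,
                "n": self.counts,
                "se": self.se,
            }
        )


@dataclass
class LocalStateProfile:
    """Binned mean local perception state, overall and by observer opinion."""

    bin_width: float
    centers: np.ndarray
    mean_local: np.ndarray
    mean_local_a: np.ndarray
    mean_local_b: np.ndarray
    counts: np.ndarray
    counts_a: np.ndarray
    counts_b: np.ndarray
    window: tuple[int, int] | None = None

    @property
    def populated(self) -> np.ndarray:
        return self.counts > 0

    def se_local(self) -> np.ndarray:
        """Binomial-style standard error of ``mean_local`` per bin."""
        with np.errstate(invalid="ignore", divide="ignore"):
            var = self.mean_local * (1.0 - self.mean_local)
            return np.sqrt(var / np.where(self.counts > 0, self.counts, np.nan))

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "s_bin": self.centers,
                "mean_local": self.mean_local,
                "mean_local_A": self.mean_local_a,
                "mean_local_B": self.mean_local_b,
                "n": self.counts,
                "n_A": self.counts_a,
                "n_B": self.counts_b,
            }
        )


@dataclass
class RevisionCounts:
    """Opinion-changing revisions per state bin and direction.

    ``r_a[k]`` counts B→A revisions observed at states in bin ``k`` and
    ``r_b[k]`` counts A→B revisions; the state is the one immediately
    before the revision took effect.
    """

    bin_width: float
    centers: np.ndarray
    r_a: np.ndarray
    r_b: np.ndarray
    window: tuple[int, int] | None = None

    @property
    def total(self) -> int:
        return int(self.r_a.sum() + self.r_b.sum())

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {"s_bin": self.centers, "r_a": self.r_a, "r_b": self.r_b}
        )


def _binned_mean(
    s: np.ndarray, values: np.ndarray, bin_width: float
) -> tuple[np.ndarray, np.ndarray, np.ndarray, np.ndarray]:
    centers = bin_centers(bin_width)
    k = len(centers)
    idx = bin_index(s, bin_width)
    counts = np.bincount(idx, minlength=k)
    sums = np.bincount(idx, weights=values, minlength=k)
    sq_sums = np.bincount(idx, weights=values * values, minlength=k)
    with np.errstate(invalid="ignore", divide="ignore"):
        mean = np.where(counts > 0, sums / np.maximum(counts, 1), np.nan)
        var = sq_sums / np.maximum(counts, 1) - mean**2
        var = np.clip(var, 0.0, None)
        se = np.where(counts > 1, np.sqrt(var / np.maximum(counts, 1)), np.nan)
    return centers, mean, counts, se


def delta_profile(
    logs: Iterable[EventLog | RunSummary],
    window: tuple[int, int] | None = None,
    bin_width: float | None = None,
) -> DeltaProfile:
    """Mean one-step drift ``Δs(s)`` binned over the pre-step state.

    The window ``(t0, t1]`` selects the changes arriving at iterations
    ``t0 < t <= t1``; each contributes one sample keyed by the state
    before the step, so every run adds exactly ``t1 - t0`` samples.  The
    default bin width is ``1/N``.
    """
    summaries = _as_summaries(logs, window)
    s = np.concatenate([sm.delta_s_before for sm in summaries])
    d = np.concatenate([sm.delta for sm in summaries])
    if bin_width is None:
        bin_width = _natural_bin_width(summaries)
    centers, mean, counts, se = _binned_mean(s, d, bin_width)
    return DeltaProfile(bin_width, centers, mean, counts, se, summaries[0].window)


def _natural_bin_width(summaries: Sequence[RunSummary]) -> float:
    # s is discrete in steps of 1/N, so 1/N is the finest faithful bin.
    return 1.0 / summaries[0].n_agents


def local_state_profile(
    logs: Iterable[EventLog | RunSummary],
    window: tuple[int, int] | None = None,
    bin_width: float | None = None,
) -> LocalStateProfile:
    """Mean local perception state per global-state bin.

    Averages run flat over all defined (agent, iteration, run) samples in
    a bin — undefined (empty-memory) samples are excluded from numerator
    and denominator alike — and are additionally split by the observer's
    own opinion.
    """
    summaries = _as_summaries(logs, window)
    s = np.concatenate([sm.local_s for sm in summaries])
    frac = np.concatenate([sm.local_frac for sm in summaries])
    opinion = np.concatenate([sm.local_opinion for sm in summaries])
    if s.size == 0:
        raise ValueError("no defined local-state samples in the window")
    if bin_width is None:
        bin_width = _natural_bin_width(summaries)

    centers, mean, counts, _ = _binned_mean(s, frac, bin_width)
    is_a = opinion == A
    _, mean_a, counts_a, _ = _binned_mean(s[is_a], frac[is_a], bin_width)
    _, mean_b, counts_b, _ = _binned_mean(s[~is_a], frac[~is_a], bin_width)
    return LocalStateProfile(
        bin_width,
        centers,
        mean,
        mean_a,
        mean_b,
        counts,
        counts_a,
        counts_b,
        summaries[0].window,
    )


def revision_counts(
    logs: Iterable[EventLog | RunSummary],
    window: tuple[int, int] | None = None,
    bin_width: float | None = None,
) -> RevisionCounts:
    """Directional opinion-change counts per state bin.

    Only revisions that actually flip the opinion are counted; a revision
    whose memory majority confirms the current opinion changes nothing
    and enters neither ``r_a`` nor ``r_b``.
    """
    summaries = _as_summaries(logs, window)
    if bin_width is None:
        bin_width = _natural_bin_width(summaries)
    centers = bin_centers(bin_width)
    k = len(centers)
    r_a = np.zeros(k, dtype=np.int64)
    r_b = np.zeros(k, dtype=np.int64)
    for sm in summaries:
        if sm.rev_s.size == 0:
            continue
        idx = bin_index(sm.rev_s, bin_width)
        to_a = sm.rev_new == A
        r_a += np.bincount(idx[to_a], minlength=k)
        r_b += np.bincount(idx[~to_a], minlength=k)
    return RevisionCounts(bin_width, centers, r_a, r_b, summaries[0].window)


@dataclass
class LineFit:
    """Weighted least-squares line through a binned profile."""

    slope: float
    intercept: float
    residual_rms: float
    n_bins: int

    def predict(self, s: np.ndarray | float) -> np.ndarray | float:
        return self.slope * np.asarray(s) + self.intercept


def fit_local_line(profile: LocalStateProfile) -> LineFit:
    """Count-weighted linear fit of ``mean_local`` against the bin centre.

    Under well mixing the result estimates the perception line with slope
    ``1 - 2γ`` and intercept ``γ``.
    """
    mask = profile.populated & np.isfinite(profile.mean_local)
    if mask.sum() < 2:
        raise ValueError("need at least two populated bins to fit a line")
    x = profile.centers[mask]
    y = profile.mean_local[mask]
    w = profile.counts[mask].astype(float)
    sw = np.sqrt(w)
    design = np.column_stack([x, np.ones_like(x)])
    coef, *_ = np.linalg.lstsq(design * sw[:, None], y * sw, rcond=None)
    slope, intercept = float(coef[0]), float(coef[1])
    resid = y - (slope * x + intercept)
    rms = float(np.sqrt(np.average(resid**2, weights=w)))
    return LineFit(slope, intercept, rms, int(mask.sum()))
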