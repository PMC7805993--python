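"""Tests for the urn model: game mechanics, estimator, fits, drift law."""

from __future__ import annotations

import numpy as np
import pytest

import swarmopinion as sw
from swarmopinion.observables import RevisionCounts, bin_centers, bin_index
from swarmopinion.urn import FeedbackProfile


def _counts_at(centers_and_counts, bin_width=0.05):
    centers = bin_centers(bin_width)
    r_a = np.zeros(len(centers), dtype=np.int64)
    r_b = np.zeros(len(centers), dtype=np.int64)
    for s, ra, rb in centers_and_counts:
        k = bin_index(s, bin_width)
        r_a[k], r_b[k] = ra, rb
    return RevisionCounts(bin_width, centers, r_a, r_b)


def test_urn_delta_vanishes_at_symmetry():
    profile = FeedbackProfile(b0=0.8, b1=0.3, b2=-0.1, e=0.2)
    assert sw.urn_delta(0.5, profile) == 0.0
    neutral = FeedbackProfile(b0=0.5, e=0.2)
    assert np.allclose(sw.urn_delta(np.linspace(0, 1, 11), neutral), 0.0)


def test_urn_delta_hand_value():
    # 4 * e * (P_fb - 1/2) * (s - 1/2) = 4 * 0.25 * 0.5 * 0.5 = 0.25
    profile = FeedbackProfile(b0=1.0, e=0.25)
    assert sw.urn_delta(1.0, profile) == pytest.approx(0.25)
    assert sw.urn_delta(1.0, FeedbackProfile(b0=1.0, e=0.125)) == pytest.approx(0.125)


def test_urn_delta_antisymmetry():
    profile = FeedbackProfile(b0=0.4, b1=1.2, b2=-2.0, e=0.7)
    s = np.linspace(0.0, 1.0, 101)
    assert np.allclose(sw.urn_delta(1.0 - s, profile), -sw.urn_delta(s, profile), atol=1e-14)


def test_urn_delta_requires_time_scale():
    with pytest.raises(ValueError):
        sw.urn_delta(0.3, FeedbackProfile(b0=0.6))


def test_estimate_pfb_bound_extremes():
    """A revision ratio at one bound maps to feedback 1, at the other to 0."""
    s = 0.8
    # ratio r_a/(r_a+r_b) = s  ->  estimate 1
    counts = _counts_at([(s, 80, 20)])
    est = sw.estimate_pfb(counts)
    k = bin_index(s, counts.bin_width)
    assert est.estimate[k] == pytest.approx(1.0)
    # ratio = 1 - s  ->  estimate 0
    counts = _counts_at([(s, 20, 80)])
    est = sw.estimate_pfb(counts)
    assert est.estimate[k] == pytest.approx(0.0)


def test_estimate_pfb_analytic_rates():
    """Counts at the closed-form revision rates invert to the exact P_fb.

    At state s with feedback probability P the toward-A revision rate is
    s*P + (1-s)*(1-P); plugging those expected counts into the estimator
    must return P itself.
    """
    for s, p in [(0.8, 0.7), (0.3, 0.2), (0.65, 0.9)]:
        rate_a = s * p + (1 - s) * (1 - p)
        n = 100_000
        counts = _counts_at([(s, round(n * rate_a), n - round(n * rate_a))])
        est = sw.estimate_pfb(counts)
        k = bin_index(s, counts.bin_width)
        assert est.estimate[k] == pytest.approx(p, abs=1e-4)


def test_estimate_pfb_mirrored_convention():
    """With r_b in the numerator the transform returns 1 - P_fb."""
    s, p = 0.8, 0.7
    rate_a = s * p + (1 - s) * (1 - p)
    counts = _counts_at([(s, round(1e5 * rate_a), round(1e5 * (1 - rate_a)))])
    k = bin_index(s, counts.bin_width)
    est_b = sw.estimate_pfb(counts, numerator="r_b")
    assert est_b.estimate[k] == pytest.approx(1.0 - p, abs=1e-4)


def test_estimate_pfb_midpoint_invalid():
    counts = _counts_at([(0.5, 30, 30), (0.7, 10, 10)])
    est = sw.estimate_pfb(counts)
    assert not est.valid[bin_index(0.5, counts.bin_width)]
    assert est.valid[bin_index(0.7, counts.bin_width)]
    with pytest.raises(ValueError):
        sw.estimate_pfb(_counts_at([(0.5, 30, 30)]))


@pytest.mark.parametrize("p_fb", [0.2, 0.7, 0.9])
def test_urn_game_estimator_recovery(p_fb):
    """Pinned-state urn revisions invert to the generating P_fb (3 SE)."""
    profile = FeedbackProfile(b0=p_fb)
    bw = 0.05
    for s in (0.2, 0.35, 0.65, 0.8):
        n_turns = 20_000
        run = sw.simulate_urn(100, profile, n_turns, seed=hash((p_fb, s)) % 2**31, pin_state=s)
        counts = run.revision_counts(bw)
        k = bin_index(s, bw)
        total = counts.r_a[k] + counts.r_b[k]
        ratio = counts.r_a[k] / total
        # Bound compliance in expectation (printed constraint of the
        # estimator): the ratio sits inside [min(s,1-s), max(s,1-s)].
        se_ratio = np.sqrt(ratio * (1 - ratio) / total)
        assert min(s, 1 - s) - 3 * se_ratio <= ratio <= max(s, 1 - s) + 3 * se_ratio
        est = sw.estimate_pfb(counts)
        se_est = se_ratio / abs(2 * s - 1)
        assert abs(est.estimate[k] - p_fb) < 3 * se_est


def test_fit_pfb_exact_recovery():
    centers = np.linspace(0.0, 1.0, 21)
    u = centers - 0.5
    y = 0.6 + 0.8 * u**2 - 1.0 * u**4
    samples = sw.PfbSamples(
        centers=centers,
        estimate=y,
        weight=np.full(21, 50),
        valid=np.abs(u) > 1e-9,
    )
    fit = sw.fit_pfb(samples)
    assert fit.b0 == pytest.approx(0.6, abs=1e-8)
    assert fit.b1 == pytest.approx(0.8, abs=1e-8)
    assert fit.b2 == pytest.approx(-1.0, abs=1e-8)


def test_fit_pfb_constant_samples():
    centers = np.linspace(0.0, 1.0, 21)
    samples = sw.PfbSamples(
        centers=centers,
        estimate=np.full(21, 0.5),
        weight=np.full(21, 10),
        valid=np.abs(centers - 0.5) > 1e-9,
    )
    fit = sw.fit_pfb(samples)
    assert fit.b0 == pytest.approx(0.5, abs=1e-10)
    assert fit.b1 == pytest.approx(0.0, abs=1e-9)
    assert fit.b2 == pytest.approx(0.0, abs=1e-9)


def test_fit_pfb_mirror_symmetric_by_construction():
    fit = FeedbackProfile(b0=0.47, b1=1.3, b2=-3.1)
    s = np.linspace(0.0, 1.0, 101)
    # Symmetry is structural (even basis in u = s - 1/2); the only wiggle
    # room is the rounding of 1 - s itself.
    assert np.allclose(fit.pfb(s), fit.pfb(1.0 - s), atol=1e-12, rtol=0)


def test_fit_pfb_rank_deficient():
    centers = np.array([0.4, 0.6, 0.5])
    samples = sw.PfbSamples(
        centers=centers,
        estimate=np.array([0.5, 0.5, np.nan]),
        weight=np.array([5, 5, 0]),
        valid=np.array([True, True, False]),
    )
    with pytest.raises(ValueError):
        sw.fit_pfb(samples)  # |u| = 0.1 twice: only one distinct magnitude


def test_fit_e_noiseless_and_degenerate():
    feedback = FeedbackProfile(b0=0.7, b1=0.5, b2=-0.3)
    centers = np.linspace(0.0, 1.0, 41)
    truth = feedback.with_e(0.1)
    profile = sw.DeltaProfile(
        bin_width=0.025,
        centers=centers,
        mean_delta=sw.urn_delta(centers, truth),
        counts=np.full(41, 30),
        se=np.full(41, np.nan),
    )
    assert sw.fit_e(profile, feedback) == pytest.approx(0.1, abs=1e-10)

    zero = sw.DeltaProfile(
        bin_width=0.025,
        centers=centers,
        mean_delta=np.zeros(41),
        counts=np.full(41, 30),
        se=np.full(41, np.nan),
    )
    neutral = FeedbackProfile(b0=0.5)
    with pytest.warns(RuntimeWarning):
        assert sw.fit_e(zero, neutral) == 0.0


def test_fit_e_noisy_recovery():
    feedback = FeedbackProfile(b0=0.7, b1=0.5, b2=-0.3)
    centers = np.linspace(0.0, 1.0, 41)
    truth = feedback.with_e(0.1)
    clean = sw.urn_delta(centers, truth)
    x = 4.0 * (np.asarray(feedback.pfb(centers)) - 0.5) * (centers - 0.5)
    rng = np.random.default_rng(23)
    sd = 1e-3
    e_hat = sw.fit_e(
        sw.DeltaProfile(
            bin_width=0.025,
            centers=centers,
            mean_delta=clean + rng.normal(0, sd, 41),
            counts=np.full(41, 30),
            se=np.full(41, np.nan),
        ),
        feedback,
    )
    se_e = sd / np.sqrt((x**2).sum())  # equal weights: OLS slope SE
    assert abs(e_hat - 0.1) < 3 * se_e


def test_urn_game_absorbing_under_pure_positive_feedback():
    run = sw.simulate_urn(50, FeedbackProfile(b0=1.0), 2000, seed=3, s0=0.9)
    assert run.s[-1] == 1.0
    assert np.all(np.abs(np.diff(run.s)) <= 1 / 50 + 1e-12)


def test_urn_game_negative_feedback_centers():
    run = sw.simulate_urn(50, FeedbackProfile(b0=0.0), 20_000, seed=4, s0=0.9)
    # Negative feedback erodes any majority; the long-run mean sits at 1/2.
    assert abs(run.s[2000:].mean() - 0.5) < 0.05


def test_urn_game_step_size():
    run = sw.simulate_urn(20, FeedbackProfile(b0=0.6), 500, seed=5, s0=0.5)
    steps = np.diff(run.s) * 20
    assert set(np.round(steps).astype(int)) <= {-1, 0, 1}
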