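"""End-to-end orchestration: ensemble → profiles → both model fits.

A pipeline run simulates an ensemble of the density-classification
scenario (optionally sweeping the initial A-fraction to cover the state
axis, which at desk scale substitutes for the enormous ensembles needed
to reach extreme states from a symmetric start), measures the drift,
local-state and revision profiles in a common window, calibrates the
contrarian Galam model and the urn model against them, and writes every
artifact plus a provenance manifest.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

from .config import SwarmConfig
from .galam import GalamFit, GalamParams, corrected_delta, fit_contrarian
from .io import make_manifest, write_profile
from .observables import (
    DeltaProfile,
    LocalStateProfile,
    RevisionCounts,
    delta_profile,
    local_state_profile,
    revision_counts,
)
from .simulate import RunSummary, default_window, derive_seeds, run_ensemble
from .urn import FeedbackProfile, estimate_pfb, fit_e, fit_pfb, urn_delta


def collect_ensemble(
    config: SwarmConfig,
    n_repetitions: int | None = None,
    base_seed: int | None = None,
    s0_values: Sequence[float] | None = None,
    window: tuple[int, int] | None = None,
) -> list[RunSummary]:
    """Run ``n_repetitions`` independent runs per initial A-fraction.

    Seeds: one base seed is derived per ``s0`` value from the root seed,
    then per-run seeds from that, so any slice of the ensemble is
    independently reproducible.
    """
    if s0_values is None:
        s0_values = [config.initial_fraction_a]
    if base_seed is None:
        base_seed = config.seed
    if window is None:
        window = default_window(config)
    base_seeds = derive_seeds(base_seed, len(s0_values))
    summaries: list[RunSummary] = []
    for s0, bs in zip(s0_values, base_seeds):
        cfg = config.replace(initial_fraction_a=float(s0))
        summaries.extend(run_ensemble(cfg, n_repetitions, base_seed=bs, window=window))
    return summaries


@dataclass
class PipelineResult:
    """Everything a pipeline run produced, in memory."""

    delta: DeltaProfile
    local: LocalStateProfile
    revisions: RevisionCounts
    galam_fit: GalamFit
    urn_fit: FeedbackProfile
    comparison: pd.DataFrame


def pipeline_run(
    config: SwarmConfig,
    n_repetitions: int | None = None,
    seed: int | None = None,
    out_dir: str | Path | None = None,
    s0_values: Sequence[float] | None = None,
    window: tuple[int, int] | None = None,
    bin_width: float | None = None,
) -> PipelineResult:
    """Simulate, measure, calibrate both models, and (optionally) persist.

    The comparison table has one row per populated drift bin with the
    measured mean drift and both model predictions.  When ``out_dir`` is
    given, profiles go to CSV, fitted parameters to JSON, and a manifest
    with checksums ties them together.
    """
    if seed is None:
        seed = config.seed
    if window is None:
        window = default_window(config)

    try:
        summaries = collect_ensemble(config, n_repetitions, seed, s0_values, window)
    except Exception as exc:
        raise RuntimeError(f"pipeline stage 'simulate' failed: {exc}") from exc

    try:
        delta = delta_profile(summaries, window, bin_width)
        local = local_state_profile(summaries, window, bin_width)
        revs = revision_counts(summaries, window, bin_width)
    except Exception as exc:
        raise RuntimeError(f"pipeline stage 'profile' failed: {exc}") from exc

    try:
        gfit = fit_contrarian(delta, gamma=config.gamma)
    except Exception as exc:
        raise RuntimeError(f"pipeline stage 'fit-galam' failed: {exc}") from exc

    try:
        ufit = fit_pfb(estimate_pfb(revs))
        ufit = ufit.with_e(fit_e(delta, ufit))
    except Exception as exc:
        raise RuntimeError(f"pipeline stage 'fit-urn' failed: {exc}") from exc

    mask = delta.populated & np.isfinite(delta.mean_delta)
    s = delta.centers[mask]
    gparams = GalamParams(a=gfit.a, d=gfit.d, gamma=config.gamma)
    comparison = pd.DataFrame(
        {
            "s_bin": s,
            "measured_delta": delta.mean_delta[mask],
            "n": delta.counts[mask],
            "galam_delta": corrected_delta(s, gparams),
            "urn_delta": urn_delta(s, ufit),
        }
    )

    result = PipelineResult(delta, local, revs, gfit, ufit, comparison)
    if out_dir is not None:
        _persist(result, config, seed, n_repetitions, s0_values, window, delta.bin_width, Path(out_dir))
    return result


def _persist(
    result: PipelineResult,
    config: SwarmConfig,
    seed: int,
    n_repetitions: int | None,
    s0_values: Sequence[float] | None,
    window: tuple[int, int],
    bin_width: float,
    out_dir: Path,
) -> None:
    out_dir.mkdir(parents=True, exist_ok=True)
    write_profile(result.delta, out_dir / "delta_profile.csv", manifest="manifest.json")
    write_profile(result.local, out_dir / "local_state.csv", manifest="manifest.json")
    write_profile(result.revisions, out_dir / "revisions.csv", manifest="manifest.json")
    with open(out_dir / "galam_fit.json", "w") as fh:
        json.dump(
            {
                "a": result.galam_fit.a,
                "d": result.galam_fit.d,
                "gamma": config.gamma,
                "residual_rms": result.galam_fit.residual_rms,
                "rms_inside": result.galam_fit.rms_inside,
                "rms_outside": result.galam_fit.rms_outside,
                "diagnostic_interval": list(result.galam_fit.diagnostic_interval),
            },
            fh,
            indent=2,
        )
        fh.write("\n")
    with open(out_dir / "urn_fit.json", "w") as fh:
        json.dump(
            {
                "b0": result.urn_fit.b0,
                "b1": result.urn_fit.b1,
                "b2": result.urn_fit.b2,
                "e": result.urn_fit.e,
            },
            fh,
            indent=2,
        )
        fh.write("\n")
    result.comparison.to_csv(out_dir / "comparison.csv", index=False)

    filenames = [
        "delta_profile.csv",
        "local_state.csv",
        "revisions.csv",
        "galam_fit.json",
        "urn_fit.json",
        "comparison.csv",
    ]
    manifest = make_manifest(
        config,
        seed,
        n_repetitions if n_repetitions is not None else config.n_repetitions,
        list(s0_values) if s0_values is not None else [config.initial_fraction_a],
        window,
        bin_width,
        out_dir,
        filenames,
    )
    manifest.save(out_dir / "manifest.json")
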