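"""Persistence: profile tables as commented CSV, manifests as JSON.

Every profile (drift, local state, revisions) is written as a CSV with a
small ``#``-comment header carrying the bin width, measurement window
and a manifest reference, so a file is self-describing and reading
inverts writing.  A run manifest records the full configuration, the
root seed and the seed-derivation scheme, the package version, and a
checksum inventory of the files produced — enough to regenerate every
output byte from the code.
"""

from __future__ import annotations

import dataclasses
import datetime
import hashlib
import json
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from .config import SwarmConfig
from .observables import DeltaProfile, LocalStateProfile, RevisionCounts

_MAGIC = "swarmopinion-profile v1"

_SCHEMAS = {
    "delta": ["s_bin", "mean_delta", "n", "se"],
    "local": ["s_bin", "mean_local", "mean_local_A", "mean_local_B", "n", "n_A", "n_B"],
    "revisions": ["s_bin", "r_a", "r_b"],
}


@dataclass
class ProfileTable:
    """A typed tabular container for any of the binned profiles."""

    kind: str  # "delta" | "local" | "revisions"
    frame: pd.DataFrame
    bin_width: float
    window: tuple[int, int] | None = None
    manifest: str | None = None

    def __post_init__(self) -> None:
        if self.kind not in _SCHEMAS:
            raise ValueError(f"unknown profile kind {self.kind!r}")
        missing = [c for c in _SCHEMAS[self.kind] if c not in self.frame.columns]
        if missing:
            raise ValueError(f"{self.kind} table missing columns: {missing}")

    def to_profile(self) -> DeltaProfile | LocalStateProfile | RevisionCounts:
        f = self.frame
        if self.kind == "delta":
            return DeltaProfile(
                bin_width=self.bin_width,
                centers=f["s_bin"].to_numpy(float),
                mean_delta=f["mean_delta"].to_numpy(float),
                counts=f["n"].to_numpy(np.int64),
                se=f["se"].to_numpy(float),
                window=self.window,
            )
        if self.kind == "local":
            return LocalStateProfile(
                bin_width=self.bin_width,
                centers=f["s_bin"].to_numpy(float),
                mean_local=f["mean_local"].to_numpy(float),
                mean_local_a=f["mean_local_A"].to_numpy(float),
                mean_local_b=f["mean_local_B"].to_numpy(float),
                counts=f["n"].to_numpy(np.int64),
                counts_a=f["n_A"].to_numpy(np.int64),
                counts_b=f["n_B"].to_numpy(np.int64),
                window=self.window,
            )
        return RevisionCounts(
            bin_width=self.bin_width,
            centers=f["s_bin"].to_numpy(float),
            r_a=f["r_a"].to_numpy(np.int64),
            r_b=f["r_b"].to_numpy(np.int64),
            window=self.window,
        )


_KINDS = {DeltaProfile: "delta", LocalStateProfile: "local", RevisionCounts: "revisions"}


def as_table(
    profile: DeltaProfile | LocalStateProfile | RevisionCounts | ProfileTable,
    manifest: str | None = None,
) -> ProfileTable:
    if isinstance(profile, ProfileTable):
        return profile
    kind = _KINDS[type(profile)]
    return ProfileTable(
        kind=kind,
        frame=profile.to_frame(),
        bin_width=profile.bin_width,
        window=profile.window,
        manifest=manifest,
    )


def write_profile(profile, path: str | Path, manifest: str | None = None) -> None:
    """Write a profile (or table) as commented CSV; see :func:`read_profile`."""
    table = as_table(profile, manifest)
    path = Path(path)
    window = "-" if table.window is None else f"{table.window[0]}..{table.window[1]}"
    header = [
        f"# {_MAGIC}",
        f"# kind: {table.kind}",
        f"# bin_width: {table.bin_width!r}",
        f"# window: {window}",
        f"# manifest: {table.manifest or '-'}",
    ]
    with open(path, "w") as fh:
        fh.write("\n".join(header) + "\n")
        table.frame.to_csv(fh, index=False)


def read_profile(path: str | Path) -> ProfileTable:
    """Read a commented-CSV profile written by :func:`write_profile`."""
    path = Path(path)
    meta: dict[str, str] = {}
    with open(path) as fh:
        first = fh.readline().strip()
        if first != f"# {_MAGIC}":
            raise ValueError(f"{path}: not a profile file (bad magic line)")
        pos = fh.tell()
        while True:
            line = fh.readline()
            if not line.startswith("#"):
                fh.seek(pos)
                break
            pos = fh.tell()
            key, _, value = line[1:].strip().partition(":")
            meta[key.strip()] = value.strip()
        frame = pd.read_csv(fh)
    try:
        kind = meta["kind"]
        bin_width = float(meta["bin_width"])
    except KeyError as exc:
        raise ValueError(f"{path}: missing header field {exc}") from exc
    window = None
    if meta.get("window", "-") != "-":
        lo, _, hi = meta["window"].partition("..")
        window = (int(lo), int(hi))
    manifest = None if meta.get("manifest", "-") == "-" else meta["manifest"]
    return ProfileTable(kind=kind, frame=frame, bin_width=bin_width, window=window, manifest=manifest)


def sha256_file(path: str | Path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(1 << 16), b""):
            h.update(chunk)
    return h.hexdigest()


@dataclass
class RunManifest:
    """Provenance record: config + seeds + version + output checksums."""

    config: dict
    root_seed: int
    seed_scheme: str
    n_repetitions: int
    s0_values: list[float]
    window: tuple[int, int]
    bin_width: float
    version: str
    created: str
    files: dict[str, str]  # filename -> sha256

    def save(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            json.dump(dataclasses.asdict(self), fh, indent=2)
            fh.write("\n")

    @classmethod
    def load(cls, path: str | Path) -> "RunManifest":
        with open(path) as fh:
            raw = json.load(fh)
        raw["window"] = tuple(raw["window"])
        return cls(**raw)

    @property
    def swarm_config(self) -> SwarmConfig:
        return SwarmConfig(**self.config)


def make_manifest(
    config: SwarmConfig,
    root_seed: int,
    n_repetitions: int,
    s0_values: list[float],
    window: tuple[int, int],
    bin_width: float,
    out_dir: str | Path,
    filenames: list[str],
) -> RunManifest:
    from . import __version__

    out_dir = Path(out_dir)
    return RunManifest(
        config=config.to_dict(),
        root_seed=root_seed,
        seed_scheme="SeedSequence(root).generate_state per s0; per-run likewise",
        n_repetitions=n_repetitions,
        s0_values=list(map(float, s0_values)),
        window=tuple(window),
        bin_width=float(bin_width),
        version=__version__,
        created=datetime.datetime.now(datetime.timezone.utc).isoformat(),
        files={name: sha256_file(out_dir / name) for name in filenames},
    )
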