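"""Discrete-time simulation of mobile agents with noisy opinion perception.

``N`` point agents move like frictionless billiard balls in the unit
square: straight lines at constant speed, specular reflection at the
walls, and an elastic bounce whenever two agents come within the
avoidance radius ``r``.  The same radius is the perception range: at the
onset of each encounter both agents perceive the other's binary opinion,
corrupted independently with probability ``gamma``, and append it to an
internal memory.  Once the memory holds ``memory_size`` entries the agent
adopts the strict majority opinion of the memory and clears it.

Because agents travel only a small fraction of the arena between
revisions, the population is not well mixed: an agent's memory samples
its spatial neighbourhood, and opinions correlate with position.  The
event log produced here is the raw material for measuring that effect.

Conventions
-----------
* Opinions are encoded as integers: ``A == 1``, ``B == 0``.
* An encounter is the transition of a pair from out-of-range to
  in-range.  A pair that stays within range for several iterations
  contributes one perception per agent, at the onset only.
* Per iteration: synchronous motion of all agents from the same position
  snapshot (with wall reflection folded in), then encounter resolution
  in ascending pair order (bounce + mutual perception), with revisions
  applied immediately when a memory fills.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Iterator, Sequence

import numpy as np
from scipy.spatial.distance import pdist

from .config import SwarmConfig

#: Opinion labels.  ``A`` is the opinion whose population fraction is the
#: global state ``s``.
A: int = 1
B: int = 0

_EPS = 1e-12

_triu_cache: dict[int, tuple[np.ndarray, np.ndarray]] = {}


def _condensed_pairs(n: int) -> tuple[np.ndarray, np.ndarray]:
    """Row/column indices of the condensed upper-triangle ordering."""
    if n not in _triu_cache:
        _triu_cache[n] = np.triu_indices(n, k=1)
    return _triu_cache[n]


@dataclass
class Particle:
    """Microscopic state of a single agent."""

    position: np.ndarray  # shape (2,), componentwise in [0, world_side]
    heading: np.ndarray  # shape (2,), unit norm
    opinion: int  # A or B
    memory: list[int] = field(default_factory=list)


@dataclass
class RevisionEvent:
    """An opinion reconsideration after a full memory.

    ``old == new`` is allowed (the majority confirmed the current
    opinion); observables that count opinion *changes* filter on
    ``old != new``.  ``s_before`` is the global state immediately before
    the revision took effect.
    """

    time: int
    agent: int
    old: int
    new: int
    s_before: float


@dataclass
class IterationEvents:
    """Everything that happened during one call to :func:`advance`."""

    encounters: list[tuple[int, int]] = field(default_factory=list)
    revisions: list[RevisionEvent] = field(default_factory=list)


class SwarmState:
    """Array-backed microscopic state of the whole swarm.

    Positions and headings live in ``(N, 2)`` float arrays, opinions in an
    integer array, and memories as per-agent lists (encounters are sparse,
    so list appends are cheap).  ``in_range_pairs`` holds the unordered
    index pairs currently within the avoidance radius; it is what makes
    encounter *onsets* detectable.
    """

    def __init__(
        self,
        positions: np.ndarray,
        headings: np.ndarray,
        opinions: np.ndarray,
        memories: list[list[int]] | None = None,
        time: int = 0,
    ) -> None:
        self.positions = np.asarray(positions, dtype=float)
        self.headings = np.asarray(headings, dtype=float)
        self.opinions = np.asarray(opinions, dtype=np.int64)
        n = self.positions.shape[0]
        self.memories: list[list[int]] = memories if memories is not None else [[] for _ in range(n)]
        self.time = time
        self.in_range_pairs: set[tuple[int, int]] = set()

    @property
    def n_agents(self) -> int:
        return self.positions.shape[0]

    @property
    def n_a(self) -> int:
        return int(self.opinions.sum())

    def particle(self, i: int) -> Particle:
        """A copy of agent ``i`` as a standalone :class:`Particle`."""
        return Particle(
            position=self.positions[i].copy(),
            heading=self.headings[i].copy(),
            opinion=int(self.opinions[i]),
            memory=list(self.memories[i]),
        )

    def particles(self) -> Iterator[Particle]:
        return (self.particle(i) for i in range(self.n_agents))


@dataclass
class EventLog:
    """Complete record of one simulation run.

    ``s[t]`` is the global state after ``t`` iterations (``s[0]`` is the
    initial state).  Revision events carry the state immediately before
    each revision.  ``snap_*`` arrays hold per-agent snapshots (opinion,
    A-count and fill level of the memory) taken at the end of each
    iteration inside the recording window — enough to reconstruct every
    local perception state.
    """

    config: SwarmConfig
    seed: int
    s: np.ndarray  # (T+1,)
    rev_time: np.ndarray  # (R,) int
    rev_agent: np.ndarray  # (R,) int
    rev_old: np.ndarray  # (R,) int
    rev_new: np.ndarray  # (R,) int
    rev_s: np.ndarray  # (R,) float, state before the revision
    snap_times: np.ndarray  # (W,) int
    snap_opinion: np.ndarray  # (W, N) int8
    snap_mem_a: np.ndarray  # (W, N) int16
    snap_mem_len: np.ndarray  # (W, N) int16

    @property
    def n_iterations(self) -> int:
        return len(self.s) - 1

    def n_opinion_changes(self) -> int:
        return int(np.sum(self.rev_old != self.rev_new))


def perceive(true_opinion: int, gamma: float, rng: np.random.Generator) -> int:
    """Noisy perception of a binary opinion.

    Returns ``true_opinion`` with probability ``1 - gamma`` and the
    opposite opinion with probability ``gamma``.
    """
    if not 0.0 <= gamma <= 1.0:
        raise ValueError("gamma must lie in [0, 1]")
    if rng.random() < gamma:
        return A + B - true_opinion
    return true_opinion


def maybe_revise(particle: Particle, memory_size: int) -> RevisionEvent | None:
    """Apply the memory-majority revision rule to a single particle.

    If the memory holds ``memory_size`` entries the particle adopts the
    strict majority opinion (``memory_size`` odd, so no ties) and clears
    its memory; otherwise nothing happens.  The returned event has
    ``s_before`` unset (``nan``); the simulation engine fills it in.
    """
    if len(particle.memory) > memory_size:
        raise ValueError("memory overfull")
    if len(particle.memory) < memory_size:
        return None
    n_a = sum(1 for o in particle.memory if o == A)
    new = A if 2 * n_a > memory_size else B
    old = particle.opinion
    particle.opinion = new
    particle.memory = []
    return RevisionEvent(time=-1, agent=-1, old=old, new=new, s_before=math.nan)


def init_swarm(config: SwarmConfig, seed: int | None = None) -> SwarmState:
    """Initial microscopic state.

    Positions i.i.d. uniform on the square, headings i.i.d. uniform on
    directions, memories empty.  Exactly ``round(initial_fraction_a * N)``
    agents hold opinion A; which agents is randomised.
    """
    rng = np.random.default_rng(config.seed if seed is None else seed)
    n = config.n_agents
    positions = rng.uniform(0.0, config.world_side, size=(n, 2))
    angles = rng.uniform(0.0, 2.0 * math.pi, size=n)
    headings = np.column_stack([np.cos(angles), np.sin(angles)])
    n_a = round(config.initial_fraction_a * n)
    opinions = np.zeros(n, dtype=np.int64)
    opinions[rng.permutation(n)[:n_a]] = A
    return SwarmState(positions, headings, opinions)


def _reflect_walls(state: SwarmState, side: float) -> None:
    # Speed << side, so a single mirror fold per axis suffices.
    pos, hdg = state.positions, state.headings
    for ax in range(2):
        lo = pos[:, ax] < 0.0
        if lo.any():
            pos[lo, ax] = -pos[lo, ax]
            hdg[lo, ax] = -hdg[lo, ax]
        hi = pos[:, ax] > side
        if hi.any():
            pos[hi, ax] = 2.0 * side - pos[hi, ax]
            hdg[hi, ax] = -hdg[hi, ax]


def _bounce(state: SwarmState, i: int, j: int, rng: np.random.Generator) -> None:
    # Elastic equal-mass bounce: exchange the velocity components along
    # the line of centres, then renormalise so speed stays constant.
    n = state.positions[j] - state.positions[i]
    dist = math.hypot(n[0], n[1])
    if dist < _EPS:
        # Coincident agents: random contact normal.
        ang = rng.uniform(0.0, 2.0 * math.pi)
        n = np.array([math.cos(ang), math.sin(ang)])
    else:
        n = n / dist
    vi, vj = state.headings[i], state.headings[j]
    pi = vi @ n
    pj = vj @ n
    vi_new = vi + (pj - pi) * n
    vj_new = vj + (pi - pj) * n
    for idx, v in ((i, vi_new), (j, vj_new)):
        norm = math.hypot(v[0], v[1])
        if norm < _EPS:
            ang = rng.uniform(0.0, 2.0 * math.pi)
            v = np.array([math.cos(ang), math.sin(ang)])
            norm = 1.0
        state.headings[idx] = v / norm


def _append_and_maybe_revise(
    state: SwarmState,
    observer: int,
    observed_opinion: int,
    config: SwarmConfig,
    rng: np.random.Generator,
    events: IterationEvents,
) -> None:
    state.memories[observer].append(perceive(observed_opinion, config.gamma, rng))
    if len(state.memories[observer]) == config.memory_size:
        n_a = sum(state.memories[observer])
        new = A if 2 * n_a > config.memory_size else B
        old = int(state.opinions[observer])
        s_before = state.n_a / state.n_agents
        state.opinions[observer] = new
        state.memories[observer] = []
        events.revisions.append(
            RevisionEvent(time=state.time, agent=observer, old=old, new=new, s_before=s_before)
        )


def advance(
    state: SwarmState, config: SwarmConfig, rng: np.random.Generator
) -> tuple[SwarmState, IterationEvents]:
    """One synchronous iteration, mutating ``state`` in place.

    Motion first (all agents displaced by ``speed`` along their current
    heading, with specular wall reflection), then encounter resolution:
    every pair newly within ``radius`` bounces and exchanges one noisy
    mutual perception, processed in ascending index order.  An agent
    whose memory fills revises immediately; surplus perceptions in the
    same iteration start the fresh memory.
    """
    events = IterationEvents()
    state.time += 1
    state.positions += config.speed * state.headings
    _reflect_walls(state, config.world_side)

    # Condensed pairwise distances; in-range pairs are sparse, so only
    # the few hit indices are expanded to (i, j) tuples.
    d2 = pdist(state.positions, "sqeuclidean")
    hits = np.nonzero(d2 <= config.radius * config.radius)[0]
    iu, ju = _condensed_pairs(state.n_agents)
    current = {(int(iu[k]), int(ju[k])) for k in hits}

    new_pairs = sorted(current - state.in_range_pairs)
    for i, j in new_pairs:
        _bounce(state, i, j, rng)
        events.encounters.append((i, j))
        # The mutual perceptions of one encounter are simultaneous: both
        # agents perceive the opinion the other held at the onset, even if
        # the first perception triggers an immediate revision.
        opinion_i = int(state.opinions[i])
        opinion_j = int(state.opinions[j])
        _append_and_maybe_revise(state, i, opinion_j, config, rng, events)
        _append_and_maybe_revise(state, j, opinion_i, config, rng, events)
    state.in_range_pairs = current
    return state, events


def _snapshot(state: SwarmState, snap_opinion, snap_mem_a, snap_mem_len, row: int) -> None:
    snap_opinion[row] = state.opinions
    for i, mem in enumerate(state.memories):
        snap_mem_a[row, i] = sum(mem)
        snap_mem_len[row, i] = len(mem)


def run(
    config: SwarmConfig,
    seed: int | None = None,
    record_window: tuple[int, int] | None = None,
) -> EventLog:
    """Execute one full simulation run and return its :class:`EventLog`.

    ``record_window = (t0, t1]`` restricts the per-agent memory snapshots
    (not the global-state trace or the revision events, which are always
    complete) to iterations ``t0 < t <= t1``; by default snapshots cover
    the whole run.  Bit-reproducible for a fixed seed.
    """
    if seed is None:
        seed = config.seed
    t_max = config.n_iterations
    if record_window is None:
        record_window = (0, t_max)
    w0, w1 = record_window
    if not (0 <= w0 < w1 <= t_max):
        raise ValueError(f"record_window {record_window} outside run length {t_max}")

    rng = np.random.default_rng(seed)
    state = init_swarm(config, seed=int(rng.integers(0, 2**31)))
    n = config.n_agents
    s = np.empty(t_max + 1)
    s[0] = state.n_a / n
    revisions: list[RevisionEvent] = []
    n_snap = w1 - w0
    snap_times = np.arange(w0 + 1, w1 + 1)
    snap_opinion = np.zeros((n_snap, n), dtype=np.int8)
    snap_mem_a = np.zeros((n_snap, n), dtype=np.int16)
    snap_mem_len = np.zeros((n_snap, n), dtype=np.int16)

    for t in range(1, t_max + 1):
        _, events = advance(state, config, rng)
        s[t] = state.n_a / n
        revisions.extend(events.revisions)
        if w0 < t <= w1:
            _snapshot(state, snap_opinion, snap_mem_a, snap_mem_len, t - w0 - 1)

    return EventLog(
        config=config,
        seed=seed,
        s=s,
        rev_time=np.array([e.time for e in revisions], dtype=np.int64),
        rev_agent=np.array([e.agent for e in revisions], dtype=np.int64),
        rev_old=np.array([e.old for e in revisions], dtype=np.int64),
        rev_new=np.array([e.new for e in revisions], dtype=np.int64),
        rev_s=np.array([e.s_before for e in revisions]),
        snap_times=snap_times,
        snap_opinion=snap_opinion,
        snap_mem_a=snap_mem_a,
        snap_mem_len=snap_mem_len,
    )


@dataclass
class RunSummary:
    """Windowed measurement samples extracted from one run.

    Keeps only what the observables need — one-step state changes keyed
    by the pre-step state, defined local perception states with the
    observer's opinion, and opinion-change revisions with the state at
    revision — so ensembles of many runs stay small in memory.
    """

    window: tuple[int, int]
    n_agents: int
    delta_s_before: np.ndarray  # (W,) state before each one-step change
    delta: np.ndarray  # (W,) the change itself
    local_s: np.ndarray  # (L,) global state at each defined local sample
    local_frac: np.ndarray  # (L,) fraction of A entries in the memory
    local_opinion: np.ndarray  # (L,) observer opinion
    rev_s: np.ndarray  # (R,) state before each opinion-changing revision
    rev_old: np.ndarray  # (R,)
    rev_new: np.ndarray  # (R,)


def default_window(config: SwarmConfig, length: int = 100) -> tuple[int, int]:
    """The standard measurement window: the final ``length`` iterations."""
    return (max(0, config.n_iterations - length), config.n_iterations)


def summarize_log(log: EventLog, window: tuple[int, int] | None = None) -> RunSummary:
    """Reduce an :class:`EventLog` to the samples inside a window.

    The window ``(t0, t1]`` selects: state changes arriving at
    ``t0 < t <= t1`` (each keyed by the state before the step), memory
    snapshots at those iterations (empty memories are undefined and
    dropped), and opinion-changing revisions at those iterations.
    """
    if window is None:
        window = default_window(log.config)
    w0, w1 = window
    t_max = log.n_iterations
    if not (0 <= w0 < w1 <= t_max):
        raise ValueError(f"window {window} outside run length {t_max}")

    delta_s_before = log.s[w0:w1]
    delta = log.s[w0 + 1 : w1 + 1] - log.s[w0:w1]

    in_snap = (log.snap_times > w0) & (log.snap_times <= w1)
    if in_snap.sum() != w1 - w0:
        raise ValueError(f"window {window} not covered by recorded snapshots")
    mem_len = log.snap_mem_len[in_snap]
    mem_a = log.snap_mem_a[in_snap]
    opinion = log.snap_opinion[in_snap]
    # Global state at each snapshot iteration, broadcast across agents.
    s_at = np.broadcast_to(log.s[log.snap_times[in_snap]][:, None], mem_len.shape)
    defined = mem_len > 0
    local_s = s_at[defined]
    local_frac = mem_a[defined] / mem_len[defined]
    local_opinion = opinion[defined].astype(np.int64)

    in_win = (log.rev_time > w0) & (log.rev_time <= w1) & (log.rev_old != log.rev_new)
    return RunSummary(
        window=(w0, w1),
        n_agents=log.config.n_agents,
        delta_s_before=delta_s_before.copy(),
        delta=delta,
        local_s=local_s,
        local_frac=local_frac,
        local_opinion=local_opinion,
        rev_s=log.rev_s[in_win],
        rev_old=log.rev_old[in_win],
        rev_new=log.rev_new[in_win],
    )


def derive_seeds(base_seed: int, n: int) -> list[int]:
    """Per-run seeds: ``SeedSequence(base_seed).generate_state(n)``.

    A documented, deterministic counter scheme so ensembles are
    reproducible and trivially parallelisable.
    """
    ss = np.random.SeedSequence(base_seed)
    return [int(x) for x in ss.generate_state(n, dtype=np.uint32)]


def run_ensemble(
    config: SwarmConfig,
    n_repetitions: int | None = None,
    base_seed: int | None = None,
    window: tuple[int, int] | None = None,
) -> list[RunSummary]:
    """Independent runs reduced to windowed measurement summaries.

    Seeds are derived from ``base_seed`` via :func:`derive_seeds`.  The
    default measurement window is the final 100 iterations.
    """
    if n_repetitions is None:
        n_repetitions = config.n_repetitions
    if n_repetitions < 1:
        raise ValueError("n_repetitions must be >= 1")
    if base_seed is None:
        base_seed = config.seed
    if window is None:
        window = default_window(config)
    seeds = derive_seeds(base_seed, n_repetitions)
    summaries = []
    for run_seed in seeds:
        log = run(config, seed=run_seed, record_window=window)
        summaries.append(summarize_log(log, window))
    return summaries
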