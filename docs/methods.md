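# Methods

## The microscopic scenario

`N` point agents move at constant speed in straight lines inside the
unit square, reflecting specularly off the walls and bouncing
elastically off each other as soon as a pair comes within the avoidance
radius `r`.  The same radius is the perception range: at the *onset* of
an encounter (the out-of-range → in-range transition) both agents
perceive the other's binary opinion, flipped independently with
probability `γ`, and append it to an internal memory.  When the memory
reaches `memory_size` entries (odd, default 5) the agent adopts the
strict majority of the memory and clears it.  The macroscopic state is
`s = A_count / N`.

Reference parameters: `N = 150`, side length 1, `r = 0.01`, speed 0.01
per iteration, `γ = 0.2`, memory 5, 8000 iterations per run, with
measurements taken in the final 100 iterations.  Desk-scale ensembles
use fewer/shorter runs; see "Study sizes" below.

Choices the scenario definition leaves open, resolved as follows:

- **Bounce.**  On encounter onset the two agents exchange the velocity
  components along the line of centres (elastic, equal masses) and the
  headings are renormalised to unit length so the speed is exactly
  constant at all times.  Coincident positions get a random contact
  normal.
- **Perception granularity.**  One mutual perception per encounter
  onset, not per in-range iteration — a slow fly-by must not fill a
  memory by itself.  A pair that separates beyond `r` and re-enters
  counts as a new encounter.  Since avoidance and perception radii are
  equal, every bounce is also a perception event.
- **Ordering.**  Per iteration: synchronous motion of all agents from
  the same snapshot (wall reflection folded into the move), then
  encounter resolution in ascending pair order.  The two perceptions of
  one encounter are simultaneous: each agent perceives the opinion the
  other held at onset, even if the first perception triggers an
  immediate revision.  An agent may gain several perceptions in one
  iteration; revision fires the moment the memory fills, and surplus
  perceptions start the fresh memory.
- **Initialisation.**  Positions i.i.d. uniform, headings i.i.d. uniform
  on directions, and an exact quota `round(s₀·N)` of A-opinions.  The
  configurable `s₀` is what lets desk-scale ensembles cover the state
  axis; the reference setting reaches extreme states only through very
  large ensembles.
- **Seeding.**  One root seed; per-condition and per-run seeds derived
  through `numpy.random.SeedSequence.generate_state`, so any slice of an
  ensemble reproduces independently.

## Observables

All measurements are keyed to a window `(t₀, t₁]` late in the run and
binned over `s` (natural width `1/N`; coarser widths for small
ensembles; empty bins are reported missing, never zero-imputed):

- **Drift profile** `Δs(s)`: mean of `s_{t+1} − s_t` keyed by the
  pre-step state, with per-bin standard errors.
- **Local perception state**: the fraction of A entries in an agent's
  memory (undefined for empty memories, which are excluded from both
  numerator and denominator), averaged flat over all defined
  (agent, time, run) samples per bin, overall and split by the
  observer's own opinion.  Flat sample averaging (rather than averaging
  per-run means) is the direct reading of an ensemble-and-population
  average; with balanced run lengths the two differ negligibly.
- **Revision counts** `r_a(s)`, `r_b(s)`: opinion-*changing* revisions
  per bin and direction at the state immediately before the change.
  Majority-confirming revisions change nothing and are not counted.

Under well mixing the mean local state is the line `(1 − 2γ)s + γ`; its
measured deviation, and in particular the dependence on the observer's
own opinion (A-observers see more A than average for `s < 0.8`, and
mirrored for B), is the package's evidence of spatially correlated
opinions.

**Sampling errors.**  A memory persists for roughly the revision
turnover time (~100 iterations at reference parameters), so the ~100
window snapshots of one agent are strongly autocorrelated.  Tests that
compare local-state means against a band therefore use an effective
sample size of `n / window_length` — approximately one independent
memory per agent per window — instead of the raw sample count.  Drift
samples are much less correlated (each is a population-level increment)
and use their empirical per-bin standard errors.

## Galam model with contrarians

The composed drift is `d·(g(c₁·s + c₂, a) − s)` with `g` the
group-size-`m` majority map with contrarian fraction `a`, and
`(c₁, c₂) = (1 − 2γ, γ)` by default (an empirically fitted perception
line may override).  Two readings of where the amplitude `d` acts are
possible; the default multiplies the *drift*, so `d` scales magnitudes
without moving fixed points — consistent with a fixed-point narrative
(merge at `a_c`, locations 0, ½, 1) that is stated independently of
`d`.  The alternative `d·g(·) − s` is available behind a switch.

- **Fixed points**: sign-change scan of the drift on a uniform grid
  (step 1e−4) refined by Brent's method to 1e−10; duplicates merged at
  1e−6 (far below the grid so near-merge root pairs stay distinct).
  Stability from the drift slope by central difference with step 1e−4 —
  wide enough that at a degenerate (saddle-node) root, where the drift
  is O(u³), the probe (≈1e−12) stays above the ~1e−16 floating-point
  noise of the polynomial evaluation; a 1e−6 probe would be
  noise-dominated there.
- **Critical contrarian density**: bisection on `a` over the count of
  stable fixed points (tolerance 1e−8), cross-checked against the
  closed-form merge condition `(1 − 2a)(1 − 2γ)·P_m′(½) = 1` with
  `P₅′(½) = 30/16`, i.e. `a_c(0.2) = 1/18`.  For `γ ≥ 7/30` noise alone
  is monostabilising and `a_c` is negative: `a` is allowed in (−1, 1),
  a negative value acting as an effective conformist excess.  The
  bistable window below a negative `a_c` is narrow (the composed map
  leaves the unit interval), so the bracket search steps by 0.05.
- **Fitting `(a, d)`**: count-weighted least squares over populated
  bins, bounds `a ∈ [0, 0.5)`, `d ∈ (0, 10]`, multi-started from a
  coarse grid.  Diagnostics report residual RMS inside and outside the
  central interval `0.17 < s < 0.83`, where the contrarian correction
  is known to degrade.  An identically zero profile is rejected as
  unidentifiable rather than silently fitted.

## Urn model

The two-draw game and the drift law `Δs = 4e(P_fb(s) − ½)(s − ½)` are
implemented as stated.  The feedback estimator inverts the revision
mix: with `ρ_a = r_a/(r_a + r_b)`, the mechanics give
`ρ_a = s·P + (1 − s)(1 − P)`, hence `P = (ρ_a − 1 + s)/(2s − 1)` for
`s ≠ ½`, with `ρ` constrained to `[min(s, 1−s), max(s, 1−s)]`.  Putting
`r_b` in the numerator instead yields `1 − P` under the same mechanics;
both orientations are exposed, and the default is the one under which
feedback probabilities used to generate revisions are recovered
(verified by a simulate→estimate round trip at pinned states).

Finite-count ratios may violate the bound; they are clipped to the
nearest bound before the transform, which lands every estimate in
[0, 1] exactly.  Bins at `s = ½` are structurally uninformative and
flagged invalid.  The quartic fit uses the even basis `{1, u², u⁴}` in
`u = s − ½` (symmetry by construction, never by penalty), weighted by
per-bin revision totals — which also down-weights the low-leverage bins
next to `½`.  The fitted polynomial is unconstrained; evaluation clamps
to [0, 1] with a warning.  The time scale `e` has the closed-form
weighted solution `Σw·y·x / Σw·x²` with `x = 4(P_fb − ½)(s − ½)`.

## Study sizes and what the reduced-scale tests show

The reference ensemble (10⁶ runs × 8000 iterations) is far beyond a
test suite.  The package's measurement ensemble uses `N = 150`,
`γ = 0.2`, 1000 iterations with the final 100 as window, 13 initial
fractions spanning [0.02, 0.98] at 20 runs each, plus 100 extra runs at
each of four extreme initial fractions so the tail bins carry enough
samples to resolve systematic model error there (~90 s total).

At this scale the suite verifies: the measured perception line matches
`0.6s + 0.2` to within a bounded correlation bias; the
opinion-conditioned bias has the correct sign everywhere it is
measurable; the urn pipeline (estimate → quartic fit → time-scale fit)
reproduces the sign pattern of the measured drift and places interior
stable states on both sides of ½; and the contrarian model calibrated
on the central interval misfits the tails more than the centre in
noise-normalised terms.  The raw (count-weighted) inside/outside
residual comparison is *not* asserted: at desk scale it is dominated by
the very unequal per-bin sampling noise and its direction is unstable.

Two caveats about what passing does not show.  First, the desk-scale
ensemble reaches extreme states mostly through extreme initial
fractions whose spatial correlations have had only ~10 revision
turnovers to develop, whereas the reference setting reaches them
through rare late-time excursions of fully clustered swarms; the
correlation signatures measured here are therefore conservative.
Second, with ~1300 window revisions per tail condition the feedback
polynomial's tail coefficients (`b₁`, `b₂`) remain noisy; only the
structure (crossings of ½, hence interior attractors) is stable across
seeds, and only that structure is asserted.

## Degenerate inputs and edge conventions

Coincident particles get a random contact normal; a zero post-exchange
heading is replaced by a random direction.  A revision memory is always
odd-sized, so ties cannot occur.  In the urn game a required switch
with no eligible agent (at `s ∈ {0, 1}`) is a no-op, making unanimity
absorbing exactly when `P_fb = 1`.  Config files reject unknown keys;
profile CSVs round-trip missing bins as `n = 0` with empty mean fields.
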