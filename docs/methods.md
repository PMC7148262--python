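# Methods

## Experiment state machine

A session moves `created → in_progress → ended`, each transition at most
once; the first `trial.begin()` promotes the session and captures the clock
origin. Trials move `not_started → in_progress → done`. Illegal transitions
(double begin, end-before-begin, operations on an ended session) raise
`LifecycleError` and leave state untouched — the property suite drives
random operation sequences and checks that no sequence can produce a status
regression, a gap in the `1..N` trial numbering, or `end_time ≤ start_time`.

Timestamps are seconds since session begin, read from an injectable
zero-argument clock (default `time.monotonic`; `ManualClock` for simulated
or scripted sessions) and serialized with three decimals. Degenerate case:
if a trial begins and ends within one clock tick, the end time is nudged up
by one ulp so the `end > start` invariant holds rather than silently
recording a zero-length interval backwards.

Results are accepted while a trial is in progress *and* after it is done
(post-hoc scoring is common); only a never-begun trial refuses them. Event
hooks run in registration order; a hook exception is logged and swallowed
so a buggy callback cannot abort data collection mid-session.

## Settings cascade

Resolution walks the explicit parent chain trial → block → session →
profile and returns the first hit; a miss at every level raises an error
naming the key and the levels searched (a sentinel return would let typos
masquerade as missing manipulations). Keys are case-sensitive exact
strings; values must be JSON-serializable, checked at assignment time.
Profiles populate the level *below* the session, so programmatic session
values override profile values, and merging the same profile twice is
idempotent. Profiles target the session level only; per-block or per-trial
profile sections are not supported.

## Data store

The write path is a FIFO queue serviced by one daemon thread: producers
enqueue `(path, payload, hooks)` tasks and continue immediately; `drain()`
blocks until everything previously enqueued is on disk (written, flushed,
fsynced). One worker means per-destination write order equals enqueue
order, so the last payload enqueued for a path is the one that survives. A
failed write never raises into experiment code: it is recorded per task and
reported when the session ends. Destinations must resolve inside the output
root; anything else is refused before queuing. Post-write hooks (fired with
the written path after a successful write) are the extension point for
shipping files to external storage; the core contains no network code.

Behavioral rows carry the identity columns
(`experiment, ppid, session_num, trial_num, block_num, start_time,
end_time`), then the session's declared `settings_to_log` resolved per
trial, then result columns in first-seen order across the session. The
column set is identical on every row, with blanks where a trial lacks a
value; a never-begun trial produces no row. Booleans serialize as
lower-case `true`/`false`, times with three decimals, and the dialect is
comma-delimited, LF-terminated, minimally quoted CSV. The session directory
is `base_dir/experiment/ppid/S<session:03d>`; re-using a directory that
already holds data is refused unless overwrite is explicitly requested.

## Tracking

Trackers buffer `(time, *fields)` rows while their trial is in progress;
times are trial-relative seconds and must be strictly increasing. The
library is tick-driven — the caller records one row per tick of whatever
clock it owns (a simulation here; a display loop at, e.g., 90 Hz in an
interactive deployment), so `duration × rate` ticks yield exactly that many
rows. On trial end each tracker flushes one CSV per trial named
`<tracker>_T<trial:03d>.csv`, joinable to the behavioral row on the trial
number; an empty buffer still yields a header-only file. Pose rows use
meters with y up, z anterior-posterior, x lateral, and Euler angles in
degrees; no unit conversion is ever applied.

## Swinging-room simulation

The room pitches about the floor-center x-axis with angle
`θ(t) = A sin(2π f t)`, defaults `A = 5°`, `f = 0.25 Hz`, logged for 10 s
at 90 Hz per trial (θ ≡ 0 in the normal condition). Head position follows
a discrete mean-reverting random walk with a visually coupled term on the
anterior-posterior axis:

```
p(t+Δ) = p(t) + λ (p_rest − p(t)) + η(t) + c [θ(t+Δ) − θ(t)] ẑ
```

with `η` i.i.d. zero-mean Gaussian per axis. Parameters, per tick of
`Δ = 1/90 s`:

| parameter | adult | child | meaning |
|---|---|---|---|
| `noise_sd_m` | 0.0008 | 0.0016 | random-walk scale per axis (m/tick) |
| `mean_reversion` (λ) | 0.02 | 0.02 | fractional pull toward rest posture |
| `coupling_m_per_deg` (c) | 0.002 | 0.002 | AP displacement per degree of room pitch |
| `rest_height_m` | 1.6 | 1.3 | rest head height (free; does not affect path length) |

The recursion is an AR(1) in the deviation from rest and is evaluated
exactly with a linear filter, so trajectories are deterministic given a
seeded generator. Summing the coupled increments makes the AP displacement
track `c·θ(t)` (attenuated ~0.66× by the mean reversion at 0.25 Hz), i.e.,
a ±10 mm visually driven oscillation before damping.

The numbers are deliberately arbitrary: the model is a stand-in for human
sway that builds in exactly two orderings — children noisier than adults,
and an extra movement component when the room oscillates — and nothing
else. It has none of the spectral structure, intermittency, or adaptation
of real sway, so passing tests demonstrate the *pipeline* (settings →
trials → tracking → files → statistic), not biomechanical fidelity.
Quantitatively, doubling `noise_sd_m` roughly doubles mean path length
(≈ 1.15 m adult vs ≈ 2.30 m child over 10 s), a large, seed-robust gap.
The condition effect is much smaller: the coupled term adds only ~4 mm to
the expected 10-s path at adult noise levels, about one standard error of
a 50-per-group mean difference, so while its *expected* direction is
oscillating > normal, the realized group means at a given master seed can
order either way. This is a known limitation of the chosen calibration and
the reason condition-direction checks are made at a fixed master seed.

Per-participant randomness derives from `SeedSequence([master_seed,
group_code, index])`, so each participant's trajectory and condition order
are a stable substream: enlarging a cohort never changes existing
participants' data. Condition order is a per-participant random permutation
of (normal, oscillating).

## Doubling worked example

`doubling_demo` builds the canonical two-block, ten-trial session: stimulus
sequence `8 3 4 7 4 9 5 10 6 3` as per-trial settings, `manipulation`
false at the session and overridden true on block 2 (no per-trial storage),
responses from an injectable responder (a perfect doubler by default), and
a scripted clock reproducing the reference begin/end times. Custom stimulus
sequences split ceil/floor into the two blocks and run on a uniform
one-second schedule.

## Problem sizes

The test suite and acceptance script use the protocol sizes throughout:
10-trial demo sessions, 100-trial cascade examples, 40 s of oscillation for
the spectral check (frequency resolution 0.025 Hz, so the 0.25 Hz peak is
an exact bin), 1,000-task queue stress, and the full 50 + 50 cohort with
two 900-sample trials per participant (a run of a few seconds).
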