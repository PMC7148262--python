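# trialkit

A headless, engine-agnostic experiment-management core for trial-based
human-behavior research. It provides the "nuts and bolts" that sit behind a
behavioral experiment — the session–block–trial state machine, cascading
settings, behavioral and continuous data files, a deferred durable write
queue, and a participant registry — without any stimulus presentation,
rendering, or hardware code. Whatever drives the experiment (a game engine,
a psychophysics loop, or the bundled simulation) calls into the library;
the library never owns a frame loop.

## The model

Experiments follow the session–block–trial structure:

- a **session** is one complete run by one participant;
- a **block** groups consecutive trials sharing a manipulation;
- a **trial** is one stimulus–response unit with begin/end timestamps and
  a mapping of named results.

Block numbers are `1..B` and trial numbers are *session-global* `1..N`, both
assigned automatically in creation order. Independent variables live in a
**settings cascade**: a lookup at the trial level falls back to the block,
then the session, then an optional JSON settings profile, so a parameter can
be stored once for the whole session and overridden on the single trial that
deviates. Lifecycle events (`on_session_begin`, `on_trial_begin`,
`on_trial_end`, `on_session_end`) invoke registered hooks in order.

Outputs are plain CSV under `base_dir/experiment/participant/S###/`:
`trial_results.csv` (one behavioral row per begun trial),
`<tracker>_T###.csv` (one continuous file per tracker per trial, joinable on
trial number), `log.txt`, and a `participant_list.csv` registry beside the
session tree. All writes go through a FIFO background queue so the
experiment loop is never blocked by disk latency; ending the session drains
the queue before returning.

The package ships a complete synthetic case study of the *swinging-room*
paradigm: a virtual room pitches sinusoidally about the floor-center x-axis
(amplitude 5°, frequency 0.25 Hz) while head position is logged at 90 Hz
over two 10-s trials (room static vs. oscillating). Postural instability is
indexed by the head **path length**

$$L = \sum_{k} \lVert p_{k+1} - p_k \rVert_2 ,$$

the sum of point-to-point distances over a trial. Head motion comes from an
explicitly synthetic sway model (a mean-reverting Gaussian random walk with
a visually coupled anterior-posterior component — see `docs/methods.md`),
with children given a larger noise scale than adults.

## Worked example

The classic worked example is a two-block, ten-trial task in which the
participant sees a number *x* and must answer 2*x*; block 2 runs with a
session setting `manipulation` overridden to `true` at the block level.

```
$ trialkit demo-doubling --ppid P01 --out data
session written to data/doubling/P01/S001
$ head -4 data/doubling/P01/S001/trial_results.csv
experiment,ppid,session_num,trial_num,block_num,start_time,end_time,manipulation,x,response
doubling,P01,1,1,1,0.000,1.153,false,8,16
doubling,P01,1,2,1,1.153,2.112,false,3,6
doubling,P01,1,3,1,2.112,2.950,false,4,8
```

Each row is one trial: timestamps are seconds since session begin, the
`manipulation` and `x` columns are settings resolved per trial through the
cascade, and `response` is the recorded result (`16 = 2·8`, and so on).

The cohort study runs end to end from one seed:

```
$ trialkit swingroom --n-adults 50 --n-children 50 --seed 1 --out data
study summary written to data/study_results.csv
mean path length [normal]: 1.728 m
mean path length [oscillating]: 1.729 m
```

which writes one full session directory per synthetic participant (two
trials each, with 900-sample head trajectories) plus a tidy
`study_results.csv` of `ppid, group, condition, path_length_m`. With the
default sway parameters, children's mean path length (≈ 2.30 m) is about
twice the adults' (≈ 1.15 m). `trialkit validate <session_dir>` checks an
existing session directory against the output schema.

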