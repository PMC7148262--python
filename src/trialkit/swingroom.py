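"""Swinging-room postural-sway simulation and the doubling worked example.

The swinging-room paradigm perturbs vision while leaving kinesthetic cues
intact: the participant stands in a virtual room (3 m high, 6 m wide, 6 m
deep) that either stays still (*normal* condition) or pitches sinusoidally
about the x-axis through the floor-center point (*oscillating* condition),
with amplitude 5 degrees and frequency 0.25 Hz. Head position is logged at
90 Hz for 10 s per trial, and the path length of the head — the sum of all
point-to-point Euclidean distances over a trial — indexes postural
instability (longer path = more sway).

Since no real participants are available here, head motion comes from an
explicitly synthetic sway model: a mean-reverting Gaussian random walk
around a rest posture, with a visually driven component that displaces the
head along the anterior-posterior (z) axis in proportion to the room's
pitch angle. Per tick of length :math:`\\Delta`:

.. math::

   p_{t+\\Delta} = p_t + \\lambda\\,(p_\\text{rest} - p_t) + \\eta_t
                  + c\\,[\\theta(t+\\Delta) - \\theta(t)]\\,\\hat z

with :math:`\\eta_t` i.i.d. zero-mean Gaussian per axis (scale
``noise_sd_m``), :math:`\\lambda` the mean-reversion fraction, :math:`c`
the visual coupling gain in meters per degree, and :math:`\\theta` the room
angle (identically zero in the normal condition). Children are emulated by
a larger per-tick noise scale than adults, so both known directional
effects — children sway more than adults, and everyone sways more when the
room oscillates — are built into the generator. The model is a caricature:
it reproduces those orderings and nothing else (no biomechanics, no
spectral structure of real sway, no learning across trials).

This module also doubles as the package's fixture generator: it builds full
sessions through the core model, records trajectories through trackers,
and writes standard session directories.
"""

from __future__ import annotations

import math
import tempfile
from dataclasses import dataclass
from pathlib import Path
from typing import Any, Callable, Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy.signal import lfilter

from .core import ManualClock, create_session
from .datastore import PARTICIPANT_LIST_FILENAME, ParticipantRegistry, SessionStore
from .tracking import PoseTracker, TrajectorySample

__all__ = [
    "SwingRoomParams",
    "SwayParams",
    "ADULT_SWAY",
    "CHILD_SWAY",
    "CONDITIONS",
    "room_angle",
    "simulate_trial",
    "path_length",
    "spectral_peak_hz",
    "run_study",
    "doubling_demo",
    "DOUBLING_X",
    "DOUBLING_SCHEDULE",
    "STUDY_RESULTS_FILENAME",
]

CONDITIONS = ("normal", "oscillating")
STUDY_RESULTS_FILENAME = "study_results.csv"


@dataclass(frozen=True)
class SwingRoomParams:
    """Room geometry, oscillation and logging parameters.

    Defaults are the case-study protocol: a 3x6x6 m room pitching about the
    floor-center with amplitude 5 deg at 0.25 Hz, two 10-s trials logged at
    90 Hz (the refresh rate of common VR headsets).
    """

    amplitude_deg: float = 5.0
    freq_hz: float = 0.25
    duration_s: float = 10.0
    sample_rate_hz: float = 90.0
    height_m: float = 3.0
    width_m: float = 6.0
    depth_m: float = 6.0

    def __post_init__(self) -> None:
        for name in ("amplitude_deg", "freq_hz", "duration_s",
                     "sample_rate_hz", "height_m", "width_m", "depth_m"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")
        n = self.duration_s * self.sample_rate_hz
        if abs(n - round(n)) > 1e-9:
            raise ValueError("duration_s * sample_rate_hz must be integral")

    @property
    def n_samples(self) -> int:
        return round(self.duration_s * self.sample_rate_hz)


@dataclass(frozen=True)
class SwayParams:
    """Synthetic sway-model parameters for one participant group.

    ``noise_sd_m`` is the per-tick random-walk scale per axis;
    ``mean_reversion`` the per-tick fractional pull toward the rest
    posture; ``coupling_m_per_deg`` the visually driven anterior-posterior
    displacement per degree of room pitch. The defaults (0.8 mm/tick for
    adults, 1.6 mm/tick for children, reversion 0.02, coupling 2 mm/deg)
    are arbitrary but make both group and condition orderings detectable
    in cohorts of 50 per group.
    """

    group: str = "adult"
    noise_sd_m: float = 0.0008
    mean_reversion: float = 0.02
    coupling_m_per_deg: float = 0.002
    rest_height_m: float = 1.6
    seed: int | None = None

    def __post_init__(self) -> None:
        if self.noise_sd_m < 0:
            raise ValueError("noise_sd_m must be >= 0")
        if self.coupling_m_per_deg < 0:
            raise ValueError("coupling_m_per_deg must be >= 0")
        if not 0.0 <= self.mean_reversion <= 1.0:
            raise ValueError("mean_reversion must be in [0, 1]")


ADULT_SWAY = SwayParams(group="adult", noise_sd_m=0.0008, rest_height_m=1.6)
CHILD_SWAY = SwayParams(group="child", noise_sd_m=0.0016, rest_height_m=1.3)


def room_angle(t: float | np.ndarray, params: SwingRoomParams) -> float | np.ndarray:
    """Room pitch angle (degrees) at time ``t`` in the oscillating condition.

    ``amplitude_deg * sin(2 pi freq_hz t)``; the normal condition simply
    never evaluates this (the angle is identically zero there).
    """
    return params.amplitude_deg * np.sin(2.0 * np.pi * params.freq_hz * np.asarray(t))


def simulate_trial(
    condition: str,
    sway: SwayParams,
    room: SwingRoomParams | None = None,
    rng: np.random.Generator | None = None,
) -> pd.DataFrame:
    """Simulate one trial's head trajectory.

    Returns a DataFrame with columns ``time, pos_x, pos_y, pos_z, rot_x,
    rot_y, rot_z`` and ``room.n_samples`` rows at ``1/sample_rate_hz``
    spacing, starting from the rest posture. Head rotation is not modeled
    and is reported as zero. Deterministic given a seeded ``rng`` (or
    ``sway.seed`` when ``rng`` is omitted).
    """
    if condition not in CONDITIONS:
        raise ValueError(f"condition must be one of {CONDITIONS}, got {condition!r}")
    room = room or SwingRoomParams()
    if rng is None:
        rng = np.random.default_rng(sway.seed)
    n = room.n_samples
    t = np.arange(n) / room.sample_rate_hz
    theta = room_angle(t, room) if condition == "oscillating" else np.zeros(n)

    rest = np.array([0.0, sway.rest_height_m, 0.0])
    pos = np.tile(rest, (n, 1))
    if n > 1:
        # increments: noise plus visually driven z displacement
        u = rng.normal(0.0, sway.noise_sd_m, size=(n - 1, 3))
        u[:, 2] += sway.coupling_m_per_deg * np.diff(theta)
        # deviation from rest follows q_{k+1} = (1-lambda) q_k + u_k, q_0 = 0,
        # which is an AR(1) filter applied to the increments
        a = 1.0 - sway.mean_reversion
        pos[1:] += lfilter([1.0], [1.0, -a], u, axis=0)

    return pd.DataFrame({
        "time": t,
        "pos_x": pos[:, 0], "pos_y": pos[:, 1], "pos_z": pos[:, 2],
        "rot_x": 0.0, "rot_y": 0.0, "rot_z": 0.0,
    })


def _positions(samples: Any) -> np.ndarray:
    if isinstance(samples, pd.DataFrame):
        return samples[["pos_x", "pos_y", "pos_z"]].to_numpy(dtype=float)
    if isinstance(samples, np.ndarray):
        if samples.ndim == 2 and samples.shape[1] == 3:
            return samples.astype(float)
        raise ValueError("array input must have shape (n, 3)")
    if isinstance(samples, Iterable):
        rows = [(s.pos_x, s.pos_y, s.pos_z) for s in samples]
        return np.asarray(rows, dtype=float).reshape(-1, 3)
    raise TypeError(f"cannot extract positions from {type(samples).__name__}")


def path_length(samples: pd.DataFrame | np.ndarray | Sequence[TrajectorySample]) -> float:
    """Sum of consecutive point-to-point 3-D distances, in meters.

    Rotations are ignored. A single sample has zero path length; an empty
    input is an error.
    """
    pos = _positions(samples)
    if len(pos) == 0:
        raise ValueError("path_length requires at least one sample")
    if len(pos) == 1:
        return 0.0
    return float(np.linalg.norm(np.diff(pos, axis=0), axis=1).sum())


def spectral_peak_hz(values: np.ndarray, sample_rate_hz: float) -> float:
    """Frequency (Hz) of the largest non-DC magnitude in the DFT of a trace."""
    values = np.asarray(values, dtype=float)
    spectrum = np.abs(np.fft.rfft(values - values.mean()))
    freqs = np.fft.rfftfreq(len(values), d=1.0 / sample_rate_hz)
    return float(freqs[int(np.argmax(spectrum))])


# ---------------------------------------------------------------------------
# Full cohort study
# ---------------------------------------------------------------------------

def _participant_rng(master_seed: int, group_code: int, index: int) -> np.random.Generator:
    # Substream per participant: stable under changes to cohort sizes.
    return np.random.default_rng(
        np.random.SeedSequence([int(master_seed), group_code, index]))


def run_study(
    n_adults: int = 50,
    n_children: int = 50,
    base_dir: str | Path | None = None,
    sway_by_group: Mapping[str, SwayParams] | None = None,
    room: SwingRoomParams | None = None,
    master_seed: int = 0,
    overwrite: bool = False,
) -> pd.DataFrame:
    """Run the synthetic two-condition cohort study end to end.

    Each synthetic participant performs one full session of two trials —
    normal and oscillating, in per-participant random order — through the
    core model: the condition is stored as a trial setting, the head
    trajectory is recorded through a pose tracker (one CSV per trial), the
    per-trial path length goes into the behavioral results, and the
    participant's group is upserted into the registry.

    Returns a tidy DataFrame with one row per trial (``ppid, group,
    condition, path_length_m``); with ``base_dir`` set, session
    directories plus ``study_results.csv`` are written there. Fully
    reproducible from ``master_seed``.
    """
    if n_adults < 1 or n_children < 1:
        raise ValueError("need at least one participant per group")
    sway_by_group = dict(sway_by_group or {"adult": ADULT_SWAY, "child": CHILD_SWAY})
    room = room or SwingRoomParams()

    tmp: tempfile.TemporaryDirectory | None = None
    if base_dir is None:
        tmp = tempfile.TemporaryDirectory(prefix="trialkit-study-")
        out_dir = Path(tmp.name)
    else:
        out_dir = Path(base_dir)
    registry = ParticipantRegistry(out_dir / PARTICIPANT_LIST_FILENAME)

    rows: list[dict[str, Any]] = []
    try:
        for group_code, (group, n) in enumerate(
                [("adult", n_adults), ("child", n_children)]):
            sway = sway_by_group[group]
            for i in range(1, n + 1):
                ppid = f"{group}{i:03d}"
                rng = _participant_rng(master_seed, group_code, i)
                order = [CONDITIONS[j] for j in rng.permutation(2)]

                clock = ManualClock()
                session = create_session("swingroom", ppid, 1, clock=clock)
                SessionStore(out_dir, session, overwrite=True)
                tracker = PoseTracker("head_pose")
                session.trackers.append(tracker)
                session.settings_to_log = ["condition"]
                block = session.create_block(0)
                for condition in order:
                    block.create_trial({"condition": condition})

                for trial in block.trials:
                    condition = trial.settings.get("condition")
                    traj = simulate_trial(condition, sway, room, rng=rng)
                    trial.begin()
                    data = traj.to_numpy()
                    for row in data:
                        tracker.record(row[0], row[1:])
                    clock.advance(room.duration_s)
                    length = path_length(traj)
                    trial.add_result("path_length_m", length)
                    trial.end()
                    rows.append({"ppid": ppid, "group": group,
                                 "condition": condition,
                                 "path_length_m": length})
                session.end()
                registry.upsert(ppid, {"group": group})
        registry.save()
        results = pd.DataFrame(rows, columns=["ppid", "group", "condition",
                                              "path_length_m"])
        if base_dir is not None:
            results.to_csv(out_dir / STUDY_RESULTS_FILENAME, index=False,
                           lineterminator="\n")
        return results
    finally:
        if tmp is not None:
            tmp.cleanup()


# ---------------------------------------------------------------------------
# Doubling worked example
# ---------------------------------------------------------------------------

#: Stimulus sequence of the two-block, ten-trial doubling demo (the
#: participant sees x and answers 2x; block 2 runs with manipulation=true).
DOUBLING_X: tuple[int, ...] = (8, 3, 4, 7, 4, 9, 5, 10, 6, 3)

#: Scripted per-trial (begin, end) times in seconds for the default demo,
#: reproducing the reference behavioral output of the worked example.
DOUBLING_SCHEDULE: tuple[tuple[float, float], ...] = (
    (0.000, 1.153), (1.153, 2.112), (2.112, 2.950), (2.950, 3.921),
    (3.921, 4.727), (4.727, 5.826), (5.826, 6.863), (6.863, 7.693),
    (7.693, 8.839), (8.839, 9.992),
)


def doubling_demo(
    base_dir: str | Path,
    ppid: str = "P01",
    session_num: int = 1,
    x_values: Sequence[int] | None = None,
    responder: Callable[[int], Any] | None = None,
    overwrite: bool = False,
    profile: Mapping[str, Any] | None = None,
) -> Path:
    """Run the two-block doubling experiment and return its session directory.

    The participant is shown a number ``x`` on each trial and must answer
    ``2x``; ``responder`` maps stimulus to response (a perfect doubler by
    default). Trials split into two blocks (ceil/floor halves); the session
    sets ``manipulation=false`` and block 2 overrides it to ``true``, so
    the second half resolves the flag through the cascade without per-trial
    storage. Per-trial settings carry ``x``; results carry ``response``.
    """
    x_values = tuple(DOUBLING_X if x_values is None else x_values)
    if not x_values:
        raise ValueError("x_values must be nonempty")
    responder = responder or (lambda x: 2 * x)

    clock = ManualClock()
    session = create_session("doubling", ppid, session_num,
                             {"manipulation": False}, clock=clock)
    if profile:
        session.apply_profile(profile)
    store = SessionStore(base_dir, session, overwrite=overwrite)
    session.settings_to_log = ["manipulation", "x"]

    n_first = math.ceil(len(x_values) / 2)
    block1 = session.create_block(0)
    block2 = session.create_block(0, {"manipulation": True})
    for i, x in enumerate(x_values):
        block = block1 if i < n_first else block2
        block.create_trial({"x": x})

    if len(x_values) == len(DOUBLING_SCHEDULE):
        schedule = DOUBLING_SCHEDULE
    else:
        schedule = tuple((float(i), float(i) + 1.0)
                         for i in range(len(x_values)))

    for trial, (t_begin, t_end) in zip(session.trials, schedule):
        clock.set(t_begin)
        trial.begin()
        trial.add_result("response", responder(trial.settings.get("x")))
        clock.set(t_end)
        trial.end()
    session.end()
    return store.session_dir
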