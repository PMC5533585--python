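"""Single-molecule track segmentation, classification, and velocity.

Particles imaged on microtubules (one frame per 0.5 s) produce 1-D
position-time tracks.  An event is classified by its excursions relative to
running extrema:

* diffusive — at least one excursion greater than 600 nm in each direction
  (a rise of > 600 nm above the running minimum and a drop of > 600 nm
  below the running maximum both occur);
* processive — net unidirectional displacement greater than 600 nm with no
  opposing excursion greater than 600 nm;
* non-motile — everything else.

A track that changes apparent behavior is split into multiple events by a
deterministic, time-reversal-symmetric rule: the local speed at each frame
is the magnitude of the least-squares slope over a centered window, frames
are labeled motile/static against a single speed threshold, the labels are
majority-smoothed, and maximal constant-label runs become events.

Velocities are least-squares slopes of position against time, computed only
for processive events spanning more than five frames; diffusive and
non-motile events never enter velocity statistics.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

PROCESSIVE = "processive"
DIFFUSIVE = "diffusive"
NON_MOTILE = "non_motile"

DEFAULT_REVERSAL_NM = 600.0
DEFAULT_MIN_VELOCITY_FRAMES = 5   # strict: need more than this many intervals
DEFAULT_WINDOW = 5                # frames, odd, for local speed
DEFAULT_SPEED_THRESHOLD = 50.0    # nm/s separating static from motile
DEFAULT_MIN_RUN_FRAMES = 20       # shorter motile/static runs are absorbed


@dataclass
class Track:
    """A 1-D time-position series for one particle."""

    track_id: str
    times: np.ndarray      # seconds, strictly increasing
    positions: np.ndarray  # nm along the microtubule axis, signed
    label: str | None = None  # generating class, when known (simulations)

    def __post_init__(self):
        self.times = np.asarray(self.times, dtype=float)
        self.positions = np.asarray(self.positions, dtype=float)
        if self.times.size != self.positions.size or self.times.size < 2:
            raise ValueError("track needs >= 2 aligned (time, position) points")
        if not np.all(np.diff(self.times) > 0):
            raise ValueError("times must be strictly increasing")
        if not (np.isfinite(self.times).all() and np.isfinite(self.positions).all()):
            raise ValueError("track values must be finite")


@dataclass
class EventSegment:
    """One classified behavior stretch of a track.

    ``start``/``stop`` are frame indices into the parent track (inclusive);
    ``velocity`` is defined only for processive events spanning more than
    the minimum frame count, otherwise None.
    """

    track_id: str
    start: int
    stop: int
    times: np.ndarray
    positions: np.ndarray
    event_class: str
    velocity: float | None = None

    @property
    def n_frames(self) -> int:
        """Number of frame intervals spanned."""
        return self.stop - self.start


@dataclass
class MotilitySummary:
    """Velocity statistics and class composition over a set of tracks.

    Velocity statistics are over magnitudes, as read off a kymograph:
    direction is a property of the individual event, not of the pooled
    distribution."""

    mean_velocity: float  # nm/s magnitude, NaN when no qualifying event
    sd_velocity: float
    n_velocity: int       # qualifying processive events
    fractions: dict       # class -> fraction of all events
    n_events: int


def max_excursions(positions: np.ndarray) -> tuple[float, float]:
    """(max rise above running minimum, max drop below running maximum).

    The rise is the largest upward excursion anywhere in the series, the
    drop the largest downward one; both computed from running extrema in a
    single pass.
    """
    pos = np.asarray(positions, dtype=float)
    running_min = np.minimum.accumulate(pos)
    running_max = np.maximum.accumulate(pos)
    rise = float(np.max(pos - running_min))
    drop = float(np.max(running_max - pos))
    return rise, drop


def classify_event(
    positions, reversal_nm: float = DEFAULT_REVERSAL_NM
) -> str:
    """Classify one event's positions by the excursion rules.

    Diffusive takes precedence: excursions greater than ``reversal_nm`` in
    both directions.  Processive requires net displacement greater than
    ``reversal_nm`` with the opposing excursion at most ``reversal_nm``
    (the same floor makes the three classes a partition).  Classification
    is invariant to position offset and to sign flips.
    """
    pos = np.asarray(positions, dtype=float)
    if pos.size < 2:
        raise ValueError("event needs >= 2 points")
    rise, drop = max_excursions(pos)
    if rise > reversal_nm and drop > reversal_nm:
        return DIFFUSIVE
    net = pos[-1] - pos[0]
    opposing = drop if net >= 0 else rise
    if abs(net) > reversal_nm and opposing <= reversal_nm:
        return PROCESSIVE
    return NON_MOTILE


def local_speeds(track: Track, window: int = DEFAULT_WINDOW) -> np.ndarray:
    """Magnitude of the least-squares slope in a centered window per frame.

    The window is clipped at the track ends; the construction is symmetric
    under time reversal, so segment boundaries mirror exactly.
    """
    if window < 2:
        raise ValueError("window must span at least 2 frames")
    half = window // 2
    n = track.times.size
    speeds = np.empty(n)
    for i in range(n):
        lo, hi = max(0, i - half), min(n, i + half + 1)
        t, x = track.times[lo:hi], track.positions[lo:hi]
        speeds[i] = abs(np.polyfit(t, x, 1)[0]) if t.size >= 2 else 0.0
    return speeds


def _majority_smooth(states: np.ndarray) -> np.ndarray:
    """Centered 3-point majority filter iterated to a fixed point (ends
    untouched); symmetric under reversal.  At the fixed point no interior
    single-frame state remains (a binary isolated value always flips), so
    every interior run spans at least two frames."""
    current = states.copy()
    for _ in range(states.size):
        out = current.copy()
        for i in range(1, current.size - 1):
            if current[i - 1] == current[i + 1] != current[i]:
                out[i] = current[i - 1]
        if np.array_equal(out, current):
            break
        current = out
    return current


def _absorb_short_runs(runs: list[tuple], min_run_frames: int) -> list[tuple]:
    """Merge runs spanning fewer than ``min_run_frames`` frames into their
    longer adjacent neighbor, shortest run first, until every remaining run
    is long enough (or one run is left)."""
    runs = list(runs)

    def span(run):
        return run[1] - run[0] + 1

    while len(runs) > 1:
        shortest = min(range(len(runs)), key=lambda k: (span(runs[k]), k))
        if span(runs[shortest]) >= min_run_frames:
            break
        left = shortest - 1 if shortest > 0 else None
        right = shortest + 1 if shortest < len(runs) - 1 else None
        if left is None:
            into = right
        elif right is None:
            into = left
        else:
            into = left if span(runs[left]) >= span(runs[right]) else right
        lo = min(runs[shortest][0], runs[into][0])
        hi = max(runs[shortest][1], runs[into][1])
        runs[min(shortest, into)] = (lo, hi)
        runs.pop(max(shortest, into))
    return runs


def segment_events(
    track: Track,
    reversal_nm: float = DEFAULT_REVERSAL_NM,
    window: int = DEFAULT_WINDOW,
    speed_threshold: float = DEFAULT_SPEED_THRESHOLD,
    min_velocity_frames: int = DEFAULT_MIN_VELOCITY_FRAMES,
    min_run_frames: int = DEFAULT_MIN_RUN_FRAMES,
    velocity_mode: str = "slope",
) -> list[EventSegment]:
    """Split a track at apparent behavior changes and classify each piece.

    Frames are labeled motile/static by thresholding the centered-window
    local speed, majority-smoothed, and maximal constant-label runs become
    events; the runs partition the frames exactly (the cut falls between
    frames, which keeps boundaries mirror-exact under time reversal).
    Runs shorter than ``min_run_frames`` frames are absorbed into their
    longer neighbor: a genuine behavior change must persist, otherwise a
    diffusive stretch — whose local speed flickers across the threshold —
    would shatter into fragments.  Each event is classified with
    :func:`classify_event` and, if processive and longer than
    ``min_velocity_frames`` frame intervals, assigned a velocity.
    """
    states = local_speeds(track, window) > speed_threshold
    states = _majority_smooth(states)
    runs = []  # inclusive (start, stop) frame runs of constant state
    start = 0
    for i in range(1, states.size):
        if states[i] != states[i - 1]:
            runs.append((start, i - 1))
            start = i
    runs.append((start, states.size - 1))
    runs = _absorb_short_runs(runs, min_run_frames)

    segments = []
    for start, stop in runs:
        times = track.times[start : stop + 1]
        positions = track.positions[start : stop + 1]
        event_class = classify_event(positions, reversal_nm)
        seg = EventSegment(
            track_id=track.track_id,
            start=start,
            stop=stop,
            times=times,
            positions=positions,
            event_class=event_class,
        )
        seg.velocity = event_velocity(
            seg, min_velocity_frames=min_velocity_frames, mode=velocity_mode
        )
        segments.append(seg)
    return segments


def event_velocity(
    segment: EventSegment,
    min_velocity_frames: int = DEFAULT_MIN_VELOCITY_FRAMES,
    mode: str = "slope",
) -> float | None:
    """Signed velocity (nm/s) of a processive event, or None when excluded.

    Only processive events spanning strictly more than
    ``min_velocity_frames`` frame intervals qualify.  ``mode='slope'``
    fits a least-squares line of position against time; ``mode='endpoint'``
    divides net displacement by duration.
    """
    if segment.event_class != PROCESSIVE:
        return None
    if segment.n_frames <= min_velocity_frames:
        return None
    if mode == "slope":
        return float(np.polyfit(segment.times, segment.positions, 1)[0])
    if mode == "endpoint":
        return float(
            (segment.positions[-1] - segment.positions[0])
            / (segment.times[-1] - segment.times[0])
        )
    raise ValueError(f"unknown velocity mode {mode!r}")


def summarize_motility(
    tracks: list[Track],
    reversal_nm: float = DEFAULT_REVERSAL_NM,
    window: int = DEFAULT_WINDOW,
    speed_threshold: float = DEFAULT_SPEED_THRESHOLD,
    min_velocity_frames: int = DEFAULT_MIN_VELOCITY_FRAMES,
    min_run_frames: int = DEFAULT_MIN_RUN_FRAMES,
    velocity_mode: str = "slope",
) -> MotilitySummary:
    """Segment and classify every track; summarize velocities and classes.

    Mean and SD cover the velocity magnitudes of qualifying processive
    events only; class fractions cover all events.  With no qualifying
    event the mean and SD are NaN and ``n_velocity`` is 0.
    """
    if not tracks:
        raise ValueError("need at least one track")
    events: list[EventSegment] = []
    for track in tracks:
        events.extend(
            segment_events(
                track,
                reversal_nm=reversal_nm,
                window=window,
                speed_threshold=speed_threshold,
                min_velocity_frames=min_velocity_frames,
                min_run_frames=min_run_frames,
                velocity_mode=velocity_mode,
            )
        )
    velocities = [abs(e.velocity) for e in events if e.velocity is not None]
    counts = {cls: 0 for cls in (PROCESSIVE, DIFFUSIVE, NON_MOTILE)}
    for e in events:
        counts[e.event_class] += 1
    n_events = len(events)
    fractions = {cls: counts[cls] / n_events for cls in counts}
    if velocities:
        arr = np.asarray(velocities)
        mean, sd = float(arr.mean()), float(arr.std(ddof=1)) if arr.size > 1 else 0.0
    else:
        mean, sd = float("nan"), float("nan")
    return MotilitySummary(
        mean_velocity=mean,
        sd_velocity=sd,
        n_velocity=len(velocities),
        fractions=fractions,
        n_events=n_events,
    )


def classify_track(
    track: Track, reversal_nm: float = DEFAULT_REVERSAL_NM
) -> str:
    """Whole-track classification (no segmentation), used when each track
    is a single behavior — e.g. against simulation ground truth."""
    return classify_event(track.positions, reversal_nm)
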