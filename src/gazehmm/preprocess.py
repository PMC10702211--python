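"""Preprocessing of raw binocular gaze recordings.

Turns per-sample binocular screen coordinates into clean monocular
streams and dispersion-based fixation sequences:

1. average the two eyes (single valid eye used as-is),
2. linearly interpolate blink gaps up to a maximum duration,
3. screen-time quality control (trials with less than half the trial
   on screen are unreliable),
4. I-DT fixation detection.

A "stream" is a triple of aligned arrays ``(t, x, y)`` with NaN marking
missing coordinates.  The sample interval is ``1000 / rate_hz`` ms.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = [
    "GazeTrial",
    "FixationSequence",
    "EmptyTrialError",
    "average_eyes",
    "interpolate_gaps",
    "total_screen_time",
    "trial_passes_qc",
    "detect_fixations",
    "preprocess_trial",
    "read_gaze_csv",
    "write_fixations_csv",
    "read_fixations_csv",
]

SAMPLE_INTERVAL_MS = 1000.0 / 90.0

GAZE_CSV_COLUMNS = [
    "child_id", "face_type", "t_ms", "lx", "ly", "rx", "ry", "l_valid", "r_valid",
]
FIXATION_CSV_COLUMNS = [
    "child_id", "face_type", "fix_idx", "x", "y", "onset_ms", "duration_ms",
]


class EmptyTrialError(ValueError):
    """Raised when a trial contains no samples at all."""


@dataclass
class GazeTrial:
    """One child x one face: raw binocular samples.

    ``left`` and ``right`` are (n, 2) arrays of screen coordinates with
    NaN rows where the eye was not tracked.  ``t`` is milliseconds from
    trial onset, strictly increasing.
    """

    child_id: str
    face_type: str
    t: np.ndarray
    left: np.ndarray
    right: np.ndarray
    screen: tuple[int, int] = (1920, 1080)
    trial_duration: float = 8000.0

    def __post_init__(self) -> None:
        self.t = np.asarray(self.t, dtype=float)
        self.left = np.asarray(self.left, dtype=float).reshape(-1, 2)
        self.right = np.asarray(self.right, dtype=float).reshape(-1, 2)
        if self.t.size and np.any(np.diff(self.t) <= 0):
            raise ValueError("trial samples must be strictly increasing in t")
        if np.any(self.t < 0):
            raise ValueError("timestamps must be non-negative")


@dataclass
class FixationSequence:
    """Ordered fixations of one child on one face; the HMM observation unit."""

    child_id: str
    face_type: str
    x: np.ndarray = field(default_factory=lambda: np.empty(0))
    y: np.ndarray = field(default_factory=lambda: np.empty(0))
    onset_ms: np.ndarray = field(default_factory=lambda: np.empty(0))
    duration_ms: np.ndarray = field(default_factory=lambda: np.empty(0))

    def __post_init__(self) -> None:
        self.x = np.asarray(self.x, dtype=float)
        self.y = np.asarray(self.y, dtype=float)
        self.onset_ms = np.asarray(self.onset_ms, dtype=float)
        self.duration_ms = np.asarray(self.duration_ms, dtype=float)
        if len(self) and np.any(self.duration_ms <= 0):
            raise ValueError("fixation durations must be positive")
        if len(self) > 1:
            ends = self.onset_ms[:-1] + self.duration_ms[:-1]
            if np.any(self.onset_ms[1:] < ends - 1e-9):
                raise ValueError("fixations must be time-ordered and non-overlapping")

    def __len__(self) -> int:
        return self.x.size

    def positions(self) -> np.ndarray:
        """(n, 2) array of fixation centroids — the HMM observations."""
        return np.column_stack([self.x, self.y])


def average_eyes(trial: GazeTrial) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Average the two eyes into one monocular stream.

    Per timestamp: the mean of both eyes when both are valid, the single
    valid eye otherwise, NaN when neither is tracked.
    """
    if trial.t.size == 0:
        raise EmptyTrialError(f"trial {trial.child_id}/{trial.face_type} has no samples")
    lv = np.all(np.isfinite(trial.left), axis=1)
    rv = np.all(np.isfinite(trial.right), axis=1)
    xy = np.full((trial.t.size, 2), np.nan)
    both = lv & rv
    xy[both] = (trial.left[both] + trial.right[both]) / 2.0
    xy[lv & ~rv] = trial.left[lv & ~rv]
    xy[rv & ~lv] = trial.right[rv & ~lv]
    return trial.t.copy(), xy[:, 0], xy[:, 1]


def _gap_duration(t: np.ndarray, start: int, stop: int) -> float:
    # duration between last valid and next valid timestamp minus one interval
    return (t[stop] - t[start - 1]) - SAMPLE_INTERVAL_MS


def interpolate_gaps(
    t: np.ndarray, x: np.ndarray, y: np.ndarray, max_gap_ms: float = 75.0
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Fill short missing runs (blinks) by linear interpolation.

    A maximal missing run flanked by valid samples is interpolated when
    its duration is at most ``max_gap_ms``; longer runs and runs touching
    the stream edges stay missing.  Valid samples are never modified.
    """
    x = np.asarray(x, dtype=float).copy()
    y = np.asarray(y, dtype=float).copy()
    missing = ~(np.isfinite(x) & np.isfinite(y))
    if not missing.any() or missing.all():
        return t, x, y
    n = len(t)
    i = 0
    while i < n:
        if not missing[i]:
            i += 1
            continue
        j = i
        while j < n and missing[j]:
            j += 1
        if i > 0 and j < n and _gap_duration(t, i, j) <= max_gap_ms:
            frac = (t[i:j] - t[i - 1]) / (t[j] - t[i - 1])
            x[i:j] = x[i - 1] + frac * (x[j] - x[i - 1])
            y[i:j] = y[i - 1] + frac * (y[j] - y[i - 1])
        i = j
    return t, x, y


def total_screen_time(
    x: np.ndarray, y: np.ndarray, screen: tuple[int, int] = (1920, 1080)
) -> float:
    """Total on-screen gaze time in ms: one sample interval per valid
    sample whose position lies within the screen bounds."""
    w, h = screen
    valid = np.isfinite(x) & np.isfinite(y)
    on = valid & (x >= 0) & (x < w) & (y >= 0) & (y < h)
    return float(on.sum()) * SAMPLE_INTERVAL_MS


def trial_passes_qc(
    x: np.ndarray, y: np.ndarray, screen: tuple[int, int] = (1920, 1080),
    min_screen_time_ms: float = 4000.0,
) -> bool:
    """True iff total screen time (post-interpolation) is >= the threshold.

    A trial with more than half its gaze data missing is unreliable;
    exactly the threshold is retained ("less than" excluded).
    """
    return total_screen_time(x, y, screen) >= min_screen_time_ms


def detect_fixations(
    t: np.ndarray,
    x: np.ndarray,
    y: np.ndarray,
    dispersion_px: float = 50.0,
    min_duration_ms: float = 100.0,
    child_id: str = "",
    face_type: str = "",
) -> FixationSequence:
    """Dispersion-threshold (I-DT) fixation detection.

    Maximal windows whose dispersion ``(max x - min x) + (max y - min y)``
    stays within ``dispersion_px`` and that last at least
    ``min_duration_ms`` become fixations at the window centroid.
    Missing samples break windows.
    """
    valid = np.isfinite(x) & np.isfinite(y)
    fx, fy, fon, fdur = [], [], [], []
    n = len(t)
    i = 0
    while i < n:
        if not valid[i]:
            i += 1
            continue
        # maximal run of valid samples starting at i
        run_end = i
        while run_end < n and valid[run_end]:
            run_end += 1
        j = i
        while j < run_end:
            k = j + 1
            xmin = xmax = x[j]
            ymin = ymax = y[j]
            while k < run_end:
                xmin2, xmax2 = min(xmin, x[k]), max(xmax, x[k])
                ymin2, ymax2 = min(ymin, y[k]), max(ymax, y[k])
                if (xmax2 - xmin2) + (ymax2 - ymin2) > dispersion_px:
                    break
                xmin, xmax, ymin, ymax = xmin2, xmax2, ymin2, ymax2
                k += 1
            dur = (k - j) * SAMPLE_INTERVAL_MS
            if dur >= min_duration_ms:
                fx.append(float(np.mean(x[j:k])))
                fy.append(float(np.mean(y[j:k])))
                fon.append(float(t[j]))
                fdur.append(dur)
                j = k
            else:
                j += 1
        i = run_end
    return FixationSequence(child_id, face_type, fx, fy, fon, fdur)


def preprocess_trial(
    trial: GazeTrial,
    max_gap_ms: float = 75.0,
    min_screen_time_ms: float = 4000.0,
    dispersion_px: float = 50.0,
    min_duration_ms: float = 100.0,
) -> FixationSequence | None:
    """Full preprocessing of one trial; None if the trial fails QC."""
    t, x, y = average_eyes(trial)
    t, x, y = interpolate_gaps(t, x, y, max_gap_ms=max_gap_ms)
    if not trial_passes_qc(x, y, trial.screen, min_screen_time_ms):
        return None
    return detect_fixations(
        t, x, y, dispersion_px=dispersion_px, min_duration_ms=min_duration_ms,
        child_id=trial.child_id, face_type=trial.face_type,
    )


# ---------------------------------------------------------------------------
# CSV dialects

def read_gaze_csv(path) -> list[GazeTrial]:
    """Read the cohort gaze CSV into one GazeTrial per child x face.

    Columns: child_id,face_type,t_ms,lx,ly,rx,ry,l_valid,r_valid.
    Invalid eyes (validity flag 0 or empty coordinates) become NaN.
    """
    df = pd.read_csv(path)
    missing = set(GAZE_CSV_COLUMNS) - set(df.columns)
    if missing:
        raise ValueError(f"gaze CSV missing columns: {sorted(missing)}")
    trials = []
    for (cid, face), g in df.groupby(["child_id", "face_type"], sort=True):
        g = g.sort_values("t_ms")
        left = g[["lx", "ly"]].to_numpy(dtype=float)
        right = g[["rx", "ry"]].to_numpy(dtype=float)
        left[g["l_valid"].to_numpy(dtype=float) == 0] = np.nan
        right[g["r_valid"].to_numpy(dtype=float) == 0] = np.nan
        trials.append(GazeTrial(str(cid), str(face), g["t_ms"].to_numpy(dtype=float), left, right))
    return trials


def write_fixations_csv(path, sequences: list[FixationSequence]) -> None:
    rows = []
    for seq in sequences:
        for i in range(len(seq)):
            rows.append((seq.child_id, seq.face_type, i,
                         seq.x[i], seq.y[i], seq.onset_ms[i], seq.duration_ms[i]))
    pd.DataFrame(rows, columns=FIXATION_CSV_COLUMNS).to_csv(path, index=False)


def read_fixations_csv(path) -> list[FixationSequence]:
    df = pd.read_csv(path)
    missing = set(FIXATION_CSV_COLUMNS) - set(df.columns)
    if missing:
        raise ValueError(f"fixation CSV missing columns: {sorted(missing)}")
    out = []
    for (cid, face), g in df.groupby(["child_id", "face_type"], sort=True):
        g = g.sort_values("fix_idx")
        out.append(FixationSequence(str(cid), str(face),
                                    g["x"].to_numpy(), g["y"].to_numpy(),
                                    g["onset_ms"].to_numpy(), g["duration_ms"].to_numpy()))
    return out
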