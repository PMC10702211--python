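"""Synthetic gaze-cohort generator.

Ground-truth cohorts for exercising the whole pipeline without any
recorded data: children are drawn from one of two archetype gaze HMMs —

* *holistic*: two broad ROIs, one on the upper face center and one on
  the lower facial contour, with sticky self-transitions and sequences
  that tend to start at the contour;
* *analytic*: two tight ROIs, an eye band and the face center/mouth,
  with a high switching probability;

fixation sequences sampled from the archetype are expanded to 90 Hz
binocular samples with per-sample jitter, a horizontal binocular
disparity, and Poisson blink gaps.  A synthetic cognitive score is
linearly (negatively, by default) related to each child's true H-A
value.  Ground truth is written alongside the data and is never read by
the analysis stages.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .geometry import FaceGeometry, DEFAULT_GEOMETRY
from .metrics import ha_scale
from .preprocess import GazeTrial, FixationSequence, SAMPLE_INTERVAL_MS, GAZE_CSV_COLUMNS
from .vbhmm import GaussianROI, GazeHMM, log_likelihood, sample_sequence

__all__ = [
    "ArchetypeSpec",
    "CohortSpec",
    "make_archetypes",
    "simulate_child",
    "simulate_scores",
    "simulate_cohort",
]

HOLISTIC = "holistic"
ANALYTIC = "analytic"


@dataclass
class ArchetypeSpec:
    """A named generator pattern: an HMM plus a fixation-duration law
    (truncated normal: mean ms, sd ms, lower floor ms)."""

    name: str
    hmm: GazeHMM
    fixation_duration_law: tuple[float, float, float] = (300.0, 100.0, 100.0)


@dataclass
class CohortSpec:
    """Study conditions for a simulated cohort.

    Defaults emulate the acquisition geometry and timing of the study
    design this package reproduces: 8000 ms trials at 90 Hz on a
    centered 900x940 px face shown on a 1920x1080 px screen, three face
    types per child, and a cohort in which holistic viewers are the
    majority.  ``cognitive_effect`` is (baseline, slope, noise_sd)
    linking the true H-A value to a synthetic developmental score.
    """

    n_children: int = 60
    holistic_fraction: float = 0.6
    faces: tuple[str, ...] = ("female", "child", "male")
    trial_ms: float = 8000.0
    rate_hz: float = 90.0
    jitter_sd: float = 6.0
    binocular_offset: float = 8.0
    blink_rate: float = 0.2           # blinks per second
    blink_dur_log_mean: float = math.log(60.0)
    blink_dur_log_sd: float = 0.4
    cognitive_effect: tuple[float, float, float] = (95.0, -40.0, 8.0)
    rng_seed: int | None = None
    geometry: FaceGeometry = field(default_factory=FaceGeometry)

    def __post_init__(self) -> None:
        if not 0.0 <= self.holistic_fraction <= 1.0:
            raise ValueError("holistic_fraction must be in [0, 1]")
        if self.rate_hz <= 0 or self.trial_ms <= 0:
            raise ValueError("rates and durations must be positive")


def make_archetypes(geometry: FaceGeometry = DEFAULT_GEOMETRY) -> tuple[ArchetypeSpec, ArchetypeSpec]:
    """Build the (holistic, analytic) archetype generators for a stimulus.

    ROI placement is parameterized by the stimulus rectangle: the
    holistic archetype spreads two broad Gaussians over the upper face
    center and the lower facial contour; the analytic archetype uses a
    tight eye-band ROI and a tight face-center ROI with frequent
    switching.  By construction the holistic archetype has the larger
    total covariance trace and the analytic one the larger off-diagonal
    transition mass.
    """
    x0, y0, x1, y1 = geometry.stimulus_rect
    cx = (x0 + x1) / 2.0
    h = y1 - y0

    def at(fy: float) -> float:
        return y0 + fy * h

    holistic = GazeHMM(
        priors=np.array([0.7, 0.3]),
        transitions=np.array([[0.80, 0.20],
                              [0.15, 0.85]]),
        emissions=[
            GaussianROI([cx, at(0.766)], np.diag([240.0 ** 2, 60.0 ** 2])),   # contour band
            GaussianROI([cx, at(0.404)], np.diag([200.0 ** 2, 80.0 ** 2])),   # face center
        ],
    )
    analytic = GazeHMM(
        priors=np.array([0.6, 0.4]),
        transitions=np.array([[0.30, 0.70],
                              [0.65, 0.35]]),
        emissions=[
            GaussianROI([cx, at(0.351)], np.diag([150.0 ** 2, 40.0 ** 2])),   # eye band
            GaussianROI([cx, at(0.649)], np.diag([60.0 ** 2, 60.0 ** 2])),    # center/mouth
        ],
    )
    return (ArchetypeSpec(HOLISTIC, holistic), ArchetypeSpec(ANALYTIC, analytic))


def _sample_trial_fixations(arch: ArchetypeSpec, cohort: CohortSpec,
                            rng: np.random.Generator,
                            child_id: str, face: str) -> FixationSequence:
    # draw generously, then cut to the trial window
    mean_dur = arch.fixation_duration_law[0]
    n_guess = int(cohort.trial_ms / mean_dur * 2) + 5
    seq = sample_sequence(arch.hmm, n_guess, rng,
                          duration_law=arch.fixation_duration_law,
                          child_id=child_id, face_type=face)
    keep = seq.onset_ms < cohort.trial_ms
    x, y = seq.x[keep], seq.y[keep]
    on, dur = seq.onset_ms[keep], seq.duration_ms[keep]
    dur = np.minimum(dur, cohort.trial_ms - on)  # truncate last fixation
    return FixationSequence(child_id, face, x, y, on, dur)


def _blink_mask(n: int, cohort: CohortSpec, rng: np.random.Generator) -> np.ndarray:
    """Boolean mask of samples hidden by blinks (Poisson arrivals,
    lognormal durations)."""
    mask = np.zeros(n, dtype=bool)
    t_total = cohort.trial_ms / 1000.0
    n_blinks = rng.poisson(cohort.blink_rate * t_total)
    dt = 1000.0 / cohort.rate_hz
    for _ in range(n_blinks):
        start = rng.uniform(0.0, cohort.trial_ms)
        dur = rng.lognormal(cohort.blink_dur_log_mean, cohort.blink_dur_log_sd)
        i0 = int(np.ceil(start / dt))
        i1 = int(np.floor((start + dur) / dt)) + 1
        mask[max(i0, 0):min(i1, n)] = True
    return mask


def simulate_child(
    archetype: ArchetypeSpec,
    cohort: CohortSpec,
    rng: np.random.Generator,
    child_id: str = "c000",
) -> tuple[dict[str, GazeTrial], dict[str, FixationSequence]]:
    """Simulate one child: a GazeTrial per face plus the ground-truth
    fixation sequences that generated them."""
    trials: dict[str, GazeTrial] = {}
    truth: dict[str, FixationSequence] = {}
    dt = 1000.0 / cohort.rate_hz
    n = int(round(cohort.trial_ms / dt))
    t = np.arange(n) * dt
    half = cohort.binocular_offset / 2.0
    for face in cohort.faces:
        fix = _sample_trial_fixations(archetype, cohort, rng, child_id, face)
        truth[face] = fix
        # map each sample to its covering fixation
        idx = np.searchsorted(fix.onset_ms, t, side="right") - 1
        idx = np.clip(idx, 0, len(fix) - 1)
        base = np.column_stack([fix.x[idx], fix.y[idx]])
        base = base + rng.normal(0.0, cohort.jitter_sd, size=base.shape)
        noise_l = rng.normal(0.0, 1.0, size=base.shape)
        noise_r = rng.normal(0.0, 1.0, size=base.shape)
        left = base + noise_l
        right = base + noise_r
        left[:, 0] -= half
        right[:, 0] += half
        blink = _blink_mask(n, cohort, rng)
        left[blink] = np.nan
        right[blink] = np.nan
        trials[face] = GazeTrial(child_id, face, t, left, right,
                                 screen=cohort.geometry.screen,
                                 trial_duration=cohort.trial_ms)
    return trials, truth


def true_ha_value(truth: dict[str, FixationSequence],
                  holistic: ArchetypeSpec, analytic: ArchetypeSpec) -> float:
    """Mean (over faces) H-A value of the ground-truth fixation
    sequences under the two archetype HMMs."""
    vals = []
    for fix in truth.values():
        h = log_likelihood(holistic.hmm, fix)
        a = log_likelihood(analytic.hmm, fix)
        vals.append(ha_scale(h, a))
    return float(np.mean(vals))


def simulate_scores(truth_table: pd.DataFrame, cohort: CohortSpec,
                    rng: np.random.Generator) -> pd.DataFrame:
    """Synthetic cognitive score per child:
    baseline + slope * true H-A + Gaussian noise."""
    baseline, slope, noise_sd = cohort.cognitive_effect
    scores = (baseline
              + slope * truth_table["true_ha"].to_numpy()
              + rng.normal(0.0, noise_sd, size=len(truth_table)))
    return pd.DataFrame({"child_id": truth_table["child_id"], "score": scores})


def simulate_cohort(
    cohort: CohortSpec,
    rng: np.random.Generator | None = None,
) -> tuple[pd.DataFrame, pd.DataFrame, pd.DataFrame]:
    """Simulate a full cohort.

    Returns (gaze, truth, scores):
    * gaze — the raw binocular sample table in the gaze CSV dialect;
    * truth — child_id, archetype, true mean H-A, per-face fixation counts;
    * scores — child_id, synthetic cognitive score.
    """
    if rng is None:
        rng = np.random.default_rng(cohort.rng_seed)
    hol, ana = make_archetypes(cohort.geometry)
    n_hol = int(round(cohort.n_children * cohort.holistic_fraction))
    labels = [HOLISTIC] * n_hol + [ANALYTIC] * (cohort.n_children - n_hol)
    gaze_rows = []
    truth_rows = []
    for i, label in enumerate(labels):
        cid = f"c{i:03d}"
        arch = hol if label == HOLISTIC else ana
        trials, truth = simulate_child(arch, cohort, rng, cid)
        for face, tr in trials.items():
            lv = np.all(np.isfinite(tr.left), axis=1).astype(int)
            rv = np.all(np.isfinite(tr.right), axis=1).astype(int)
            gaze_rows.append(pd.DataFrame({
                "child_id": cid, "face_type": face, "t_ms": tr.t,
                "lx": tr.left[:, 0], "ly": tr.left[:, 1],
                "rx": tr.right[:, 0], "ry": tr.right[:, 1],
                "l_valid": lv, "r_valid": rv,
            }))
        row = {"child_id": cid, "archetype": label,
               "true_ha": true_ha_value(truth, hol, ana)}
        for face in cohort.faces:
            row[f"n_fix_{face}"] = len(truth[face])
        truth_rows.append(row)
    gaze = (pd.concat(gaze_rows, ignore_index=True)[GAZE_CSV_COLUMNS]
            if gaze_rows else pd.DataFrame(columns=GAZE_CSV_COLUMNS))
    truth_df = pd.DataFrame(truth_rows)
    scores = (simulate_scores(truth_df, cohort, rng)
              if len(truth_df) else pd.DataFrame(columns=["child_id", "score"]))
    return gaze, truth_df, scores
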