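"""End-to-end orchestration: preprocess -> fit -> cluster -> H-A table.

Library-level entry points shared by the command-line interface, the
examples and the acceptance checks.  Each stage consumes and produces
plain data structures (fixation sequences, per-child HMM dictionaries,
GroupModels, pandas tables), so stages can be run, cached and tested
independently.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .cluster import ClusterConfig, GroupModel, cluster_hmms, label_groups, HOLISTIC, ANALYTIC
from .geometry import FaceGeometry
from .metrics import HAScaleRecord, ha_record, ha_table
from .preprocess import FixationSequence, GazeTrial, preprocess_trial
from .vbhmm import GazeHMM, VBConfig, select_model

__all__ = [
    "preprocess_cohort",
    "fit_cohort",
    "cluster_cohort",
    "child_assignments",
    "compute_ha_table",
]


def preprocess_cohort(
    trials: list[GazeTrial],
    max_gap_ms: float = 75.0,
    min_screen_time_ms: float = 4000.0,
    dispersion_px: float = 50.0,
    min_duration_ms: float = 100.0,
) -> tuple[list[FixationSequence], list[tuple[str, str]]]:
    """Preprocess every trial; returns (fixation sequences, excluded
    (child_id, face_type) pairs that failed QC)."""
    kept, excluded = [], []
    for tr in trials:
        seq = preprocess_trial(tr, max_gap_ms, min_screen_time_ms,
                               dispersion_px, min_duration_ms)
        if seq is None or len(seq) == 0:
            excluded.append((tr.child_id, tr.face_type))
        else:
            kept.append(seq)
    return kept, excluded


def fit_cohort(
    sequences: list[FixationSequence],
    config: VBConfig | None = None,
    rng: np.random.Generator | None = None,
) -> dict[tuple[str, str], GazeHMM]:
    """Fit one VB-HMM per child x face (state count selected per model)."""
    cfg = config or VBConfig()
    if rng is None:
        rng = np.random.default_rng(cfg.rng_seed)
    by_key: dict[tuple[str, str], list[FixationSequence]] = {}
    for seq in sequences:
        by_key.setdefault((seq.child_id, seq.face_type), []).append(seq)
    models = {}
    for key in sorted(by_key):
        models[key] = select_model(by_key[key], cfg, rng)
    return models


def cluster_cohort(
    models: dict[tuple[str, str], GazeHMM],
    geometry: FaceGeometry,
    config: ClusterConfig | None = None,
    rng: np.random.Generator | None = None,
) -> dict[str, GroupModel]:
    """Cluster per-child models separately for each face type and label
    the resulting groups holistic/analytic."""
    cfg = config or ClusterConfig()
    if rng is None:
        rng = np.random.default_rng(cfg.rng_seed)
    faces = sorted({face for _, face in models})
    out = {}
    for face in faces:
        face_models = {cid: m for (cid, f), m in models.items() if f == face}
        gm = cluster_hmms(face_models, K_groups=2, config=cfg, rng=rng)
        out[face] = label_groups(gm, geometry)
    return out


def child_assignments(face_groups: dict[str, GroupModel]) -> dict[str, str]:
    """Per-child pattern label by majority vote over the face types."""
    votes: dict[str, list[str]] = {}
    for gm in face_groups.values():
        for cid in gm.assignments:
            votes.setdefault(cid, []).append(gm.label_of(cid))
    out = {}
    for cid, labs in votes.items():
        labs = [l for l in labs if l in (HOLISTIC, ANALYTIC)]
        if not labs:
            out[cid] = "unlabeled"
            continue
        n_h = labs.count(HOLISTIC)
        n_a = labs.count(ANALYTIC)
        if n_h == n_a:
            out[cid] = labs[0]  # tie: first labeled face decides
        else:
            out[cid] = HOLISTIC if n_h > n_a else ANALYTIC
    return out


def compute_ha_table(
    sequences: list[FixationSequence],
    face_groups: dict[str, GroupModel],
) -> pd.DataFrame:
    """Per-child, per-face H-A table under each face's representatives.

    Requires every face's group model to carry holistic/analytic labels.
    """
    records: list[HAScaleRecord] = []
    assigns = child_assignments(face_groups)
    for seq in sequences:
        gm = face_groups.get(seq.face_type)
        if gm is None:
            continue
        labels = {v: k for k, v in gm.group_labels.items()}
        if HOLISTIC not in labels or ANALYTIC not in labels:
            raise ValueError(f"groups for face {seq.face_type!r} are unlabeled")
        hol = gm.representatives[labels[HOLISTIC]]
        ana = gm.representatives[labels[ANALYTIC]]
        records.append(ha_record(seq.child_id, seq.face_type, seq, hol, ana))
    return ha_table(records, assigns)
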