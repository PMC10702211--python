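"""Grouping per-child gaze HMMs and deriving representative HMMs.

The discovery step of the analysis: per-child HMMs are clustered into a
small number of groups (default two) and each group is summarized by a
representative HMM.  The objective is hierarchical-EM style: maximize
the expected log-likelihood, under each input HMM's own distribution, of
its group's representative.  The expectation is approximated by virtual
samples — each input HMM generates ``n_virtual`` sequences of length
``virtual_length`` — and the algorithm alternates (a) reassigning each
input to the representative that gives its virtual samples the highest
mean log-likelihood and (b) refitting each representative on its
members' virtual samples, until assignments stabilize.

Groups are then labeled *holistic* (broad ROIs, little eye-region mass)
or *analytic* (tight ROIs concentrated on the eye region) by a
configurable heuristic, since the field assigns these labels by
inspection of the representative models.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.stats import multivariate_normal

from .geometry import FaceGeometry, DEFAULT_GEOMETRY
from .vbhmm import GazeHMM, VBConfig, fit_vbhmm, sample_sequence, batch_log_likelihood

__all__ = ["GroupModel", "ClusterConfig", "cluster_hmms", "label_groups"]

HOLISTIC = "holistic"
ANALYTIC = "analytic"
UNLABELED = "unlabeled"


@dataclass
class ClusterConfig:
    n_virtual: int = 100          # virtual sequences drawn per input HMM
    virtual_length: int = 20      # fixations per virtual sequence
    n_restarts: int = 2
    max_rounds: int = 30
    rep_n_states: int = 3         # state count of refit representatives (VB may prune)
    rep_restarts: int = 2
    rng_seed: int | None = None

    def vb_config(self) -> VBConfig:
        # k-means init + capped iterations: refits on large virtual-sample
        # pools converge quickly and run inside the alternation loop
        return VBConfig(n_restarts=self.rep_restarts, max_iterations=60,
                        init="kmeans", rng_seed=None)


@dataclass
class GroupModel:
    """Cluster assignments plus one representative HMM per group."""

    representatives: list[GazeHMM]
    assignments: dict[str, int]
    group_labels: dict[int, str] = field(default_factory=dict)
    objective: float = float("nan")
    objective_trace: list[float] = field(default_factory=list)

    def __post_init__(self) -> None:
        K = len(self.representatives)
        for g in self.assignments.values():
            if not (0 <= g < K):
                raise ValueError(f"assignment to nonexistent group {g}")
        if not self.group_labels:
            self.group_labels = {g: UNLABELED for g in range(K)}

    def label_of(self, child_id: str) -> str:
        return self.group_labels.get(self.assignments[child_id], UNLABELED)

    def to_dict(self) -> dict:
        return {
            "representatives": [m.to_dict() for m in self.representatives],
            "assignments": self.assignments,
            "labels": {str(k): v for k, v in self.group_labels.items()},
            "objective": self.objective,
        }

    def save(self, path) -> None:
        with open(path, "w") as fh:
            json.dump(self.to_dict(), fh, indent=1)

    @classmethod
    def load(cls, path) -> "GroupModel":
        with open(path) as fh:
            d = json.load(fh)
        return cls(
            representatives=[GazeHMM.from_dict(m) for m in d["representatives"]],
            assignments={k: int(v) for k, v in d["assignments"].items()},
            group_labels={int(k): v for k, v in d["labels"].items()},
            objective=float(d.get("objective", float("nan"))),
        )

    def assignments_frame(self) -> pd.DataFrame:
        rows = [(cid, g, self.group_labels.get(g, UNLABELED))
                for cid, g in sorted(self.assignments.items())]
        return pd.DataFrame(rows, columns=["child_id", "group", "label"])


def _mean_loglik(rep: GazeHMM, samples: np.ndarray) -> float:
    return float(batch_log_likelihood(rep, samples).mean())


def _refit(samples: np.ndarray, cfg: ClusterConfig, rng: np.random.Generator) -> GazeHMM:
    seqs = list(samples)
    vb = cfg.vb_config()
    K = min(cfg.rep_n_states, sum(len(s) for s in seqs))
    model, _ = fit_vbhmm(seqs, K, vb, rng)
    return model


def cluster_hmms(
    models: dict[str, GazeHMM] | list[GazeHMM],
    K_groups: int = 2,
    config: ClusterConfig | None = None,
    rng: np.random.Generator | None = None,
) -> GroupModel:
    """Cluster HMMs into ``K_groups`` groups with one representative each.

    ``models`` maps child id to fitted HMM (a list gets integer-string
    ids).  Multiple seeded restarts are run and the solution with the
    best objective (total mean virtual-sample log-likelihood under the
    assigned representatives) is kept.
    """
    cfg = config or ClusterConfig()
    if isinstance(models, list):
        models = {str(i): m for i, m in enumerate(models)}
    ids = sorted(models)
    n = len(ids)
    if n < K_groups:
        raise ValueError(f"{n} models cannot form {K_groups} groups")
    if rng is None:
        rng = np.random.default_rng(cfg.rng_seed)

    # fixed virtual samples: (n, N_v, L_v, 2)
    virtual = np.stack([
        np.stack([
            sample_sequence(models[cid], cfg.virtual_length, rng).positions()
            for _ in range(cfg.n_virtual)
        ]) for cid in ids
    ])

    best: GroupModel | None = None
    for restart in range(cfg.n_restarts):
        if restart == 0:
            init = _linkage_init([models[cid] for cid in ids], virtual, K_groups)
        else:
            init = rng.permutation(np.arange(n) % K_groups)
        gm = _cluster_once(ids, virtual, K_groups, cfg, rng, init)
        if best is None or gm.objective > best.objective:
            best = gm
    return best


def _linkage_init(models: list[GazeHMM], virtual: np.ndarray,
                  K_groups: int) -> np.ndarray:
    """Initial assignment from symmetrized expected log-likelihood
    distances between the input HMMs (average-linkage clustering).

    A random split lets freshly refit representatives memorize their own
    members and stall the alternation at the first round; distances
    under the *input* models avoid that trap.
    """
    from scipy.cluster.hierarchy import fcluster, linkage
    from scipy.spatial.distance import squareform

    n, n_v, L, _ = virtual.shape
    flat = virtual.reshape(-1, L, 2)
    ll = np.stack([
        batch_log_likelihood(m, flat).reshape(n, n_v).mean(axis=1)
        for m in models
    ], axis=1)  # ll[i, j] = model i's virtual samples under model j
    self_ll = np.diag(ll)
    D = (self_ll[:, None] - ll) + (self_ll[None, :] - ll.T)
    D = np.maximum(0.5 * (D + D.T), 0.0)
    np.fill_diagonal(D, 0.0)
    Z = linkage(squareform(D, checks=False), method="average")
    labels = fcluster(Z, t=K_groups, criterion="maxclust") - 1
    return labels.astype(int)


def _objective(ll: np.ndarray, assign: np.ndarray) -> float:
    return float(ll[np.arange(len(assign)), assign].sum())


def _cluster_once(ids, virtual, K_groups, cfg, rng, init_assign=None) -> GroupModel:
    n = len(ids)
    if init_assign is None:
        init_assign = rng.permutation(np.arange(n) % K_groups)
    assign = np.asarray(init_assign, dtype=int)
    for g in range(K_groups):
        if not np.any(assign == g):
            assign[rng.integers(n)] = g
    reps = [_refit(virtual[assign == g].reshape(-1, cfg.virtual_length, 2), cfg, rng)
            for g in range(K_groups)]
    trace: list[float] = []
    prev_obj = -np.inf
    for _ in range(cfg.max_rounds):
        # (a) assignment step
        ll = np.stack([
            batch_log_likelihood(rep, virtual.reshape(-1, cfg.virtual_length, 2))
            .reshape(n, cfg.n_virtual).mean(axis=1)
            for rep in reps
        ], axis=1)  # (n, K_groups)
        new_assign = ll.argmax(axis=1)
        for g in range(K_groups):  # re-seed empty groups from the worst-fit member
            if not np.any(new_assign == g):
                worst = int(ll.max(axis=1).argmin())
                new_assign[worst] = g
        obj = _objective(ll, new_assign)
        trace.append(obj)
        converged = np.array_equal(new_assign, assign)
        assign = new_assign
        if converged:
            break
        # (b) refit step — accept only if the objective does not decrease
        new_reps = [
            _refit(virtual[assign == g].reshape(-1, cfg.virtual_length, 2), cfg, rng)
            for g in range(K_groups)
        ]
        new_ll = np.stack([
            batch_log_likelihood(rep, virtual.reshape(-1, cfg.virtual_length, 2))
            .reshape(n, cfg.n_virtual).mean(axis=1)
            for rep in new_reps
        ], axis=1)
        if _objective(new_ll, assign) >= obj:
            reps = new_reps
        else:
            break
        prev_obj = obj
    return GroupModel(
        representatives=reps,
        assignments={cid: int(g) for cid, g in zip(ids, assign)},
        objective=trace[-1] if trace else float("nan"),
        objective_trace=trace,
    )


# ---------------------------------------------------------------------------
# holistic / analytic labeling

def _roi_spread(model: GazeHMM) -> float:
    return float(sum(np.trace(r.cov) for r in model.emissions))


def _eye_region_mass(model: GazeHMM, geometry: FaceGeometry) -> float:
    """Stationary probability mass of the model inside the eye-region box."""
    x0, y0, x1, y1 = geometry.eye_box
    pi = model.stationary_distribution()
    mass = 0.0
    for p, roi in zip(pi, model.emissions):
        mvn = multivariate_normal(roi.mean, roi.cov)
        rect = (mvn.cdf([x1, y1]) - mvn.cdf([x0, y1])
                - mvn.cdf([x1, y0]) + mvn.cdf([x0, y0]))
        mass += p * max(rect, 0.0)
    return float(mass)


def label_groups(
    group_model: GroupModel,
    geometry: FaceGeometry = DEFAULT_GEOMETRY,
    override: dict[int, str] | None = None,
) -> GroupModel:
    """Attach holistic/analytic labels to a two-group model.

    Heuristic: the group whose representative has the larger total ROI
    spread (sum of covariance traces) is the holistic candidate; the one
    with more stationary mass inside the eye-region box is the analytic
    candidate.  When both point to the same group the evidence is
    contradictory and the groups stay unlabeled (with a warning).  An
    explicit ``override`` mapping wins over the heuristic.
    """
    if override:
        labels = dict(group_model.group_labels)
        labels.update(override)
        group_model.group_labels = labels
        return group_model
    if len(group_model.representatives) != 2:
        raise ValueError("labeling requires exactly 2 groups")
    spread = [_roi_spread(m) for m in group_model.representatives]
    eye = [_eye_region_mass(m, geometry) for m in group_model.representatives]
    hol = int(np.argmax(spread))
    ana = int(np.argmax(eye))
    if hol == ana:
        warnings.warn(
            "holistic/analytic heuristics disagree; groups left unlabeled",
            stacklevel=2,
        )
        group_model.group_labels = {0: UNLABELED, 1: UNLABELED}
    else:
        group_model.group_labels = {hol: HOLISTIC, ana: ANALYTIC}
    return group_model
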