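"""Variational-Bayesian hidden Markov models with 2-D Gaussian emissions.

Each child's fixation sequence is modelled by an HMM whose hidden states
are person-specific regions of interest (ROIs): 2-D Gaussians over
fixation position.  Parameters — start probabilities, the transition
matrix and the Gaussian ROIs — are estimated by variational-Bayesian EM
with conjugate priors (Dirichlet on the start vector and on each
transition row, Normal–Wishart on each emission).  The variational lower
bound penalizes complexity, so the number of ROIs is selected by fitting
over a range of state counts and keeping the model with the highest
bound.

Observations are fixation (x, y) positions only; durations are not part
of the emission model.  All likelihoods are natural-log.
"""

from __future__ import annotations

import hashlib
import json
import math
from dataclasses import dataclass, field, asdict

import numpy as np
from scipy.special import digamma, gammaln, multigammaln
from scipy.stats import truncnorm

from .preprocess import FixationSequence

__all__ = [
    "GaussianROI",
    "GazeHMM",
    "VBConfig",
    "DegenerateDataError",
    "fit_vbhmm",
    "select_model",
    "log_likelihood",
    "sample_sequence",
]

_D = 2  # observation dimension
_LOG2PI = math.log(2.0 * math.pi)


def _lse(a: np.ndarray, axis: int) -> np.ndarray:
    """Fast log-sum-exp along an axis (tolerates -inf slices)."""
    m = np.max(a, axis=axis, keepdims=True)
    safe = np.where(np.isfinite(m), m, 0.0)
    with np.errstate(divide="ignore"):
        out = np.log(np.sum(np.exp(a - safe), axis=axis)) + safe.squeeze(axis)
    return out


class DegenerateDataError(ValueError):
    """Raised when the data cannot support the requested model."""


@dataclass
class GaussianROI:
    """One region of interest: a 2-D Gaussian over fixation position."""

    mean: np.ndarray
    cov: np.ndarray

    def __post_init__(self) -> None:
        self.mean = np.asarray(self.mean, dtype=float).reshape(_D)
        self.cov = np.asarray(self.cov, dtype=float).reshape(_D, _D)
        if not np.allclose(self.cov, self.cov.T, atol=1e-8):
            raise ValueError("ROI covariance must be symmetric")
        if np.any(np.linalg.eigvalsh(self.cov) <= 0):
            raise ValueError("ROI covariance must be positive-definite")


@dataclass
class GazeHMM:
    """A fitted gaze HMM: start probabilities, transitions, Gaussian ROIs."""

    priors: np.ndarray
    transitions: np.ndarray
    emissions: list[GaussianROI]
    train_loglik: float = float("nan")

    def __post_init__(self) -> None:
        self.priors = np.asarray(self.priors, dtype=float)
        self.transitions = np.asarray(self.transitions, dtype=float)
        K = self.n_states
        if not (1 <= K <= 6):
            raise ValueError(f"state count {K} outside 1..6")
        if self.priors.shape != (K,) or self.transitions.shape != (K, K):
            raise ValueError("inconsistent parameter shapes")
        if np.any(self.priors < 0) or np.any(self.transitions < 0):
            raise ValueError("probabilities must be non-negative")
        if abs(self.priors.sum() - 1.0) > 1e-9:
            raise ValueError("priors must sum to 1")
        if np.any(np.abs(self.transitions.sum(axis=1) - 1.0) > 1e-9):
            raise ValueError("transition rows must sum to 1")

    @property
    def n_states(self) -> int:
        return len(self.emissions)

    # -- serialization ----------------------------------------------------
    def to_dict(self, config_digest: str | None = None) -> dict:
        d = {
            "n_states": self.n_states,
            "priors": self.priors.tolist(),
            "transitions": self.transitions.tolist(),
            "emissions": [
                {"mean": r.mean.tolist(), "cov": r.cov.tolist()} for r in self.emissions
            ],
            "train_loglik": self.train_loglik,
        }
        if config_digest is not None:
            d["config_digest"] = config_digest
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "GazeHMM":
        return cls(
            priors=np.array(d["priors"]),
            transitions=np.array(d["transitions"]),
            emissions=[GaussianROI(np.array(e["mean"]), np.array(e["cov"]))
                       for e in d["emissions"]],
            train_loglik=float(d.get("train_loglik", float("nan"))),
        )

    def save(self, path, config_digest: str | None = None) -> None:
        with open(path, "w") as fh:
            json.dump(self.to_dict(config_digest), fh, indent=1)

    @classmethod
    def load(cls, path) -> "GazeHMM":
        with open(path) as fh:
            return cls.from_dict(json.load(fh))

    def stationary_distribution(self) -> np.ndarray:
        """Stationary distribution of the transition chain."""
        vals, vecs = np.linalg.eig(self.transitions.T)
        i = int(np.argmin(np.abs(vals - 1.0)))
        v = np.real(vecs[:, i])
        v = np.abs(v)
        return v / v.sum()


@dataclass
class VBConfig:
    """Hyperparameters and fitting schedule for the VB-HMM.

    ``dirichlet_prior``/``dirichlet_transition`` are the symmetric
    Dirichlet concentrations on the start vector and on each transition
    row.  The emission prior is a Normal–Wishart centered on
    ``prior_mean`` (defaults to the stimulus center) with a small
    precision scale ``kappa0`` (so ROI means roam the stimulus freely)
    and a scale matrix sized to a typical horizontal face band — wide
    in x, tight in y.  A band-scaled prior rather than a stimulus-wide
    one keeps state-count selection informative at realistic sequence
    lengths (tens of fixations).
    """

    K_range: tuple[int, int] = (1, 6)
    n_restarts: int = 100
    max_iterations: int = 200
    convergence_tolerance: float = 1e-6
    dirichlet_prior: float = 1.0
    dirichlet_transition: float = 1.0
    prior_mean: tuple[float, float] = (960.0, 540.0)
    kappa0: float = 0.05
    dof0: float = 5.0
    prior_scale: tuple[float, float] = (200.0, 50.0)  # SD-scale of the NW scale matrix
    init: str = "kmeans"  # "kmeans" | "random"
    stimulus_rect: tuple[float, float, float, float] = (510.0, 70.0, 1410.0, 1010.0)
    cov_floor: float = 1.0  # px^2 eigenvalue floor on point-estimate covariances
    prune_threshold: float = 0.1  # expected-count threshold for dropping states
    rng_seed: int | None = None

    def __post_init__(self) -> None:
        if self.n_restarts < 1:
            raise ValueError("n_restarts must be >= 1")
        if self.convergence_tolerance <= 0:
            raise ValueError("convergence_tolerance must be > 0")

    def digest(self) -> str:
        return hashlib.sha1(
            json.dumps(asdict(self), sort_keys=True).encode()
        ).hexdigest()[:12]


# ---------------------------------------------------------------------------
# batched log-space forward-backward

def _forward_logsum(logB: np.ndarray, logpi: np.ndarray, logA: np.ndarray) -> np.ndarray:
    """Batched forward pass; returns per-sequence log-normalizers.

    logB: (B, T, K) per-step log emission scores.
    """
    la = logpi[None, :] + logB[:, 0, :]
    for t in range(1, logB.shape[1]):
        la = logB[:, t, :] + _lse(la[:, :, None] + logA[None, :, :], axis=1)
    return _lse(la, axis=1)


def _forward_backward(logB, logpi, logA):
    """Batched smoothing.  Returns (gamma, xi_sum, loglik).

    gamma: (B, T, K) posterior state responsibilities;
    xi_sum: (K, K) expected transition counts summed over batch and time;
    loglik: (B,) log-normalizers.
    """
    B, T, K = logB.shape
    la = np.empty((B, T, K))
    la[:, 0] = logpi[None, :] + logB[:, 0]
    for t in range(1, T):
        la[:, t] = logB[:, t] + _lse(la[:, t - 1][:, :, None] + logA[None], axis=1)
    lb = np.zeros((B, T, K))
    for t in range(T - 2, -1, -1):
        lb[:, t] = _lse(logA[None] + (logB[:, t + 1] + lb[:, t + 1])[:, None, :], axis=2)
    loglik = _lse(la[:, -1], axis=1)
    lg = la + lb - loglik[:, None, None]
    gamma = np.exp(lg)
    xi_sum = np.zeros((K, K))
    for t in range(T - 1):
        lxi = (la[:, t][:, :, None] + logA[None]
               + (logB[:, t + 1] + lb[:, t + 1])[:, None, :]
               - loglik[:, None, None])
        xi_sum += np.exp(lxi).sum(axis=0)
    return gamma, xi_sum, loglik


# ---------------------------------------------------------------------------
# variational posterior

class _Posterior:
    """Variational posterior over HMM parameters (arrays over K states)."""

    def __init__(self, K: int, cfg: VBConfig):
        self.K = K
        self.cfg = cfg
        self.alpha0 = cfg.dirichlet_prior
        self.beta0 = cfg.dirichlet_transition
        self.m0 = np.asarray(cfg.prior_mean, dtype=float)
        self.kappa0 = cfg.kappa0
        self.nu0 = cfg.dof0
        # NW scale matrix: inverse scale sized to the stimulus extent
        psi0 = np.diag(np.asarray(cfg.prior_scale, dtype=float) ** 2) * self.nu0
        self.W0 = np.linalg.inv(psi0)
        self.logdetW0 = float(np.linalg.slogdet(self.W0)[1])
        # posterior parameters (start at prior)
        self.alpha = np.full(K, self.alpha0)
        self.beta = np.full((K, K), self.beta0)
        self.m = np.tile(self.m0, (K, 1))
        self.kappa = np.full(K, self.kappa0)
        self.nu = np.full(K, self.nu0)
        self.W = np.tile(self.W0, (K, 1, 1))

    # -- expectations used in the E-step ---------------------------------
    def expected_log_start(self) -> np.ndarray:
        return digamma(self.alpha) - digamma(self.alpha.sum())

    def expected_log_trans(self) -> np.ndarray:
        return digamma(self.beta) - digamma(self.beta.sum(axis=1))[:, None]

    def expected_log_emission(self, X: np.ndarray) -> np.ndarray:
        """E_q[log N(x | mu_k, Sigma_k)] for all points; X (n, 2) -> (n, K)."""
        n = X.shape[0]
        out = np.empty((n, self.K))
        for k in range(self.K):
            elogdet = (digamma(0.5 * (self.nu[k] + 1 - np.arange(1, _D + 1))).sum()
                       + _D * math.log(2.0) + np.linalg.slogdet(self.W[k])[1])
            d = X - self.m[k]
            quad = self.nu[k] * np.einsum("ni,ij,nj->n", d, self.W[k], d)
            out[:, k] = 0.5 * elogdet - _D / (2.0 * self.kappa[k]) - 0.5 * quad - _LOG2PI
        return out

    # -- M-step -----------------------------------------------------------
    def update(self, first, trans, Nk, Sx, Sxx) -> None:
        self.alpha = self.alpha0 + first
        self.beta = self.beta0 + trans
        Nk = np.maximum(Nk, 0.0)
        self.kappa = self.kappa0 + Nk
        self.nu = self.nu0 + Nk
        safe = np.maximum(Nk, 1e-12)
        xbar = Sx / safe[:, None]
        self.m = (self.kappa0 * self.m0[None, :] + Sx) / self.kappa[:, None]
        Winv0 = np.linalg.inv(self.W0)
        for k in range(self.K):
            S = Sxx[k] - np.outer(Sx[k], xbar[k])
            d0 = xbar[k] - self.m0
            Winv = (Winv0 + S
                    + (self.kappa0 * Nk[k] / (self.kappa0 + Nk[k])) * np.outer(d0, d0))
            self.W[k] = np.linalg.inv(0.5 * (Winv + Winv.T))

    # -- KL terms of the lower bound --------------------------------------
    def kl(self) -> float:
        total = _kl_dirichlet(self.alpha, np.full(self.K, self.alpha0))
        for j in range(self.K):
            total += _kl_dirichlet(self.beta[j], np.full(self.K, self.beta0))
        for k in range(self.K):
            total += _kl_normal_wishart(
                self.m[k], self.kappa[k], self.W[k], self.nu[k],
                self.m0, self.kappa0, self.W0, self.nu0,
            )
        return total

    # -- point estimate ----------------------------------------------------
    def point_model(self, train_loglik: float = float("nan")) -> GazeHMM:
        priors = self.alpha / self.alpha.sum()
        A = self.beta / self.beta.sum(axis=1)[:, None]
        rois = []
        for k in range(self.K):
            denom = self.nu[k] - _D - 1.0
            cov = np.linalg.inv(self.W[k]) / (denom if denom > 0.5 else self.nu[k])
            cov = _floor_cov(cov, self.cfg.cov_floor)
            rois.append(GaussianROI(self.m[k], cov))
        return GazeHMM(priors, A, rois, train_loglik)


def _floor_cov(cov: np.ndarray, floor: float) -> np.ndarray:
    vals, vecs = np.linalg.eigh(0.5 * (cov + cov.T))
    vals = np.maximum(vals, floor)
    return (vecs * vals) @ vecs.T


def _kl_dirichlet(a: np.ndarray, b: np.ndarray) -> float:
    sa = a.sum()
    return float(
        gammaln(sa) - gammaln(b.sum())
        - (gammaln(a) - gammaln(b)).sum()
        + ((a - b) * (digamma(a) - digamma(sa))).sum()
    )


def _log_wishart_B(W: np.ndarray, n: float) -> float:
    return float(-0.5 * n * np.linalg.slogdet(W)[1]
                 - 0.5 * n * _D * math.log(2.0)
                 - multigammaln(0.5 * n, _D))


def _kl_normal_wishart(mq, kq, Wq, nq, mp, kp, Wp, np_) -> float:
    elogdet = (digamma(0.5 * (nq + 1 - np.arange(1, _D + 1))).sum()
               + _D * math.log(2.0) + np.linalg.slogdet(Wq)[1])
    # Wishart part
    kl_w = (_log_wishart_B(Wq, nq) - _log_wishart_B(Wp, np_)
            + 0.5 * (nq - np_) * elogdet
            + 0.5 * nq * (np.trace(np.linalg.inv(Wp) @ Wq) - _D))
    # Normal part (conditional on the precision)
    d = mq - mp
    quad = nq * d @ Wq @ d
    kl_n = 0.5 * (_D * math.log(kq / kp) - _D + kp * (_D / kq + quad))
    return float(kl_w + kl_n)


# ---------------------------------------------------------------------------
# fitting

def _group_by_length(obs: list[np.ndarray]) -> dict[int, np.ndarray]:
    groups: dict[int, list[np.ndarray]] = {}
    for o in obs:
        groups.setdefault(o.shape[0], []).append(o)
    return {L: np.stack(v) for L, v in groups.items()}


def _estep(post: _Posterior, groups: dict[int, np.ndarray]):
    K = post.K
    logpi = post.expected_log_start()
    logA = post.expected_log_trans()
    first = np.zeros(K)
    trans = np.zeros((K, K))
    Nk = np.zeros(K)
    Sx = np.zeros((K, _D))
    Sxx = np.zeros((K, _D, _D))
    total_ll = 0.0
    for L, batch in groups.items():  # batch: (B, L, 2)
        B = batch.shape[0]
        flat = batch.reshape(-1, _D)
        logB = post.expected_log_emission(flat).reshape(B, L, K)
        gamma, xi_sum, ll = _forward_backward(logB, logpi, logA)
        total_ll += float(ll.sum())
        first += gamma[:, 0, :].sum(axis=0)
        trans += xi_sum
        g = gamma.reshape(-1, K)  # (B*L, K)
        Nk += g.sum(axis=0)
        Sx += g.T @ flat
        Sxx += np.einsum("nk,ni,nj->kij", g, flat, flat)
    return first, trans, Nk, Sx, Sxx, total_ll


def _init_posterior(post: _Posterior, obs_flat: np.ndarray, obs: list[np.ndarray],
                    rng: np.random.Generator, cfg: VBConfig) -> None:
    K = post.K
    if cfg.init == "kmeans":
        means = obs_flat[rng.choice(len(obs_flat), size=K, replace=False)]
        for _ in range(10):
            d2 = ((obs_flat[:, None, :] - means[None]) ** 2).sum(axis=2)
            lab = d2.argmin(axis=1)
            for k in range(K):
                if np.any(lab == k):
                    means[k] = obs_flat[lab == k].mean(axis=0)
    else:
        x0, y0, x1, y1 = cfg.stimulus_rect
        means = np.column_stack([rng.uniform(x0, x1, K), rng.uniform(y0, y1, K)])
    d2 = ((obs_flat[:, None, :] - means[None]) ** 2).sum(axis=2)
    lab = d2.argmin(axis=1)
    g = np.zeros((len(obs_flat), K))
    g[np.arange(len(obs_flat)), lab] = 1.0
    g = 0.9 * g + 0.1 / K  # soften hard assignment
    # accumulate init stats sequence-wise for start/transition counts
    first = np.zeros(K)
    trans = np.zeros((K, K))
    i = 0
    for o in obs:
        T = o.shape[0]
        gs = g[i:i + T]
        first += gs[0]
        for t in range(T - 1):
            trans += np.outer(gs[t], gs[t + 1])
        i += T
    Nk = g.sum(axis=0)
    Sx = g.T @ obs_flat
    Sxx = np.einsum("nk,ni,nj->kij", g, obs_flat, obs_flat)
    post.update(first, trans, Nk, Sx, Sxx)


def _vbem_once(obs: list[np.ndarray], K: int, cfg: VBConfig,
               rng: np.random.Generator):
    post = _Posterior(K, cfg)
    obs_flat = np.concatenate(obs, axis=0)
    _init_posterior(post, obs_flat, obs, rng, cfg)
    groups = _group_by_length(obs)
    elbo_trace: list[float] = []
    prev = -np.inf
    for _ in range(cfg.max_iterations):
        first, trans, Nk, Sx, Sxx, ll = _estep(post, groups)
        elbo = ll - post.kl()
        elbo_trace.append(elbo)
        post.update(first, trans, Nk, Sx, Sxx)
        if elbo - prev < cfg.convergence_tolerance * (1.0 + abs(elbo)):
            break
        prev = elbo
    return post, elbo_trace, Nk


def _prune(post: _Posterior, Nk: np.ndarray, cfg: VBConfig) -> tuple[GazeHMM, np.ndarray]:
    keep = np.flatnonzero(Nk >= cfg.prune_threshold)
    if keep.size == 0:
        keep = np.array([int(Nk.argmax())])
    model = post.point_model()
    priors = model.priors[keep]
    priors /= priors.sum()
    A = model.transitions[np.ix_(keep, keep)]
    A /= A.sum(axis=1)[:, None]
    rois = [model.emissions[k] for k in keep]
    return GazeHMM(priors, A, rois), keep


def _as_obs(sequences) -> list[np.ndarray]:
    obs = []
    for s in sequences:
        if isinstance(s, FixationSequence):
            if len(s) == 0:
                raise DegenerateDataError("empty fixation sequence")
            obs.append(s.positions())
        else:
            a = np.asarray(s, dtype=float).reshape(-1, _D)
            if a.shape[0] == 0:
                raise DegenerateDataError("empty fixation sequence")
            obs.append(a)
    return obs


def fit_vbhmm(sequences, K: int, config: VBConfig | None = None,
              rng: np.random.Generator | None = None) -> tuple[GazeHMM, float]:
    """Fit a K-state VB-HMM; returns the best restart and its lower bound.

    ``sequences`` is a list of FixationSequence (or (n, 2) arrays).  The
    model returned is the point estimate (posterior means) of the restart
    with the highest variational lower bound; states whose expected count
    is negligible are pruned, so the effective state count may be below K.
    """
    cfg = config or VBConfig()
    obs = _as_obs(sequences)
    if not obs:
        raise DegenerateDataError("no sequences provided")
    n_total = sum(o.shape[0] for o in obs)
    if n_total < K:
        raise DegenerateDataError(f"{n_total} fixations cannot support K={K} states")
    if rng is None:
        rng = np.random.default_rng(cfg.rng_seed)
    best = None
    for _ in range(cfg.n_restarts):
        post, trace, Nk = _vbem_once(obs, K, cfg, rng)
        if best is None or trace[-1] > best[1][-1]:
            best = (post, trace, Nk)
    post, trace, Nk = best
    model, _ = _prune(post, Nk, cfg)
    model.train_loglik = float(sum(log_likelihood(model, o) for o in obs))
    model.elbo_trace = trace  # type: ignore[attr-defined]
    return model, float(trace[-1])


def select_model(sequences, config: VBConfig | None = None,
                 rng: np.random.Generator | None = None) -> GazeHMM:
    """Fit over the configured range of state counts; return the model
    with the highest variational lower bound (ties toward fewer states)."""
    cfg = config or VBConfig()
    if rng is None:
        rng = np.random.default_rng(cfg.rng_seed)
    lo, hi = cfg.K_range
    obs = _as_obs(sequences)
    if not obs:
        raise DegenerateDataError("no sequences provided")
    n_total = sum(o.shape[0] for o in obs)
    best_model, best_bound = None, -np.inf
    for K in range(lo, hi + 1):
        if n_total < K:
            break
        model, bound = fit_vbhmm(obs, K, cfg, rng)
        if bound > best_bound + 1e-9:
            best_model, best_bound = model, bound
    if best_model is None:
        raise DegenerateDataError("no state count could be fit")
    best_model.selection_bound = best_bound  # type: ignore[attr-defined]
    return best_model


# ---------------------------------------------------------------------------
# likelihood and sampling under the point-estimate model

def _log_emission_matrix(model: GazeHMM, X: np.ndarray) -> np.ndarray:
    K = model.n_states
    out = np.empty((X.shape[0], K))
    for k, roi in enumerate(model.emissions):
        d = X - roi.mean
        cinv = np.linalg.inv(roi.cov)
        _, logdet = np.linalg.slogdet(roi.cov)
        quad = np.einsum("ni,ij,nj->n", d, cinv, d)
        out[:, k] = -0.5 * (quad + logdet) - _LOG2PI
    return out


def log_likelihood(model: GazeHMM, sequence) -> float:
    """Exact forward-algorithm log marginal likelihood (nats)."""
    X = _as_obs([sequence])[0]
    logB = _log_emission_matrix(model, X)[None]  # (1, T, K)
    with np.errstate(divide="ignore"):
        logpi = np.log(model.priors)
        logA = np.log(model.transitions)
    return float(_forward_logsum(logB, logpi, logA)[0])


def batch_log_likelihood(model: GazeHMM, batch: np.ndarray) -> np.ndarray:
    """Forward log-likelihoods of a (B, T, 2) stack of equal-length sequences."""
    B, T, _ = batch.shape
    logB = _log_emission_matrix(model, batch.reshape(-1, _D)).reshape(B, T, -1)
    with np.errstate(divide="ignore"):
        logpi = np.log(model.priors)
        logA = np.log(model.transitions)
    return _forward_logsum(logB, logpi, logA)


def sample_sequence(
    model: GazeHMM,
    length: int,
    rng: np.random.Generator,
    duration_law: tuple[float, float, float] = (300.0, 100.0, 100.0),
    child_id: str = "",
    face_type: str = "",
) -> FixationSequence:
    """Draw a fixation sequence from the HMM.

    States follow priors/transitions, positions the state Gaussians.
    Durations come from a truncated normal ``(mean, sd, floor)`` in ms.
    """
    if length < 1:
        raise ValueError("length must be >= 1")
    K = model.n_states
    states = np.empty(length, dtype=int)
    states[0] = rng.choice(K, p=model.priors)
    for t in range(1, length):
        states[t] = rng.choice(K, p=model.transitions[states[t - 1]])
    pos = np.empty((length, _D))
    for t, k in enumerate(states):
        pos[t] = rng.multivariate_normal(model.emissions[k].mean, model.emissions[k].cov)
    mean, sd, floor = duration_law
    a = (floor - mean) / sd
    dur = truncnorm.rvs(a, np.inf, loc=mean, scale=sd, size=length, random_state=rng)
    onsets = np.concatenate([[0.0], np.cumsum(dur)[:-1]])
    seq = FixationSequence(child_id, face_type, pos[:, 0], pos[:, 1], onsets, dur)
    seq.states = states  # type: ignore[attr-defined]  # ground truth for tests
    return seq
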