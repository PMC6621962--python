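"""Three-state hidden Markov model for movement behavior.

States emit step lengths from gamma distributions and turning angles
from von Mises distributions; the latent chain is first-order Markov.
After fitting, states are relabeled in increasing order of gamma mean so
that state 0 is "encamped", 1 "foraging" and 2 "movement"; only
movement-state steps feed the selection analyses.

The likelihood is maximized directly (L-BFGS-B on unconstrained
parameters, forward algorithm in log space) with multiple randomized
restarts, because the surface is multimodal.  The initial distribution
is tied to the stationary distribution of the transition matrix.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
from numba import njit
from scipy import optimize, special, stats

STATE_NAMES = ("encamped", "foraging", "movement")
N_STATES = 3


@dataclass
class HMMFit:
    """Converged maximum-likelihood parameters for the 3-state model."""

    step_means: np.ndarray  # gamma mean (m) per state, ascending
    step_sds: np.ndarray
    angle_means: np.ndarray  # von Mises location per state (radians)
    angle_kappas: np.ndarray
    tpm: np.ndarray  # 3x3 transition matrix
    initial: np.ndarray  # stationary distribution of tpm
    log_likelihood: float
    converged: bool
    n_obs: int = 0

    @property
    def n_parameters(self) -> int:
        return 4 * N_STATES + N_STATES * (N_STATES - 1)

    @property
    def aic(self) -> float:
        return -2.0 * self.log_likelihood + 2.0 * self.n_parameters


@njit(cache=True)
def _forward_logsumexp(log_em, log_tpm, log_delta):
    """Forward algorithm in log space; returns total log-likelihood."""
    T, K = log_em.shape
    alpha = log_delta + log_em[0]
    work = np.empty(K)
    for t in range(1, T):
        new = np.empty(K)
        for j in range(K):
            for i in range(K):
                work[i] = alpha[i] + log_tpm[i, j]
            m = work.max()
            s = 0.0
            for i in range(K):
                s += math.exp(work[i] - m)
            new[j] = m + math.log(s) + log_em[t, j]
        alpha = new
    m = alpha.max()
    s = 0.0
    for i in range(K):
        s += math.exp(alpha[i] - m)
    return m + math.log(s)


@njit(cache=True)
def _viterbi(log_em, log_tpm, log_delta):
    T, K = log_em.shape
    back = np.zeros((T, K), np.int64)
    score = log_delta + log_em[0]
    for t in range(1, T):
        new = np.empty(K)
        for j in range(K):
            best, arg = -1e300, 0
            for i in range(K):
                v = score[i] + log_tpm[i, j]
                if v > best:
                    best, arg = v, i
            new[j] = best + log_em[t, j]
            back[t, j] = arg
        score = new
    path = np.empty(T, np.int64)
    path[-1] = np.argmax(score)
    for t in range(T - 2, -1, -1):
        path[t] = back[t + 1, path[t + 1]]
    return path


def stationary_distribution(tpm: np.ndarray) -> np.ndarray:
    """Left eigenvector of the transition matrix for eigenvalue 1."""
    vals, vecs = np.linalg.eig(tpm.T)
    v = np.real(vecs[:, np.argmin(np.abs(vals - 1.0))])
    v = np.abs(v)
    return v / v.sum()


def _prepare_lengths(lengths: np.ndarray) -> np.ndarray:
    """Replace zero step lengths with half the minimum positive length."""
    lengths = np.asarray(lengths, float).copy()
    pos = lengths[lengths > 0]
    if pos.size == 0:
        raise ValueError("all step lengths are zero")
    lengths[lengths <= 0] = 0.5 * pos.min()
    return lengths


def log_emissions(
    lengths: np.ndarray,
    angles: np.ndarray,
    step_means: np.ndarray,
    step_sds: np.ndarray,
    angle_means: np.ndarray,
    angle_kappas: np.ndarray,
) -> np.ndarray:
    """T x 3 log emission densities; NaN angles contribute no angular term."""
    means = np.asarray(step_means, float)
    sds = np.asarray(step_sds, float)
    shape = means**2 / sds**2
    scale = sds**2 / means
    le = stats.gamma.logpdf(lengths[:, None], shape[None, :], scale=scale[None, :])
    defined = ~np.isnan(angles)
    if defined.any():
        a = angles[defined, None]
        la = (
            np.asarray(angle_kappas)[None, :] * np.cos(a - np.asarray(angle_means)[None, :])
            - np.log(2 * np.pi)
            - np.log(special.i0(np.asarray(angle_kappas)))[None, :]
        )
        le[defined] += la
    return le


def _unpack(theta: np.ndarray) -> tuple[np.ndarray, ...]:
    means = np.exp(theta[0:3])
    sds = np.exp(theta[3:6])
    mus = theta[6:9]
    kappas = np.exp(theta[9:12])
    logits = theta[12:18].reshape(3, 2)
    tpm = np.empty((3, 3))
    for i in range(3):
        row = np.ones(3)
        off = np.exp(logits[i])
        cols = [c for c in range(3) if c != i]
        row[cols] = off
        tpm[i] = row / row.sum()
    return means, sds, mus, kappas, tpm


def _neg_log_lik(theta: np.ndarray, lengths: np.ndarray, angles: np.ndarray) -> float:
    means, sds, mus, kappas, tpm = _unpack(theta)
    le = log_emissions(lengths, angles, means, sds, mus, kappas)
    if not np.all(np.isfinite(le)):
        return 1e12
    delta = stationary_distribution(tpm)
    ll = _forward_logsumexp(le, np.log(tpm), np.log(delta))
    return -ll if np.isfinite(ll) else 1e12


def forward_log_likelihood(
    lengths,
    angles,
    step_means,
    step_sds,
    angle_means,
    angle_kappas,
    tpm,
    initial=None,
) -> float:
    """Log-likelihood of a step sequence under fixed parameters."""
    lengths = _prepare_lengths(np.asarray(lengths, float))
    angles = np.asarray(angles, float)
    tpm = np.asarray(tpm, float)
    delta = stationary_distribution(tpm) if initial is None else np.asarray(initial, float)
    le = log_emissions(lengths, angles, np.asarray(step_means), np.asarray(step_sds),
                       np.asarray(angle_means), np.asarray(angle_kappas))
    return float(_forward_logsumexp(le, np.log(tpm), np.log(delta)))


def fit_hmm(
    lengths,
    angles,
    n_restarts: int = 10,
    seed: int = 0,
    initial_means: np.ndarray | None = None,
) -> HMMFit:
    """Maximum-likelihood 3-state fit with randomized restarts.

    Parameters
    ----------
    lengths, angles
        Step lengths (m) and turning angles (radians; NaN where
        undefined, e.g. the first step of a burst).
    initial_means
        Optional starting gamma means; default uses the 15/50/85th
        length quantiles, perturbed per restart.
    """
    lengths = _prepare_lengths(np.asarray(lengths, float))
    angles = np.asarray(angles, float)
    if lengths.size < 200:
        raise ValueError("need at least 200 steps to fit the HMM")
    rng = np.random.default_rng(seed)
    base_means = (
        np.asarray(initial_means, float)
        if initial_means is not None
        else np.quantile(lengths, [0.15, 0.5, 0.85])
    )
    best = None
    for r in range(n_restarts):
        jitter = rng.uniform(0.7, 1.4, 3) if r else np.ones(3)
        means0 = np.sort(base_means * jitter)
        sds0 = means0 * rng.uniform(0.5, 1.0, 3)
        mus0 = rng.vonmises(0.0, 0.5, 3) if r else np.array([math.pi, 0.0, 0.0])
        kappas0 = rng.uniform(0.2, 2.0, 3) if r else np.array([0.5, 1.0, 2.0])
        theta0 = np.concatenate(
            [np.log(means0), np.log(sds0), mus0, np.log(kappas0), np.full(6, math.log(0.15))]
        )
        res = optimize.minimize(
            _neg_log_lik, theta0, args=(lengths, angles), method="L-BFGS-B",
            options={"maxiter": 500},
        )
        if best is None or res.fun < best.fun:
            best = res
    if best is None or not np.isfinite(best.fun) or best.fun >= 1e12:
        raise RuntimeError("HMM fit failed to converge in any restart")

    means, sds, mus, kappas, tpm = _unpack(best.x)
    order = np.argsort(means)  # canonical labels: ascending gamma mean
    tpm = tpm[np.ix_(order, order)]
    fit = HMMFit(
        step_means=means[order],
        step_sds=sds[order],
        angle_means=np.arctan2(np.sin(mus[order]), np.cos(mus[order])),
        angle_kappas=kappas[order],
        tpm=tpm,
        initial=stationary_distribution(tpm),
        log_likelihood=-float(best.fun),
        converged=bool(best.success or best.fun < 1e12),
        n_obs=int(lengths.size),
    )
    return fit


def decode_states(fit: HMMFit, lengths, angles) -> np.ndarray:
    """Viterbi most-probable state path (0 encamped, 1 foraging, 2 movement)."""
    lengths = _prepare_lengths(np.asarray(lengths, float))
    angles = np.asarray(angles, float)
    le = log_emissions(lengths, angles, fit.step_means, fit.step_sds, fit.angle_means, fit.angle_kappas)
    return np.asarray(_viterbi(le, np.log(fit.tpm), np.log(fit.initial)))


def label_behavior(fit: HMMFit, steps):
    """Add a behavior_state column (state names) to a step table."""
    out = steps.copy()
    states = decode_states(fit, steps["length"].to_numpy(), steps["turning_angle"].to_numpy())
    out["behavior_state"] = [STATE_NAMES[s] for s in states]
    return out


def extract_movement_steps(steps):
    """Keep only movement-state steps for downstream selection analyses."""
    return steps.loc[steps["behavior_state"] == "movement"].reset_index(drop=True)
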