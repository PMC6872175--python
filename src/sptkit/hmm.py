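"""Hidden-Markov segmentation of a trajectory into discrete diffusive states.

A membrane protein can alternate between, e.g., fast free diffusion and
transient trapping.  Per frame, the 2D instantaneous displacement
``dr_t = r_{t+1} - r_t`` of a particle in state k is modelled as an
isotropic Gaussian with per-dimension variance ``sigma_k^2 = 2 * D_k * dt``
and mean ``mu_k = v_k * dt`` (zero unless the drift variant is used), while
the hidden state follows a first-order Markov chain.

:class:`DisplacementHMM` fits this model by expectation-maximization
(log-space forward-backward, multiple seeded restarts, monotone
log-likelihood), :meth:`HMMResults.decode` returns the Viterbi path, and
:func:`select_model` chooses the state count K and emission form
(D vs D+V) by BIC.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .tracks import Trajectory

_VAR_FLOOR = 1e-12
_LOG2PI = np.log(2.0 * np.pi)


class HMMError(ValueError):
    pass


@dataclass(frozen=True)
class DisplacementSeq:
    """Per-frame 2D displacements (um) of one reindexed track."""

    dxy: np.ndarray  # (n, 2)
    dt: float

    def __len__(self) -> int:
        return len(self.dxy)


def displacements(traj: Trajectory) -> DisplacementSeq:
    """Consecutive-frame displacement vectors; the track must be contiguous."""
    if not traj.is_contiguous:
        raise HMMError(
            f"track {traj.track_id} has frame gaps; reindex_blink_gaps first"
        )
    dxy = np.column_stack([np.diff(traj.x), np.diff(traj.y)])
    return DisplacementSeq(dxy=dxy, dt=traj.dt)


@dataclass
class HMMState:
    """One diffusive state: diffusivity, optional drift, and occupancy."""

    D: float               # um^2/s, from sigma^2 = 2*D*dt
    v: tuple = (0.0, 0.0)  # um/s, from mu = v*dt
    occupancy: float = 0.0


@dataclass
class HMMResults:
    """Fitted diffusive-state model for one displacement sequence.

    States are sorted by increasing D.  ``loglike_history`` records the EM
    log-likelihood per iteration of the winning restart (non-decreasing).
    """

    K: int
    model_kind: str
    states: list
    transmat: np.ndarray
    startprob: np.ndarray
    log_likelihood: float
    n_iter: int
    converged: bool
    loglike_history: np.ndarray
    seq: DisplacementSeq
    selection_scores: dict = field(default_factory=dict)

    @property
    def D_states(self) -> np.ndarray:
        return np.array([s.D for s in self.states])

    @property
    def n_params(self) -> int:
        p = (self.K - 1) + self.K * (self.K - 1) + self.K
        if self.model_kind == "DV":
            p += 2 * self.K
        return p

    @property
    def bic(self) -> float:
        return -2.0 * self.log_likelihood + self.n_params * np.log(len(self.seq))

    def decode(self) -> np.ndarray:
        """Viterbi maximum-probability state path (one label per displacement)."""
        logB = _log_emissions(self.seq, self.states, self.model_kind)
        return _viterbi(np.log(np.clip(self.startprob, 1e-300, None)),
                        np.log(np.clip(self.transmat, 1e-300, None)), logB)

    def summary(self) -> str:
        lines = [
            "Displacement HMM Results",
            "=" * 52,
            f"{'states (K)':<22}{self.K:>10d}",
            f"{'emission model':<22}{self.model_kind:>10}",
            f"{'n displacements':<22}{len(self.seq):>10d}",
            f"{'log-likelihood':<22}{self.log_likelihood:>14.4f}",
            f"{'BIC':<22}{self.bic:>14.4f}",
            f"{'converged':<22}{str(self.converged):>10}",
            "-" * 52,
            f"{'state':<7}{'D (um^2/s)':>12}{'v (um/s)':>18}{'occupancy':>12}",
        ]
        for i, s in enumerate(self.states, 1):
            lines.append(
                f"{i:<7}{s.D:>12.5g}{f'({s.v[0]:.3g}, {s.v[1]:.3g})':>18}"
                f"{s.occupancy:>12.3f}"
            )
        return "\n".join(lines)


def _log_emissions(seq: DisplacementSeq, states, model_kind: str) -> np.ndarray:
    dxy = seq.dxy
    n, K = len(dxy), len(states)
    logB = np.empty((n, K))
    for k, st in enumerate(states):
        var = max(2.0 * st.D * seq.dt, _VAR_FLOOR)
        mu = np.asarray(st.v) * seq.dt if model_kind == "DV" else np.zeros(2)
        sq = np.sum((dxy - mu) ** 2, axis=1)
        logB[:, k] = -_LOG2PI - np.log(var) - sq / (2.0 * var)
    return logB


def _viterbi(log_pi, log_A, logB) -> np.ndarray:
    n, K = logB.shape
    delta = log_pi + logB[0]
    psi = np.zeros((n, K), dtype=np.int64)
    for t in range(1, n):
        scores = delta[:, None] + log_A
        psi[t] = np.argmax(scores, axis=0)
        delta = scores[psi[t], np.arange(K)] + logB[t]
    path = np.empty(n, dtype=np.int64)
    path[-1] = int(np.argmax(delta))
    for t in range(n - 2, -1, -1):
        path[t] = psi[t + 1, path[t + 1]]
    return path


class DisplacementHMM:
    """Gaussian-displacement hidden Markov model for one trajectory.

    Parameters
    ----------
    seq : DisplacementSeq or Trajectory
        Displacement sequence (a Trajectory is converted automatically).
    K : int
        Number of diffusive states.
    model : {'D', 'DV'}
        'D' fits diffusivities only (zero-mean emissions); 'DV' adds a
        per-state drift velocity.
    loc_sigma : float
        Optional localization-noise floor; when positive the emission
        variance is ``2*D*dt + 2*loc_sigma^2`` per dimension (off by
        default, matching the plain emission model).
    """

    def __init__(self, seq, K: int = 1, model: str = "D", loc_sigma: float = 0.0):
        if isinstance(seq, Trajectory):
            seq = displacements(seq)
        if K < 1:
            raise HMMError("K must be >= 1")
        if model not in ("D", "DV"):
            raise HMMError("model must be 'D' or 'DV'")
        if len(seq) < 10 * K:
            raise HMMError(f"sequence length {len(seq)} < 10*K = {10 * K}")
        if np.all(seq.dxy == 0.0):
            raise HMMError("all displacements are zero; nothing to segment")
        self.seq = seq
        self.K = int(K)
        self.model_kind = model
        self.loc_sigma = float(loc_sigma)

    # -- EM internals ------------------------------------------------------

    def _init_params(self, rng):
        dxy = self.seq.dxy
        K = self.K
        r2 = np.sum(dxy**2, axis=1)
        order = np.argsort(r2)
        groups = np.array_split(order, K)
        variances = []
        means = []
        for g in groups:
            v = max(np.mean(r2[g]) / 2.0, _VAR_FLOOR)  # per-dimension
            variances.append(v * float(rng.lognormal(0.0, 0.3)))
            means.append(dxy[g].mean(axis=0) if self.model_kind == "DV"
                         else np.zeros(2))
        A = np.full((K, K), 0.1 / max(K - 1, 1))
        np.fill_diagonal(A, 0.9 if K > 1 else 1.0)
        pi = np.full(K, 1.0 / K)
        return pi, A, np.array(variances), np.array(means)

    def _var_to_state(self, var: float) -> float:
        eff = var - 2.0 * self.loc_sigma**2
        return max(eff, 0.0) / (2.0 * self.seq.dt)

    def _em_run(self, rng, max_iter: int, tol: float):
        # scaled forward-backward (Rabiner); per-row max of logB factored out
        # so extreme emission ratios cannot underflow the scaling constants
        dxy = self.seq.dxy
        n, K = len(dxy), self.K
        pi, A, var, mu = self._init_params(rng)
        history = []
        prev_ll = -np.inf
        converged = False
        gamma = np.full((n, K), 1.0 / K)
        for it in range(max_iter):
            states = [HMMState(D=self._var_to_state(var[k]), v=tuple(mu[k] / self.seq.dt))
                      for k in range(K)]
            logB = _log_emissions(self.seq, states, self.model_kind)
            bmax = logB.max(axis=1)
            B = np.exp(logB - bmax[:, None])
            alpha = np.empty((n, K))
            c = np.empty(n)
            a = pi * B[0]
            c[0] = a.sum()
            alpha[0] = a / c[0]
            for t in range(1, n):
                a = (alpha[t - 1] @ A) * B[t]
                c[t] = a.sum()
                alpha[t] = a / c[t]
            ll = float(np.log(c).sum() + bmax.sum())
            history.append(ll)
            if ll - prev_ll < tol and it > 0:
                converged = True
                break
            prev_ll = ll
            beta = np.empty((n, K))
            beta[-1] = 1.0
            for t in range(n - 2, -1, -1):
                beta[t] = (A @ (B[t + 1] * beta[t + 1])) / c[t + 1]
            gamma = alpha * beta
            gamma /= np.clip(gamma.sum(axis=1, keepdims=True), 1e-300, None)
            if K > 1 and n > 1:
                wgt = B[1:] * beta[1:] / c[1:, None]
                xi_num = A * (alpha[:-1].T @ wgt)
                A = xi_num / np.clip(xi_num.sum(axis=1, keepdims=True), 1e-300, None)
            pi = gamma[0] / gamma[0].sum()
            w = gamma.sum(axis=0)
            if self.model_kind == "DV":
                mu = (gamma.T @ dxy) / np.clip(w[:, None], 1e-300, None)
            for k in range(K):
                diff = dxy - mu[k]
                var[k] = max(
                    float((gamma[:, k] @ np.sum(diff**2, axis=1))
                          / np.clip(2.0 * w[k], 1e-300, None)),
                    _VAR_FLOOR,
                )
        occ = gamma.sum(axis=0) / n if n else np.full(K, np.nan)
        states = [HMMState(D=self._var_to_state(var[k]),
                           v=tuple(mu[k] / self.seq.dt), occupancy=float(occ[k]))
                  for k in range(K)]
        return ll, pi, A, states, np.array(history), converged

    def fit(self, n_restarts: int = 10, seed: int = 0, max_iter: int = 500,
            tol: float = 1e-6) -> HMMResults:
        """EM fit; best of ``n_restarts`` seeded initializations by log-likelihood."""
        rng = np.random.default_rng(seed)
        best = None
        for _ in range(max(1, n_restarts)):
            out = self._em_run(rng, max_iter, tol)
            if best is None or out[0] > best[0]:
                best = out
        ll, pi, A, states, history, converged = best
        order = np.argsort([s.D for s in states])
        states = [states[i] for i in order]
        A = A[np.ix_(order, order)]
        pi = pi[order]
        return HMMResults(
            K=self.K, model_kind=self.model_kind, states=states,
            transmat=A, startprob=pi, log_likelihood=ll,
            n_iter=len(history), converged=converged,
            loglike_history=history, seq=self.seq,
        )


def fit_hmm(seq, K: int, model: str = "D", n_restarts: int = 10,
            seed: int = 0) -> HMMResults:
    """Functional wrapper around :class:`DisplacementHMM`."""
    return DisplacementHMM(seq, K=K, model=model).fit(n_restarts=n_restarts,
                                                      seed=seed)


def select_model(seq, K_max: int = 3, models=("D", "DV"), n_restarts: int = 10,
                 seed: int = 0) -> HMMResults:
    """Fit all candidate (K, emission-form) models and return the BIC minimizer.

    All candidate scores are retained in ``selection_scores`` keyed by
    ``'K{K}_{model}'``.
    """
    if isinstance(seq, Trajectory):
        seq = displacements(seq)
    candidates = {}
    scores = {}
    for model in models:
        for K in range(1, K_max + 1):
            fit = DisplacementHMM(seq, K=K, model=model).fit(
                n_restarts=n_restarts, seed=seed)
            key = f"K{K}_{model}"
            candidates[key] = fit
            scores[key] = fit.bic
    best_key = min(scores, key=scores.get)
    best = candidates[best_key]
    best.selection_scores = scores
    return best
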