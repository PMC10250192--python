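"""Continuous-time Markov chain utilities shared by trait and range mapping.

Provides cached transition matrices P(t) = exp(Qt) and endpoint-conditioned
path sampling by uniformization.  Uniformization rewrites the CTMC as a
Poisson number of jumps of a discrete chain R = I + Q/L (L the fastest exit
rate); conditioned on the endpoints, the jump count, the intermediate states
and the jump times can each be sampled exactly, which avoids the unbounded
running time of naive rejection sampling on long or state-rich branches.
"""

from __future__ import annotations

import math

import numpy as np
from scipy.linalg import expm

__all__ = ["CTMCPropagator", "PathSamplingError"]

#: stop extending the Poisson series once this much mass is covered
_POISSON_TAIL = 1e-10
_MAX_JUMPS = 100_000


class PathSamplingError(RuntimeError):
    pass


def _clean_probability_matrix(P: np.ndarray) -> np.ndarray:
    P = np.where(P < 0, 0.0, P)
    return P


class CTMCPropagator:
    """Transition matrices and conditioned paths for a fixed generator Q."""

    def __init__(self, Q: np.ndarray):
        Q = np.asarray(Q, dtype=float)
        if Q.ndim != 2 or Q.shape[0] != Q.shape[1]:
            raise ValueError("Q must be square")
        if np.any(Q - np.diag(np.diag(Q)) < -1e-12):
            raise ValueError("off-diagonal rates must be non-negative")
        if np.max(np.abs(Q.sum(axis=1))) > 1e-8 * max(1.0, np.max(np.abs(Q))):
            raise ValueError("rows of Q must sum to zero")
        self.Q = Q
        self.k = Q.shape[0]
        self._Pcache: dict[float, np.ndarray] = {}
        self._use_eig = False
        if self.k >= 2:
            try:
                w, V = np.linalg.eig(Q)
                Vinv = np.linalg.inv(V)
                if np.linalg.cond(V) < 1e10:
                    self._w, self._V, self._Vinv = w, V, Vinv
                    self._use_eig = True
            except np.linalg.LinAlgError:
                pass
        # uniformization pieces
        self.rate = float(np.max(-np.diag(Q)))
        if self.rate > 0:
            self.R = np.eye(self.k) + Q / self.rate
            self._Rpow = [np.eye(self.k), self.R]
        else:
            self.R = np.eye(self.k)
            self._Rpow = [np.eye(self.k)]

    # ------------------------------------------------------------------ P(t)
    def P(self, t: float) -> np.ndarray:
        t = float(t)
        if t < 0:
            raise ValueError("negative branch length")
        got = self._Pcache.get(t)
        if got is not None:
            return got
        if t == 0.0:
            P = np.eye(self.k)
        elif self._use_eig:
            P = (self._V * np.exp(self._w * t)) @ self._Vinv
            P = _clean_probability_matrix(np.real(P))
        else:
            P = _clean_probability_matrix(expm(self.Q * t))
        self._Pcache[t] = P
        return P

    def P_batch(self, ts) -> np.ndarray:
        """Transition matrices for a vector of durations, shape (B, k, k)."""
        ts = np.asarray(ts, dtype=float)
        if self._use_eig:
            E = np.exp(np.multiply.outer(ts, self._w))
            P = np.einsum("ij,bj,jk->bik", self._V, E, self._Vinv)
            return _clean_probability_matrix(np.real(P))
        return np.stack([self.P(t) for t in ts])

    def _R_power(self, n: int) -> np.ndarray:
        while len(self._Rpow) <= n:
            self._Rpow.append(self._Rpow[-1] @ self.R)
        return self._Rpow[n]

    # ------------------------------------------------------------ path draws
    def sample_path(
        self, a: int, b: int, t: float, rng: np.random.Generator
    ) -> list[tuple[int, float]]:
        """Sample a state path on [0, t] conditioned on X(0)=a, X(t)=b.

        Returns ordered ``(state, duration)`` segments whose durations sum to
        ``t``; adjacent segments differ in state and the first segment starts
        in ``a``.
        """
        if t == 0.0 or self.rate == 0.0 or self.rate * t == 0.0:
            if a != b:
                raise PathSamplingError(
                    "zero-length or rate-degenerate branch with differing endpoints"
                )
            return [(a, t)]
        Pab = self.P(t)[a, b]
        if Pab <= 0.0:
            raise PathSamplingError(
                f"endpoint pair ({a}->{b}) has zero probability on branch of length {t}"
            )
        lt = self.rate * t
        # --- number of uniformized jumps
        u = rng.random() * Pab
        log_pois = -lt
        acc = 0.0
        pois_cdf = 0.0
        n = 0
        while True:
            pois = math.exp(log_pois)
            pois_cdf += pois
            acc += pois * self._R_power(n)[a, b]
            # remaining series mass is bounded by the Poisson tail (R powers
            # are stochastic), so stop once that tail is negligible
            if acc >= u or (1.0 - pois_cdf) <= _POISSON_TAIL:
                break
            n += 1
            if n > _MAX_JUMPS:
                raise PathSamplingError("jump-count series did not converge")
            log_pois += math.log(lt) - math.log(n)
        # --- intermediate states of the jump chain
        states = [a]
        for i in range(1, n):
            rem = n - i
            probs = self.R[states[-1], :] * self._R_power(rem)[:, b]
            s = probs.sum()
            if s <= 0:
                raise PathSamplingError("conditioned jump-chain step has zero mass")
            states.append(int(rng.choice(self.k, p=probs / s)))
        if n >= 1:
            states.append(b)
        # --- jump times are uniform order statistics on (0, t)
        times = np.sort(rng.random(n)) * t if n else np.empty(0)
        segments: list[tuple[int, float]] = []
        cur_state = a
        cur_start = 0.0
        for i in range(n):
            if states[i + 1] != cur_state:  # drop virtual (self) jumps
                segments.append((cur_state, float(times[i] - cur_start)))
                cur_state = states[i + 1]
                cur_start = float(times[i])
        segments.append((cur_state, float(t - cur_start)))
        return segments


def stationary_distribution(Q: np.ndarray) -> np.ndarray:
    """Stationary distribution of an irreducible generator (solves pi Q = 0)."""
    Q = np.asarray(Q, dtype=float)
    k = Q.shape[0]
    A = np.vstack([Q.T, np.ones(k)])
    b = np.zeros(k + 1)
    b[-1] = 1.0
    pi, *_ = np.linalg.lstsq(A, b, rcond=None)
    pi = np.clip(pi, 0.0, None)
    return pi / pi.sum()
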