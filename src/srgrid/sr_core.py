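"""Successor-representation mathematics.

The successor matrix M holds discounted expected future *state* occupancies
under a policy: M(s, s') = E[sum_t gamma^t 1(s_t = s') | s_0 = s]. Values
decompose linearly as V = M w, where the converged weight w(s') is the
policy-averaged one-step reward at s'. H is the state-action analogue over
(state, action) pairs, decoding directly into Q values.

All updates treat the absorbing terminal pseudo-state as a zero occupancy
row: the discounted continuation gamma*M(TERMINAL, :) (resp. H) is the zero
vector. Matrices are plain ``numpy`` arrays; state-action pairs are indexed
``s * n_actions + a``.
"""

from __future__ import annotations

import logging

import numpy as np

from .gridworld import N_ACTIONS, TERMINAL

log = logging.getLogger(__name__)


def sa_index(s: int, a: int, n_actions: int = N_ACTIONS) -> int:
    """Flat index of state-action (s, a)."""
    return s * n_actions + a


def td_error(r: float, gamma: float, v_next: float, v_cur: float) -> float:
    """Reward-prediction error delta = r + gamma * v_next - v_cur.

    ``v_next`` must be 0 when the successor is terminal.
    """
    return r + gamma * v_next - v_cur


def sr_td_update(M: np.ndarray, s: int, s_next: int,
                 alpha_sr: float, gamma: float) -> np.ndarray:
    """TD update of the successor matrix row for an experienced s -> s'.

    M(s,:) <- M(s,:) + alpha * [1_s + gamma * M(s',:) - M(s,:)], with a zero
    continuation at the terminal pseudo-state. Updates row ``s`` in place and
    returns M; no other row changes.
    """
    if s == TERMINAL:
        raise ValueError("cannot update the TERMINAL row")
    row = M[s]
    if s_next == s:  # self-transition: continuation is the pre-update row
        row *= 1.0 - alpha_sr + alpha_sr * gamma
        row[s] += alpha_sr
        return M
    row *= 1.0 - alpha_sr
    row[s] += alpha_sr
    if s_next != TERMINAL:
        row += (alpha_sr * gamma) * M[s_next]
    return M


def weight_update_td(w: np.ndarray, features: np.ndarray, delta: float,
                     alpha_w: float, mode: str = "normalized") -> np.ndarray:
    """Linear-TD weight update from a scalar TD error and a feature row.

    ``normalized`` divides by the squared feature norm (normalized LMS), so
    alpha_w keeps its interpretation as a proportional step size regardless
    of the occupancy row's scale; ``plain`` is the unscaled gradient step.
    With punctate (one-hot) features the two coincide.
    """
    if mode == "normalized":
        norm = float(features @ features)
        if norm == 0.0:
            log.warning("all-zero feature row; skipping weight update")
            return w
        w += (alpha_w * delta / norm) * features
    elif mode == "plain":
        w += alpha_w * delta * features
    else:
        raise ValueError(f"unknown mode {mode!r}")
    return w


def weight_update_direct(w: np.ndarray, s: int, r: float,
                         alpha_w: float) -> np.ndarray:
    """Delta-rule learning of the one-step reward: w(s) <- w(s)+a*(r-w(s))."""
    if s == TERMINAL:
        raise ValueError("cannot update the TERMINAL weight")
    w[s] += alpha_w * (r - w[s])
    return w


def value_from_sr(M: np.ndarray, w: np.ndarray) -> np.ndarray:
    """Decode state values V = M w from occupancies and reward weights."""
    M = np.asarray(M)
    w = np.asarray(w)
    if M.shape[1] != w.shape[0]:
        raise ValueError(f"dimension mismatch: M is {M.shape}, w is {w.shape}")
    return M @ w


def successor_from_transition(T: np.ndarray, gamma: float,
                              method: str = "inversion",
                              n_terms: int = 500) -> np.ndarray:
    """Exact successor matrix of a (sub)stochastic one-step matrix T.

    ``inversion`` solves M = (I - gamma T)^-1 directly; ``series`` sums the
    truncated Neumann series sum_{n<=N} gamma^n T^n (N = ``n_terms``; at
    gamma = 0.95 the default truncation error ~7e-12 is below test
    tolerances). Rows of absorbing states (all-zero T rows) come out as
    one-hots; the terminal pseudo-state is implicit (mass simply exits).
    """
    T = np.asarray(T, dtype=float)
    n = T.shape[0]
    if T.shape != (n, n):
        raise ValueError("T must be square")
    if method == "inversion":
        return np.linalg.inv(np.eye(n) - gamma * T)
    if method == "series":
        M = np.eye(n)
        P = np.eye(n)
        for _ in range(n_terms):
            P = gamma * (P @ T)
            M += P
        return M
    raise ValueError(f"unknown method {method!r}")


def h_online_update(H: np.ndarray, sa: int, sa_next: int,
                    alpha_sr: float, gamma: float) -> np.ndarray:
    """On-policy TD update of the state-action successor matrix row.

    H(sa,:) <- H(sa,:) + alpha * [1_sa + gamma * H(s'a',:) - H(sa,:)], zero
    continuation when the successor state is terminal (pass ``TERMINAL``).
    """
    row = H[sa]
    if sa_next == sa:  # self-transition: continuation is the pre-update row
        row *= 1.0 - alpha_sr + alpha_sr * gamma
        row[sa] += alpha_sr
        return H
    row *= 1.0 - alpha_sr
    row[sa] += alpha_sr
    if sa_next != TERMINAL:
        row += (alpha_sr * gamma) * H[sa_next]
    return H


def h_offpolicy_replay_update(H: np.ndarray, w: np.ndarray, sa: int,
                              next_sa_candidates, alpha_sr: float,
                              gamma: float, rng) -> np.ndarray:
    """Off-policy (Q-learning-like) replay update of a stored sample.

    The continuation row is chosen greedily among the actions available in
    the sample's successor state: a'* = argmax_{a'} H(s'a',:) . w, ties
    broken uniformly with ``rng``. An empty candidate list (terminal or
    blocked successor) gives a zero continuation.
    """
    cands = list(next_sa_candidates)
    if not cands:
        return h_online_update(H, sa, TERMINAL, alpha_sr, gamma)
    if len(cands) == 1:
        best = cands[0]
    else:
        q = H[cands] @ w
        m = q.max()
        best_ix = [i for i, v in enumerate(q) if v >= m - 1e-12]
        best = cands[best_ix[rng.randrange(len(best_ix))]] \
            if len(best_ix) > 1 else cands[int(np.argmax(q))]
    return h_online_update(H, sa, best, alpha_sr, gamma)


def q_from_h(H: np.ndarray, w: np.ndarray) -> np.ndarray:
    """Decode state-action values Q = H w."""
    H = np.asarray(H)
    w = np.asarray(w)
    if H.shape[1] != w.shape[0]:
        raise ValueError(f"dimension mismatch: H is {H.shape}, w is {w.shape}")
    return H @ w


def export_matrix_csv(M: np.ndarray, labels, path) -> None:
    """Write a dense matrix as CSV with a header row/column of labels."""
    import pandas as pd

    labels = list(labels)
    pd.DataFrame(np.asarray(M), index=labels, columns=labels).to_csv(path)
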