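"""Independent reference implementations used only by the tests.

These are deliberately naive: dense matrices, explicit Python loops, and
exhaustive enumeration, written without reference to the package's
internals so that agreement is evidence and not tautology.
"""

from __future__ import annotations

import itertools

import numpy as np


def dense_round_matrix(A: np.ndarray, S: np.ndarray, beta: float,
                       gamma: float) -> np.ndarray:
    """One-round dense transfer matrix W1 @ W2 over the attribute nodes.

    W1 is the attribute-to-drug pass with deg^gamma receiver weighting;
    W2 the drug-to-attribute pass with class weights beta / 1-beta and
    deg^gamma shares within a class.  Degrees are total degrees in the
    union graph [A | S].
    """
    A = np.asarray(A, float)
    S = np.asarray(S, float)
    D, T = A.shape
    B = S.shape[1]
    n_attr = T + B
    deg_drug = A.sum(axis=1) + S.sum(axis=1)
    deg_attr = np.concatenate([A.sum(axis=0), S.sum(axis=0)])

    def attr_edge(u: int, v: int) -> float:
        return A[u, v] if v < T else S[u, v - T]

    W1 = np.zeros((n_attr, D))
    for v in range(n_attr):
        nbrs = [u for u in range(D) if attr_edge(u, v) > 0]
        tot = sum(deg_drug[u] ** gamma for u in nbrs)
        for u in nbrs:
            W1[v, u] = deg_drug[u] ** gamma / tot

    W2 = np.zeros((D, n_attr))
    for u in range(D):
        t_nbrs = [v for v in range(T) if A[u, v] > 0]
        b_nbrs = [T + v for v in range(B) if S[u, v] > 0]
        if t_nbrs and b_nbrs:
            wT, wB = beta, 1.0 - beta
        else:
            wT, wB = (1.0, 0.0) if t_nbrs else (0.0, 1.0)
        for nbrs, w in ((t_nbrs, wT), (b_nbrs, wB)):
            if not nbrs or w == 0.0:
                continue
            tot = sum(deg_attr[v] ** gamma for v in nbrs)
            for v in nbrs:
                W2[u, v] = w * deg_attr[v] ** gamma / tot

    return W1 @ W2


def dense_initial(A: np.ndarray, S: np.ndarray, alpha: float) -> np.ndarray:
    """Initial resource row per drug: alpha on targets, 1-alpha on bits."""
    A = np.asarray(A, float)
    S = np.asarray(S, float)
    D, T = A.shape
    B = S.shape[1]
    F0 = np.zeros((D, T + B))
    for u in range(D):
        t_nbrs = [v for v in range(T) if A[u, v] > 0]
        b_nbrs = [T + v for v in range(B) if S[u, v] > 0]
        if t_nbrs and b_nbrs:
            for v in t_nbrs:
                F0[u, v] = alpha / len(t_nbrs)
            for v in b_nbrs:
                F0[u, v] = (1.0 - alpha) / len(b_nbrs)
        elif t_nbrs:
            for v in t_nbrs:
                F0[u, v] = 1.0 / len(t_nbrs)
        else:
            for v in b_nbrs:
                F0[u, v] = 1.0 / len(b_nbrs)
    return F0


def dense_diffusion_scores(A: np.ndarray, S: np.ndarray, alpha: float,
                           beta: float, gamma: float, k: int) -> np.ndarray:
    """Target scores for every drug: f0 . (W1 W2)^k, dense and explicit."""
    T = np.asarray(A).shape[1]
    W = dense_round_matrix(A, S, beta, gamma)
    F = dense_initial(A, S, alpha)
    for _ in range(k):
        F = F @ W
    return F[:, :T]


def random_adjacency(rng: np.random.Generator, D: int, T: int, B: int,
                     p_dt: float = 0.25, p_db: float = 0.2):
    """Random binary A (D x T) and S (D x B) where every drug, every used
    target column and every used bit column has at least one edge."""
    A = (rng.random((D, T)) < p_dt).astype(float)
    S = (rng.random((D, B)) < p_db).astype(float)
    for u in range(D):  # no isolated drugs
        if A[u].sum() + S[u].sum() == 0:
            if rng.random() < 0.5 and T:
                A[u, rng.integers(T)] = 1.0
            else:
                S[u, rng.integers(B)] = 1.0
    A = A[:, A.sum(axis=0) > 0]
    S = S[:, S.sum(axis=0) > 0]
    return A, S


def hypergeom_upper_enumerated(k: int, K: int, n: int, N: int) -> float:
    """P(X >= k) by enumerating every size-n draw from an N-element urn
    whose first K elements are 'successes'."""
    hist = overlap_histogram(K, n, N)
    total = sum(hist)
    return sum(hist[i] for i in range(k, len(hist))) / total


def overlap_histogram(K: int, n: int, N: int) -> list[int]:
    """hist[i] = number of size-n subsets of range(N) with i elements < K."""
    hist = [0] * (min(K, n) + 1)
    for draw in itertools.combinations(range(N), n):
        hist[sum(1 for x in draw if x < K)] += 1
    return hist
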