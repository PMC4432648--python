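"""Exact continuous-time Markov chain oracle on tiny rings.

Enumerates all 3^N configurations of a 1-D ring (N <= 7), builds the exact
master-equation generator for the seven elementary processes with the
neighborhood-average rate convention (each neighbor-mediated event enters
with rate c_k times the eligible-neighbor fraction), and solves for the
stationary distribution.  Serves as a brute-force validator for the KMC
simulator and for quantifying the accuracy of the mean-field factorisation
<A_i B_j> ~ <A_i><B_j>.

Note on time units: the rejection KMC measures time in units of the total
rate sum, so its stationary occupancies — which are invariant under a global
time rescaling — are directly comparable to this chain's.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass

import numpy as np
from scipy import sparse
from scipy.sparse.csgraph import connected_components

from .model import M, S, X, ModelParams

__all__ = [
    "ChainSpec",
    "build_generator",
    "stationary_distribution",
    "moments",
    "Moments",
]


@dataclass(frozen=True)
class ChainSpec:
    """A tiny ring whose full configuration space is enumerable."""

    N: int
    params: ModelParams

    def __post_init__(self) -> None:
        if not 3 <= self.N <= 7:
            raise ValueError("ring length N must be in [3, 7]")
        if self.params.h % self.N == 0:
            raise ValueError("h must not be congruent to 0 modulo N")

    @property
    def n_states(self) -> int:
        return 3**self.N

    def state_digits(self) -> np.ndarray:
        """(3^N, N) array of per-site occupancy codes, index = base-3 word."""
        codes = np.arange(self.n_states)
        digits = np.empty((self.n_states, self.N), dtype=np.int8)
        for i in range(self.N - 1, -1, -1):
            digits[:, i] = codes % 3
            codes //= 3
        return digits

    def encode(self, config) -> int:
        idx = 0
        for c in config:
            idx = idx * 3 + int(c)
        return idx


def build_generator(spec: ChainSpec) -> sparse.csr_matrix:
    """Exact transition-rate matrix Q over all 3^N ring configurations.

    Off-diagonal Q[i, j] is the total rate of single-site events taking
    configuration i to j; the diagonal makes rows sum to zero.
    """
    p = spec.params
    n = spec.N
    h = p.h % n
    digits = spec.state_digits()
    pow3 = 3 ** np.arange(n - 1, -1, -1)

    rows, cols, vals = [], [], []
    for idx in range(spec.n_states):
        conf = digits[idx]
        for i in range(n):
            nb = (conf[(i - 1) % n], conf[(i + 1) % n])
            lr = (conf[(i - h) % n], conf[(i + h) % n])
            cur = conf[i]
            events: list[tuple[int, float]] = []
            if cur == S:
                if p.b_X > 0:
                    events.append((X, p.b_X))
                frac_lr_x = (lr[0] == X) * 0.5 + (lr[1] == X) * 0.5
                m_rate = p.b_M + p.l_X * frac_lr_x
                if m_rate > 0:
                    events.append((M, m_rate))
            elif cur == X:
                frac_nb_m = (nb[0] == M) * 0.5 + (nb[1] == M) * 0.5
                rate = p.d_X + p.s_M * frac_nb_m
                if rate > 0:
                    events.append((S, rate))
            else:
                frac_nb_x = (nb[0] == X) * 0.5 + (nb[1] == X) * 0.5
                rate = p.d_M + p.s_X * frac_nb_x
                if rate > 0:
                    events.append((S, rate))
            for new, rate in events:
                jdx = idx + (new - cur) * pow3[i]
                rows.append(idx)
                cols.append(jdx)
                vals.append(rate)

    q = sparse.coo_matrix((vals, (rows, cols)),
                          shape=(spec.n_states, spec.n_states)).tocsr()
    diag = -np.asarray(q.sum(axis=1)).ravel()
    if (diag > 1e-12).any():
        raise AssertionError("positive diagonal anomaly in generator")
    q = q + sparse.diags(diag)
    return q.tocsr()


def stationary_distribution(generator: sparse.spmatrix) -> np.ndarray:
    """Solve pi Q = 0, sum(pi) = 1; requires an irreducible chain.

    Raises on reducible chains, naming the closed (absorbing) communicating
    classes.  The returned vector satisfies ||pi Q||_inf <= 1e-12.
    """
    n = generator.shape[0]
    off = generator.copy().tolil()
    off.setdiag(0)
    n_comp, labels = connected_components(off.tocsr(), directed=True,
                                          connection="strong")
    if n_comp > 1:
        # a class is closed if no edge leaves it
        coo = off.tocoo()
        leaves = set(labels[coo.row[(labels[coo.row] != labels[coo.col])
                                    & (coo.data > 0)]])
        closed = sorted(set(range(n_comp)) - leaves)
        raise ValueError(
            f"chain is reducible ({n_comp} strong components; closed classes "
            f"{closed}): stationary distribution not unique"
        )
    a = generator.toarray().T
    a[-1, :] = 1.0
    b = np.zeros(n)
    b[-1] = 1.0
    pi = np.linalg.solve(a, b)
    residual = np.abs(pi @ generator.toarray()).max()
    if residual > 1e-12:
        # polish with one step of iterative refinement
        corr = np.linalg.lstsq(a, b - a @ pi, rcond=None)[0]
        pi = pi + corr
        residual = np.abs(pi @ generator.toarray()).max()
    if residual > 1e-12:
        raise RuntimeError(f"stationary residual {residual:.2e} exceeds 1e-12")
    return pi


@dataclass
class Moments:
    x_mean: np.ndarray            # <X_i> per site
    m_mean: np.ndarray            # <M_i> per site
    s_mean: np.ndarray            # <S_i> per site
    pair_xm_nn: np.ndarray        # <X_i M_{i+1}> per site
    pair_xs_lr: np.ndarray        # <X_i S_{i+h}> per site
    factorization_error: float    # max_ij |<X_i M_j> - <X_i><M_j>|


def moments(pi: np.ndarray, spec: ChainSpec) -> Moments:
    """Exact single-site and pair expectations under pi, plus the worst-case
    mean-field factorisation error over all (X_i, M_j) pairs."""
    digits = spec.state_digits()
    n = spec.N
    h = spec.params.h % n
    xi = (digits == X).astype(float)   # (n_states, N)
    mi = (digits == M).astype(float)
    si = (digits == S).astype(float)
    x_mean = pi @ xi
    m_mean = pi @ mi
    s_mean = pi @ si

    pair_xm_nn = np.array([pi @ (xi[:, i] * mi[:, (i + 1) % n]) for i in range(n)])
    pair_xs_lr = np.array([pi @ (xi[:, i] * si[:, (i + h) % n]) for i in range(n)])

    err = 0.0
    for i in range(n):
        for j in range(n):
            if i == j:
                continue
            joint = pi @ (xi[:, i] * mi[:, j])
            err = max(err, abs(joint - x_mean[i] * m_mean[j]))
    return Moments(x_mean, m_mean, s_mean, pair_xm_nn, pair_xs_lr, float(err))
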