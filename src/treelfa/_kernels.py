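"""JIT-compiled Gibbs sweep kernels.

All randomness is consumed from pre-generated uniform arrays so that every
draw is attributable to a single numpy PCG64 stream owned by the caller;
the kernels themselves are deterministic functions of their inputs.
"""

import numpy as np
from numba import njit


@njit(fastmath=True)
def z_sweep(W, Z, N, M1, Mtot, lik, alpha, u):
    """One systematic scan of the collapsed topic-assignment update.

    P(Z_ds = k | ...) ∝ (N_dk^{-ds} + alpha_k) * lik[s, W_ds, k], where
    lik[s, 1, k] = phi_ks and lik[s, 0, k] = 1 - phi_ks (clamped > 0 by the
    caller).  Count tables are maintained incrementally: N (D x K assignments
    per individual), Mtot (K x S assignments per code), M1 (K x S assignments
    with W = 1).
    """
    D, S = W.shape
    K = N.shape[1]
    cum = np.empty(K)
    t = 0
    for d in range(D):
        for s in range(S):
            w = W[d, s]
            k_old = Z[d, s]
            N[d, k_old] -= 1
            Mtot[k_old, s] -= 1
            if w == 1:
                M1[k_old, s] -= 1
            tot = 0.0
            for k in range(K):
                tot += (N[d, k] + alpha[k]) * lik[s, w, k]
                cum[k] = tot
            r = u[t] * tot
            t += 1
            k_new = 0
            while cum[k_new] < r:
                k_new += 1
            Z[d, s] = k_new
            N[d, k_new] += 1
            Mtot[k_new, s] += 1
            if w == 1:
                M1[k_new, s] += 1


@njit(fastmath=True)
def indicator_sweep(
    I, phi, code_of, parent, child_ptr, child_idx,
    a0, b0, lb0, a1, b1, lb1, rho01, rho11, u,
):
    """Single-site Gibbs update of all indicators, topic-major, in
    topological node order.

    The unnormalised weight of state i at a node combines the Beta density
    of the node's phi under prior i (code nodes only), the transition from
    the parent's state, and the transitions to each child's current state.
    Computed in log space for stability.
    """
    K, n = I.shape
    t = 0
    lw = np.empty(2)
    for k in range(K):
        for j in range(n):
            for i in range(2):
                acc = 0.0
                c = code_of[j]
                if c >= 0:
                    x = phi[k, c]
                    if i == 1:
                        acc += (a1 - 1.0) * np.log(x) + (b1 - 1.0) * np.log1p(-x) - lb1
                    else:
                        acc += (a0 - 1.0) * np.log(x) + (b0 - 1.0) * np.log1p(-x) - lb0
                ps = 0 if parent[j] < 0 else I[k, parent[j]]
                p1 = rho11 if ps == 1 else rho01
                acc += np.log(p1) if i == 1 else np.log1p(-p1)
                q1 = rho11 if i == 1 else rho01
                for cc in range(child_ptr[j], child_ptr[j + 1]):
                    if I[k, child_idx[cc]] == 1:
                        acc += np.log(q1)
                    else:
                        acc += np.log1p(-q1)
                lw[i] = acc
            m = lw[0] if lw[0] > lw[1] else lw[1]
            w0 = np.exp(lw[0] - m)
            w1 = np.exp(lw[1] - m)
            I[k, j] = 1 if u[t] * (w0 + w1) < w1 else 0
            t += 1


@njit(fastmath=True)
def lda_sweep(doc, word, z, n_dk, n_kw, n_k, alpha, eta, u):
    """One collapsed-Gibbs scan over the token list of the LDA baseline."""
    T = doc.shape[0]
    K = n_dk.shape[1]
    S = n_kw.shape[1]
    cum = np.empty(K)
    Seta = S * eta
    for t in range(T):
        d = doc[t]
        w = word[t]
        k_old = z[t]
        n_dk[d, k_old] -= 1
        n_kw[k_old, w] -= 1
        n_k[k_old] -= 1
        tot = 0.0
        for k in range(K):
            tot += (n_dk[d, k] + alpha[k]) * (n_kw[k, w] + eta) / (n_k[k] + Seta)
            cum[k] = tot
        r = u[t] * tot
        k_new = 0
        while cum[k_new] < r:
            k_new += 1
        z[t] = k_new
        n_dk[d, k_new] += 1
        n_kw[k_new, w] += 1
        n_k[k_new] += 1
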