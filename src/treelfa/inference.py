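"""Partially collapsed Gibbs sampling for tree-informed latent factor
allocation, Gibbs-EM optimisation of the Dirichlet concentration alpha, the
collapsed-Gibbs LDA baseline, and held-out topic-weight inference.

The topic-weight vectors theta are integrated out analytically
(Dirichlet-multinomial collapse), leaving per-variable topic assignments Z,
per-topic indicators I, code probabilities phi, and tree-transition
probabilities rho as the sampled state.  A full systematic scan updates
Z, then I, then phi, then rho.  Chains are independent given seeds derived
from a master seed; all randomness flows through numpy PCG64 generators.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, replace

import numpy as np
from scipy.special import betaln, psi

from . import _kernels
from .generative import DiagnosisMatrix, Hyperparams, TopicState
from .ontology import OntologyTree, flatten_tree

PHI_EPS = 1e-12  # keeps Bernoulli and Beta densities finite


def _as_seedseq(seed) -> np.random.SeedSequence:
    if isinstance(seed, np.random.SeedSequence):
        return seed
    return np.random.SeedSequence(seed)

__all__ = [
    "ChainSchedule",
    "ChainRun",
    "PosteriorSamples",
    "simulation_schedule",
    "reduced_schedule",
    "top100_schedule",
    "top436_schedule",
    "z_conditional",
    "sample_phi",
    "indicator_conditional",
    "sample_indicator",
    "sample_rho",
    "TreeLFASampler",
    "run_chain",
    "alpha_m_step",
    "gibbs_em",
    "infer_theta_heldout",
    "lda_run_chain",
]


# ---------------------------------------------------------------------------
# Schedules
# ---------------------------------------------------------------------------

@dataclass
class ChainSchedule:
    """Chain layout: burn-in, thinned sample collection and (optionally)
    the two Gibbs-EM stages, each a triple (EM iterations, Gibbs sweeps per
    E-step, Z samples collected per E-step)."""

    n_chains: int = 1
    burn_in: int = 1000
    n_samples: int = 10
    thin_interval: int = 20
    em_stage1: tuple[int, int, int] = (0, 0, 0)
    em_stage2: tuple[int, int, int] = (0, 0, 0)
    mode: str = "simulation"

    def __post_init__(self) -> None:
        counts = (self.n_chains, self.burn_in, self.n_samples, self.thin_interval,
                  *self.em_stage1, *self.em_stage2)
        if any(c < 0 for c in counts):
            raise ValueError("schedule counts must be >= 0")


def simulation_schedule() -> ChainSchedule:
    """Full-scale benchmark schedule: 10 chains, 15,000 burn-in, 20 samples
    per chain at a thinning interval of 100; alpha fixed at truth (no EM)."""
    return ChainSchedule(n_chains=10, burn_in=15_000, n_samples=20,
                         thin_interval=100, mode="simulation")


def reduced_schedule() -> ChainSchedule:
    """Desk-scale benchmark schedule: 2 chains, 3,000 burn-in, 10 samples
    per chain at a thinning interval of 20."""
    return ChainSchedule(n_chains=2, burn_in=3_000, n_samples=10,
                         thin_interval=20, mode="simulation")


def top100_schedule() -> ChainSchedule:
    """Real-data preset for ~100 codes: two-stage Gibbs-EM for alpha
    (2,000 x (20 sweeps, 1 sample), then 200 x (200 sweeps, 10 samples)),
    followed by 10 chains with 5,000 burn-in and 50 samples at interval 100."""
    return ChainSchedule(n_chains=10, burn_in=5_000, n_samples=50,
                         thin_interval=100, em_stage1=(2000, 20, 1),
                         em_stage2=(200, 200, 10), mode="real")


def top436_schedule() -> ChainSchedule:
    """Real-data preset for ~436 codes: Gibbs-EM stages of 1,500 and 350
    iterations, 3 chains, 50 samples at interval 200."""
    return ChainSchedule(n_chains=3, burn_in=5_000, n_samples=50,
                         thin_interval=200, em_stage1=(1500, 20, 1),
                         em_stage2=(350, 200, 10), mode="real")


# ---------------------------------------------------------------------------
# Posterior containers
# ---------------------------------------------------------------------------

@dataclass
class ChainRun:
    """Thinned posterior samples from one chain."""

    phi: np.ndarray     # (n_samples, K, S)
    I: np.ndarray       # (n_samples, K, n_nodes)
    rho: np.ndarray     # (n_samples, 2) — columns rho01, rho11
    N: np.ndarray       # (n_samples, D, K) assignment count tables
    seed: object = None

    def mean_phi(self) -> np.ndarray:
        return self.phi.mean(axis=0)


@dataclass
class PosteriorSamples:
    """Per-chain samples plus the alpha and schedule they were drawn under."""

    chains: list[ChainRun]
    alpha: np.ndarray
    schedule: ChainSchedule
    seed: object = None

    @property
    def n_chains(self) -> int:
        return len(self.chains)

    def all_phi(self) -> np.ndarray:
        """All phi samples pooled over chains, shape (total_samples, K, S)."""
        return np.concatenate([c.phi for c in self.chains], axis=0)

    def chain_labels(self) -> np.ndarray:
        return np.concatenate(
            [np.full(len(c.phi), i) for i, c in enumerate(self.chains)]
        )


# ---------------------------------------------------------------------------
# Single-site conditionals (reference implementations of the sweep kernels)
# ---------------------------------------------------------------------------

def z_conditional(N_minus: np.ndarray, alpha: np.ndarray, phi_col: np.ndarray,
                  w: int) -> np.ndarray:
    """Collapsed conditional P(Z_ds = k | Z^{-ds}, W, phi, alpha).

    ``N_minus`` are the individual's assignment counts excluding the current
    variable.  The conditional is (N_k^{-ds} + alpha_k) * phi_ks^w *
    (1-phi_ks)^(1-w), normalised.
    """
    phi_col = np.clip(np.asarray(phi_col, float), PHI_EPS, 1 - PHI_EPS)
    lik = phi_col if w == 1 else 1.0 - phi_col
    weights = (np.asarray(N_minus, float) + np.asarray(alpha, float)) * lik
    tot = weights.sum()
    if tot <= 0:
        raise FloatingPointError(
            "all-zero assignment weights; clamp phi away from {0,1}"
        )
    return weights / tot


def sample_phi(k: int, s: int, I_ks: int, Z: np.ndarray, W: np.ndarray,
               hyper: Hyperparams, rng) -> float:
    """Conjugate Beta draw for phi_ks given assignments and data:
    Beta(a_I + c1, b_I + c0) with c1/c0 the diagnosed/undiagnosed counts
    among variables of code s currently assigned to topic k."""
    a, b = hyper.beta_active if I_ks == 1 else hyper.beta_inactive
    assigned = Z[:, s] == k
    c1 = int(np.sum(W[assigned, s] == 1))
    c0 = int(assigned.sum()) - c1
    return rng.beta(a + c1, b + c0)


def indicator_conditional(k: int, node: int, I: np.ndarray, phi: np.ndarray,
                          rho: tuple[float, float], tree: OntologyTree,
                          hyper: Hyperparams) -> float:
    """P(I_{k,node} = 1 | everything else), from the Beta density of the
    node's phi (code nodes only), the parent transition and the child
    transitions."""
    rho01, rho11 = rho
    parent = tree.parent_index()
    code_of = {j: i for i, j in enumerate(tree.code_node_index())}
    logw = np.zeros(2)
    if node in code_of:
        x = float(np.clip(phi[k, code_of[node]], PHI_EPS, 1 - PHI_EPS))
        for i, (a, b) in enumerate([hyper.beta_inactive, hyper.beta_active]):
            logw[i] += (a - 1) * np.log(x) + (b - 1) * np.log1p(-x) - betaln(a, b)
    ps = 0 if parent[node] < 0 else int(I[k, parent[node]])
    p1 = rho11 if ps == 1 else rho01
    logw += np.log([1 - p1, p1])
    name = tree.nodes[node]
    for child in tree.children_of[name]:
        cs = int(I[k, tree.node_index[child]])
        for i, q1 in enumerate([rho01, rho11]):
            logw[i] += np.log(q1) if cs == 1 else np.log1p(-q1)
    logw -= logw.max()
    w = np.exp(logw)
    return float(w[1] / w.sum())


def sample_indicator(k: int, node: int, I: np.ndarray, phi: np.ndarray,
                     rho: tuple[float, float], tree: OntologyTree,
                     hyper: Hyperparams, rng) -> int:
    return int(rng.random() < indicator_conditional(k, node, I, phi, rho, tree, hyper))


def transition_counts(I: np.ndarray, tree: OntologyTree) -> np.ndarray:
    """Edge counts n[i, j] of parent-state-i -> child-state-j transitions,
    pooled over topics and edges; the root counts as state 0."""
    parent = np.asarray(tree.parent_index())
    parent_state = np.where(parent < 0, 0, I[:, np.maximum(parent, 0)])
    n = np.zeros((2, 2), dtype=np.int64)
    for i in range(2):
        for j in range(2):
            n[i, j] = int(np.sum((parent_state == i) & (I == j)))
    return n


def sample_rho(I: np.ndarray, tree: OntologyTree, hyper: Hyperparams,
               rng) -> tuple[float, float]:
    """Conjugate Beta draws for the tree-Markov transition probabilities."""
    n = transition_counts(I, tree)
    a01, b01 = hyper.rho01_prior
    a11, b11 = hyper.rho11_prior
    rho01 = rng.beta(a01 + n[0, 1], b01 + n[0, 0])
    rho11 = rng.beta(a11 + n[1, 1], b11 + n[1, 0])
    return float(rho01), float(rho11)


# ---------------------------------------------------------------------------
# The sampler
# ---------------------------------------------------------------------------

class TreeLFASampler:
    """Holds the mutable Gibbs state for one chain and performs sweeps.

    The flat-prior baseline (flatLFA) is this same sampler run on the
    flattened (star) tree; on a star no parent is ever active, so rho11 is
    drawn from its prior and never enters the likelihood.
    """

    def __init__(self, data: DiagnosisMatrix, tree: OntologyTree,
                 hyper: Hyperparams, rng, mode: str = "simulation"):
        if tree.n_codes != data.S:
            raise ValueError("tree code set does not match data columns")
        self.data = data
        self.tree = tree
        self.hyper = hyper
        self.rng = rng
        K, D, S = hyper.K, data.D, data.S
        self.W = np.ascontiguousarray(data.W, dtype=np.int8)

        # Static tree geometry for the kernels.
        self.parent = np.asarray(tree.parent_index(), dtype=np.int64)
        code_nodes = tree.code_node_index()
        self.code_of = np.full(tree.n_nodes, -1, dtype=np.int64)
        for ci, nj in enumerate(code_nodes):
            self.code_of[nj] = ci
        counts = np.zeros(tree.n_nodes + 1, dtype=np.int64)
        child_lists = [
            [tree.node_index[c] for c in tree.children_of[n]] for n in tree.nodes
        ]
        counts[1:] = [len(cl) for cl in child_lists]
        self.child_ptr = np.cumsum(counts)
        self.child_idx = np.asarray(
            [c for cl in child_lists for c in cl], dtype=np.int64
        )

        self.alpha = hyper.alpha.copy()
        self.I = np.zeros((K, tree.n_nodes), dtype=np.int8)
        a0, b0 = hyper.beta_inactive
        if mode == "simulation":
            self.phi = rng.beta(a0, b0, size=(K, S))
            self.Z = rng.integers(0, K, size=(D, S), dtype=np.int32)
        elif mode == "real":
            self.phi = rng.beta(1.0, 5e6, size=(K, S))
            self.Z = rng.integers(0, K, size=(D, S), dtype=np.int32)
            self.Z[self.W.sum(axis=1) == 0, :] = 0  # healthy -> empty topic
        else:
            raise ValueError(f"unknown mode: {mode!r}")
        self._rebuild_counts()
        self.rho01, self.rho11 = sample_rho(self.I, tree, hyper, rng)

    def _rebuild_counts(self) -> None:
        K = self.hyper.K
        D, S = self.W.shape
        self.N = np.zeros((D, K), dtype=np.int64)
        self.Mtot = np.zeros((K, S), dtype=np.int64)
        self.M1 = np.zeros((K, S), dtype=np.int64)
        for k in range(K):
            mask = self.Z == k
            self.N[:, k] = mask.sum(axis=1)
            self.Mtot[k] = mask.sum(axis=0)
            self.M1[k] = (mask & (self.W == 1)).sum(axis=0)

    # -- sweep components ---------------------------------------------------

    def sweep_z(self) -> None:
        phi_c = np.clip(self.phi, PHI_EPS, 1 - PHI_EPS)
        S, K = phi_c.shape[1], phi_c.shape[0]
        lik = np.empty((S, 2, K))
        lik[:, 1, :] = phi_c.T
        lik[:, 0, :] = 1.0 - phi_c.T
        u = self.rng.random(self.W.size)
        _kernels.z_sweep(self.W, self.Z, self.N, self.M1, self.Mtot,
                         lik, self.alpha, u)

    def sweep_indicators(self) -> None:
        a0, b0 = self.hyper.beta_inactive
        a1, b1 = self.hyper.beta_active
        phi_c = np.clip(self.phi, PHI_EPS, 1 - PHI_EPS)
        u = self.rng.random(self.I.size)
        _kernels.indicator_sweep(
            self.I, phi_c, self.code_of, self.parent,
            self.child_ptr, self.child_idx,
            a0, b0, float(betaln(a0, b0)), a1, b1, float(betaln(a1, b1)),
            self.rho01, self.rho11, u,
        )

    def sweep_phi(self) -> None:
        a0, b0 = self.hyper.beta_inactive
        a1, b1 = self.hyper.beta_active
        Icode = self.I[:, np.asarray(self.tree.code_node_index())]
        a = np.where(Icode == 1, a1, a0)
        b = np.where(Icode == 1, b1, b0)
        c1 = self.M1
        c0 = self.Mtot - self.M1
        self.phi = self.rng.beta(a + c1, b + c0)

    def sweep_rho(self) -> None:
        self.rho01, self.rho11 = sample_rho(self.I, self.tree, self.hyper, self.rng)

    def sweep(self) -> None:
        """One full systematic scan: Z, then I, then phi, then rho."""
        self.sweep_z()
        self.sweep_indicators()
        self.sweep_phi()
        self.sweep_rho()

    def check_counts(self) -> None:
        """Debug assertion that count tables are consistent with Z."""
        N, Mtot, M1 = self.N, self.Mtot, self.M1
        self._rebuild_counts()
        assert np.array_equal(N, self.N)
        assert np.array_equal(Mtot, self.Mtot)
        assert np.array_equal(M1, self.M1)

    def snapshot(self):
        return (self.phi.copy(), self.I.copy(),
                np.array([self.rho01, self.rho11]), self.N.copy())

    def topic_state(self) -> TopicState:
        return TopicState(I=self.I.copy(), phi=self.phi.copy(),
                          rho01=self.rho01, rho11=self.rho11)


def gibbs_sweep(sampler: TreeLFASampler) -> TreeLFASampler:
    """Functional alias for one full systematic scan."""
    sampler.sweep()
    return sampler


def _run_single_chain(data, tree, hyper, schedule, rng, seed_tag=None,
                      alpha=None) -> ChainRun:
    sampler = TreeLFASampler(data, tree, hyper, rng, mode=schedule.mode)
    if alpha is not None:
        sampler.alpha = np.asarray(alpha, dtype=float)
    for _ in range(schedule.burn_in):
        sampler.sweep()
    phis, Is, rhos, Ns = [], [], [], []
    for _ in range(schedule.n_samples):
        for _ in range(max(schedule.thin_interval, 1)):
            sampler.sweep()
        phi, I, rho, N = sampler.snapshot()
        phis.append(phi)
        Is.append(I)
        rhos.append(rho)
        Ns.append(N.astype(np.int32))
    empty = lambda shape: np.empty((0, *shape))
    K, S, n = hyper.K, data.S, tree.n_nodes
    return ChainRun(
        phi=np.stack(phis) if phis else empty((K, S)),
        I=np.stack(Is) if Is else empty((K, n)),
        rho=np.stack(rhos) if rhos else empty((2,)),
        N=np.stack(Ns) if Ns else empty((data.D, K)),
        seed=seed_tag,
    )


def run_chain(data: DiagnosisMatrix, tree: OntologyTree, hyper: Hyperparams,
              schedule: ChainSchedule, seed, alpha=None) -> PosteriorSamples:
    """Run ``schedule.n_chains`` independent chains; per-chain generators are
    spawned from the master seed so chain results do not depend on execution
    order or thread count."""
    ss = _as_seedseq(seed)
    children = ss.spawn(schedule.n_chains)
    chains = [
        _run_single_chain(data, tree, hyper, schedule,
                          np.random.default_rng(child), seed_tag=str(child),
                          alpha=alpha)
        for child in children
    ]
    final_alpha = np.asarray(alpha, float) if alpha is not None else hyper.alpha.copy()
    return PosteriorSamples(chains=chains, alpha=final_alpha,
                            schedule=schedule, seed=seed)


# ---------------------------------------------------------------------------
# Gibbs-EM for alpha
# ---------------------------------------------------------------------------

def alpha_m_step(count_samples, alpha_init, floor: float = 1e-4,
                 tol: float = 1e-8, max_iter: int = 1000) -> np.ndarray:
    """Maximise the Dirichlet-multinomial log-likelihood of assignment-count
    tables over alpha by fixed-point iteration (Minka's update):

        alpha_k <- alpha_k * sum_{m,d} [psi(N_dk + alpha_k) - psi(alpha_k)]
                           / sum_{m,d} [psi(N_d + A) - psi(A)],  A = sum alpha

    All collected Z samples enter one joint likelihood.  Entries are floored
    at ``floor`` to keep the Dirichlet proper.
    """
    N = np.concatenate([np.asarray(m, dtype=float) for m in count_samples], axis=0)
    row_tot = N.sum(axis=1)
    alpha = np.maximum(np.asarray(alpha_init, dtype=float).copy(), floor)
    for _ in range(max_iter):
        A = alpha.sum()
        num = (psi(N + alpha) - psi(alpha)).sum(axis=0)
        den = (psi(row_tot + A) - psi(A)).sum()
        new = np.maximum(alpha * num / den, floor)
        if np.max(np.abs(new - alpha)) < tol:
            return new
        alpha = new
    warnings.warn("alpha fixed-point iteration did not converge; "
                  "returning last iterate")
    return alpha


def gibbs_em(data: DiagnosisMatrix, tree: OntologyTree, hyper: Hyperparams,
             schedule: ChainSchedule, seed):
    """Two-stage Gibbs-EM for alpha followed by final posterior sampling.

    Each E-step advances one Gibbs chain by the stage's sweep count and
    collects the stated number of Z count tables (evenly spaced); the M-step
    re-optimises alpha on them.  Final sampling then runs ``run_chain`` with
    alpha fixed at the optimum.
    """
    ss = _as_seedseq(seed)
    em_seed, final_seed = ss.spawn(2)
    rng = np.random.default_rng(em_seed)
    sampler = TreeLFASampler(data, tree, hyper, rng, mode=schedule.mode)
    alpha = sampler.alpha.copy()
    for n_iter, n_sweeps, n_z in (schedule.em_stage1, schedule.em_stage2):
        if n_iter == 0 or n_sweeps == 0 or n_z == 0:
            continue
        stride = max(n_sweeps // n_z, 1)
        for _ in range(n_iter):
            tables = []
            done = 0
            for j in range(n_z):
                for _ in range(min(stride, n_sweeps - done)):
                    sampler.sweep()
                    done += 1
                tables.append(sampler.N.copy())
            alpha = alpha_m_step(tables, alpha)
            sampler.alpha = alpha
    samples = run_chain(data, tree, hyper, schedule, final_seed, alpha=alpha)
    return alpha, samples


# ---------------------------------------------------------------------------
# Held-out topic weights
# ---------------------------------------------------------------------------

def infer_theta_heldout(data_test: DiagnosisMatrix, phi_fixed: np.ndarray,
                        alpha_fixed, schedule: ChainSchedule, seed) -> np.ndarray:
    """Posterior-mean topic weights for held-out individuals with phi and
    alpha fixed at training values: Gibbs over Z only, theta recovered from
    count tables and averaged over chains and samples."""
    from .postprocess import theta_from_counts

    phi = np.clip(np.asarray(phi_fixed, dtype=float), PHI_EPS, 1 - PHI_EPS)
    K, S = phi.shape
    alpha = np.broadcast_to(np.atleast_1d(np.asarray(alpha_fixed, float)), (K,)).copy()
    W = np.ascontiguousarray(data_test.W, dtype=np.int8)
    D = W.shape[0]
    lik = np.empty((S, 2, K))
    lik[:, 1, :] = phi.T
    lik[:, 0, :] = 1.0 - phi.T

    ss = _as_seedseq(seed)
    theta_acc = np.zeros((D, K))
    n_acc = 0
    for child in ss.spawn(schedule.n_chains):
        rng = np.random.default_rng(child)
        Z = rng.integers(0, K, size=(D, S), dtype=np.int32)
        N = np.stack([(Z == k).sum(axis=1) for k in range(K)], axis=1).astype(np.int64)
        M1 = np.zeros((K, S), dtype=np.int64)
        Mtot = np.zeros((K, S), dtype=np.int64)  # unused by theta; kept consistent
        for k in range(K):
            Mtot[k] = (Z == k).sum(axis=0)
            M1[k] = ((Z == k) & (W == 1)).sum(axis=0)
        for _ in range(schedule.burn_in):
            _kernels.z_sweep(W, Z, N, M1, Mtot, lik, alpha, rng.random(W.size))
        for i in range(schedule.n_samples):
            for _ in range(max(schedule.thin_interval, 1)):
                _kernels.z_sweep(W, Z, N, M1, Mtot, lik, alpha, rng.random(W.size))
            theta_acc += theta_from_counts(N, alpha)
            n_acc += 1
    return theta_acc / max(n_acc, 1)


# ---------------------------------------------------------------------------
# LDA baseline
# ---------------------------------------------------------------------------

def lda_run_chain(data: DiagnosisMatrix, K: int, alpha, eta: float,
                  schedule: ChainSchedule, seed) -> PosteriorSamples:
    """Collapsed-Gibbs LDA over the bag of diagnosed codes.

    Individuals with no diagnoses carry no tokens and are excluded (with a
    warning).  Posterior topic samples are the smoothed empirical
    distributions (n_kw + eta) / (n_k + S*eta); topics are points on the
    S-simplex, unlike the Bernoulli topics of the tree model.
    """
    W = np.asarray(data.W)
    D, S = W.shape
    keep = W.sum(axis=1) > 0
    if not keep.all():
        warnings.warn(f"excluding {int((~keep).sum())} individuals with no "
                      "diagnosed codes from LDA")
    rows, cols = np.nonzero(W[keep])
    doc = rows.astype(np.int64)
    word = cols.astype(np.int64)
    n_docs = int(keep.sum())
    alpha = np.broadcast_to(np.atleast_1d(np.asarray(alpha, float)), (K,)).copy()

    ss = _as_seedseq(seed)
    chains = []
    for child in ss.spawn(schedule.n_chains):
        rng = np.random.default_rng(child)
        z = rng.integers(0, K, size=doc.size, dtype=np.int64)
        n_dk = np.zeros((n_docs, K), dtype=np.int64)
        n_kw = np.zeros((K, S), dtype=np.int64)
        n_k = np.zeros(K, dtype=np.int64)
        np.add.at(n_dk, (doc, z), 1)
        np.add.at(n_kw, (z, word), 1)
        np.add.at(n_k, z, 1)

        def sweep():
            _kernels.lda_sweep(doc, word, z, n_dk, n_kw, n_k, alpha,
                               float(eta), rng.random(doc.size))

        for _ in range(schedule.burn_in):
            sweep()
        phis, Ns = [], []
        for i in range(schedule.n_samples):
            for _ in range(max(schedule.thin_interval, 1)):
                sweep()
            phis.append((n_kw + eta) / (n_k + S * eta)[:, None])
            full_N = np.zeros((D, K), dtype=np.int32)
            full_N[keep] = n_dk
            Ns.append(full_N)
        chains.append(ChainRun(
            phi=np.stack(phis) if phis else np.empty((0, K, S)),
            I=np.empty((len(phis), 0, 0)),
            rho=np.empty((len(phis), 0)),
            N=np.stack(Ns) if Ns else np.empty((0, D, K)),
            seed=str(child),
        ))
    return PosteriorSamples(chains=chains, alpha=alpha,
                            schedule=schedule, seed=seed)


# ---------------------------------------------------------------------------
# Convenience front door
# ---------------------------------------------------------------------------

def fit(data: DiagnosisMatrix, tree: OntologyTree, model: str,
        hyper: Hyperparams, schedule: ChainSchedule, seed,
        alpha=None):
    """Train one of the three models; ``flatlfa`` flattens the tree and
    switches to the flat rho01 prior if the caller has not overridden it."""
    if model == "treelfa":
        return run_chain(data, tree, hyper, schedule, seed, alpha=alpha)
    if model == "flatlfa":
        flat_hyper = replace(hyper, rho01_prior=(7.0, 20.0)) \
            if hyper.rho01_prior == (4.8, 20.0) else hyper
        return run_chain(data, flatten_tree(tree), flat_hyper, schedule,
                         seed, alpha=alpha)
    if model == "lda":
        return lda_run_chain(data, hyper.K, alpha if alpha is not None
                             else hyper.alpha, hyper.eta, schedule, seed)
    raise ValueError(f"unknown model: {model!r}")
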