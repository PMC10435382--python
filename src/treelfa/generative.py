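"""The treeLFA probability model and its simulator.

The model factorises the D x S Bernoulli probability matrix of a binary
diagnosis matrix W into a K x S topic matrix phi (each entry a per-code
Bernoulli probability) and a D x K topic-weight matrix theta:

    theta_d ~ Dirichlet(alpha)
    Z_ds    ~ Categorical(theta_d)
    W_ds    ~ Bernoulli(phi[Z_ds, s])

Topics get a structured spike-and-slab prior: a Markov process run from the
root of the disease-ontology tree assigns each node a binary indicator I
(active/inactive) with transitions rho01 = P(I=1 | parent inactive) and
rho11 = P(I=1 | parent active); phi for active codes is drawn from one Beta
prior, for inactive codes from another (much sparser) one.  Small rho01 with
large rho11 yields sparse topics whose active codes cluster on branches of
the ontology.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
import scipy.io
import scipy.sparse

from .ontology import OntologyTree

__all__ = [
    "Hyperparams",
    "TopicState",
    "DiagnosisMatrix",
    "sim_hyperparams",
    "top100_hyperparams",
    "top436_hyperparams",
    "sample_topics_from_prior",
    "make_sim_topics",
    "simulate_dataset",
]


@dataclass
class Hyperparams:
    """Prior hyperparameters of the model.

    ``beta_active``/``beta_inactive`` are the Beta(a, b) priors on phi for
    active/inactive codes; ``rho01_prior``/``rho11_prior`` the Beta priors on
    the tree-Markov transition probabilities; ``alpha`` the Dirichlet
    concentration over the K topic weights; ``eta`` the Dirichlet
    concentration of the LDA baseline's topics.
    """

    K: int
    alpha: np.ndarray
    beta_active: tuple[float, float] = (2.0, 4.0)
    beta_inactive: tuple[float, float] = (0.3, 80.0)
    rho01_prior: tuple[float, float] = (4.8, 20.0)
    rho11_prior: tuple[float, float] = (20.0, 4.8)
    eta: float = 0.01

    def __post_init__(self) -> None:
        self.alpha = np.atleast_1d(np.asarray(self.alpha, dtype=float))
        if self.alpha.size == 1:
            self.alpha = np.full(self.K, float(self.alpha[0]))
        if self.alpha.size != self.K:
            raise ValueError("alpha must be scalar or length K")
        pairs = [
            self.alpha,
            self.beta_active,
            self.beta_inactive,
            self.rho01_prior,
            self.rho11_prior,
            (self.eta,),
        ]
        if any(np.any(np.asarray(p, dtype=float) <= 0) for p in pairs):
            raise ValueError("all hyperparameters must be strictly positive")

    def with_alpha(self, alpha) -> "Hyperparams":
        return replace(self, alpha=np.asarray(alpha, dtype=float))


def sim_hyperparams(K: int = 4, alpha=1.0, flat: bool = False) -> Hyperparams:
    """Simulation-study preset: phi ~ Beta(2,4)/Beta(0.3,80); tree-prior
    rho01 ~ Beta(4.8,20), rho11 ~ Beta(20,4.8); on a flat (star) tree
    rho01 ~ Beta(7,20), tuned to the same expected number of active codes."""
    hp = Hyperparams(K=K, alpha=np.asarray(alpha, dtype=float))
    if flat:
        hp = replace(hp, rho01_prior=(7.0, 20.0))
    return hp


def top100_hyperparams(K: int = 11, alpha=None) -> Hyperparams:
    """Preset for real diagnosis data of ~100 common codes."""
    if alpha is None:
        alpha = np.r_[1.0, np.full(K - 1, 0.1)]
    return Hyperparams(
        K=K, alpha=alpha, rho01_prior=(3.0, 20.0), rho11_prior=(3.0, 3.0)
    )


def top436_hyperparams(K: int = 100, alpha=None) -> Hyperparams:
    """Preset for larger code sets with rare diseases (sparser phi priors)."""
    if alpha is None:
        alpha = np.r_[1.0, np.full(K - 1, 0.1)]
    return Hyperparams(
        K=K,
        alpha=alpha,
        beta_active=(1.2, 3.0),
        beta_inactive=(0.1, 3000.0),
        rho01_prior=(3.0, 20.0),
        rho11_prior=(3.0, 3.0),
    )


@dataclass
class TopicState:
    """Topic-side latent state: indicators, probabilities, transitions.

    ``I`` is K x n_nodes over all non-root tree nodes (column order =
    ``tree.nodes``); ``phi`` is K x S over observed codes (column order =
    ``tree.code_order``).
    """

    I: np.ndarray
    phi: np.ndarray
    rho01: float
    rho11: float

    def __post_init__(self) -> None:
        self.I = np.asarray(self.I, dtype=np.int8)
        self.phi = np.asarray(self.phi, dtype=float)
        if np.any(self.phi < 0) or np.any(self.phi > 1):
            raise ValueError("phi entries must lie in [0, 1]")

    @property
    def K(self) -> int:
        return self.phi.shape[0]

    @property
    def S(self) -> int:
        return self.phi.shape[1]


@dataclass
class DiagnosisMatrix:
    """A binary individual x disease-code matrix with identifiers."""

    W: np.ndarray
    individual_ids: list[str] = field(default_factory=list)
    code_ids: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        W = np.asarray(self.W)
        if not np.isin(W, (0, 1)).all():
            raise ValueError("diagnosis matrix entries must be 0/1")
        self.W = W.astype(np.int8)
        if not self.individual_ids:
            self.individual_ids = [f"ind{i}" for i in range(self.W.shape[0])]
        if not self.code_ids:
            self.code_ids = [f"code{j}" for j in range(self.W.shape[1])]

    @property
    def D(self) -> int:
        return self.W.shape[0]

    @property
    def S(self) -> int:
        return self.W.shape[1]

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.W, index=self.individual_ids, columns=self.code_ids)

    def save_tsv(self, path) -> None:
        self.to_frame().to_csv(path, sep="\t", index_label="individual")

    @classmethod
    def load_tsv(cls, path) -> "DiagnosisMatrix":
        df = pd.read_csv(path, sep="\t", index_col=0)
        return cls(df.to_numpy(), list(df.index.astype(str)), list(df.columns))

    def save_mtx(self, prefix) -> None:
        """Write ``<prefix>.mtx`` plus sidecar ``.individuals``/``.codes``."""
        scipy.io.mmwrite(f"{prefix}.mtx", scipy.sparse.coo_matrix(self.W))
        for ext, ids in ((".individuals", self.individual_ids), (".codes", self.code_ids)):
            with open(f"{prefix}{ext}", "wt", encoding="utf-8") as fh:
                fh.write("\n".join(ids) + "\n")

    @classmethod
    def load_mtx(cls, prefix) -> "DiagnosisMatrix":
        W = np.asarray(scipy.io.mmread(f"{prefix}.mtx").todense())
        ids = []
        for ext in (".individuals", ".codes"):
            with open(f"{prefix}{ext}", "rt", encoding="utf-8") as fh:
                ids.append(fh.read().split())
        return cls(W, ids[0], ids[1])


def sample_topics_from_prior(
    tree: OntologyTree, hyper: Hyperparams, seed=None
) -> TopicState:
    """Draw a TopicState from the structured prior.

    rho01/rho11 are drawn once (shared across topics and edges); per topic
    the indicators are swept root-to-leaf with the root's latent state fixed
    at 0, then phi for code nodes is drawn from the active or inactive Beta
    prior according to the node's indicator.
    """
    rng = np.random.default_rng(seed)
    rho01 = rng.beta(*hyper.rho01_prior)
    rho11 = rng.beta(*hyper.rho11_prior)
    parent = np.asarray(tree.parent_index())
    K, n = hyper.K, tree.n_nodes
    I = np.zeros((K, n), dtype=np.int8)
    for k in range(K):
        for j in range(n):  # topological order: parent state already drawn
            p_active = rho01 if parent[j] < 0 or I[k, parent[j]] == 0 else rho11
            I[k, j] = rng.random() < p_active
    code_idx = np.asarray(tree.code_node_index())
    a1, b1 = hyper.beta_active
    a0, b0 = hyper.beta_inactive
    Icode = I[:, code_idx]
    phi = np.where(
        Icode == 1,
        rng.beta(a1, b1, size=Icode.shape),
        rng.beta(a0, b0, size=Icode.shape),
    )
    return TopicState(I=I, phi=phi, rho01=rho01, rho11=rho11)


def make_sim_topics(
    tree: OntologyTree, setting: str = "correct_prior", active_prob: float = 0.5
) -> TopicState:
    """The four hand-constructed benchmark topics on the 20-code tree.

    ``correct_prior``: topics 1-3 each activate one branch (a second-layer
    node plus its three children, 4 codes); topic 4 activates two full
    branches (8 codes) — an arrangement a sparse tree-Markov prior favours.

    ``incorrect_prior``: same per-topic active-code counts, but active codes
    are chosen so that no parent-child pair is ever jointly active (active
    parents have inactive children and vice versa), deliberately clashing
    with the tree prior.

    Active codes get phi = ``active_prob`` (the heatmap's single non-zero
    level, a documented constant), inactive codes get phi = 0.
    """
    if not (0 < active_prob <= 1):
        raise ValueError("active_prob must be in (0, 1]")
    branch = {i: [f"N{i}"] + [f"N{i}-{j}" for j in range(1, 4)] for i in range(1, 6)}
    if setting == "correct_prior":
        active = [branch[1], branch[2], branch[3], branch[4] + branch[5]]
    elif setting == "incorrect_prior":
        children = {i: branch[i][1:] for i in range(1, 6)}
        active = [
            ["N1"] + children[2],
            ["N3"] + children[4],
            ["N5"] + children[1],
            ["N2", "N4"] + children[3] + children[5],
        ]
    else:
        raise ValueError(f"unknown topic setting: {setting!r}")

    K, S = 4, tree.n_codes
    phi = np.zeros((K, S))
    I = np.zeros((K, tree.n_nodes), dtype=np.int8)
    for k, codes in enumerate(active):
        for c in codes:
            phi[k, tree.code_index[c]] = active_prob
            I[k, tree.node_index[c]] = 1
    return TopicState(I=I, phi=phi, rho01=0.1, rho11=0.9)


def simulate_dataset(
    topics: TopicState, alpha, D: int, seed=None, code_ids=None
):
    """Simulate a diagnosis matrix from the generative process.

    Returns ``(DiagnosisMatrix, theta_true, Z_true)``; deterministic given
    ``seed`` (PCG64).  ``alpha`` may be a scalar (symmetric Dirichlet) or a
    length-K vector.
    """
    if D < 1:
        raise ValueError("D must be >= 1")
    rng = np.random.default_rng(seed)
    K, S = topics.K, topics.S
    alpha = np.broadcast_to(np.atleast_1d(np.asarray(alpha, float)), (K,))
    theta = rng.dirichlet(alpha, size=D)
    # Vectorised categorical draw via inverse-CDF on per-row cumulative theta.
    cum = np.cumsum(theta, axis=1)
    u = rng.random((D, S))
    Z = (u[:, :, None] > cum[:, None, :]).sum(axis=2).astype(np.int32)
    W = (rng.random((D, S)) < topics.phi[Z, np.arange(S)]).astype(np.int8)
    data = DiagnosisMatrix(W, code_ids=list(code_ids) if code_ids else [])
    return data, theta, Z
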