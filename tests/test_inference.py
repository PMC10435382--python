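import numpy as np
import pytest
from scipy import stats

from treelfa import (
    DiagnosisMatrix,
    Hyperparams,
    build_sim_tree,
    flatten_tree,
    make_sim_topics,
    sim_hyperparams,
    simulate_dataset,
)
from treelfa.inference import (
    ChainSchedule,
    TreeLFASampler,
    alpha_m_step,
    fit,
    indicator_conditional,
    infer_theta_heldout,
    lda_run_chain,
    run_chain,
    sample_phi,
    sample_rho,
    transition_counts,
    z_conditional,
)
from treelfa.postprocess import theta_from_counts


class TestZConditional:
    def test_single_topic(self):
        p = z_conditional([5], [0.1], [0.4], 1)
        assert p == pytest.approx([1.0])

    def test_symmetry(self):
        p = z_conditional([2, 2], [0.5, 0.5], [0.3, 0.3], 0)
        assert p == pytest.approx([0.5, 0.5])

    def test_worked_example(self):
        # (N + alpha) * phi^w: (2.1*0.5, 0.1*0.9) = (1.05, 0.09)
        p = z_conditional([2, 0], [0.1, 0.1], [0.5, 0.9], 1)
        assert p == pytest.approx([1.05 / 1.14, 0.09 / 1.14], abs=1e-4)

    def test_absence_uses_one_minus_phi(self):
        p = z_conditional([0, 0], [1.0, 1.0], [0.9, 0.1], 0)
        assert p == pytest.approx([0.1 / 1.0, 0.9 / 1.0], abs=1e-12)


class TestSamplePhi:
    def test_no_assignments_prior_draw(self, sim_hyper, rng):
        Z = np.zeros((10, 2), dtype=int)  # everything assigned to topic 0
        W = np.ones((10, 2), dtype=int)
        draws = [
            sample_phi(1, 0, 1, Z, W, sim_hyper, np.random.default_rng(s))
            for s in range(4000)
        ]
        # prior Beta(2, 4) mean 1/3
        assert np.mean(draws) == pytest.approx(2 / 6, abs=0.01)

    def test_posterior_beta_parameters(self, rng):
        hyper = Hyperparams(K=1, alpha=1.0, beta_active=(2.0, 4.0))
        Z = np.zeros((10, 1), dtype=int)
        W = np.ones((10, 1), dtype=int)  # c1=10, c0=0 -> Beta(12, 4)
        draws = [
            sample_phi(0, 0, 1, Z, W, hyper, np.random.default_rng(s))
            for s in range(4000)
        ]
        assert np.mean(draws) == pytest.approx(12 / 16, abs=0.01)

    def test_concentration_at_empirical_rate(self):
        hyper = Hyperparams(K=1, alpha=1.0)
        D = 20_000
        W = np.r_[np.ones(15_000), np.zeros(5_000)].astype(int)[:, None]
        Z = np.zeros((D, 1), dtype=int)
        d = sample_phi(0, 0, 1, Z, W, hyper, np.random.default_rng(0))
        assert d == pytest.approx(0.75, abs=0.02)


class TestSampleIndicator:
    def test_hand_computed_leaf(self):
        """Leaf code with inactive parent: P(I=1) equals
        rho01*Beta(phi;a1,b1) / [rho01*Beta(phi;a1,b1) + (1-rho01)*Beta(phi;a0,b0)]."""
        tree = build_sim_tree()
        hyper = Hyperparams(K=1, alpha=1.0, beta_active=(2, 4),
                            beta_inactive=(0.3, 80))
        phi_val, rho01 = 0.01, 0.2
        node = tree.node_index["N1-1"]
        I = np.zeros((1, tree.n_nodes), dtype=np.int8)
        phi = np.full((1, 20), phi_val)
        got = indicator_conditional(0, node, I, phi, (rho01, 0.8), tree, hyper)
        f1 = stats.beta.pdf(phi_val, 2, 4)
        f0 = stats.beta.pdf(phi_val, 0.3, 80)
        expected = rho01 * f1 / (rho01 * f1 + (1 - rho01) * f0)
        assert got == pytest.approx(expected, rel=1e-9)

    def test_equal_transitions_depend_on_phi_only(self):
        """With rho01 = rho11 the Markov factors cancel for childless nodes."""
        tree = build_sim_tree()
        hyper = sim_hyperparams(K=1)
        node = tree.node_index["N2-3"]
        phi = np.full((1, 20), 0.3)
        for parent_state in (0, 1):
            I = np.zeros((1, tree.n_nodes), dtype=np.int8)
            I[0, tree.node_index["N2"]] = parent_state
            p = indicator_conditional(0, node, I, phi, (0.4, 0.4), tree, hyper)
            f1 = stats.beta.pdf(0.3, 2, 4)
            f0 = stats.beta.pdf(0.3, 0.3, 80)
            assert p == pytest.approx(0.4 * f1 / (0.4 * f1 + 0.6 * f0), rel=1e-9)

    def test_internal_noncode_node_prefers_inactive(self):
        """A non-code internal node with inactive parent and children and a
        small rho01 has P(I=1) < 0.5."""
        from treelfa.ontology import parse_tree

        tree = parse_tree(
            [("block", "root"), ("a", "block"), ("b", "block")], codes=["a", "b"]
        )
        hyper = sim_hyperparams(K=1)
        I = np.zeros((1, 3), dtype=np.int8)
        phi = np.full((1, 2), 0.01)
        p = indicator_conditional(
            0, tree.node_index["block"], I, phi, (0.1, 0.8), tree, hyper
        )
        assert p < 0.5


class TestSampleRho:
    def test_prior_means_without_data(self, sim_tree, sim_hyper):
        draws11 = []
        flat = flatten_tree(sim_tree)
        I_flat = np.zeros((4, flat.n_nodes), dtype=np.int8)
        for s in range(3000):
            r01, r11 = sample_rho(I_flat, flat, sim_hyper,
                                  np.random.default_rng(s))
            draws11.append(r11)
        # flat star: no active parents -> rho11 drawn from its prior Beta(20,4.8)
        assert np.mean(draws11) == pytest.approx(20 / 24.8, abs=0.01)

    def test_transition_counts_all_inactive(self, sim_tree):
        I = np.zeros((4, sim_tree.n_nodes), dtype=np.int8)
        n = transition_counts(I, sim_tree)
        assert n[0, 0] == 4 * 20  # K * edges
        assert n[0, 1] == n[1, 0] == n[1, 1] == 0

    def test_transition_counts_full_branch(self, sim_tree, correct_topics):
        n = transition_counts(correct_topics.I, sim_tree)
        # correct-prior topics: active branches are parent+children blocks
        # topic k activates b_k branches: edges root->parent active = b_k
        assert n[0, 1] == 3 + 2  # five active branch roots over 4 topics...
        # (3 single-branch topics + 1 two-branch topic = 5 root->active edges)
        assert n[1, 1] == 5 * 3  # each active parent has 3 active children
        assert n[1, 0] == 0

    def test_rho_posterior_recovery_with_fixed_indicators(self):
        """With I fixed at a large simulated truth, the conjugate posterior
        means of rho01/rho11 sit within 3 posterior SDs of the truth."""
        from treelfa.ontology import parse_tree

        rows = [(f"p{i}", "root") for i in range(100)]
        rows += [(f"p{i}-c{j}", f"p{i}") for i in range(100) for j in range(9)]
        tree = parse_tree(rows)
        hyper = sim_hyperparams(K=8)
        true01, true11 = 0.2, 0.8
        rng = np.random.default_rng(5)
        parent = np.asarray(tree.parent_index())
        I = np.zeros((8, tree.n_nodes), dtype=np.int8)
        for k in range(8):
            for j in range(tree.n_nodes):
                pa = 0 if parent[j] < 0 else I[k, parent[j]]
                pr = true11 if pa == 1 else true01
                I[k, j] = rng.random() < pr
        n = transition_counts(I, tree)
        a01, b01 = hyper.rho01_prior
        a11, b11 = hyper.rho11_prior
        post01 = stats.beta(a01 + n[0, 1], b01 + n[0, 0])
        post11 = stats.beta(a11 + n[1, 1], b11 + n[1, 0])
        assert abs(post01.mean() - true01) < 3 * post01.std()
        assert abs(post11.mean() - true11) < 3 * post11.std()


class TestSweepMechanics:
    def test_counts_stay_consistent(self, small_dataset, sim_tree, sim_hyper):
        data, _, _ = small_dataset
        s = TreeLFASampler(data, sim_tree, sim_hyper,
                           np.random.default_rng(0))
        for _ in range(3):
            s.sweep()
        s.check_counts()  # raises on inconsistency
        assert (s.N.sum(axis=1) == data.S).all()

    def test_deterministic_given_seed(self, small_dataset, sim_tree, sim_hyper):
        data, _, _ = small_dataset
        out = []
        for _ in range(2):
            s = TreeLFASampler(data, sim_tree, sim_hyper,
                               np.random.default_rng(99))
            for _ in range(5):
                s.sweep()
            out.append((s.phi.copy(), s.Z.copy(), s.I.copy()))
        assert np.array_equal(out[0][0], out[1][0])
        assert np.array_equal(out[0][1], out[1][1])
        assert np.array_equal(out[0][2], out[1][2])

    def test_flatlfa_is_treelfa_on_star_tree(self, small_dataset, sim_tree):
        """Identical trajectories from identical seeds: the flat baseline is
        exactly the tree sampler run on the flattened tree."""
        data, _, _ = small_dataset
        schedule = ChainSchedule(n_chains=2, burn_in=20, n_samples=3,
                                 thin_interval=2)
        a = fit(data, sim_tree, "flatlfa", sim_hyperparams(), schedule, seed=5)
        b = run_chain(data, flatten_tree(sim_tree), sim_hyperparams(flat=True),
                      schedule, seed=5)
        for ca, cb in zip(a.chains, b.chains):
            assert np.array_equal(ca.phi, cb.phi)
            assert np.array_equal(ca.N, cb.N)

    def test_empty_schedule_collects_nothing(self, small_dataset, sim_tree,
                                             sim_hyper):
        data, _, _ = small_dataset
        schedule = ChainSchedule(n_chains=1, burn_in=3, n_samples=0,
                                 thin_interval=1)
        ps = run_chain(data, sim_tree, sim_hyper, schedule, seed=0)
        assert ps.chains[0].phi.shape[0] == 0


class TestAlphaMStep:
    def test_degenerate_single_topic(self):
        N = np.tile([20, 0, 0], (200, 1))
        alpha = alpha_m_step([N], [1.0, 1.0, 1.0])
        assert alpha[0] / alpha.sum() > 0.99

    def test_symmetric_counts_give_symmetric_alpha(self, rng):
        theta = rng.dirichlet([1, 1, 1], size=2000)
        N = rng.multinomial(30, theta)
        alpha = alpha_m_step([N], [0.5, 0.5, 0.5])
        assert np.ptp(alpha) / alpha.mean() < 0.15

    def test_parameter_recovery(self):
        """Counts simulated from alpha = (1, 0.1, 0.1) at D = 10^4 recover
        each entry within 10%."""
        rng = np.random.default_rng(2024)
        true = np.array([1.0, 0.1, 0.1])
        theta = rng.dirichlet(true, size=10_000)
        N = rng.multinomial(50, theta)
        alpha = alpha_m_step([N], np.ones(3))
        assert np.all(np.abs(alpha - true) / true < 0.10)

    def test_multiple_tables_jointly(self, rng):
        true = np.array([0.8, 0.4])
        tables = []
        for _ in range(3):
            theta = rng.dirichlet(true, size=3000)
            tables.append(rng.multinomial(40, theta))
        alpha = alpha_m_step(tables, np.ones(2))
        assert np.all(np.abs(alpha - true) / true < 0.15)


class TestHeldoutTheta:
    def test_single_topic_theta_is_one(self):
        data = DiagnosisMatrix(np.array([[1, 0], [0, 0]]))
        sched = ChainSchedule(n_chains=1, burn_in=5, n_samples=3,
                              thin_interval=1)
        theta = infer_theta_heldout(data, np.array([[0.5, 0.5]]), [1.0],
                                    sched, seed=0)
        assert np.allclose(theta, 1.0)

    def test_healthy_individual_loads_empty_topic(self):
        phi = np.array([[0.4] * 10, [1e-6] * 10])
        data = DiagnosisMatrix(np.zeros((1, 10), dtype=int))
        sched = ChainSchedule(n_chains=2, burn_in=50, n_samples=20,
                              thin_interval=2)
        theta = infer_theta_heldout(data, phi, [0.5, 0.5], sched, seed=1)
        assert theta[0, 1] > 0.8

    def test_matches_exhaustive_enumeration(self):
        """Posterior mean theta on a 2-code/2-topic toy agrees with exact
        enumeration of all K^S assignment vectors."""
        phi = np.array([[0.8, 0.2], [0.1, 0.7]])
        alpha = np.array([0.7, 1.3])
        W = np.array([[1, 1]])
        # exact: sum over Z in {0,1}^2 of P(W|Z) P(Z) theta(N(Z))
        weights, thetas = [], []
        for z0 in (0, 1):
            for z1 in (0, 1):
                lik = phi[z0, 0] * phi[z1, 1]
                # collapsed P(Z): Dirichlet-multinomial over the sequence
                pz = alpha[z0] * (alpha[z1] + (z0 == z1)) / (
                    alpha.sum() * (alpha.sum() + 1)
                )
                N = np.array([(z0 == 0) + (z1 == 0), (z0 == 1) + (z1 == 1)])
                weights.append(lik * pz)
                thetas.append(theta_from_counts(N, alpha))
        exact = np.average(thetas, axis=0, weights=weights)
        sched = ChainSchedule(n_chains=20, burn_in=100, n_samples=50,
                              thin_interval=1)
        est = infer_theta_heldout(DiagnosisMatrix(W), phi, alpha, sched, seed=3)
        assert np.allclose(est[0], exact, atol=0.01)


class TestLDA:
    def test_single_topic_recovers_frequencies(self, rng):
        W = (rng.random((300, 5)) < [0.6, 0.3, 0.2, 0.1, 0.5]).astype(int)
        W[W.sum(axis=1) == 0, 0] = 1
        data = DiagnosisMatrix(W)
        sched = ChainSchedule(n_chains=1, burn_in=10, n_samples=5,
                              thin_interval=1)
        ps = lda_run_chain(data, K=1, alpha=1.0, eta=0.01, schedule=sched,
                           seed=0)
        topic = ps.all_phi().mean(axis=0)[0]
        freq = W.sum(axis=0) / W.sum()
        assert np.allclose(topic, freq, atol=0.01)

    def test_healthy_individuals_excluded_with_warning(self):
        W = np.zeros((4, 3), dtype=int)
        W[0, 0] = 1
        sched = ChainSchedule(n_chains=1, burn_in=2, n_samples=1,
                              thin_interval=1)
        with pytest.warns(UserWarning, match="excluding"):
            ps = lda_run_chain(DiagnosisMatrix(W), K=2, alpha=1.0, eta=0.01,
                               schedule=sched, seed=0)
        # count tables cover all D individuals; healthy rows stay zero
        assert ps.chains[0].N.shape[1:] == (4, 2)
        assert ps.chains[0].N[:, 1:, :].sum() == 0

    def test_two_topic_recovery(self):
        """Disjoint-support topics are recovered up to label order."""
        rng = np.random.default_rng(8)
        phi = np.zeros((2, 8))
        phi[0, :4] = 0.25
        phi[1, 4:] = 0.25
        D = 1500
        which = rng.integers(0, 2, D)
        W = np.zeros((D, 8), dtype=int)
        for d in range(D):
            codes = rng.choice(np.flatnonzero(phi[which[d]]), size=3,
                               replace=False)
            W[d, codes] = 1
        sched = ChainSchedule(n_chains=1, burn_in=100, n_samples=10,
                              thin_interval=5)
        ps = lda_run_chain(DiagnosisMatrix(W), K=2, alpha=0.1, eta=0.01,
                           schedule=sched, seed=1)
        topics = ps.all_phi().mean(axis=0)
        left = topics[:, :4].sum(axis=1)
        assert {round(v) for v in left} == {0, 1}
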