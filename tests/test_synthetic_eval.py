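"""Sampling, fixture networks, KLD/SHD protocol, CV harness."""

import numpy as np
import pytest

from anblearn import (Dataset, NetworkModel, PriorSpec, Structure,
                      VariableSpec, asymptotic_eval, class_posterior_kld,
                      cross_validate_accuracy, fit_eap, forward_sample,
                      random_discrete_network, reference_optimal_anb, shd)

BINARY = ("1", "2")


class TestForwardSample:
    def test_deterministic_cpts_give_constant_rows(self):
        structure = Structure((frozenset(), frozenset({0})), class_index=0)
        variables = [VariableSpec("A", BINARY), VariableSpec("B", BINARY)]
        model = NetworkModel(structure=structure, variables=variables,
                             cpts=[np.array([[1.0, 0.0]]),
                                   np.array([[0.0, 1.0], [0.5, 0.5]])])
        ds = forward_sample(model, 10, seed=0)
        assert np.array_equal(ds.rows, np.tile([1, 2], (10, 1)))

    def test_zero_rows(self):
        net = random_discrete_network(3, 1, seed=61)
        assert forward_sample(net, 0, seed=0).n_rows == 0

    def test_same_seed_same_sample(self):
        net = random_discrete_network(4, 2, seed=62)
        a = forward_sample(net, 500, seed=9)
        b = forward_sample(net, 500, seed=9)
        assert np.array_equal(a.rows, b.rows)

    def test_marginal_frequency_concentrates(self):
        structure = Structure((frozenset(),), class_index=0)
        model = NetworkModel(structure=structure,
                             variables=[VariableSpec("A", BINARY)],
                             cpts=[np.array([[0.3, 0.7]])])
        ds = forward_sample(model, 10_000, seed=3)
        freq = np.mean(ds.rows[:, 0] == 1)
        assert abs(freq - 0.3) < 3 * np.sqrt(0.3 * 0.7 / 10_000)


class TestRandomDiscreteNetwork:
    def test_same_seed_identical(self):
        a = random_discrete_network(5, 2, seed=63, anb_like=True)
        b = random_discrete_network(5, 2, seed=63, anb_like=True)
        assert a.structure.parent_sets == b.structure.parent_sets
        for x, y in zip(a.cpts, b.cpts):
            assert np.array_equal(x, y)

    def test_anb_like_satisfies_anb_constraint(self):
        for seed in range(5):
            net = random_discrete_network(6, 2, seed=seed, anb_like=True)
            assert net.structure.is_anb()

    def test_max_parents_zero_gives_disconnected_network(self):
        net = random_discrete_network(5, 0, seed=64)
        assert all(not ps for ps in net.structure.parent_sets)

    def test_parent_bound_respected(self):
        net = random_discrete_network(7, 2, seed=65, anb_like=True)
        for i, ps in enumerate(net.structure.parent_sets):
            if i != 0:
                assert len(ps - {0}) <= 2

    def test_cpts_valid(self):
        net = random_discrete_network(5, 2, cardinalities=[2, 3, 2, 3, 2], seed=66)
        net.validate(atol=1e-9)


class TestClassPosteriorKld:
    def _class_only(self, theta):
        """Class plus one deterministic feature so a single configuration
        carries all the weight."""
        structure = Structure((frozenset(), frozenset()), class_index=0)
        variables = [VariableSpec("C", BINARY), VariableSpec("X", BINARY)]
        return NetworkModel(structure=structure, variables=variables,
                            cpts=[np.array([theta]), np.array([[1.0, 0.0]])])

    def test_identical_models_give_zero(self):
        m = self._class_only([0.4, 0.6])
        assert class_posterior_kld(m, m, m) == 0.0

    def test_hand_worked_single_configuration_value(self):
        a = self._class_only([0.5, 0.5])
        b = self._class_only([0.75, 0.25])
        expected = 0.75 * np.log(1.5) + 0.25 * np.log(0.5)
        assert class_posterior_kld(a, b, b) == pytest.approx(expected, abs=1e-12)

    def test_nonnegative_on_random_model_pairs(self):
        ref = random_discrete_network(4, 1, seed=67, anb_like=True)
        sample = forward_sample(ref, 300, seed=68)
        m_true = fit_eap(sample, ref.structure)
        nb = Structure((frozenset(),) + tuple(frozenset({0}) for _ in range(3)),
                       class_index=0)
        m_nb = fit_eap(sample, nb)
        assert class_posterior_kld(m_nb, m_true, ref) >= 0.0

    def test_classification_equivalent_fits_give_zero(self):
        """Markov-equivalent ANB structures EAP-fitted on the same sample
        have identical posteriors, so the divergence vanishes."""
        ref = random_discrete_network(3, 1, seed=69, anb_like=True)
        sample = forward_sample(ref, 200, seed=70)
        chain = Structure((frozenset(), frozenset({0}), frozenset({0, 1})),
                          class_index=0)
        flipped = Structure((frozenset(), frozenset({0, 2}), frozenset({0})),
                            class_index=0)
        m1 = fit_eap(sample, chain, PriorSpec(1.0))
        m2 = fit_eap(sample, flipped, PriorSpec(1.0))
        assert class_posterior_kld(m1, m2, ref) == pytest.approx(0.0, abs=1e-12)


class TestReferenceOptimalAnb:
    def test_naive_bayes_truth_recovers_naive_bayes(self):
        structure = Structure((frozenset(),) + tuple(frozenset({0})
                                                     for _ in range(3)),
                              class_index=0)
        variables = [VariableSpec(f"V{i}", BINARY) for i in range(4)]
        rng = np.random.default_rng(71)
        cpts = [np.array([[0.4, 0.6]])]
        for _ in range(3):
            p = rng.uniform(0.15, 0.85, size=2)
            cpts.append(np.column_stack([p, 1 - p]))
        net = NetworkModel(structure=structure, variables=variables, cpts=cpts)
        ref = reference_optimal_anb(net)
        assert ref.parent_sets == structure.parent_sets

    def test_feature_edge_of_the_truth_is_retained(self):
        """An anb_like truth with a feature-feature edge needs that edge in
        any ANB I-map; the reference must keep it (up to direction)."""
        for seed in range(3):
            net = random_discrete_network(4, 1, seed=72 + seed, anb_like=True)
            ref = reference_optimal_anb(net)
            truth_links = {frozenset(e) for e in net.structure.edges()}
            ref_links = {frozenset(e) for e in ref.edges()}
            assert truth_links <= ref_links
            assert ref.is_anb()


class TestAsymptoticEval:
    def test_empty_sizes_give_empty_report(self):
        net = random_discrete_network(4, 1, seed=73, anb_like=True)
        report = asymptotic_eval(net, [], seed=0)
        assert report.sizes == () and report.shd == () and report.kld == ()

    def test_recovery_on_a_compliant_fixture(self):
        net = random_discrete_network(5, 2, seed=74, anb_like=True)
        report = asymptotic_eval(net, [100, 10_000], seed=75)
        assert len(report.shd) == 2 and len(report.kld) == 2
        assert all(k >= 0 for k in report.kld)
        assert report.shd[-1] == 0


class TestCrossValidateAccuracy:
    def test_single_class_data_scores_one(self):
        rows = np.column_stack([np.ones(20, dtype=np.int64),
                                np.tile([1, 2], 10)])
        ds = Dataset([VariableSpec("C", BINARY), VariableSpec("X", BINARY)], rows, 0)
        for method in ("nb", "anb"):
            assert cross_validate_accuracy(ds, method, 4, seed=0) == 1.0

    def test_decisive_feature_reaches_high_accuracy(self):
        rng = np.random.default_rng(76)
        n = 400
        c = rng.integers(1, 3, n)
        x = np.where(rng.random(n) < 0.02, 3 - c, c)
        ds = Dataset([VariableSpec("C", BINARY), VariableSpec("X", BINARY)],
                     np.column_stack([c, x]), 0)
        assert cross_validate_accuracy(ds, "nb", 10, seed=1) >= 0.95

    def test_too_many_folds_rejected(self):
        ds = Dataset([VariableSpec("C", BINARY), VariableSpec("X", BINARY)],
                     np.array([[1, 1], [2, 2]]), 0)
        with pytest.raises(ValueError):
            cross_validate_accuracy(ds, "nb", 3, seed=0)

    def test_gbn_and_fsanb_methods_run(self):
        rng = np.random.default_rng(77)
        n = 120
        c = rng.integers(1, 3, n)
        x1 = np.where(rng.random(n) < 0.1, 3 - c, c)
        x2 = rng.integers(1, 3, n)
        ds = Dataset([VariableSpec(v, BINARY) for v in ("C", "A", "B")],
                     np.column_stack([c, x1, x2]), 0)
        for method in ("gbn", "fsanb"):
            acc = cross_validate_accuracy(ds, method, 3, seed=2)
            assert 0.0 <= acc <= 1.0
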