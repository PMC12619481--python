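"""Mixture fits, event posteriors, Kendall ordering, event-centers, bootstrap."""

import numpy as np
import pytest

from t2ebm.ebm import (
    MixtureFit,
    bootstrap_sequence,
    central_ordering,
    estimate_event_centers,
    fit_abnormality_model,
    fit_ebm,
    pairwise_cost,
    posterior_abnormality,
    prob_kendall_distance,
    quantize_severity,
    total_distance,
)
from t2ebm.synthetic import generate_cohort
from conftest import small_spec


class TestAbnormalityModel:
    def test_recovers_well_separated_components(self, rng):
        ctl = rng.normal(0, 1, 100)
        pat = np.concatenate([rng.normal(0, 1, 40), rng.normal(10, 1, 60)])
        x = np.concatenate([ctl, pat])
        is_ctl = np.arange(200) < 100
        fit = fit_abnormality_model(x, is_ctl, rng=rng)
        assert abs(fit.mu_n - 0) < 0.3
        assert abs(fit.mu_a - 10) < 0.3
        assert fit.w_a == pytest.approx(0.3, abs=0.05)

    def test_null_signal_small_abnormal_weight(self, rng):
        x = rng.normal(0, 1, 300)
        is_ctl = np.arange(300) < 150
        fit = fit_abnormality_model(x, is_ctl, rng=rng)
        assert fit.w_a < 0.5

    def test_loglik_nondecreasing(self, rng):
        x = np.concatenate([rng.normal(0, 1, 120), rng.normal(3, 1, 80)])
        is_ctl = np.arange(200) < 120
        fit = fit_abnormality_model(x, is_ctl, rng=rng)
        assert (np.diff(fit.loglik_trace) >= -1e-6).all()

    def test_minimum_group_sizes(self, rng):
        x = rng.normal(size=15)
        with pytest.raises(ValueError, match="10 subjects"):
            fit_abnormality_model(x, np.arange(15) < 5, rng=rng)


class TestPosterior:
    def _fit(self, w=0.5):
        return MixtureFit(0.0, 1.0, 2.0, 1.0, w, 0.0, np.zeros(1), True)

    def test_equal_density_midpoint_is_half(self):
        assert posterior_abnormality(self._fit(), 1.0) == pytest.approx(0.5)

    def test_logistic_closed_form(self):
        # equal-variance Gaussians: posterior = 1/(1 + exp(-2x + 2))
        assert posterior_abnormality(self._fit(), 1.5) == pytest.approx(
            1 / (1 + np.exp(-2 * 1.5 + 2)), abs=1e-12)
        assert posterior_abnormality(self._fit(), 1.5) == pytest.approx(0.7311, abs=1e-4)

    def test_limits(self):
        fit = self._fit()
        assert posterior_abnormality(fit, 40.0) == pytest.approx(1.0)
        assert posterior_abnormality(fit, -40.0) == pytest.approx(0.0)

    def test_monotone_for_equal_variances(self):
        fit = self._fit(w=0.3)
        x = np.linspace(-10, 10, 201)
        p = posterior_abnormality(fit, x)
        assert (np.diff(p) >= 0).all()


class TestQuantize:
    @pytest.mark.parametrize(
        "p,expected",
        [(0.0, 0.0), (1.0, 1.0), (0.30, 1 / 3), (0.5, 2 / 3),  # tie rounds up
         (1 / 6, 1 / 3), (0.9, 1.0), (0.1, 0.0)],
    )
    def test_nearest_level_ties_up(self, p, expected):
        assert quantize_severity(p) == pytest.approx(expected)

    def test_out_of_range(self):
        with pytest.raises(ValueError):
            quantize_severity(1.2)


class TestKendallDistance:
    def test_concordant_zero(self):
        assert prob_kendall_distance([0, 1, 2], [0.9, 0.6, 0.2]) == 0.0

    def test_fully_discordant_hand_value(self):
        # pairs (1,2): .4, (1,3): .7, (2,3): .3 -> 1.4
        d = prob_kendall_distance([0, 1, 2], [0.2, 0.6, 0.9])
        assert d == pytest.approx(1.4)

    def test_ties_cost_nothing(self):
        assert prob_kendall_distance([2, 0, 1], [0.5, 0.5, 0.5]) == 0.0

    def test_binary_posteriors_reduce_to_classic_kendall(self, rng):
        p = rng.integers(0, 2, 6).astype(float)
        ordering = rng.permutation(6)
        d = prob_kendall_distance(ordering, p)
        q = p[ordering]
        classic = sum(1 for i in range(6) for j in range(i + 1, 6) if q[j] > q[i])
        assert d == classic

    def test_pairwise_cost_consistency(self, rng):
        P = rng.random((20, 5))
        C = pairwise_cost(P)
        ordering = rng.permutation(5)
        direct = sum(prob_kendall_distance(ordering, P[s]) for s in range(20))
        assert total_distance(ordering, C) == pytest.approx(direct)


class TestCentralOrdering:
    def test_shared_posteriors_give_descending_order(self):
        P = np.tile([0.9, 0.5, 0.1], (8, 1))
        seq = central_ordering(P)
        assert (seq.ordering == [0, 1, 2]).all()
        assert seq.total_distance == pytest.approx(0.0)

    def test_heuristic_matches_exhaustive(self, rng):
        """K=4, n=50: the local-search path equals brute force over 24
        permutations."""
        P = rng.random((50, 4))
        exact = central_ordering(P, exhaustive_limit=7)
        heur = central_ordering(P, exhaustive_limit=0)
        assert heur.total_distance == pytest.approx(exact.total_distance, abs=1e-9)

    def test_complement_reverses_ordering(self, rng):
        P = rng.random((30, 5))
        seq = central_ordering(P)
        seq_rev = central_ordering(1.0 - P)
        assert (seq_rev.ordering == seq.ordering[::-1]).all()

    def test_empty_patient_rows_error(self):
        with pytest.raises(ValueError, match="patient"):
            central_ordering(np.zeros((4, 3)), patient_mask=np.zeros(4, bool))

    def test_oracle_equivalence_random_fixtures(self, rng):
        """Local search equals exhaustive minimization on random K<=6 panels."""
        for _ in range(20):
            K = int(rng.integers(3, 7))
            P = rng.random((int(rng.integers(10, 40)), K))
            exact = central_ordering(P, exhaustive_limit=7)
            heur = central_ordering(P, exhaustive_limit=0)
            assert heur.total_distance == pytest.approx(
                exact.total_distance, abs=1e-9)


class TestEventCenters:
    def test_single_subject_rank_formula(self):
        # ranks (1,2,3) -> centers ((m-0.5)/3) = (1/6, 1/2, 5/6)
        P = np.array([[1.0, 0.5, 0.0]])
        ec = estimate_event_centers([0, 1, 2], P)
        assert np.allclose(ec, [1 / 6, 1 / 2, 5 / 6])

    def test_identical_subjects_match_single(self):
        P = np.tile([0.95, 0.4, 0.1, 0.02], (25, 1))
        single = estimate_event_centers([0, 1, 2, 3], P[:1])
        many = estimate_event_centers([0, 1, 2, 3], P)
        assert np.allclose(single, many)

    def test_bounded_and_sorted_for_any_input(self, rng):
        P = rng.random((40, 6))
        ec = estimate_event_centers(rng.permutation(6), P)
        assert (ec >= 0).all() and (ec <= 1).all()
        assert (np.diff(ec) >= -1e-12).all()

    def test_uninformative_posteriors_error(self):
        with pytest.raises(ValueError, match="certainty"):
            estimate_event_centers([0, 1], np.full((5, 2), 0.5))


class TestBootstrap:
    def test_b1_is_permutation_matrix(self, rng):
        spec = small_spec(K=4, n_pat=80, n_ctl=60, seed=41, mu_abnormal=4.0)
        cohort, truth = generate_cohort(spec)
        X = cohort.biomarkers.drop(columns="id").to_numpy()
        ctl = truth.group == "control"
        F, ecs = bootstrap_sequence(X, ctl, B=1, rng=rng)
        assert F.shape == (4, 4)
        assert np.allclose(F.sum(axis=0), 1) and np.allclose(F.sum(axis=1), 1)
        assert set(np.unique(F)) <= {0.0, 1.0}

    def test_noise_free_pinned_stages_identity(self, rng):
        """A perfectly staged, nearly noise-free cohort: every resample
        recovers the pinned identity sequence, so F is the identity."""
        K, n = 4, 120
        stages = np.repeat(np.arange(K + 1), n // (K + 1))[:n]
        spec = small_spec(K=K, n_pat=70, n_ctl=50, seed=42,
                          sd_normal=0.05, sd_abnormal=0.05, mu_abnormal=6.0,
                          sequence=tuple(range(K)), stages=stages,
                          covariate_effects=(0, 0, 0))
        cohort, truth = generate_cohort(spec)
        X = cohort.biomarkers.drop(columns="id").to_numpy()
        ctl = truth.group == "control"
        F, _ = bootstrap_sequence(X, ctl, B=8, rng=rng)
        assert np.allclose(F, np.eye(K))

    def test_rows_and_columns_sum_to_one(self, rng):
        spec = small_spec(K=5, n_pat=60, n_ctl=40, seed=43)
        cohort, truth = generate_cohort(spec)
        X = cohort.biomarkers.drop(columns="id").to_numpy()
        ctl = truth.group == "control"
        F, ecs = bootstrap_sequence(X, ctl, B=5, rng=rng)
        assert np.allclose(F.sum(axis=0), 1, atol=1e-9)
        assert np.allclose(F.sum(axis=1), 1, atol=1e-9)
        assert ecs.shape == (5, 5)
        assert (ecs >= 0).all() and (ecs <= 1).all()


class TestFitEBM:
    def test_strong_separation_recovers_pinned_sequence(self, rng):
        K, n = 5, 150
        stages = np.tile(np.arange(K + 1), n // (K + 1) + 1)[:n]
        spec = small_spec(K=K, n_pat=90, n_ctl=60, seed=44,
                          mu_abnormal=6.0, sequence=(2, 0, 4, 1, 3),
                          stages=stages, covariate_effects=(0, 0, 0))
        cohort, truth = generate_cohort(spec)
        X = cohort.biomarkers.drop(columns="id").to_numpy()
        ctl = truth.group == "control"
        ebm = fit_ebm(X, ctl, rng=rng)
        assert (ebm.sequence.ordering == truth.sequence).all()
        assert ebm.posteriors.shape == X.shape
        assert ((ebm.posteriors >= 0) & (ebm.posteriors <= 1)).all()
        ec = ebm.sequence.event_centers
        assert (np.diff(ec) >= -1e-12).all()
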