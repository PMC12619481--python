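"""Generator invariants: ground truth consistency, mixture structure, presets."""

import numpy as np
import pytest
from scipy import stats

from t2ebm.synthetic import (
    BatterySpec,
    CohortSpec,
    battery_presets,
    generate_battery_items,
    generate_cohort,
)
from conftest import small_spec


class TestGroundTruth:
    def test_sequence_is_permutation_and_centers_increasing(self, default_cohort):
        cohort, truth, spec = default_cohort
        K = spec.K
        assert sorted(truth.sequence) == list(range(K))
        assert truth.event_centers.min() >= 0 and truth.event_centers.max() <= 1
        assert (np.diff(truth.event_centers) > 0).all()
        assert truth.stages.min() >= 0 and truth.stages.max() <= K

    def test_same_seed_bit_identical(self):
        spec = small_spec(seed=11)
        c1, t1 = generate_cohort(spec)
        c2, t2 = generate_cohort(spec)
        assert c1.biomarkers.equals(c2.biomarkers)
        assert c1.covariates.equals(c2.covariates)
        assert (t1.stages == t2.stages).all()

    def test_pinned_sequence_stable_across_seeds(self):
        seq = (3, 1, 4, 0, 2)
        a = generate_cohort(small_spec(seed=1, sequence=seq))[1]
        b = generate_cohort(small_spec(seed=2, sequence=seq))[1]
        assert (a.sequence == np.array(seq)).all()
        assert (a.sequence == b.sequence).all()
        assert not np.array_equal(
            generate_cohort(small_spec(seed=1, sequence=seq))[0].biomarkers.values,
            generate_cohort(small_spec(seed=2, sequence=seq))[0].biomarkers.values,
        )


class TestBiomarkerGeneration:
    def test_noise_free_limit_is_step_function(self):
        """With vanishing sds and a large gap, each subject's harmonized
        biomarker vector is a step along the true sequence."""
        spec = small_spec(sd_normal=1e-9, sd_abnormal=1e-9,
                          mu_normal=0.0, mu_abnormal=10.0, seed=3)
        cohort, truth = generate_cohort(spec)
        X = cohort.biomarkers.drop(columns="id").to_numpy()
        pos = np.empty(spec.K, dtype=int)
        pos[truth.sequence] = np.arange(spec.K)
        confound_margin = 2.0   # linear covariate effects perturb the levels
        for s in range(len(X)):
            expected = np.where(pos < truth.stages[s], 10.0, 0.0)
            assert np.abs(X[s] - expected).max() < confound_margin

    def test_all_stage_zero_draws_only_normal(self):
        n = 50
        spec = small_spec(n_pat=30, n_ctl=20, seed=4,
                          stages=np.zeros(n, dtype=int),
                          covariate_effects=(0.0, 0.0, 0.0))
        cohort, truth = generate_cohort(spec)
        X = cohort.biomarkers.drop(columns="id").to_numpy()
        # normal component is N(0, 1): nothing should sit near mu_abnormal=2
        assert (truth.stages == 0).all()
        assert X.mean() == pytest.approx(0.0, abs=0.15)

    def test_first_event_more_abnormal_than_last(self):
        """Monte-Carlo check of the generative definition: among patients the
        biomarker at sequence position 1 is on average more abnormal than
        the one at the last position."""
        spec = small_spec(n_pat=300, n_ctl=100, seed=5,
                          covariate_effects=(0.0, 0.0, 0.0))
        cohort, truth = generate_cohort(spec)
        X = cohort.biomarkers.drop(columns="id").to_numpy()
        pat = truth.group == "patient"
        first = X[pat][:, truth.sequence[0]]
        last = X[pat][:, truth.sequence[-1]]
        assert first.mean() > last.mean() + 0.5

    def test_mixture_matches_stage_weighted_components(self):
        """KS test: generated values for one biomarker follow the
        stage-implied two-component mixture."""
        spec = small_spec(n_pat=3000, n_ctl=2000, seed=6,
                          covariate_effects=(0.0, 0.0, 0.0))
        cohort, truth = generate_cohort(spec)
        X = cohort.biomarkers.drop(columns="id").to_numpy()
        pos = np.empty(spec.K, dtype=int)
        pos[truth.sequence] = np.arange(spec.K)
        j = truth.sequence[2]          # a mid-sequence biomarker
        w = float((pos[j] < truth.stages).mean())

        def mix_cdf(x):
            return (1 - w) * stats.norm.cdf(x, 0, 1) + w * stats.norm.cdf(x, 2, 1)

        res = stats.ks_1samp(X[:, j], mix_cdf)
        assert res.pvalue > 0.01

    def test_monotone_prevalence_along_sequence(self):
        spec = small_spec(K=8, n_pat=1200, n_ctl=800, seed=7)
        cohort, truth = generate_cohort(spec)
        pos = np.empty(8, dtype=int)
        pos[truth.sequence] = np.arange(8)
        frac = [(pos[truth.sequence[m]] < truth.stages).mean() for m in range(8)]
        assert (np.diff(frac) <= 0).all()

    def test_patient_stages_dominate_controls(self):
        spec = small_spec(n_pat=500, n_ctl=500, seed=8)
        _, truth = generate_cohort(spec)
        pat = truth.group == "patient"
        assert truth.stages[pat].mean() > truth.stages[~pat].mean()


class TestValidation:
    @pytest.mark.parametrize(
        "field,kw",
        [
            ("sd_normal", dict(sd_normal=0.0)),
            ("sd_abnormal", dict(sd_abnormal=-1.0)),
            ("mu_abnormal", dict(mu_abnormal=-2.0)),
            ("K", dict(biomarkers=("only_one",), directions={"only_one": True})),
        ],
    )
    def test_invalid_spec_names_field(self, field, kw):
        with pytest.raises(ValueError, match=field.split("_")[0]):
            generate_cohort(small_spec(**kw))


class TestBatteryItems:
    def test_single_factor_items_perfectly_correlated(self, rng):
        b = BatterySpec("toy", ["i1", "i2", "i3"], [0, 0, 0], 1,
                        loading=1.0, noise_sd=0.0)
        f = rng.standard_normal((100, 1))
        items = generate_battery_items(b, f, rng)
        corr = np.corrcoef(items.to_numpy(), rowvar=False)
        assert np.allclose(corr, 1.0)

    def test_two_orthogonal_factors_rank_two(self, rng):
        b = BatterySpec("toy", ["a1", "a2", "b1", "b2"], [0, 0, 1, 1], 2,
                        loading=1.0, noise_sd=0.0)
        f = rng.standard_normal((200, 2))
        items = generate_battery_items(b, f, rng)
        ev = np.linalg.eigvalsh(np.cov(items.to_numpy(), rowvar=False))
        assert (ev > 1e-10).sum() == 2

    def test_zero_factor_column_rejected(self):
        b = BatterySpec("bad", ["i1", "i2"], [0, 0], 2)
        with pytest.raises(ValueError, match="factor 1"):
            b.validate()

    def test_presets_match_named_item_groups(self):
        presets = {b.name: b for b in battery_presets()}
        assert len(presets["CVLT"].items) == 17
        assert presets["CVLT"].n_factors == 4
        assert len(presets["STROOP"].items) == 11
        assert presets["STROOP"].n_factors == 2
        assert len(presets["WCST"].items) == 15
        assert presets["WCST"].n_factors == 4

    def test_kaiser_rule_recovers_preset_factor_count(self, rng):
        """CVLT-like preset at n=500: the population correlation structure
        implied by loading 0.8 / noise 0.6 puts exactly n_factors
        eigenvalues above 1."""
        from t2ebm.pca import fit_pca

        preset = [b for b in battery_presets() if b.name == "CVLT"][0]
        f = rng.standard_normal((500, preset.n_factors))
        items = generate_battery_items(preset, f, rng)
        model = fit_pca(items)
        assert model.n_selected == preset.n_factors
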