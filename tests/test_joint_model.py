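"""Joint logistic model, GRS arithmetic and model-fit statistics."""

import numpy as np
import pandas as pd
import pytest

from amdgrs import (CaseControlStudy, FittedRiskModel, SimulationConfig,
                    SnpDefinition, SnpPanel, compare_grs_groups, compute_grs,
                    fit_joint_model, grs_for_study, mcfadden_r2,
                    or_per_grs_unit, simulate_cohort)
from amdgrs.errors import FitError
from amdgrs.model import model_from_panel_weights


def two_snp_panel():
    return SnpPanel((SnpDefinition("snp1", "A", "A", "A", "G"),
                     SnpDefinition("snp2", "B", "B", "A", "G")))


class TestFitJointModel:
    def test_large_n_consistency(self):
        cfg = SimulationConfig(
            panel=two_snp_panel(), freqs=(0.3, 0.4),
            per_allele_or=(2.0, 3.0), target_prevalence=0.2,
            n_cases=25_000, n_controls=25_000, seed=17)
        model = fit_joint_model(simulate_cohort(cfg), cfg.panel)
        ors = model.odds_ratios()
        assert 1.9 < ors[0] < 2.1
        assert 2.85 < ors[1] < 3.15

    def test_duplicated_column_is_rank_deficient(self):
        rng = np.random.default_rng(3)
        g = rng.binomial(2, 0.4, size=200)
        study = CaseControlStudy(
            subjects=[f"s{i}" for i in range(200)],
            status=rng.integers(0, 2, 200),
            dosage=pd.DataFrame({"snp1": g, "snp2": g}))
        with pytest.raises(FitError, match="snp2"):
            fit_joint_model(study, two_snp_panel())

    def test_reported_or_lies_inside_own_ci(self, study_cohort, panel13):
        model = fit_joint_model(study_cohort, panel13)
        ci = model.or_ci95()
        ors = model.odds_ratios()
        assert np.all(ci[:, 0] <= ors) and np.all(ors <= ci[:, 1])
        assert model.gradient_norm < 1e-6


class TestComputeGrs:
    def _model(self, a, betas):
        return FittedRiskModel(intercept=a, betas=np.asarray(betas, float),
                               snp_ids=tuple(f"s{i}" for i in
                                             range(len(betas))))

    def test_all_zero_dosages_give_intercept(self):
        m = self._model(-10.13, [0.5, 1.2, 0.1])
        assert compute_grs(m, [0, 0, 0]).values[0] == pytest.approx(-10.13)

    def test_arithmetic(self):
        m = self._model(0.0, [np.log(2), np.log(3)])
        assert compute_grs(m, [1, 2]).values[0] == \
            pytest.approx(0.69315 + 2 * 1.09861, abs=1e-4)

    def test_affine_increment_equals_beta(self):
        rng = np.random.default_rng(0)
        betas = rng.normal(size=5)
        m = self._model(rng.normal(), betas)
        x = rng.integers(0, 2, size=5)
        base = compute_grs(m, x).values[0]
        for i in range(5):
            bumped = x.copy()
            bumped[i] += 1
            assert compute_grs(m, bumped).values[0] - base == \
                pytest.approx(betas[i], abs=1e-12)

    def test_length_mismatch_rejected(self):
        with pytest.raises(ValueError, match="length"):
            compute_grs(self._model(0, [1.0, 2.0]), [1, 1, 1])


class TestMcFaddenR2:
    def test_zero_for_null_weights(self, small_cohort, panel13):
        null = FittedRiskModel(intercept=float(np.log(
            small_cohort.n_cases / small_cohort.n_controls)),
            betas=np.zeros(13), snp_ids=tuple(panel13.ids))
        assert mcfadden_r2(null, small_cohort) == pytest.approx(0.0,
                                                                abs=1e-9)

    def test_matches_direct_log_likelihood(self, small_cohort, panel13):
        model = fit_joint_model(small_cohort, panel13)
        # independent computation straight from the definition
        eta = model.intercept + small_cohort.dosage.to_numpy() @ model.betas
        p = 1 / (1 + np.exp(-eta))
        y = small_cohort.status
        llf = np.sum(y * np.log(p) + (1 - y) * np.log1p(-p))
        n1, n0 = small_cohort.n_cases, small_cohort.n_controls
        pbar = n1 / (n1 + n0)
        llnull = n1 * np.log(pbar) + n0 * np.log(1 - pbar)
        assert mcfadden_r2(model, small_cohort) == \
            pytest.approx(1 - llf / llnull, abs=1e-10)

    def test_invariant_to_order(self, small_cohort, panel13):
        model = fit_joint_model(small_cohort, panel13)
        r2 = mcfadden_r2(model, small_cohort)
        perm = np.random.default_rng(1).permutation(small_cohort.n)
        reordered = CaseControlStudy(
            subjects=[small_cohort.subjects[i] for i in perm],
            status=small_cohort.status[perm],
            dosage=small_cohort.dosage.iloc[perm].reset_index(drop=True))
        rev_panel = SnpPanel(tuple(reversed(panel13.snps)))
        model_rev = fit_joint_model(reordered, rev_panel)
        assert mcfadden_r2(model_rev, reordered) == pytest.approx(r2,
                                                                  abs=1e-8)

    def test_grows_toward_one_with_effect_size(self):
        rng = np.random.default_rng(5)
        g = rng.binomial(2, 0.5, size=600)
        panel = SnpPanel((SnpDefinition("snp1", "A", "A", "A", "G"),))
        r2s = []
        for beta in (0.5, 1.5, 3.0):
            y = (rng.random(600) <
                 1 / (1 + np.exp(-(-beta + beta * g)))).astype(int)
            study = CaseControlStudy(
                subjects=[f"s{i}" for i in range(600)], status=y,
                dosage=pd.DataFrame({"snp1": g}))
            model = fit_joint_model(study, panel)
            r2s.append(mcfadden_r2(model, study))
        assert r2s[0] < r2s[1] < r2s[2] < 1.0


class TestOrPerGrsUnit:
    def test_in_sample_identity_is_e(self, small_cohort, panel13):
        model = fit_joint_model(small_cohort, panel13)
        scores = grs_for_study(model, small_cohort)
        or_, ci = or_per_grs_unit(small_cohort, scores)
        assert or_ == pytest.approx(np.e, abs=1e-4)
        assert ci[0] < np.e < ci[1]

    def test_halved_scores_square_the_or(self, small_cohort, panel13):
        from amdgrs import RiskScoreSet
        model = fit_joint_model(small_cohort, panel13)
        scores = grs_for_study(model, small_cohort)
        or_half, _ = or_per_grs_unit(
            small_cohort, RiskScoreSet(scores.values / 2))
        assert or_half == pytest.approx(np.e ** 2, rel=1e-3)

    def test_out_of_sample_near_e(self, panel13):
        from amdgrs import default_config
        train = simulate_cohort(default_config(seed=21, n_cases=800,
                                               n_controls=800))
        test = simulate_cohort(default_config(seed=22, n_cases=800,
                                              n_controls=800))
        model = fit_joint_model(train, panel13)
        or_, ci = or_per_grs_unit(test, grs_for_study(model, test))
        assert ci[0] < np.e < ci[1]

    def test_constant_scores_rejected(self, small_cohort):
        from amdgrs import RiskScoreSet
        with pytest.raises(FitError):
            or_per_grs_unit(small_cohort,
                            RiskScoreSet(np.ones(small_cohort.n)))


class TestCompareGrsGroups:
    def test_identical_groups_are_null(self):
        g = [1.0, 2.0, 3.0]
        res = compare_grs_groups(g, g)
        assert res.t == pytest.approx(0.0)
        assert res.p_value == pytest.approx(1.0)
        assert not res.significant

    def test_closed_form_welch(self):
        res = compare_grs_groups([1.0, 2.0], [3.0, 4.0])
        assert res.t == pytest.approx(-2.8284, abs=1e-4)
        assert res.df == pytest.approx(2.0, abs=1e-9)
        assert res.p_value == pytest.approx(0.1056, abs=1e-4)

    def test_power_for_study_scale_shift(self):
        # 0.4 GRS-unit shift at n=300/600, score SD ~1.3: the Welch test
        # at the Bonferroni threshold 0.05/3 should detect it >90% of
        # the time
        rng = np.random.default_rng(8)
        hits = 0
        reps = 500
        for _ in range(reps):
            a = rng.normal(0.4, 1.3, size=300)
            b = rng.normal(0.0, 1.3, size=600)
            hits += compare_grs_groups(a, b).significant
        assert hits / reps > 0.9

    def test_zero_variance_rejected(self):
        with pytest.raises(ValueError):
            compare_grs_groups([1.0, 1.0], [1.0, 1.0])


class TestWeightExport:
    def test_panel_weights_round_trip(self, small_cohort, panel13):
        model = fit_joint_model(small_cohort, panel13)
        weighted = panel13.with_weights(dict(zip(model.snp_ids,
                                                 model.betas)))
        imported = model_from_panel_weights(weighted, model.intercept)
        a = grs_for_study(model, small_cohort).values
        b = grs_for_study(imported, small_cohort).values
        assert np.allclose(a, b, atol=1e-12)

    def test_missing_weights_rejected(self, panel13):
        with pytest.raises(ValueError, match="fixed weights"):
            model_from_panel_weights(panel13, 0.0)
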