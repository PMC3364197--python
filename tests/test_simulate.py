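"""Synthetic-cohort generator: calibration, sampling and LD structure."""

import numpy as np
import pytest
from scipy.special import expit, logit

from amdgrs import (calibrate_intercept, default_config,
                    expected_case_allele_freq, hwe_exact_test,
                    simulate_cohort, simulate_from_group_freqs)
from amdgrs.errors import SimulationError
from amdgrs.reference import CASE_FREQS, CONTROL_FREQS
from amdgrs.simulate import (_draw_genotypes, _cached_intercept,
                             max_feasible_r2)


class TestCalibrateIntercept:
    def test_null_effect_closed_form(self):
        alpha = calibrate_intercept([0.3], [0.0], 0.1)
        assert alpha == pytest.approx(logit(0.1), abs=1e-9)

    def test_single_snp_matches_grid_oracle(self):
        # independent oracle: dense grid scan of the 3-term enumeration
        p, beta, target = 0.5, np.log(2.0), 0.10
        probs = np.array([0.25, 0.5, 0.25])
        grid = np.linspace(-6, 0, 2_000_001)
        prev = probs @ expit(grid[None, :] + beta * np.arange(3)[:, None])
        expected = grid[np.argmin(np.abs(prev - target))]
        alpha = calibrate_intercept([p], [beta], target)
        assert alpha == pytest.approx(expected, abs=1e-5)
        assert probs @ expit(alpha + beta * np.arange(3)) == \
            pytest.approx(target, abs=1e-10)

    def test_full_panel_against_monte_carlo(self, panel13):
        cfg = default_config(seed=0)
        alpha = calibrate_intercept(cfg.freqs, cfg.betas, 0.15,
                                    panel=panel13)
        rng = np.random.default_rng(12345)
        n = 1_000_000
        G = rng.binomial(2, np.array(cfg.freqs), size=(n, 13))
        prev_hat = expit(alpha + G @ cfg.betas).mean()
        se = np.sqrt(0.15 * 0.85 / n)
        assert abs(prev_hat - 0.15) < 3 * se

    def test_degenerate_prevalence_rejected(self):
        from amdgrs.errors import CalibrationError
        with pytest.raises(CalibrationError):
            calibrate_intercept([0.5], [0.0], 1.0)


class TestExpectedCaseFreq:
    def test_null_or_leaves_frequency_unchanged(self):
        assert expected_case_allele_freq(0.37, 1.0, -2.0) == \
            pytest.approx(0.37, abs=1e-12)

    def test_rare_disease_limit(self):
        # P(g|case) ∝ HWE(g)·OR^g when the intercept is very negative
        assert expected_case_allele_freq(0.189, 3.13, -30.0) == \
            pytest.approx(0.4217, abs=5e-4)

    def test_monotone_in_or_rare_disease(self):
        # in the rare-disease limit P(g|case) ∝ HWE(g)·OR^g, so the case
        # frequency rises monotonically to 1 as the OR grows
        vals = [expected_case_allele_freq(0.5, o, -30.0)
                for o in (1, 2, 5, 20, 1000, 1e6)]
        assert np.all(np.diff(vals) > 0)
        assert vals[-1] > 0.99


class TestSimulateCohort:
    def test_null_model_arms_match(self):
        cfg = default_config(seed=5, n_cases=400, n_controls=400)
        cfg = type(cfg)(panel=cfg.panel, freqs=cfg.freqs,
                        per_allele_or=(1.0,) * 13, target_prevalence=0.15,
                        n_cases=400, n_controls=400, seed=5)
        st = simulate_cohort(cfg)
        fc = st.dosage[st.case_mask].mean(axis=0) / 2
        fu = st.dosage[~st.case_mask].mean(axis=0) / 2
        for p, diff in zip(cfg.freqs, np.abs(fc - fu)):
            se = np.sqrt(2 * p * (1 - p) / (2 * 400))
            assert diff < 3.5 * se

    def test_same_seed_same_cohort(self):
        cfg = default_config(seed=42, n_cases=150, n_controls=100)
        a, b = simulate_cohort(cfg), simulate_cohort(cfg)
        assert a.dosage.equals(b.dosage)
        assert (a.status == b.status).all()

    @staticmethod
    def _joint_case_freq_oracle(cfg, alpha, j):
        """Exact case allele frequency for SNP j: marginalise the
        disease probability over the burden of the other 12 SNPs."""
        from amdgrs.simulate import _anonymous_panel, _score_distribution
        others = [i for i in range(len(cfg.panel)) if i != j]
        sub = type(cfg)(panel=_anonymous_panel(len(others)),
                        freqs=tuple(cfg.freqs[i] for i in others),
                        per_allele_or=tuple(cfg.per_allele_or[i]
                                            for i in others),
                        target_prevalence=cfg.target_prevalence,
                        n_cases=1, n_controls=1)
        vals, probs = _score_distribution(sub)
        p = cfg.freqs[j]
        beta = np.log(cfg.per_allele_or[j])
        hwe = [(1 - p) ** 2, 2 * p * (1 - p), p * p]
        w = [hwe[g] * float(probs @ expit(alpha + beta * g + vals))
             for g in range(3)]
        return (w[1] + 2 * w[2]) / (2 * sum(w))

    def test_case_frequencies_match_enumeration_oracle(self, study_cohort,
                                                       panel13):
        cfg = default_config(seed=11)
        alpha = _cached_intercept(cfg)
        fc = study_cohort.dosage[study_cohort.case_mask].mean(axis=0) / 2
        for j, snp in enumerate(panel13.ids):
            expect = self._joint_case_freq_oracle(cfg, alpha, j)
            se = np.sqrt(expect * (1 - expect) / (2 * 986))
            assert abs(fc.iloc[j] - expect) < 3.5 * se, snp

    def test_single_snp_oracle_exact_in_rare_disease_limit(self):
        cfg = default_config(seed=0, target_prevalence=0.001)
        alpha = _cached_intercept(cfg)
        j = list(cfg.panel.ids).index("rs10490924")
        joint = self._joint_case_freq_oracle(cfg, alpha, j)
        # single-SNP enumeration with any very negative intercept
        single = expected_case_allele_freq(cfg.freqs[j],
                                           cfg.per_allele_or[j], -30.0)
        assert single == pytest.approx(joint, abs=2e-3)

    def test_simulated_case_freqs_track_published_direction(self,
                                                            study_cohort):
        # every SNP was simulated with OR>1, so case freq must exceed
        # control freq at study scale for the strong loci
        fc = study_cohort.dosage[study_cohort.case_mask].mean(axis=0) / 2
        fu = study_cohort.dosage[~study_cohort.case_mask].mean(axis=0) / 2
        strong = ["rs1061170", "rs10490924", "rs800292"]
        for snp in strong:
            assert fc[snp] > fu[snp] + 0.03

    def test_unreachable_composition_errors(self):
        cfg = default_config(seed=0, n_cases=10_000_000, n_controls=10,
                             target_prevalence=0.01)
        with pytest.raises(SimulationError):
            simulate_cohort(cfg)

    def test_population_prevalence_conserved(self):
        cfg = default_config(seed=9)
        alpha = _cached_intercept(cfg)
        rng = np.random.default_rng(77)
        n = 200_000
        G = _draw_genotypes(cfg, n, rng)
        y = rng.random(n) < expit(alpha + G @ cfg.betas)
        se = np.sqrt(0.15 * 0.85 / n)
        assert abs(y.mean() - 0.15) < 3 * se


class TestGroupFreqSimulation:
    def test_equal_freqs_give_null_auc(self):
        from amdgrs import fit_joint_model, grs_for_study, roc_auc
        st = simulate_from_group_freqs([0.4, 0.6], [0.4, 0.6],
                                       800, 800, seed=2)
        from amdgrs import SnpPanel, SnpDefinition
        panel = SnpPanel((SnpDefinition("snp1", "A", "A", "A", "G"),
                          SnpDefinition("snp2", "B", "B", "A", "G")))
        model = fit_joint_model(st, panel)
        auc = roc_auc(grs_for_study(model, st), st.status)
        assert abs(auc - 0.5) < 0.05

    def test_empty_arm_rejected(self):
        with pytest.raises(SimulationError):
            simulate_from_group_freqs([0.4], [0.4], 0, 100, seed=1)

    def test_published_freqs_reproduce_single_snp_auc(self):
        # large draw from the published case/control frequencies of the
        # strongest CFH variant: empirical AUC near the enumerated value
        from amdgrs import snp_auc_from_genotype_distributions, roc_auc
        p_case, p_ctrl = CASE_FREQS["rs1061170"], CONTROL_FREQS["rs1061170"]
        st = simulate_from_group_freqs([p_case], [p_ctrl], 20_000, 20_000,
                                       seed=8)
        emp = roc_auc(st.dosage.iloc[:, 0].to_numpy(), st.status)
        def hwe(p):
            return [(1 - p) ** 2, 2 * p * (1 - p), p * p]
        exact = snp_auc_from_genotype_distributions(hwe(p_case), hwe(p_ctrl))
        assert exact == pytest.approx(0.67308, abs=5e-5)
        assert abs(emp - exact) < 0.006


class TestHweAndLd:
    def test_simulated_controls_respect_hwe(self):
        # null calibration: exact HWE test at alpha=0.001 should pass in
        # >=99% of replicate simulations
        rng = np.random.default_rng(31)
        fails = 0
        reps = 300
        for _ in range(reps):
            g = rng.binomial(2, 0.3, size=600)
            p = hwe_exact_test(int((g == 0).sum()), int((g == 1).sum()),
                               int((g == 2).sum()))
            fails += p < 0.001
        assert fails / reps <= 0.01

    def test_ld_coupling_hits_target_r2(self):
        cfg = default_config(seed=13, ld=True)
        rng = np.random.default_rng(99)
        G = _draw_genotypes(cfg, 200_000, rng)
        ids = list(cfg.panel.ids)
        # CFH: rs800292 targets r2=0.150 with rs1061170 (feasible)
        i, j = ids.index("rs1061170"), ids.index("rs800292")
        r = np.corrcoef(G[:, i], G[:, j])[0, 1]
        assert r ** 2 == pytest.approx(0.150, abs=0.02)
        assert r > 0  # positive risk-allele coupling by default

    def test_infeasible_r2_clipped_with_warning(self):
        cfg = default_config(seed=1, ld=True)
        # APOE risk alleles at freqs 0.079/0.881 cannot reach r2=0.783
        assert max_feasible_r2(0.079, 0.881) < 0.783
        with pytest.warns(UserWarning, match="infeasible"):
            simulate_cohort(type(cfg)(
                panel=cfg.panel, freqs=cfg.freqs,
                per_allele_or=cfg.per_allele_or, target_prevalence=0.15,
                n_cases=20, n_controls=20, ld_r2=cfg.ld_r2, seed=1))
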