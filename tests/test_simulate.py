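"""Synthetic cohort generator: LD blocks, disease model, survival, truth."""

import numpy as np
import pandas as pd
import pytest

from bnbmla.freq import contingency_or, logistic_fit, logrank_test
from bnbmla.simulate import (
    CohortConfig,
    EffectModel,
    LDBlockSpec,
    SurvivalModel,
    compensated_interaction_mains,
    generate_block_genotypes,
    generate_cohort,
    simulate_case_control,
    simulate_survival,
    write_cohort,
)


class TestCaseControlModel:
    def test_null_model_half_prevalence(self):
        geno = pd.DataFrame({"rs1": np.zeros(20_000, dtype=int)})
        cov = pd.DataFrame(index=geno.index)
        y = simulate_case_control(geno, cov, EffectModel(), seed=0)
        assert abs(y.mean() - 0.5) < 3 * 0.5 / np.sqrt(len(y))

    def test_single_main_effect_recovered_by_logistic_refit(self):
        spec = LDBlockSpec.independent("rs1", maf=0.3)
        geno = generate_block_genotypes(spec, 20_000, seed=1)
        cov = pd.DataFrame(index=geno.index)
        model = EffectModel(main_effects={"rs1": np.log(2.0)})
        y = simulate_case_control(geno, cov, model, seed=1)
        fit = logistic_fit(geno["rs1"].to_numpy(), y)
        lo, hi = fit.ci95[1]
        assert lo <= 2.0 <= hi

    @staticmethod
    def _interaction_cohort(model, n=50_000, maf=0.3):
        spec1, spec2 = LDBlockSpec.independent("rs1", maf), LDBlockSpec.independent("rs2", maf)
        geno = pd.concat(
            [generate_block_genotypes(spec1, n, seed=2), generate_block_genotypes(spec2, n, seed=3)],
            axis=1,
        )
        y = simulate_case_control(geno, pd.DataFrame(index=geno.index), model, seed=4)
        c1 = (geno["rs1"] > 0).to_numpy()
        c2 = (geno["rs2"] > 0).to_numpy()
        return y, c1, c2

    @staticmethod
    def _or_of(y, exposed, rows):
        a = int((y[rows][exposed[rows]] == 1).sum())
        b = int((y[rows][~exposed[rows]] == 1).sum())
        c = int((y[rows][exposed[rows]] == 0).sum())
        d = int((y[rows][~exposed[rows]] == 0).sum())
        return (a * d) / (b * c)

    def test_bare_joint_carrier_term_stratified_ors(self):
        # main effects 0, joint-carrier effect ln 3: within the
        # partner-carrier stratum the OR is ~3, within the partner
        # non-carrier stratum it is ~1 (stratified 2x2 tables)
        beta = float(np.log(3.0))
        model = EffectModel(interaction_effects={("rs1", "rs2"): beta})
        y, c1, c2 = self._interaction_cohort(model)
        assert self._or_of(y, c1, c2) == pytest.approx(3.0, rel=0.15)
        assert self._or_of(y, c1, ~c2) == pytest.approx(1.0, abs=0.1)

    def test_compensated_construction_nulls_the_marginals(self):
        # the planted "pure interaction" adds compensating carrier main
        # effects so the unconditional marginal ORs sit inside [0.9, 1.1]
        maf = 0.3
        beta = float(np.log(3.0))
        carrier_q = 1 - (1 - maf) ** 2
        m = compensated_interaction_mains(beta, carrier_q)
        model = EffectModel(
            interaction_effects={("rs1", "rs2"): beta},
            carrier_main_effects={"rs1": m, "rs2": m},
        )
        y, c1, c2 = self._interaction_cohort(model, maf=maf)
        all_rows = np.ones(len(y), dtype=bool)
        assert 0.9 <= self._or_of(y, c1, all_rows) <= 1.1
        assert 0.9 <= self._or_of(y, c2, all_rows) <= 1.1
        # the epistatic contrast survives: carrier-stratum OR exceeds the
        # non-carrier-stratum OR by ~exp(beta)
        ratio = self._or_of(y, c1, c2) / self._or_of(y, c1, ~c2)
        assert ratio == pytest.approx(3.0, rel=0.2)

    def test_unknown_locus_rejected(self):
        geno = pd.DataFrame({"rs1": [0, 1]})
        with pytest.raises(KeyError):
            simulate_case_control(
                geno, pd.DataFrame(index=geno.index), EffectModel(main_effects={"rsX": 1.0}), seed=0
            )


class TestSurvivalModel:
    def test_overwhelming_censoring_no_events(self):
        strata = pd.DataFrame({"g": ["a"] * 200})
        model = SurvivalModel(baseline_hazard=0.05, censoring_rate=1e6)
        time, event, cat = simulate_survival(strata, model, seed=0)
        assert event.sum() == 0
        assert np.all(time < 0.01)
        assert set(cat) == {"na"}

    def test_null_hazard_ratios_null_logrank(self):
        strata = pd.DataFrame({"g": ["a"] * 1000 + ["b"] * 1000})
        model = SurvivalModel(
            baseline_hazard=0.1, hazard_ratios={"g": {"a": 1.0, "b": 1.0}}, censoring_rate=0.01
        )
        time, event, _ = simulate_survival(strata, model, seed=1)
        chi2, _, p = logrank_test(time, event, strata["g"].to_numpy())
        assert p > 0.01

    def test_hazard_ratio_three_detected(self):
        # two groups, HR 3, n = 2,000: ordered 5-year survival and a
        # significant log-rank in nearly all replicates
        detected = 0
        for rep in range(20):
            strata = pd.DataFrame({"g": ["lo"] * 1000 + ["hi"] * 1000})
            model = SurvivalModel(
                baseline_hazard=0.05, hazard_ratios={"g": {"lo": 1.0, "hi": 3.0}}, censoring_rate=0.02
            )
            time, event, cat = simulate_survival(strata, model, seed=100 + rep)
            surv_lo = (cat[:1000] == "survived").sum() / 1000
            surv_hi = (cat[1000:] == "survived").sum() / 1000
            _, _, p = logrank_test(time, event, strata["g"].to_numpy())
            if surv_lo > surv_hi and p < 0.01:
                detected += 1
        assert detected >= 19  # >= 95% of replicates

    def test_missing_stratum_ratio_rejected(self):
        strata = pd.DataFrame({"g": ["a", "b"]})
        model = SurvivalModel(baseline_hazard=0.1, hazard_ratios={"g": {"a": 1.0}})
        with pytest.raises(KeyError):
            simulate_survival(strata, model, seed=0)


class TestCohortAssembly:
    def test_column_bookkeeping(self):
        cfg = CohortConfig(n_cases=60, n_controls=60, n_null_snps=4,
                           direct_effects={"rsD1": 0.5}, seed=1)
        ds, truth = generate_cohort(cfg)
        snps = 5  # 4 nulls + 1 direct
        outcomes = {"outcome", "os5", "efs5"}
        covariates = {"gender", "lineage", "hyperdiploid", "risk_group"}
        assert ds.n_variables == snps + len(outcomes) + len(covariates)
        assert truth.direct_loci == {"rsD1"}
        assert len(truth.null_loci) == 4

    def test_determinism(self):
        cfg = CohortConfig(n_cases=50, n_controls=50, n_null_snps=3, seed=5)
        ds1, t1 = generate_cohort(cfg)
        ds2, t2 = generate_cohort(cfg)
        pd.testing.assert_frame_equal(ds1.data, ds2.data)
        assert t1.to_json() == t2.to_json()

    def test_full_size_cohort_row_count(self):
        cfg = CohortConfig(n_cases=543, n_controls=529, n_null_snps=2, seed=2)
        ds, _ = generate_cohort(cfg)
        assert ds.n_samples == 1072
        assert (ds.data["outcome"] == 1).sum() == 543

    def test_genotype_marginals_match_founder_maf(self):
        cfg = CohortConfig(n_cases=5000, n_controls=5000, n_null_snps=0,
                           redundant_groups=[{"loci": ["rsR1", "rsR2"], "maf": 0.3}],
                           with_subtypes=False, with_survival=False, seed=3)
        ds, _ = generate_cohort(cfg)
        for snp in ("rsR1", "rsR2"):
            maf_hat = ds.data[snp].mean() / 2
            se = np.sqrt(0.3 * 0.7 / (2 * ds.n_samples))
            assert abs(maf_hat - 0.3) < 4 * se

    def test_redundant_groups_high_r2(self):
        from bnbmla.ld import pairwise_ld

        cfg = CohortConfig(n_cases=500, n_controls=500,
                           redundant_groups=[{"loci": ["rsR1", "rsR2", "rsR3"], "maf": 0.25}],
                           with_subtypes=False, with_survival=False, seed=4)
        ds, truth = generate_cohort(cfg)
        assert truth.redundant_groups == [{"rsR1", "rsR2", "rsR3"}]
        for a, b in [("rsR1", "rsR2"), ("rsR2", "rsR3")]:
            assert pairwise_ld(ds.data[a].to_numpy(), ds.data[b].to_numpy()).r2 >= 0.95

    def test_round_trip_to_disk(self, tmp_path):
        from bnbmla.dataset import read_genotype_table
        from bnbmla.simulate import PlantedTruth

        cfg = CohortConfig(n_cases=30, n_controls=30, n_null_snps=2, seed=6)
        ds, truth = generate_cohort(cfg)
        data_path, truth_path = write_cohort(ds, truth, tmp_path / "cohort")
        raw = read_genotype_table(data_path, target_name="outcome")
        assert len(raw.sample_ids) == 60
        assert set(raw.snp_names) == set(ds.snp_names)
        back = PlantedTruth.from_json(truth_path.read_text())
        assert back.null_loci == truth.null_loci
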