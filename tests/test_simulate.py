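"""Synthetic-cohort generator: design arithmetic, determinism, closure,
spike behaviour, clinical couplings and origin assignment."""

import numpy as np
import pandas as pd
import pytest

from conftest import small_design
from ragut.io import classify_origin
from ragut.simulate import (GroundTruth, SimulationDesign,
                            disease_activity, generate_cohort_design,
                            simulate_clinical_indices, simulate_cohort,
                            simulate_origin_metadata, simulate_species_profiles)
from ragut.stats import wilcoxon_rank_sum


class TestCohortDesign:
    def test_default_design_yields_110_samples(self):
        cohort = generate_cohort_design(SimulationDesign())
        assert len(cohort.df) == 22 + 22 * 4 == 110
        assert cohort.df.groupby("arm").size().to_dict() == \
            {"HQT": 13 * 4, "LEF": 9 * 4, "none": 22}

    def test_small_design_arithmetic(self):
        d = SimulationDesign(n_hc=2, n_ra=2, n_hqt=1, n_lef=1)
        cohort = generate_cohort_design(d)
        assert len(cohort.df) == 2 + 2 * 4

    def test_inconsistent_arm_split_rejected(self):
        with pytest.raises(ValueError):
            SimulationDesign(n_ra=10, n_hqt=4, n_lef=4)

    def test_same_seed_identical_metadata(self):
        c1 = generate_cohort_design(SimulationDesign(rng_seed=5))
        c2 = generate_cohort_design(SimulationDesign(rng_seed=5))
        pd.testing.assert_frame_equal(c1.df, c2.df)


class TestSpeciesProfiles:
    def test_compositional_closure(self, small_cohort):
        sums = small_cohort.species.values().sum(axis=0)
        np.testing.assert_allclose(sums, 100.0, atol=1e-6)

    def test_spiked_sets_disjoint(self, small_cohort):
        gt = small_cohort.ground_truth
        assert not set(gt.spiked_up) & set(gt.spiked_down)

    def test_full_determinism_under_fixed_seed(self):
        a = simulate_cohort(small_design(seed=21))
        b = simulate_cohort(small_design(seed=21))
        pd.testing.assert_frame_equal(a.species.data, b.species.data)
        pd.testing.assert_frame_equal(a.kos.data, b.kos.data)
        pd.testing.assert_frame_equal(a.cohort.df, b.cohort.df)
        assert a.ground_truth.spiked_up == b.ground_truth.spiked_up

    def test_null_cohort_detection_near_alpha(self):
        rates = []
        for seed in range(5):
            sc = simulate_cohort(small_design(seed=100 + seed, effect_fold=1.0,
                                              n_species=80))
            cohort, table = sc.cohort, sc.species
            hc = cohort.samples(group="HC", timepoint="M0")
            ra = cohort.samples(group="RA", timepoint="M0")
            x = table.data[ra].to_numpy()
            y = table.data[hc].to_numpy()
            ps = [wilcoxon_rank_sum(x[i], y[i]).p_value
                  for i in range(table.n_features)]
            rates.append(np.mean(np.array(ps) < 0.05))
        assert np.mean(rates) == pytest.approx(0.05, abs=0.035)

    def test_detection_rate_monotone_in_effect_fold(self):
        def rate(fold, seed):
            sc = simulate_cohort(small_design(seed=seed, effect_fold=fold))
            cohort, table, gt = sc.cohort, sc.species, sc.ground_truth
            hc = cohort.samples(group="HC", timepoint="M0")
            ra = cohort.samples(group="RA", timepoint="M0")
            spiked = gt.spiked_up + gt.spiked_down
            hits = sum(
                wilcoxon_rank_sum(table.data.loc[f, ra].to_numpy(),
                                  table.data.loc[f, hc].to_numpy()).p_value < 0.05
                for f in spiked)
            return hits / len(spiked)

        seeds = range(3)
        rates = [np.mean([rate(f, 200 + s) for s in seeds]) for f in (1.0, 2.0, 4.0)]
        assert rates[0] <= rates[1] + 0.05 <= rates[2] + 0.10
        assert rates[2] > 0.8

    def test_hqt_restores_faster_than_lef_on_ground_truth(self):
        sc = simulate_cohort(small_design(seed=31))
        gt, cohort, table = sc.ground_truth, sc.cohort, sc.species
        hc = cohort.samples(group="HC")
        spiked = gt.spiked_up + gt.spiked_down
        ref = np.log(table.data.loc[spiked, hc] + 1e-6).mean(axis=1)

        def mean_abs_logfold(arm):
            ids = cohort.samples(arm=arm, timepoint="M6")
            vals = np.log(table.data.loc[spiked, ids] + 1e-6).mean(axis=1)
            return float(np.abs(vals - ref).mean())

        assert mean_abs_logfold("HQT") < mean_abs_logfold("LEF")


class TestClinicalIndices:
    def test_zero_couplings_no_group_difference(self):
        design = small_design(seed=41)
        cohort = generate_cohort_design(design)
        table, gt = simulate_species_profiles(design, cohort)
        null_couplings = {
            "ESR": dict(base=20.0, slope=0.0, noise=1.0, floor=0.0,
                        arm_response={"HQT": 0.0, "LEF": 0.0}, ra_only=False)}
        filled = simulate_clinical_indices(cohort, table, gt, design,
                                           couplings=null_couplings)
        hc = filled.index_values("ESR", filled.samples(group="HC"))
        ra = filled.index_values("ESR", filled.samples(group="RA", timepoint="M0"))
        assert abs(hc.mean() - ra.mean()) < 2.0

    def test_inflammation_up_and_ast_down_in_patients(self):
        diffs_esr, rhos_ast = [], []
        for seed in range(5):
            sc = simulate_cohort(small_design(seed=300 + seed))
            hc = sc.cohort.samples(group="HC")
            ra0 = sc.cohort.samples(group="RA", timepoint="M0")
            diffs_esr.append(sc.cohort.index_values("ESR", ra0).mean()
                             - sc.cohort.index_values("ESR", hc).mean())
            d = disease_activity(sc.species, sc.ground_truth)
            base = hc + ra0
            from ragut.stats import spearman_rho
            rhos_ast.append(spearman_rho(
                d.loc[base].to_numpy(),
                sc.cohort.index_values("AST", base).to_numpy()).statistic)
        assert np.mean(diffs_esr) > 10
        assert np.mean(rhos_ast) < -0.2


class TestOriginMetadata:
    def _gt(self):
        return GroundTruth(
            spiked_up=[f"k__B|p__P|c__C|o__O|f__F|g__G|s__Up{i}" for i in range(20)],
            spiked_down=[f"k__B|p__P|c__C|o__O|f__F|g__G|s__Dn{i}" for i in range(10)],
            enterotype={}, contribution=None)

    def test_p_oral_one_all_oral(self):
        design = small_design(p_oral_up=1.0)
        recs = simulate_origin_metadata(self._gt(), design)
        up = [r for r in recs if r.species.startswith("Up")]
        assert all(classify_origin(r.host_name, r.isolation) == "oral" for r in up)

    def test_p_oral_zero_none_oral(self):
        design = small_design(p_oral_up=0.0)
        recs = simulate_origin_metadata(self._gt(), design)
        up = [r for r in recs if r.species.startswith("Up")]
        assert not any(classify_origin(r.host_name, r.isolation) == "oral" for r in up)

    def test_default_oral_fraction_binomial(self):
        fractions = []
        for seed in range(10):
            design = small_design(seed=seed)
            recs = simulate_origin_metadata(self._gt(), design)
            up = [r for r in recs if r.species.startswith("Up")]
            fractions.append(np.mean([r.origin == "oral" for r in up]))
        # 10 x Binomial(20, 0.6): mean within ~3 pooled standard errors
        assert np.mean(fractions) == pytest.approx(0.6, abs=0.11)


class TestFunctionalProfiles:
    def test_ko_values_linear_in_species_without_noise(self):
        sc = simulate_cohort(small_design(seed=51, ko_noise_sd=0.0))
        expected = sc.ground_truth.contribution.to_numpy() @ sc.species.values()
        np.testing.assert_allclose(sc.kos.values(), expected, rtol=1e-10)

    def test_pathway_rows_are_member_ko_sums(self, small_cohort):
        sc = small_cohort
        for pw_row in sc.pathways.feature_ids[:5]:
            pw = pw_row.split(":")[0]
            members = sorted(set(sc.kegg_map[pw]))
            expected = sc.kos.data.loc[members].sum(axis=0)
            np.testing.assert_allclose(sc.pathways.data.loc[pw_row].to_numpy(),
                                       expected.to_numpy(), rtol=1e-10)

    def test_every_ko_mapped_to_a_pathway(self, small_cohort):
        mapped = set(k for kos in small_cohort.kegg_map.values() for k in kos)
        assert mapped == set(small_cohort.kos.feature_ids)
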