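"""Structure-level and voxel-wise sex-dimorphism tests."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from dimorphmap import dimorphism, mixedlm, simulate


class TestStructureSexTest:
    def test_nine_timepoints_give_nine_df(self, small_cohort):
        table, cfg, archs = small_cohort
        res = dimorphism.structure_sex_test(table, "arch1", "relative")
        assert res.lrt.df == 9

    def test_planted_dimorphism_detected(self, small_cohort):
        table, cfg, archs = small_cohort
        res = dimorphism.structure_sex_test(table, "arch1", "relative")
        assert res.lrt.pvalue < 1e-3

    def test_permuted_sex_labels_kill_the_signal(self, small_cohort):
        """Shuffling mouse-level sex labels yields null-like p-values."""
        table, cfg, archs = small_cohort
        rng = np.random.default_rng(0)
        ps = []
        mice = sorted(table["mouse_id"].unique())
        for _ in range(30):
            perm = dict(zip(mice, rng.permutation([
                table.loc[table.mouse_id == m, "sex"].iloc[0] for m in mice])))
            shuffled = table.assign(sex=table["mouse_id"].map(perm))
            ps.append(dimorphism.structure_sex_test(shuffled, "arch1", "relative").lrt.pvalue)
        # roughly uniform: not systematically tiny
        assert np.median(ps) > 0.05
        assert stats.kstest(ps, "uniform").pvalue > 1e-3

    def test_absent_structure_rejected(self, small_cohort):
        table, *_ = small_cohort
        with pytest.raises(ValueError, match="absent"):
            dimorphism.structure_sex_test(table, "nope")

    def test_bands_cover_both_sexes_at_all_ages(self, small_cohort):
        table, *_ = small_cohort
        res = dimorphism.structure_sex_test(table, "arch1", "relative")
        assert set(res.bands["sex"]) == {"F", "M"}
        assert len(res.bands) == 18
        assert (res.bands["se"] > 0).all()


class TestEarliestTimepoint:
    def test_reference_age_contrast_equals_sex_main_effect(self, small_cohort):
        table, *_ = small_cohort
        res = dimorphism.structure_sex_test(table, "arch2", "relative")
        timing = dimorphism.earliest_dimorphic_timepoint(table, "arch2", "relative")
        first = timing.table.iloc[0]
        assert first["estimate"] == pytest.approx(res.fit_full.params[1], rel=1e-6)

    def test_late_onset_effect_detected_late(self):
        """Effect planted from day 17 onward is first seen at day 17+."""
        hits = []
        for seed in range(10):
            cfg = simulate.CohortConfig(seed=seed)
            arch = simulate.default_archetypes(amplitude=0.06)[3]  # late female
            t = simulate.generate_cohort(cfg, [arch], n_background_structures=0)
            timing = dimorphism.earliest_dimorphic_timepoint(t, "arch4", "relative")
            if timing.earliest_age is not None:
                hits.append(timing.earliest_age)
        assert len(hits) >= 8
        assert np.median(hits) >= 17

    def test_null_structure_mostly_undetected(self):
        found = 0
        for seed in range(20):
            cfg = simulate.CohortConfig(seed=seed, n_per_sex=8)
            t = simulate.generate_cohort(cfg, (), n_background_structures=1)
            timing = dimorphism.earliest_dimorphic_timepoint(t, "bg0", "relative")
            found += timing.earliest_age is not None
        # per-age alpha=0.05 over 9 uncorrected looks -> familywise ~ 1/3
        assert found <= 12


class TestVoxelwise:
    def test_planted_rois_recovered(self, relative_fields):
        """Sensitivity and realized FDR pooled over replicate cohorts."""
        fields, atlas, archs, truth = relative_fields
        tp = fp = pos = 0
        for seed in (None, 31, 32):
            if seed is None:
                flds = fields
            else:
                cfg = simulate.CohortConfig(seed=seed, dropout_rate=0.0)
                flds, _ = simulate.generate_determinant_fields(cfg, truth.shape, archs)
                flds = [f for f in flds if f.kind == "relative"]
            vmap = dimorphism.voxelwise_sex_test(flds, mask=atlas.brain_mask)
            sig = vmap.significant(0.1)
            tp += (sig & truth).sum()
            fp += (sig & ~truth).sum()
            pos += truth.sum()
        assert tp / pos >= 0.8
        assert fp / max(tp + fp, 1) <= 0.15

    def test_qvalues_dominate_pvalues_inside_mask(self, relative_fields):
        fields, atlas, *_ = relative_fields
        vmap = dimorphism.voxelwise_sex_test(fields, mask=atlas.brain_mask)
        m = vmap.mask
        assert np.all(vmap.qvalues[m] >= vmap.pvalues[m] - 1e-12)
        assert np.isnan(vmap.statistic[~m]).all()

    def test_null_fields_calibrated(self):
        """Fraction of voxels with p<0.05 near nominal on pure-noise fields."""
        cfg = simulate.CohortConfig(seed=21, n_per_sex=14, sigma_mouse=0.0,
                                    dropout_rate=0.0)
        fields, atlas = simulate.generate_determinant_fields(cfg, (20, 20, 20), ())
        rel = [f for f in fields if f.kind == "relative"]
        vmap = dimorphism.voxelwise_sex_test(rel, mask=atlas.brain_mask)
        frac = np.nanmean(vmap.pvalues[vmap.mask] < 0.05)
        assert 0.04 <= frac <= 0.06

    def test_absolute_fields_pick_up_global_scale(self, planted_fields):
        """On brain-scale-confounded data the absolute-determinant variant
        spreads the dimorphic set beyond the planted ROIs."""
        fields, atlas, archs, truth = planted_fields
        # confound: rescale male absolute fields globally
        confounded = []
        for f in fields:
            if f.kind != "absolute":
                continue
            v = f.values + (0.05 if f.sex == "M" else 0.0)
            confounded.append(simulate.DeterminantField(
                values=v, kind="absolute", voxel_volume=f.voxel_volume,
                mouse_id=f.mouse_id, sex=f.sex, age_days=f.age_days))
        vmap_abs = dimorphism.voxelwise_sex_test(confounded, mask=atlas.brain_mask)
        rel = [f for f in fields if f.kind == "relative"]
        vmap_rel = dimorphism.voxelwise_sex_test(rel, mask=atlas.brain_mask)
        extra_abs = (vmap_abs.significant(0.1) & ~truth).sum()
        extra_rel = (vmap_rel.significant(0.1) & ~truth).sum()
        assert extra_abs > 10 * max(extra_rel, 1)

    def test_rank_time_coding_and_quadratic_growth_run(self, relative_fields):
        fields, atlas, archs, truth = relative_fields
        small = atlas.labels == 1
        v1 = dimorphism.voxelwise_sex_test(fields, mask=small, time_coding="rank")
        v2 = dimorphism.voxelwise_sex_test(fields, mask=small, growth="quadratic")
        assert v1.df == 2.0 and v2.df == 3.0
        assert np.nanmedian(v1.pvalues[small]) < 0.05

    def test_random_slope_variant_agrees_on_strong_signal(self, relative_fields):
        fields, atlas, archs, truth = relative_fields
        roi = atlas.labels == 1
        sub = np.zeros_like(roi)
        sub[np.argwhere(roi)[:6, 0], np.argwhere(roi)[:6, 1], np.argwhere(roi)[:6, 2]] = True
        v = dimorphism.voxelwise_sex_test(fields, mask=sub, random_slope=True)
        assert np.nanmedian(v.pvalues[sub]) < 0.05


class TestAgeCentered:
    def test_centered_at_zero_matches_uncentered_coefficient(self, relative_fields):
        fields, atlas, *_ = relative_fields
        mask = atlas.labels == 2
        m0 = dimorphism.age_centered_sex_map(fields, mask, 0.0)
        Y, sexes, ages, mice = dimorphism._stack_fields(fields, mask)
        s = (sexes == "M").astype(float)
        t = ages / ages.max()
        X = np.column_stack([np.ones_like(t), s, t, s * t])
        fit = mixedlm.fit_lme_ml_batch(Y, X, mice)
        est, se, df = mixedlm.contrast_inference_batch(
            fit["_prob"], np.array([0.0, 1.0, 0.0, 0.0]))
        assert np.allclose(m0.statistic[mask], est / se, atol=1e-8)

    def test_reparameterization_identity(self, relative_fields):
        """Centered sex coefficient = a2 + a4 t' from the uncentered fit."""
        fields, atlas, *_ = relative_fields
        mask = atlas.labels == 3
        Y, sexes, ages, mice = dimorphism._stack_fields(fields, mask)
        s = (sexes == "M").astype(float)
        tmax = ages.max()
        X = np.column_stack([np.ones_like(ages), s, ages / tmax, s * ages / tmax])
        fit = mixedlm.fit_lme_ml_batch(Y, X, mice)
        for tp in (3.0, 17.0, 65.0):
            Xc = np.column_stack([np.ones_like(ages), s, (ages - tp) / tmax,
                                  s * (ages - tp) / tmax])
            fitc = mixedlm.fit_lme_ml_batch(Y, Xc, mice)
            pred = fit["params"][:, 1] + fit["params"][:, 3] * tp / tmax
            assert np.abs(fitc["params"][:, 1] - pred).max() < 1e-8
            assert np.abs(fitc["loglik"] - fit["loglik"]).max() < 1e-6

    def test_crossover_roi_flips_t_sign(self, relative_fields):
        fields, atlas, *_ = relative_fields
        roi3 = atlas.labels == 3  # crossover archetype
        early = dimorphism.age_centered_sex_map(fields, roi3, 5.0)
        late = dimorphism.age_centered_sex_map(fields, roi3, 65.0)
        assert np.nanmean(early.statistic[roi3]) > 0
        assert np.nanmean(late.statistic[roi3]) < 0

    def test_out_of_range_age_rejected(self, relative_fields):
        fields, atlas, *_ = relative_fields
        with pytest.raises(ValueError, match="range"):
            dimorphism.age_centered_sex_map(fields, atlas.labels == 1, 120.0)

    def test_threshold_taken_from_oldest_age(self, relative_fields):
        fields, atlas, archs, truth = relative_fields
        mask = atlas.brain_mask
        maps = dimorphism.age_centered_maps(fields, mask, ages=[3.0, 65.0])
        assert maps[3.0]["p_threshold"] == maps[65.0]["p_threshold"]


class TestVarianceFTest:
    def test_identical_samples_give_f_one_p_one(self):
        rows = []
        for i, v in enumerate([1.0, 1.1, 1.2, 1.3]):
            for sex in ("M", "F"):
                rows.append((f"{sex}{i}", sex, 10.0, 0, "s", v, 100.0))
        t = pd.DataFrame(rows, columns=["mouse_id", "sex", "age_days",
                                        "timepoint_index", "structure",
                                        "volume_mm3", "brain_volume_mm3"])
        F, p = dimorphism.variance_equality_ftest(t, "s", 10.0)
        assert F == pytest.approx(1.0)
        assert p == pytest.approx(1.0)

    def test_planted_variance_ratio_recovered(self):
        Fs = []
        rng = np.random.default_rng(0)
        for _ in range(60):
            rows = []
            m = 1.0 + rng.normal(0, 0.2, 50)
            f = 1.0 + rng.normal(0, 0.1, 50)
            for i in range(50):
                rows.append((f"M{i}", "M", 10.0, 0, "s", m[i], 100.0))
                rows.append((f"F{i}", "F", 10.0, 0, "s", f[i], 100.0))
            t = pd.DataFrame(rows, columns=["mouse_id", "sex", "age_days",
                                            "timepoint_index", "structure",
                                            "volume_mm3", "brain_volume_mm3"])
            F, p = dimorphism.variance_equality_ftest(t, "s", 10.0)
            assert 0.0 <= p <= 1.0
            Fs.append(F)
        assert np.median(Fs) == pytest.approx(4.0, rel=0.15)

    def test_insufficient_observations_rejected(self):
        t = pd.DataFrame([("M0", "M", 10.0, 0, "s", 1.0, 100.0),
                          ("F0", "F", 10.0, 0, "s", 1.0, 100.0)],
                         columns=["mouse_id", "sex", "age_days", "timepoint_index",
                                  "structure", "volume_mm3", "brain_volume_mm3"])
        with pytest.raises(ValueError):
            dimorphism.variance_equality_ftest(t, "s", 10.0)
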