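import dataclasses

import numpy as np
import pytest
from scipy import stats as sps

from kneevbr import relaxometry as rx
from kneevbr import stats as st
from kneevbr import synthetic as syn
from kneevbr.core import LABEL_NAMES, RelaxationMap
from kneevbr.errors import DesignError, GridMismatchError, KneeVBRError

from conftest import make_records


def _map(vol, mask=None):
    vol = np.asarray(vol, float)
    mask = np.ones(vol.shape, bool) if mask is None else mask
    return RelaxationMap(
        time_ms=np.where(mask, vol, np.nan), s0=np.zeros_like(vol),
        r_squared=np.ones_like(vol), converged=mask, mask=mask)


def _stack(values, records, shape=None):
    """CohortStack from an (n, V) matrix on a trivial 3D grid."""
    values = np.asarray(values, float)
    if shape is None:
        shape = (1, 1, values.shape[1])
    mask = np.ones(shape, bool)
    return st.CohortStack(values=values, common_mask=mask, subjects=records)


class TestBuildCohortStack:
    def test_identical_masks_intersect_to_same(self, atlas16):
        records = make_records(10)
        maps = [_map(np.full(atlas16.labels.shape, 40.0), atlas16.foreground)
                for _ in range(10)]
        stack = st.build_cohort_stack(maps, records)
        np.testing.assert_array_equal(stack.common_mask, atlas16.foreground)

    def test_missing_voxel_dropped_at_full_coverage(self, atlas16):
        records = make_records(10)
        masks = [atlas16.foreground.copy() for _ in range(10)]
        vox = tuple(np.argwhere(atlas16.foreground)[0])
        masks[3][vox] = False
        maps = [_map(np.full(atlas16.labels.shape, 40.0), m) for m in masks]
        stack = st.build_cohort_stack(maps, records, min_coverage_fraction=1.0)
        assert not stack.common_mask[vox]
        assert stack.common_mask.sum() == atlas16.foreground.sum() - 1

    def test_half_coverage_retains_voxel(self, atlas16):
        records = make_records(10)
        masks = [atlas16.foreground.copy() for _ in range(10)]
        vox = tuple(np.argwhere(atlas16.foreground)[0])
        masks[3][vox] = False
        maps = [_map(np.full(atlas16.labels.shape, 40.0), m) for m in masks]
        stack = st.build_cohort_stack(maps, records, min_coverage_fraction=0.5)
        assert stack.common_mask[vox]
        assert np.isnan(stack.values[3, 0]) or np.isfinite(stack.values[3]).sum() \
            == stack.values.shape[1] - 1

    def test_grid_mismatch_errors(self, atlas16):
        records = make_records(4)
        maps = [_map(np.zeros((16, 16, 16))) for _ in range(3)]
        maps.append(_map(np.zeros((8, 8, 8))))
        with pytest.raises(GridMismatchError):
            st.build_cohort_stack(maps, records)

    def test_too_few_subjects_errors(self):
        records = make_records(3)
        maps = [_map(np.full((4, 4, 4), 40.0)) for _ in range(3)]
        with pytest.raises(DesignError, match="subjects"):
            st.build_cohort_stack(maps, records)

    def test_missing_covariates_excluded_with_log(self, atlas16, caplog):
        records = make_records(8)
        records[2] = dataclasses.replace(records[2], age=float("nan"))
        maps = [_map(np.full(atlas16.labels.shape, 40.0), atlas16.foreground)
                for _ in range(8)]
        with caplog.at_level("WARNING", logger="kneevbr.stats"):
            stack = st.build_cohort_stack(maps, records)
        assert stack.n_subjects == 7
        assert records[2].subject_id in caplog.text


class TestGroupDifference:
    def test_identical_groups_zero_noise_null(self):
        records = make_records(20, grade_split="grade_patellar_tendinosis")
        stack = _stack(np.full((20, 6), 40.0), records)
        spm = st.voxelwise_group_difference(stack, "grade_patellar_tendinosis",
                                            covariates=())
        np.testing.assert_allclose(spm.effect[stack.common_mask], 0.0, atol=1e-10)
        np.testing.assert_allclose(spm.p[stack.common_mask], 1.0)
        assert spm.meta["degenerate"][stack.common_mask].all()

    def test_sign_convention_minus10pct(self):
        # without-group 40 ms, with-group 44 ms => effect -> -10%
        records = make_records(40, grade_split="grade_patellar_tendinosis")
        vals = np.where(np.arange(40)[:, None] < 20, 40.0, 44.0) * np.ones((1, 5))
        rng = np.random.default_rng(0)
        vals = vals + rng.normal(0, 1e-4, vals.shape)
        stack = _stack(vals, records)
        spm = st.voxelwise_group_difference(stack, "grade_patellar_tendinosis",
                                            covariates=())
        np.testing.assert_allclose(spm.effect[stack.common_mask], -10.0, atol=1e-3)
        assert (spm.p[stack.common_mask] < 0.05).all()

    def test_group_duplicated_as_covariate_is_rank_deficient(self):
        records = make_records(20, grade_split="grade_patellar_tendinosis")
        stack = _stack(np.random.default_rng(0).normal(40, 1, (20, 4)), records)
        dup = np.array([0.0] * 10 + [1.0] * 10)
        with pytest.raises(DesignError, match="collinear"):
            st.voxelwise_group_difference(
                stack, "grade_patellar_tendinosis", covariates=(),
                extra_covariates={"dup": dup})

    def test_both_groups_required(self):
        records = make_records(10)
        records = [dataclasses.replace(r, grade_quadriceps_tendinosis=0)
                   for r in records]
        stack = _stack(np.full((10, 3), 40.0), records)
        with pytest.raises(DesignError, match="nonempty"):
            st.voxelwise_group_difference(stack, "grade_quadriceps_tendinosis",
                                          covariates=())

    def test_adjustment_reduces_confounded_psv(self):
        # site drives both group membership and relaxation; adjusting for it
        # must reduce false-positive volume vs. the unadjusted analysis
        rng = np.random.default_rng(5)
        records = make_records(60)
        is_a = np.array([r.site == "site_A" for r in records])
        # group tracks site strongly but not perfectly (else rank-deficient)
        group = np.where(rng.random(60) < np.where(is_a, 0.9, 0.1), 1.0, 0.0)
        # no true group effect: pure site shift
        shift = np.where(is_a, 3.0, 0.0)
        vals = 40.0 + shift[:, None] + rng.normal(0, 1.0, (60, 200))
        stack = _stack(vals, records, shape=(1, 10, 20))
        adj = st.threshold_and_cluster(st.voxelwise_group_difference(
            stack, group, covariates=("site",)))
        unadj = st.threshold_and_cluster(st.voxelwise_group_difference(
            stack, group, covariates=()))
        assert unadj.sig_mask.sum() > adj.sig_mask.sum()
        assert adj.sig_mask.mean() < 0.15


class TestPartialCorrelation:
    def test_reduces_to_pearson_without_covariates(self, rng):
        records = make_records(12)
        vals = rng.normal(45, 4, (12, 7))
        y = rng.normal(80, 10, 12)
        stack = _stack(vals, records)
        spm = st.voxelwise_partial_correlation(stack, y, covariates=())
        for v in range(7):
            r_ref, p_ref = sps.pearsonr(vals[:, v], y)
            assert spm.effect[stack.common_mask][v] == pytest.approx(r_ref, abs=1e-12)
            assert spm.p[stack.common_mask][v] == pytest.approx(p_ref, rel=1e-9)

    def test_self_correlation_is_one(self, rng):
        records = make_records(10)
        vals = rng.normal(45, 4, (10, 3))
        stack = _stack(vals, records)
        spm = st.voxelwise_partial_correlation(stack, vals[:, 1], covariates=())
        assert spm.effect[stack.common_mask][1] == pytest.approx(1.0)

    def test_matches_double_residualization_oracle(self, rng):
        # independent brute-force: residualize outcome and voxel on the
        # covariate separately with lstsq, then correlate the residuals
        records = make_records(8)
        vals = rng.normal(45, 4, (8, 5))
        stack = _stack(vals, records)
        spm = st.voxelwise_partial_correlation(stack, "koos_Symptoms",
                                               covariates=("age",))
        y = np.array([r.koos_subscales["Symptoms"] for r in records])
        Z = np.column_stack([np.ones(8), [r.age for r in records]])
        for v in range(5):
            x = vals[:, v]
            res_x = x - Z @ np.linalg.lstsq(Z, x, rcond=None)[0]
            res_y = y - Z @ np.linalg.lstsq(Z, y, rcond=None)[0]
            r_bf = float(np.corrcoef(res_x, res_y)[0, 1])
            assert abs(spm.effect[stack.common_mask][v] - r_bf) < 1e-10

    def test_zero_outcome_variance_errors(self):
        records = make_records(10)
        stack = _stack(np.random.default_rng(0).normal(40, 1, (10, 3)), records)
        with pytest.raises(DesignError, match="variance"):
            st.voxelwise_partial_correlation(stack, np.full(10, 5.0))

    def test_insufficient_df_errors(self):
        records = make_records(4)
        stack = _stack(np.random.default_rng(0).normal(40, 1, (4, 3)), records)
        with pytest.raises(DesignError, match="n - k - 2"):
            st.voxelwise_partial_correlation(
                stack, np.arange(4.0), covariates=("age", "bmi"))

    def test_recovers_seeded_negative_slope_sign(self, rng):
        records = make_records(30)
        vals = rng.normal(50, 2, (30, 10))
        y = 90.0 - 3.0 * vals[:, 4] + rng.normal(0, 1, 30)
        stack = _stack(vals, records)
        spm = st.voxelwise_partial_correlation(stack, y, covariates=("age",))
        assert spm.effect[stack.common_mask][4] < -0.9


class TestThresholdAndCluster:
    def _spm(self, p_vol):
        p_vol = np.asarray(p_vol, float)
        return st.SPMResult(
            effect=np.zeros_like(p_vol), p=p_vol,
            common_mask=np.ones(p_vol.shape, bool), analysis_kind="difference")

    def test_all_p_one_yields_nothing(self):
        out = st.threshold_and_cluster(self._spm(np.ones((4, 4, 4))))
        assert out.sig_mask.sum() == 0
        assert out.clusters == []

    def test_two_disjoint_blobs(self):
        p = np.ones((8, 8, 8))
        p[0, 0, 0:3] = 0.01
        p[5, 5, 2:5] = 0.01
        out = st.threshold_and_cluster(self._spm(p))
        assert len(out.clusters) == 2
        assert sorted(c.size for c in out.clusters) == [3, 3]
        assert all(c.mean_p == pytest.approx(0.01) for c in out.clusters)

    def test_diagonal_merges_at_26_not_6(self):
        p = np.ones((4, 4, 4))
        p[1, 1, 1] = 0.01
        p[2, 2, 2] = 0.01
        assert len(st.threshold_and_cluster(self._spm(p), connectivity=26).clusters) == 1
        assert len(st.threshold_and_cluster(self._spm(p), connectivity=6).clusters) == 2

    def test_min_cluster_size_prunes_sig_mask(self):
        p = np.ones((6, 6, 6))
        p[0, 0, 0] = 0.01       # singleton
        p[3, 3, 1:5] = 0.01     # size 4
        out = st.threshold_and_cluster(self._spm(p), min_cluster_voxels=2)
        assert len(out.clusters) == 1
        assert out.sig_mask.sum() == 4

    def test_cluster_voxels_partition_sig_mask(self):
        rng = np.random.default_rng(8)
        p = np.where(rng.random((10, 10, 10)) < 0.2, 0.01, 1.0)
        out = st.threshold_and_cluster(self._spm(p))
        total = sum(c.size for c in out.clusters)
        assert total == out.sig_mask.sum()


class TestSummaries:
    def test_psv_ratio(self, atlas16):
        sig = np.zeros(atlas16.labels.shape, bool)
        mt = atlas16.labels == atlas16.label_of("MT")
        idx = np.argwhere(mt)[:25]
        sig[tuple(idx.T)] = True
        spm = st.SPMResult(
            effect=np.full(sig.shape, -12.0), p=np.where(sig, 0.01, 1.0),
            common_mask=atlas16.foreground, analysis_kind="difference",
            sig_mask=sig)
        summ = st.summarize_by_compartment(spm, atlas16)
        row = summ.row("MT")
        assert row["psv_pct"] == pytest.approx(100.0 * 25 / mt.sum())
        assert row["apd_pct"] == pytest.approx(-12.0)

    def test_empty_intersection_flagged_nan(self, atlas16):
        spm = st.SPMResult(
            effect=np.zeros(atlas16.labels.shape),
            p=np.ones(atlas16.labels.shape),
            common_mask=atlas16.foreground, analysis_kind="correlation",
            sig_mask=np.zeros(atlas16.labels.shape, bool))
        summ = st.summarize_by_compartment(spm, atlas16)
        assert summ.table["n_sig_voxels"].sum() == 0
        assert summ.table["avg_r"].isna().all()

    def test_matches_bruteforce_voxel_loop(self, atlas16, rng):
        p = rng.random(atlas16.labels.shape)
        effect = rng.normal(0, 10, atlas16.labels.shape)
        spm = st.SPMResult(effect=effect, p=p, common_mask=atlas16.foreground,
                           analysis_kind="difference")
        spm = st.threshold_and_cluster(spm, alpha=0.05)
        summ = st.summarize_by_compartment(spm, atlas16)
        for lab, name in LABEL_NAMES.items():
            n_comp = n_sig = 0
            eff_sum = p_sum = 0.0
            for ijk in np.argwhere(atlas16.labels == lab):
                i, j, k = ijk
                n_comp += 1
                if spm.sig_mask[i, j, k]:
                    n_sig += 1
                    eff_sum += effect[i, j, k]
                    p_sum += p[i, j, k]
            row = summ.row(name)
            assert row["psv_pct"] == pytest.approx(100.0 * n_sig / n_comp, abs=1e-12)
            if n_sig:
                assert row["apd_pct"] == pytest.approx(eff_sum / n_sig, abs=1e-12)
                assert row["avg_p"] == pytest.approx(p_sum / n_sig, abs=1e-12)


class TestNeglogP:
    @pytest.mark.parametrize("p,expected", [
        (1.0, 0.0),
        (0.05, 13.0103),   # 10 * log10(20)
        (0.01, 20.0),
    ])
    def test_closed_form_values(self, p, expected):
        spm = st.SPMResult(
            effect=np.zeros((1, 1, 1)), p=np.full((1, 1, 1), p),
            common_mask=np.ones((1, 1, 1), bool), analysis_kind="difference")
        assert st.neglog_p_map(spm)[0, 0, 0] == pytest.approx(expected, abs=1e-4)

    def test_zero_p_clipped(self):
        spm = st.SPMResult(
            effect=np.zeros((1, 1, 1)), p=np.zeros((1, 1, 1)),
            common_mask=np.ones((1, 1, 1), bool), analysis_kind="difference")
        out = st.neglog_p_map(spm)
        assert np.isfinite(out[0, 0, 0])

    def test_undefined_outside_mask(self):
        mask = np.zeros((2, 1, 1), bool)
        mask[0] = True
        spm = st.SPMResult(effect=np.zeros((2, 1, 1)), p=np.full((2, 1, 1), 0.5),
                           common_mask=mask, analysis_kind="difference")
        out = st.neglog_p_map(spm)
        assert np.isfinite(out[0, 0, 0])
        assert np.isnan(out[1, 0, 0])


class TestPermutation:
    def test_parametric_and_permutation_agree(self, rng):
        records = make_records(24, grade_split="grade_patellar_tendinosis")
        vals = rng.normal(45, 2, (24, 150))
        stack = _stack(vals, records, shape=(1, 10, 15))
        spm = st.voxelwise_group_difference(stack, "grade_patellar_tendinosis",
                                            covariates=("age",))
        perm = st.permutation_group_p(stack, "grade_patellar_tendinosis",
                                      covariates=("age",), n_permutations=499,
                                      rng=7)
        agree = np.abs(spm.p[stack.common_mask] - perm[stack.common_mask]) <= 0.05
        assert agree.mean() >= 0.95


class TestContrastBattery:
    def test_empty_contrast_list_gives_empty_tables_with_headers(self, atlas16):
        records = make_records(10)
        vals = np.random.default_rng(0).normal(45, 2,
                                               (10, int(atlas16.foreground.sum())))
        stack = st.CohortStack(values=vals, common_mask=atlas16.foreground,
                               subjects=records)
        battery = st.run_contrast_battery({"t1rho": stack}, [], atlas16)
        assert list(battery.correlation_table().columns) == [
            "modality", "outcome", "compartment", "psv_correlated_pct",
            "average_r", "average_p"]
        assert len(battery.correlation_table()) == 0
        assert len(battery.difference_table()) == 0

    def test_unknown_field_lists_available(self, atlas16):
        records = make_records(10)
        vals = np.random.default_rng(0).normal(45, 2,
                                               (10, int(atlas16.foreground.sum())))
        stack = st.CohortStack(values=vals, common_mask=atlas16.foreground,
                               subjects=records)
        with pytest.raises(KneeVBRError, match="available fields"):
            st.run_contrast_battery(
                {"t1rho": stack}, [st.Contrast("difference", "grade_nope")],
                atlas16)

    def test_effect_phantom_mt_max_psv_negative_apd(self, atlas16):
        # -10% MT effect over the whole compartment, low noise: MT must carry
        # the largest PSV and a negative APD
        eff = syn.EffectSpec(
            target_compartments=("MT",), affected_fraction_of_compartment=1.0,
            group_variable="grade_patellar_tendinosis",
            true_percentage_difference=-10.0, between_subject_sd_pct=0.5)
        records = make_records(40, seed=4, grade_split="grade_patellar_tendinosis")
        cohort = syn.generate_cohort(40, atlas=atlas16, effects=[eff],
                                     records=records, noise_sd=0.5,
                                     modalities=("t1rho",), seed=21)
        maps = [rx.fit_monoexponential(cohort.series(r.subject_id, "t1rho"),
                                       mask=atlas16.foreground)
                for r in cohort.records]
        stack = st.build_cohort_stack(maps, cohort.records)
        battery = st.run_contrast_battery(
            {"t1rho": stack},
            [st.Contrast("difference", "grade_patellar_tendinosis")], atlas16)
        (spm, summ), = battery.results.values()
        table = summ.table.set_index("compartment")
        assert table["psv_pct"].idxmax() == "MT"
        assert table.loc["MT", "apd_pct"] < 0


class TestSignConventionProperty:
    def test_recovered_apd_sign_matches_injection(self, atlas16):
        hits = 0
        for seed in range(6):
            sign = -1.0 if seed % 2 else 1.0
            eff = syn.EffectSpec(
                target_compartments=("PAT",), affected_fraction_of_compartment=1.0,
                group_variable="grade_quadriceps_tendinosis",
                true_percentage_difference=sign * 10.0,
                between_subject_sd_pct=0.5)
            records = make_records(30, seed=seed,
                                   grade_split="grade_quadriceps_tendinosis")
            cohort = syn.generate_cohort(30, atlas=atlas16, effects=[eff],
                                         records=records, noise_sd=0.5,
                                         modalities=("t1rho",), seed=100 + seed)
            maps = [rx.fit_monoexponential(cohort.series(r.subject_id, "t1rho"),
                                           mask=atlas16.foreground)
                    for r in cohort.records]
            stack = st.build_cohort_stack(maps, cohort.records)
            spm = st.threshold_and_cluster(st.voxelwise_group_difference(
                stack, "grade_quadriceps_tendinosis"))
            summ = st.summarize_by_compartment(spm, atlas16)
            apd = summ.row("PAT")["apd_pct"]
            if np.isfinite(apd) and np.sign(apd) == np.sign(sign):
                hits += 1
        assert hits >= 5
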