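"""Voxel-wise group inference: design construction, GLM oracles, cluster
labeling against a flood-fill reference, dual-threshold correction, strata."""

import numpy as np
import pytest

from anxvbm import synthetic as syn
from anxvbm import vbm
from anxvbm.stats import oneway_anova


@pytest.fixture(scope="module")
def planted():
    """Shared dataset with one strong AD mean shift in a known ROI."""
    cohort = syn.generate_cohort(syn.CohortSpec(n_per_group=30, rng_seed=1))
    ispec = syn.default_image_spec(grid_shape=(12, 14, 12), noise_sd=0.05)
    sd_eff = syn.realized_noise_sd(ispec, rng_seed=2)
    roi = syn.box_roi(ispec.grid_shape, (4, 8, 6), (4, 4, 4)) & ispec.mask
    eff = [syn.PlantedEffect(roi, "group_mean_shift", 1.5 * sd_eff, "AD")]
    stack = syn.generate_images(cohort, ispec, eff, rng_seed=3, site_offset_sd=0.02)
    design = vbm.build_design(cohort)
    return cohort, ispec, roi, stack, design


class TestBuildDesign:
    def test_column_count_three_groups_two_sites(self):
        cohort = syn.generate_cohort(syn.CohortSpec(n_per_group=10, n_sites=2, rng_seed=0))
        d = vbm.build_design(cohort)
        # intercept + 2 group + age + sex + education + 1 site
        assert d.matrix.shape[1] == 7
        assert d.metadata["reference_group"] == "HC"

    def test_missing_covariate_errors(self, small_cohort):
        broken = small_cohort.copy()
        broken.loc[0, "education"] = np.nan
        with pytest.raises(ValueError, match="education"):
            vbm.build_design(broken)

    def test_single_site_column_dropped(self):
        cohort = syn.generate_cohort(syn.CohortSpec(n_per_group=10, n_sites=1, rng_seed=0))
        d = vbm.build_design(cohort)
        assert not any(c.startswith("site") for c in d.column_names)

    def test_rows_follow_cohort_order(self, small_cohort):
        d1 = vbm.build_design(small_cohort)
        perm = small_cohort.sample(frac=1, random_state=0).reset_index(drop=True)
        d2 = vbm.build_design(perm)
        order = [small_cohort.id.tolist().index(i) for i in perm.id]
        np.testing.assert_allclose(d2.matrix, d1.matrix[order])


class TestVoxelwiseAncova:
    def test_single_voxel_no_covariates_matches_closed_form(self, rng):
        # per-voxel partial F with only group columns == one-way ANOVA F
        cohort = syn.generate_cohort(syn.CohortSpec(n_per_group=15, n_sites=1, rng_seed=4))
        n = len(cohort)
        stack = rng.normal(size=(n, 4, 4, 4))
        mask = np.ones((4, 4, 4), dtype=bool)
        design = vbm.build_design(cohort, covariate_names=(), include_site=False)
        fmap = vbm.voxelwise_ancova(stack, design, mask)
        groups = cohort.group.to_numpy()
        for idx in [(0, 0, 0), (1, 2, 3), (3, 3, 3)]:
            vals = stack[(slice(None), *idx)]
            ref = oneway_anova([vals[groups == g] for g in ("AD", "NAD", "HC")])
            assert fmap.values[idx] == pytest.approx(ref.statistic, rel=1e-8)

    def test_peak_f_inside_planted_roi(self, planted):
        _, ispec, roi, stack, design = planted
        fmap = vbm.voxelwise_ancova(stack, design, ispec.mask)
        peak = np.unravel_index(np.nanargmax(fmap.values), fmap.values.shape)
        assert roi[peak]

    def test_identical_images_undefined_everywhere(self, small_cohort, small_ispec):
        stack = np.broadcast_to(
            small_ispec.baseline_template, (len(small_cohort),) + small_ispec.grid_shape
        )
        design = vbm.build_design(small_cohort)
        fmap = vbm.voxelwise_ancova(np.array(stack), design, small_ispec.mask)
        assert fmap.n_undefined == small_ispec.mask.sum()
        assert np.isnan(fmap.values[small_ispec.mask]).all()

    def test_constant_offset_leaves_f_unchanged(self, planted):
        _, ispec, _, stack, design = planted
        f1 = vbm.voxelwise_ancova(stack, design, ispec.mask)
        f2 = vbm.voxelwise_ancova(stack + 5.0, design, ispec.mask)
        np.testing.assert_allclose(
            f1.values[ispec.mask], f2.values[ispec.mask], rtol=1e-8, equal_nan=True
        )

    def test_misaligned_design_errors(self, planted):
        _, ispec, _, stack, design = planted
        with pytest.raises(ValueError):
            vbm.voxelwise_ancova(stack[:-1], design, ispec.mask)


class TestPosthocT:
    def test_positive_t_in_roi_for_ad_contrast(self, planted):
        _, ispec, roi, stack, design = planted
        tmap = vbm.posthoc_t(stack, design, ("AD", "NAD"), ispec.mask)
        assert np.nanmean(tmap.values[roi]) > 2.0

    def test_antisymmetry(self, planted):
        _, ispec, _, stack, design = planted
        t1 = vbm.posthoc_t(stack, design, ("AD", "NAD"), ispec.mask)
        t2 = vbm.posthoc_t(stack, design, ("NAD", "AD"), ispec.mask)
        np.testing.assert_allclose(
            t1.values[ispec.mask], -t2.values[ispec.mask], rtol=1e-8, equal_nan=True
        )

    def test_t_squared_equals_f_for_two_groups(self, rng):
        cohort = syn.generate_cohort(syn.CohortSpec(n_per_group=15, n_sites=1, rng_seed=4))
        pat = cohort[cohort.group.isin(["AD", "NAD"])].reset_index(drop=True)
        stack = rng.normal(size=(len(pat), 4, 4, 4))
        mask = np.ones((4, 4, 4), dtype=bool)
        design = vbm.build_design(pat, covariate_names=(), include_site=False)
        f = vbm.voxelwise_ancova(stack, design, mask).values
        t = vbm.posthoc_t(stack, design, ("AD", "NAD"), mask).values
        np.testing.assert_allclose(t[mask] ** 2, f[mask], rtol=1e-8)

    def test_unknown_group_errors(self, planted):
        _, ispec, _, stack, design = planted
        with pytest.raises(ValueError):
            vbm.posthoc_t(stack, design, ("AD", "XX"), ispec.mask)


def _flood_fill_components(binary, conn26):
    """Brute-force connected components by DFS; oracle for label_clusters."""
    offsets = [
        (i, j, k)
        for i in (-1, 0, 1)
        for j in (-1, 0, 1)
        for k in (-1, 0, 1)
        if (i, j, k) != (0, 0, 0) and (conn26 or abs(i) + abs(j) + abs(k) == 1)
    ]
    seen = np.zeros_like(binary, dtype=bool)
    comps = []
    for start in map(tuple, np.argwhere(binary)):
        if seen[start]:
            continue
        comp, todo = set(), [start]
        seen[start] = True
        while todo:
            v = todo.pop()
            comp.add(v)
            for off in offsets:
                w = tuple(np.add(v, off))
                if all(0 <= w[d] < binary.shape[d] for d in range(3)) and binary[w] and not seen[w]:
                    seen[w] = True
                    todo.append(w)
        comps.append(frozenset(comp))
    return set(comps)


@pytest.mark.parametrize("conn26", [True, False])
def test_cluster_labeling_matches_flood_fill(conn26, rng):
    structure = vbm.CONNECTIVITY_26 if conn26 else vbm.CONNECTIVITY_6
    for _ in range(200):
        binary = rng.random((8, 8, 8)) < 0.2
        labels, n = vbm.label_clusters(binary, structure)
        got = {
            frozenset(map(tuple, np.argwhere(labels == k))) for k in range(1, n + 1)
        }
        assert got == _flood_fill_components(binary, conn26)


class TestDualThresholdClusters:
    def test_planted_effect_recovered_with_dice_overlap(self, planted):
        _, ispec, roi, stack, design = planted
        fmap = vbm.voxelwise_ancova(stack, design, ispec.mask)
        clusters = vbm.dual_threshold_clusters(
            fmap, stack, design, 0.001, 0.05, 100, affine=ispec.affine, rng=0
        )
        assert clusters
        roi_set = set(map(tuple, np.argwhere(roi)))
        best = max(
            2 * len(set(map(tuple, c.voxel_indices)) & roi_set) / (c.size + len(roi_set))
            for c in clusters
        )
        assert best > 0.5

    def test_no_suprathreshold_voxels_gives_empty_list(self, small_cohort, small_ispec):
        stack = syn.generate_images(small_cohort, small_ispec, [], rng_seed=8)
        design = vbm.build_design(small_cohort)
        fmap = vbm.voxelwise_ancova(stack, design, small_ispec.mask)
        # absurdly strict voxel threshold -> no candidates, not an error
        clusters = vbm.dual_threshold_clusters(
            fmap, stack, design, 1e-12, 0.05, 100, rng=0
        )
        assert clusters == []

    def test_voxel_p_one_spans_mask_component(self, planted):
        _, ispec, _, stack, design = planted
        fmap = vbm.voxelwise_ancova(stack, design, ispec.mask)
        candidates = []
        for binary in vbm._supra_binaries(fmap, 1.0):
            labels, n = vbm.label_clusters(binary, vbm.CONNECTIVITY_26)
            candidates.extend(
                np.sum(labels == k) for k in range(1, n + 1)
            )
        # the ellipsoid mask is one connected component
        assert sorted(candidates)[-1] == ispec.mask.sum() - fmap.n_undefined

    def test_peak_mni_uses_affine(self, planted):
        _, ispec, roi, stack, design = planted
        fmap = vbm.voxelwise_ancova(stack, design, ispec.mask)
        clusters = vbm.dual_threshold_clusters(
            fmap, stack, design, 0.001, 0.05, 100, affine=ispec.affine, rng=0
        )
        c = clusters[0]
        expected = ispec.affine @ np.array([*c.peak_index, 1.0])
        assert c.peak_mni == pytest.approx(tuple(expected[:3]))


class TestExtractAndCorrelate:
    def test_constant_image_returns_constant(self, small_ispec):
        stack = np.full((5,) + small_ispec.grid_shape, 3.25)
        cluster = vbm.Cluster(np.argwhere(small_ispec.mask)[:10], 10, 0.0, (0, 0, 0), (0, 0, 0))
        np.testing.assert_allclose(vbm.extract_cluster_gmv(stack, cluster), 3.25)

    def test_singleton_cluster_returns_voxel_value(self, rng):
        stack = rng.normal(size=(4, 5, 5, 5))
        cluster = vbm.Cluster(np.array([[2, 3, 1]]), 1, 0.0, (2, 3, 1), (0, 0, 0))
        np.testing.assert_allclose(
            vbm.extract_cluster_gmv(stack, cluster), stack[:, 2, 3, 1]
        )

    def test_empty_cluster_errors(self, small_ispec):
        stack = np.zeros((3,) + small_ispec.grid_shape)
        cluster = vbm.Cluster(np.empty((0, 3), int), 0, 0.0, (0, 0, 0), (0, 0, 0))
        with pytest.raises(ValueError):
            vbm.extract_cluster_gmv(stack, cluster)

    def test_planted_shift_recovered_in_cluster_means(self, planted):
        cohort, ispec, roi, stack, design = planted
        cluster = vbm.Cluster(np.argwhere(roi), int(roi.sum()), 0.0, (0, 0, 0), (0, 0, 0))
        vals = vbm.extract_cluster_gmv(stack, cluster)
        is_ad = (cohort.group == "AD").to_numpy()
        is_nad = (cohort.group == "NAD").to_numpy()
        sd_eff = syn.realized_noise_sd(ispec, rng_seed=2)
        diff = vals[is_ad].mean() - vals[is_nad].mean()
        assert diff == pytest.approx(1.5 * sd_eff, abs=3 * sd_eff / np.sqrt(roi.sum()))

    def test_roi_clinical_correlation_detects_planted_signal(self):
        cohort = syn.generate_cohort(syn.CohortSpec(n_per_group=89, rng_seed=21))
        pat = cohort[cohort.group.isin(["AD", "NAD"])].reset_index(drop=True)
        ispec = syn.default_image_spec(grid_shape=(12, 14, 12), noise_sd=0.05)
        sd_eff = syn.realized_noise_sd(ispec, rng_seed=22)
        roi = syn.box_roi(ispec.grid_shape, (4, 8, 6), (4, 4, 4)) & ispec.mask
        eff = [syn.PlantedEffect(roi, "hama_signal", 0.5 * sd_eff)]
        stack = syn.generate_images(pat, ispec, eff, rng_seed=23, site_offset_sd=0.02)
        cluster = vbm.Cluster(np.argwhere(roi), int(roi.sum()), 0.0, (0, 0, 0), (0, 0, 0))
        vals = vbm.extract_cluster_gmv(stack, cluster)
        r, p = vbm.roi_clinical_correlation(vals, pat.hama14.to_numpy(float), pat)
        assert r > 0 and p < 0.05

    def test_no_covariates_reduces_to_pearson(self, rng, patients):
        from anxvbm.stats import pearson_r

        vals = rng.normal(size=len(patients))
        hama = patients.hama14.to_numpy(float)
        r, p = vbm.roi_clinical_correlation(vals, hama, patients,
                                            covariate_names=(), include_site=False)
        assert (r, p) == pytest.approx(pearson_r(vals, hama))


class TestAgeStratifiedRerun:
    def test_single_age_stratum(self, small_ispec):
        cohort = syn.generate_cohort(syn.CohortSpec(n_per_group=12, rng_seed=2))
        cohort["age"] = 30.0
        stack = syn.generate_images(cohort, small_ispec, [], rng_seed=3)
        with pytest.warns(UserWarning):
            reports = vbm.age_stratified_rerun(stack, cohort, small_ispec.mask, n_perm=100)
        assert list(reports) == ["25<=age<=40"]

    def test_boundary_ages_belong_to_middle_stratum(self, small_ispec):
        cohort = syn.generate_cohort(syn.CohortSpec(n_per_group=12, rng_seed=2))
        cohort["age"] = np.resize([25.0, 40.0], len(cohort))
        stack = syn.generate_images(cohort, small_ispec, [], rng_seed=3)
        with pytest.warns(UserWarning):
            reports = vbm.age_stratified_rerun(stack, cohort, small_ispec.mask, n_perm=100)
        assert list(reports) == ["25<=age<=40"]

    def test_age_independent_effect_found_in_each_powered_stratum(self):
        cohort = syn.generate_cohort(syn.CohortSpec(n_per_group=60, rng_seed=31))
        ispec = syn.default_image_spec(grid_shape=(12, 14, 12), noise_sd=0.05)
        sd_eff = syn.realized_noise_sd(ispec, rng_seed=32)
        roi = syn.box_roi(ispec.grid_shape, (4, 8, 6), (4, 4, 4)) & ispec.mask
        eff = [syn.PlantedEffect(roi, "group_mean_shift", 3.0 * sd_eff, "AD")]
        stack = syn.generate_images(cohort, ispec, eff, rng_seed=33)
        reports = vbm.age_stratified_rerun(stack, cohort, ispec.mask, n_perm=100,
                                           affine=ispec.affine)
        assert reports  # at least one stratum is adequately powered
        for name, clusters in reports.items():
            assert clusters, f"planted effect missed in stratum {name}"
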