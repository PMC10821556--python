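"""The calibrated cohort generator: mean fitting, sampling, measurement layer."""

import numpy as np
import pandas as pd
import pytest

from glycoserum.glycan_core import MassConfig
from glycoserum.simulate import (
    GROUP_TRAIT_TARGETS,
    CohortSpec,
    calibrate_group_means,
    emit_covariates,
    emit_peaklists,
    generate_cohort,
    normal_group_targets,
    sample_subjects,
)
from glycoserum.spectra import AnnotationConfig, GlycanProfile, annotate, normalize_profile
from glycoserum.stats import pearson
from glycoserum.traits import compute_traits


def traits_of(vec, library):
    return compute_traits(GlycanProfile("m", dict(vec)), library).as_dict()


class TestCalibrateGroupMeans:
    def test_benign_column_reproduced(self, library):
        vec, residuals = calibrate_group_means(GROUP_TRAIT_TARGETS["benign"], library)
        t = traits_of(vec, library)
        assert t["man"] == pytest.approx(2.98, abs=1e-6)
        assert t["s_total"] == pytest.approx(82.11, abs=1e-6)
        assert t["g_total"] == pytest.approx(7.73, abs=1e-6)
        # the printed B total (11.72) disagrees with its own components by a
        # rounding unit; the fit sits on the component sum
        assert t["b_total"] == pytest.approx(3.36 + 8.35, abs=1e-6)
        assert t["b_total"] == pytest.approx(11.72, abs=0.011)
        assert max(abs(r) for r in residuals.values()) < 1e-6

    @pytest.mark.parametrize("group", ["early", "late"])
    def test_cancer_columns_reproduced(self, group, library):
        vec, _ = calibrate_group_means(GROUP_TRAIT_TARGETS[group], library)
        t = traits_of(vec, library)
        tgt = GROUP_TRAIT_TARGETS[group]
        for trait in ("man", "g0", "s1", "s2", "s3", "s4", "f_sialo", "b_neutral"):
            assert t[trait] == pytest.approx(tgt[trait][0], abs=1e-6), trait

    def test_vector_is_a_closed_composition(self, library):
        vec, _ = calibrate_group_means(GROUP_TRAIT_TARGETS["late"], library)
        assert vec.sum() == pytest.approx(100.0, abs=1e-9)
        assert (vec > 0).all()

    def test_disjoint_targets_fit_exactly(self, library):
        sub = {k: library[k] for k in ("H5N2", "H3N3", "H4N3", "H5N4", "H5N4S1", "H5N4S2", "H6N5S3", "H7N6S4")}
        targets = {
            "man": (10.0, 1.0), "g0": (10.0, 1.0), "g1": (10.0, 1.0), "g2": (10.0, 1.0),
            "g_total": (20.0, 1.0), "s1": (20.0, 1.0), "s2": (30.0, 1.0), "s3": (5.0, 1.0),
            "s4": (5.0, 1.0), "s_total": (60.0, 1.0), "f_neutral": (0.0, 1.0),
            "f_sialo": (0.0, 1.0), "f_total": (0.0, 1.0), "b_neutral": (0.0, 1.0),
            "b_sialo": (0.0, 1.0), "b_total": (0.0, 1.0),
        }
        vec, residuals = calibrate_group_means(targets, sub)
        assert vec["H5N2"] == pytest.approx(10.0, abs=1e-9)
        assert vec["H5N4S2"] == pytest.approx(30.0, abs=1e-9)

    def test_doubled_targets_infeasible(self, library):
        doubled = {k: (2 * m, sd) for k, (m, sd) in GROUP_TRAIT_TARGETS["benign"].items()}
        with pytest.raises(ValueError, match="infeasible"):
            calibrate_group_means(doubled, library)

    def test_additivity_violation_reported(self, library):
        broken = dict(GROUP_TRAIT_TARGETS["benign"])
        broken["s_total"] = (70.0, 3.51)
        with pytest.raises(ValueError, match="additivity"):
            calibrate_group_means(broken, library)


@pytest.fixture(scope="module")
def fitted(library):
    return {g: calibrate_group_means(GROUP_TRAIT_TARGETS[g], library)[0] for g in ("benign", "early")}


class TestSampleSubjects:
    def test_sd_of_total_sialylation_matches_target(self, fitted, library):
        spec = CohortSpec(seed=3)
        subjects = [(f"B{i:03d}", "benign") for i in range(70)]
        truth = sample_subjects(spec, fitted, library, subjects, np.random.default_rng(3))
        sd = truth.traits["s_total"].std(ddof=1)
        assert sd == pytest.approx(3.51, rel=0.20)

    def test_group_mean_sits_on_calibrated_vector(self, fitted, library):
        spec = CohortSpec(seed=4)
        subjects = [(f"E{i:03d}", "early") for i in range(35)]
        truth = sample_subjects(spec, fitted, library, subjects, np.random.default_rng(4))
        assert np.allclose(truth.abundances.mean(axis=0), fitted["early"].to_numpy(), atol=1e-9)

    def test_ground_truth_traits_consistent_with_abundances(self, fitted, library):
        spec = CohortSpec(seed=5)
        subjects = [(f"B{i:03d}", "benign") for i in range(10)]
        truth = sample_subjects(spec, fitted, library, subjects, np.random.default_rng(5))
        for sid in truth.abundances.index:
            recomputed = compute_traits(
                GlycanProfile(sid, truth.abundances.loc[sid].to_dict()), library
            ).as_dict()
            for k, v in recomputed.items():
                assert truth.traits.loc[sid, k] == pytest.approx(v, abs=1e-12)

    def test_same_seed_identical_cohort(self, library):
        c1 = generate_cohort(CohortSpec(group_sizes={"normal": 4, "benign": 4, "cancer": 4}, seed=9))
        c2 = generate_cohort(CohortSpec(group_sizes={"normal": 4, "benign": 4, "cancer": 4}, seed=9))
        pd.testing.assert_frame_equal(c1.truth.abundances, c2.truth.abundances)
        pd.testing.assert_frame_equal(c1.metadata, c2.metadata)
        for p1, p2 in zip(c1.peaklists, c2.peaklists):
            assert np.array_equal(p1.mz, p2.mz) and np.array_equal(p1.intensity, p2.intensity)


class TestEmitPeaklists:
    def test_noise_free_round_trip_is_exact(self, library, mass_cfg):
        spec = CohortSpec(mz_jitter_ppm=0.0, centroid_jitter_ppm=0.0, noise_peaks=0, spot_cv=0.0, seed=1)
        vec, _ = calibrate_group_means(GROUP_TRAIT_TARGETS["benign"], library)
        abund = pd.DataFrame([vec], index=["B001"])
        pls = emit_peaklists(abund, mass_cfg, spec, library, np.random.default_rng(0))
        assert len(pls) == 3
        for pl in pls:
            prof = normalize_profile(annotate(pl, library.values(), mass_cfg), "B001")
            for k in vec.index:
                assert prof[k] == pytest.approx(vec[k], abs=1e-9)

    def test_moderate_jitter_recovery_within_half_point(self, library, mass_cfg):
        # 30 ppm spot drift + 10 ppm centroid noise + 5 noise peaks; intensity
        # scatter off to isolate the mass-error contribution
        spec = CohortSpec(spot_cv=0.0, seed=2)
        vec, _ = calibrate_group_means(GROUP_TRAIT_TARGETS["benign"], library)
        abund = pd.DataFrame([vec] * 10, index=[f"B{i:03d}" for i in range(10)])
        pls = emit_peaklists(abund, mass_cfg, spec, library, np.random.default_rng(2))
        from glycoserum.glycan_core import theoretical_mz
        from glycoserum.spectra import recalibrate
        cal = [theoretical_mz(a.composition, mass_cfg) for a in library.values()]
        errs = []
        for pl in pls:
            prof = normalize_profile(
                annotate(recalibrate(pl, cal), library.values(), mass_cfg), pl.sample_id
            )
            errs.append(max(abs(prof[k] - vec[k]) for k in vec.index))
        assert np.mean(errs) < 0.5


@pytest.fixture(scope="module")
def cohort140():
    return generate_cohort(CohortSpec(group_sizes={"benign": 70, "cancer": 70}, seed=11))


class TestEmitCovariates:
    def test_targeted_correlations_recovered(self, cohort140):
        meta = cohort140.metadata.set_index("sample_id")
        tr = cohort140.truth.traits
        r_s = pearson(tr["s_total"], meta["CA125"].reindex(tr.index)).r
        r_m = pearson(tr["man"], meta["CA125"].reindex(tr.index)).r
        assert -0.41 <= r_s <= -0.11
        assert r_m == pytest.approx(0.29, abs=0.15)
        assert r_m > 0

    def test_he4_independent_of_glycome(self, cohort140):
        meta = cohort140.metadata.set_index("sample_id")
        tr = cohort140.truth.traits
        for trait in ("s_total", "man", "g0", "g1"):
            assert abs(pearson(tr[trait], meta["HE4"].reindex(tr.index)).r) < 0.2

    def test_zero_targets_give_independence(self, cohort140, library):
        spec = CohortSpec(
            group_sizes={"benign": 70, "cancer": 70},
            correlation_targets={"s_total": 0.0, "man": 0.0},
            seed=11,
        )
        tr = cohort140.truth.traits
        groups = cohort140.metadata.set_index("sample_id")["group"].reindex(tr.index)
        cov = emit_covariates(tr, groups, spec, np.random.default_rng(1))
        assert abs(pearson(tr["s_total"], cov["CA125"]).r) < 0.1
        assert abs(pearson(tr["man"], cov["CA125"]).r) < 0.1

    def test_unattainable_joint_targets_rejected(self, cohort140):
        spec = CohortSpec(
            group_sizes={"benign": 70, "cancer": 70},
            correlation_targets={"s_total": 0.95, "s2": -0.95},
            seed=11,
        )
        tr = cohort140.truth.traits
        groups = cohort140.metadata.set_index("sample_id")["group"].reindex(tr.index)
        with pytest.raises(ValueError, match="unattainable"):
            emit_covariates(tr, groups, spec, np.random.default_rng(1))


class TestNormalGroupConvention:
    def test_directional_shifts(self):
        n = normal_group_targets()
        b = GROUP_TRAIT_TARGETS["benign"]
        assert n["man"][0] < b["man"][0]
        assert n["g0"][0] < b["g0"][0]
        assert n["b_neutral"][0] < b["b_neutral"][0]
        assert n["s_total"][0] > b["s_total"][0]
        assert n["s_total"][0] == pytest.approx(sum(n[k][0] for k in ("s1", "s2", "s3", "s4")), abs=1e-9)

    def test_normal_targets_are_feasible(self, library):
        vec, residuals = calibrate_group_means(normal_group_targets(), library)
        assert max(abs(r) for r in residuals.values()) < 1e-6
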