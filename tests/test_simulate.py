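"""Synthetic cohort generator: determinism, injections, clinical scores."""

import numpy as np
import pytest

from hubcausal.grids import BoldSeries, VolumeGrid
from hubcausal.preprocess import gm_mask_from_prob, motion_qc
from hubcausal.simulate import (
    EffectSpec,
    assign_clinical_scores,
    default_gm_prob,
    generate_cohort,
    inject_directed_coupling,
    inject_hub,
)


@pytest.fixture(scope="module")
def small_grid():
    return VolumeGrid.from_spacing((10, 12, 10), origin_mm=(-15, -18, -15))


def small_effects():
    """Effects scaled to a 10x12x10 grid (everything interior)."""
    return EffectSpec(
        hub_centers=((-6.0, 0.0, 0.0), (6.0, 0.0, 0.0)),
        hub_radius_mm=5.0,
        hub_gain=1.2,
        coupling_targets=((-6.0, 12.0, 0.0), (6.0, 12.0, 0.0)),
        coupling_radius_mm=4.0,
        coupling_strength=0.6,
    )


class TestDeterminism:
    def test_same_seed_identical_table_and_voxels(self, small_grid):
        kw = dict(n_patients=3, n_controls=3, grid=small_grid, n_volumes=40,
                  effects=small_effects(), seed=9)
        a = generate_cohort(**kw)
        b = generate_cohort(**kw)
        assert a.subjects.equals(b.subjects)
        for sid in a.subjects["subject_id"]:
            np.testing.assert_array_equal(a.bold_for(sid).data, b.bold_for(sid).data)

    def test_different_seeds_differ(self, small_grid):
        kw = dict(n_patients=2, n_controls=2, grid=small_grid, n_volumes=30,
                  effects=small_effects())
        a = generate_cohort(seed=1, **kw)
        b = generate_cohort(seed=2, **kw)
        assert not np.array_equal(
            a.bold_for("tin001").data, b.bold_for("tin001").data
        )


class TestInjectHub:
    def _bold(self, grid, rng, T=60):
        return BoldSeries(grid, rng.standard_normal((*grid.dims, T)))

    def test_gain_zero_is_identity(self, small_grid, rng):
        bold = self._bold(small_grid, rng)
        out = inject_hub(bold, (0, 0, 0), 5.0, 0.0, np.zeros(60))
        np.testing.assert_array_equal(out.data, bold.data)

    def test_large_gain_drives_suprathreshold_correlations(self, small_grid, rng):
        bold = self._bold(small_grid, rng, T=120)
        sig = np.sin(np.arange(120) / 4.0)
        sig = (sig - sig.mean()) / sig.std()
        gm = np.ones(small_grid.dims, dtype=bool)
        out = inject_hub(bold, (0.0, 0.0, 0.0), 5.0, 5.0, sig, gm_mask=gm, gm_gain=0.75)
        sphere = small_grid.sphere((0.0, 0.0, 0.0), 5.0)
        hub_series = out.data[sphere]
        other = out.data[~sphere & gm]
        rs = [
            np.corrcoef(hub_series[i % len(hub_series)], other[j])[0, 1]
            for i, j in zip(range(18), range(0, 180, 10))
        ]
        assert np.mean(rs) > 0.25

    def test_sub_voxel_radius_modifies_exactly_one_voxel(self, small_grid, rng):
        bold = self._bold(small_grid, rng)
        out = inject_hub(bold, (0.0, 0.0, 0.0), 2.0, 1.0, np.ones(60))
        changed = np.any(out.data != bold.data, axis=3)
        assert changed.sum() == 1

    def test_negative_radius_rejected(self, small_grid, rng):
        with pytest.raises(ValueError, match="radius"):
            inject_hub(self._bold(small_grid, rng), (0, 0, 0), -1.0, 1.0, np.ones(60))


class TestInjectCoupling:
    def _bold(self, grid, rng, T=80):
        return BoldSeries(grid, rng.standard_normal((*grid.dims, T)))

    def test_strength_zero_is_identity(self, small_grid, rng):
        bold = self._bold(small_grid, rng)
        out = inject_directed_coupling(bold, (-6, 0, 0), (6, 0, 0), 4.0, 0.0)
        np.testing.assert_array_equal(out.data, bold.data)

    def test_target_receives_exact_delayed_source_mean(self, small_grid, rng):
        bold = self._bold(small_grid, rng)
        src_c, tgt_c = (-6.0, 0.0, 0.0), (6.0, 0.0, 0.0)
        out = inject_directed_coupling(bold, src_c, tgt_c, 4.0, 0.7, lag=2)
        src = small_grid.sphere(src_c, 4.0)
        tgt = small_grid.sphere(tgt_c, 4.0)
        src_mean = bold.data[src].mean(axis=0)
        delta = out.data[tgt][0] - bold.data[tgt][0]
        np.testing.assert_allclose(delta[2:], 0.7 * src_mean[:-2], atol=1e-12)
        np.testing.assert_allclose(delta[:2], 0.0, atol=1e-12)
        # source untouched
        np.testing.assert_array_equal(out.data[src], bold.data[src])

    def test_overlapping_spheres_rejected(self, small_grid, rng):
        with pytest.raises(ValueError, match="overlap"):
            inject_directed_coupling(
                self._bold(small_grid, rng), (0, 0, 0), (3, 0, 0), 5.0, 1.0
            )

    def test_reverse_direction_stays_at_null_level(self, small_grid):
        """Coupling must not raise the reverse-direction F above its null."""
        from hubcausal.granger import bivariate_gc

        src_c, tgt_c = (-6.0, 0.0, 0.0), (6.0, 0.0, 0.0)
        src = small_grid.sphere(src_c, 4.0)
        tgt = small_grid.sphere(tgt_c, 4.0)
        rng = np.random.default_rng(77)
        null_f, coupled_rev_f = [], []
        for i in range(100):
            bold = self._bold(small_grid, rng, T=120)
            out = inject_directed_coupling(bold, src_c, tgt_c, 4.0, 1.0, lag=1)
            x = out.data[src].mean(axis=0)
            y = out.data[tgt].mean(axis=0)
            _, f_yx, _ = bivariate_gc(x, y, 1)
            coupled_rev_f.append(f_yx)
            xn = bold.data[src].mean(axis=0)
            yn = bold.data[tgt].mean(axis=0)
            _, f_yx_null, _ = bivariate_gc(xn, yn, 1)
            null_f.append(f_yx_null)
        crit = np.percentile(null_f, 95)
        assert np.mean(np.array(coupled_rev_f) > crit) <= 0.12


class TestClinicalScores:
    def _records(self, n_pat=24, n_ctl=22):
        import pandas as pd

        rows = [{"subject_id": f"t{i}", "group": "tinnitus", "thq": np.nan}
                for i in range(n_pat)]
        rows += [{"subject_id": f"c{i}", "group": "control", "thq": np.nan}
                 for i in range(n_ctl)]
        return pd.DataFrame(rows)

    def test_target_r_half_recovered(self, rng):
        records = self._records()
        strengths = rng.normal(0.6, 0.2, 24)
        out = assign_clinical_scores(records, strengths, 0.5, seed=4)
        thq = out.loc[out["group"] == "tinnitus", "thq"].to_numpy()
        r = np.corrcoef(thq, strengths)[0, 1]
        assert 0.35 <= r <= 0.65
        assert 35 <= thq.mean() <= 65

    def test_target_r_zero_stays_near_null(self, rng):
        records = self._records()
        strengths = rng.normal(0.6, 0.2, 24)
        out = assign_clinical_scores(records, strengths, 0.0, seed=8)
        thq = out.loc[out["group"] == "tinnitus", "thq"].to_numpy()
        assert abs(np.corrcoef(thq, strengths)[0, 1]) < 0.4

    def test_controls_keep_absent_thq(self, rng):
        records = self._records()
        out = assign_clinical_scores(records, rng.normal(0.6, 0.2, 24), 0.5, seed=1)
        assert out.loc[out["group"] == "control", "thq"].isna().all()

    def test_fewer_than_three_patients_rejected(self, rng):
        records = self._records(n_pat=2, n_ctl=5)
        with pytest.raises(ValueError, match="3 patients"):
            assign_clinical_scores(records, np.ones(2), 0.5, seed=0)


class TestCohortStructure:
    @pytest.fixture(scope="class")
    def cohort(self, small_grid):
        return generate_cohort(
            n_patients=6, n_controls=5, grid=small_grid, n_volumes=50,
            effects=small_effects(), seed=31,
        )

    def test_clinical_fields_present_iff_patient(self, cohort):
        df = cohort.subjects
        pat = df["group"] == "tinnitus"
        assert df.loc[pat, "thq"].notna().all()
        assert df.loc[pat, "tinnitus_duration"].notna().all()
        assert df.loc[~pat, "thq"].isna().all()
        assert df.loc[~pat, "tinnitus_duration"].isna().all()

    def test_hearing_thresholds_below_inclusion_limit(self, cohort):
        df = cohort.subjects
        assert (df["hearing_left"] < 25).all()
        assert (df["hearing_right"] < 25).all()

    def test_gm_probabilities_in_unit_interval(self, cohort):
        assert cohort.gm_prob.data.min() >= 0
        assert cohort.gm_prob.data.max() <= 1

    def test_hub_degree_elevated_in_patients(self, cohort, small_grid):
        """Direct computation: mean weighted degree inside the hub spheres is
        higher for a patient than for a control."""
        from hubcausal.degree import degree_map
        from hubcausal.preprocess import preprocess_bold

        gm = gm_mask_from_prob(cohort.gm_prob, 0.2)
        eff = cohort.effects
        hub = np.zeros(small_grid.dims, dtype=bool)
        for c in eff.hub_centers:
            hub |= small_grid.sphere(c, eff.hub_radius_mm)
        hub &= gm.data

        def hub_degree(sid):
            pre = preprocess_bold(cohort.bold_for(sid), discard=5)
            res = degree_map(pre, gm, 0.25, "weighted")
            return res.raw.data[hub].mean()

        pat = np.mean([hub_degree(s) for s in ("tin001", "tin002", "tin003")])
        ctl = np.mean([hub_degree(s) for s in ("ctl001", "ctl002", "ctl003")])
        assert pat > ctl

    def test_manifest_records_ground_truth(self, cohort):
        m = cohort.manifest()
        assert m["effects"]["hub_gain"] == pytest.approx(1.2)
        assert len(m["coupling_strength_by_subject"]) == 6

    def test_high_motion_subject_fails_qc(self, small_grid):
        cohort = generate_cohort(
            n_patients=3, n_controls=3, grid=small_grid, n_volumes=30,
            effects=small_effects(), seed=2, high_motion_subject=True,
        )
        assert len(cohort.subjects) == 7
        qc = motion_qc(cohort.motion_for("tin004"), 2.0, 2.0)
        assert not qc.passed
        others_pass = [
            motion_qc(cohort.motion_for(s), 2.0, 2.0).passed
            for s in cohort.subjects["subject_id"] if s != "tin004"
        ]
        assert all(others_pass)

    def test_cohort_write_layout(self, small_grid, tmp_path):
        cohort = generate_cohort(
            n_patients=2, n_controls=2, grid=small_grid, n_volumes=20,
            effects=small_effects(), seed=5,
        )
        out = cohort.write(tmp_path / "cohort")
        assert (out / "subjects.csv").exists()
        assert (out / "gm_prob.nii.gz").exists()
        assert (out / "effects_manifest.json").exists()
        assert len(list((out / "bold").glob("*.nii.gz"))) == 4
        assert len(list((out / "motion").glob("*.txt"))) == 4


def test_hub_center_outside_grid_rejected(small_grid):
    eff = EffectSpec(hub_centers=((500.0, 0.0, 0.0),))
    with pytest.raises(ValueError, match="outside"):
        generate_cohort(n_patients=2, n_controls=2, grid=small_grid,
                        n_volumes=20, effects=eff, seed=0)


def test_nonpositive_counts_rejected(small_grid):
    with pytest.raises(ValueError, match="positive"):
        generate_cohort(n_patients=0, n_controls=5, grid=small_grid,
                        n_volumes=20, effects=small_effects(), seed=0)
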