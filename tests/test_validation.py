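"""Motion screening, denoising, Fisher-z maps and the covariate GLM."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from ticnet.grid import BinaryMask, make_grid
from ticnet.inference import PermutationScheme
from ticnet.specificity import two_sample_glm_tmap
from ticnet.grid import ScalarVolume
from ticnet.validation import (
    DenoiseConfig,
    ParticipantScan,
    censor_and_screen,
    denoise,
    framewise_displacement,
    group_difference_clusters,
    motion_comparison,
    participant_fz_map,
)


def _scan(bold, motion=None, nuisance=None, tr=0.8, group="patient"):
    t = bold.shape[0]
    return ParticipantScan(
        participant_id="sub-test",
        bold=bold,
        motion=np.zeros((t, 6)) if motion is None else motion,
        nuisance=np.zeros((t, 2)) if nuisance is None else nuisance,
        tr_seconds=tr, age=12.0, sex="F", site="siteA", group=group,
    )


class TestFramewiseDisplacement:
    def test_zero_motion_gives_zero_fd(self):
        assert np.all(framewise_displacement(np.zeros((20, 6))) == 0.0)

    def test_single_translation_step(self):
        motion = np.zeros((10, 6))
        motion[5:, 0] = 0.3
        fd = framewise_displacement(motion)
        assert fd[5] == pytest.approx(0.3)
        assert np.all(np.delete(fd, 5) == 0.0)

    def test_rotation_projected_onto_50mm_sphere(self):
        motion = np.zeros((10, 6))
        motion[4:, 3] = 0.01  # radians
        fd = framewise_displacement(motion)
        assert fd[4] == pytest.approx(0.5)

    def test_first_frame_is_zero_and_offsets_ignored(self):
        rng = np.random.default_rng(0)
        motion = rng.standard_normal((30, 6)).cumsum(axis=0) * 0.01
        fd = framewise_displacement(motion)
        assert fd[0] == 0.0
        shifted = framewise_displacement(motion + np.arange(6))
        assert np.allclose(fd, shifted)

    def test_wrong_column_count_rejected(self):
        with pytest.raises(ValueError):
            framewise_displacement(np.zeros((10, 5)))


class TestCensorAndScreen:
    def _motion_with_jumps(self, t, n_jumps, start=10):
        """Staircase translations: each jump produces exactly one FD > 0.5."""
        motion = np.zeros((t, 6))
        jump_frames = np.linspace(start, t - 1, n_jumps).astype(int)
        level = 0.0
        for f in jump_frames:
            level += 0.8
            motion[f:, 0] = level
        return motion

    def test_quiet_scan_keeps_everything(self):
        cfg = DenoiseConfig(min_volumes=10)
        scan = _scan(np.zeros((50, 4)))
        out = censor_and_screen(scan, cfg)
        assert out.included and out.n_kept == 50 - cfg.discard_initial

    def test_twenty_bad_frames_of_310_fails_the_300_screen(self):
        motion = self._motion_with_jumps(314, 20)
        scan = _scan(np.zeros((314, 4)), motion=motion)
        out = censor_and_screen(scan, DenoiseConfig())
        assert out.n_kept == 290
        assert not out.included

    def test_exactly_300_remaining_is_included(self):
        motion = self._motion_with_jumps(314, 10)
        scan = _scan(np.zeros((314, 4)), motion=motion)
        out = censor_and_screen(scan, DenoiseConfig())
        assert out.n_kept == 300
        assert out.included


class TestDenoise:
    def test_nuisance_identical_to_voxel_series_removes_it(self):
        rng = np.random.default_rng(1)
        t = 104
        series = rng.standard_normal(t)
        bold = np.column_stack([series, rng.standard_normal(t)])
        nuis = np.column_stack([series, rng.standard_normal(t)])
        cleaned = denoise(_scan(bold, nuisance=nuis), DenoiseConfig(min_volumes=50))
        assert np.max(np.abs(cleaned[:, 0])) < 1e-8

    @pytest.mark.parametrize("freq,bound,keep", [
        (0.05, 0.9, True),    # inside the 0.008-0.09 Hz pass band
        (0.2, 0.1, False),    # outside: attenuated at least tenfold
        (0.18, 0.1, False),   # 2x the high edge: >= 20 dB attenuation
    ])
    def test_bandpass_frequency_response(self, freq, bound, keep):
        t, tr = 504, 0.8
        time = np.arange(t) * tr
        series = np.sin(2 * np.pi * freq * time)
        bold = np.tile(series[:, None], (1, 2))
        cleaned = denoise(_scan(bold, tr=tr), DenoiseConfig(min_volumes=100))
        ratio = cleaned[:, 0].std() / series[4:].std()
        if keep:
            assert ratio >= bound
        else:
            assert ratio <= bound

    def test_collinear_nuisance_columns_warn_and_drop(self):
        rng = np.random.default_rng(2)
        t = 104
        col = rng.standard_normal(t)
        nuis = np.column_stack([col, col])
        with pytest.warns(UserWarning, match="collinear"):
            denoise(_scan(rng.standard_normal((t, 3)), nuisance=nuis),
                    DenoiseConfig(min_volumes=50))

    def test_band_must_fit_under_nyquist(self):
        scan = _scan(np.zeros((50, 2)), tr=10.0)  # Nyquist 0.05 Hz < 0.09
        with pytest.raises(ValueError, match="Nyquist"):
            denoise(scan, DenoiseConfig(min_volumes=10))


class TestParticipantFz:
    def _world(self):
        grid = make_grid((4, 4, 4), voxel_mm=2.0)
        brain = BinaryMask(grid, np.ones(grid.dims, bool))
        seed = np.zeros(grid.dims, bool)
        seed[0, 0, 0] = True
        return grid, brain, BinaryMask(grid, seed)

    def test_known_correlation_maps_to_atanh(self):
        grid, brain, seed = self._world()
        rng = np.random.default_rng(3)
        t = 200
        s = rng.standard_normal(t)
        s = (s - s.mean()) / np.linalg.norm(s - s.mean())
        e = rng.standard_normal(t)
        e -= e.mean()
        e -= (e @ s) * s
        e /= np.linalg.norm(e)
        ts = rng.standard_normal((t, brain.size))
        ts[:, 0] = s
        ts[:, 1] = 0.5 * s + np.sqrt(0.75) * e
        fz = participant_fz_map(ts, seed, brain)
        assert fz[1] == pytest.approx(np.arctanh(0.5), abs=1e-10)
        assert fz[1] == pytest.approx(0.5493, abs=1e-4)

    def test_odd_symmetry(self):
        grid, brain, seed = self._world()
        rng = np.random.default_rng(4)
        ts = rng.standard_normal((60, brain.size))
        fz = participant_fz_map(ts, seed, brain)
        flipped = ts.copy()
        flipped[:, 1:] *= -1
        fz2 = participant_fz_map(flipped, seed, brain)
        assert np.allclose(fz2[1:], -fz[1:], atol=1e-12)


class TestGroupDifferenceClusters:
    def _fz_world(self, n_per_group=8, v=None, seed=0):
        grid = make_grid((6, 6, 6), voxel_mm=2.0)
        mask = BinaryMask(grid, np.ones(grid.dims, bool))
        rng = np.random.default_rng(seed)
        n = 2 * n_per_group
        fz = rng.standard_normal((n, mask.size)) * 0.2
        cov = pd.DataFrame({
            "group": ["patient"] * n_per_group + ["control"] * n_per_group,
            "age": rng.uniform(6, 17, n),
            "sex": rng.choice(["M", "F"], n),
            "site": np.tile(["siteA", "siteB"], n // 2),
        })
        return grid, mask, fz, cov

    def test_constant_covariates_reduce_to_two_sample_t(self):
        grid, mask, fz, cov = self._fz_world()
        cov["age"] = 10.0
        cov["sex"] = "F"
        cov["site"] = "siteA"
        with pytest.warns(UserWarning):
            res = group_difference_clusters(
                fz, cov, grid, mask,
                scheme=PermutationScheme(n_perm=10, rng_seed=0))
        n_half = len(cov) // 2
        case = [ScalarVolume(grid, row.reshape(grid.dims)) for row in fz[:n_half]]
        ctrl = [ScalarVolume(grid, row.reshape(grid.dims)) for row in fz[n_half:]]
        expected = two_sample_glm_tmap(case, ctrl)
        assert np.allclose(res.group_t.values, expected.values, atol=1e-8)

    def test_planted_group_difference_forms_significant_cluster(self):
        grid, mask, fz, cov = self._fz_world(n_per_group=10, seed=5)
        effect_vox = np.zeros(grid.dims, bool)
        effect_vox[2:5, 2:5, 2:5] = True
        cols = np.flatnonzero(effect_vox.ravel())
        fz[: len(cov) // 2][:, cols] += 1.0
        res = group_difference_clusters(
            fz, cov, grid, mask, scheme=PermutationScheme(n_perm=100, rng_seed=1))
        sig = [c for c in res.clusters if c.fwe_p < 0.05]
        assert len(sig) == 1
        assert sig[0].sign == 1
        assert sig[0].peak_t > res.t_height
        # per-participant mean Fz in the cluster separates the groups
        fz_tab = res.per_group_cluster_fz
        pat = fz_tab.loc[fz_tab["group"] == "patient", "cluster_1"].mean()
        con = fz_tab.loc[fz_tab["group"] == "control", "cluster_1"].mean()
        assert pat > con + 0.5

    def test_site_with_single_group_warns(self):
        grid, mask, fz, cov = self._fz_world()
        cov.loc[cov["group"] == "patient", "site"] = "siteC"
        with pytest.warns(UserWarning, match="site"):
            group_difference_clusters(
                fz, cov, grid, mask, scheme=PermutationScheme(n_perm=5, rng_seed=0))

    def test_too_few_participants_rejected(self):
        grid, mask, fz, cov = self._fz_world(n_per_group=2)
        with pytest.raises(ValueError):
            group_difference_clusters(fz, cov, grid, mask)


class TestMotionComparison:
    def test_identical_groups(self):
        t, p = motion_comparison([0.2, 0.2, 0.2], [0.2, 0.2, 0.2])
        assert t == 0.0 and p == 1.0

    def test_matches_scipy_oracle(self):
        rng = np.random.default_rng(6)
        a = rng.uniform(0.1, 0.4, 12)
        b = rng.uniform(0.1, 0.5, 15)
        t, p = motion_comparison(a, b)
        expected = stats.ttest_ind(a, b, equal_var=True)
        assert t == pytest.approx(expected.statistic)
        assert p == pytest.approx(expected.pvalue)

    def test_symmetry_under_group_swap(self):
        a, b = [0.1, 0.3, 0.2], [0.25, 0.15, 0.4, 0.3]
        t1, p1 = motion_comparison(a, b)
        t2, p2 = motion_comparison(b, a)
        assert t1 == pytest.approx(-t2)
        assert p1 == pytest.approx(p2)


class TestTableReaders:
    def test_headerless_six_column_motion(self, tmp_path):
        from ticnet.validation import read_motion_table
        rng = np.random.default_rng(7)
        motion = np.column_stack([rng.normal(0, 0.1, (20, 3)),
                                  rng.normal(0, 0.002, (20, 3))])
        path = tmp_path / "motion.txt"
        np.savetxt(path, motion)
        back = read_motion_table(path)
        assert np.allclose(back, motion, atol=1e-12)

    def test_confounds_style_named_columns(self, tmp_path):
        from ticnet.validation import read_motion_table
        rng = np.random.default_rng(8)
        df = pd.DataFrame({
            "framewise_displacement": rng.random(10),
            "rot_x": rng.normal(0, 0.001, 10),
            "rot_y": rng.normal(0, 0.001, 10),
            "rot_z": rng.normal(0, 0.001, 10),
            "trans_x": rng.normal(0, 0.1, 10),
            "trans_y": rng.normal(0, 0.1, 10),
            "trans_z": rng.normal(0, 0.1, 10),
        })
        path = tmp_path / "confounds.tsv"
        df.to_csv(path, sep="\t", index=False)
        back = read_motion_table(path)
        assert np.allclose(back[:, 0], df["trans_x"])
        assert np.allclose(back[:, 3], df["rot_x"])

    def test_degree_like_rotations_are_rejected(self, tmp_path):
        from ticnet.validation import read_motion_table
        motion = np.zeros((5, 6))
        motion[:, 3] = 45.0  # plainly degrees
        path = tmp_path / "deg.txt"
        np.savetxt(path, motion)
        with pytest.raises(ValueError, match="radians"):
            read_motion_table(path)

    def test_covariates_reader_validates_columns_and_groups(self, tmp_path):
        from ticnet.validation import read_covariates_table
        df = pd.DataFrame({"id": ["a", "b"], "age": [10, 12],
                           "sex": ["M", "F"], "site": ["s1", "s2"],
                           "group": ["patient", "control"]})
        path = tmp_path / "cov.tsv"
        df.to_csv(path, sep="\t", index=False)
        back = read_covariates_table(path)
        assert list(back["id"]) == ["a", "b"]
        df.loc[0, "group"] = "case"
        df.to_csv(path, sep="\t", index=False)
        with pytest.raises(ValueError, match="group"):
            read_covariates_table(path)
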