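"""Task-PLS decomposition, permutation inference and bootstrap stability."""

import numpy as np
import pandas as pd
import pytest

import neurolex as nx


def make_input(rng, n_cond=3, n_subj=8, n_feat=6, effect=None):
    arr = rng.standard_normal((n_cond, n_subj, n_feat))
    if effect is not None:
        arr += effect[:, None, :]
    return nx.PlsInput.from_stack(arr)


def svd_oracle(arr):
    """Independent singular values via eigen-decomposition of R R^T."""
    m = arr.mean(axis=1)
    r = m - m.mean(axis=0, keepdims=True)
    eig = np.linalg.eigvalsh(r @ r.T)
    return np.sqrt(np.clip(eig, 0, None))[::-1], r


class TestFit:
    def test_identical_condition_means_yield_no_lvs(self, rng):
        base = rng.standard_normal((1, 6, 5))
        arr = np.repeat(base, 3, axis=0)   # same subject rows per condition
        assert nx.fit_task_pls(nx.PlsInput.from_stack(arr)) == []

    def test_two_conditions_give_single_symmetric_lv(self, rng):
        inp = make_input(rng, n_cond=2, effect=rng.standard_normal((2, 6)))
        lvs = nx.fit_task_pls(inp)
        assert len(lvs) == 1
        np.testing.assert_allclose(np.abs(lvs[0].design_saliences),
                                   [1 / np.sqrt(2)] * 2, atol=1e-12)

    def test_singular_values_match_eigen_oracle(self, rng):
        arr = rng.standard_normal((3, 5, 6))
        lvs = nx.fit_task_pls(nx.PlsInput.from_stack(arr))
        s_oracle, r = svd_oracle(arr)
        got = [lv.singular_value for lv in lvs]
        np.testing.assert_allclose(got, s_oracle[: len(got)], atol=1e-10)
        # sum s^2 equals squared Frobenius norm of the centered matrix
        assert np.sum(np.square(got)) == pytest.approx(np.sum(r * r), rel=1e-10)
        assert sum(lv.covariance_explained for lv in lvs) == pytest.approx(1.0)

    def test_salience_orthonormality(self, rng):
        arr = rng.standard_normal((4, 6, 10))
        lvs = nx.fit_task_pls(nx.PlsInput.from_stack(arr))
        u = np.column_stack([lv.design_saliences for lv in lvs])
        v = np.column_stack([lv.feature_saliences for lv in lvs])
        np.testing.assert_allclose(u.T @ u, np.eye(len(lvs)), atol=1e-8)
        np.testing.assert_allclose(v.T @ v, np.eye(len(lvs)), atol=1e-8)

    def test_deterministic_sign_convention(self, rng):
        arr = rng.standard_normal((3, 5, 6))
        for _ in range(3):
            lvs = nx.fit_task_pls(nx.PlsInput.from_stack(arr))
            for lv in lvs:
                assert lv.feature_saliences[np.argmax(np.abs(lv.feature_saliences))] > 0

    def test_scale_equivariance(self, rng):
        arr = rng.standard_normal((3, 5, 6))
        lv1 = nx.fit_task_pls(nx.PlsInput.from_stack(arr))[0]
        lv1c = nx.fit_task_pls(nx.PlsInput.from_stack(3.0 * arr))[0]
        assert lv1c.singular_value == pytest.approx(3.0 * lv1.singular_value)
        np.testing.assert_allclose(lv1c.design_saliences, lv1.design_saliences,
                                   atol=1e-10)

    def test_nan_input_rejected_and_column_drop(self, rng):
        arr = rng.standard_normal((2, 4, 5))
        arr[0, 1, 3] = np.nan
        with pytest.raises(ValueError, match="missing"):
            nx.PlsInput.from_stack(arr)
        inp = nx.PlsInput.from_stack(arr, drop_nan_columns=True)
        assert inp.data.shape[1] == 4 and inp.n_dropped_columns == 1


class TestPermutation:
    def test_overwhelming_effect_gives_p_zero(self, rng):
        effect = np.array([[10.0] * 6, [0.0] * 6, [-10.0] * 6]) * 20
        inp = make_input(rng, effect=effect)
        lvs = nx.fit_task_pls(inp)
        p = nx.permutation_test(inp, lvs, n_perm=200, rng=rng)
        assert p[0] == 0.0 and lvs[0].perm_p == 0.0

    def test_fixed_seed_reproducible(self, rng):
        inp = make_input(rng)
        lvs = nx.fit_task_pls(inp)
        p1 = nx.permutation_test(inp, lvs, n_perm=50, rng=np.random.default_rng(3))
        p2 = nx.permutation_test(inp, lvs, n_perm=50, rng=np.random.default_rng(3))
        np.testing.assert_array_equal(p1, p2)

    def test_single_condition_rejected(self, rng):
        inp = nx.PlsInput(rng.standard_normal((4, 3)), n_subjects=4,
                          n_conditions=1)
        with pytest.raises(ValueError, match="2 conditions"):
            nx.permutation_test(inp, [], n_perm=10, rng=rng)

    def test_null_rejection_rate_calibrated(self, rng):
        # exchangeable data: LV1 perm p < .05 should occur at ~5%
        hits = 0
        n_data = 120
        for _ in range(n_data):
            inp = make_input(rng, n_subj=10, n_feat=12)
            lvs = nx.fit_task_pls(inp)
            hits += nx.permutation_test(inp, lvs, n_perm=60, rng=rng)[0] < 0.05
        # binomial 99% band around .05 for 120 draws
        assert 1 <= hits <= 13


class TestBootstrap:
    def test_duplicating_subjects_shrinks_se(self, rng):
        effect = rng.standard_normal((3, 8)) * 2
        arr = rng.standard_normal((3, 6, 8)) + effect[:, None, :]
        inp = nx.PlsInput.from_stack(arr)
        lvs = nx.fit_task_pls(inp)
        r1 = nx.bootstrap_stability(inp, lvs, n_boot=150,
                                    rng=np.random.default_rng(5))
        arr2 = np.concatenate([arr, arr], axis=1)
        inp2 = nx.PlsInput.from_stack(arr2)
        lvs2 = nx.fit_task_pls(inp2)
        r2 = nx.bootstrap_stability(inp2, lvs2, n_boot=150,
                                    rng=np.random.default_rng(5))
        assert np.median(np.abs(r2[0])) > np.median(np.abs(r1[0]))

    def test_scale_invariance_of_ratios(self, rng):
        arr = rng.standard_normal((3, 6, 8))
        inp = nx.PlsInput.from_stack(arr)
        lvs = nx.fit_task_pls(inp)
        r1 = nx.bootstrap_stability(inp, lvs, n_boot=80,
                                    rng=np.random.default_rng(9))
        inp2 = nx.PlsInput.from_stack(7.0 * arr)
        lvs2 = nx.fit_task_pls(inp2)
        r2 = nx.bootstrap_stability(inp2, lvs2, n_boot=80,
                                    rng=np.random.default_rng(9))
        np.testing.assert_allclose(r1, r2, atol=1e-8)

    def test_too_few_subjects_rejected(self, rng):
        inp = make_input(rng, n_subj=2)
        lvs = nx.fit_task_pls(inp)
        with pytest.raises(ValueError, match="3 subjects"):
            nx.bootstrap_stability(inp, lvs, n_boot=10, rng=rng)

    def test_fixed_seed_reproducible(self, rng):
        inp = make_input(rng)
        lvs = nx.fit_task_pls(inp)
        r1 = nx.bootstrap_stability(inp, lvs, n_boot=40, rng=np.random.default_rng(1))
        lvs = nx.fit_task_pls(inp)
        r2 = nx.bootstrap_stability(inp, lvs, n_boot=40, rng=np.random.default_rng(1))
        np.testing.assert_array_equal(r1, r2)


class TestStableWindows:
    def make_lv(self, bsr, sal=None):
        lv = nx.PlsLatentVariable(
            design_saliences=np.array([0.7, -0.7]),
            feature_saliences=np.asarray(sal if sal is not None
                                         else np.sign(bsr) * 0.1, dtype=float),
            singular_value=1.0, covariance_explained=1.0)
        lv.bootstrap_ratios = np.asarray(bsr, dtype=float)
        return lv

    def index(self, n, channel="Pz", dt=2.0, start=100.0):
        return pd.DataFrame({"channel": channel,
                             "position": start + dt * np.arange(n)})

    def test_all_below_threshold_empty(self):
        lv = self.make_lv(np.full(20, 1.5))
        assert nx.extract_stable_windows(lv, self.index(20)).empty

    def test_single_forced_window(self):
        bsr = np.zeros(40)
        bsr[10:26] = 2.5                       # positions 120..150 ms
        lv = self.make_lv(bsr)
        w = nx.extract_stable_windows(lv, self.index(40), min_run_ms=10.0)
        assert len(w) == 1
        assert (w.start.iloc[0], w.end.iloc[0]) == (120.0, 150.0)
        assert w.sign.iloc[0] == 1

    def test_short_runs_dropped_by_min_duration(self):
        bsr = np.zeros(40)
        bsr[5:8] = 3.0                          # 3 samples = 6 ms < 10 ms
        lv = self.make_lv(bsr)
        assert nx.extract_stable_windows(lv, self.index(40), min_run_ms=10.0).empty

    def test_sign_change_splits_runs(self):
        bsr = np.concatenate([np.full(10, 3.0), np.full(10, -3.0)])
        sal = np.concatenate([np.full(10, 0.2), np.full(10, -0.2)])
        lv = self.make_lv(bsr, sal)
        w = nx.extract_stable_windows(lv, self.index(20), min_run_ms=10.0)
        assert len(w) == 2 and list(w.sign) == [1, -1]

    def test_scale_features_allow_single_point(self):
        bsr = np.zeros(22)
        bsr[3] = 2.4
        lv = self.make_lv(bsr)
        idx = pd.DataFrame({"channel": "Fz", "position": 2.0 * np.arange(1, 23)})
        w = nx.extract_stable_windows(lv, idx, scale_features=True)
        assert len(w) == 1 and w.start.iloc[0] == 8.0


class TestRunTaskPls:
    def test_descriptive_mode_skips_inference(self, rng):
        inp = make_input(rng)
        res = nx.run_task_pls(inp, n_perm=0, n_boot=0)
        assert res.lvs and res.lvs[0].perm_p is None
        assert res.lvs[0].bootstrap_ratios is None
        assert res.stable_windows is None
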