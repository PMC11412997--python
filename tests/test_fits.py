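"""Model fits, category contrasts, latency, trial-level fits, behavior."""

import numpy as np
import pandas as pd
import pytest

from wmrsa import fits, models, rsm, synth
from conftest import brute_force_spearman


def _random_rsm_stack(rng, n_subj, w, f, n):
    stacks = []
    for _ in range(n_subj):
        x = rng.standard_normal((w, f, n, 8))
        stack = np.einsum("wfnd,wfmd->wfnm", x, x)
        norm = np.sqrt(np.einsum("wfnn->wfn", stack))
        stack = stack / (norm[:, :, :, None] * norm[:, :, None, :])
        stacks.append(stack)
    return stacks


class TestModelFitMap:
    def test_self_fit_identity(self, rng):
        """Using a subject's own RSM as the model returns rho = 1 (z capped)."""
        cats = np.repeat(np.arange(3), 4)
        stacks = _random_rsm_stack(rng, 2, 2, 2, 12)
        fm = fits.model_fit_map(
            [stacks[0], stacks[0]],
            stacks[0][0, 0],
            cats,
            np.arange(2),
            np.arange(2),
        )
        assert fm.z[0, 0, 0] == pytest.approx(np.arctanh(fits.RHO_CAP))
        assert fm.z[1, 0, 0] == pytest.approx(np.arctanh(fits.RHO_CAP))

    def test_null_fits_center_on_zero(self, rng):
        cats = np.repeat(np.arange(3), 4)
        stim = synth.make_stimulus_set(3, 4)
        stacks = _random_rsm_stack(rng, 10, 3, 3, 12)
        fm = fits.model_fit_map(
            stacks,
            models.category_model(stim),
            cats,
            np.arange(3),
            np.arange(3),
        )
        assert abs(fm.z.mean()) < 0.05
        assert np.nanmax(np.abs(fm.t)) < 6.0

    def test_masked_vectors_partition_all_pairs(self, rng):
        cats = np.repeat(np.arange(3), 4)
        stacks = _random_rsm_stack(rng, 4, 1, 1, 12)
        model = rng.standard_normal((12, 12))
        model = (model + model.T) / 2
        zs = {}
        for mask in ("all", "within", "between"):
            zs[mask] = fits.model_fit_map(
                stacks, model, cats, [0.0], [10.0], mask=mask
            )
        iu = np.triu_indices(12, k=1)
        within = cats[iu[0]] == cats[iu[1]]
        # the within- and between-mask pair sets concatenate to the full set
        assert within.sum() + (~within).sum() == iu[0].size
        # and each masked fit matches a brute-force Spearman on its subset
        vec0 = stacks[0][0, 0][iu]
        mvec = model[iu]
        assert np.tanh(zs["within"].z[0, 0, 0]) == pytest.approx(
            brute_force_spearman(vec0[within], mvec[within]), abs=1e-10
        )
        assert np.tanh(zs["between"].z[0, 0, 0]) == pytest.approx(
            brute_force_spearman(vec0[~within], mvec[~within]), abs=1e-10
        )
        assert np.tanh(zs["all"].z[0, 0, 0]) == pytest.approx(
            brute_force_spearman(vec0, mvec), abs=1e-10
        )

    def test_group_stats_invariant_to_subject_order(self, rng):
        cats = np.repeat(np.arange(3), 4)
        stim = synth.make_stimulus_set(3, 4)
        stacks = _random_rsm_stack(rng, 6, 2, 2, 12)
        fm1 = fits.model_fit_map(
            stacks, models.category_model(stim), cats, [0, 1], [0, 1]
        )
        fm2 = fits.model_fit_map(
            stacks[::-1], models.category_model(stim), cats, [0, 1], [0, 1]
        )
        assert np.allclose(fm1.t, fm2.t)

    def test_constant_model_rejected(self, rng):
        stacks = _random_rsm_stack(rng, 3, 1, 1, 6)
        with pytest.raises(ValueError, match="constant"):
            fits.model_fit_map(
                stacks, np.ones((6, 6)), np.repeat([0, 1], 3), [0.0], [3.0]
            )

    def test_item_set_mismatch_rejected(self, rng):
        stacks = _random_rsm_stack(rng, 3, 1, 1, 6)
        with pytest.raises(ValueError, match="item set"):
            fits.model_fit_map(
                stacks, np.eye(5), np.repeat([0, 1], 3), [0.0], [3.0]
            )


def _feature_series(rng, n_items, n_windows, d, categories, trials=None):
    if trials is None:
        trials = [{i} for i in range(n_items)]
    return rsm.FeatureSeries(
        data=rng.standard_normal((n_items, n_windows, d)),
        window_times=np.arange(n_windows) * 0.1,
        items=np.arange(n_items),
        categories=np.asarray(categories),
        contributing_trials=[set(t) for t in trials],
        scope="band:beta",
    )


class TestCategoryContrast:
    def test_overlap_exclusion_bookkeeping(self, rng):
        # items of different categories presented in overlapping trials are
        # excluded; the same pair without overlap is included
        cats = [0, 1, 0, 1]
        trials = [{1, 3}, {3, 5}, {7, 8}, {4, 5}]
        feats = _feature_series(rng, 4, 2, 10, cats, trials)
        excl = fits._overlap_exclusion(feats, feats)
        iu = np.triu_indices(4, k=1)
        pairs = {(int(a), int(b)): bool(e) for a, b, e in zip(iu[0], iu[1], excl)}
        assert pairs[(0, 1)] is True  # trials {1,3} and {3,5} share trial 3
        assert pairs[(0, 3)] is False  # trials {1,3} and {4,5} do not overlap
        assert pairs[(1, 3)] is True  # trial 5 shared

    def test_null_data_contrast_centers_on_zero(self, rng):
        cats = np.repeat(np.arange(3), 4)
        feats = [_feature_series(rng, 12, 3, 30, cats) for _ in range(10)]
        gm = fits.category_contrast(feats)
        assert abs(gm.subject_maps.mean()) < 0.05
        assert np.max(np.abs(gm.t)) < 6.0

    def test_injected_templates_give_diagonal_dominant_ees(self, rng):
        cats = np.repeat(np.arange(3), 4)
        tpl = rng.standard_normal((3, 40))
        feats = []
        for _ in range(6):
            f = _feature_series(rng, 12, 4, 40, cats)
            # category template active only at matching windows 1 and 2
            for i, c in enumerate(cats):
                f.data[i, 1] += 2.0 * tpl[c]
                f.data[i, 2] += 2.0 * tpl[c]
            feats.append(f)
        gm = fits.category_contrast(feats, n_perm=100, seed=0)
        diag = np.diag(gm.t)
        assert diag[1] > 3 and diag[2] > 3
        assert gm.t[0, 0] < diag[1]
        assert len(gm.clusters.significant(0.05)) >= 1

    def test_antisymmetric_under_role_swap(self, rng):
        """Swapping the roles of same and different pairs negates the map."""
        cats = np.repeat([0, 1, 2], 2)
        feats = [_feature_series(rng, 6, 2, 12, cats) for _ in range(5)]
        gm = fits.category_contrast(feats)
        iu = np.triu_indices(6, k=1)
        same = cats[iu[0]] == cats[iu[1]]
        for s, f in enumerate(feats):
            z = fits._pairwise_z(f, f)[:, :, iu[0], iu[1]]
            swapped = z[..., ~same].mean(-1) - z[..., same].mean(-1)
            assert np.allclose(gm.subject_maps[s], -swapped, atol=1e-10)

    def test_cross_phase_maps_and_ragged_item_sets(self, rng):
        cats_a = np.repeat(np.arange(3), 4)
        feats_a, feats_b = [], []
        for s in range(4):
            fa = _feature_series(rng, 12, 3, 20, cats_a)
            keep = np.sort(rng.choice(12, size=8, replace=False))
            fb = rsm.FeatureSeries(
                data=rng.standard_normal((8, 2, 20)),
                window_times=np.arange(2) * 0.1,
                items=fa.items[keep],
                categories=cats_a[keep],
                contributing_trials=[fa.contributing_trials[k] for k in keep],
                scope="band:beta",
            )
            fa_sub = rsm.FeatureSeries(
                data=fa.data[keep],
                window_times=fa.window_times,
                items=fa.items[keep],
                categories=cats_a[keep],
                contributing_trials=[fa.contributing_trials[k] for k in keep],
                scope=fa.scope,
            )
            feats_a.append(fa_sub)
            feats_b.append(fb)
        gm = fits.category_contrast(feats_a, feats_b, n_perm=60, seed=1)
        assert gm.subject_maps.shape == (4, 3, 2)
        assert gm.clusters is not None

    def test_zero_surviving_pairs_rejected(self, rng):
        cats = [0, 0, 1, 1]
        trials = [{1}, {2}, {1, 2}, {1, 2}]  # every cross-category pair overlaps
        feats = [_feature_series(rng, 4, 2, 10, cats, trials)]
        feats.append(_feature_series(rng, 4, 2, 10, cats, trials))
        with pytest.raises(ValueError, match="zero surviving"):
            fits.category_contrast(feats)


class TestLatency:
    def test_no_effect_onsets_undefined(self, rng):
        tc_a = rng.standard_normal((6, 30)) * 0.05
        tc_b = rng.standard_normal((6, 30)) * 0.05
        res = fits.latency_comparison(
            tc_a, tc_b, np.arange(30) * 0.01, n_perm=100, seed=0
        )
        assert res.onset_a is None and res.onset_b is None
        assert res.onset_difference is None

    def test_identical_effects_no_region_difference(self, rng):
        base = np.zeros(30)
        base[10:20] = 1.0
        tc_a = base + rng.standard_normal((8, 30)) * 0.3
        tc_b = base + rng.standard_normal((8, 30)) * 0.3
        res = fits.latency_comparison(
            tc_a, tc_b, np.arange(30) * 0.01, n_perm=200, seed=1
        )
        assert res.onset_a is not None and res.onset_b is not None
        assert len(res.difference.significant(0.05)) == 0

    def test_constructed_delay_recovered(self, rng):
        times = np.arange(60) * 0.01
        eff_a = (times >= 0.1).astype(float)
        eff_b = (times >= 0.3).astype(float)
        tc_a = eff_a + rng.standard_normal((10, 60)) * 0.1
        tc_b = eff_b + rng.standard_normal((10, 60)) * 0.1
        res = fits.latency_comparison(tc_a, tc_b, times, n_perm=200, seed=2)
        assert res.onset_difference == pytest.approx(0.2, abs=0.011)

    def test_single_subject_region_rejected(self, rng):
        with pytest.raises(ValueError, match="2 subjects"):
            fits.latency_comparison(
                rng.standard_normal((1, 10)),
                rng.standard_normal((4, 10)),
                np.arange(10) * 0.01,
            )


class TestTrialLevelFit:
    def _subject(self, rng, effect_in_correct, n_pres=24, w=2, f=2):
        cats = np.arange(n_pres) % 4
        item_of = np.arange(n_pres) % 8
        correct = (np.arange(n_pres) < n_pres // 2).astype(float)
        rng.shuffle(correct)
        tpl = rng.standard_normal((4, 30))
        feats = rng.standard_normal((n_pres, w, f, 30)) * 1.0
        for r in range(n_pres):
            if effect_in_correct and correct[r] == 1:
                feats[r] += tpl[cats[r]]
        x = feats.transpose(1, 2, 0, 3)
        stack = np.einsum("wfnd,wfmd->wfnm", x, x)
        return stack, item_of, correct

    def test_toy_row_matches_brute_force(self, rng):
        stack = rng.standard_normal((1, 1, 3, 3))
        stack = stack + stack.transpose(0, 1, 3, 2)
        item_of = np.array([0, 1, 2])
        model = rng.standard_normal((3, 3))
        model = (model + model.T) / 2
        res = fits.trial_level_fit(
            [stack, stack],
            [item_of, item_of],
            [np.array([1, 1, 0]), np.array([1, 0, 0])],
            model,
            min_trials=1,
        )
        # brute-force the row fit for presentation 0 of subject 0
        expected = brute_force_spearman(stack[0, 0, 0, [1, 2]], model[0, [1, 2]])
        # reconstruct from the condition means: trial 0 is 'correct'
        assert res.subject_diff_maps.shape == (2, 1, 1)
        z00 = np.arctanh(np.clip(expected, -fits.RHO_CAP, fits.RHO_CAP))
        # subject 1: correct = {0}, incorrect = {1, 2}
        z_pres = []
        for r in range(3):
            others = [k for k in range(3) if k != r]
            rho = brute_force_spearman(
                stack[0, 0, r, others], model[item_of[r], item_of[others]]
            )
            z_pres.append(np.arctanh(np.clip(rho, -fits.RHO_CAP, fits.RHO_CAP)))
        assert res.subject_diff_maps[1, 0, 0] == pytest.approx(
            z_pres[0] - 0.5 * (z_pres[1] + z_pres[2]), abs=1e-10
        )
        assert z00 == pytest.approx(z_pres[0])

    def test_subject_without_incorrect_trials_excluded(self, rng):
        s1 = self._subject(rng, True)
        s2 = self._subject(rng, True)
        stack3, item3, _ = self._subject(rng, True)
        all_correct = np.ones(item3.size)
        model = np.eye(8)
        model[0, 1] = model[1, 0] = 1.0
        res = fits.trial_level_fit(
            [s1[0], s2[0], stack3],
            [s1[1], s2[1], item3],
            [s1[2], s2[2], all_correct],
            model,
            min_trials=5,
        )
        assert res.kept_subjects.tolist() == [0, 1]

    def test_effect_only_in_correct_trials_recovered(self, rng):
        subs = [self._subject(rng, True) for _ in range(8)]
        stim = synth.make_stimulus_set(4, 2)
        model = models.category_model(stim)
        res = fits.trial_level_fit(
            [s[0] for s in subs],
            [s[1] for s in subs],
            [s[2] for s in subs],
            model,
            n_perm=100,
            seed=0,
        )
        sig = res.clusters.significant(0.05)
        assert len(sig) >= 1 and sig[0].mass > 0


class TestBehavior:
    def _tables(self, rng, n_subjects, p_single=0.8, p_multi=0.75):
        stim = synth.make_stimulus_set(6, 10)
        tables = []
        for s in range(n_subjects):
            spec = synth.SyntheticSpec(
                n_trials_per_session=60,
                p_correct_single=p_single,
                p_correct_multi=p_multi,
            )
            tables.append(
                synth.simulate_trial_table(
                    stim, spec, rng=np.random.default_rng([s, 99])
                )
            )
        return tables

    def test_recovers_condition_means(self, rng):
        out = fits.behavioral_summary(self._tables(rng, 20))
        assert out["mean_single"] == pytest.approx(0.8, abs=0.04)
        assert out["mean_multi"] == pytest.approx(0.75, abs=0.04)
        assert out["t"] is not None

    def test_all_correct_flags_degenerate_test(self, rng):
        tables = self._tables(rng, 3, p_single=1.0, p_multi=1.0)
        out = fits.behavioral_summary(tables)
        assert out["mean_single"] == 1.0 and out["mean_multi"] == 1.0
        assert out["t"] is None and "zero variance" in out["note"]

    def test_single_subject_group_test_refused(self, rng):
        out = fits.behavioral_summary(self._tables(rng, 1))
        assert out["t"] is None and "fewer than 2" in out["note"]
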