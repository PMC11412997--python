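"""CCI, RSM consistency, slope fits and MDS stress-1."""

import numpy as np
import pytest

from wmrsa import geometry, synth
from wmrsa.models import LayeredModelRSMs
from conftest import brute_force_spearman


def block_rsm(categories, within=1.0, between=0.0):
    categories = np.asarray(categories)
    m = np.where(categories[:, None] == categories[None, :], within, between)
    m = m.astype(float)
    np.fill_diagonal(m, 1.0)
    return m


class TestCCI:
    def test_perfectly_clustered_rsm_gives_one(self, stim6x10):
        m = block_rsm(stim6x10.category_of)
        assert geometry.cci(m, stim6x10.category_of) == pytest.approx(1.0)

    def test_uniform_rsm_gives_zero(self, stim6x10):
        for c in (0.0, 0.37, -0.2):
            m = block_rsm(stim6x10.category_of, within=c, between=c)
            assert geometry.cci(m, stim6x10.category_of) == pytest.approx(0.0)

    def test_hand_enumerated_four_item_toy(self):
        cats = [0, 0, 1, 1]
        m = np.eye(4)
        m[0, 1] = m[1, 0] = 0.8
        m[2, 3] = m[3, 2] = 0.4
        for (i, j), v in zip([(0, 2), (0, 3), (1, 2), (1, 3)], [0.1, 0.2, 0.3, 0.4]):
            m[i, j] = m[j, i] = v
        expected = (0.8 + 0.4) / 2 - (0.1 + 0.2 + 0.3 + 0.4) / 4
        assert geometry.cci(m, cats) == pytest.approx(expected, abs=1e-12)

    def test_invariant_to_joint_permutation(self, stim6x10, rng):
        m = rng.standard_normal((60, 60))
        m = (m + m.T) / 2
        np.fill_diagonal(m, 1.0)
        cats = stim6x10.category_of
        perm = rng.permutation(60)
        assert geometry.cci(m[np.ix_(perm, perm)], cats[perm]) == pytest.approx(
            geometry.cci(m, cats), abs=1e-12
        )

    def test_small_category_rejected(self):
        m = np.eye(3)
        with pytest.raises(ValueError, match="at least 2 items"):
            geometry.cci(m, [0, 0, 1])


class TestCCIPermutation:
    def test_clustered_rsm_is_significant(self, stim6x10):
        m = block_rsm(stim6x10.category_of, within=0.5, between=0.0)
        res = geometry.cci_permutation_test(m, stim6x10.category_of, n_perm=200, seed=1)
        assert res.significant and res.p < 0.05
        assert res.cci == pytest.approx(0.5)

    def test_label_symmetric_rsm_has_degenerate_null(self):
        cats = [0, 0, 1, 1, 2, 2]
        m = np.full((6, 6), 0.3)
        np.fill_diagonal(m, 1.0)
        res = geometry.cci_permutation_test(m, cats, n_perm=50, seed=0)
        assert res.cci == pytest.approx(0.0)
        assert res.null_q95 == pytest.approx(0.0)

    def test_profile_identity_cci_equals_mean_difference(self, stim6x10, rng):
        m = rng.standard_normal((60, 60))
        m = (m + m.T) / 2
        np.fill_diagonal(m, 1.0)
        res = geometry.cci_permutation_test(m, stim6x10.category_of, n_perm=50, seed=2)
        assert res.cci == pytest.approx(res.mean_within - res.mean_between)

    def test_too_few_permutations_rejected(self, stim6x10):
        m = block_rsm(stim6x10.category_of)
        with pytest.raises(ValueError, match="at least 20"):
            geometry.cci_permutation_test(m, stim6x10.category_of, n_perm=5)


def _stack(mats, timepoints=None):
    if timepoints is None:
        rsms = [[m] for m in mats]
    else:
        rsms = timepoints
    return LayeredModelRSMs(
        rsms=rsms, layers=[f"L{i}" for i in range(len(rsms))], source="simulated"
    )


class TestConsistency:
    def test_identical_rsms_correlate_at_one(self, rng):
        m = rng.standard_normal((8, 8))
        m = (m + m.T) / 2
        c = geometry.consistency(_stack([m, m.copy()]))
        assert c[0, 1] == pytest.approx(1.0)

    def test_matches_brute_force_on_three_rsm_stack(self, rng):
        mats = []
        for _ in range(3):
            m = rng.standard_normal((6, 6))
            mats.append((m + m.T) / 2)
        c = geometry.consistency(_stack(mats))
        iu = np.triu_indices(6, k=1)
        for i in range(3):
            for j in range(i + 1, 3):
                assert c[i, j] == pytest.approx(
                    brute_force_spearman(mats[i][iu], mats[j][iu]), abs=1e-12
                )

    def test_across_time_mode(self, rng):
        layer = []
        for _ in range(4):
            m = rng.standard_normal((6, 6))
            layer.append((m + m.T) / 2)
        out = geometry.consistency(
            _stack(None, timepoints=[layer]), mode="across_time"
        )
        assert len(out) == 1 and out[0].size == 3
        iu = np.triu_indices(6, k=1)
        assert out[0][0] == pytest.approx(
            brute_force_spearman(layer[0][iu], layer[1][iu])
        )

    def test_single_rsm_rejected(self, rng):
        m = np.eye(4)
        with pytest.raises(ValueError, match="at least 2"):
            geometry.consistency(_stack([m]))


class TestSlopes:
    def test_exact_linear_between_slopes(self, stim6x10):
        # between-category correlations fall linearly 0.3 -> 0.0 over 7 layers
        mats = [
            block_rsm(stim6x10.category_of, within=0.3, between=0.3 - 0.05 * k)
            for k in range(7)
        ]
        fit = geometry.slope_analysis(_stack(mats), stim6x10.category_of)
        assert np.allclose(fit.slopes_between, -0.05, atol=1e-12)
        assert np.allclose(fit.slopes_within, 0.0, atol=1e-12)
        assert fit.slopes_within.size == 270
        assert fit.slopes_between.size == 1500

    def test_matches_brute_force_polyfit(self, rng):
        cats = np.repeat([0, 1], 3)
        mats = []
        for _ in range(5):
            m = rng.standard_normal((6, 6))
            mats.append((m + m.T) / 2)
        fit = geometry.slope_analysis(_stack(mats), cats)
        iu = np.triu_indices(6, k=1)
        vals = np.stack([m[iu] for m in mats])
        expected = np.stack(
            [np.polyfit(np.arange(5), vals[:, p], 1)[0] for p in range(15)]
        )
        within = cats[iu[0]] == cats[iu[1]]
        assert np.allclose(fit.slopes_within, expected[within], atol=1e-10)
        assert np.allclose(fit.slopes_between, expected[~within], atol=1e-10)

    def test_flat_within_schedule_not_significant(self, stim6x10):
        sched = synth.GeometrySchedule(
            n_layers=7,
            n_timepoints=1,
            within_by_layer=[0.3] * 7,
            between_by_layer=list(np.linspace(0.3, 0.0, 7)),
            noise_sd=0.05,
            seed=21,
        )
        stack = synth.simulate_layered_rsms(sched, stim6x10)
        fit = geometry.slope_analysis(stack, stim6x10.category_of)
        assert abs(fit.mean_within) < 0.01
        assert fit.p_between < 1e-6 and fit.mean_between < 0
        assert fit.p_within > 0 and fit.p_within <= 1  # exact analytic p

    def test_constant_offset_recovered_by_paired_comparison(self, stim6x10, rng):
        base = []
        for k in range(4):
            m = rng.standard_normal((60, 60)) * 0.05 + 0.2
            base.append((m + m.T) / 2)
        d = 0.03  # stack B's pairwise slopes offset by a constant
        shifted = [m + d * k for k, m in enumerate(base)]
        fit_a = geometry.slope_analysis(_stack(base), stim6x10.category_of)
        fit_b = geometry.slope_analysis(_stack(shifted), stim6x10.category_of)
        mean_diff, t, p = geometry.compare_slopes(fit_b, fit_a)
        assert mean_diff == pytest.approx(d, abs=1e-10)

    def test_too_few_layers_rejected(self, stim6x10):
        mats = [block_rsm(stim6x10.category_of)] * 2
        with pytest.raises(ValueError, match="3 layers"):
            geometry.slope_analysis(_stack(mats), stim6x10.category_of)


def grid_search_stress_1d(d, lo=-1.5, hi=1.5, coarse=0.05, refine=0.005):
    """Exhaustive 1-D embedding search for a 4-point distance matrix."""
    iu = np.triu_indices(4, k=1)
    target = d[iu]

    def stress_at(coords):
        dd = np.abs(coords[:, :, None] - coords[:, None, :])[:, iu[0], iu[1]]
        return np.sqrt(((dd - target) ** 2).sum(axis=1) / (target**2).sum())

    best = None
    grid = np.arange(lo, hi + coarse / 2, coarse)
    for stage_grid, center in ((grid, None), (None, "refine")):
        if center is None:
            a, b, c = np.meshgrid(stage_grid, stage_grid, stage_grid, indexing="ij")
            coords = np.stack(
                [np.zeros(a.size), a.ravel(), b.ravel(), c.ravel()], axis=1
            )
        else:
            offs = np.arange(-coarse, coarse + refine / 2, refine)
            a, b, c = np.meshgrid(
                best_coords[1] + offs, best_coords[2] + offs, best_coords[3] + offs,
                indexing="ij",
            )
            coords = np.stack(
                [np.zeros(a.size), a.ravel(), b.ravel(), c.ravel()], axis=1
            )
        s = stress_at(coords)
        k = int(s.argmin())
        best, best_coords = float(s[k]), coords[k]
    return best


class TestMDSStress:
    def test_equilateral_triangle_embeds_exactly_in_2d(self):
        rsm = np.full((3, 3), 0.5)
        np.fill_diagonal(rsm, 1.0)
        curve = geometry.mds_stress(rsm, dims=2, seed=0)
        assert curve.stress[0] == pytest.approx(0.0, abs=1e-6)

    def test_stress_non_increasing_in_dimension(self, rng):
        m = rng.uniform(-0.2, 0.8, size=(8, 8))
        m = (m + m.T) / 2
        np.fill_diagonal(m, 1.0)
        curve = geometry.mds_stress(m, dims=np.arange(1, 6), seed=1)
        assert np.all(np.diff(curve.stress) <= 0.01)  # optimizer tolerance

    def test_1d_stress_matches_grid_search_oracle(self, rng):
        m = rng.uniform(0.0, 0.9, size=(4, 4))
        m = (m + m.T) / 2
        np.fill_diagonal(m, 1.0)
        d = 1.0 - m
        np.fill_diagonal(d, 0.0)
        oracle = grid_search_stress_1d(d)
        curve = geometry.mds_stress(m, dims=1, seed=2, n_init=8)
        assert curve.stress[0] == pytest.approx(oracle, abs=1e-3)

    def test_subsampling_repeats_and_coords(self, rng):
        m = rng.uniform(0.0, 0.8, size=(10, 10))
        m = (m + m.T) / 2
        np.fill_diagonal(m, 1.0)
        curve = geometry.mds_stress(m, dims=[1, 2], n_repeats=5, match_n=6, seed=3)
        assert curve.stress_repeats.shape == (5, 2)
        assert curve.coords_2d.shape == (10, 2)

    def test_excessive_dimension_rejected(self):
        m = np.eye(4)
        with pytest.raises(ValueError, match="dims"):
            geometry.mds_stress(m, dims=4)
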