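import numpy as np
import pytest

from graicar.alignment import AlignedComponent
from graicar.group import (
    consistency_null,
    group_map,
    inter_subject_consistency,
    intra_subject_reliability,
    null_thresholds,
    select_significant,
    subject_centrality,
    summarize_component,
)
from graicar.ica import Realization
from graicar.similarity import build_fsm


def make_ac(members, mrep, seed_pair=None):
    mrep = np.asarray(mrep, dtype=float)
    return AlignedComponent(members=list(members),
                            seed_pair=seed_pair or (members[0], members[1]),
                            reproducibility_matrix=mrep)


class TestConsistency:
    def test_mean_of_constant_block(self):
        ac = make_ac([(0, 0, 0), (1, 0, 0)], [[1.0, 0.5], [0.5, 1.0]])
        assert inter_subject_consistency(ac, 0, 1) == pytest.approx(0.5)

    def test_two_realizations_each_mean(self):
        # cross-block NMIs {0.2, 0.4, 0.6, 0.8} -> 0.5
        members = [(0, 0, 0), (0, 1, 0), (1, 0, 0), (1, 1, 0)]
        m = np.eye(4)
        m[0, 2], m[0, 3], m[1, 2], m[1, 3] = 0.2, 0.4, 0.6, 0.8
        m[2, 0], m[3, 0], m[2, 1], m[3, 1] = 0.2, 0.4, 0.6, 0.8
        ac = make_ac(members, m)
        assert inter_subject_consistency(ac, 0, 1) == pytest.approx(0.5)

    def test_absent_subject_is_zero(self):
        ac = make_ac([(0, 0, 0), (1, 0, 0)], np.eye(2))
        assert inter_subject_consistency(ac, 0, 5) == 0.0

    def test_same_subject_rejected(self):
        ac = make_ac([(0, 0, 0), (1, 0, 0)], np.eye(2))
        with pytest.raises(ValueError):
            inter_subject_consistency(ac, 1, 1)

    def test_identical_subjects_give_one(self, rng):
        maps = rng.standard_normal((2, 500))
        res = [Realization(s, 0, maps, np.zeros((3, 2))) for s in range(2)]
        fsm = build_fsm(res)
        members = [(0, 0, 0), (1, 0, 0)]
        mrep = fsm.raw[np.ix_([0, 2], [0, 2])]
        np.fill_diagonal(mrep, 1.0)
        ac = make_ac(members, mrep)
        assert inter_subject_consistency(ac, 0, 1) == pytest.approx(1.0, abs=1e-6)


class TestCentrality:
    def test_forced_arithmetic(self):
        alpha = np.zeros((3, 3))
        alpha[0, 1] = alpha[1, 0] = 0.4
        alpha[0, 2] = alpha[2, 0] = 0.6
        assert subject_centrality(alpha, 0) == pytest.approx(0.5)

    def test_uniform_alpha(self):
        alpha = np.full((4, 4), 0.3)
        np.fill_diagonal(alpha, 0)
        for i in range(4):
            assert subject_centrality(alpha, i) == pytest.approx(0.3)

    def test_matches_row_mean_oracle(self, rng):
        a = rng.uniform(0, 1, (5, 5))
        alpha = (a + a.T) / 2
        np.fill_diagonal(alpha, 0)
        for i in range(5):
            expected = np.delete(alpha[i], i).mean()
            assert subject_centrality(alpha, i) == pytest.approx(expected)

    def test_single_subject_rejected(self):
        with pytest.raises(ValueError):
            subject_centrality(np.zeros((1, 1)), 0)


class TestReliability:
    def test_single_realization_convention(self):
        ac = make_ac([(0, 0, 0), (1, 0, 0)], np.eye(2))
        assert intra_subject_reliability(ac, 0) == 1.0

    def test_mean_of_within_pairs(self):
        members = [(0, 0, 0), (0, 1, 1), (0, 2, 0), (1, 0, 0)]
        m = np.eye(4)
        m[0, 1] = m[1, 0] = 0.3
        m[0, 2] = m[2, 0] = 0.5
        m[1, 2] = m[2, 1] = 0.4
        ac = make_ac(members, m)
        assert intra_subject_reliability(ac, 0) == pytest.approx((0.3 + 0.5 + 0.4) / 3)
        # {0.3, 0.5} -> 0.4 when only two members
        ac2 = make_ac(members[:2] + [members[3]], m[np.ix_([0, 1, 3], [0, 1, 3])])
        assert intra_subject_reliability(ac2, 0) == pytest.approx(0.3)


class TestGroupMap:
    def _setup(self, rng, n_subjects=2, maps=None):
        reals, members = [], []
        for s in range(n_subjects):
            m = maps[s] if maps is not None else rng.standard_normal((1, 300))
            reals.append(Realization(s, 0, np.atleast_2d(m), np.zeros((3, 1))))
            members.append((s, 0, 0))
        mrep = np.full((n_subjects, n_subjects), 0.5)
        np.fill_diagonal(mrep, 1.0)
        return reals, make_ac(members, mrep)

    def test_identical_member_maps_returned_exactly(self, rng):
        m = rng.standard_normal(300)
        reals, ac = self._setup(rng, 3, maps=[m, m, m])
        out = group_map(ac, reals, beta=np.ones(3), tau=np.ones(3))
        np.testing.assert_allclose(out, m)

    def test_degenerate_weight_selects_single_subject(self, rng):
        m0, m1 = rng.standard_normal(300), rng.standard_normal(300)
        reals, ac = self._setup(rng, 2, maps=[m0, m1])
        out = group_map(ac, reals, beta=np.array([1.0, 0.0]), tau=np.ones(2))
        # sign-harmonized to the seed map (subject 0's)
        np.testing.assert_allclose(out, m0)

    def test_all_zero_weights_fall_back_to_mean(self, rng):
        m0, m1 = rng.standard_normal(300), rng.standard_normal(300)
        reals, ac = self._setup(rng, 2, maps=[m0, m1])
        out = group_map(ac, reals, beta=np.zeros(2), tau=np.zeros(2))
        sign = np.sign(np.corrcoef(m1, m0)[0, 1])
        np.testing.assert_allclose(out, (m0 + sign * m1) / 2)

    def test_invariant_to_member_order(self, rng):
        maps = [rng.standard_normal(300) for _ in range(3)]
        reals, ac = self._setup(rng, 3, maps=maps)
        out1 = group_map(ac, reals, np.array([1, 0.5, 0.2]), np.ones(3))
        ac.members = ac.members[::-1]
        out2 = group_map(ac, reals, np.array([1, 0.5, 0.2]), np.ones(3))
        np.testing.assert_allclose(out1, out2)

    def test_planted_shared_source_recovered(self, small_cohort):
        from graicar.workflow import GraicarConfig, run_group_graicar

        datasets, truth = small_cohort
        res = run_group_graicar([d for d in datasets if d.group == "A"],
                                GraicarConfig(n_components=2, n_realizations=3, seed=0))
        shared = truth.spatial_maps[truth.source_membership.index("shared")]
        best = max(abs(np.corrcoef(gc.map, shared)[0, 1]) for gc in res.components)
        assert best > 0.95


class TestNull:
    def _noise_fsm(self, n_subjects=4, d=2, c=2, v=400, seed=0):
        g = np.random.default_rng(seed)
        res = [Realization(s, r, g.standard_normal((c, v)), np.zeros((3, c)))
               for s in range(n_subjects) for r in range(d)]
        return build_fsm(res)

    def test_threshold_deterministic_given_seed(self):
        fsm = self._noise_fsm()
        assert consistency_null(fsm, 100, seed=4) == consistency_null(fsm, 100, seed=4)

    def test_roughly_five_percent_of_own_draws_exceed(self):
        fsm = self._noise_fsm(seed=3)
        thr, draws = consistency_null(fsm, 400, seed=9, return_distribution=True)
        frac = (draws > thr).mean()
        assert 0.02 <= frac <= 0.06  # by definition of the 95th percentile

    def test_shared_component_beats_noise_null(self, rng):
        shared = rng.standard_normal(400)
        res = []
        for s in range(4):
            maps = np.vstack([shared + 0.1 * rng.standard_normal(400),
                              rng.standard_normal((3, 400))])
            res.append(Realization(s, 0, maps, np.zeros((3, 4))))
        fsm = build_fsm(res)
        thr = consistency_null(fsm, 200, seed=1)
        mrep_idx = [fsm.index_of(s, 0, 0) for s in range(4)]
        mrep = fsm.raw[np.ix_(mrep_idx, mrep_idx)]
        np.fill_diagonal(mrep, 1.0)
        ac = make_ac([(s, 0, 0) for s in range(4)], mrep)
        gc = summarize_component(ac, res, 4)
        assert gc.mean_consistency > thr

    def test_small_resample_count_warns(self, caplog):
        import logging

        fsm = self._noise_fsm()
        with caplog.at_level(logging.WARNING):
            consistency_null(fsm, 10, seed=0)
        assert any("unstable" in r.message for r in caplog.records)

    def test_pair_threshold_above_mean_threshold(self):
        fsm = self._noise_fsm(seed=5)
        mean_thr, pair_thr = null_thresholds(fsm, 200, seed=2)
        # single pairs fluctuate more than means of pairs
        assert pair_thr >= mean_thr


class TestSelect:
    def _components(self, small_cohort):
        from graicar.workflow import GraicarConfig, run_group_graicar

        datasets, _ = small_cohort
        return run_group_graicar([d for d in datasets if d.group == "B"],
                                 GraicarConfig(n_components=2, n_realizations=3, seed=3))

    def test_threshold_extremes(self, small_cohort):
        res = self._components(small_cohort)
        assert select_significant(res.components, threshold=1.1) == []
        assert len(select_significant(res.components, threshold=0.0)) == len(res.components)

    def test_subject_level_marks_representatives(self, small_cohort):
        res = self._components(small_cohort)
        sig = select_significant(res.components, res.threshold,
                                 subject_level=True, n_resamples=100, seed=0)
        assert sig, "expected at least one significant component"
        for gc in sig:
            assert set(gc.representative_subjects) <= set(range(8))


def test_alpha_tau_beta_ranges(small_cohort):
    from graicar.workflow import GraicarConfig, run_group_graicar

    datasets, _ = small_cohort
    res = run_group_graicar([d for d in datasets if d.group == "A"][:4],
                            GraicarConfig(n_components=2, n_realizations=2, seed=1))
    for gc in res.components:
        assert np.all((gc.alpha >= 0) & (gc.alpha <= 1))
        np.testing.assert_array_equal(gc.alpha, gc.alpha.T)
        np.testing.assert_array_equal(np.diag(gc.alpha), 0.0)
        assert np.all((gc.tau >= 0) & (gc.tau <= 1))
        assert np.all((gc.beta >= 0) & (gc.beta <= 1))
        for i in range(4):
            assert gc.tau[i] == pytest.approx(np.delete(gc.alpha[i], i).mean())
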