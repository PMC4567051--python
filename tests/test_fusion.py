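import itertools

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from cropfuse import (ClassifierOutput, FusionConfig, ObjectMap,
                      alpha_quadratic_entropy, fuse_object, m_voting_pixel,
                      p_fusion_pixel, run_fusion)
from conftest import random_classifier_outputs
from _oracles import (oracle_entropy, oracle_mvote, oracle_mvote_object,
                      oracle_pfusion, oracle_pfusion_object)


class TestAlphaQuadraticEntropy:
    def test_degenerate_distribution_is_zero(self):
        assert alpha_quadratic_entropy([1.0, 0.0, 0.0]) == pytest.approx(0.0)

    def test_uniform_binary_is_one(self):
        assert alpha_quadratic_entropy([0.5, 0.5]) == pytest.approx(1.0)

    def test_hand_computed_three_class(self):
        # (2/3)(sqrt(0.21) + sqrt(0.16) + sqrt(0.09))
        assert alpha_quadratic_entropy([0.7, 0.2, 0.1]) == pytest.approx(0.7722, abs=1e-4)

    def test_matches_loop_oracle_on_random_rows(self):
        rng = np.random.default_rng(0)
        for _ in range(100):
            k = rng.integers(2, 6)
            p = rng.dirichlet(np.ones(k))
            for alpha in (0.3, 0.5, 1.0):
                assert alpha_quadratic_entropy(p, alpha=alpha) == pytest.approx(
                    oracle_entropy(p, alpha=alpha))

    def test_maximal_at_uniform_by_grid_search(self):
        for k in (2, 3, 4):
            h_uniform = alpha_quadratic_entropy(np.full(k, 1 / k))
            best, best_h = None, -1.0
            grid = np.linspace(0, 1, 21)
            for combo in itertools.product(grid, repeat=k - 1):
                last = 1.0 - sum(combo)
                if last < -1e-9:
                    continue
                p = np.array(list(combo) + [max(last, 0.0)])
                p = p / p.sum()
                h = alpha_quadratic_entropy(p)
                assert h <= h_uniform + 1e-9
                if h > best_h:
                    best_h, best = h, p
            # the grid argmax sits next to the uniform distribution
            np.testing.assert_allclose(best, np.full(k, 1 / k), atol=0.05)

    def test_monotone_decrease_toward_vertex(self):
        k = 4
        uniform = np.full(k, 1 / k)
        vertex = np.eye(k)[0]
        ts = np.linspace(0, 1, 50)
        hs = [alpha_quadratic_entropy((1 - t) * uniform + t * vertex) for t in ts]
        assert np.all(np.diff(hs) < 1e-12)

    @given(st.integers(2, 5), st.integers(0, 10_000))
    @settings(max_examples=60, deadline=None)
    def test_bounds_hold_for_random_distributions(self, k, seed):
        p = np.random.default_rng(seed).dirichlet(np.ones(k))
        h = alpha_quadratic_entropy(p)
        assert -1e-9 <= h <= 1 + 1e-9

    def test_invalid_distribution_rejected(self):
        with pytest.raises(ValueError):
            alpha_quadratic_entropy([0.7, 0.7])
        with pytest.raises(ValueError):
            alpha_quadratic_entropy([0.5, 0.5], alpha=1.5)


class TestMVotingPixel:
    def test_strict_majority_wins(self):
        out = m_voting_pixel(np.array([[1], [1], [2]]),
                             np.array([[0.9], [0.9], [0.0]]))
        assert out.labels[0] == 1 and not out.tie_break_used[0]

    def test_three_way_tie_goes_to_least_uncertain(self):
        out = m_voting_pixel(np.array([[1], [2], [3]]),
                             np.array([[0.5], [0.2], [0.9]]))
        assert out.labels[0] == 2 and out.tie_break_used[0]

    def test_single_classifier_identity(self):
        out = m_voting_pixel(np.array([[1, 2, 1]]), np.array([[0.3, 0.3, 0.3]]))
        np.testing.assert_array_equal(out.labels, [1, 2, 1])

    def test_matches_enumeration_oracle_exhaustively(self):
        """All 27 label assignments for F=3, K=3, random uncertainties."""
        rng = np.random.default_rng(1)
        for labels in itertools.product([1, 2, 3], repeat=3):
            for _ in range(5):
                unc = rng.random(3)
                got = m_voting_pixel(np.array(labels)[:, None], unc[:, None])
                assert got.labels[0] == oracle_mvote(list(labels), list(unc))

    def test_shape_mismatch_rejected(self):
        with pytest.raises(ValueError):
            m_voting_pixel(np.ones((3, 2), int), np.ones((3, 3)))


class TestPFusionPixel:
    def test_hand_arithmetic_complement_mode(self):
        proba = np.array([[[0.6, 0.4]], [[0.3, 0.7]]])
        unc = np.array([[0.2], [0.8]])
        # scores: 0.8*0.6 + 0.2*0.3 = 0.54 vs 0.8*0.4 + 0.2*0.7 = 0.46
        out = p_fusion_pixel(proba, unc, "complement")
        assert out.labels[0] == 1
        assert p_fusion_pixel(proba, unc, "literal").labels[0] == 2

    def test_identical_inputs_reduce_to_argmax(self):
        p = np.array([0.2, 0.5, 0.3])
        proba = np.stack([p[None, :]] * 3)
        unc = np.full((3, 1), 0.4)
        for mode in ("complement", "literal"):
            assert p_fusion_pixel(proba, unc, mode).labels[0] == 2

    def test_single_classifier_identity_any_mode(self):
        p = np.array([[0.1, 0.6, 0.3]])
        for mode in ("complement", "literal"):
            assert p_fusion_pixel(p[None], np.array([[0.7]]), mode).labels[0] == 2

    def test_all_zero_weights_fall_back_to_mean(self):
        proba = np.array([[[0.2, 0.8]], [[0.9, 0.1]]])
        unc = np.zeros((2, 1))  # literal mode weights all zero
        with pytest.warns(UserWarning, match="all-zero"):
            out = p_fusion_pixel(proba, unc, "literal")
        assert out.labels[0] == 1  # mean = (0.55, 0.45)


class TestObjectLevel:
    def test_singleton_objects_equal_pixel_level(self):
        rng = np.random.default_rng(2)
        outs = random_classifier_outputs(rng, 80, 3)
        objects = ObjectMap(object_id=np.arange(80))
        for strategy in ("m_voting", "p_fusion"):
            for mode in ("complement", "literal"):
                pix = run_fusion(outs, FusionConfig(strategy, "pixel", mode))
                obj = run_fusion(outs, FusionConfig(strategy, "object", mode),
                                 objects=objects)
                np.testing.assert_array_equal(pix.labels, obj.labels)

    def test_pooled_majority(self):
        # object of 2 pixels, F=3: votes {1: 5, 2: 1} -> class 1
        labels = np.array([[1, 1], [1, 1], [1, 2]])
        proba = np.zeros((3, 2, 2))
        for f in range(3):
            for p in range(2):
                proba[f, p, labels[f, p] - 1] = 1.0
        outs = [ClassifierOutput(labels=labels[f], proba=proba[f]) for f in range(3)]
        fused = fuse_object(outs, ObjectMap(object_id=np.zeros(2, int)),
                            FusionConfig("m_voting", "object"))
        np.testing.assert_array_equal(fused.labels, [1, 1])

    def test_pooled_tie_breaks_on_least_uncertain_pair(self):
        # two pixels, F=3 -> 6 votes split 3/3; the least-uncertain pair says 2
        labels = np.array([[1, 2], [2, 1], [1, 2]])
        unc = np.array([[0.5, 0.1], [0.6, 0.7], [0.8, 0.9]])
        proba = np.zeros((3, 2, 2))
        for f in range(3):
            for p in range(2):
                proba[f, p, labels[f, p] - 1] = 1.0
        outs = [ClassifierOutput(labels=labels[f], proba=proba[f]) for f in range(3)]
        fused = fuse_object(outs, ObjectMap(object_id=np.zeros(2, int)),
                            FusionConfig("m_voting", "object"),
                            uncertainties=unc)
        # least uncertainty 0.1 at (f=0, pixel=1) proposing class 2
        np.testing.assert_array_equal(fused.labels, [2, 2])
        assert fused.tie_break_used.all()

    def test_matches_object_oracles_on_random_objects(self):
        rng = np.random.default_rng(3)
        n, K = 60, 3
        outs = random_classifier_outputs(rng, n, K)
        obj_ids = rng.integers(0, 12, size=n)
        objects = ObjectMap(object_id=obj_ids)
        unc = np.stack([
            [oracle_entropy(o.proba[i]) for i in range(n)] for o in outs])
        for strategy in ("m_voting", "p_fusion"):
            fused = run_fusion(outs, FusionConfig(strategy, "object"), objects=objects)
            for oid in np.unique(obj_ids):
                members = np.flatnonzero(obj_ids == oid)
                labs = [[int(o.labels[i]) for o in outs] for i in members]
                uncs = [[unc[f, i] for f in range(3)] for i in members]
                if strategy == "m_voting":
                    want = oracle_mvote_object(labs, uncs)
                else:
                    probas = [[o.proba[i].tolist() for o in outs] for i in members]
                    want = oracle_pfusion_object(probas, uncs)
                assert np.all(fused.labels[members] == want), (strategy, oid)


class TestRunFusion:
    def test_unanimous_outputs_pass_through(self):
        rng = np.random.default_rng(4)
        out = random_classifier_outputs(rng, 50, 3, n_classifiers=1)[0]
        outs = [out, out, out]
        objects = ObjectMap(object_id=np.repeat(np.arange(10), 5))
        for strategy in ("m_voting", "p_fusion"):
            for level in ("pixel", "object"):
                fused = run_fusion(outs, FusionConfig(strategy, level),
                                   objects=objects)
                if level == "pixel":
                    np.testing.assert_array_equal(fused.labels, out.labels)

    def test_invariant_to_classifier_order(self):
        rng = np.random.default_rng(5)
        outs = random_classifier_outputs(rng, 120, 4)
        objects = ObjectMap(object_id=rng.integers(0, 20, 120))
        for strategy in ("m_voting", "p_fusion"):
            for level in ("pixel", "object"):
                cfg = FusionConfig(strategy, level)
                base = run_fusion(outs, cfg, objects=objects)
                for perm in itertools.permutations(range(3)):
                    shuffled = run_fusion([outs[i] for i in perm], cfg,
                                          objects=objects)
                    np.testing.assert_array_equal(base.labels, shuffled.labels)

    def test_pixel_oracle_equivalence_on_random_instances(self):
        """Vectorized pipeline vs literal per-pixel enumeration, 200 pixels."""
        rng = np.random.default_rng(6)
        outs = random_classifier_outputs(rng, 200, 3)
        unc = [[oracle_entropy(o.proba[i]) for i in range(200)] for o in outs]
        mv = run_fusion(outs, FusionConfig("m_voting", "pixel"))
        for i in range(200):
            labs = [int(o.labels[i]) for o in outs]
            us = [unc[f][i] for f in range(3)]
            assert mv.labels[i] == oracle_mvote(labs, us)
        for mode in ("complement", "literal"):
            pf = run_fusion(outs, FusionConfig("p_fusion", "pixel", mode))
            for i in range(200):
                probas = [o.proba[i].tolist() for o in outs]
                us = [unc[f][i] for f in range(3)]
                assert pf.labels[i] == oracle_pfusion(probas, us, mode)

    def test_mismatched_pixel_sets_rejected(self):
        rng = np.random.default_rng(7)
        a = random_classifier_outputs(rng, 10, 3, 1)[0]
        b = random_classifier_outputs(rng, 12, 3, 1)[0]
        with pytest.raises(ValueError, match="mismatch"):
            run_fusion([a, b], FusionConfig("m_voting", "pixel"))
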