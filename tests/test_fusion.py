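"""Decision-fusion rules, priors, MCDF prediction and the MCFF comparator."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from hrea.backbone import BackboneConfig, ProbabilityVector, build_backbone
from hrea.fusion import (
    ClassPriors,
    FusionInput,
    build_mcff,
    estimate_priors,
    fuse,
    fuse_ds,
    fuse_max,
    fuse_nb,
    fuse_sum,
    mcdf_predict,
    mcff_predict_proba,
)
from hrea.preprocessing import LabeledWindow
from hrea.synthetic import generate_action


def pv(*probs):
    return ProbabilityVector(np.array(probs, dtype=float))


def fin(*vectors):
    return FusionInput(tuple(pv(*v) for v in vectors))


def random_posterior_pair(rng, n_classes=6):
    p = rng.dirichlet(np.ones(n_classes))
    q = rng.dirichlet(np.ones(n_classes))
    return fin(p, q)


class TestMaxRule:
    def test_single_largest_entry_wins(self):
        assert fuse_max(fin((0.6, 0.4), (0.3, 0.7))).predicted_class == 1

    def test_uniform_channel_never_beats_confident(self):
        assert fuse_max(fin((0.9, 0.1), (0.5, 0.5))).predicted_class == 0

    def test_identical_channels_match_single_argmax(self):
        p = (0.2, 0.5, 0.1, 0.1, 0.05, 0.05)
        assert fuse_max(fin(p, p)).predicted_class == int(np.argmax(p))


class TestSumRule:
    def test_largest_sum_wins(self):
        r = fuse_sum(fin((0.6, 0.4), (0.3, 0.7)))
        assert np.allclose(r.scores, [0.9, 1.1])
        assert r.predicted_class == 1

    def test_uniform_channel_is_constant_shift(self):
        p = (0.1, 0.6, 0.1, 0.1, 0.05, 0.05)
        u = (1 / 6,) * 6
        assert fuse_sum(fin(p, u)).predicted_class == int(np.argmax(p))

    def test_tie_breaks_to_lowest_class(self):
        assert fuse_sum(fin((0.5, 0.5), (0.5, 0.5))).predicted_class == 0


class TestDsRule:
    def test_product_scores(self):
        r = fuse_ds(fin((0.6, 0.4), (0.3, 0.7)))
        # products (0.18, 0.28), K = 1 - 0.46
        assert r.predicted_class == 1
        assert np.allclose(r.scores, np.array([0.18, 0.28]) / 0.54)

    def test_uniform_channel_preserves_argmax(self):
        p = (0.1, 0.6, 0.1, 0.1, 0.05, 0.05)
        u = (1 / 6,) * 6
        assert fuse_ds(fin(p, u)).predicted_class == 1

    def test_more_than_two_channels_rejected(self):
        u = (0.5, 0.5)
        with pytest.raises(ValueError, match="2 channels"):
            fuse_ds(fin(u, u, u))

    def test_decision_equals_product_rule_on_random_pairs(self):
        rng = np.random.default_rng(17)
        for _ in range(1000):
            inputs = random_posterior_pair(rng)
            P = inputs.as_matrix()
            oracle = int(np.argmax(P[0] * P[1]))
            assert fuse_ds(inputs).predicted_class == oracle

    def test_degenerate_K_falls_back_to_products(self):
        # one-hot agreement: sum of products = 1, K = 0
        r = fuse_ds(fin((1.0, 0.0), (1.0, 0.0)))
        assert r.predicted_class == 0


class TestNbRule:
    def test_uniform_priors_match_product_rule(self):
        inputs = fin((0.6, 0.4), (0.3, 0.7))
        nb = fuse_nb(inputs, ClassPriors(np.array([0.5, 0.5])))
        assert nb.predicted_class == int(np.argmax([0.18, 0.28]))

    def test_prior_weighting_arithmetic(self):
        r = fuse_nb(fin((0.6, 0.4), (0.6, 0.4)),
                    ClassPriors(np.array([0.25, 0.75])))
        assert np.allclose(r.scores, [0.09, 0.12])
        assert r.predicted_class == 1

    def test_prior_decides_between_uniform_channels(self):
        u = (0.5, 0.5)
        r = fuse_nb(fin(u, u), ClassPriors(np.array([0.9, 0.1])))
        assert r.predicted_class == 0

    def test_unnormalized_priors_rejected(self):
        with pytest.raises(ValueError, match="sum to 1"):
            ClassPriors(np.array([0.5, 0.2]))


class TestEstimatePriors:
    def test_empirical_frequencies(self):
        p = estimate_priors([0, 0, 1, 2], n_classes=6)
        assert np.allclose(p.priors, [0.5, 0.25, 0.25, 0, 0, 0])

    def test_balanced_labels_uniform_over_observed(self):
        p = estimate_priors([0, 1, 2] * 10, n_classes=3)
        assert np.allclose(p.priors, 1 / 3)

    def test_laplace_smoothing(self):
        p = estimate_priors([0], n_classes=6, smoothing=1.0)
        assert np.allclose(p.priors, [2 / 7] + [1 / 7] * 5)

    def test_empty_rejected(self):
        with pytest.raises(ValueError):
            estimate_priors([])


class TestRuleProperties:
    @settings(max_examples=40, deadline=None, derandomize=True)
    @given(st.integers(0, 2**31 - 1))
    def test_permutation_equivariance(self, seed):
        rng = np.random.default_rng(seed)
        inputs = random_posterior_pair(rng)
        perm = rng.permutation(6)
        permuted = FusionInput(tuple(
            ProbabilityVector(p.probs[perm]) for p in inputs.probabilities
        ))
        priors = ClassPriors(rng.dirichlet(np.ones(6)))
        p_priors = ClassPriors(priors.priors[perm])
        for rule, kw, pkw in (("max", {}, {}), ("sum", {}, {}), ("ds", {}, {}),
                              ("nb", {"priors": priors}, {"priors": p_priors})):
            base = fuse(inputs, rule, **kw).predicted_class
            moved = fuse(permuted, rule, **pkw).predicted_class
            # permuting classes permutes the decision (up to tie placement)
            scores = fuse(inputs, rule, **kw).scores
            if np.sum(scores == scores.max()) == 1:
                # new[i] = old[perm[i]], so the winner moves to perm^-1(base)
                assert int(np.flatnonzero(perm == base)[0]) == moved

    def test_agreeing_channels_fix_every_rule(self):
        rng = np.random.default_rng(23)
        priors = ClassPriors(np.full(6, 1 / 6))
        for _ in range(200):
            p = rng.dirichlet(np.ones(6))
            q = rng.dirichlet(np.ones(6))
            c = int(np.argmax(p))
            if int(np.argmax(q)) != c:
                q = q.copy()
                q[c], q[np.argmax(q)] = q.max(), q[c]
                if int(np.argmax(q)) != c:
                    continue
            inputs = fin(p, q)
            for rule in ("max", "sum", "ds", "nb"):
                assert fuse(inputs, rule, priors=priors).predicted_class == c

    def test_fusion_beats_weaker_channel_statistically(self):
        # independent channel errors; every rule should at least match the
        # weaker channel's accuracy
        rng = np.random.default_rng(31)
        n, C = 2000, 3
        truth = rng.integers(0, C, n)
        accs = (0.8, 0.65)

        def channel(acc):
            out = []
            for t in truth:
                c = t if rng.random() < acc else int((t + rng.integers(1, C)) % C)
                p = np.full(C, 0.0)
                p[c] = rng.uniform(0.5, 0.8)
                p[p == 0] = (1 - p[c]) / (C - 1)
                out.append(p)
            return np.array(out)

        P1, P2 = channel(accs[0]), channel(accs[1])
        single = [np.mean(np.argmax(P, 1) == truth) for P in (P1, P2)]
        weaker = min(single)
        priors = ClassPriors(np.full(C, 1 / C))
        for rule in ("max", "sum", "ds", "nb"):
            fused = [fuse(fin(P1[i], P2[i]), rule, priors=priors).predicted_class
                     for i in range(n)]
            assert np.mean(np.array(fused) == truth) >= weaker

    def test_unknown_rule_rejected(self):
        with pytest.raises(ValueError, match="unknown fusion rule"):
            fuse(fin((0.5, 0.5), (0.5, 0.5)), "median")


@pytest.fixture(scope="module")
def small_models():
    return build_backbone(BackboneConfig(seed=0)), build_backbone(BackboneConfig(seed=1))


class TestMcdfPredict:
    def test_all_rule_names_dispatch(self, small_models):
        m1, m2 = small_models
        rec = generate_action("A1", 2, seed=3)
        for rule in ("max", "sum", "ds", "nb"):
            result = mcdf_predict(rec, m1, m2, rule)
            assert result.rule == rule
            assert 0 <= result.predicted_class < 6


class TestMcff:
    def test_concatenated_feature_length(self):
        model = build_mcff(BackboneConfig(seed=0))
        # one channel flattens to 25 * 16 = 400; head sees both channels
        assert model.feature_length == 400
        assert model.head.layers[0].params["W"].shape == (800, 6)

    def test_output_valid_probability(self):
        model = build_mcff(BackboneConfig(seed=0))
        w = LabeledWindow(np.zeros((128, 3)), 0)
        p = mcff_predict_proba(model, w, w)
        assert abs(p.probs.sum() - 1.0) < 1e-6

    def test_seeded_build_reproducible(self):
        a = build_mcff(BackboneConfig(seed=9))
        b = build_mcff(BackboneConfig(seed=9))
        for na, nb_ in zip(a.nets(), b.nets()):
            for (i, name), layer, _ in na.parameters():
                other = dict((k, l.params[n]) for k, l, n in nb_.parameters())
                assert np.array_equal(layer.params[name], other[(i, name)])

    def test_transfer_initialized_extractors_share_pretrained_convs(self):
        pre = build_backbone(BackboneConfig(seed=12))
        model = build_mcff(BackboneConfig(seed=3), pretrained=pre)
        src = pre.conv_layers()
        from hrea._nn import Conv1D
        for extractor in model.extractors:
            dst = [l for l in extractor.layers if isinstance(l, Conv1D)]
            for d, s in zip(dst, src):
                assert np.array_equal(d.params["W"], s.params["W"])
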