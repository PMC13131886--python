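"""Attribution axioms, event detection, selection rules, network assignment."""

import numpy as np
import pytest
from scipy import stats

from dualpath import xai
from dualpath.nn import ArchitectureConfig, DualPathClassifier
from dualpath.xai import (AttributionBundle, EventWindow, assign_networks,
                          attention_ig_concordance, core_presence,
                          detect_events, event_top_rois, integrated_gradients,
                          saliency_indices, top_k_rois)


def _bundle(sid, ig_t, ig_p=None, attn=None):
    R, T = ig_t.shape
    return AttributionBundle(sid, ig_t,
                             ig_p if ig_p is not None else ig_t.sum(axis=1),
                             attn if attn is not None else np.full(T, 1 / T))


class TestIntegratedGradients:
    def test_linear_model_closed_form(self, tiny_arch):
        # for a linear map F(x) = w.x with zero baseline, IG is exactly w*x
        rng = np.random.default_rng(0)
        R, T, M = 4, 12, 3

        class LinearModel:
            w = rng.normal(size=(R, T)).astype(np.float32)

            def forward(self, x, meta, train=False):
                f = (x * self.w[None]).sum(axis=(1, 2))
                logits = np.stack([f, -f], axis=1)
                return {"fused": logits, "global": logits, "mil": logits,
                        "attention": np.full((len(x), T), 1 / T)}

            def input_gradient(self, x, meta, target, branch="fused"):
                sgn = 1.0 if target == 0 else -1.0
                return sgn * np.repeat(self.w[None], len(x), axis=0)

        model = LinearModel()
        x = rng.normal(size=(R, T))
        attr = integrated_gradients(model, x, np.zeros(M), target=0, n_steps=32)
        np.testing.assert_allclose(attr, model.w * x, rtol=1e-5)

    def test_zero_for_input_equal_baseline(self, tiny_arch):
        model = DualPathClassifier(tiny_arch, seed=0)
        x = np.random.default_rng(1).normal(size=(6, 20)).astype(np.float32)
        attr = integrated_gradients(model, x, np.zeros(4), target=1,
                                    baseline=x.copy(), n_steps=16)
        np.testing.assert_allclose(attr, 0.0, atol=1e-7)

    @pytest.mark.parametrize("branch", ["fused", "global", "mil"])
    def test_completeness_on_random_model(self, tiny_arch, branch):
        model = DualPathClassifier(tiny_arch, seed=2)
        rng = np.random.default_rng(3)
        x = rng.normal(size=(6, 24)).astype(np.float32)
        meta = rng.normal(size=4).astype(np.float32)
        attr = integrated_gradients(model, x, meta, target=1, n_steps=128,
                                    branch=branch)
        f_x = xai.branch_output(model, x, meta, 1, branch)
        f_0 = xai.branch_output(model, np.zeros_like(x), meta, 1, branch)
        gap = abs(attr.sum() - (f_x - f_0))
        assert gap < 0.01 * max(abs(f_x - f_0), 1e-6)


class TestTopK:
    def test_five_percent_of_246_is_twelve(self):
        scores = np.arange(246, dtype=float)
        sel = top_k_rois(scores, 0.05)
        assert len(sel) == 12
        assert sel == list(range(234, 246))

    def test_hundred_regions_five_largest(self):
        rng = np.random.default_rng(0)
        scores = rng.normal(size=100)
        sel = top_k_rois(scores, 0.05)
        assert len(sel) == 5
        assert set(sel) == set(np.argsort(-scores)[:5])

    def test_tie_at_rank_k_deterministic_lower_index(self):
        scores = np.zeros(10)
        scores[[2, 5]] = 1.0  # tie below: everything else equal
        sel1 = top_k_rois(scores, 0.3)
        sel2 = top_k_rois(scores, 0.3)
        assert sel1 == sel2 == [0, 2, 5]

    def test_all_zero_scores_warns(self):
        with pytest.warns(UserWarning):
            sel = top_k_rois(np.zeros(40), 0.05)
        assert sel == [0, 1]


class TestDetectEvents:
    def _null_attention(self, rng, n=25, T=120):
        raw = rng.gamma(2.0, size=(n, T))
        return raw / raw.sum(axis=1, keepdims=True)

    def test_false_event_rate_under_null(self):
        # same generating distribution for both groups: across 100 null
        # simulations fewer than 5% produce any surviving window
        rng = np.random.default_rng(0)
        false_events = 0
        for _ in range(100):
            a = self._null_attention(rng)
            b = self._null_attention(rng)
            false_events += len(detect_events(a, b)) > 0
        assert false_events / 100 < 0.05

    def test_planted_shift_detected(self):
        rng = np.random.default_rng(1)
        a = self._null_attention(rng, n=30)
        b = self._null_attention(rng, n=30)
        a[:, 40:60] += 0.02  # clear case-group excess in one window
        wins = detect_events(a, b)
        assert len(wins) >= 1
        best = max(wins, key=lambda w: min(w.end_tr, 60) - max(w.start_tr, 40))
        inter = len(set(range(best.start_tr, best.end_tr)) & set(range(40, 60)))
        union = len(set(range(best.start_tr, best.end_tr)) | set(range(40, 60)))
        assert inter / union >= 0.5
        assert best.direction == "case"

    def test_alpha_one_covers_whole_run(self):
        rng = np.random.default_rng(2)
        a = self._null_attention(rng)
        b = self._null_attention(rng)
        wins = detect_events(a, b, alpha=1.0)
        assert len(wins) == 1
        assert (wins[0].start_tr, wins[0].end_tr) == (0, 120)

    def test_min_len_filters_single_frame_flickers(self):
        rng = np.random.default_rng(3)
        a = self._null_attention(rng, n=40)
        b = self._null_attention(rng, n=40)
        a[:, 10] += 0.05  # one-frame blip
        wins = detect_events(a, b, min_len=3)
        assert all(not (w.start_tr <= 10 < w.end_tr) or
                   (w.end_tr - w.start_tr) >= 3 for w in wins)


class TestConcordance:
    def test_proportional_series_r_one(self):
        rng = np.random.default_rng(0)
        base = rng.random(50) + 0.1
        bundles = []
        for i in range(6):
            ig = np.tile(base, (4, 1)) * (i + 1)
            bundles.append(_bundle(f"s{i}", ig, attn=base / base.sum()))
        out = attention_ig_concordance(bundles, np.array([1, 1, 1, 0, 0, 0]) == 1)
        assert out["case"][0] == pytest.approx(1.0)
        assert out["control"][0] == pytest.approx(1.0)

    def test_independent_series_usually_uncorrelated(self):
        rng = np.random.default_rng(1)
        small = 0
        n_seeds = 100
        for _ in range(n_seeds):
            ig = rng.normal(size=(3, 100))
            attn = rng.dirichlet(np.ones(100))
            bundles = [_bundle("a", ig, attn=attn),
                       _bundle("b", rng.normal(size=(3, 100)),
                               attn=rng.dirichlet(np.ones(100)))] * 2
            out = attention_ig_concordance(bundles, np.array([1, 1, 0, 0]) == 1)
            small += abs(out["case"][0]) < 0.3
        assert small / n_seeds >= 0.90

    def test_matches_manual_pearson(self):
        rng = np.random.default_rng(2)
        bundles = [_bundle(f"s{i}", rng.normal(size=(5, 40)),
                           attn=rng.dirichlet(np.ones(40))) for i in range(4)]
        mask = np.array([1, 1, 0, 0]) == 1
        out = attention_ig_concordance(bundles, mask)
        A = np.stack([b.attention for b in bundles[:2]]).mean(axis=0)
        G = np.stack([np.abs(b.ig_time_resolved).mean(axis=0)
                      for b in bundles[:2]]).mean(axis=0)
        manual = (((A - A.mean()) * (G - G.mean())).sum()
                  / np.sqrt(((A - A.mean()) ** 2).sum() * ((G - G.mean()) ** 2).sum()))
        assert out["case"][0] == pytest.approx(manual, abs=1e-12)


class TestEventTopRoisAndIndices:
    def test_whole_run_constant_ig_matches_pooled_selection(self):
        rng = np.random.default_rng(0)
        R, T = 30, 40
        profile = rng.random(R)
        ig = np.tile(profile[:, None], (1, T))
        bundles = [_bundle("a", ig, ig_p=ig.sum(axis=1))]
        w = EventWindow(1, 0, T, 0.0, 0.01, "case")
        assert event_top_rois(bundles, w) == top_k_rois(np.abs(ig.sum(axis=1)), 0.05)

    def test_indices_homogeneity_and_constant_case(self):
        R, T = 10, 20
        ig = np.full((R, T), 0.7)
        b1 = _bundle("a", ig, ig_p=np.full(R, -0.7))
        b2 = _bundle("b", 2 * ig, ig_p=np.full(R, -1.4))
        w = EventWindow(1, 5, 15, 0.0, 0.01, "case")
        out = saliency_indices([b1, b2], [0, 1, 2], [[3, 4]], [w])
        assert out[0].global_index == pytest.approx(0.7)
        assert out[0].event_indices[0] == pytest.approx(0.7)
        assert out[1].global_index == pytest.approx(2 * out[0].global_index)


class TestCorePresence:
    def test_majority_rule_three_of_four(self):
        sets = [[1, 2], [1, 3], [1, 4], [5, 6]]
        cpm = core_presence(sets, 8, threshold=3,
                            region_ids=[f"r{i}" for i in range(8)])
        assert cpm.core_regions == ["r1"]
        assert "r5" in cpm.event_specific_regions["E4"]

    def test_five_of_six_is_core(self):
        sets = [[0]] * 5 + [[1]]
        cpm = core_presence(sets, 4, threshold=3)
        assert cpm.matrix.iloc[0].sum() == 5
        assert len(cpm.core_regions) == 1

    def test_disjoint_sets_core_empty_all_specific(self):
        sets = [[0], [1], [2]]
        cpm = core_presence(sets, 5, threshold=2)
        assert cpm.core_regions == []
        specific = [r for rs in cpm.event_specific_regions.values() for r in rs]
        assert len(specific) == 3


class TestAssignNetworks:
    def test_maximal_overlap_and_full_containment(self):
        roi = np.array([1] * 10 + [2] * 4)
        net = np.array([7] * 6 + [8] * 4 + [9] * 4)
        df = assign_networks(roi, net).set_index("region_id")
        assert df.loc[1, "network"] == 7
        assert df.loc[1, "proportion"] == pytest.approx(0.6)
        assert df.loc[2, "network"] == 9
        assert df.loc[2, "proportion"] == 1.0

    def test_tie_breaks_low_id_with_flag(self):
        roi = np.array([3] * 4)
        net = np.array([5, 5, 2, 2])
        df = assign_networks(roi, net)
        assert df.iloc[0]["network"] == 2
        assert bool(df.iloc[0]["tie"])

    def test_zero_overlap_unassigned(self):
        roi = np.array([1, 1, 0, 0])
        net = np.array([0, 0, 4, 4])
        df = assign_networks(roi, net)
        assert df.iloc[0]["network"] == "unassigned"
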