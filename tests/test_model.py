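"""Two-branch classifier: shapes, gradients, determinism, learning behavior."""

import numpy as np
import pytest

import mpradesign as m
from mpradesign.errors import ConfigError


class TestArchitectureShapes:
    def test_conv_pool_length_sequence(self):
        spec = m.ModelSpec(l_site=10)
        assert spec.conv_lengths() == (80, 40, 36, 18)
        assert spec.flat_units == 576
        assert spec.joint_input == 976

    def test_parameter_counts_follow_shape_arithmetic(self):
        net = m.build_model(m.ModelSpec(l_site=100), seed=0)
        assert net.params["wc1"].size + net.params["bc1"].size == 32 * (8 * 4) + 32  # 1056
        assert net.params["wc2"].size + net.params["bc2"].size == 32 * (32 * 5) + 32  # 5152
        assert net.params["wj"].size + net.params["bj"].size == 976 * 256 + 256  # 250112

    @pytest.mark.parametrize("l_site", [10, 1060])
    def test_forward_finite_on_ones(self, l_site):
        net = m.build_model(m.ModelSpec(l_site=l_site), seed=1)
        out = net.forward(np.ones((3, l_site)), np.ones((3, 8, 81)))
        assert out.shape == (3,)
        assert np.all(np.isfinite(out))

    def test_collapsing_stack_rejected(self):
        with pytest.raises(ConfigError):
            m.build_model(m.ModelSpec(l_site=5, n_bins=5), seed=0)

    def test_dimension_mismatch_rejected(self):
        net = m.build_model(m.ModelSpec(l_site=10), seed=0)
        with pytest.raises(ConfigError):
            net.forward(np.ones((2, 11)), np.ones((2, 8, 81)))


class TestGradients:
    def test_analytic_matches_numerical_gradient(self):
        spec = m.ModelSpec(l_site=7, n_markers=3, n_bins=11, conv1_kernels=4,
                           conv2_kernels=4, conv2_width=3, site_units=5, joint_units=6)
        net = m.build_model(spec, seed=3)
        rng = np.random.default_rng(0)
        xs = rng.normal(size=(4, 7))
        xn = rng.gamma(2.0, size=(4, 3, 11))
        y = np.array([1.0, 0.0, 1.0, 0.0])
        _, grads = net.loss_and_grads(xs, xn, y)
        eps = 1e-6
        for k, p in net.params.items():
            idx = tuple(rng.integers(0, s) for s in p.shape)
            orig = p[idx]
            p[idx] = orig + eps
            lp, _ = net.loss_and_grads(xs, xn, y)
            p[idx] = orig - eps
            lm, _ = net.loss_and_grads(xs, xn, y)
            p[idx] = orig
            assert grads[k][idx] == pytest.approx((lp - lm) / (2 * eps), abs=1e-6, rel=1e-4)

    def test_single_step_reduces_regularized_loss(self):
        spec = m.ModelSpec(l_site=6, n_markers=2, n_bins=9, conv1_kernels=3,
                           conv2_kernels=3, conv2_width=2, site_units=4, joint_units=4)
        net = m.build_model(spec, seed=5)
        rng = np.random.default_rng(1)
        xs, xn = rng.normal(size=(2, 6)), rng.gamma(2.0, size=(2, 2, 9))
        y = np.array([1.0, 0.0])
        l2 = 5e-4
        loss0, grads = net.loss_and_grads(xs, xn, y, l2=l2)
        opt = m.nn.Adam(net.params, lr=1e-5, l2=l2,
                        decay_params=set(m.TwoBranchNet.WEIGHT_KEYS))
        opt.step(grads)
        loss1, _ = net.loss_and_grads(xs, xn, y, l2=l2)
        assert loss1 < loss0


class TestTraining:
    def test_identical_histories_and_predictions_under_seed(self):
        spec = m.ModelSpec(l_site=8, n_markers=2, n_bins=9, conv1_kernels=3,
                           conv2_kernels=3, conv2_width=2, site_units=6, joint_units=6)
        rng = np.random.default_rng(2)
        xs, xn = rng.normal(size=(60, 8)), rng.gamma(2.0, size=(60, 2, 9))
        y = (rng.uniform(size=60) < 0.3).astype(float)
        runs = []
        for _ in range(2):
            net = m.build_model(spec, seed=9)
            res = m.train(net, xs, xn, y, m.TrainConfig(epochs=3, batch_size=16, seed=9))
            runs.append((res.loss_history, m.predict(net, xs, xn)))
        assert runs[0][0] == runs[1][0]
        assert np.array_equal(runs[0][1], runs[1][1])

    def test_loss_decreases_on_separable_data(self, trained_pipeline):
        hist = trained_pipeline["result"].loss_history
        assert len(hist) == 10
        assert hist[-1] < hist[0]

    def test_holdout_auroc_high_with_planted_signal(self, trained_pipeline):
        tp = trained_pipeline
        scores = m.predict(tp["net"], tp["xs_va"], tp["xn_va"])
        assert m.auroc(scores, tp["y"][~tp["train_mask"]]) >= 0.85

    def test_empty_and_single_class_rejected(self):
        spec = m.ModelSpec(l_site=4, n_markers=2, n_bins=9, conv1_kernels=2,
                           conv2_kernels=2, conv2_width=2, site_units=3, joint_units=3)
        net = m.build_model(spec, seed=0)
        with pytest.raises(ConfigError):
            m.train(net, np.ones((0, 4)), np.ones((0, 2, 9)), np.array([]), m.TrainConfig())
        with pytest.raises(ConfigError):
            m.train(net, np.ones((4, 4)), np.ones((4, 2, 9)), np.ones(4), m.TrainConfig())


class TestPredict:
    def test_scores_strictly_inside_unit_interval(self, trained_pipeline):
        tp = trained_pipeline
        s = m.predict(tp["net"], tp["xs_va"], tp["xn_va"])
        assert np.all((s > 0) & (s < 1))

    def test_duplicate_inputs_identical_scores(self, trained_pipeline):
        tp = trained_pipeline
        xs = np.vstack([tp["xs_va"][:1], tp["xs_va"][:1]])
        xn = np.vstack([tp["xn_va"][:1], tp["xn_va"][:1]])
        s = m.predict(tp["net"], xs, xn)
        assert s[0] == s[1]


class TestAblation:
    def _train_auroc(self, branches, site_effect, nbhd_effect, seed):
        base = dict(n_variants=4000, positive_fraction=0.1, n_site_scores=10,
                    n_tissue_annotations=2, informative_fraction=0.4,
                    missing_fraction=0.0, seed=seed)
        cfg_var = m.SynthConfig(effect_size=1.0, **base)
        v = m.generate_variants(cfg_var)
        scores = m.generate_site_scores(v, m.SynthConfig(effect_size=site_effect, **base))
        nbhd = m.generate_neighborhood_tracks(v, m.SynthConfig(effect_size=nbhd_effect, **base))
        y = v.LABEL.to_numpy().astype(float)
        rng = np.random.default_rng(seed)
        tr = rng.uniform(size=len(y)) < 0.8
        site = scores.to_numpy()
        std = m.Standardizer().fit(site[tr], nbhd[tr])
        xs_tr, xn_tr = std.transform(site[tr], nbhd[tr])
        xs_va, xn_va = std.transform(site[~tr], nbhd[~tr])
        spec = m.ModelSpec(l_site=site.shape[1], branches=branches)
        net = m.build_model(spec, seed=seed)
        m.train(net, xs_tr, xn_tr, y[tr], m.TrainConfig(epochs=8, seed=seed))
        return m.auroc(m.predict(net, xs_va, xn_va), y[~tr])

    def test_neighborhood_signal_needs_conv_branch(self):
        """Signal planted only in the marker tracks: full model beats site-only."""
        full = np.mean([self._train_auroc("both", 0.0, 2.0, s) for s in (0, 1)])
        site_only = np.mean([self._train_auroc("site", 0.0, 2.0, s) for s in (0, 1)])
        assert full > site_only + 0.05

    def test_site_signal_needs_site_branch(self):
        full = np.mean([self._train_auroc("both", 2.0, 0.0, s) for s in (0, 1)])
        nbhd_only = np.mean([self._train_auroc("neighborhood", 2.0, 0.0, s) for s in (0, 1)])
        assert full > nbhd_only + 0.05


class TestSignalMonotonicity:
    def test_auroc_non_decreasing_in_effect_size(self):
        """Validation AUROC tracks the planted effect size (2-seed average)."""
        helper = TestAblation()
        means = [
            np.mean([helper._train_auroc("both", e, e, s) for s in (0, 1)])
            for e in (0.0, 1.5, 3.0)
        ]
        assert means[0] + 0.02 < means[1]
        assert means[2] >= means[1] - 0.02
        assert 0.35 <= means[0] <= 0.65


class TestCheckpoint:
    def test_save_load_roundtrip(self, trained_pipeline, tmp_path):
        tp = trained_pipeline
        path = tmp_path / "model.npz"
        m.save_checkpoint(tp["net"], path)
        clone = m.load_checkpoint(path)
        assert clone.spec == tp["spec"]
        a = m.predict(tp["net"], tp["xs_va"], tp["xn_va"])
        b = m.predict(clone, tp["xs_va"], tp["xn_va"])
        assert np.array_equal(a, b)
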