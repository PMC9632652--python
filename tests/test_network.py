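import dataclasses

import numpy as np
import pytest

from msdaelm import (
    BackboneSpec,
    ConfigurationError,
    ImageDomainSpec,
    InputError,
    KernelSpec,
    SpecificExtractorSpec,
    TrainingConfig,
    alpha_schedule,
    build_model,
    ensemble_predict,
    extract_deep_features,
    gen_image_domains,
    task_loss,
    train,
)
from msdaelm.network import EnsemblePrediction


def tiny_domains(seed=0, n=6, size=16, noise=0.15, n_sources=3):
    tpl = ImageDomainSpec(n_per_class=n, noise_sigma=noise)
    doms = gen_image_domains(tpl, [tpl] * n_sources, image_size=size, seed=seed)
    return doms[0], doms[1:]


def tiny_model(seed=0, size=16, n_sources=3):
    return build_model(
        BackboneSpec(input_shape=(1, size, size), stage_channels=(4, 6)),
        SpecificExtractorSpec((4, 4, 4)),
        n_sources=n_sources,
        seed=seed,
    )


class TestBuildModel:
    def test_three_source_structure(self):
        m = tiny_model(n_sources=3)
        assert len(m.specifics) == 3
        assert len(m.predictors) == 3
        counts = m.parameter_count()
        assert counts["common"] > 0 and counts["specific"] > 0

    def test_single_source_degenerates(self):
        m = tiny_model(n_sources=1)
        assert len(m.specifics) == 1
        pred = m.predict(np.zeros((2, 1, 16, 16)))
        assert len(pred.per_predictor) == 1

    def test_forward_bit_identical_across_constructions(self, rng):
        imgs = rng.normal(size=(4, 1, 16, 16))
        p1 = tiny_model(seed=9).predict(imgs)
        p2 = tiny_model(seed=9).predict(imgs)
        assert np.array_equal(p1.averaged, p2.averaged)

    def test_unregistered_backbone_rejected(self):
        with pytest.raises(ConfigurationError, match="resnet50"):
            build_model(BackboneSpec(kind="resnet50"), SpecificExtractorSpec())

    def test_specific_spec_requires_three_stages(self):
        with pytest.raises(ConfigurationError):
            SpecificExtractorSpec((8, 8))


class TestAlphaSchedule:
    @pytest.mark.parametrize(
        "progress, theta, mode, expected",
        [
            (0.0, 10.0, "clamped_exp_decay", 1.0),
            (1.0, 10.0, "clamped_exp_decay", 0.0),  # raw value < 0, clamped
            (0.5, 10.0, "clamped_exp_decay", 0.0),
            (0.0, 10.0, "progressive", 0.0),
        ],
    )
    def test_endpoints(self, progress, theta, mode, expected):
        assert alpha_schedule(progress, theta, mode) == pytest.approx(expected)

    def test_progressive_monotone_to_one(self):
        vals = [alpha_schedule(p, 10.0, "progressive")
                for p in np.linspace(0, 1, 21)]
        assert all(a <= b for a, b in zip(vals, vals[1:]))
        assert 0.0 <= min(vals) and max(vals) <= 1.0


class TestEnsemblePredict:
    def test_identical_outputs_passthrough(self):
        v = np.array([0.3, 0.7])
        pred = ensemble_predict([v, v, v])
        assert pred.averaged == pytest.approx(v)

    def test_arithmetic_mean(self):
        pred = ensemble_predict([np.array([1.0, 0.0]), np.array([0.0, 1.0]),
                                 np.array([0.5, 0.5])])
        assert pred.averaged == pytest.approx([0.5, 0.5])

    def test_permutation_invariant(self, rng):
        outs = [v / v.sum() for v in rng.uniform(0.1, 1, size=(3, 4))]
        a = ensemble_predict(outs).averaged
        b = ensemble_predict(outs[::-1]).averaged
        assert a == pytest.approx(b, abs=1e-12)

    def test_seeded_outputs_match_manual_mean(self, rng):
        outs = [v / v.sum() for v in rng.uniform(0.1, 1, size=(5, 3))]
        pred = ensemble_predict(outs)
        assert pred.averaged == pytest.approx(np.mean(outs, axis=0), abs=1e-12)

    def test_invalid_probability_rejected(self):
        with pytest.raises(InputError):
            ensemble_predict([np.array([0.9, 0.3])])


class TestTaskLoss:
    def test_confident_correct_is_zero(self):
        pred = EnsemblePrediction([], np.array([1.0, 0.0]))
        assert task_loss(pred, 0) == pytest.approx(0.0, abs=1e-9)

    def test_uniform_is_log2(self):
        pred = EnsemblePrediction([], np.array([0.5, 0.5]))
        assert task_loss(pred, 1) == pytest.approx(np.log(2), abs=1e-9)

    def test_batch_matches_manual_mean(self, rng):
        p = rng.uniform(0.05, 1, size=(6, 2))
        p /= p.sum(axis=1, keepdims=True)
        y = rng.integers(0, 2, 6)
        pred = EnsemblePrediction([], p)
        manual = -np.mean([np.log(p[i, y[i]]) for i in range(6)])
        assert task_loss(pred, y) == pytest.approx(manual, abs=1e-12)

    def test_zero_probability_floored(self):
        pred = EnsemblePrediction([], np.array([0.0, 1.0]))
        assert task_loss(pred, 0) == pytest.approx(-np.log(1e-12))


class TestTraining:
    def test_alpha_zero_reduces_to_task_loss(self):
        target, sources = tiny_domains()
        model = tiny_model()
        cfg = TrainingConfig(batch_size=4, iterations=5, alpha_override=0.0,
                             seed=1)
        hist = train(model, sources, target, cfg)
        for lb in hist.losses:
            assert lb.l_total == pytest.approx(lb.l_task, abs=1e-12)
            assert lb.alpha == 0.0

    def test_fixed_seed_bit_identical_history(self):
        losses = []
        for _ in range(2):
            target, sources = tiny_domains(seed=3)
            model = tiny_model(seed=3)
            cfg = TrainingConfig(batch_size=4, iterations=12, seed=7,
                                 alpha_mode="progressive")
            hist = train(model, sources, target, cfg)
            losses.append([(lb.l_mmd, lb.l_task, lb.l_total)
                           for lb in hist.losses])
        assert losses[0] == losses[1]

    def test_alignment_loss_decreases_under_shift(self):
        """On domains with real distribution shift the alignment loss falls
        well below its starting value; on identically distributed domains it
        starts at (and stays near) the mini-batch sampling-noise floor."""
        tpl = ImageDomainSpec(n_per_class=10, noise_sigma=0.15)
        shifted = [dataclasses.replace(tpl, brightness=0.4),
                   dataclasses.replace(tpl, contrast=1.6),
                   dataclasses.replace(tpl, brightness=-0.3)]
        doms = gen_image_domains(tpl, shifted, image_size=16, seed=5)
        model = tiny_model(seed=5)
        cfg = TrainingConfig(batch_size=8, iterations=60, alpha_override=1.0,
                             seed=5)
        hist = train(model, doms[1:], doms[0], cfg, KernelSpec())
        start = np.mean([lb.l_mmd for lb in hist.losses[:5]])
        end = np.mean([lb.l_mmd for lb in hist.losses[-5:]])
        assert end < 0.5 * start

        # no-shift control: the loss is bounded by the batch noise floor
        target, sources = tiny_domains(seed=5, n=10)
        model = tiny_model(seed=5)
        hist0 = train(model, sources, target, cfg, KernelSpec())
        assert np.mean([lb.l_mmd for lb in hist0.losses[-10:]]) < 1.0

    def test_missing_class_names_domain(self):
        target, sources = tiny_domains()
        bad = sources[0]
        bad.labels[:] = 0  # drop class 1 entirely
        model = tiny_model()
        cfg = TrainingConfig(batch_size=4, iterations=2, seed=0)
        with pytest.raises(InputError, match="S1"):
            train(model, sources, target, cfg)

    def test_source_count_mismatch(self):
        target, sources = tiny_domains()
        model = tiny_model(n_sources=2)
        with pytest.raises(InputError):
            train(model, sources, target,
                  TrainingConfig(batch_size=4, iterations=1))


class TestFeatureExtraction:
    def test_feature_count_formula(self):
        # 16+32 common channels, 3 specific extractors of 8 channels -> 72
        m = build_model(
            BackboneSpec(input_shape=(1, 16, 16), stage_channels=(16, 32)),
            SpecificExtractorSpec((8, 8, 8)), n_sources=3, seed=0,
        )
        assert m.feature_dim() == 72
        target, _ = tiny_domains(n=2)
        fs = extract_deep_features(m, target)
        assert fs.n_features == 72
        assert fs.feature_names[0] == "common1_c0"
        assert fs.feature_names[-1] == "spec2_c7"

    @pytest.mark.parametrize("n_sources", [1, 2, 3])
    def test_count_invariance(self, n_sources):
        m = tiny_model(n_sources=n_sources)
        assert m.feature_dim() == 4 + 6 + n_sources * 4

    def test_same_image_identical_rows(self):
        m = tiny_model()
        img = np.random.default_rng(0).normal(size=(1, 1, 16, 16))
        from msdaelm import LabeledImageSet

        iset = LabeledImageSet(np.concatenate([img, img]), np.array([0, 0]))
        fs = extract_deep_features(m, iset)
        assert np.array_equal(fs.features[0], fs.features[1])


class TestPseudoLabels:
    def test_unlabeled_target_mode_runs(self):
        """Pseudo-label mode uses the current ensemble argmax for the
        conditional terms; training stays finite and reproducible."""
        target, sources = tiny_domains(seed=2)
        model = tiny_model(seed=2)
        cfg = TrainingConfig(batch_size=4, iterations=6, seed=2,
                             pseudo_labels=True, alpha_override=0.5)
        hist = train(model, sources, target, cfg)
        assert len(hist.losses) == 6
        assert all(np.isfinite(lb.l_total) for lb in hist.losses)
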