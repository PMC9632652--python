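import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from msdaelm import (
    DegenerateInputError,
    InputError,
    KernelSpec,
    LabeledFeatureSet,
    adaptation_factor,
    class_wasserstein_weights,
    conditional_mmd,
    gaussian_kernel,
    mmd_squared,
    multisource_mmd_loss,
    pair_divergence,
    wasserstein_distance,
)
from msdaelm.divergence import DivergenceReport

from .oracles import mmd_squared_bruteforce, wasserstein_1d_sorted


class TestGaussianKernel:
    @pytest.mark.parametrize(
        "x, y, sigma, expected",
        [
            ([1.0, 2.0], [1.0, 2.0], 0.7, 1.0),          # zero distance
            ([0.0], [2.0], np.sqrt(2.0), np.exp(-1.0)),  # ||x-y||^2 = 2 sigma^2
            ([0.0, 0.0], [3.0, 4.0], 5.0, np.exp(-0.5)),
        ],
    )
    def test_closed_form_values(self, x, y, sigma, expected):
        spec = KernelSpec(bandwidth=sigma)
        assert gaussian_kernel(x, y, spec) == pytest.approx(expected, abs=1e-12)
        assert gaussian_kernel(y, x, spec) == gaussian_kernel(x, y, spec)

    def test_dimension_mismatch_rejected(self):
        with pytest.raises(InputError):
            gaussian_kernel([0.0, 1.0], [0.0], KernelSpec(bandwidth=1.0))

    def test_nonpositive_bandwidth_rejected(self):
        with pytest.raises(Exception):
            KernelSpec(bandwidth=-1.0)


class TestMmdSquared:
    def test_identical_multisets_give_zero(self, rng):
        X = rng.normal(size=(9, 4))
        assert mmd_squared(X, X.copy(), KernelSpec(bandwidth=1.0)) <= 1e-10

    def test_singletons_closed_form(self):
        spec = KernelSpec(bandwidth=1.5)
        x, y = np.array([[0.0, 0.0]]), np.array([[1.0, 2.0]])
        expected = 2.0 - 2.0 * gaussian_kernel(x[0], y[0], spec)
        assert mmd_squared(x, y, spec) == pytest.approx(expected, abs=1e-12)

    @pytest.mark.parametrize("seed", range(10))
    @pytest.mark.parametrize("n,m", [(3, 3), (8, 5), (20, 11)])
    def test_matches_bruteforce_triple_sum(self, seed, n, m):
        rng = np.random.default_rng(seed)
        X = rng.normal(size=(n, 2))
        Y = rng.normal(size=(m, 2)) + 0.4
        sigma = 0.9
        ours = mmd_squared(X, Y, KernelSpec(bandwidth=sigma))
        assert ours == pytest.approx(mmd_squared_bruteforce(X, Y, sigma),
                                     abs=1e-12)

    def test_symmetric_in_arguments(self, rng):
        X = rng.normal(size=(7, 3))
        Y = rng.normal(size=(5, 3)) + 1.0
        spec = KernelSpec(bandwidth="median")
        assert mmd_squared(X, Y, spec) == pytest.approx(
            mmd_squared(Y, X, spec), abs=1e-12
        )

    def test_empty_set_rejected(self, rng):
        with pytest.raises(InputError):
            mmd_squared(np.empty((0, 2)), rng.normal(size=(3, 2)))


class TestConditionalMmd:
    def test_identical_single_class(self, rng):
        X = rng.normal(size=(6, 2))
        a = LabeledFeatureSet(X, np.zeros(6, dtype=int), domain_id="A")
        b = LabeledFeatureSet(X.copy(), np.zeros(6, dtype=int), domain_id="B")
        out = conditional_mmd(a, b, KernelSpec(bandwidth=1.0))
        assert set(out) == {0}
        assert out[0] <= 1e-10

    def test_per_class_restriction(self, rng):
        X0 = rng.normal(size=(5, 2))
        X1a = rng.normal(size=(5, 2)) + 2.0
        X1b = rng.normal(size=(5, 2)) - 2.0
        y = np.array([0] * 5 + [1] * 5)
        a = LabeledFeatureSet(np.vstack([X0, X1a]), y, domain_id="A")
        b = LabeledFeatureSet(np.vstack([X0, X1b]), y, domain_id="B")
        out = conditional_mmd(a, b, KernelSpec(bandwidth=1.0))
        assert out[0] <= 1e-10
        assert out[1] > 0.1

    def test_matches_manual_slicing(self, two_class_pair):
        src, tgt = two_class_pair(n=12)
        spec = KernelSpec(bandwidth=1.3)
        out = conditional_mmd(src, tgt, spec)
        for l in (0, 1):
            manual = mmd_squared(src.features[src.labels == l],
                                 tgt.features[tgt.labels == l], spec)
            assert out[l] == pytest.approx(manual, abs=1e-12)

    def test_disjoint_classes_rejected(self, rng):
        a = LabeledFeatureSet(rng.normal(size=(4, 2)), np.zeros(4, dtype=int))
        b = LabeledFeatureSet(rng.normal(size=(4, 2)), np.ones(4, dtype=int))
        with pytest.raises(DegenerateInputError):
            conditional_mmd(a, b)

    def test_partial_class_overlap_warns_and_drops(self, rng):
        a = LabeledFeatureSet(rng.normal(size=(6, 2)),
                              np.array([0, 0, 0, 1, 1, 1]))
        b = LabeledFeatureSet(rng.normal(size=(4, 2)), np.zeros(4, dtype=int))
        with pytest.warns(UserWarning, match="missing"):
            out = conditional_mmd(a, b)
        assert set(out) == {0}


class TestWasserstein:
    def test_identical_sets_zero(self, rng):
        X = rng.normal(size=(6, 3))
        assert wasserstein_distance(X, X.copy()) == pytest.approx(0.0, abs=1e-12)

    def test_singletons_euclidean_distance(self):
        x, y = np.array([[0.0, 0.0]]), np.array([[3.0, 4.0]])
        assert wasserstein_distance(x, y) == pytest.approx(5.0, abs=1e-12)

    @pytest.mark.parametrize("seed", range(8))
    def test_equal_size_1d_matches_sorting_oracle(self, seed):
        rng = np.random.default_rng(seed)
        a = rng.normal(size=(15, 1))
        b = rng.normal(size=(15, 1)) + 0.7
        assert wasserstein_distance(a, b) == pytest.approx(
            wasserstein_1d_sorted(a, b), abs=1e-9
        )

    @pytest.mark.parametrize("seed", range(5))
    def test_unequal_size_1d_matches_scipy(self, seed):
        from scipy.stats import wasserstein_distance as scipy_w1

        rng = np.random.default_rng(seed)
        a = rng.normal(size=(9, 1))
        b = rng.normal(size=(13, 1)) + 0.3
        assert wasserstein_distance(a, b) == pytest.approx(
            scipy_w1(a.ravel(), b.ravel()), abs=1e-9
        )

    @pytest.mark.parametrize("seed", range(10))
    def test_triangle_inequality(self, seed):
        rng = np.random.default_rng(seed)
        A = rng.normal(size=(6, 2))
        B = rng.normal(size=(6, 2)) + 1.0
        C = rng.normal(size=(6, 2)) - 0.5
        ab = wasserstein_distance(A, B)
        bc = wasserstein_distance(B, C)
        ac = wasserstein_distance(A, C)
        assert ac <= ab + bc + 1e-8

    def test_size_guard(self, rng):
        big = rng.normal(size=(513, 1))
        with pytest.raises(InputError, match="512"):
            wasserstein_distance(big, big)


class TestAdaptationFactor:
    @pytest.mark.parametrize(
        "w_g, w_by_class, expected",
        [
            (1.0, {0: 0.5, 1: 0.5}, 0.5),
            (2.0, {0: 0.0, 1: 0.0}, 0.0),
            (0.0, {0: 0.3, 1: 0.7}, 1.0),
        ],
    )
    def test_closed_form_corners(self, w_g, w_by_class, expected):
        assert adaptation_factor(w_g, w_by_class) == pytest.approx(expected)

    def test_zero_everything_falls_back_to_half(self):
        with pytest.warns(UserWarning, match="identical"):
            assert adaptation_factor(0.0, {0: 0.0, 1: 0.0}) == 0.5

    def test_bounds_and_monotonicity(self, rng):
        for _ in range(50):
            wg = float(rng.uniform(0, 3))
            w0, w1 = rng.uniform(0.01, 3, size=2)
            mu = adaptation_factor(wg, {0: w0, 1: w1})
            assert 0.0 <= mu <= 1.0
            # increasing a class weight raises mu; increasing W_g lowers it
            assert adaptation_factor(wg, {0: w0 + 0.5, 1: w1}) >= mu
            assert adaptation_factor(wg + 0.5, {0: w0, 1: w1}) <= mu


class TestPairDivergence:
    def test_identical_domains_all_zero(self, rng):
        X = rng.normal(size=(10, 3))
        y = np.array([0, 1] * 5)
        a = LabeledFeatureSet(X, y, domain_id="A")
        b = LabeledFeatureSet(X.copy(), y.copy(), domain_id="B")
        r = pair_divergence(a, b)
        assert r.combined == pytest.approx(0.0, abs=1e-10)
        assert r.mmd_marginal == pytest.approx(0.0, abs=1e-10)
        assert r.mu == 0.5  # defined fallback for identical domains

    def test_combined_recombines_components(self, two_class_pair):
        src, tgt = two_class_pair(n=14)
        r = pair_divergence(src, tgt, KernelSpec(bandwidth=1.1))
        manual = (1 - r.mu) * r.mmd_marginal + r.mu * sum(
            r.mmd_conditional_by_class.values()
        )
        assert r.combined == pytest.approx(manual, abs=1e-12)
        # cross-check mu against the independently computed weights
        assert r.mu == pytest.approx(
            adaptation_factor(r.w_global, r.w_by_class), abs=1e-12
        )

    def test_pure_global_shift_strictly_interior_mu(self, rng):
        y = np.array([0, 1] * 10)
        X = rng.normal(size=(20, 4)) + 1.5 * y[:, None]
        a = LabeledFeatureSet(X, y, domain_id="A")
        b = LabeledFeatureSet(X + np.array([4.0, 0, 0, 0]), y, domain_id="B")
        r = pair_divergence(a, b)
        assert 0.0 < r.mu < 1.0
        assert r.combined > 0.0

    def test_combined_zero_iff_components_zero(self, two_class_pair):
        src, tgt = two_class_pair(n=12, offset=1.0)
        r = pair_divergence(src, tgt)
        assert r.combined > 1e-6
        assert r.mmd_marginal > 0 or any(
            v > 0 for v in r.mmd_conditional_by_class.values()
        )

    def test_centered_class_weights_ignore_translation(self, rng):
        """A pure translation leaves the (centered) class weights at the
        finite-sample noise floor while the global weight tracks the shift."""
        y = np.array([0, 1] * 25)
        X = rng.normal(size=(50, 6)) + 1.5 * y[:, None]
        shift = np.zeros(6)
        shift[3] = 6.0
        a = LabeledFeatureSet(X, y, domain_id="A")
        b = LabeledFeatureSet(X + shift, y, domain_id="B")
        w_l = class_wasserstein_weights(a, b)
        w_g = wasserstein_distance(a, b)
        assert w_g > 5.5
        assert all(v < 2.5 for v in w_l.values())


class TestMultisourceLoss:
    def test_mean_of_combined(self):
        def rep(c):
            return DivergenceReport(0.0, {}, 0.0, {}, 0.5, c)

        assert multisource_mmd_loss([rep(0.1), rep(0.2), rep(0.6)]) == pytest.approx(0.3)
        assert multisource_mmd_loss([rep(0.4)] * 3) == pytest.approx(0.4)
        assert multisource_mmd_loss([rep(0.0)] * 3) == 0.0

    def test_empty_rejected(self):
        with pytest.raises(InputError):
            multisource_mmd_loss([])


class TestMuDirections:
    """Marginal-dominant shift pulls mu below 0.5; conditional-dominant
    pushes it above — the qualitative behavior of the adaptation factor."""

    def test_marginal_vs_conditional_shift(self):
        from msdaelm import feature_preset, gen_feature_domains

        hits = {"marginal_shift": 0, "conditional_shift": 0}
        n_seeds = 20
        for preset, want_low in (("marginal_shift", True),
                                 ("conditional_shift", False)):
            tpl, srcs = feature_preset(preset)
            for seed in range(n_seeds):
                doms = gen_feature_domains(tpl, [srcs[0]], seed)
                r = pair_divergence(doms[1], doms[0])
                ok = (r.mu < 0.5) if want_low else (r.mu > 0.5)
                hits[preset] += ok
        assert hits["marginal_shift"] >= int(0.8 * n_seeds)
        assert hits["conditional_shift"] >= int(0.8 * n_seeds)


class TestMultiKernel:
    def test_bandwidth_ladder_average(self, rng):
        """The multi-kernel MMD is the mean of single-kernel MMDs over the
        sigma ladder, and keeps the self-distance-zero property."""
        from msdaelm.divergence import _MULTI_KERNEL_SCALES

        X = rng.normal(size=(8, 2))
        Y = rng.normal(size=(6, 2)) + 0.5
        multi = mmd_squared(X, Y, KernelSpec(bandwidth=1.2, n_kernels=5))
        singles = [mmd_squared(X, Y, KernelSpec(bandwidth=1.2 * s))
                   for s in _MULTI_KERNEL_SCALES]
        assert multi == pytest.approx(np.mean(singles), abs=1e-12)
        assert mmd_squared(X, X.copy(),
                           KernelSpec(bandwidth=1.2, n_kernels=5)) <= 1e-10


class TestAdaptationFactorProperties:
    @given(
        w_g=st.floats(0.0, 100.0),
        w0=st.floats(0.0, 100.0),
        w1=st.floats(0.0, 100.0),
    )
    @settings(derandomize=True, max_examples=200)
    def test_always_in_unit_interval(self, w_g, w0, w1):
        import warnings

        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            mu = adaptation_factor(w_g, {0: w0, 1: w1})
        assert 0.0 <= mu <= 1.0
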