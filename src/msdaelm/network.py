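"""Multisource transfer feature-extraction network.

One *common* convolutional extractor maps images from every domain into a
shared feature space; one small *domain-specific* extractor per
source–target pair (a 1×1 → 3×3 → 1×1 convolution stack) maps that pair
into its own space, where the Wasserstein-weighted MMD divergence
(:mod:`.divergence`) is measured and minimized.  A softmax sub-predictor
per pair classifies the target stream; the ensemble prediction is the
arithmetic mean of the sub-predictor outputs, and the task loss is the
cross-entropy of that mean.  The total training objective is

    l_total = α · l_MMD + l_task,

with α following a schedule in the normalized training progress.

Everything here is plain numpy with explicit backpropagation: forward
methods cache what the matching ``backward`` needs, and a run is
bit-reproducible from a single seed.  The Wasserstein weights μ and the
kernel bandwidth σ are recomputed from each mini-batch and treated as
constants of the step (no gradient flows through them).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace

import numpy as np
from scipy.spatial.distance import cdist

from .data import LabeledFeatureSet, LabeledImageSet
from .divergence import DivergenceReport, KernelSpec, multisource_mmd_loss, pair_divergence
from .errors import ConfigurationError, InputError

__all__ = [
    "BackboneSpec",
    "SpecificExtractorSpec",
    "TrainingConfig",
    "LossBreakdown",
    "EnsemblePrediction",
    "MultiSourceModel",
    "TrainingHistory",
    "register_backbone",
    "build_model",
    "alpha_schedule",
    "ensemble_predict",
    "task_loss",
    "train",
    "extract_deep_features",
]

_PROB_FLOOR = 1e-12


# ---------------------------------------------------------------------------
# Specs and configuration


@dataclass
class BackboneSpec:
    """Common-extractor choice.

    ``tiny_cnn`` (two 3×3 conv + ReLU + 2×2 max-pool stages) always builds
    with no downloads and is the tested default.  Other kinds (e.g. a
    ResNet-50 layout with externally supplied weights) must be registered
    through :func:`register_backbone`.
    """

    kind: str = "tiny_cnn"
    input_shape: tuple[int, int, int] = (1, 32, 32)
    pretrained: bool = False
    stage_channels: tuple[int, int] = (8, 16)


@dataclass
class SpecificExtractorSpec:
    """Domain-specific extractor: fixed 1×1 → 3×3 → 1×1 convolution stack."""

    out_channels: tuple[int, int, int] = (8, 8, 8)

    def __post_init__(self) -> None:
        if len(self.out_channels) != 3 or any(c < 1 for c in self.out_channels):
            raise ConfigurationError(
                "specific extractor needs exactly three positive stage widths "
                "(1x1, 3x3, 1x1 convolutions)"
            )


@dataclass
class TrainingConfig:
    """SGD training hyperparameters.

    The defaults are the method's full-scale operating point (momentum 0.9, weight
    decay 1e−4, common/specific learning rates 0.001/0.01, batch 32, up to
    2000 iterations, θ = 10); tests and the synthetic experiments scale the
    batch and iteration counts down.  ``batch_size`` is per domain and the
    sampler keeps it class-balanced.
    """

    lr_common: float = 0.001
    lr_specific: float = 0.01
    momentum: float = 0.9
    weight_decay: float = 1e-4
    batch_size: int = 32
    iterations: int = 2000
    theta: float = 10.0
    alpha_mode: str = "clamped_exp_decay"
    alpha_override: float | None = None
    pseudo_labels: bool = False
    ensemble: bool = True
    seed: int = 0

    def __post_init__(self) -> None:
        if min(self.lr_common, self.lr_specific) <= 0:
            raise ConfigurationError("learning rates must be > 0")
        if self.batch_size < 2:
            raise ConfigurationError("batch_size must be >= 2 per domain")
        if self.iterations < 1:
            raise ConfigurationError("iterations must be >= 1")
        if self.theta <= 0:
            raise ConfigurationError("theta must be > 0")
        if self.alpha_mode not in ("clamped_exp_decay", "progressive"):
            raise ConfigurationError(f"unknown alpha_mode {self.alpha_mode!r}")


@dataclass
class LossBreakdown:
    l_mmd: float
    l_task: float
    alpha: float
    l_total: float


@dataclass
class EnsemblePrediction:
    """Per-predictor softmax outputs and their arithmetic mean."""

    per_predictor: list[np.ndarray]
    averaged: np.ndarray


@dataclass
class TrainingHistory:
    losses: list[LossBreakdown] = field(default_factory=list)
    divergences: list[list[DivergenceReport]] = field(default_factory=list)

    @property
    def mu_running_mean(self) -> list[float]:
        """Per-pair mean adaptation factor over all logged iterations."""
        if not self.divergences:
            return []
        k = len(self.divergences[0])
        return [
            float(np.mean([reports[i].mu for reports in self.divergences]))
            for i in range(k)
        ]


# ---------------------------------------------------------------------------
# Layers (forward caches feed the matching backward)


class _Conv2D:
    def __init__(self, c_in: int, c_out: int, k: int, pad: int, rng: np.random.Generator):
        std = math.sqrt(2.0 / (c_in * k * k))
        self.W = rng.normal(0.0, std, size=(c_out, c_in, k, k))
        self.b = np.zeros(c_out)
        self.k, self.pad = k, pad
        self.dW = np.zeros_like(self.W)
        self.db = np.zeros_like(self.b)
        self._xp: np.ndarray | None = None

    def forward(self, x: np.ndarray) -> np.ndarray:
        p, k = self.pad, self.k
        xp = np.pad(x, ((0, 0), (0, 0), (p, p), (p, p))) if p else x
        self._xp = xp
        B, _, Hp, Wp = xp.shape
        Ho, Wo = Hp - k + 1, Wp - k + 1
        out = np.zeros((B, self.W.shape[0], Ho, Wo))
        for di in range(k):
            for dj in range(k):
                patch = xp[:, :, di : di + Ho, dj : dj + Wo]
                out += np.einsum("oc,bchw->bohw", self.W[:, :, di, dj], patch,
                                 optimize=True)
        return out + self.b[None, :, None, None]

    def backward(self, dy: np.ndarray) -> np.ndarray:
        xp = self._xp
        k, p = self.k, self.pad
        Ho, Wo = dy.shape[2], dy.shape[3]
        dxp = np.zeros_like(xp)
        for di in range(k):
            for dj in range(k):
                patch = xp[:, :, di : di + Ho, dj : dj + Wo]
                self.dW[:, :, di, dj] += np.einsum("bohw,bchw->oc", dy, patch,
                                                   optimize=True)
                dxp[:, :, di : di + Ho, dj : dj + Wo] += np.einsum(
                    "oc,bohw->bchw", self.W[:, :, di, dj], dy, optimize=True
                )
        self.db += dy.sum(axis=(0, 2, 3))
        return dxp[:, :, p:-p or None, p:-p or None] if p else dxp

    def params(self):
        return [(self, "W"), (self, "b")]


class _ReLU:
    def forward(self, x):
        self._mask = x > 0
        return x * self._mask

    def backward(self, dy):
        return dy * self._mask

    def params(self):
        return []


class _MaxPool2:
    def forward(self, x):
        B, C, H, W = x.shape
        r = x.reshape(B, C, H // 2, 2, W // 2, 2).transpose(0, 1, 2, 4, 3, 5)
        r = r.reshape(B, C, H // 2, W // 2, 4)
        self._idx = r.argmax(-1)
        self._shape = x.shape
        return np.take_along_axis(r, self._idx[..., None], axis=-1)[..., 0]

    def backward(self, dy):
        B, C, H, W = self._shape
        dr = np.zeros((B, C, H // 2, W // 2, 4))
        np.put_along_axis(dr, self._idx[..., None], dy[..., None], axis=-1)
        dr = dr.reshape(B, C, H // 2, W // 2, 2, 2).transpose(0, 1, 2, 4, 3, 5)
        return dr.reshape(B, C, H, W)

    def params(self):
        return []


class _GlobalAvgPool:
    def forward(self, x):
        self._hw = x.shape[2] * x.shape[3]
        self._shape = x.shape
        return x.mean(axis=(2, 3))

    def backward(self, dy):
        B, C, H, W = self._shape
        return np.broadcast_to(dy[:, :, None, None], (B, C, H, W)) / self._hw

    def params(self):
        return []


class _Linear:
    def __init__(self, d_in: int, d_out: int, rng: np.random.Generator):
        std = math.sqrt(2.0 / d_in)
        self.W = rng.normal(0.0, std, size=(d_in, d_out))
        self.b = np.zeros(d_out)
        self.dW = np.zeros_like(self.W)
        self.db = np.zeros_like(self.b)

    def forward(self, x):
        self._x = x
        return x @ self.W + self.b

    def backward(self, dy):
        self.dW += self._x.T @ dy
        self.db += dy.sum(axis=0)
        return dy @ self.W.T

    def params(self):
        return [(self, "W"), (self, "b")]


class _FeatureNorm:
    """Non-affine batch standardization of pooled feature vectors.

    Pins each feature's batch variance at 1, which removes the degenerate
    minimum of the MMD alignment loss where the extractor collapses every
    sample to one point (the role batch norm plays in full-size backbones).
    Evaluation mode uses running statistics, so single-sample prediction is
    well defined and deterministic.
    """

    def __init__(self, d: int, momentum: float = 0.9, eps: float = 1e-5):
        self.run_mean = np.zeros(d)
        self.run_var = np.ones(d)
        self.momentum = momentum
        self.eps = eps

    def forward(self, x: np.ndarray, training: bool) -> np.ndarray:
        if training:
            mu = x.mean(axis=0)
            var = x.var(axis=0)
            self.run_mean = self.momentum * self.run_mean + (1 - self.momentum) * mu
            self.run_var = self.momentum * self.run_var + (1 - self.momentum) * var
        else:
            mu, var = self.run_mean, self.run_var
        self._std = np.sqrt(var + self.eps)
        self._xhat = (x - mu) / self._std
        return self._xhat

    def backward(self, dy: np.ndarray) -> np.ndarray:
        xhat = self._xhat
        return (dy - dy.mean(axis=0) - xhat * (dy * xhat).mean(axis=0)) / self._std

    def params(self):
        return []


class _Sequential:
    def __init__(self, layers):
        self.layers = layers

    def forward(self, x):
        for l in self.layers:
            x = l.forward(x)
        return x

    def backward(self, dy):
        for l in reversed(self.layers):
            dy = l.backward(dy)
        return dy

    def params(self):
        return [p for l in self.layers for p in l.params()]


# ---------------------------------------------------------------------------
# Backbones


class TinyCNNBackbone:
    """Two conv(3×3)+ReLU+pool stages; exposes per-stage activations for taps."""

    def __init__(self, spec: BackboneSpec, rng: np.random.Generator):
        c_in = spec.input_shape[0]
        ch1, ch2 = spec.stage_channels
        self.conv1 = _Conv2D(c_in, ch1, 3, 1, rng)
        self.relu1 = _ReLU()
        self.pool1 = _MaxPool2()
        self.conv2 = _Conv2D(ch1, ch2, 3, 1, rng)
        self.relu2 = _ReLU()
        self.pool2 = _MaxPool2()
        self.out_channels = ch2
        self.tap_channels = (ch1, ch2)
        self.stage_acts: tuple[np.ndarray, np.ndarray] | None = None

    def forward(self, x: np.ndarray) -> np.ndarray:
        a1 = self.relu1.forward(self.conv1.forward(x))
        h = self.pool1.forward(a1)
        a2 = self.relu2.forward(self.conv2.forward(h))
        self.stage_acts = (a1, a2)
        return self.pool2.forward(a2)

    def backward(self, dy: np.ndarray) -> np.ndarray:
        dy = self.relu2.backward(self.pool2.backward(dy))
        dy = self.conv2.backward(dy)
        dy = self.relu1.backward(self.pool1.backward(dy))
        return self.conv1.backward(dy)

    def params(self):
        return self.conv1.params() + self.conv2.params()


_BACKBONE_BUILDERS = {"tiny_cnn": TinyCNNBackbone}


def register_backbone(kind: str, builder) -> None:
    """Register an external backbone builder ``builder(spec, rng) -> module``.

    The module must expose ``forward``/``backward``/``params``,
    ``out_channels``, ``tap_channels`` and ``stage_acts`` like
    :class:`TinyCNNBackbone`.  This is the hook through which a ResNet-50
    common extractor (with externally supplied pretrained weights) plugs in.
    """
    _BACKBONE_BUILDERS[kind] = builder


class _SpecificExtractor:
    """1×1 → 3×3 → 1×1 conv stack with ReLUs, global-average-pooled output."""

    def __init__(self, c_in: int, spec: SpecificExtractorSpec, rng: np.random.Generator):
        c1, c2, c3 = spec.out_channels
        self.net = _Sequential([
            _Conv2D(c_in, c1, 1, 0, rng), _ReLU(),
            _Conv2D(c1, c2, 3, 1, rng), _ReLU(),
            _Conv2D(c2, c3, 1, 0, rng), _ReLU(),
        ])
        self.gap = _GlobalAvgPool()
        self.norm = _FeatureNorm(c3)
        self.out_dim = c3

    def forward(self, x, training: bool = False):
        self._act = self.net.forward(x)  # final post-activation map (tap)
        return self.norm.forward(self.gap.forward(self._act), training)

    def backward(self, dfeat):
        return self.net.backward(self.gap.backward(self.norm.backward(dfeat)))

    def params(self):
        return self.net.params()


# ---------------------------------------------------------------------------
# Model


@dataclass
class MultiSourceModel:
    backbone_spec: BackboneSpec
    specific_spec: SpecificExtractorSpec
    n_sources: int
    common: object
    specifics: list
    predictors: list
    n_classes: int = 2
    seed: int = 0

    def parameter_count(self) -> dict[str, int]:
        def count(params):
            return int(sum(getattr(obj, name).size for obj, name in params))

        return {
            "common": count(self.common.params()),
            "specific": count([p for s in self.specifics for p in s.params()]),
            "predictors": count([p for c in self.predictors for p in c.params()]),
        }

    def common_params(self):
        return self.common.params()

    def specific_params(self):
        out = []
        for s in self.specifics:
            out += s.params()
        for c in self.predictors:
            out += c.params()
        return out

    def forward_streams(self, images: np.ndarray) -> list[np.ndarray]:
        """Pooled specific features of one image batch, one stream per pair
        (evaluation mode: feature standardization uses running statistics)."""
        fmap = self.common.forward(images)
        return [s.forward(fmap, training=False) for s in self.specifics]

    def predict(self, images: np.ndarray) -> EnsemblePrediction:
        streams = self.forward_streams(images)
        return ensemble_predict(streams, self.predictors)

    def feature_dim(self) -> int:
        """Deep-feature count: common tap channels + per-pair specific channels."""
        return sum(self.common.tap_channels) + self.n_sources * self.specifics[0].out_dim


def build_model(
    backbone: BackboneSpec,
    specific: SpecificExtractorSpec | None = None,
    n_sources: int = 3,
    n_classes: int = 2,
    seed: int = 0,
) -> MultiSourceModel:
    """Construct the multisource model: one common extractor, ``n_sources``
    specific extractors, ``n_sources`` softmax sub-predictors."""
    specific = specific or SpecificExtractorSpec()
    if n_sources < 1:
        raise ConfigurationError("n_sources must be >= 1")
    if backbone.kind not in _BACKBONE_BUILDERS:
        raise ConfigurationError(
            f"backbone kind {backbone.kind!r} has no registered builder "
            f"(available: {sorted(_BACKBONE_BUILDERS)}); tiny_cnn needs none"
        )
    if backbone.kind != "tiny_cnn" and backbone.pretrained:
        raise ConfigurationError(
            "pretrained weights must be supplied through the registered builder"
        )
    rng = np.random.default_rng(seed)
    common = _BACKBONE_BUILDERS[backbone.kind](backbone, rng)
    specifics = [_SpecificExtractor(common.out_channels, specific, rng)
                 for _ in range(n_sources)]
    predictors = [_Linear(specifics[i].out_dim, n_classes, rng)
                  for i in range(n_sources)]
    return MultiSourceModel(backbone, specific, n_sources, common, specifics,
                            predictors, n_classes, seed)


# ---------------------------------------------------------------------------
# Schedules, prediction, losses


def alpha_schedule(iter_progress: float, theta: float = 10.0,
                   mode: str = "clamped_exp_decay") -> float:
    """MMD-loss weight α as a function of normalized progress in [0, 1].

    ``clamped_exp_decay``: max(0, 2·exp(−θ·p) − 1) — starts at 1 and
    decays, clamped where the raw formula would turn negative (a negative
    weight would *reward* divergence).  ``progressive``: 2/(1+exp(−θ·p)) − 1,
    the standard ramp from 0 toward 1 that keeps the adaptation loss active
    throughout training.
    """
    if iter_progress < 0:
        raise InputError("iter_progress must be >= 0")
    if mode == "clamped_exp_decay":
        return min(1.0, max(0.0, 2.0 * math.exp(-theta * iter_progress) - 1.0))
    if mode == "progressive":
        return 2.0 / (1.0 + math.exp(-theta * iter_progress)) - 1.0
    raise ConfigurationError(f"unknown alpha mode {mode!r}")


def _softmax(z: np.ndarray) -> np.ndarray:
    z = z - z.max(axis=-1, keepdims=True)
    e = np.exp(z)
    return e / e.sum(axis=-1, keepdims=True)


def ensemble_predict(streams, predictors=None) -> EnsemblePrediction:
    """Average the sub-predictor softmax outputs.

    ``streams`` is one feature batch (or vector) per predictor.  With
    ``predictors=None`` the streams are taken to *be* probability vectors
    already (useful for combining external predictor outputs).
    """
    if predictors is None:
        probs = [np.asarray(s, dtype=float) for s in streams]
    else:
        if len(streams) != len(predictors):
            raise InputError(
                f"{len(streams)} streams but {len(predictors)} predictors"
            )
        probs = []
        for s, c in zip(streams, predictors):
            s = np.asarray(s, dtype=float)
            z = c.forward(s) if hasattr(c, "forward") else c(s)
            probs.append(_softmax(np.asarray(z, dtype=float)))
    if not probs:
        raise InputError("ensemble_predict needs at least one stream")
    shapes = {p.shape for p in probs}
    if len(shapes) != 1:
        raise InputError(f"predictor output shapes differ: {shapes}")
    for p in probs:
        if np.any(p < -1e-9) or np.any(np.abs(p.sum(axis=-1) - 1.0) > 1e-6):
            raise InputError("predictor outputs must be probability vectors")
    return EnsemblePrediction(per_predictor=probs,
                              averaged=np.mean(probs, axis=0))


def task_loss(prediction: EnsemblePrediction, label) -> float:
    """Cross-entropy of the ensemble-averaged prediction, mean over the batch.

    Zero probability at the true class is floored at 1e−12.
    """
    p = np.atleast_2d(prediction.averaged)
    y = np.atleast_1d(np.asarray(label, dtype=int))
    if y.shape[0] != p.shape[0]:
        raise InputError("label count does not match prediction batch")
    picked = p[np.arange(len(y)), y]
    return float(-np.log(np.maximum(picked, _PROB_FLOOR)).mean())


# ---------------------------------------------------------------------------
# MMD gradients (value conventions match divergence.mmd_squared)


def _mmd_grad(X: np.ndarray, Y: np.ndarray, sigma: float, scales) -> tuple[np.ndarray, np.ndarray]:
    """∂MMD²/∂X and ∂MMD²/∂Y for the biased V-statistic Gaussian-kernel MMD,
    σ treated as a constant."""
    n, m = X.shape[0], Y.shape[0]
    dX = np.zeros_like(X)
    dY = np.zeros_like(Y)
    sq_xx = cdist(X, X, "sqeuclidean")
    sq_yy = cdist(Y, Y, "sqeuclidean")
    sq_xy = cdist(X, Y, "sqeuclidean")
    for s in scales:
        s2 = (s * sigma) ** 2
        Kxx = np.exp(-sq_xx / (2 * s2))
        Kyy = np.exp(-sq_yy / (2 * s2))
        Kxy = np.exp(-sq_xy / (2 * s2))
        # Σ_j K[i,j] (x_i − x_j) = rowsum·x_i − K@X
        g_xx = Kxx.sum(1)[:, None] * X - Kxx @ X
        g_yy = Kyy.sum(1)[:, None] * Y - Kyy @ Y
        g_xy = Kxy.sum(1)[:, None] * X - Kxy @ Y
        g_yx = Kxy.sum(0)[:, None] * Y - Kxy.T @ X
        dX += -2.0 / (n * n * s2) * g_xx + 2.0 / (n * m * s2) * g_xy
        dY += -2.0 / (m * m * s2) * g_yy + 2.0 / (n * m * s2) * g_yx
    return dX / len(scales), dY / len(scales)


def _pair_divergence_grad(
    fs: np.ndarray, ys: np.ndarray, ft: np.ndarray, yt: np.ndarray,
    report: DivergenceReport, spec: KernelSpec,
) -> tuple[np.ndarray, np.ndarray]:
    """Gradient of the combined divergence w.r.t. the pair's pooled features,
    holding μ and the bandwidths fixed at their batch values."""
    mu = report.mu
    scales = spec.scales()
    sig_m = spec.resolve_sigma(fs, ft)
    dfs, dft = _mmd_grad(fs, ft, sig_m, scales)
    dfs *= (1.0 - mu)
    dft *= (1.0 - mu)
    for l in report.mmd_conditional_by_class:
        ms, mt = ys == l, yt == l
        Xs, Xt = fs[ms], ft[mt]
        sig_l = spec.resolve_sigma(Xs, Xt)
        gs, gt = _mmd_grad(Xs, Xt, sig_l, scales)
        dfs[ms] += mu * gs
        dft[mt] += mu * gt
    return dfs, dft


# ---------------------------------------------------------------------------
# Training


class _BalancedSampler:
    """Class-balanced with-replacement mini-batch sampler for one domain."""

    def __init__(self, labels: np.ndarray, classes: np.ndarray, domain_id: str):
        self.by_class = {}
        for l in classes:
            idx = np.flatnonzero(labels == l)
            if idx.size == 0:
                raise InputError(
                    f"domain {domain_id!r} lacks class-{l} samples required by "
                    "the class-balanced sampler"
                )
            self.by_class[int(l)] = idx

    def draw(self, batch_size: int, rng: np.random.Generator) -> np.ndarray:
        per = batch_size // len(self.by_class)
        parts = [rng.choice(idx, size=per, replace=True)
                 for l, idx in sorted(self.by_class.items())]
        return np.concatenate(parts)


def _sgd_step(params, lr, cfg: TrainingConfig, velocities: dict) -> None:
    for obj, name in params:
        w = getattr(obj, name)
        g = getattr(obj, "d" + name)
        key = (id(obj), name)
        v = velocities.get(key)
        if v is None:
            v = np.zeros_like(w)
        g = g + cfg.weight_decay * w
        v = cfg.momentum * v + g
        w -= lr * v
        velocities[key] = v
        getattr(obj, "d" + name).fill(0.0)


def train(
    model: MultiSourceModel,
    sources: list[LabeledImageSet],
    target: LabeledImageSet,
    cfg: TrainingConfig,
    spec: KernelSpec | None = None,
) -> TrainingHistory:
    """Train the multisource model by minimizing α·l_MMD + l_task.

    Each iteration draws one class-balanced batch per domain, runs all
    domains through the common extractor, pairs each source stream with the
    target through its specific extractor, measures the per-pair divergence,
    takes the ensemble cross-entropy on the target batch, and applies one
    SGD-with-momentum step with separate learning rates for the common and
    the specific/predictor parameter groups.  Fully reproducible from
    ``cfg.seed``.
    """
    spec = spec or KernelSpec()
    if len(sources) != model.n_sources:
        raise InputError(
            f"model built for {model.n_sources} sources, got {len(sources)}"
        )
    classes = np.arange(model.n_classes)
    samplers = [_BalancedSampler(s.labels, classes, s.domain_id) for s in sources]
    t_sampler = _BalancedSampler(target.labels, classes, target.domain_id)
    rng = np.random.default_rng(cfg.seed)
    velocities: dict = {}
    history = TrainingHistory()
    k = model.n_sources
    used_preds = range(k) if cfg.ensemble else [0]

    for it in range(cfg.iterations):
        progress = it / cfg.iterations
        alpha = (cfg.alpha_override if cfg.alpha_override is not None
                 else alpha_schedule(progress, cfg.theta, cfg.alpha_mode))

        s_idx = [smp.draw(cfg.batch_size, rng) for smp in samplers]
        t_idx = t_sampler.draw(cfg.batch_size, rng)
        s_imgs = [src.images[idx] for src, idx in zip(sources, s_idx)]
        s_lbls = [src.labels[idx] for src, idx in zip(sources, s_idx)]
        t_imgs = target.images[t_idx]
        t_lbls = target.labels[t_idx]
        bs = [img.shape[0] for img in s_imgs]
        bt = t_imgs.shape[0]

        # --- forward: common extractor on all domains in one batch
        big = np.concatenate(s_imgs + [t_imgs], axis=0)
        fmap = model.common.forward(big)
        splits = np.cumsum(bs)[:-1].tolist() + [sum(bs)]
        maps = np.split(fmap, splits, axis=0)
        s_maps, t_map = maps[:k], maps[k]

        # --- forward: pair streams through specific extractors
        feats = []  # (f_source_i, f_target_i) pooled features per pair
        for i in range(k):
            both = model.specifics[i].forward(
                np.concatenate([s_maps[i], t_map], axis=0), training=True
            )
            feats.append((both[: bs[i]], both[bs[i]:]))

        # --- task loss (ensemble cross-entropy on the target batch)
        zs = [model.predictors[j].forward(feats[j][1]) for j in used_preds]
        probs = [_softmax(z) for z in zs]
        y_hat = np.mean(probs, axis=0)
        picked = np.maximum(y_hat[np.arange(bt), t_lbls], _PROB_FLOOR)
        l_task = float(-np.log(picked).mean())

        # --- divergence per pair (μ, σ fixed at batch values)
        yt_cond = (y_hat.argmax(axis=1) if cfg.pseudo_labels else t_lbls)
        reports = []
        for i in range(k):
            src_fs = LabeledFeatureSet(feats[i][0], s_lbls[i],
                                       domain_id=sources[i].domain_id)
            tgt_fs = LabeledFeatureSet(feats[i][1], yt_cond,
                                       domain_id=target.domain_id)
            reports.append(pair_divergence(src_fs, tgt_fs, spec))
        l_mmd = multisource_mmd_loss(reports)
        l_total = alpha * l_mmd + l_task

        # --- backward: task loss -> predictor + target-stream gradients
        dy_hat = np.zeros_like(y_hat)
        dy_hat[np.arange(bt), t_lbls] = -1.0 / (picked * bt)
        d_t_feats = [np.zeros_like(feats[i][1]) for i in range(k)]
        n_used = len(list(used_preds))
        for j, p in zip(used_preds, probs):
            inner = (p * dy_hat).sum(axis=1, keepdims=True)
            dz = (p * dy_hat - p * inner) / n_used
            d_t_feats[j] += model.predictors[j].backward(dz)

        # --- backward: MMD loss -> pair feature gradients
        d_s_feats = [np.zeros_like(feats[i][0]) for i in range(k)]
        if alpha != 0.0:
            for i in range(k):
                gs, gt = _pair_divergence_grad(
                    feats[i][0], s_lbls[i], feats[i][1], yt_cond,
                    reports[i], spec,
                )
                d_s_feats[i] += alpha / k * gs
                d_t_feats[i] += alpha / k * gt

        # --- backward through specific extractors and the common extractor
        d_fmap = np.zeros_like(fmap)
        offsets = np.concatenate([[0], np.cumsum(bs)])
        for i in range(k):
            dboth = np.concatenate([d_s_feats[i], d_t_feats[i]], axis=0)
            dmaps = model.specifics[i].backward(dboth)
            d_fmap[offsets[i]: offsets[i + 1]] += dmaps[: bs[i]]
            d_fmap[offsets[k]:] += dmaps[bs[i]:]
        model.common.backward(d_fmap)

        _sgd_step(model.common_params(), cfg.lr_common, cfg, velocities)
        _sgd_step(model.specific_params(), cfg.lr_specific, cfg, velocities)

        history.losses.append(LossBreakdown(l_mmd, l_task, alpha, l_total))
        history.divergences.append(reports)

    _recalibrate_feature_stats(model, sources, target, samplers, t_sampler,
                               cfg, rng)
    return history


def _recalibrate_feature_stats(model, sources, target, samplers, t_sampler,
                               cfg, rng, n_passes: int = 20) -> None:
    """Recompute the feature-standardization statistics with the final
    weights.

    The training loss is invariant to the scale of the pooled features, so
    the activation magnitude drifts over training and the momentum-tracked
    running statistics lag behind it, skewing evaluation-mode
    normalization.  A few statistics-only passes over freshly drawn joint
    (source+target) batches — the same batch composition the normalization
    saw during training — replace the lagged estimates.
    """
    k = model.n_sources
    n_passes = min(n_passes, cfg.iterations)
    mu_acc = [0.0] * k
    var_acc = [0.0] * k
    for _ in range(n_passes):
        s_idx = [smp.draw(cfg.batch_size, rng) for smp in samplers]
        t_idx = t_sampler.draw(cfg.batch_size, rng)
        s_imgs = [src.images[idx] for src, idx in zip(sources, s_idx)]
        t_imgs = target.images[t_idx]
        bs = [img.shape[0] for img in s_imgs]
        big = np.concatenate(s_imgs + [t_imgs], axis=0)
        fmap = model.common.forward(big)
        splits = np.cumsum(bs)[:-1].tolist() + [sum(bs)]
        maps = np.split(fmap, splits, axis=0)
        for i in range(k):
            act = model.specifics[i].net.forward(
                np.concatenate([maps[i], maps[k]], axis=0)
            )
            pooled = act.mean(axis=(2, 3))
            mu_acc[i] = mu_acc[i] + pooled.mean(axis=0)
            var_acc[i] = var_acc[i] + pooled.var(axis=0)
    for i in range(k):
        model.specifics[i].norm.run_mean = mu_acc[i] / n_passes
        model.specifics[i].norm.run_var = var_acc[i] / n_passes


# ---------------------------------------------------------------------------
# Deep-feature export


def extract_deep_features(
    model: MultiSourceModel, images: LabeledImageSet, batch_size: int = 64
) -> LabeledFeatureSet:
    """Globally average-pooled channel activations as a feature table.

    Taps: each common-extractor stage's post-activation map plus each
    specific extractor's final post-activation map, all global-average
    pooled.  Feature count = Σ common stage channels +
    n_sources × specific output channels; names encode the layer of origin
    (``common1_c0`` ... ``spec2_c7``).
    """
    rows = []
    for start in range(0, images.n_samples, batch_size):
        batch = images.images[start : start + batch_size]
        pooled = model.common.forward(batch)
        a1, a2 = model.common.stage_acts
        parts = [a1.mean(axis=(2, 3)), a2.mean(axis=(2, 3))]
        for s in model.specifics:
            s.forward(pooled)
            parts.append(s._act.mean(axis=(2, 3)))
        rows.append(np.concatenate(parts, axis=1))
    X = np.concatenate(rows, axis=0)
    ch1, ch2 = model.common.tap_channels
    names = [f"common1_c{i}" for i in range(ch1)]
    names += [f"common2_c{i}" for i in range(ch2)]
    for j, s in enumerate(model.specifics):
        names += [f"spec{j}_c{i}" for i in range(s.out_dim)]
    return LabeledFeatureSet(X, images.labels, domain_id=images.domain_id,
                             feature_names=names)
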