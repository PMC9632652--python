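"""Distribution-divergence measures between a source and a target domain.

The alignment loss used by the transfer network combines three ingredients:

* the squared maximum mean discrepancy (MMD) between the two whole-domain
  feature distributions (marginal term),
* per-class squared MMDs between class-conditional distributions
  (conditional terms), and
* an adaptation factor μ ∈ [0, 1], computed from empirical Wasserstein-1
  distances, that weighs the conditional against the marginal term:

      M = (1 − μ)·M_marginal + μ·Σ_l M_conditional(l),
      μ = Σ_l W_l / (W_g + Σ_l W_l),

  where W_g is the global (pooled) Wasserstein distance and W_l the
  class-l Wasserstein distance.  μ → 0 flags a dominant global shift
  (marginal adaptation matters most); μ → 1 flags dominant class-structure
  shift; μ = 0.5 weighs both equally.

The class-conditional Wasserstein weights are computed on *per-domain
mean-centered* class samples.  For balanced class mixtures the raw class
distances satisfy W_g ≤ (W_0 + W_1)/2, which would pin μ ≥ 2/3 even under a
pure global translation; centering removes the shared translation so that
W_l responds to class-structure discrepancy only, giving μ the intended
direction (translation-only shift → μ near 0, class-conditional shift with
matched pooled marginals → μ near 1).

MMD uses the biased V-statistic with a Gaussian kernel

    k(x, y) = exp(−||x − y||² / 2σ²),

σ resolved by the median pairwise-distance heuristic unless fixed.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy.optimize import linear_sum_assignment, linprog
from scipy.spatial.distance import cdist

from .data import LabeledFeatureSet
from .errors import ConfigurationError, DegenerateInputError, InputError

__all__ = [
    "KernelSpec",
    "DivergenceReport",
    "gaussian_kernel",
    "median_bandwidth",
    "mmd_squared",
    "conditional_mmd",
    "wasserstein_distance",
    "class_wasserstein_weights",
    "adaptation_factor",
    "pair_divergence",
    "multisource_mmd_loss",
]

logger = logging.getLogger(__name__)

#: samples per side above which the exact transport LP is refused
WASSERSTEIN_MAX_SAMPLES = 512

#: bandwidth multipliers used when n_kernels > 1 (mixture of Gaussians)
_MULTI_KERNEL_SCALES = (0.25, 0.5, 1.0, 2.0, 4.0)


@dataclass
class KernelSpec:
    """Gaussian-kernel configuration.

    bandwidth : positive float or the string ``"median"``
        ``"median"`` resolves σ to the median pairwise Euclidean distance
        over the concatenated source+target sample, per call.
    n_kernels : int
        1 uses a single Gaussian; >1 averages Gaussians at
        σ·{2⁻², 2⁻¹, 1, 2, 2²} (first five scales).
    """

    bandwidth: float | str = "median"
    n_kernels: int = 1

    def __post_init__(self) -> None:
        if isinstance(self.bandwidth, str):
            if self.bandwidth != "median":
                raise ConfigurationError(
                    f"bandwidth must be a positive number or 'median', "
                    f"got {self.bandwidth!r}"
                )
        elif self.bandwidth <= 0:
            raise ConfigurationError(f"bandwidth must be > 0, got {self.bandwidth}")
        if self.n_kernels < 1:
            raise ConfigurationError("n_kernels must be >= 1")

    def resolve_sigma(self, X: np.ndarray, Y: np.ndarray) -> float:
        """Concrete σ for one source/target pair."""
        if self.bandwidth == "median":
            return median_bandwidth(X, Y)
        return float(self.bandwidth)

    def scales(self) -> tuple[float, ...]:
        if self.n_kernels == 1:
            return (1.0,)
        return _MULTI_KERNEL_SCALES[: self.n_kernels]


@dataclass
class DivergenceReport:
    """All divergence quantities for one source–target pair."""

    mmd_marginal: float
    mmd_conditional_by_class: dict[int, float]
    w_global: float
    w_by_class: dict[int, float]
    mu: float
    combined: float
    source_id: str = ""
    target_id: str = ""
    sigma: float = field(default=float("nan"))

    def to_dict(self) -> dict:
        return {
            "source_id": self.source_id,
            "target_id": self.target_id,
            "mmd_marginal": self.mmd_marginal,
            "mmd_conditional_by_class": {
                str(k): v for k, v in self.mmd_conditional_by_class.items()
            },
            "w_global": self.w_global,
            "w_by_class": {str(k): v for k, v in self.w_by_class.items()},
            "mu": self.mu,
            "combined": self.combined,
            "sigma": self.sigma,
        }


# ---------------------------------------------------------------------------
# Kernel and MMD


def median_bandwidth(X: np.ndarray, Y: np.ndarray) -> float:
    """Median pairwise Euclidean distance over the pooled sample.

    The standard two-sample bandwidth heuristic.  Falls back to 1.0 when the
    median is zero (all points coincide), where any σ gives MMD 0 anyway.
    """
    Z = np.vstack([np.atleast_2d(X), np.atleast_2d(Y)])
    d = cdist(Z, Z)
    iu = np.triu_indices(len(Z), k=1)
    med = float(np.median(d[iu])) if iu[0].size else 0.0
    return med if med > 0 else 1.0


def gaussian_kernel(x: np.ndarray, y: np.ndarray, spec: KernelSpec) -> float:
    """k(x, y) = exp(−||x − y||² / 2σ²) for two single feature vectors.

    With ``n_kernels > 1`` the average over the bandwidth ladder is returned.
    The ``"median"`` sentinel is not resolvable from two points; pass a
    numeric bandwidth here.
    """
    x = np.asarray(x, dtype=float).ravel()
    y = np.asarray(y, dtype=float).ravel()
    if x.shape != y.shape:
        raise InputError(f"dimension mismatch: {x.shape} vs {y.shape}")
    if spec.bandwidth == "median":
        raise ConfigurationError(
            "median bandwidth cannot be resolved from a single pair; "
            "pass a numeric bandwidth"
        )
    sq = float(np.sum((x - y) ** 2))
    sigma = float(spec.bandwidth)
    vals = [np.exp(-sq / (2.0 * (s * sigma) ** 2)) for s in spec.scales()]
    return float(np.mean(vals))


def _kernel_sums(X: np.ndarray, Y: np.ndarray, sigma: float, scales) -> float:
    """Biased V-statistic MMD² from the three kernel-matrix block means."""
    sq_xx = cdist(X, X, "sqeuclidean")
    sq_yy = cdist(Y, Y, "sqeuclidean")
    sq_xy = cdist(X, Y, "sqeuclidean")
    total = 0.0
    for s in scales:
        g = 2.0 * (s * sigma) ** 2
        total += (
            np.exp(-sq_xx / g).mean()
            - 2.0 * np.exp(-sq_xy / g).mean()
            + np.exp(-sq_yy / g).mean()
        )
    return total / len(scales)


def _as_matrix(obj) -> np.ndarray:
    if isinstance(obj, LabeledFeatureSet):
        return obj.features
    return np.atleast_2d(np.asarray(obj, dtype=float))


def mmd_squared(
    source: LabeledFeatureSet | np.ndarray,
    target: LabeledFeatureSet | np.ndarray,
    spec: KernelSpec | None = None,
) -> float:
    """Squared MMD between two empirical distributions (biased V-statistic).

    Expanded kernel form::

        (1/n²)ΣΣ k(s,s) − (2/nm)ΣΣ k(s,t) + (1/m²)ΣΣ k(t,t)

    (the cross term carries factor 2, as the expansion of the squared RKHS
    norm of the mean-embedding difference requires).  Nonnegative up to
    rounding; clipped at 0.
    """
    spec = spec or KernelSpec()
    X = _as_matrix(source)
    Y = _as_matrix(target)
    if X.shape[0] == 0 or Y.shape[0] == 0:
        raise InputError("mmd_squared requires nonempty sample sets")
    if X.shape[1] != Y.shape[1]:
        raise InputError(
            f"feature dimension mismatch: {X.shape[1]} vs {Y.shape[1]}"
        )
    sigma = spec.resolve_sigma(X, Y)
    return max(0.0, float(_kernel_sums(X, Y, sigma, spec.scales())))


def conditional_mmd(
    source: LabeledFeatureSet,
    target: LabeledFeatureSet,
    spec: KernelSpec | None = None,
) -> dict[int, float]:
    """Per-class squared MMD between class-conditional samples.

    Only classes present in *both* sets appear in the result; a class missing
    from either side is dropped with a warning.  Raises when the sets share
    no class at all.
    """
    spec = spec or KernelSpec()
    if source.labels is None or target.labels is None:
        raise InputError("conditional_mmd requires labels on both sets")
    shared = sorted(set(source.classes) & set(target.classes))
    skipped = sorted(
        (set(source.classes) | set(target.classes)) - set(shared)
    )
    if not shared:
        raise DegenerateInputError(
            f"domains {source.domain_id!r} and {target.domain_id!r} share no class"
        )
    if skipped:
        warnings.warn(
            f"classes {skipped} missing from one side of pair "
            f"({source.domain_id!r}, {target.domain_id!r}); dropped from "
            "conditional terms",
            stacklevel=2,
        )
    return {
        int(l): mmd_squared(source.class_subset(l), target.class_subset(l), spec)
        for l in shared
    }


# ---------------------------------------------------------------------------
# Wasserstein distance and the adaptation factor


def _exact_w1(X: np.ndarray, Y: np.ndarray) -> float:
    """Exact Wasserstein-1 between uniform empirical measures (Euclidean cost)."""
    n, m = X.shape[0], Y.shape[0]
    cost = cdist(X, Y)
    if n == m:
        # uniform equal-size OT reduces to an assignment problem
        r, c = linear_sum_assignment(cost)
        return float(cost[r, c].mean())
    # general case: transport LP with marginals 1/n, 1/m
    c = cost.ravel()
    A_eq = []
    b_eq = []
    for i in range(n):
        row = np.zeros(n * m)
        row[i * m : (i + 1) * m] = 1.0
        A_eq.append(row)
        b_eq.append(1.0 / n)
    for j in range(m - 1):  # drop one redundant constraint
        row = np.zeros(n * m)
        row[j::m] = 1.0
        A_eq.append(row)
        b_eq.append(1.0 / m)
    res = linprog(c, A_eq=np.array(A_eq), b_eq=np.array(b_eq), bounds=(0, None),
                  method="highs")
    if not res.success:  # pragma: no cover - HiGHS is reliable on feasible LPs
        raise RuntimeError(f"transport LP failed: {res.message}")
    return float(res.fun)


def wasserstein_distance(
    a: LabeledFeatureSet | np.ndarray, b: LabeledFeatureSet | np.ndarray
) -> float:
    """Exact empirical Wasserstein-1 distance with Euclidean ground cost.

    Solved as a linear transport problem between the uniform empirical
    measures (assignment problem when the sets have equal size).  Refuses
    more than 512 samples per side; subsample larger sets first.
    """
    X = _as_matrix(a)
    Y = _as_matrix(b)
    if X.shape[0] == 0 or Y.shape[0] == 0:
        raise InputError("wasserstein_distance requires nonempty sets")
    if X.shape[1] != Y.shape[1]:
        raise InputError(
            f"feature dimension mismatch: {X.shape[1]} vs {Y.shape[1]}"
        )
    if max(X.shape[0], Y.shape[0]) > WASSERSTEIN_MAX_SAMPLES:
        raise InputError(
            f"exact transport limited to {WASSERSTEIN_MAX_SAMPLES} samples "
            "per side; subsample larger sets"
        )
    return _exact_w1(X, Y)


def class_wasserstein_weights(
    source: LabeledFeatureSet,
    target: LabeledFeatureSet,
    classes: list[int] | None = None,
    center: bool = True,
) -> dict[int, float]:
    """Class-conditional Wasserstein weights W_l.

    By default each domain is centered on its own pooled mean first, so the
    weights respond to class-structure discrepancy rather than to a global
    translation shared by every class (see module docstring).
    """
    if source.labels is None or target.labels is None:
        raise InputError("class weights require labels on both sets")
    if classes is None:
        classes = sorted(set(source.classes) & set(target.classes))
    Xs, Xt = source.features, target.features
    if center:
        Xs = Xs - Xs.mean(axis=0, keepdims=True)
        Xt = Xt - Xt.mean(axis=0, keepdims=True)
    out: dict[int, float] = {}
    for l in classes:
        out[int(l)] = _exact_w1(Xs[source.labels == l], Xt[target.labels == l])
    return out


def adaptation_factor(
    w_global: float, w_by_class: dict[int, float] | list[float]
) -> float:
    """Adaptation factor μ = Σ_l W_l / (W_g + Σ_l W_l), in [0, 1].

    When both W_g and all W_l are zero the domains are (empirically)
    identical and every μ yields zero combined divergence; the defined
    fallback μ = 0.5 is returned with a warning.
    """
    if isinstance(w_by_class, dict):
        w_vals = list(w_by_class.values())
    else:
        w_vals = list(w_by_class)
    if w_global < 0 or any(w < 0 for w in w_vals):
        raise InputError("Wasserstein weights must be nonnegative")
    s = float(sum(w_vals))
    denom = float(w_global) + s
    if denom == 0.0:
        warnings.warn(
            "all Wasserstein weights are zero (identical domains); "
            "falling back to mu = 0.5",
            stacklevel=2,
        )
        return 0.5
    return s / denom


def pair_divergence(
    source: LabeledFeatureSet,
    target: LabeledFeatureSet,
    spec: KernelSpec | None = None,
) -> DivergenceReport:
    """Full divergence report for one source–target pair.

    combined = (1 − μ)·M_marginal + μ·Σ_l M_conditional(l), with μ from
    :func:`adaptation_factor` on the Wasserstein weights.  The same shared
    class set is used for the conditional MMD terms and for the W_l weights.
    """
    spec = spec or KernelSpec()
    m_marg = mmd_squared(source, target, spec)
    m_cond = conditional_mmd(source, target, spec)
    classes = sorted(m_cond)
    w_g = wasserstein_distance(source, target)
    w_l = class_wasserstein_weights(source, target, classes=classes)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")  # identical-domain fallback is expected here
        mu = adaptation_factor(w_g, w_l)
    if w_g == 0.0 and sum(w_l.values()) == 0.0:
        logger.info(
            "pair (%s, %s): zero Wasserstein weights, mu fallback 0.5",
            source.domain_id, target.domain_id,
        )
    combined = (1.0 - mu) * m_marg + mu * sum(m_cond.values())
    sigma = spec.resolve_sigma(source.features, target.features)
    return DivergenceReport(
        mmd_marginal=m_marg,
        mmd_conditional_by_class=m_cond,
        w_global=w_g,
        w_by_class=w_l,
        mu=mu,
        combined=combined,
        source_id=source.domain_id,
        target_id=target.domain_id,
        sigma=sigma,
    )


def multisource_mmd_loss(pairs: list[DivergenceReport]) -> float:
    """Arithmetic mean of the combined divergences over source–target pairs."""
    if not pairs:
        raise InputError("multisource_mmd_loss requires at least one pair")
    return float(np.mean([p.combined for p in pairs]))
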