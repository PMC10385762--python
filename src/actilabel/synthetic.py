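"""Synthetic paired source/target domains with planted activity structure.

Real cross-domain benchmarks (multi-sensor activity datasets) are large
external downloads; this module generates matched pairs of feature-space
domains that preserve the property the transfer method relies on: the
*structural relationships* between activity classes (their relative sizes
and inter-class affinities) survive a change of observation map, while the
raw feature coordinates do not.

The generative model: m class archetypes are drawn once in a shared latent
space and rescaled so the mean inter-archetype distance is ``separation``
times the mean within-class RMS deviation.  Each class has its own latent
covariance — full variance in an *intrinsic subspace* whose dimension grows
log-spaced from 1 to d_latent across classes, a small variance floor
elsewhere — mirroring how static postures occupy few effective degrees of
freedom in feature space while dynamic locomotion fills many.  The
intrinsic subspaces, like the archetypes, are properties of the activities
and are shared between domains.  Each domain then observes ``archetype +
latent noise`` through its own map (identity / rotation / random linear /
channel drop) at its own scale, plus isotropic observation noise.
Distance-preserving maps leave the inter-class geometry and the per-class
density signature intact, which is what makes structural label transfer
possible without any shared feature space.

Class proportions default to a moderately imbalanced profile, mirroring
real activity datasets where locomotion dominates; imbalance matters here
because cluster sizes feed the dependency-graph weights.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, replace

import numpy as np
from scipy.spatial.distance import pdist

from .features import FeatureMatrix, SensorRecording

__all__ = [
    "DomainSpec",
    "default_imbalance",
    "class_counts",
    "generate_pair",
    "generate_timeseries",
    "scenario",
    "SCENARIOS",
]

logger = logging.getLogger(__name__)

ACTIVITY_NAMES = (
    "walk", "run", "sit", "stand", "lie", "stairs_up", "stairs_down",
    "cycle", "row", "jump",
)

TRANSFORMS = ("identity", "rotation", "random-linear", "channel-drop", "rotation-drop")


@dataclass(frozen=True)
class DomainSpec:
    """Configuration of one synthetic domain.

    ``separation`` is the ratio of the mean inter-class centroid distance
    to the within-class latent spread; ``noise_sd`` is observation noise
    added after the transform; ``imbalance`` are class proportions (None
    selects the default imbalanced profile); ``scale`` multiplies the
    observed features (cosine-invariant, exercises amplitude shifts).
    """

    m: int = 5
    n: int = 1000
    d_latent: int = 8
    d_obs: int = 8
    separation: float = 4.0
    noise_sd: float = 0.3
    imbalance: tuple[float, ...] | None = None
    transform: str = "identity"
    seed: int = 0
    scale: float = 1.0
    allocation: str = "deterministic"  # or "multinomial"
    intrinsic_dims: tuple[int, ...] | None = None  # None: log-spaced 1..d_latent
    variance_floor: float = 0.25

    def __post_init__(self) -> None:
        if self.m < 2:
            raise ValueError("need at least 2 classes")
        if self.separation <= 0:
            raise ValueError("separation must be > 0")
        if self.transform not in TRANSFORMS:
            raise ValueError(f"unknown transform {self.transform!r}")
        if self.imbalance is not None:
            if len(self.imbalance) != self.m:
                raise ValueError("imbalance length must equal m")
            if abs(sum(self.imbalance) - 1.0) > 1e-9:
                raise ValueError("imbalance proportions must sum to 1")

    @property
    def proportions(self) -> tuple[float, ...]:
        return self.imbalance if self.imbalance is not None else default_imbalance(self.m)

    @property
    def class_names(self) -> list[str]:
        base = list(ACTIVITY_NAMES)
        if self.m > len(base):
            base += [f"activity_{i}" for i in range(len(base), self.m)]
        return base[: self.m]


def default_imbalance(m: int, ratio: float = 0.75) -> tuple[float, ...]:
    """Geometrically decaying class proportions (most prevalent first)."""
    w = ratio ** np.arange(m)
    return tuple((w / w.sum()).tolist())


def class_counts(spec: DomainSpec, rng: np.random.Generator | None = None) -> np.ndarray:
    """Observation count per class.

    Deterministic rule (default): ``round(p_i * n)`` with the rounding
    remainder absorbed by the largest class.  ``allocation="multinomial"``
    samples counts instead (needs ``rng``).
    """
    p = np.asarray(spec.proportions)
    if spec.allocation == "multinomial":
        if rng is None:
            raise ValueError("multinomial allocation needs an rng")
        return rng.multinomial(spec.n, p)
    counts = np.round(p * spec.n).astype(int)
    counts[np.argmax(p)] += spec.n - counts.sum()
    if np.any(counts < 1):
        raise ValueError("a class received no observations; adjust n or imbalance")
    return counts


def _intrinsic_dims(spec: DomainSpec) -> np.ndarray:
    if spec.intrinsic_dims is not None:
        if len(spec.intrinsic_dims) != spec.m:
            raise ValueError("intrinsic_dims length must equal m")
        return np.asarray(spec.intrinsic_dims, dtype=int)
    dims = np.exp(np.linspace(np.log(1), np.log(spec.d_latent), spec.m))
    return np.round(dims).astype(int)


def _draw_structure(
    spec: DomainSpec, rng: np.random.Generator
) -> tuple[np.ndarray, list[np.ndarray]]:
    """Shared latent structure: archetypes and per-class covariance factors.

    Class c's latent deviation is ``B_c @ eps`` with unit variance in an
    r_c-dimensional random subspace and ``variance_floor`` elsewhere.
    Archetypes are rescaled so the mean inter-archetype distance equals
    ``separation`` times the mean within-class RMS deviation.
    """
    m, d = spec.m, spec.d_latent
    dims = _intrinsic_dims(spec)
    factors = []
    for c in range(m):
        Q, _ = np.linalg.qr(rng.standard_normal((d, d)))
        scales = np.full(d, spec.variance_floor)
        scales[: dims[c]] = 1.0
        factors.append(Q * scales[None, :])
    rms = np.sqrt(dims + (d - dims) * spec.variance_floor**2)
    A = rng.standard_normal((m, d))
    A -= A.mean(axis=0)
    target = spec.separation * float(rms.mean())
    A *= target / float(pdist(A).mean())
    return A, factors


def _transform_matrix(spec: DomainSpec, rng: np.random.Generator) -> np.ndarray:
    d, o = spec.d_latent, spec.d_obs
    if spec.transform == "identity":
        if o != d:
            raise ValueError("identity transform requires d_obs == d_latent")
        T = np.eye(d)
    elif spec.transform == "rotation":
        if o != d:
            raise ValueError("rotation requires d_obs == d_latent")
        Q, R = np.linalg.qr(rng.standard_normal((d, d)))
        T = Q * np.sign(np.diag(R))
    elif spec.transform == "random-linear":
        T = rng.standard_normal((o, d)) / np.sqrt(d)
    elif spec.transform == "channel-drop":
        if o >= d:
            raise ValueError("channel-drop requires d_obs < d_latent")
        keep = np.sort(rng.choice(d, size=o, replace=False))
        T = np.eye(d)[keep]
    else:  # rotation-drop
        if o > d:
            raise ValueError("rotation-drop requires d_obs <= d_latent")
        Q, R = np.linalg.qr(rng.standard_normal((d, d)))
        T = (Q * np.sign(np.diag(R)))[:o]
    if np.linalg.matrix_rank(T) < min(d, o):
        warnings.warn("degenerate observation map: rank below min(d_latent, d_obs)")
    return T


def _sample_domain(
    spec: DomainSpec,
    archetypes: np.ndarray,
    factors: list[np.ndarray],
    shared_seed: int,
) -> FeatureMatrix:
    rng = np.random.default_rng([shared_seed & 0x7FFFFFFF, spec.seed & 0x7FFFFFFF])
    counts = class_counts(spec, rng)
    names = spec.class_names
    labels = np.concatenate([np.repeat(names[c], counts[c]) for c in range(spec.m)])
    class_ids = np.concatenate([np.repeat(c, counts[c]) for c in range(spec.m)])
    latent = np.repeat(archetypes, counts, axis=0)
    eps = rng.standard_normal((spec.n, spec.d_latent))
    for c in range(spec.m):
        mask = class_ids == c
        latent[mask] += eps[mask] @ factors[c].T
    order = rng.permutation(spec.n)
    labels = labels[order]
    latent = latent[order]
    T = _transform_matrix(spec, rng)
    X = latent @ T.T * spec.scale
    X += spec.noise_sd * rng.standard_normal(X.shape)
    return FeatureMatrix(
        X=X,
        feature_names=[f"f{i}" for i in range(spec.d_obs)],
        labels=labels,
    )


def generate_pair(
    spec_source: DomainSpec, spec_target: DomainSpec, shared_seed: int = 0
) -> tuple[FeatureMatrix, FeatureMatrix]:
    """Paired source and target domains over shared class archetypes.

    Both returned matrices carry labels; the target's labels are the hidden
    ground truth, intended for evaluation only (the pipeline never sees
    them).
    """
    if spec_source.m != spec_target.m:
        raise ValueError("domains must share the class count m")
    if spec_source.d_latent != spec_target.d_latent:
        raise ValueError("domains must share the latent dimension")
    rng_shared = np.random.default_rng(shared_seed & 0x7FFFFFFF)
    A, factors = _draw_structure(spec_source, rng_shared)
    # the target reuses the source archetypes and class covariances; its
    # own separation field is ignored by construction (latent structure is
    # shared, the observation map is not)
    src = _sample_domain(spec_source, A, factors, shared_seed)
    tgt = _sample_domain(spec_target, A, factors, shared_seed + 1)
    return src, tgt


def generate_timeseries(
    spec: DomainSpec,
    sampling_rate: float = 50.0,
    seconds_per_bout: float = 20.0,
    n_channels: int = 3,
) -> SensorRecording:
    """Concatenated labelled activity bouts as raw multichannel signals.

    Each class is a per-channel sinusoid signature (class-specific
    amplitude, frequency and phase) plus a slow drift and observation
    noise, enough to exercise windowing and feature extraction end to end.
    """
    if sampling_rate < 10:
        raise ValueError("sampling_rate must be >= 10 Hz")
    rng = np.random.default_rng(spec.seed & 0x7FFFFFFF)
    per_bout = int(round(seconds_per_bout * sampling_rate))
    t = np.arange(per_bout) / sampling_rate
    names = spec.class_names
    amp = 0.5 + 1.5 * rng.random((spec.m, n_channels))
    freq = 0.4 + 2.6 * rng.random((spec.m, n_channels))
    phase = 2 * np.pi * rng.random((spec.m, n_channels))
    drift = 0.05 * rng.standard_normal((spec.m, n_channels))
    chans = {f"ch{j}": [] for j in range(n_channels)}
    labels = []
    for c in range(spec.m):
        for j in range(n_channels):
            sig = (
                amp[c, j] * np.sin(2 * np.pi * freq[c, j] * t + phase[c, j])
                + drift[c, j] * t
                + spec.noise_sd * rng.standard_normal(per_bout)
            )
            chans[f"ch{j}"].append(sig)
        labels.append(np.repeat(names[c], per_bout))
    groups = (
        {"tri": ("ch0", "ch1", "ch2")} if n_channels >= 3 else {}
    )
    return SensorRecording(
        channels={k: np.concatenate(v) for k, v in chans.items()},
        sampling_rate=sampling_rate,
        labels=np.concatenate(labels),
        triaxial_groups=groups,
    )


def _base_spec(**kw) -> DomainSpec:
    return DomainSpec(**kw)


#: named transfer scenarios: (source spec, target spec) builders
SCENARIOS = {
    # different observation maps of equal dimensionality: two sensor
    # modalities viewing the same latent activities
    "cross_modality": lambda: (
        _base_spec(transform="random-linear", d_obs=12, seed=11),
        _base_spec(transform="random-linear", d_obs=12, seed=23),
    ),
    # rotated frame in the source, rotated-and-truncated in the target:
    # a sensor moved to a body site observing fewer effective axes
    "cross_location": lambda: (
        _base_spec(transform="rotation", d_obs=8, seed=31),
        _base_spec(transform="rotation-drop", d_obs=6, seed=47),
    ),
    # same observation map, different wearer: extra noise and gain shift
    "cross_subject": lambda: (
        _base_spec(transform="identity", seed=5, noise_sd=0.3),
        _base_spec(transform="identity", seed=17, noise_sd=0.45, scale=1.2),
    ),
}


def scenario(
    name: str, shared_seed: int = 0, **overrides
) -> tuple[FeatureMatrix, FeatureMatrix]:
    """Generate a named transfer scenario; ``overrides`` apply to both
    domain specs (e.g. ``n=500``)."""
    if name not in SCENARIOS:
        raise ValueError(f"unknown scenario {name!r}; choose from {sorted(SCENARIOS)}")
    spec_s, spec_t = SCENARIOS[name]()
    if overrides:
        spec_s = replace(spec_s, **overrides)
        spec_t = replace(spec_t, **overrides)
    return generate_pair(spec_s, spec_t, shared_seed=shared_seed)
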