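"""Sliding-window segmentation and time-domain feature extraction.

Raw wearable recordings (accelerometer, gyroscope, stretch, ... channels) are
cut into fixed-length sliding windows and each window is summarised by a
vector of time-domain statistics commonly used in inertial-sensor activity
recognition: peak amplitude, median, mean, max, min, variance, standard
deviation (sample, N-1), RMS, peak-to-peak, zero-value rate, entropy,
skewness, kurtosis, energy, range and mean absolute deviation per channel,
plus mean magnitude and elevation angle per declared triaxial (x, y, z)
channel group.

Conventions
-----------
* Windows are half-open sample ranges ``[start, end)``; timestamps are
  seconds from the start of the recording.
* A window's label is the majority per-sample label, ties broken by the
  first-occurring label inside the window; windows containing no labelled
  samples are dropped from labelled matrices.
* Features are computed per channel and concatenated; column order is
  channel-major in the channel declaration order, features within a channel
  in the order of :data:`CHANNEL_FEATURES`, triaxial-group features last.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "SensorRecording",
    "FeatureMatrix",
    "CHANNEL_FEATURES",
    "TRIAXIAL_FEATURES",
    "segment_windows",
    "channel_features",
    "triaxial_features",
    "window_features",
    "extract_feature_matrix",
    "reduce_dimensions",
    "read_recording_csv",
]

#: per-channel features, in output order
CHANNEL_FEATURES = (
    "peak_amplitude",
    "median",
    "mean",
    "maximum",
    "minimum",
    "variance",
    "std",
    "rms",
    "peak_to_peak",
    "zero_rate",
    "entropy",
    "skewness",
    "kurtosis",
    "energy",
    "range",
    "mad",
)

#: per-triaxial-group features, in output order
TRIAXIAL_FEATURES = ("mean_magnitude", "angle")

_ENTROPY_EPS = 1e-12


@dataclass
class SensorRecording:
    """Multichannel sensor time series sampled at a fixed rate.

    Parameters
    ----------
    channels
        Mapping channel name -> 1-D real array; all channels equal length.
    sampling_rate
        Samples per second, > 0.
    labels
        Optional per-sample categorical labels (aligned 1:1 with samples).
    triaxial_groups
        Optional mapping group name -> (x, y, z) channel-name triple for
        which magnitude/angle features are computed.
    """

    channels: dict[str, np.ndarray]
    sampling_rate: float
    labels: np.ndarray | None = None
    triaxial_groups: dict[str, tuple[str, str, str]] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.sampling_rate <= 0:
            raise ValueError("sampling_rate must be > 0")
        if not self.channels:
            raise ValueError("recording has no channels")
        self.channels = {k: np.asarray(v, dtype=float) for k, v in self.channels.items()}
        lengths = {len(v) for v in self.channels.values()}
        if len(lengths) != 1:
            raise ValueError(f"channels have unequal lengths: {sorted(lengths)}")
        if self.labels is not None:
            self.labels = np.asarray(self.labels)
            if len(self.labels) != self.n_samples:
                raise ValueError("labels must align 1:1 with samples")
        for name, trio in self.triaxial_groups.items():
            missing = [c for c in trio if c not in self.channels]
            if missing:
                raise ValueError(f"triaxial group {name!r} references unknown channels {missing}")

    @property
    def n_samples(self) -> int:
        return len(next(iter(self.channels.values())))

    @property
    def duration_s(self) -> float:
        return self.n_samples / self.sampling_rate


@dataclass
class FeatureMatrix:
    """n windows x d features with per-window metadata.

    ``X`` rows correspond to windows in temporal order; ``window_start`` /
    ``window_end`` are seconds (half-open ``[start, end)``); ``labels`` is an
    optional per-window categorical vector.
    """

    X: np.ndarray
    feature_names: list[str]
    labels: np.ndarray | None = None
    window_start: np.ndarray | None = None
    window_end: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.X = np.asarray(self.X, dtype=float)
        if self.X.ndim != 2:
            raise ValueError("X must be 2-D")
        if self.X.shape[0] < 1:
            raise ValueError("feature matrix needs at least one window")
        if self.X.shape[1] != len(self.feature_names):
            raise ValueError("feature_names length must match X columns")
        if not np.all(np.isfinite(self.X)):
            raise ValueError("feature matrix contains NaN/Inf")
        if self.labels is not None:
            self.labels = np.asarray(self.labels)
            if len(self.labels) != self.n:
                raise ValueError("labels length must match number of windows")

    @property
    def n(self) -> int:
        return self.X.shape[0]

    @property
    def d(self) -> int:
        return self.X.shape[1]

    def to_frame(self) -> pd.DataFrame:
        df = pd.DataFrame(self.X, columns=self.feature_names)
        if self.labels is not None:
            df.insert(0, "label", self.labels)
        if self.window_end is not None:
            df.insert(0, "window_end", self.window_end)
        if self.window_start is not None:
            df.insert(0, "window_start", self.window_start)
        return df

    def to_csv(self, path) -> None:
        self.to_frame().to_csv(path, index=False)

    @classmethod
    def from_frame(cls, df: pd.DataFrame) -> "FeatureMatrix":
        meta = [c for c in ("window_start", "window_end", "label") if c in df.columns]
        feats = [c for c in df.columns if c not in meta]
        return cls(
            X=df[feats].to_numpy(dtype=float),
            feature_names=list(feats),
            labels=df["label"].to_numpy() if "label" in meta else None,
            window_start=df["window_start"].to_numpy() if "window_start" in meta else None,
            window_end=df["window_end"].to_numpy() if "window_end" in meta else None,
        )

    @classmethod
    def from_csv(cls, path) -> "FeatureMatrix":
        return cls.from_frame(pd.read_csv(path))


def segment_windows(
    rec: SensorRecording, window_s: float, overlap_frac: float
) -> list[tuple[int, int]]:
    """Half-open sample ranges of a sliding window over the recording.

    The stride is ``window_s * (1 - overlap_frac)``; only windows fully
    inside the recording are kept, so the window count is
    ``floor((T - w) / stride) + 1`` for a recording of duration ``T``.
    """
    if not 0 <= overlap_frac < 1:
        raise ValueError("overlap_frac must be in [0, 1)")
    w = int(round(window_s * rec.sampling_rate))
    if w < 2:
        raise ValueError("window must span at least 2 samples")
    stride = max(1, int(round(window_s * (1 - overlap_frac) * rec.sampling_rate)))
    n = rec.n_samples
    if n < w:
        raise ValueError(
            f"recording too short: {n} samples < one window of {w} samples"
        )
    return [(s, s + w) for s in range(0, n - w + 1, stride)]


def _majority_label(labels: np.ndarray) -> object:
    """Majority vote; ties broken by the first-occurring label."""
    first_pos: dict[object, int] = {}
    counts: dict[object, int] = {}
    for pos, lab in enumerate(labels):
        counts[lab] = counts.get(lab, 0) + 1
        first_pos.setdefault(lab, pos)
    return max(counts, key=lambda lab: (counts[lab], -first_pos[lab]))


def channel_features(s: np.ndarray, include_sign_change_rate: bool = False) -> np.ndarray:
    """Time-domain feature vector of a single-channel window.

    Notes on conventions:

    * variance / std use the sample (N-1) denominator;
    * ``zero_rate`` is the fraction of exactly-zero samples (the printed
      formula); an optional ``sign_change_rate`` (fraction of consecutive
      sign changes) can be appended for users who want the conventional
      zero-crossing rate;
    * entropy is computed on the normalised magnitudes
      ``p_i = (|s_i| + eps) / sum(|s_j| + eps)`` with natural log, which
      keeps it finite for arbitrary real signals and reduces to the plain
      formula on non-negative normalised input;
    * skewness/kurtosis are 0 by convention on constant windows.
    """
    s = np.asarray(s, dtype=float)
    n = s.size
    if n < 2:
        raise ValueError("window must contain at least 2 samples")
    mu = s.mean()
    mx, mn = s.max(), s.min()
    var = s.var(ddof=1)
    sd = np.sqrt(var)
    dev = s - mu
    if sd > 0:
        skew = np.mean(dev**3) / sd**3
        kurt = np.mean(dev**4) / sd**4
    else:
        skew = kurt = 0.0
    p = np.abs(s) + _ENTROPY_EPS
    p = p / p.sum()
    vals = [
        mx - mu,                      # peak amplitude
        float(np.median(s)),          # median
        mu,                           # mean
        mx,                           # maximum
        mn,                           # minimum
        var,                          # variance
        sd,                           # std
        float(np.sqrt(np.mean(s**2))),  # rms
        mx - mn,                      # peak to peak
        float(np.mean(s == 0)),       # zero-valued sample rate
        float(-(p * np.log(p)).sum()),  # entropy
        skew,
        kurt,
        float((s**2).sum()),          # energy
        mx - mn,                      # range
        float(np.abs(dev).mean()),    # mean absolute deviation
    ]
    if include_sign_change_rate:
        sgn = np.sign(s)
        nz = sgn[sgn != 0]
        changes = int(np.sum(nz[1:] != nz[:-1])) if nz.size > 1 else 0
        vals.append(changes / n)
    return np.asarray(vals, dtype=float)


def triaxial_features(sx: np.ndarray, sy: np.ndarray, sz: np.ndarray) -> np.ndarray:
    """Mean magnitude and maximum elevation angle of a triaxial window.

    The angle per sample is ``arctan(z / sqrt(x^2 + y^2))``; when the
    horizontal norm is zero the arctan limit ``sign(z) * pi/2`` is used.
    """
    sx = np.asarray(sx, dtype=float)
    sy = np.asarray(sy, dtype=float)
    sz = np.asarray(sz, dtype=float)
    mag = np.sqrt(sx**2 + sy**2 + sz**2)
    horiz = np.sqrt(sx**2 + sy**2)
    with np.errstate(divide="ignore"):
        ratio = np.divide(sz, horiz, out=np.zeros_like(sz), where=horiz > 0)
        ang = np.where(horiz > 0, np.arctan(ratio), np.sign(sz) * np.pi / 2)
    return np.asarray([mag.mean(), ang.max()], dtype=float)


def window_features(
    s: np.ndarray,
    triaxial: tuple[np.ndarray, np.ndarray, np.ndarray] | None = None,
    include_sign_change_rate: bool = False,
) -> np.ndarray:
    """Feature vector of one window: channel features, then (optionally)
    the triaxial features of the given (x, y, z) arrays."""
    out = channel_features(s, include_sign_change_rate)
    if triaxial is not None:
        out = np.concatenate([out, triaxial_features(*triaxial)])
    return out


def extract_feature_matrix(
    rec: SensorRecording,
    window_s: float = 2.0,
    overlap_frac: float = 0.25,
    include_sign_change_rate: bool = False,
) -> FeatureMatrix:
    """Segment a recording and extract the per-window feature matrix."""
    windows = segment_windows(rec, window_s, overlap_frac)
    ch_feats = list(CHANNEL_FEATURES)
    if include_sign_change_rate:
        ch_feats.append("sign_change_rate")
    names = [f"{ch}__{f}" for ch in rec.channels for f in ch_feats]
    names += [f"{g}__{f}" for g in rec.triaxial_groups for f in TRIAXIAL_FEATURES]

    rows, labels, keep = [], [], []
    for wi, (a, b) in enumerate(windows):
        parts = [
            channel_features(sig[a:b], include_sign_change_rate)
            for sig in rec.channels.values()
        ]
        for gx, gy, gz in rec.triaxial_groups.values():
            parts.append(
                triaxial_features(
                    rec.channels[gx][a:b], rec.channels[gy][a:b], rec.channels[gz][a:b]
                )
            )
        rows.append(np.concatenate(parts))
        if rec.labels is not None:
            lab_win = rec.labels[a:b]
            mask = pd.notna(lab_win)
            if not mask.any():
                continue  # unlabeled window dropped from labelled matrices
            labels.append(_majority_label(lab_win[mask]))
        keep.append(wi)

    fs = rec.sampling_rate
    if rec.labels is not None:
        windows = [windows[i] for i in keep]
        rows = [rows[i] for i in keep]
    starts = np.asarray([a / fs for a, _ in windows])
    ends = np.asarray([b / fs for _, b in windows])
    return FeatureMatrix(
        X=np.vstack(rows),
        feature_names=names,
        labels=np.asarray(labels) if rec.labels is not None else None,
        window_start=starts,
        window_end=ends,
    )


def reduce_dimensions(
    F: FeatureMatrix,
    n_components: int = 2,
    seed: int = 42,
    method: str = "umap",
) -> FeatureMatrix:
    """Optionally embed the feature matrix into a lower-dimensional space.

    ``method="none"`` is a pass-through returning an identical matrix;
    ``method="umap"`` runs UMAP with a fixed ``random_state`` so repeated
    calls on the same input are identical.
    """
    if method == "none":
        return FeatureMatrix(
            X=F.X.copy(),
            feature_names=list(F.feature_names),
            labels=None if F.labels is None else F.labels.copy(),
            window_start=F.window_start,
            window_end=F.window_end,
        )
    if n_components >= F.d:
        raise ValueError(f"n_components={n_components} must be < d={F.d}")
    if F.n < n_components + 1:
        raise ValueError("need at least n_components + 1 observations")
    if method != "umap":
        raise ValueError(f"unknown reduction method {method!r}")
    import umap  # deferred: numba-backed import is slow

    emb = umap.UMAP(n_components=n_components, random_state=seed).fit_transform(F.X)
    return FeatureMatrix(
        X=np.asarray(emb, dtype=float),
        feature_names=[f"umap_{i}" for i in range(n_components)],
        labels=None if F.labels is None else F.labels.copy(),
        window_start=F.window_start,
        window_end=F.window_end,
    )


def read_recording_csv(
    path,
    sampling_rate: float | None = None,
    triaxial_groups: Mapping[str, Sequence[str]] | None = None,
) -> SensorRecording:
    """Read a raw recording CSV: optional ``t`` (seconds) column, one column
    per channel, optional ``label`` column.  ``sampling_rate`` is inferred
    from ``t`` when not given."""
    df = pd.read_csv(path)
    if sampling_rate is None:
        if "t" not in df.columns:
            raise ValueError("sampling_rate not given and no 't' column present")
        dt = np.diff(df["t"].to_numpy(dtype=float))
        if len(dt) == 0 or not np.all(dt > 0):
            raise ValueError("cannot infer sampling rate from 't' column")
        sampling_rate = 1.0 / float(np.median(dt))
    labels = df["label"].to_numpy() if "label" in df.columns else None
    channels = {
        c: df[c].to_numpy(dtype=float)
        for c in df.columns
        if c not in ("t", "label")
    }
    groups = {k: tuple(v) for k, v in (triaxial_groups or {}).items()}
    return SensorRecording(
        channels=channels, sampling_rate=sampling_rate, labels=labels,
        triaxial_groups=groups,
    )
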