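"""Baseline-relative time-domain feature extraction.

Each trial is cut into non-overlapping 3-s windows; the first window is the
baseline (for SEED-style 60-s trials the first 3 s of the viewing period
serves as baseline), and every later window becomes one training example
after subtracting the baseline element-wise.  The amplitude changes are
z-scored per channel and presented to the recurrent model with time as the
leading example axis (``examples x timesteps x channels``).

Label mapping: DEAP-style continuous (valence, arousal) ratings are
thresholded at 5 into the four circumplex quadrants HVHA / LVHA / LVLA /
HVLA; SEED-style {-1, 0, 1} trial labels map directly to
negative / neutral / positive.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import NamedTuple

import numpy as np

from .errors import DegenerateChannelError, DomainError, LengthError, ShapeError
from .io import SubjectRecording

DEAP_CLASS_NAMES = ("HVHA", "LVHA", "LVLA", "HVLA")
SEED_CLASS_NAMES = ("negative", "neutral", "positive")

STANDARDIZE_SCOPES = ("per_subject_channel", "train_stats_channel")


class QuadrantLabel(NamedTuple):
    class_id: int
    name: str


@dataclass
class ChannelStats:
    """Per-channel mean and standard deviation fitted by :func:`standardize`."""

    mean: np.ndarray  # (channels,)
    std: np.ndarray   # (channels,) — epsilon-guarded, never zero

    def apply(self, features: np.ndarray) -> np.ndarray:
        return (features - self.mean) / self.std


@dataclass
class FeatureSet:
    """Baseline-subtracted, standardized 3-s examples with class labels."""

    features: np.ndarray        # (examples, timesteps, channels)
    class_ids: np.ndarray       # (examples,) ints in 0..K-1
    class_names: tuple[str, ...]
    provenance: np.ndarray      # (examples, 2) = (trial index, segment index)
    sampling_rate: int
    stats: ChannelStats | None = None
    standardized: bool = True

    def __post_init__(self) -> None:
        self.features = np.asarray(self.features, dtype=np.float64)
        self.class_ids = np.asarray(self.class_ids, dtype=np.int64)
        self.provenance = np.asarray(self.provenance, dtype=np.int64)
        if self.features.ndim != 3:
            raise ShapeError("features must be (examples, timesteps, channels)")
        n = self.features.shape[0]
        if self.class_ids.shape != (n,) or self.provenance.shape != (n, 2):
            raise ShapeError("class_ids/provenance do not match example count")
        uniq = {tuple(row) for row in self.provenance}
        if len(uniq) != n:
            raise ShapeError("provenance (trial, segment) pairs must be unique")

    @property
    def n_classes(self) -> int:
        return len(self.class_names)


def segment_trial(
    trial: np.ndarray,
    sampling_rate: int,
    window_seconds: float = 3.0,
    *,
    allow_truncate: bool = False,
) -> np.ndarray:
    """Cut a ``channels x samples`` trial into consecutive 3-s windows.

    Returns ``(n_windows, channels, window_samples)`` in temporal order.
    The sample count must be an exact multiple of the window unless
    ``allow_truncate`` drops the remainder explicitly.
    """
    trial = np.asarray(trial)
    if trial.ndim != 2:
        raise ShapeError(f"trial must be (channels, samples), got {trial.shape}")
    window = int(round(window_seconds * sampling_rate))
    if window < 1:
        raise LengthError("window must span at least one sample")
    channels, samples = trial.shape
    remainder = samples % window
    if remainder and not allow_truncate:
        raise LengthError(
            f"{samples} samples is not a multiple of the {window}-sample "
            f"window (remainder {remainder}); enable truncation to drop it"
        )
    n = samples // window
    return trial[:, : n * window].reshape(channels, n, window).transpose(1, 0, 2)


def split_baseline(segments: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Peel the first window off as baseline; the rest are experimental."""
    segments = np.asarray(segments)
    if segments.shape[0] < 2:
        raise LengthError(
            f"need at least 2 segments (baseline + 1), got {segments.shape[0]}"
        )
    return segments[0], segments[1:]


def baseline_subtract(baseline: np.ndarray, experimental: np.ndarray) -> np.ndarray:
    """Amplitude change of each experimental window relative to baseline."""
    baseline = np.asarray(baseline, dtype=np.float64)
    experimental = np.asarray(experimental, dtype=np.float64)
    if experimental.shape[-baseline.ndim:] != baseline.shape:
        raise ShapeError(
            f"segment shape {experimental.shape[1:]} does not match "
            f"baseline {baseline.shape}"
        )
    return experimental - baseline


def standardize(
    features: np.ndarray,
    scope_indices: np.ndarray | None = None,
    *,
    eps_guard: bool = True,
    eps: float = 1e-12,
) -> tuple[np.ndarray, ChannelStats]:
    """Z-score ``(examples, timesteps, channels)`` per channel.

    Statistics are fitted over all examples, or over ``scope_indices`` only
    (the leakage-safe train-statistics mode), and returned so the identical
    affine map can be reapplied to held-out data.  A constant channel yields
    all zeros under the epsilon guard, or raises when the guard is off.
    """
    features = np.asarray(features, dtype=np.float64)
    fit = features if scope_indices is None else features[scope_indices]
    mean = fit.mean(axis=(0, 1))
    std = fit.std(axis=(0, 1))
    if (std < eps).any():
        if not eps_guard:
            bad = np.nonzero(std < eps)[0].tolist()
            raise DegenerateChannelError(f"constant channel(s) {bad}")
        std = np.where(std < eps, 1.0, std)
    stats = ChannelStats(mean=mean, std=std)
    return stats.apply(features), stats


def map_labels_deap(
    valence: float,
    arousal: float,
    threshold: float = 5.0,
    *,
    strict: bool = True,
) -> QuadrantLabel:
    """Map (valence, arousal) ratings in [1, 9] to a circumplex quadrant.

    ``strict`` means high <=> rating strictly greater than the threshold
    (so a rating exactly at 5 counts as low); ``strict=False`` uses >=.
    """
    for name, r in (("valence", valence), ("arousal", arousal)):
        if not (1.0 <= r <= 9.0):
            raise DomainError(f"{name} rating {r} outside [1, 9]")
    high = (lambda r: r > threshold) if strict else (lambda r: r >= threshold)
    hv, ha = high(valence), high(arousal)
    class_id = {(True, True): 0, (False, True): 1,
                (False, False): 2, (True, False): 3}[(hv, ha)]
    return QuadrantLabel(class_id, DEAP_CLASS_NAMES[class_id])


def trial_class_ids(
    rec: SubjectRecording, threshold: float = 5.0, *, strict: bool = True
) -> tuple[np.ndarray, tuple[str, ...]]:
    """Per-trial class ids for either label style of a recording."""
    if rec.label_style == "ratings":
        v = rec.labels[:, rec.label_names.index("valence")]
        a = rec.labels[:, rec.label_names.index("arousal")]
        ids = np.array(
            [map_labels_deap(vi, ai, threshold, strict=strict).class_id
             for vi, ai in zip(v, a)],
            dtype=np.int64,
        )
        return ids, DEAP_CLASS_NAMES
    raw = rec.labels[:, 0]
    if not np.isin(raw, (-1, 0, 1)).all():
        raise DomainError("categorical labels must be in {-1, 0, 1}")
    return (raw + 1).astype(np.int64), SEED_CLASS_NAMES


@dataclass
class FeatureConfig:
    window_seconds: float = 3.0
    threshold: float = 5.0
    strict_threshold: bool = True
    standardize_scope: str = "per_subject_channel"
    allow_truncate: bool = False

    def __post_init__(self) -> None:
        if self.standardize_scope not in STANDARDIZE_SCOPES:
            raise DomainError(
                f"standardize_scope must be one of {STANDARDIZE_SCOPES}"
            )


def build_feature_set(
    rec: SubjectRecording, config: FeatureConfig | None = None
) -> FeatureSet:
    """Compose segmentation, baseline subtraction, standardization and labels.

    A DEAP-shaped recording yields 40 x 20 = 800 examples of 384 timesteps x
    32 channels; a stacked SEED recording yields 45 x 19 = 855 examples of
    600 x 32.  Under the ``train_stats_channel`` scope the returned features
    are left raw (``standardized=False``) for the pipeline to standardize
    with training-set statistics only.
    """
    config = config or FeatureConfig()
    ids, names = trial_class_ids(
        rec, config.threshold, strict=config.strict_threshold
    )
    feats, labels, prov = [], [], []
    for t in range(rec.data.shape[0]):
        segments = segment_trial(
            rec.data[t], rec.sampling_rate, config.window_seconds,
            allow_truncate=config.allow_truncate,
        )
        baseline, experimental = split_baseline(segments)
        diff = baseline_subtract(baseline, experimental)
        feats.append(diff)
        labels.extend([ids[t]] * diff.shape[0])
        prov.extend((t, s + 1) for s in range(diff.shape[0]))
    # (examples, channels, window) -> (examples, timesteps, channels):
    # the recurrence axis is time, with channels as per-step features
    features = np.concatenate(feats, axis=0).transpose(0, 2, 1)
    stats = None
    standardized = config.standardize_scope == "per_subject_channel"
    if standardized:
        features, stats = standardize(features)
    return FeatureSet(
        features=features,
        class_ids=np.asarray(labels),
        class_names=names,
        provenance=np.asarray(prov),
        sampling_rate=rec.sampling_rate,
        stats=stats,
        standardized=standardized,
    )
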