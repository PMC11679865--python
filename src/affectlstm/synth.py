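"""Class-conditional synthetic EEG generator.

Recordings mimic the two benchmark array layouts (40 x 32 x 8064 at 128 Hz
with valence/arousal ratings; 45 x 32 x 12,000 at 200 Hz with {-1, 0, 1}
labels) with a signal model matched to the baseline-relative feature
pipeline: the first 3-s window of every trial is pure Gaussian noise, and
each later window additionally carries the trial's class effect — a fixed
per-channel amplitude offset plus a class-specific oscillation inside the
4-45 Hz passband.  Because the effect lives only in the experimental
windows, baseline subtraction recovers it directly, making the generator
its own ground truth for the extraction pipeline.

The ``snr`` knob is effect amplitude / noise standard deviation; at
``snr=0`` the class-conditional distributions are identical and any
classifier's expected accuracy is chance.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import scipy.io

from .errors import DomainError
from .features import FeatureSet
from .io import DEAP_LABEL_NAMES, SubjectRecording

#: snr used for "high signal-to-noise" experiments throughout the package.
HIGH_SNR = 4.0


@dataclass
class SynthConfig:
    """Generator settings; defaults reproduce the DEAP array layout."""

    dialect: str = "DEAP"          # 'DEAP' (ratings) or 'SEED' (categorical)
    trials: int = 40
    channels: int = 32
    samples: int = 8064
    sampling_rate: int = 128
    snr: float = 1.0               # effect amplitude / noise sd
    noise_sd: float = 1.0
    baseline_seconds: float = 3.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.dialect not in ("DEAP", "SEED"):
            raise DomainError(f"dialect must be DEAP or SEED, got {self.dialect}")
        if min(self.trials, self.channels, self.samples) < 1:
            raise DomainError("trials, channels, samples must be >= 1")
        if self.snr < 0:
            raise DomainError("snr must be >= 0")

    @property
    def n_classes(self) -> int:
        return 4 if self.dialect == "DEAP" else 3

    @classmethod
    def desk(cls, seed: int = 0, snr: float = HIGH_SNR,
             dialect: str = "DEAP") -> "SynthConfig":
        """Desk-scale profile: 8 trials x 8 channels, full trial length."""
        if dialect == "DEAP":
            return cls(dialect="DEAP", trials=8, channels=8, samples=8064,
                       sampling_rate=128, snr=snr, seed=seed)
        return cls(dialect="SEED", trials=9, channels=8, samples=12_000,
                   sampling_rate=200, snr=snr, seed=seed)


def class_effects(cfg: SynthConfig) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Deterministic per-class effect parameters for a config.

    Returns ``(offsets, osc_gain, freqs)``: offsets ``(K, channels)`` are
    the constant amplitude shifts, osc_gain ``(K, channels)`` scales the
    class oscillation per channel, freqs ``(K,)`` are oscillation
    frequencies inside the 4-45 Hz passband.
    """
    k = cfg.n_classes
    amp = cfg.snr * cfg.noise_sd
    rng = np.random.default_rng([cfg.seed, 7919])  # patterns keyed to the seed
    offsets = amp * rng.uniform(-1.0, 1.0, size=(k, cfg.channels))
    osc_gain = amp * rng.uniform(-1.0, 1.0, size=(k, cfg.channels))
    freqs = np.linspace(6.0, 30.0, k)
    return offsets, osc_gain, freqs


def _quadrant_ratings(class_id: int, rng: np.random.Generator) -> np.ndarray:
    """Ratings in the quadrant interiors so the threshold rule recovers the
    class exactly (high ~ U(6.5, 8.5), low ~ U(1.5, 3.5))."""
    hv, ha = {0: (True, True), 1: (False, True),
              2: (False, False), 3: (True, False)}[class_id]
    high = lambda: rng.uniform(6.5, 8.5)
    low = lambda: rng.uniform(1.5, 3.5)
    valence = high() if hv else low()
    arousal = high() if ha else low()
    return np.array([valence, arousal, rng.uniform(1, 9), rng.uniform(1, 9)])


def generate_recording(cfg: SynthConfig) -> SubjectRecording:
    """Draw one synthetic subject recording.

    Trials cycle through the classes in balanced proportion (order
    shuffled).  Identical configs give bit-identical recordings.
    """
    if cfg.snr == 0 and cfg.noise_sd == 0:
        import warnings

        warnings.warn("zero noise with zero effect: degenerate configuration",
                      stacklevel=2)
    rng = np.random.default_rng(cfg.seed)
    k = cfg.n_classes
    class_ids = rng.permutation(np.resize(np.arange(k), cfg.trials))
    data = rng.normal(0.0, cfg.noise_sd,
                      size=(cfg.trials, cfg.channels, cfg.samples))
    offsets, osc_gain, freqs = class_effects(cfg)
    b0 = int(round(cfg.baseline_seconds * cfg.sampling_rate))
    t_axis = np.arange(cfg.samples - b0) / cfg.sampling_rate
    for trial, cid in enumerate(class_ids):
        phase = rng.uniform(0, 2 * np.pi)
        wave = np.sin(2 * np.pi * freqs[cid] * t_axis + phase)
        data[trial, :, b0:] += (offsets[cid][:, None]
                                + osc_gain[cid][:, None] * wave[None, :])
    if cfg.dialect == "DEAP":
        labels = np.stack([_quadrant_ratings(cid, rng) for cid in class_ids])
        label_names = DEAP_LABEL_NAMES
        canonical = (cfg.trials, cfg.channels, cfg.samples,
                     cfg.sampling_rate) == (40, 32, 8064, 128)
        tag = "DEAP" if canonical else "SYNTHETIC"
    else:
        labels = (class_ids - 1).astype(float)[:, None]
        label_names = ("emotion",)
        canonical = (cfg.trials, cfg.channels, cfg.samples,
                     cfg.sampling_rate) == (45, 32, 12_000, 200)
        tag = "SEED" if canonical else "SYNTHETIC"
    return SubjectRecording(
        subject_id=f"synth-{cfg.dialect.lower()}-{cfg.seed}",
        dataset_tag=tag,
        data=data,
        sampling_rate=cfg.sampling_rate,
        labels=labels,
        label_names=label_names,
    )


def effect_recovery_check(cfg: SynthConfig, extracted: FeatureSet) -> dict:
    """Compare per-class feature means against the injected offsets.

    ``extracted`` must hold *raw* (un-standardized) baseline-subtracted
    features of a recording generated from ``cfg``.  The mean over a class's
    examples and timesteps estimates that class's channel offset (the
    oscillation averages out over whole windows up to phase effects).
    Segments of one trial are correlated — they share the subtracted
    baseline and the oscillation phase — so standard errors are clustered
    at the trial level: per-trial means first, then spread across trials.
    Returns the estimates, their standard errors, the injected truth and
    z-scores of the discrepancy.
    """
    if extracted.standardized:
        raise DomainError(
            "effect recovery needs raw features; extract with "
            "standardize_scope='train_stats_channel' to defer z-scoring")
    offsets, _, _ = class_effects(cfg)
    k = cfg.n_classes
    estimates = np.zeros((k, cfg.channels))
    se = np.zeros((k, cfg.channels))
    trials = extracted.provenance[:, 0]
    for cid in range(k):
        mask = extracted.class_ids == cid
        trial_means = np.stack([
            extracted.features[mask & (trials == t)].mean(axis=(0, 1))
            for t in np.unique(trials[mask])
        ])                                        # (n_trials, channels)
        estimates[cid] = trial_means.mean(axis=0)
        n = trial_means.shape[0]
        if n > 1:
            se[cid] = trial_means.std(axis=0, ddof=1) / np.sqrt(n)
    z = (estimates - offsets) / np.where(se > 0, se, np.inf)
    return {"estimates": estimates, "se": se, "injected": offsets, "z": z}


# ---------------------------------------------------------------------------
# dialect fixture writers (for exercising the dataset readers without data)


def write_deap_pickle(rec: SubjectRecording, path) -> None:
    """Serialize a recording in the pickle dialect ({'data', 'labels'})."""
    import pickle

    with open(path, "wb") as fh:
        pickle.dump({"data": rec.data, "labels": rec.labels}, fh)


def write_deap_mat(rec: SubjectRecording, path) -> None:
    """Serialize a recording in the MATLAB dialect."""
    scipy.io.savemat(str(path), {"data": rec.data, "labels": rec.labels})


def write_seed_session(path, trials: np.ndarray, prefix: str = "synth") -> None:
    """Write a session-file fixture: one '<prefix>_eeg<k>' matrix per trial.

    ``trials`` is ``(n_trials, n_montage_channels, samples)`` at 200 Hz.
    """
    payload = {f"{prefix}_eeg{k + 1}": np.asarray(trial)
               for k, trial in enumerate(trials)}
    scipy.io.savemat(str(path), payload)
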