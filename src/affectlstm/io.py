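"""Reading, writing and validating subject-level EEG containers.

Two dataset dialects are supported:

* **DEAP** — one serialized mapping per subject with entries ``data``
  (40 trials x 32 EEG channels x 8064 samples at 128 Hz; files that still
  carry the 8 peripheral channels, i.e. 40 x 40 x 8064, are sliced to the
  first 32 EEG channels) and ``labels`` (40 x 4 continuous ratings in
  [1, 9]: valence, arousal, liking, dominance).  Both the Python-pickle
  and the MATLAB container variants are read.
* **SEED** — MATLAB session files holding 15 per-trial matrices of 62
  channels at 200 Hz; trials are cropped to the middle 60 s and reduced to
  a caller-chosen 32-channel subset.  Three sessions stack to the canonical
  45-trial subject array.

A canonical HDF5 layout (``/data``, ``/labels`` plus identifying
attributes) gives a bit-exact round trip for any valid recording,
synthetic or real.
"""

from __future__ import annotations

import json
import pickle
import re
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import h5py
import numpy as np
import scipy.io

from .errors import (
    ChannelError,
    FormatError,
    LengthError,
    ShapeError,
    VersionError,
)

LAYOUT_VERSION = 1

DEAP_LABEL_NAMES = ("valence", "arousal", "liking", "dominance")
DEAP_SHAPE = (40, 32, 8064)
DEAP_RATE = 128
SEED_SHAPE = (45, 32, 12_000)
SEED_RATE = 200
SEED_TRIAL_SAMPLES = 12_000

#: The 62-electrode order of SEED session files (international 10-20 layout).
SEED_62_CHANNELS = (
    "FP1", "FPZ", "FP2", "AF3", "AF4", "F7", "F5", "F3", "F1", "FZ",
    "F2", "F4", "F6", "F8", "FT7", "FC5", "FC3", "FC1", "FCZ", "FC2",
    "FC4", "FC6", "FT8", "T7", "C5", "C3", "C1", "CZ", "C2", "C4",
    "C6", "T8", "TP7", "CP5", "CP3", "CP1", "CPZ", "CP2", "CP4", "CP6",
    "TP8", "P7", "P5", "P3", "P1", "PZ", "P2", "P4", "P6", "P8",
    "PO7", "PO5", "PO3", "POZ", "PO4", "PO6", "PO8", "CB1", "O1", "OZ",
    "O2", "CB2",
)

#: The 32 SEED electrodes matching the DEAP (Geneva-order) EEG positions.
#: The choice of subset is a configuration input; this list is a convenience
#: default matching DEAP's electrode names, not a claim about any study.
DEAP_32_CHANNELS = (
    "FP1", "AF3", "F3", "F7", "FC5", "FC1", "C3", "T7", "CP5", "CP1",
    "P3", "P7", "PO3", "O1", "OZ", "PZ", "FP2", "AF4", "FZ", "F4",
    "F8", "FC6", "FC2", "CZ", "C4", "T8", "CP6", "CP2", "P4", "P8",
    "PO4", "O2",
)

#: Per-session trial labels of the SEED protocol (-1 negative, 0 neutral,
#: 1 positive), in stimulus order.
SEED_SESSION_LABELS = (1, 0, -1, -1, 0, 1, -1, 0, 1, 1, 0, -1, 0, 1, -1)


@dataclass
class SubjectRecording:
    """One subject's trial tensor plus labels.

    ``data`` is ``trials x channels x samples`` in microvolt-scale arbitrary
    units; ``labels`` is ``trials x label_dims``.  ``dataset_tag`` in
    {'DEAP', 'SEED', 'SYNTHETIC'} controls which dialect invariants apply;
    SYNTHETIC recordings may take any positive shape.
    """

    subject_id: str
    dataset_tag: str
    data: np.ndarray
    sampling_rate: int
    labels: np.ndarray
    label_names: tuple[str, ...]

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data, dtype=np.float64)
        self.labels = np.asarray(self.labels, dtype=np.float64)
        self.label_names = tuple(str(n) for n in self.label_names)
        self.validate()

    @property
    def label_style(self) -> str:
        """'ratings' for valence/arousal columns, 'categorical' for SEED-like."""
        if len(self.label_names) >= 2 and self.label_names[:2] == ("valence", "arousal"):
            return "ratings"
        return "categorical"

    def validate(self) -> None:
        if self.dataset_tag not in ("DEAP", "SEED", "SYNTHETIC"):
            raise FormatError(f"unknown dataset_tag {self.dataset_tag!r}")
        if self.data.ndim != 3:
            raise ShapeError(f"data must be 3-D, got {self.data.ndim}-D")
        if min(self.data.shape) < 1:
            raise ShapeError(f"data dimensions must be >= 1, got {self.data.shape}")
        if not np.isfinite(self.data).all():
            raise FormatError("data contains non-finite values")
        if not np.isfinite(self.labels).all():
            raise FormatError("labels contain non-finite values")
        if self.labels.ndim != 2 or self.labels.shape[0] != self.data.shape[0]:
            raise ShapeError(
                f"labels must be (trials={self.data.shape[0]}, label_dims), "
                f"got {self.labels.shape}"
            )
        if len(self.label_names) != self.labels.shape[1]:
            raise ShapeError("label_names length must match label columns")
        if self.sampling_rate <= 0 or int(self.sampling_rate) != self.sampling_rate:
            raise FormatError("sampling_rate must be a positive integer")
        if self.dataset_tag == "DEAP":
            if self.data.shape != DEAP_SHAPE:
                raise ShapeError(
                    f"DEAP data must be {DEAP_SHAPE}, got {self.data.shape}"
                )
            if self.sampling_rate != DEAP_RATE:
                raise FormatError(f"DEAP sampling rate must be {DEAP_RATE}")
            if self.label_names != DEAP_LABEL_NAMES:
                raise FormatError(
                    f"DEAP labels must be {DEAP_LABEL_NAMES}, got {self.label_names}"
                )
            if self.labels.min() < 1 or self.labels.max() > 9:
                raise FormatError("DEAP ratings must lie in [1, 9]")
        elif self.dataset_tag == "SEED":
            if self.data.shape != SEED_SHAPE:
                raise ShapeError(
                    f"SEED data must be {SEED_SHAPE}, got {self.data.shape}"
                )
            if self.sampling_rate != SEED_RATE:
                raise FormatError(f"SEED sampling rate must be {SEED_RATE}")
            if not np.isin(self.labels, (-1, 0, 1)).all():
                raise FormatError("SEED labels must be in {-1, 0, 1}")


def read_deap(path: str | Path) -> SubjectRecording:
    """Read one DEAP per-subject file (pickle or MATLAB dialect).

    Returns a recording with labels ordered (valence, arousal, liking,
    dominance).  Files carrying the 8 peripheral channels (40 x 40 x 8064)
    are reduced to the leading 32 EEG channels; any other channel count is
    rejected rather than coerced.
    """
    path = Path(path)
    mapping = _load_mapping(path)
    for key in ("data", "labels"):
        if key not in mapping:
            raise FormatError(f"{path}: missing required entry {key!r}")
    data = np.asarray(mapping["data"], dtype=np.float64)
    labels = np.asarray(mapping["labels"], dtype=np.float64)
    if data.ndim == 3 and data.shape[:1] == (40,) and data.shape[1] == 40 \
            and data.shape[2] == DEAP_SHAPE[2]:
        data = data[:, :32, :]  # drop GSR/HR/EMG peripherals
    if data.shape != DEAP_SHAPE:
        raise ShapeError(
            f"{path}: expected data shape {DEAP_SHAPE} (or 40 x 40 x 8064 "
            f"with peripherals), found {data.shape}"
        )
    if labels.shape != (40, 4):
        raise ShapeError(f"{path}: expected labels shape (40, 4), found {labels.shape}")
    return SubjectRecording(
        subject_id=path.stem,
        dataset_tag="DEAP",
        data=data,
        sampling_rate=DEAP_RATE,
        labels=labels,
        label_names=DEAP_LABEL_NAMES,
    )


def _load_mapping(path: Path) -> dict:
    """Load a {name: array} mapping from a pickle or MATLAB container."""
    try:
        return scipy.io.loadmat(str(path))
    except (ValueError, NotImplementedError, OSError):
        pass
    try:
        with open(path, "rb") as fh:
            obj = pickle.load(fh, encoding="latin1")
    except Exception as exc:  # noqa: BLE001 - convert any parse failure
        raise FormatError(f"{path}: not a MATLAB or pickle mapping ({exc})") from exc
    if not isinstance(obj, dict):
        raise FormatError(f"{path}: pickle payload is not a mapping")
    return obj


_SEED_TRIAL_RE = re.compile(r"_eeg(\d+)$")


def read_seed(
    paths: str | Path | Sequence[str | Path],
    channel_subset: Sequence[str],
    *,
    montage: Sequence[str] = SEED_62_CHANNELS,
    trial_labels: Sequence[int] = SEED_SESSION_LABELS,
    subject_id: str | None = None,
) -> SubjectRecording:
    """Read SEED session file(s) into a recording.

    Each session file holds 15 per-trial ``channels x samples`` matrices at
    200 Hz whose row order follows ``montage``.  Every trial is cropped to
    its middle 60 s (12,000 samples, centred window) and reduced to
    ``channel_subset`` in the requested order.  Passing three session paths
    stacks them into the canonical 45-trial array; a single path yields a
    15-trial SYNTHETIC-tagged recording (per-session mode).
    """
    if isinstance(paths, (str, Path)):
        paths = [paths]
    montage = [str(c) for c in montage]
    subset = [str(c) for c in channel_subset]
    missing = [c for c in subset if c not in montage]
    if missing:
        raise ChannelError(f"channels not in montage: {missing}")
    rows = [montage.index(c) for c in subset]

    sessions = []
    for p in paths:
        sessions.append(_read_seed_session(Path(p), rows, len(montage)))
    data = np.concatenate(sessions, axis=0)
    labels = np.asarray(list(trial_labels) * len(sessions), dtype=np.float64)
    if labels.shape[0] != data.shape[0]:
        raise FormatError(
            f"{labels.shape[0]} labels for {data.shape[0]} trials; pass "
            "trial_labels matching the per-session trial count"
        )
    tag = "SEED" if data.shape == SEED_SHAPE else "SYNTHETIC"
    if subject_id is None:
        subject_id = Path(paths[0]).stem
    return SubjectRecording(
        subject_id=subject_id,
        dataset_tag=tag,
        data=data,
        sampling_rate=SEED_RATE,
        labels=labels[:, None],
        label_names=("emotion",),
    )


def _read_seed_session(path: Path, rows: list[int], n_montage: int) -> np.ndarray:
    mat = scipy.io.loadmat(str(path))
    trials: dict[int, np.ndarray] = {}
    for key, value in mat.items():
        m = _SEED_TRIAL_RE.search(key)
        if m:
            trials[int(m.group(1))] = np.asarray(value, dtype=np.float64)
    if not trials:
        raise FormatError(f"{path}: no '*_eeg<k>' trial entries found")
    out = []
    for k in sorted(trials):
        arr = trials[k]
        if arr.ndim != 2 or arr.shape[0] != n_montage:
            raise ShapeError(
                f"{path}: trial {k} must be ({n_montage}, samples), found {arr.shape}"
            )
        n = arr.shape[1]
        if n < SEED_TRIAL_SAMPLES:
            raise LengthError(
                f"{path}: trial {k} has {n} samples "
                f"(< {SEED_TRIAL_SAMPLES}; shorter than 60 s at {SEED_RATE} Hz)"
            )
        start = (n - SEED_TRIAL_SAMPLES) // 2  # centred 60-s window
        out.append(arr[rows, start : start + SEED_TRIAL_SAMPLES])
    return np.stack(out, axis=0)


# ---------------------------------------------------------------------------
# canonical HDF5 layout


def write_canonical(rec: SubjectRecording, path: str | Path) -> None:
    """Write ``rec`` to the canonical HDF5 layout.

    Layout: datasets ``/data`` and ``/labels``; root attributes
    ``subject_id``, ``dataset_tag``, ``sampling_rate``, ``label_names``
    and ``layout_version``.  Arrays round-trip bit-exactly.
    """
    rec.validate()
    with h5py.File(path, "w") as fh:
        fh.create_dataset("data", data=rec.data)
        fh.create_dataset("labels", data=rec.labels)
        fh.attrs["subject_id"] = rec.subject_id
        fh.attrs["dataset_tag"] = rec.dataset_tag
        fh.attrs["sampling_rate"] = int(rec.sampling_rate)
        fh.attrs["label_names"] = list(rec.label_names)
        fh.attrs["layout_version"] = LAYOUT_VERSION


def read_canonical(path: str | Path) -> SubjectRecording:
    with h5py.File(path, "r") as fh:
        version = fh.attrs.get("layout_version")
        if version != LAYOUT_VERSION:
            raise VersionError(f"{path}: unknown layout version {version!r}")
        for name in ("data", "labels"):
            if name not in fh:
                raise FormatError(f"{path}: missing dataset /{name}")
        return SubjectRecording(
            subject_id=str(fh.attrs["subject_id"]),
            dataset_tag=str(fh.attrs["dataset_tag"]),
            data=fh["data"][()],
            sampling_rate=int(fh.attrs["sampling_rate"]),
            labels=fh["labels"][()],
            label_names=tuple(str(n) for n in fh.attrs["label_names"]),
        )


# ---------------------------------------------------------------------------
# evaluation reports


@dataclass
class EvalReport:
    """Per-subject evaluation outcome.

    ``confusion`` rows are true classes; ``loss_trace`` lists
    ``(iteration, global_best_loss)`` pairs from the swarm (empty when no
    search ran).  ``accuracy`` must equal trace/sum of the confusion matrix.
    """

    subject_id: str
    accuracy: float
    confusion: np.ndarray
    best_hyperparams: dict
    loss_trace: list[tuple[int, float]] = field(default_factory=list)
    seed: int | None = None
    mode: str = "proposed"
    n_evaluations: int = 0

    def __post_init__(self) -> None:
        self.confusion = np.asarray(self.confusion, dtype=np.int64)
        self.validate()

    def validate(self) -> None:
        c = self.confusion
        if c.ndim != 2 or c.shape[0] != c.shape[1]:
            raise ShapeError(f"confusion must be square, got {c.shape}")
        if (c < 0).any():
            raise FormatError("confusion entries must be non-negative")
        total = int(c.sum())
        if total > 0 and abs(self.accuracy - np.trace(c) / total) > 1e-9:
            raise FormatError("accuracy does not equal trace/sum of confusion")
        losses = [loss for _, loss in self.loss_trace]
        if any(b > a + 1e-12 for a, b in zip(losses, losses[1:])):
            raise FormatError("loss_trace must be non-increasing")


def write_report(report: EvalReport, path: str | Path) -> None:
    """Persist a report as JSON plus a CSV confusion matrix.

    The JSON field order is fixed; the confusion matrix additionally goes to
    ``<stem>_confusion.csv`` next to the JSON file.
    """
    report.validate()
    path = Path(path)
    payload = {
        "subject_id": report.subject_id,
        "accuracy": report.accuracy,
        "best_hyperparams": report.best_hyperparams,
        "confusion": report.confusion.tolist(),
        "loss_trace": [[int(i), float(l)] for i, l in report.loss_trace],
        "seed": report.seed,
        "mode": report.mode,
        "n_evaluations": report.n_evaluations,
    }
    path.write_text(json.dumps(payload, indent=2) + "\n")
    csv_path = path.with_name(path.stem + "_confusion.csv")
    np.savetxt(csv_path, report.confusion, fmt="%d", delimiter=",")


def read_report(path: str | Path) -> EvalReport:
    payload = json.loads(Path(path).read_text())
    return EvalReport(
        subject_id=payload["subject_id"],
        accuracy=payload["accuracy"],
        confusion=np.asarray(payload["confusion"]),
        best_hyperparams=payload["best_hyperparams"],
        loss_trace=[(int(i), float(l)) for i, l in payload["loss_trace"]],
        seed=payload.get("seed"),
        mode=payload.get("mode", "proposed"),
        n_evaluations=payload.get("n_evaluations", 0),
    )
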