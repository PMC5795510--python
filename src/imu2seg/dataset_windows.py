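"""Windowing, labeling and dataset assembly for the assignment/alignment tasks.

The networks consume fixed windows of ``T = 128`` IMU samples (about two
seconds at 60 Hz) with the six channels ordered accelerometer x, y, z then
gyroscope x, y, z.  Consecutive windows are shifted by a hop of 16 samples.
Each window carries an assignment label (the segment the IMU is mounted on),
an alignment label (the stereographic 3-vector of the constant
sensor-to-segment quaternion of that take), the subject id, a source tag
(``real`` or ``simulated``) and the index of the mounting variation.

Splitting follows leave-one-subject-out (LOSO): every window of the test
subject goes to the test set, and the remaining windows are shuffled into a
95/5 train/validation split (over windows, seeded).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np

from imu2seg.body_model import I2SPose, SegmentClass
from imu2seg.imu_simulator import ImuSignal
from imu2seg.rotmath import stereographic_project

__all__ = [
    "WINDOW_LENGTH",
    "WINDOW_HOP",
    "Window",
    "WindowLabels",
    "DatasetSplit",
    "make_windows",
    "loso_split",
    "mix_sources",
    "stack_windows",
    "alignment_label",
]

WINDOW_LENGTH = 128
WINDOW_HOP = 16


@dataclass(frozen=True)
class Window:
    """One labeled 128 x 6 training/evaluation example."""

    data: np.ndarray                    # (128, 6) float32, acc then gyr
    assignment: SegmentClass
    alignment: np.ndarray               # stereographic 3-vector, |s| <= 1
    subject: str
    source: str = "simulated"           # "real" | "simulated"
    variation: int = 0

    def __post_init__(self) -> None:
        if self.data.shape != (WINDOW_LENGTH, 6):
            raise ValueError(f"window data must be ({WINDOW_LENGTH}, 6)")
        if self.source not in ("real", "simulated"):
            raise ValueError("source must be 'real' or 'simulated'")
        s = np.asarray(self.alignment, float).reshape(3)
        if np.linalg.norm(s) > 1.0 + 1e-9:
            raise ValueError("alignment label must be a canonical stereographic vector")
        object.__setattr__(self, "alignment", s)


@dataclass(frozen=True)
class WindowLabels:
    """Labels shared by every window cut from one recording."""

    assignment: SegmentClass
    alignment: np.ndarray
    subject: str
    source: str = "simulated"
    variation: int = 0


def alignment_label(i2s: I2SPose) -> np.ndarray:
    """Stereographic regression target of a sensor-to-segment pose."""
    return stereographic_project(i2s.quaternion)


def make_windows(signal: ImuSignal, labels: WindowLabels,
                 window: int = WINDOW_LENGTH, hop: int = WINDOW_HOP) -> list:
    """Cut a signal into labeled windows starting at 0, hop, 2*hop, ...

    A signal shorter than one window yields an empty list (with a warning).
    """
    data = signal.to_array().astype(np.float32)
    n = len(data)
    if n < window:
        warnings.warn(f"signal of length {n} shorter than window {window}; "
                      "no windows produced", stacklevel=2)
        return []
    starts = range(0, n - window + 1, hop)
    return [Window(data=data[s:s + window],
                   assignment=labels.assignment,
                   alignment=np.asarray(labels.alignment, float),
                   subject=labels.subject,
                   source=labels.source,
                   variation=labels.variation)
            for s in starts]


@dataclass
class DatasetSplit:
    """Subject-disjoint train/validation/test window collections."""

    train: list
    validation: list
    test: list
    test_subject: str = ""
    seed: int = 0

    def __post_init__(self) -> None:
        test_subjects = {w.subject for w in self.test}
        trainval_subjects = {w.subject for w in self.train} | {
            w.subject for w in self.validation}
        if test_subjects & trainval_subjects:
            raise ValueError("test subjects leak into train/validation")


def loso_split(windows: list, test_subject: str, *, val_fraction: float = 0.05,
               seed: int = 0) -> DatasetSplit:
    """Leave-one-subject-out split with a seeded 95/5 train/validation shuffle."""
    subjects = {w.subject for w in windows}
    if test_subject not in subjects:
        raise ValueError(f"unknown subject {test_subject!r}")
    if len(subjects) < 2:
        raise ValueError("need at least two subjects for a LOSO split")
    test = [w for w in windows if w.subject == test_subject]
    rest = [w for w in windows if w.subject != test_subject]
    rng = np.random.default_rng(seed)
    order = rng.permutation(len(rest))
    n_val = int(round(val_fraction * len(rest)))
    val_idx = set(order[:n_val].tolist())
    validation = [rest[i] for i in sorted(val_idx)]
    train = [rest[i] for i in range(len(rest)) if i not in val_idx]
    return DatasetSplit(train=train, validation=validation, test=test,
                        test_subject=test_subject, seed=seed)


def mix_sources(real: list, simulated: list, *, include_real: bool = True,
                include_simulated: bool = True) -> tuple[list, float]:
    """Concatenate real and simulated windows; report the realized real fraction.

    Returns ``(windows, real_fraction)`` where the fraction is over the
    included windows (0.0 when none are real, e.g. simulation-only training).
    """
    out = []
    if include_real:
        out.extend(real)
    if include_simulated:
        out.extend(simulated)
    n_real = sum(1 for w in out if w.source == "real")
    frac = n_real / len(out) if out else 0.0
    return out, frac


def stack_windows(windows: list) -> dict:
    """Stack a window list into contiguous arrays for batched training.

    Returns a dict with ``X`` (N, 128, 6) float32, ``y`` (N,) int64 class
    indices, ``s`` (N, 3) float32 stereographic targets, plus ``subject``,
    ``source`` and ``variation`` arrays.
    """
    if not windows:
        raise ValueError("empty window list")
    return {
        "X": np.stack([w.data for w in windows]).astype(np.float32),
        "y": np.array([int(w.assignment) for w in windows], dtype=np.int64),
        "s": np.stack([w.alignment for w in windows]).astype(np.float32),
        "subject": np.array([w.subject for w in windows]),
        "source": np.array([w.source for w in windows]),
        "variation": np.array([w.variation for w in windows], dtype=np.int64),
    }
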