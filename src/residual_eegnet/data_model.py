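"""Core EEG data types: montage, epochs, labels, subject-disjoint splits.

The target recordings are 64-channel scalp EEG sampled at 160 Hz during a
cued motor-execution protocol (rest / left-fist / right-fist); each cue
spans 4.5 s, i.e. one 64x720 epoch.  Splits are always *cross-subject*:
test, train and validation sets never share a participant, so measured
accuracy reflects generalization to unseen people.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field
from enum import IntEnum

import numpy as np

from residual_eegnet._rng import substream

log = logging.getLogger(__name__)

SAMPLING_RATE_HZ = 160.0
N_CHANNELS = 64
EPOCH_DURATION_S = 4.5
EPOCH_SAMPLES = round(EPOCH_DURATION_S * SAMPLING_RATE_HZ)  # 720

#: EDF header order of the 64 electrodes (international 10-10 system) in the
#: PhysioNet motor movement/imagery recordings.
PHYSIONET_CHANNELS: tuple[str, ...] = (
    "FC5", "FC3", "FC1", "FCz", "FC2", "FC4", "FC6",
    "C5", "C3", "C1", "Cz", "C2", "C4", "C6",
    "CP5", "CP3", "CP1", "CPz", "CP2", "CP4", "CP6",
    "Fp1", "Fpz", "Fp2",
    "AF7", "AF3", "AFz", "AF4", "AF8",
    "F7", "F5", "F3", "F1", "Fz", "F2", "F4", "F6", "F8",
    "FT7", "FT8",
    "T7", "T8", "T9", "T10",
    "TP7", "TP8",
    "P7", "P5", "P3", "P1", "Pz", "P2", "P4", "P6", "P8",
    "PO7", "PO3", "POz", "PO4", "PO8",
    "O1", "Oz", "O2", "Iz",
)

#: Participants who did not complete the protocol; removed before splitting.
DEFAULT_EXCLUDED_SUBJECTS = frozenset({88, 89, 92, 100})


class TaskLabel(IntEnum):
    """Three-class task encoding, stable across the whole pipeline."""

    REST = 0
    LEFT = 1
    RIGHT = 2


#: Annotation codes on fist-movement runs.
ANNOTATION_CODES = {"T0": TaskLabel.REST, "T1": TaskLabel.LEFT, "T2": TaskLabel.RIGHT}


class MontageError(ValueError):
    pass


@dataclass(frozen=True)
class Montage:
    """Ordered 64-electrode naming with label -> position lookup."""

    labels: tuple[str, ...]

    def __post_init__(self):
        if len(self.labels) != N_CHANNELS:
            raise MontageError(f"expected {N_CHANNELS} labels, got {len(self.labels)}")
        if len(set(self.labels)) != N_CHANNELS:
            raise MontageError("duplicate electrode labels")

    def index_of(self, label: str) -> int:
        try:
            return self.labels.index(label)
        except ValueError:
            raise MontageError(f"unknown electrode {label!r}") from None


def build_montage(channel_names) -> Montage:
    """Build a montage preserving the input (e.g. EDF header) ordering."""
    return Montage(tuple(channel_names))


def default_montage() -> Montage:
    return Montage(PHYSIONET_CHANNELS)


@dataclass
class EEGEpoch:
    """One trial: a channels x samples matrix plus its provenance.

    Values are microvolts before normalization and unitless afterwards.
    """

    data: np.ndarray
    subject_id: int
    session_id: int
    label: TaskLabel
    sampling_rate: float = SAMPLING_RATE_HZ

    def __post_init__(self):
        self.data = np.asarray(self.data, dtype=np.float64)
        if self.data.ndim != 2 or self.data.shape[0] != N_CHANNELS:
            raise ValueError(
                f"epoch must have {N_CHANNELS} channel rows, got shape {self.data.shape}"
            )
        if not np.all(np.isfinite(self.data)):
            raise ValueError("epoch contains non-finite values")
        self.label = TaskLabel(self.label)

    @property
    def n_samples(self) -> int:
        return self.data.shape[1]


@dataclass
class Recording:
    """An annotated multichannel recording (one run of one session).

    ``annotations`` is a list of ``(onset_s, duration_s, code)`` with codes
    drawn from :data:`ANNOTATION_CODES` (T0 rest, T1 left fist, T2 right
    fist on fist-movement runs).
    """

    data: np.ndarray  # (channels, samples)
    sampling_rate: float
    annotations: list[tuple[float, float, str]]
    subject_id: int
    session_id: int
    channel_names: tuple[str, ...] = PHYSIONET_CHANNELS


def load_edf(path, subject_id: int, session_id: int) -> Recording:
    """Read an EDF+ file (signals, labels and T0/T1/T2 annotations).

    Requires the optional ``mne`` dependency.  Rejects sampling rates
    other than 160 Hz rather than resampling.
    """
    import mne  # noqa: deferred heavy import

    raw = mne.io.read_raw_edf(path, preload=True, verbose="error")
    sfreq = float(raw.info["sfreq"])
    if not math.isclose(sfreq, SAMPLING_RATE_HZ):
        raise ValueError(f"expected {SAMPLING_RATE_HZ} Hz recording, got {sfreq}")
    ann = [
        (float(onset), float(dur), str(desc))
        for onset, dur, desc in zip(
            raw.annotations.onset, raw.annotations.duration, raw.annotations.description
        )
    ]
    names = tuple(name.strip(".") for name in raw.ch_names)
    return Recording(
        data=raw.get_data() * 1e6,  # volts -> microvolts
        sampling_rate=sfreq,
        annotations=ann,
        subject_id=subject_id,
        session_id=session_id,
        channel_names=names,
    )


@dataclass
class EpochingResult:
    epochs: list[EEGEpoch]
    skipped: int = 0


def epoch_recording(recording: Recording, duration_s: float = EPOCH_DURATION_S) -> EpochingResult:
    """Cut one fixed-length epoch per annotation onset.

    Windows are half-open ``[start, start + n)`` in 0-based samples with
    ``start = round(onset * fs)`` and ``n = round(duration_s * fs)``.
    Annotations whose window would run past the end of the recording are
    skipped and counted.  Unknown annotation codes raise.
    """
    fs = recording.sampling_rate
    if not math.isclose(fs, SAMPLING_RATE_HZ):
        raise ValueError(f"expected {SAMPLING_RATE_HZ} Hz recording, got {fs}")
    n = round(duration_s * fs)
    total = recording.data.shape[1]
    out: list[EEGEpoch] = []
    skipped = 0
    for onset, _dur, code in recording.annotations:
        if code not in ANNOTATION_CODES:
            raise ValueError(f"unknown annotation code {code!r}")
        start = round(onset * fs)
        if start < 0 or start + n > total:
            skipped += 1
            log.info(
                "skipping annotation %s at %.3fs: window [%d, %d) exceeds %d samples",
                code, onset, start, start + n, total,
            )
            continue
        out.append(
            EEGEpoch(
                data=recording.data[:, start : start + n].copy(),
                subject_id=recording.subject_id,
                session_id=recording.session_id,
                label=ANNOTATION_CODES[code],
                sampling_rate=fs,
            )
        )
    return EpochingResult(epochs=out, skipped=skipped)


def exclude_subjects(subject_ids, excluded=DEFAULT_EXCLUDED_SUBJECTS) -> set[int]:
    """Remove incomplete participants; log exclusions that were absent."""
    ids = set(subject_ids)
    for ex in sorted(excluded):
        if ex in ids:
            ids.discard(ex)
        else:
            log.info("requested exclusion %s not present in subject set", ex)
    return ids


@dataclass
class SplitPlan:
    """Subject-disjoint test set plus k-fold train/validation assignments."""

    test_subjects: frozenset[int]
    folds: list[tuple[frozenset[int], frozenset[int]]]
    seed: int = 0

    def __post_init__(self):
        self.test_subjects = frozenset(self.test_subjects)
        self.folds = [(frozenset(tr), frozenset(va)) for tr, va in self.folds]
        self.validate()

    def validate(self) -> None:
        non_test: set[int] = set()
        for tr, va in self.folds:
            non_test |= tr | va
        if self.test_subjects & non_test:
            raise ValueError("test subjects leak into a fold")
        all_val: set[int] = set()
        for i, (tr, va) in enumerate(self.folds):
            if tr & va:
                raise ValueError(f"fold {i}: train and validation overlap")
            if tr | va != non_test:
                raise ValueError(f"fold {i}: train+val must cover all non-test subjects")
            if all_val & va:
                raise ValueError(f"fold {i}: validation subjects reused across folds")
            all_val |= va
        if all_val != non_test:
            raise ValueError("validation folds must partition the non-test subjects")

    @property
    def non_test_subjects(self) -> frozenset[int]:
        out: set[int] = set()
        for tr, va in self.folds:
            out |= tr | va
        return frozenset(out)


def make_split_plan(subject_ids, n_test: int = 20, n_folds: int = 5, seed: int = 0) -> SplitPlan:
    """Randomly hold out ``n_test`` subjects, k-fold the rest.

    The test draw is uniform without replacement; the remaining subjects
    are shuffled once and chunked into ``n_folds`` contiguous validation
    sets whose sizes differ by at most one.  Deterministic given ``seed``.
    """
    ids = sorted(set(subject_ids))
    if n_test >= len(ids):
        raise ValueError(f"n_test={n_test} must be smaller than {len(ids)} subjects")
    if n_folds < 1 or n_folds > len(ids) - n_test:
        raise ValueError("invalid fold count")
    rng = substream(seed, "split")
    test = set(rng.choice(ids, size=n_test, replace=False).tolist())
    rest = np.array([s for s in ids if s not in test])
    rng.shuffle(rest)
    chunks = np.array_split(rest, n_folds)
    rest_set = frozenset(rest.tolist())
    folds = [(rest_set - frozenset(c.tolist()), frozenset(c.tolist())) for c in chunks]
    return SplitPlan(test_subjects=frozenset(test), folds=folds, seed=seed)


def epochs_by_subject(epochs: list[EEGEpoch], subjects) -> list[EEGEpoch]:
    """Select the epochs belonging to ``subjects`` (order preserved)."""
    wanted = set(subjects)
    return [ep for ep in epochs if ep.subject_id in wanted]


def stack_epochs(epochs: list[EEGEpoch], dtype=np.float64):
    """Stack epochs into ``(N, 1, channels, samples)`` plus label/subject arrays."""
    if not epochs:
        raise ValueError("no epochs to stack")
    x = np.stack([ep.data for ep in epochs]).astype(dtype)[:, None, :, :]
    y = np.array([int(ep.label) for ep in epochs], dtype=np.int64)
    subj = np.array([ep.subject_id for ep in epochs], dtype=np.int64)
    return x, y, subj
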