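"""Synthetic single-beat ECG datasets in the preprocessed beat-matrix dialect.

A beat is a fixed-length row of amplitudes in [0, 1]: the active part of the
beat (``beat_duration`` samples) is a sum of five Gaussian bumps standing in
for the P, Q, R, S and T waves, min-max normalized, and the remainder of the
row is zero padding — the visible structure of the widely used preprocessed
MIT-BIH / ECG5000 beat CSVs (187 amplitude columns plus one binary label
column).  The generator's goal is class-separable, [0,1]-bounded,
zero-padded vectors, not physiological realism.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
from sklearn.model_selection import train_test_split

__all__ = [
    "BeatMorphology", "DatasetSpec", "SignalDataset", "SplitSpec",
    "BeatsCsvFormatError", "normal_morphology", "abnormal_morphology",
    "generate_beat", "generate_dataset", "split_dataset",
    "read_beats_csv", "write_beats_csv",
]

DEFAULT_SIGNAL_LENGTH = 187


class BeatsCsvFormatError(ValueError):
    """Malformed beat-matrix CSV (ragged row, non-numeric cell, bad label)."""


@dataclass(frozen=True)
class BeatMorphology:
    """Five-bump (P, Q, R, S, T) description of a single beat.

    Centers and widths are fractions of the active beat length; amplitudes
    are signed and unitless (the beat is min-max rescaled afterwards).
    """

    wave_centers: tuple[float, ...] = (0.10, 0.22, 0.28, 0.34, 0.60)
    wave_amplitudes: tuple[float, ...] = (0.15, -0.12, 1.00, -0.25, 0.30)
    wave_widths: tuple[float, ...] = (0.040, 0.012, 0.020, 0.015, 0.060)
    beat_duration: int = 130

    def __post_init__(self) -> None:
        if not (len(self.wave_centers) == len(self.wave_amplitudes)
                == len(self.wave_widths) == 5):
            raise ValueError("morphology needs exactly 5 waves (P,Q,R,S,T)")
        if any(w <= 0 for w in self.wave_widths):
            raise ValueError("wave_widths must be positive")
        if any(not 0.0 <= c <= 1.0 for c in self.wave_centers):
            raise ValueError("wave_centers must lie in [0, 1]")
        if self.beat_duration < 2:
            raise ValueError("beat_duration must be >= 2 samples")


def normal_morphology() -> BeatMorphology:
    """Default normal-beat morphology."""
    return BeatMorphology()


def abnormal_morphology() -> BeatMorphology:
    """Default abnormal-beat morphology.

    Relative to the normal beat: QRS complex widened by 60%, R amplitude
    reduced by 30%, T wave inverted — a learnable but noisy class contrast.
    """
    base = normal_morphology()
    widths = list(base.wave_widths)
    for i in (1, 2, 3):  # Q, R, S
        widths[i] *= 1.6
    amps = list(base.wave_amplitudes)
    amps[2] *= 0.7        # reduced R
    amps[4] *= -1.0       # inverted T
    return replace(base, wave_widths=tuple(widths),
                   wave_amplitudes=tuple(amps), beat_duration=140)


def _default_morphologies() -> dict[int, BeatMorphology]:
    return {0: normal_morphology(), 1: abnormal_morphology()}


@dataclass(frozen=True)
class DatasetSpec:
    """Full description of a synthetic dataset; generation is a pure
    function of this object (including ``seed``).

    Defaults mirror the MIT-BIH beat-matrix profile: 187 samples per beat,
    4,045 normal / 10,505 abnormal beats.
    """

    signal_length: int = DEFAULT_SIGNAL_LENGTH
    n_per_class: dict[int, int] = field(
        default_factory=lambda: {0: 4045, 1: 10505})
    morphology_per_class: dict[int, BeatMorphology] = field(
        default_factory=_default_morphologies)
    noise_sd: float = 0.25
    seed: int = 0
    name: str = "synthetic"

    def __post_init__(self) -> None:
        if not self.n_per_class:
            raise ValueError("n_per_class must not be empty")
        if any(c < 0 for c in self.n_per_class.values()):
            raise ValueError("class counts must be >= 0")
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be >= 0")
        for label, morph in self.morphology_per_class.items():
            if morph.beat_duration > self.signal_length:
                raise ValueError(
                    f"class {label}: beat_duration {morph.beat_duration} "
                    f"exceeds signal_length {self.signal_length}")


@dataclass
class SignalDataset:
    """Labeled beat matrix: n x signal_length amplitudes in [0,1] plus
    binary labels (0 = normal, 1 = abnormal)."""

    beats: np.ndarray
    labels: np.ndarray
    name: str = ""
    source: str = "synthetic"  # {"synthetic", "file"}

    def __post_init__(self) -> None:
        self.beats = np.asarray(self.beats, dtype=float)
        self.labels = np.asarray(self.labels, dtype=int)
        if self.beats.ndim != 2:
            raise ValueError("beats must be a 2-D matrix")
        if self.beats.shape[0] != self.labels.shape[0]:
            raise ValueError("row count must equal label count")

    @property
    def n(self) -> int:
        return self.beats.shape[0]

    @property
    def signal_length(self) -> int:
        return self.beats.shape[1]


@dataclass(frozen=True)
class SplitSpec:
    """Train/test split parameters (default 70/30, stratified)."""

    train_fraction: float = 0.70
    stratified: bool = True
    seed: int = 0

    def __post_init__(self) -> None:
        if not 0.0 < self.train_fraction < 1.0:
            raise ValueError("train_fraction must lie strictly in (0, 1)")


def generate_beat(morph: BeatMorphology, signal_length: int,
                  noise_sd: float, rng: np.random.Generator) -> np.ndarray:
    """One beat: five Gaussian bumps + i.i.d. Gaussian noise over the active
    ``beat_duration`` samples, min-max rescaled to [0,1], zero-padded."""
    if signal_length <= 0:
        raise ValueError("signal_length must be positive")
    if morph.beat_duration > signal_length:
        raise ValueError("beat_duration exceeds signal_length")
    d = morph.beat_duration
    t = np.arange(d) / (d - 1)
    active = np.zeros(d)
    for c, a, w in zip(morph.wave_centers, morph.wave_amplitudes,
                       morph.wave_widths):
        active += a * np.exp(-0.5 * ((t - c) / w) ** 2)
    if noise_sd > 0:
        active = active + rng.normal(0.0, noise_sd, size=d)
    lo, hi = active.min(), active.max()
    if hi > lo:
        active = (active - lo) / (hi - lo)
    else:  # flat beat: no information to rescale
        active = np.zeros(d)
    out = np.zeros(signal_length)
    out[:d] = active
    return out


def generate_dataset(spec: DatasetSpec) -> SignalDataset:
    """Generate the dataset described by ``spec`` (deterministic in seed).

    Classes are generated in sorted-label order and the rows are then
    shuffled with the same seeded generator.
    """
    rng = np.random.default_rng(spec.seed)
    rows, labels = [], []
    for label in sorted(spec.n_per_class):
        count = spec.n_per_class[label]
        try:
            morph = spec.morphology_per_class[label]
        except KeyError:
            raise ValueError(f"no morphology for class {label}") from None
        for _ in range(count):
            rows.append(generate_beat(morph, spec.signal_length,
                                      spec.noise_sd, rng))
            labels.append(label)
    beats = (np.array(rows) if rows
             else np.empty((0, spec.signal_length)))
    labels = np.array(labels, dtype=int)
    order = rng.permutation(len(labels))
    return SignalDataset(beats=beats[order], labels=labels[order],
                         name=spec.name, source="synthetic")


def split_dataset(ds: SignalDataset,
                  spec: SplitSpec) -> tuple[SignalDataset, SignalDataset]:
    """Disjoint, exhaustive train/test partition.

    Train size is round(n * train_fraction); the stratified split preserves
    each label's proportion to within one sample.  A class with fewer than
    2 members degrades the split to unstratified with a warning.
    """
    if ds.n == 0:
        raise ValueError("cannot split an empty dataset")
    n_train = int(round(ds.n * spec.train_fraction))
    n_train = min(max(n_train, 1), ds.n - 1)
    stratify = ds.labels if spec.stratified else None
    if spec.stratified:
        _, counts = np.unique(ds.labels, return_counts=True)
        if counts.min() < 2:
            warnings.warn("a class has fewer than 2 members; "
                          "falling back to an unstratified split")
            stratify = None
    idx_train, idx_test = train_test_split(
        np.arange(ds.n), train_size=n_train, random_state=spec.seed,
        shuffle=True, stratify=stratify)
    mk = lambda idx, tag: SignalDataset(
        beats=ds.beats[idx], labels=ds.labels[idx],
        name=f"{ds.name}/{tag}" if ds.name else tag, source=ds.source)
    return mk(idx_train, "train"), mk(idx_test, "test")


def write_beats_csv(ds: SignalDataset, path) -> None:
    """Headerless CSV: signal_length float columns then one integer label."""
    df = pd.DataFrame(ds.beats)
    df["label"] = ds.labels
    df.to_csv(path, header=False, index=False, float_format="%.17g")


def read_beats_csv(path, name: str | None = None) -> SignalDataset:
    """Read a beat-matrix CSV (amplitude columns + trailing binary label).

    Raises :class:`BeatsCsvFormatError` naming the offending 0-based row for
    ragged rows, non-numeric cells, or labels outside {0, 1}.
    """
    try:
        df = pd.read_csv(path, header=None, skip_blank_lines=True,
                         float_precision="round_trip")
    except pd.errors.ParserError as exc:
        raise BeatsCsvFormatError(f"ragged or malformed CSV: {exc}") from exc
    if df.shape[1] < 2:
        raise BeatsCsvFormatError(
            "beat CSV needs at least one amplitude column and a label")
    values = df.apply(pd.to_numeric, errors="coerce").to_numpy(dtype=float)
    bad = np.flatnonzero(np.isnan(values).any(axis=1))
    if bad.size:
        raise BeatsCsvFormatError(
            f"row {bad[0]}: ragged row or non-numeric cell")
    beats, labels = values[:, :-1], values[:, -1]
    if not np.all(np.isin(labels, (0.0, 1.0))):
        row = int(np.flatnonzero(~np.isin(labels, (0.0, 1.0)))[0])
        raise BeatsCsvFormatError(f"row {row}: label outside {{0, 1}}")
    return SignalDataset(beats=beats, labels=labels.astype(int),
                         name=name or str(path), source="file")
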