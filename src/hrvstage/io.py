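"""Readers, writers and the shared time conventions.

All modules share a single set of conventions defined here:

* time origin is the recording start (t = 0 s);
* epochs are 30 s long, 0-indexed, and cover the half-open interval
  ``[30*e, 30*e + 30)``;
* sleep stages use the 4-class alphabet ``W, R, N1N2, N3`` and every matrix
  or vector indexed by class uses that column order.

File formats are plain UTF-8 CSV/text with '.' decimals and '#' comments.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

EPOCH_LEN_S = 30.0

#: Fixed project-wide class order.  Never reorder.
STAGES = ("W", "R", "N1N2", "N3")
STAGE_INDEX = {s: i for i, s in enumerate(STAGES)}


class ValidationError(ValueError):
    """Raised when an input file violates a structural invariant."""


class ParseError(ValueError):
    """Raised when an input file cannot be tokenized."""


@dataclass
class IBISeries:
    """A timestamped inter-beat-interval sequence.

    ``rr_ms[i]`` is the interval ending at ``beat_times_s[i]``.  ``valid``
    marks beats usable for feature computation; invalid beats keep their
    original values so cleaning is non-destructive.
    """

    beat_times_s: np.ndarray
    rr_ms: np.ndarray
    valid: np.ndarray
    recording_id: str = ""
    duration_s: float = 0.0

    def __post_init__(self) -> None:
        self.beat_times_s = np.asarray(self.beat_times_s, dtype=float)
        self.rr_ms = np.asarray(self.rr_ms, dtype=float)
        self.valid = np.asarray(self.valid, dtype=bool)
        n = self.beat_times_s.size
        if not (self.rr_ms.size == n and self.valid.size == n):
            raise ValidationError("beat_times_s, rr_ms and valid must have equal length")
        if n and np.any(np.diff(self.beat_times_s) <= 0):
            raise ValidationError("beat times must be strictly increasing")
        if n and np.any(self.rr_ms <= 0):
            raise ValidationError("all RR intervals must be positive")
        if self.duration_s == 0.0 and n:
            self.duration_s = float(self.beat_times_s[-1])
        if n and self.duration_s < self.beat_times_s[-1] - 1e-9:
            raise ValidationError("duration_s must cover the last beat")

    @property
    def n_beats(self) -> int:
        return int(self.beat_times_s.size)

    @property
    def valid_fraction(self) -> float:
        return float(self.valid.mean()) if self.valid.size else 0.0

    def valid_only(self) -> "IBISeries":
        m = self.valid
        return IBISeries(self.beat_times_s[m], self.rr_ms[m], np.ones(m.sum(), bool),
                         self.recording_id, self.duration_s)


@dataclass(frozen=True)
class EpochGrid:
    """The 30-s epoch grid of a recording: epoch e covers [30e, 30e+30)."""

    n_epochs: int
    epoch_len_s: float = EPOCH_LEN_S

    def epoch_of(self, t_s: float | np.ndarray) -> np.ndarray:
        return np.floor(np.asarray(t_s) / self.epoch_len_s).astype(int)

    def center_of(self, epoch: int) -> float:
        return self.epoch_len_s * epoch + self.epoch_len_s / 2.0

    @property
    def duration_s(self) -> float:
        return self.n_epochs * self.epoch_len_s


@dataclass
class Hypnogram:
    """One 4-class stage label per 30-s epoch."""

    stages: np.ndarray  # array of str from STAGES

    def __post_init__(self) -> None:
        self.stages = np.asarray(self.stages, dtype=object)
        bad = set(self.stages) - set(STAGES)
        if bad:
            raise ValidationError(f"unknown stage labels: {sorted(bad)}")

    def __len__(self) -> int:
        return int(self.stages.size)

    def to_indices(self) -> np.ndarray:
        return np.array([STAGE_INDEX[s] for s in self.stages], dtype=int)

    @classmethod
    def from_indices(cls, idx: Sequence[int]) -> "Hypnogram":
        return cls(np.array([STAGES[i] for i in idx], dtype=object))


@dataclass
class SoftLabelMatrix:
    """Per-epoch annotator fractions, columns in STAGES order (W, R, N1N2, N3)."""

    fractions: np.ndarray  # (n_epochs, 4)

    def __post_init__(self) -> None:
        self.fractions = np.asarray(self.fractions, dtype=float)
        if self.fractions.ndim != 2 or self.fractions.shape[1] != 4:
            raise ValidationError("fractions must be (n_epochs, 4)")
        if self.fractions.size and not np.allclose(self.fractions.sum(axis=1), 1.0, atol=1e-9):
            raise ValidationError("each soft-label row must sum to 1")
        if np.any(self.fractions < -1e-12) or np.any(self.fractions > 1 + 1e-12):
            raise ValidationError("fractions must lie in [0, 1]")

    def __len__(self) -> int:
        return int(self.fractions.shape[0])

    def consensus(self) -> Hypnogram:
        """Row-wise argmax; ties resolved by the fixed column order."""
        return Hypnogram.from_indices(np.argmax(self.fractions, axis=1))


@dataclass
class RecordingMeta:
    recording_id: str
    participant_id: str
    age: float | None = None
    sex: str | None = None          # {"M", "F"}
    bmi: float | None = None
    group: str | None = None        # {healthy, apnea, insomnia, parkinson, plmd}

    def __post_init__(self) -> None:
        if self.age is not None and not self.age > 0:
            raise ValidationError("age must be positive")
        if self.bmi is not None and not self.bmi > 0:
            raise ValidationError("bmi must be positive")
        if self.sex is not None and self.sex not in ("M", "F"):
            raise ValidationError(f"sex must be M or F, got {self.sex!r}")


# ---------------------------------------------------------------------------
# RR file IO


def read_rr_file(path: str | Path, dialect: str = "time_rr") -> IBISeries:
    """Read a plain-text RR file.

    ``rr_only``: one RR interval (ms) per line; beat times are reconstructed
    by cumulative sum, anchoring the first beat at ``rr_ms[0]/1000`` s.
    ``time_rr``: two comma-separated columns ``beat_time_s, rr_ms``.
    Lines beginning with '#' are skipped; a ``# duration_s=<x>`` comment, if
    present, sets the recording span (otherwise the last beat time is used).
    """
    path = Path(path)
    times: list[float] = []
    rrs: list[float] = []
    duration_s = 0.0
    with open(path, encoding="utf-8") as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.strip()
            if not line or line.startswith("#"):
                if line.startswith("#") and "duration_s=" in line:
                    try:
                        duration_s = float(line.split("duration_s=")[1].split()[0])
                    except (ValueError, IndexError):
                        pass
                continue
            tokens = [t for t in line.replace(",", " ").split() if t]
            try:
                values = [float(t) for t in tokens]
            except ValueError as exc:
                raise ParseError(f"{path.name}:{lineno}: non-numeric token in {line!r}") from exc
            if dialect == "rr_only":
                if len(values) != 1:
                    raise ParseError(f"{path.name}:{lineno}: expected 1 column, got {len(values)}")
                rrs.append(values[0])
            elif dialect == "time_rr":
                if len(values) != 2:
                    raise ParseError(f"{path.name}:{lineno}: expected 2 columns, got {len(values)}")
                times.append(values[0])
                rrs.append(values[1])
            else:
                raise ValueError(f"unknown dialect {dialect!r}")
    rr = np.asarray(rrs, dtype=float)
    if dialect == "rr_only":
        t = np.cumsum(rr) / 1000.0
    else:
        t = np.asarray(times, dtype=float)
    return IBISeries(t, rr, np.ones(rr.size, dtype=bool), recording_id=path.stem,
                     duration_s=duration_s)


def write_rr_file(series: IBISeries, path: str | Path) -> None:
    """Write the ``time_rr`` dialect (beat_time_s, rr_ms)."""
    with open(path, "w", encoding="utf-8") as fh:
        fh.write("# beat_time_s,rr_ms\n")
        fh.write(f"# duration_s={series.duration_s:.6f}\n")
        for t, rr in zip(series.beat_times_s, series.rr_ms):
            fh.write(f"{t:.6f},{rr:.6f}\n")


def clean_ibi(series: IBISeries, rr_min_ms: float = 300.0, rr_max_ms: float = 2000.0,
              rel_jump: float = 0.3) -> IBISeries:
    """Mark artifact beats invalid.

    A beat is invalid if its RR lies outside ``[rr_min_ms, rr_max_ms]`` or
    deviates from the median of its 5 nearest valid neighbours (by beat
    index, the beat itself excluded) by more than ``rel_jump`` relative.
    Values are retained; only the validity mask changes.
    """
    n = series.n_beats
    if n == 0:
        return series
    rr = series.rr_ms
    valid = series.valid & (rr >= rr_min_ms) & (rr <= rr_max_ms)
    vidx = np.flatnonzero(valid)
    out = valid.copy()
    m = vidx.size
    if m >= 2:
        arr = rr[vidx]
        # 5 nearest valid neighbours by beat order, tie toward the past;
        # near the series edges fewer neighbours remain after excluding self.
        offsets = np.array([-3, -2, -1, 1, 2, 3])
        pos = np.arange(m)[:, None] + offsets[None, :]
        pos = np.clip(pos, 0, m - 1)
        vals = arr[pos].astype(float)
        vals[pos == np.arange(m)[:, None]] = np.nan
        if m > 6:
            vals[3:-3, -1] = np.nan  # interior rows keep exactly 5 neighbours
        med = np.nanmedian(vals, axis=1)
        jump = np.abs(arr - med) / np.where(med > 0, med, np.inf)
        out[vidx[jump > rel_jump]] = False
    return replace(series, valid=out)


def build_epoch_grid(series: IBISeries) -> EpochGrid:
    if series.duration_s < EPOCH_LEN_S:
        raise ValidationError("recording shorter than one 30-s epoch")
    return EpochGrid(n_epochs=int(series.duration_s // EPOCH_LEN_S))


# ---------------------------------------------------------------------------
# Hypnogram IO


def read_hypnogram(path: str | Path) -> tuple[Hypnogram, SoftLabelMatrix]:
    """Read an epoch-labelled CSV.

    Expects a column ``epoch`` plus either a single ``stage`` column or
    ``annotator_1..annotator_k`` columns.  Returns the per-epoch annotator
    fractions and the consensus hypnogram (argmax, ties by column order).
    """
    df = pd.read_csv(path, comment="#")
    if "epoch" not in df.columns:
        raise ParseError(f"{path}: missing 'epoch' column")
    df = df.sort_values("epoch")
    epochs = df["epoch"].to_numpy()
    if not np.array_equal(epochs, np.arange(len(epochs))):
        raise ValidationError(f"{path}: epoch column must be contiguous 0..n-1")
    label_cols = [c for c in df.columns if c == "stage" or c.startswith("annotator_")]
    if not label_cols:
        raise ParseError(f"{path}: no stage/annotator columns found")
    counts = np.zeros((len(df), 4), dtype=float)
    for col in label_cols:
        for i, token in enumerate(df[col].astype(str).str.strip()):
            if token not in STAGE_INDEX:
                raise ValidationError(f"{path}: unknown stage label {token!r} in column {col}")
            counts[i, STAGE_INDEX[token]] += 1
    soft = SoftLabelMatrix(counts / len(label_cols))
    return soft.consensus(), soft


def write_hypnogram(path: str | Path, annotations: np.ndarray) -> None:
    """Write per-annotator stage columns; ``annotations`` is (n_epochs, k) of labels."""
    annotations = np.asarray(annotations, dtype=object)
    if annotations.ndim == 1:
        annotations = annotations[:, None]
    k = annotations.shape[1]
    cols = {"epoch": np.arange(annotations.shape[0])}
    for j in range(k):
        cols[f"annotator_{j + 1}"] = annotations[:, j]
    pd.DataFrame(cols).to_csv(path, index=False)


# ---------------------------------------------------------------------------
# Feature table IO


def write_feature_table(table: "FeatureTable", path: str | Path) -> None:
    """Write a feature table CSV: header ``epoch`` + the 132 registry names.

    Missing values become empty cells; a round-trip read reproduces values
    to 1e-9.
    """
    from .registry import feature_names

    names = feature_names()
    df = pd.DataFrame(table.values, columns=names)
    df.insert(0, "epoch", np.arange(table.n_epochs))
    df.to_csv(path, index=False, float_format="%.12g", na_rep="")


def read_feature_table(path: str | Path) -> "FeatureTable":
    from .features import FeatureTable
    from .registry import feature_names

    df = pd.read_csv(path)
    names = feature_names()
    missing_cols = [c for c in names if c not in df.columns]
    if missing_cols:
        raise ValidationError(f"{path}: missing feature columns, e.g. {missing_cols[:3]}")
    values = df[list(names)].to_numpy(dtype=float)
    return FeatureTable(values=values)


# ---------------------------------------------------------------------------
# Metadata IO


def read_metadata(path: str | Path) -> list[RecordingMeta]:
    df = pd.read_csv(path, comment="#")
    metas = []
    for _, row in df.iterrows():
        metas.append(RecordingMeta(
            recording_id=str(row["recording_id"]),
            participant_id=str(row["participant_id"]),
            age=float(row["age"]) if "age" in row and pd.notna(row["age"]) else None,
            sex=str(row["sex"]) if "sex" in row and pd.notna(row["sex"]) else None,
            bmi=float(row["bmi"]) if "bmi" in row and pd.notna(row["bmi"]) else None,
            group=str(row["group"]) if "group" in row and pd.notna(row["group"]) else None,
        ))
    return metas


def write_metadata(metas: Sequence[RecordingMeta], path: str | Path) -> None:
    pd.DataFrame([{
        "recording_id": m.recording_id, "participant_id": m.participant_id,
        "age": m.age, "sex": m.sex, "bmi": m.bmi, "group": m.group,
    } for m in metas]).to_csv(path, index=False)
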