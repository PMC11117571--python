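"""Data containers and delimited-text I/O for multi-channel surface EMG.

Trials are stored as delimited text: a header row of muscle names and one
sample per row (columns = muscles). A manifest (YAML or JSON) maps subjects
to their group, task trials and MVC recording.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
import yaml

#: Muscle montage used throughout: soleus, medial/lateral gastrocnemius,
#: tibialis anterior, peroneus longus, rectus femoris, vastus medialis,
#: vastus lateralis, biceps femoris, gluteus maximus.
DEFAULT_MUSCLES: tuple[str, ...] = (
    "SL", "MG", "LG", "TA", "PL", "RF", "VM", "VL", "BF", "GM",
)

#: Processing stages a recording moves through.
STAGES = ("raw", "envelope", "normalized")

GROUPS = ("CAI", "healthy")


class SynergyKitError(Exception):
    """Base class for all package errors."""


class ConfigurationError(SynergyKitError):
    """Invalid parameter or filter configuration."""


class DataError(SynergyKitError):
    """Malformed or inconsistent input data."""


@dataclass
class EMGRecording:
    """One multi-channel EMG trial with sampling metadata.

    Parameters
    ----------
    samples : ndarray, shape (n_samples, n_muscles)
        Signal matrix, one column per muscle. Units are mV (raw) or
        fraction of MVC (normalized).
    fs : float
        Sampling rate in Hz.
    muscle_names : sequence of str
        Ordered channel labels.
    stage : {"raw", "envelope", "normalized"}
        Processing stage; envelopes are non-negative, normalized
        envelopes lie in [0, 1] (up to a small MVC-exceedance tolerance).
    """

    samples: np.ndarray
    fs: float
    muscle_names: tuple[str, ...] = DEFAULT_MUSCLES
    stage: str = "raw"
    subject_id: str | None = None
    group: str | None = None
    trial_index: int | None = None

    def __post_init__(self) -> None:
        self.samples = np.asarray(self.samples, dtype=float)
        self.muscle_names = tuple(self.muscle_names)
        if self.samples.ndim != 2:
            raise DataError("samples must be a 2-D (n_samples, n_muscles) matrix")
        if self.fs <= 0:
            raise DataError(f"sampling rate must be positive, got {self.fs}")
        if self.samples.shape[1] != len(self.muscle_names):
            raise DataError(
                f"{self.samples.shape[1]} columns but "
                f"{len(self.muscle_names)} muscle names"
            )
        if self.stage not in STAGES:
            raise DataError(f"unknown stage {self.stage!r}; expected one of {STAGES}")
        if self.stage == "envelope" and np.any(self.samples < 0):
            raise DataError("envelope-stage samples must be non-negative")

    @property
    def n_samples(self) -> int:
        return self.samples.shape[0]

    @property
    def n_muscles(self) -> int:
        return self.samples.shape[1]

    @property
    def duration_s(self) -> float:
        return self.n_samples / self.fs

    def with_samples(self, samples: np.ndarray, stage: str) -> "EMGRecording":
        """Copy of this recording with new samples and stage."""
        return replace(self, samples=samples, stage=stage)


@dataclass
class MVCReference:
    """Per-muscle maximal-voluntary-contraction envelope peaks.

    The MVC envelope peak defines 100 % activation for each muscle; task
    envelopes are divided by it during normalization.
    """

    peaks: np.ndarray
    muscle_names: tuple[str, ...] = DEFAULT_MUSCLES
    source: str | None = None

    def __post_init__(self) -> None:
        self.peaks = np.asarray(self.peaks, dtype=float)
        self.muscle_names = tuple(self.muscle_names)
        if self.peaks.shape != (len(self.muscle_names),):
            raise DataError("one MVC peak per muscle required")
        if np.any(self.peaks <= 0):
            bad = [m for m, p in zip(self.muscle_names, self.peaks) if p <= 0]
            raise DataError(f"non-positive MVC peak for muscle(s) {bad}")

    def peak_for(self, muscle: str) -> float:
        try:
            return float(self.peaks[self.muscle_names.index(muscle)])
        except ValueError:
            raise DataError(f"muscle {muscle!r} missing from MVC reference") from None


@dataclass
class ActivationMatrix:
    """Muscle activations a_n(t), muscles x time, entries in [0, 1].

    Rows follow ``muscle_names``; columns are the time-normalized landing
    phase (101 points = 0..100 % by default).
    """

    values: np.ndarray
    muscle_names: tuple[str, ...] = DEFAULT_MUSCLES
    subject_id: str | None = None
    group: str | None = None
    trial_index: int | None = None

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        self.muscle_names = tuple(self.muscle_names)
        if self.values.ndim != 2 or self.values.shape[0] != len(self.muscle_names):
            raise DataError("values must be (n_muscles, n_points) matching muscle_names")
        if np.any(self.values < -1e-12) or np.any(self.values > 1 + 1e-9):
            raise DataError("activation entries must lie in [0, 1]")
        self.values = np.clip(self.values, 0.0, 1.0)

    @property
    def n_points(self) -> int:
        return self.values.shape[1]


# ---------------------------------------------------------------------------
# delimited-text I/O


def read_trial(path: str | Path, fs: float = 1000.0, **meta) -> EMGRecording:
    """Read one trial from CSV/TSV (header = muscle names, rows = samples)."""
    path = Path(path)
    sep = "\t" if path.suffix.lower() in {".tsv", ".txt"} else ","
    df = pd.read_csv(path, sep=sep)
    return EMGRecording(
        samples=df.to_numpy(dtype=float),
        fs=fs,
        muscle_names=tuple(df.columns),
        **meta,
    )


def write_trial(rec: EMGRecording, path: str | Path) -> None:
    """Write a trial as CSV with muscle-name header."""
    pd.DataFrame(rec.samples, columns=list(rec.muscle_names)).to_csv(path, index=False)


def write_activation(act: ActivationMatrix, path: str | Path) -> None:
    """Write an activation matrix as CSV: muscle rows, percent-phase columns."""
    cols = [f"{100 * j / (act.n_points - 1):g}%" for j in range(act.n_points)]
    pd.DataFrame(act.values, index=list(act.muscle_names), columns=cols).to_csv(path)


def read_activation(path: str | Path, **meta) -> ActivationMatrix:
    df = pd.read_csv(path, index_col=0)
    return ActivationMatrix(
        values=df.to_numpy(dtype=float), muscle_names=tuple(df.index), **meta
    )


def load_manifest(path: str | Path) -> dict:
    """Load a subject manifest (YAML or JSON).

    Expected layout::

        fs: 1000
        subjects:
          S01:
            group: healthy
            mvc: mvc/S01.csv
            trials: [trials/S01_1.csv, trials/S01_2.csv, trials/S01_3.csv]
    """
    path = Path(path)
    text = path.read_text()
    manifest = json.loads(text) if path.suffix.lower() == ".json" else yaml.safe_load(text)
    if not isinstance(manifest, Mapping) or "subjects" not in manifest:
        raise DataError(f"manifest {path} must contain a 'subjects' mapping")
    for sid, entry in manifest["subjects"].items():
        if "group" not in entry or "trials" not in entry:
            raise DataError(f"manifest entry {sid!r} needs 'group' and 'trials'")
    return dict(manifest)
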