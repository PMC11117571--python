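"""Surface-EMG envelope extraction and MVC normalization.

The envelope pipeline follows common practice for landing EMG: a 50 Hz
notch removes mains interference, a zero-phase 30 Hz high-pass removes
motion artifact, full-wave rectification and a zero-phase 5 Hz low-pass
produce the linear envelope, which is then expressed as a fraction of the
muscle's maximal-voluntary-contraction (MVC) envelope peak.

All IIR filters are applied forward-backward (``filtfilt``), so the
envelope has no phase lag relative to the raw signal.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import signal

from .io import ConfigurationError, DataError, EMGRecording, MVCReference


@dataclass(frozen=True)
class FilterConfig:
    """Envelope filter settings.

    Butterworth order is the design order; forward-backward application
    doubles the effective order. The notch is an IIR peak-reject filter.
    """

    notch_hz: float = 50.0
    notch_q: float = 30.0
    highpass_hz: float = 30.0
    lowpass_hz: float = 5.0
    order: int = 4

    def validate(self, fs: float) -> None:
        corners = (self.notch_hz, self.highpass_hz, self.lowpass_hz)
        if any(c <= 0 for c in corners) or self.order < 1 or self.notch_q <= 0:
            raise ConfigurationError(f"non-positive filter parameter in {self}")
        if fs <= 2 * max(corners):
            raise ConfigurationError(
                f"fs={fs} Hz too low for filter corners {corners} (need fs > 2*corner)"
            )


DEFAULT_FILTERS = FilterConfig()


def _filtfilt_sos(sos: np.ndarray, x: np.ndarray) -> np.ndarray:
    return signal.sosfiltfilt(sos, x, axis=0)


def preprocess_emg(raw: EMGRecording, filters: FilterConfig = DEFAULT_FILTERS) -> EMGRecording:
    """Raw sEMG -> linear envelope.

    Per channel: notch(50 Hz) -> zero-phase high-pass(30 Hz) -> full-wave
    rectification -> zero-phase low-pass(5 Hz). Tiny negative filter
    ringing after the final low-pass is clipped to zero.

    Raises
    ------
    DataError
        If the recording is not raw or contains NaN.
    ConfigurationError
        If the sampling rate cannot support the filter corners.
    """
    if raw.stage != "raw":
        raise DataError(f"preprocess_emg expects a raw recording, got stage={raw.stage!r}")
    if not np.all(np.isfinite(raw.samples)):
        raise DataError("raw EMG contains NaN or infinite samples")
    filters.validate(raw.fs)

    b_notch, a_notch = signal.iirnotch(filters.notch_hz, filters.notch_q, fs=raw.fs)
    sos_hp = signal.butter(
        filters.order, filters.highpass_hz, btype="highpass", fs=raw.fs, output="sos"
    )
    sos_lp = signal.butter(
        filters.order, filters.lowpass_hz, btype="lowpass", fs=raw.fs, output="sos"
    )

    x = signal.filtfilt(b_notch, a_notch, raw.samples, axis=0)
    x = _filtfilt_sos(sos_hp, x)
    x = np.abs(x)  # full-wave rectification
    x = _filtfilt_sos(sos_lp, x)
    x = np.clip(x, 0.0, None)
    return raw.with_samples(x, stage="envelope")


def compute_mvc_peak(
    mvc_trial: EMGRecording, filters: FilterConfig = DEFAULT_FILTERS
) -> MVCReference:
    """Process an MVC recording like a task trial and take per-muscle envelope peaks.

    The peak envelope during MVC defines 100 % activation. A channel whose
    MVC envelope is identically zero would make normalization divide by
    zero and is rejected.
    """
    env = mvc_trial if mvc_trial.stage == "envelope" else preprocess_emg(mvc_trial, filters)
    peaks = env.samples.max(axis=0)
    if np.any(peaks <= 0):
        bad = [m for m, p in zip(env.muscle_names, peaks) if p <= 0]
        raise DataError(f"zero MVC envelope for muscle(s) {bad}")
    return MVCReference(
        peaks=peaks, muscle_names=env.muscle_names, source=mvc_trial.subject_id
    )


def mvc_normalize(
    envelope: EMGRecording, ref: MVCReference, clip_mvc: bool = True
) -> EMGRecording:
    """Divide each envelope channel by its MVC peak -> normalized EMG e_n(t).

    Task EMG can transiently exceed MVC; by default values are capped at
    1.0 (``clip_mvc=False`` keeps the raw ratio) so the downstream
    activation model's [0, 1] domain holds.
    """
    if envelope.stage != "envelope":
        raise DataError(f"mvc_normalize expects an envelope, got stage={envelope.stage!r}")
    peaks = np.array([ref.peak_for(m) for m in envelope.muscle_names])
    x = envelope.samples / peaks
    if clip_mvc:
        x = np.clip(x, 0.0, 1.0)
    return envelope.with_samples(x, stage="normalized")


def time_normalize(curve: np.ndarray, n_points: int = 101) -> np.ndarray:
    """Linearly resample a (n_samples, n_channels) curve onto a uniform grid.

    Maps the trial onto 0..100 % of the movement phase (101 points by
    default). Endpoints are preserved exactly; interior points are linear
    interpolants.
    """
    curve = np.asarray(curve, dtype=float)
    was_1d = curve.ndim == 1
    if was_1d:
        curve = curve[:, None]
    n = curve.shape[0]
    if n < 2:
        raise DataError("time_normalize needs at least 2 samples")
    if n_points < 2:
        raise ConfigurationError("n_points must be >= 2")
    t_in = np.linspace(0.0, 1.0, n)
    t_out = np.linspace(0.0, 1.0, n_points)
    out = np.empty((n_points, curve.shape[1]))
    for j in range(curve.shape[1]):
        out[:, j] = np.interp(t_out, t_in, curve[:, j])
    return out[:, 0] if was_1d else out
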