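"""EMG-driven muscle activation dynamics.

Normalized EMG e_n(t) is mapped to neural activation u_n(t) by a
second-order recursive discrete filter with an electromechanical delay d:

    u(t) = alpha * e(t - d) - beta1 * u(t-1) - beta2 * u(t-2)

with beta1 = C1 + C2, beta2 = C1 * C2 and the gain tied to the recursion
coefficients by alpha - beta1 - beta2 = 1, which gives the filter unit DC
gain: a sustained 100 % excitation settles at 100 % neural activation.
Stability requires |C1| < 1 and |C2| < 1 (poles inside the unit circle).

Neural activation is then passed through an exponential shape function

    a(u) = (exp(A * u) - 1) / (exp(A) - 1)

which maps [0, 1] onto [0, 1] exactly (a(0)=0, a(1)=1) and models the
nonlinear EMG-to-force relationship at low activation; A is the nonlinear
shape factor (default 1.5).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .io import ActivationMatrix, ConfigurationError, DataError, EMGRecording
from .preprocess import time_normalize


@dataclass(frozen=True)
class ActivationParams:
    """Parameters of the recursion and the nonlinear shaping.

    Parameters
    ----------
    C1, C2 : float
        Recursion constants; both must have magnitude < 1 for stability.
        Default -0.5/-0.5 gives a critically-damped-like response with
        real double pole at 0.5.
    d_ms : float
        Electromechanical delay between excitation and activation, in
        milliseconds (default 10 ms).
    A : float
        Nonlinear shape factor of the exponential map (default 1.5);
        must be nonzero.
    """

    C1: float = -0.5
    C2: float = -0.5
    d_ms: float = 10.0
    A: float = 1.5

    def __post_init__(self) -> None:
        if abs(self.C1) >= 1 or abs(self.C2) >= 1:
            raise ConfigurationError(
                f"unstable recursion: need |C1| < 1 and |C2| < 1, got "
                f"C1={self.C1}, C2={self.C2}"
            )
        if self.A == 0:
            raise ConfigurationError("shape factor A must be nonzero")
        if self.d_ms < 0:
            raise ConfigurationError("electromechanical delay must be >= 0")

    @property
    def beta1(self) -> float:
        return self.C1 + self.C2

    @property
    def beta2(self) -> float:
        return self.C1 * self.C2

    @property
    def alpha(self) -> float:
        # gain constraint alpha - beta1 - beta2 = 1 => unit DC gain
        return 1.0 + self.beta1 + self.beta2

    def delay_samples(self, fs: float) -> int:
        return int(round(self.d_ms * fs / 1000.0))


DEFAULT_PARAMS = ActivationParams()


def neural_activation(
    en: np.ndarray,
    params: ActivationParams = DEFAULT_PARAMS,
    fs: float = 1000.0,
    clip: bool = True,
) -> np.ndarray:
    """Run the second-order recursion on normalized EMG.

    ``en`` may be 1-D (one muscle) or 2-D (n_samples, n_muscles); the
    recursion runs along axis 0 with zero initial state and e(t)=0 for
    t < 0 (the first ``d`` output samples are therefore 0). The output is
    clipped to [0, 1] so the nonlinear shaping's domain holds even for
    parameter choices with transient overshoot.
    """
    en = np.asarray(en, dtype=float)
    if fs <= 0:
        raise ConfigurationError("fs must be positive")
    was_1d = en.ndim == 1
    x = en[:, None] if was_1d else en
    d = params.delay_samples(fs)
    a, b1, b2 = params.alpha, params.beta1, params.beta2

    # delayed input, zero-padded at the start
    xd = np.zeros_like(x)
    if d < x.shape[0]:
        xd[d:] = x[: x.shape[0] - d]

    u = np.zeros_like(x)
    um1 = np.zeros(x.shape[1])
    um2 = np.zeros(x.shape[1])
    for t in range(x.shape[0]):
        ut = a * xd[t] - b1 * um1 - b2 * um2
        u[t] = ut
        um2 = um1
        um1 = ut
    if clip:
        u = np.clip(u, 0.0, 1.0)
    return u[:, 0] if was_1d else u


def nonlinear_activation(un: np.ndarray, A: float = 1.5) -> np.ndarray:
    """Exponential excitation-to-activation map a(u) = (e^{Au}-1)/(e^A-1)."""
    if A == 0:
        raise ConfigurationError("shape factor A must be nonzero (linear limit not supported)")
    un = np.asarray(un, dtype=float)
    return np.expm1(A * un) / np.expm1(A)


def inverse_nonlinear_activation(an: np.ndarray, A: float = 1.5) -> np.ndarray:
    """Inverse of :func:`nonlinear_activation` on [0, 1]."""
    if A == 0:
        raise ConfigurationError("shape factor A must be nonzero")
    an = np.asarray(an, dtype=float)
    return np.log1p(an * np.expm1(A)) / A


def activation_from_emg(
    trial: EMGRecording,
    params: ActivationParams = DEFAULT_PARAMS,
    n_points: int = 101,
) -> ActivationMatrix:
    """Normalized EMG trial -> (n_muscles, n_points) activation matrix.

    The recursion and shaping run at the native sampling rate (the delay
    is physical, in ms); the resulting activation curves are then
    time-normalized to ``n_points`` across the landing phase and
    transposed to muscles x time.
    """
    if trial.stage != "normalized":
        raise DataError(
            f"activation_from_emg expects a normalized recording, got {trial.stage!r}"
        )
    u = neural_activation(trial.samples, params, trial.fs)
    a = nonlinear_activation(u, params.A)
    a101 = time_normalize(a, n_points)
    return ActivationMatrix(
        values=np.clip(a101.T, 0.0, 1.0),
        muscle_names=trial.muscle_names,
        subject_id=trial.subject_id,
        group=trial.group,
        trial_index=trial.trial_index,
    )
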