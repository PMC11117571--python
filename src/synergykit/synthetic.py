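"""Synthetic landing-EMG datasets with known ground-truth synergies.

The generator emulates a two-group single-leg landing study: 10 lower
limb muscles, two groups (a chronic-ankle-instability-like group and a
healthy-like group) of 22 subjects each, 3 trials per subject, with the
landing phase time-normalized to 101 points.

Ground truth follows the four functional modules consistently reported
for landing:

* module 1 — hip strategy (BF, GM dominant), early phase;
* module 2 — knee stabilization (RF, VM, VL, MG, LG, SL), active
  through most of the phase;
* module 3 — initial-contact ankle control (MG, LG, TA), 0–20 % of the
  phase;
* module 4 — whole-limb control (GM, RF, VM, VL, LG, SL, PL), late
  phase.

The spatial templates are block-structured over the module memberships
above; the CAI-like group applies additive deltas to specific
(module, muscle) cells (e.g. +0.18 on GM in module 1) reproducing the
group mean shifts such a study detects. Each trial realizes
V = W C + noise — the exact generative counterpart of the factorization
model — with independent per-trial module-amplitude jitter (the
trial-to-trial recruitment variability that makes the module subspace
identifiable), multiplicative log-normal noise and additive Gaussian
noise calibrated to a target SNR in dB.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import signal

from .io import ActivationMatrix, DataError, DEFAULT_MUSCLES, EMGRecording

# ---------------------------------------------------------------------------
# ground truth

#: spatial module templates over (SL, MG, LG, TA, PL, RF, VM, VL, BF, GM).
#: Block structure: each module loads its member muscles, with the
#: muscles that characterize the module (BF+GM for hip, RF for knee,
#: TA+MG for initial-contact ankle, PL+GM for whole-limb) emphasized and
#: memberships shared with other modules de-emphasized, so each module
#: has a distinctive spatial signature. Non-members carry a small
#: baseline.
MODULE_TEMPLATES: dict[str, dict[str, float]] = {
    "hip": {
        "SL": 0.02, "MG": 0.02, "LG": 0.02, "TA": 0.02, "PL": 0.02,
        "RF": 0.02, "VM": 0.02, "VL": 0.02, "BF": 1.00, "GM": 1.00,
    },
    "knee": {
        "SL": 0.45, "MG": 0.45, "LG": 0.60, "TA": 0.02, "PL": 0.02,
        "RF": 1.00, "VM": 0.60, "VL": 0.60, "BF": 0.02, "GM": 0.02,
    },
    "ankle_initial": {
        "SL": 0.02, "MG": 0.90, "LG": 0.60, "TA": 1.00, "PL": 0.02,
        "RF": 0.02, "VM": 0.02, "VL": 0.02, "BF": 0.02, "GM": 0.02,
    },
    "whole_limb": {
        "SL": 0.25, "MG": 0.02, "LG": 0.25, "TA": 0.02, "PL": 1.00,
        "RF": 0.25, "VM": 0.60, "VL": 0.60, "BF": 0.02, "GM": 0.60,
    },
}

#: temporal activation profiles per module: (center %, width %, amplitude).
#: Initial-contact ankle control peaks in the first 20 % of the phase;
#: hip loading follows; knee stabilization spans the middle of the
#: phase; whole-limb balance control dominates late in the phase.
ACTIVATION_PROFILES: dict[str, tuple[float, float, float]] = {
    "hip": (28.0, 7.0, 1.0),
    "knee": (50.0, 10.0, 1.0),
    "ankle_initial": (8.0, 5.0, 1.0),
    "whole_limb": (78.0, 7.0, 1.0),
}

#: between-subject weight dispersion per group: patients with chronic
#: ankle instability organize their modules more heterogeneously than
#: healthy controls, which is what depresses their similarity rate to
#: the healthy-derived reference synergies.
DEFAULT_WEIGHT_JITTER: dict[str, float] = {"healthy": 0.08, "CAI": 0.20}

#: CAI-like group deltas on (module index, muscle) weight cells: the mean
#: shifts a landing study of this design reports as significant.
CAI_WEIGHT_DELTAS: dict[tuple[int, str], float] = {
    (0, "GM"): +0.18,
    (1, "GM"): +0.11,
    (1, "PL"): +0.15,
    (1, "VL"): -0.16,
    (1, "LG"): -0.13,
    (2, "BF"): +0.15,
    (2, "TA"): +0.16,
    (3, "VL"): +0.14,
    (3, "BF"): -0.14,
    (3, "LG"): -0.22,
    (3, "PL"): -0.22,
}


@dataclass
class GroundTruth:
    """Known generative synergy structure behind a synthetic dataset."""

    W_true: np.ndarray  # (m, k_true), unit-norm columns
    C_true: np.ndarray  # (k_true, n_points)
    module_names: tuple[str, ...]
    muscle_names: tuple[str, ...] = DEFAULT_MUSCLES
    group_effects: dict[str, dict[tuple[int, str], float]] = field(default_factory=dict)
    seed: int | None = None

    @property
    def k_true(self) -> int:
        return self.W_true.shape[1]

    def group_W(self, group: str) -> np.ndarray:
        """Template W with the group's weight deltas applied, renormalized."""
        W = self.W_true.copy()
        for (mod, muscle), delta in self.group_effects.get(group, {}).items():
            W[self.muscle_names.index(muscle), mod] += delta
        W = np.clip(W, 0.0, None)
        return W / np.linalg.norm(W, axis=0)


def _gaussian_bump(pct: np.ndarray, center: float, width: float, amp: float) -> np.ndarray:
    return amp * np.exp(-0.5 * ((pct - center) / width) ** 2)


def make_ground_truth(
    m: int = 10,
    k_true: int = 4,
    seed: int | None = None,
    n_points: int = 101,
    template_jitter: float = 0.03,
) -> GroundTruth:
    """Build deterministic module templates with small seeded jitter.

    ``k_true <= 4`` takes the first modules of the canonical set;
    ``k_true > 4`` (or m != 10) fills remaining modules/muscles with
    seeded random non-negative structure (used only for stress tests).
    """
    if k_true > m:
        raise DataError(f"k_true={k_true} exceeds m={m}")
    rng = np.random.default_rng(seed)
    names = list(MODULE_TEMPLATES)[:k_true]
    muscles = DEFAULT_MUSCLES[:m] if m <= 10 else tuple(
        list(DEFAULT_MUSCLES) + [f"M{i}" for i in range(10, m)]
    )
    W = np.zeros((m, k_true))
    for j, name in enumerate(names):
        tmpl = MODULE_TEMPLATES[name]
        for i, muscle in enumerate(muscles):
            W[i, j] = tmpl.get(muscle, 0.05)
    for j in range(len(names), k_true):  # extra synthetic modules if requested
        W[:, j] = rng.uniform(0.05, 1.0, size=m)
        names.append(f"extra{j}")
    W += rng.normal(0.0, template_jitter, size=W.shape)
    W = np.clip(W, 0.01, None)
    W /= np.linalg.norm(W, axis=0)

    pct = np.linspace(0.0, 100.0, n_points)
    C = np.zeros((k_true, n_points))
    for j, name in enumerate(names):
        center, width, amp = ACTIVATION_PROFILES.get(
            name, (float(rng.uniform(20, 80)), float(rng.uniform(8, 25)), 0.9)
        )
        C[j] = _gaussian_bump(pct, center, width, amp)
    return GroundTruth(
        W_true=W,
        C_true=C,
        module_names=tuple(names),
        muscle_names=muscles,
        group_effects={"CAI": dict(CAI_WEIGHT_DELTAS)} if m == 10 and k_true == 4 else {},
        seed=seed,
    )


# ---------------------------------------------------------------------------
# subject / dataset synthesis


@dataclass
class SyntheticSubject:
    subject_id: str
    group: str
    trials: list[ActivationMatrix]
    W_subject: np.ndarray  # this subject's true synergy vectors (m, k_true)
    C_subject: np.ndarray  # this subject's mean activation profiles (k_true, n_points)
    seed: int


@dataclass
class SyntheticDataset:
    subjects: list[SyntheticSubject]
    ground_truth: GroundTruth
    snr_db: float
    seed: int | None

    def by_group(self, group: str) -> list[SyntheticSubject]:
        return [s for s in self.subjects if s.group == group]


def synthesize_subject(
    gt: GroundTruth,
    group: str,
    subject_seed: int,
    snr_db: float = 20.0,
    n_trials: int = 3,
    subject_id: str | None = None,
    weight_jitter: float | None = None,
    profile_jitter: float = 0.10,
    trial_amplitude_jitter: float = 0.5,
    mult_noise_sigma: float = 0.10,
) -> SyntheticSubject:
    """Realize one subject: jittered weights + per-trial noisy activations.

    The subject's own synergy vectors are the group template plus
    additive Gaussian jitter (sigma ``weight_jitter``; ``None`` takes
    the group default from :data:`DEFAULT_WEIGHT_JITTER`, falling back
    to the healthy level for unknown groups), clipped and renormalized —
    this produces the between-subject weight dispersion a real cohort
    shows, larger in the patient-like group. Per trial, each module's amplitude gets
    independent log-normal jitter (sigma ``trial_amplitude_jitter``),
    modeling trial-to-trial recruitment variability; this independent
    modulation across the 3 concatenated trials is what renders the
    modules' subspace identifiable. The activation matrix
    V = W_subj C_trial is then corrupted by multiplicative log-normal
    noise (sigma ``mult_noise_sigma``) plus additive Gaussian noise whose
    variance is set so total perturbation power matches ``snr_db``; V is
    finally clipped to [0, 1].
    """
    if np.isnan(snr_db) or snr_db == -np.inf:
        raise DataError("snr_db must be finite or +inf")
    if weight_jitter is None:
        weight_jitter = DEFAULT_WEIGHT_JITTER.get(group, DEFAULT_WEIGHT_JITTER["healthy"])
    rng = np.random.default_rng(subject_seed)
    Wg = gt.group_W(group)
    W = Wg + rng.normal(0.0, weight_jitter, size=Wg.shape)
    W = np.clip(W, 0.01, None)
    W /= np.linalg.norm(W, axis=0)
    # subject-level profile scaling
    amp_subject = np.exp(rng.normal(0.0, profile_jitter, size=gt.k_true))
    C_subj = gt.C_true * amp_subject[:, None]

    noiseless = not np.isfinite(snr_db)
    trials = []
    for ti in range(n_trials):
        amp_trial = np.exp(rng.normal(0.0, trial_amplitude_jitter, size=gt.k_true))
        V0 = W @ (C_subj * amp_trial[:, None])
        # a trial whose amplitude draw would saturate activation is scaled
        # down as a whole, which preserves V0 = W C exactly (elementwise
        # clipping would break the generative factorization)
        peak = V0.max()
        if peak > 1.0:
            V0 /= peak
        if noiseless:
            V = V0
        else:
            sig_power = float(np.mean(V0**2))
            noise_power = sig_power / (10.0 ** (snr_db / 10.0))
            mult = np.exp(rng.normal(0.0, mult_noise_sigma, size=V0.shape))
            Vm = V0 * mult
            mult_power = float(np.mean((Vm - V0) ** 2))
            add_var = max(noise_power - mult_power, 0.0)
            V = Vm + rng.normal(0.0, np.sqrt(add_var), size=V0.shape)
        V = np.clip(V, 0.0, 1.0)
        trials.append(
            ActivationMatrix(
                values=V,
                muscle_names=gt.muscle_names,
                subject_id=subject_id,
                group=group,
                trial_index=ti,
            )
        )
    return SyntheticSubject(
        subject_id=subject_id or f"{group}_{subject_seed}",
        group=group,
        trials=trials,
        W_subject=W,
        C_subject=C_subj,
        seed=subject_seed,
    )


def synthesize_dataset(
    n_per_group: int = 22,
    n_trials: int = 3,
    snr_db: float = 20.0,
    seed: int | None = 0,
    groups: tuple[str, str] = ("CAI", "healthy"),
    gt: GroundTruth | None = None,
    **subject_kwargs,
) -> SyntheticDataset:
    """Full two-group dataset (default 22 + 22 subjects, 3 trials each).

    Per-subject seeds are spawned from the master seed, so any subject is
    reproducible in isolation and the dataset is reproducible end to end.
    """
    ss = np.random.SeedSequence(seed)
    gt_seed, *subj_seeds = ss.generate_state(1 + 2 * n_per_group)
    if gt is None:
        gt = make_ground_truth(seed=int(gt_seed % 2**31))
    subjects = []
    idx = 0
    for group in groups:
        for s in range(n_per_group):
            subjects.append(
                synthesize_subject(
                    gt,
                    group,
                    subject_seed=int(subj_seeds[idx] % 2**31),
                    snr_db=snr_db,
                    n_trials=n_trials,
                    subject_id=f"{group}{s + 1:02d}",
                    **subject_kwargs,
                )
            )
            idx += 1
    return SyntheticDataset(subjects=subjects, ground_truth=gt, snr_db=snr_db, seed=seed)


# ---------------------------------------------------------------------------
# raw-EMG synthesis (for exercising the preprocessing + activation stages)


def synthesize_raw_emg(
    activation_trace: np.ndarray,
    fs: float = 1000.0,
    seed: int | None = None,
    carrier_band: tuple[float, float] = (30.0, 450.0),
    mains_amp: float = 0.05,
    baseline_noise: float = 0.01,
) -> np.ndarray:
    """Amplitude-modulated surrogate sEMG for one muscle.

    A band-limited (30–450 Hz) Gaussian carrier is modulated by the
    activation envelope, then 50 Hz mains interference and broadband
    baseline noise are added. The construction is designed so that the
    envelope pipeline (notch, high-pass, rectify, 5 Hz low-pass, MVC
    normalize) recovers the modulating envelope with correlation > 0.95.
    """
    a = np.asarray(activation_trace, dtype=float)
    if np.any(a < 0) or np.any(a > 1 + 1e-9):
        raise DataError("activation trace must lie in [0, 1]")
    n = a.size
    rng = np.random.default_rng(seed)
    sos = signal.butter(4, carrier_band, btype="bandpass", fs=fs, output="sos")
    carrier = signal.sosfilt(sos, rng.standard_normal(n))
    carrier /= np.std(carrier)
    t = np.arange(n) / fs
    mains = mains_amp * np.sin(2 * np.pi * 50.0 * t + rng.uniform(0, 2 * np.pi))
    noise = baseline_noise * rng.standard_normal(n)
    return a * carrier + mains + noise


def synthesize_raw_recording(
    activation: np.ndarray,
    fs: float = 1000.0,
    seed: int | None = None,
    muscle_names: tuple[str, ...] = DEFAULT_MUSCLES,
    **meta,
) -> EMGRecording:
    """Multi-muscle raw recording from an (n_samples, n_muscles) envelope."""
    activation = np.asarray(activation, dtype=float)
    ss = np.random.SeedSequence(seed)
    seeds = ss.generate_state(activation.shape[1])
    raw = np.column_stack(
        [
            synthesize_raw_emg(activation[:, j], fs=fs, seed=int(seeds[j] % 2**31))
            for j in range(activation.shape[1])
        ]
    )
    return EMGRecording(samples=raw, fs=fs, muscle_names=muscle_names, stage="raw", **meta)
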