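"""Muscle-synergy extraction by non-negative matrix factorization.

The activation matrix V (muscles x time, trials concatenated) is
approximated as V ~ W C with W >= 0 the synergy vectors (muscles x k,
each column one spatial module) and C >= 0 the activation coefficients
(k x time). The factors are found by Lee–Seung multiplicative updates on
the squared Frobenius cost ||V - WC||_F^2:

    W <- W * (V C^T) / (W C C^T)
    C <- C * (W^T V) / (W^T W C)

which never increase the cost. The number of synergies is selected by a
dual variance-accounted-for (VAF) protocol: the smallest k whose global
VAF exceeds 90 % while every per-muscle VAF exceeds 75 %.

Columns of W are reported with unit Euclidean norm (rows of C absorb the
scale), so muscle weights are comparable across subjects.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np

from .io import DataError

#: guard added to update denominators to avoid division by zero
EPS_DIV = 1e-12


def frobenius_loss(V: np.ndarray, W: np.ndarray, C: np.ndarray) -> float:
    """Squared Frobenius reconstruction cost ||V - WC||_F^2."""
    R = V - W @ C
    return float(np.sum(R * R))


def update_step(
    V: np.ndarray, W: np.ndarray, C: np.ndarray, eps: float = EPS_DIV
) -> tuple[np.ndarray, np.ndarray]:
    """One multiplicative update of W then C (non-increasing cost).

    Returns new arrays; inputs are not modified. A perfect factorization
    (V = WC) is a fixed point: every update ratio is 1.
    """
    V = np.asarray(V, float)
    if V.shape[0] != W.shape[0] or V.shape[1] != C.shape[1] or W.shape[1] != C.shape[0]:
        raise DataError(
            f"shape mismatch: V{V.shape}, W{W.shape}, C{C.shape}"
        )
    W = W * (V @ C.T) / (W @ C @ C.T + eps)
    C = C * (W.T @ V) / (W.T @ W @ C + eps)
    return W, C


def vaf_global(V: np.ndarray, W: np.ndarray, C: np.ndarray) -> float:
    """Global variance accounted for: 1 - ||V - WC||^2 / ||V||^2."""
    denom = float(np.sum(np.asarray(V, float) ** 2))
    if denom == 0:
        raise DataError("VAF undefined for an all-zero matrix")
    return 1.0 - frobenius_loss(V, W, C) / denom


def vaf_local(V: np.ndarray, W: np.ndarray, C: np.ndarray) -> np.ndarray:
    """Per-muscle (row-wise) variance accounted for.

    Rows of V that are identically zero have undefined VAF; they are
    reported as NaN with a warning and ignored by the rank-selection
    thresholds.
    """
    V = np.asarray(V, float)
    R = V - W @ C
    num = np.sum(R * R, axis=1)
    den = np.sum(V * V, axis=1)
    out = np.full(V.shape[0], np.nan)
    nz = den > 0
    if not np.all(nz):
        warnings.warn("all-zero muscle row(s): local VAF undefined (NaN)", stacklevel=2)
    out[nz] = 1.0 - num[nz] / den[nz]
    return out


def _normalize_columns(W: np.ndarray, C: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Scale W columns to unit L2 norm, compensating in C (WC unchanged)."""
    norms = np.linalg.norm(W, axis=0)
    norms = np.where(norms > 0, norms, 1.0)
    return W / norms, C * norms[:, None]


@dataclass
class SynergyDecomposition:
    """Result of one NNMF run: factors, diagnostics and provenance."""

    W: np.ndarray  # (m, k), unit-norm columns
    C: np.ndarray  # (k, n_total)
    k: int
    vaf_global: float
    vaf_local: np.ndarray
    loss_trace: np.ndarray  # cost per iteration of the winning restart
    seed: int | None = None
    n_restarts: int = 1
    converged: bool = True
    subject_id: str | None = None
    group: str | None = None

    @property
    def loss(self) -> float:
        return float(self.loss_trace[-1])


def nnmf_decompose(
    V: np.ndarray,
    k: int,
    seed: int | None = None,
    n_restarts: int = 20,
    max_iter: int = 1000,
    tol: float = 1e-6,
    W0: np.ndarray | None = None,
    C0: np.ndarray | None = None,
    **meta,
) -> SynergyDecomposition:
    """Best-of-restarts multiplicative-update NNMF.

    Each restart starts from uniform random factors in (0, 1] and runs
    alternating multiplicative updates until the relative cost change
    drops below ``tol`` or ``max_iter`` iterations. The restart with the
    lowest final cost wins. Passing ``W0``/``C0`` pins the initialization
    (single run; used for cross-implementation checks).

    Fixed ``seed`` + identical inputs give bit-identical output.
    """
    V = np.asarray(V, dtype=float)
    if V.ndim != 2:
        raise DataError("V must be 2-D (muscles x time)")
    if np.any(V < 0):
        raise DataError("V must be non-negative")
    m, n = V.shape
    if not 1 <= k <= m:
        raise DataError(f"k={k} outside 1..{m}")
    if np.all(V.sum(axis=1) == 0):
        raise DataError("V is all zero")

    rng = np.random.default_rng(seed)
    pinned = W0 is not None or C0 is not None
    restarts = 1 if pinned else n_restarts

    best: tuple[float, np.ndarray, np.ndarray, np.ndarray, bool] | None = None
    for _ in range(restarts):
        if pinned:
            W = np.array(W0, dtype=float, copy=True)
            C = np.array(C0, dtype=float, copy=True)
        else:
            # uniform in (0, 1]: strictly positive so no entry is locked at 0
            W = 1.0 - rng.random((m, k))
            C = 1.0 - rng.random((k, n))
        trace = [frobenius_loss(V, W, C)]
        converged = False
        for _it in range(max_iter):
            W, C = update_step(V, W, C)
            loss = frobenius_loss(V, W, C)
            trace.append(loss)
            prev = trace[-2]
            if prev - loss <= tol * max(prev, EPS_DIV):
                converged = True
                break
        if best is None or trace[-1] < best[0]:
            best = (trace[-1], W, C, np.asarray(trace), converged)

    _, W, C, trace, converged = best
    W, C = _normalize_columns(W, C)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        local = vaf_local(V, W, C)
    return SynergyDecomposition(
        W=W,
        C=C,
        k=k,
        vaf_global=vaf_global(V, W, C),
        vaf_local=local,
        loss_trace=trace,
        seed=seed,
        n_restarts=restarts,
        converged=converged,
        **meta,
    )


@dataclass
class RankSelectionResult:
    """Dual-VAF synergy-number selection across k = 1..k_max."""

    n_opt: int
    decompositions: dict[int, SynergyDecomposition]
    vaf_g_min: float
    vaf_l_min: float
    thresholds_met: bool  # False => fell through to k_max

    @property
    def selected(self) -> SynergyDecomposition:
        return self.decompositions[self.n_opt]

    def vaf_table(self) -> list[dict]:
        """Per-k VAF summary rows (for the VAF-vs-k curve)."""
        return [
            {
                "k": k,
                "vaf_global": d.vaf_global,
                "vaf_local_min": float(np.nanmin(d.vaf_local)),
            }
            for k, d in sorted(self.decompositions.items())
        ]


def select_synergy_number(
    V: np.ndarray,
    k_max: int = 8,
    vaf_g_min: float = 0.90,
    vaf_l_min: float = 0.75,
    seed: int | None = None,
    n_restarts: int = 20,
    max_iter: int = 1000,
    tol: float = 1e-6,
    strict: bool = False,
    **meta,
) -> RankSelectionResult:
    """Smallest k with global VAF >= 90 % and every muscle VAF >= 75 %.

    Thresholds are compared non-strictly within 1e-12 (``strict=True``
    switches to a strict ``>``). If no k in 1..k_max qualifies, k_max is
    returned with ``thresholds_met=False``. NaN local VAFs (all-zero
    muscle rows) are ignored.
    """
    V = np.asarray(V, dtype=float)
    k_max = min(k_max, V.shape[0])
    decomps: dict[int, SynergyDecomposition] = {}
    n_opt = None
    for k in range(1, k_max + 1):
        d = nnmf_decompose(
            V, k, seed=seed, n_restarts=n_restarts, max_iter=max_iter, tol=tol, **meta
        )
        decomps[k] = d
        local_min = np.nanmin(d.vaf_local)
        if strict:
            ok = d.vaf_global > vaf_g_min and local_min > vaf_l_min
        else:
            ok = (d.vaf_global >= vaf_g_min - 1e-12) and (local_min >= vaf_l_min - 1e-12)
        if ok:
            n_opt = k
            break
    met = n_opt is not None
    return RankSelectionResult(
        n_opt=n_opt if met else k_max,
        decompositions=decomps,
        vaf_g_min=vaf_g_min,
        vaf_l_min=vaf_l_min,
        thresholds_met=met,
    )


def assemble_data_matrix(trials: list[np.ndarray]) -> np.ndarray:
    """Concatenate per-trial (m, n_points) activation matrices column-wise."""
    if not trials:
        raise DataError("no trials to assemble")
    m = trials[0].shape[0]
    if any(t.shape[0] != m for t in trials):
        raise DataError("trials disagree on muscle count")
    return np.concatenate([np.asarray(t, float) for t in trials], axis=1)
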