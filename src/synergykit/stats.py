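"""Group statistics on synergy weights and activation-coefficient curves.

Scalar weight comparisons are routed by assumption checks: Shapiro–Wilk
normality on each group plus Levene's homogeneity of variance; when both
hold the pooled-variance two-sample t-test is used, otherwise the
Wilcoxon rank-sum test. Effect sizes are Cohen's d with the pooled
standard deviation.

Whole-curve comparisons of activation coefficients use 1-D statistical
parametric mapping: a pointwise two-sample t statistic over the 101
phase nodes, with a field-wide critical threshold taken as the (1-alpha)
quantile of the max-|t| distribution under group-label permutation.
Supra-threshold clusters are reported as phase intervals with
permutation p-values on their extent.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from itertools import combinations

import numpy as np
import pandas as pd
from scipy import stats as sps

from .io import DataError
from .sorting import SynergyMatch


# ---------------------------------------------------------------------------
# scalar tests


def route_and_test(x1, x2, alpha: float = 0.05) -> tuple[str, float, float]:
    """Assumption-routed two-sample comparison.

    Shapiro–Wilk on each sample and Levene's test (mean-centered) across
    samples, both at ``alpha``; all passing routes to the pooled-variance
    independent t-test, any failure to the Wilcoxon rank-sum test
    (exact null distribution when both n <= 25 and there are no ties,
    normal approximation with tie correction otherwise). Two-sided.

    Returns ``(test_name, statistic, p)`` with test_name in
    {"t", "wilcoxon"}.
    """
    x1 = np.asarray(x1, dtype=float)
    x2 = np.asarray(x2, dtype=float)
    if x1.size < 3 or x2.size < 3:
        raise DataError("each group needs at least 3 observations")
    if np.ptp(x1) == 0 and np.ptp(x2) == 0:
        raise DataError("both groups have zero variance; no test applies")

    def _normal(x) -> bool:
        if np.ptp(x) == 0:
            return False
        return sps.shapiro(x).pvalue > alpha

    homogeneous = sps.levene(x1, x2, center="mean").pvalue > alpha
    if _normal(x1) and _normal(x2) and homogeneous:
        res = sps.ttest_ind(x1, x2, equal_var=True)
        return "t", float(res.statistic), float(res.pvalue)
    pooled = np.concatenate([x1, x2])
    no_ties = np.unique(pooled).size == pooled.size
    method = "exact" if (no_ties and max(x1.size, x2.size) <= 25) else "asymptotic"
    res = sps.mannwhitneyu(x1, x2, alternative="two-sided", method=method)
    return "wilcoxon", float(res.statistic), float(res.pvalue)


def cohens_d(
    mean1: float, sd1: float, n1: int, mean2: float, sd2: float, n2: int
) -> float:
    """Cohen's d from summary statistics with pooled SD.

    d = (mean1 - mean2) / s_p,
    s_p = sqrt(((n1-1) sd1^2 + (n2-1) sd2^2) / (n1 + n2 - 2)).
    """
    if n1 < 2 or n2 < 2:
        raise DataError("Cohen's d needs n >= 2 per group")
    if sd1 < 0 or sd2 < 0:
        raise DataError("standard deviations must be non-negative")
    sp = np.sqrt(((n1 - 1) * sd1**2 + (n2 - 1) * sd2**2) / (n1 + n2 - 2))
    if sp == 0:
        raise DataError("pooled SD is zero; effect size undefined")
    return float((mean1 - mean2) / sp)


def cohens_d_from_samples(x1, x2) -> float:
    x1 = np.asarray(x1, float)
    x2 = np.asarray(x2, float)
    return cohens_d(
        x1.mean(), x1.std(ddof=1), x1.size, x2.mean(), x2.std(ddof=1), x2.size
    )


def effect_size_label(d: float) -> str:
    """Conventional magnitude bands for |d|.

    <0.2 small, 0.2–0.5 medium, 0.8+ large; the 0.5–0.8 gap (absent from
    some conventions) is labeled "medium-large".
    """
    m = abs(d)
    if m < 0.2:
        return "small"
    if m < 0.5:
        return "medium"
    if m < 0.8:
        return "medium-large"
    return "large"


# ---------------------------------------------------------------------------
# 1-D statistical parametric mapping (permutation max-statistic)


@dataclass
class SPMCluster:
    start_pct: float
    end_pct: float
    p: float


@dataclass
class SPMResult:
    """Pointwise t curve, field-wide threshold and supra-threshold clusters."""

    t_curve: np.ndarray
    threshold: float
    clusters: list[SPMCluster]
    alpha: float
    method: str = "permutation"

    @property
    def significant(self) -> bool:
        return bool(self.clusters)


def _t_curves(X: np.ndarray, member1: np.ndarray, n1: int, n2: int) -> np.ndarray:
    """Pointwise pooled-variance t statistic for many label permutations.

    ``member1`` is a (n_perm, n) 0/1 matrix selecting group-1 rows per
    permutation; returns (n_perm, n_nodes).
    """
    S = member1 @ X
    Q = member1 @ (X * X)
    tot = X.sum(axis=0)
    tot2 = (X * X).sum(axis=0)
    m1 = S / n1
    m2 = (tot - S) / n2
    ss1 = Q - n1 * m1**2
    ss2 = (tot2 - Q) - n2 * m2**2
    sp2 = (ss1 + ss2) / (n1 + n2 - 2)
    denom = np.sqrt(sp2 * (1.0 / n1 + 1.0 / n2))
    with np.errstate(divide="ignore", invalid="ignore"):
        t = (m1 - m2) / denom
    return np.nan_to_num(t, nan=0.0, posinf=0.0, neginf=0.0)


def _clusters_above(absT: np.ndarray, thr: float) -> list[tuple[int, int]]:
    """Maximal runs of nodes where |t| exceeds thr, as (start, end) indices."""
    above = absT > thr
    runs = []
    start = None
    for idx, flag in enumerate(above):
        if flag and start is None:
            start = idx
        elif not flag and start is not None:
            runs.append((start, idx - 1))
            start = None
    if start is not None:
        runs.append((start, len(above) - 1))
    return runs


def spm_compare_curves(
    curves1: np.ndarray,
    curves2: np.ndarray,
    alpha: float = 0.05,
    n_perm: int = 10000,
    seed: int | None = None,
    method: str = "permutation",
) -> SPMResult:
    """Compare two groups of phase-normalized curves node-by-node.

    ``curves1``/``curves2`` are (n_subjects, n_nodes). The observed
    statistic is the pooled-variance two-sample t at every node; the
    critical threshold is the (1 - alpha) quantile of max over nodes of
    |t| across ``n_perm`` random group-label permutations (two-sided
    field-wide control). Cluster p-values are permutation tail
    probabilities of supra-threshold cluster extent.

    ``method="rft"`` delegates to spm1d's random-field-theory two-sample
    test when that package is installed (validation aid only).
    """
    X1 = np.asarray(curves1, dtype=float)
    X2 = np.asarray(curves2, dtype=float)
    if X1.ndim != 2 or X2.ndim != 2 or X1.shape[1] != X2.shape[1]:
        raise DataError("curve sets must be 2-D with matching node counts")
    n1, n2 = X1.shape[0], X2.shape[0]
    if n1 < 3 or n2 < 3:
        raise DataError("each group needs at least 3 curves")
    X = np.vstack([X1, X2])
    if np.ptp(X, axis=0).max() == 0:
        raise DataError("degenerate constant curves; SPM undefined")

    if method == "rft":
        return _spm_rft(X1, X2, alpha)
    if method != "permutation":
        raise DataError(f"unknown SPM method {method!r}")
    if n_perm < 100:
        warnings.warn(f"n_perm={n_perm} is very low; threshold will be unstable", stacklevel=2)

    n = n1 + n2
    nodes = X.shape[1]
    obs_member = np.zeros((1, n))
    obs_member[0, :n1] = 1.0
    t_obs = _t_curves(X, obs_member, n1, n2)[0]

    # permutation null of the field-wide max |t|; the observed labeling is
    # included as one member of the distribution and the threshold takes
    # the conservative ('higher') order statistic, keeping the field-wise
    # error at or below alpha.
    rng = np.random.default_rng(seed)
    member = np.zeros((n_perm, n))
    member[0, :n1] = 1.0  # identity permutation
    for p in range(1, n_perm):
        member[p, rng.permutation(n)[:n1]] = 1.0
    t_perm = _t_curves(X, member, n1, n2)
    max_abs = np.abs(t_perm).max(axis=1)
    threshold = float(np.quantile(max_abs, 1.0 - alpha, method="higher"))

    pct = np.linspace(0.0, 100.0, nodes)
    clusters = []
    runs = _clusters_above(np.abs(t_obs), threshold)
    if runs:
        # null distribution of the largest supra-threshold cluster extent
        perm_extents = np.zeros(n_perm)
        for p in range(n_perm):
            pruns = _clusters_above(np.abs(t_perm[p]), threshold)
            if pruns:
                perm_extents[p] = max(e - s + 1 for s, e in pruns)
        for s, e in runs:
            extent = e - s + 1
            p_clu = float((perm_extents >= extent).mean())
            clusters.append(SPMCluster(start_pct=pct[s], end_pct=pct[e], p=p_clu))
    return SPMResult(
        t_curve=t_obs, threshold=threshold, clusters=clusters, alpha=alpha
    )


def _spm_rft(X1: np.ndarray, X2: np.ndarray, alpha: float) -> SPMResult:
    try:
        import spm1d  # type: ignore
    except ImportError as exc:  # pragma: no cover - optional dependency
        raise ImportError(
            "method='rft' requires the optional spm1d package; "
            "use the default permutation method instead"
        ) from exc
    t = spm1d.stats.ttest2(X1, X2, equal_var=True)  # pragma: no cover
    ti = t.inference(alpha, two_tailed=True)  # pragma: no cover
    pct = np.linspace(0.0, 100.0, X1.shape[1])  # pragma: no cover
    clusters = [  # pragma: no cover
        SPMCluster(start_pct=float(c.endpoints[0]), end_pct=float(c.endpoints[1]), p=float(c.P))
        for c in ti.clusters
    ]
    return SPMResult(  # pragma: no cover
        t_curve=np.asarray(t.z), threshold=float(ti.zstar), clusters=clusters,
        alpha=alpha, method="rft",
    )


# ---------------------------------------------------------------------------
# synergy-weight comparison tables


def weights_by_reference(
    matches: list[SynergyMatch], n_refs: int
) -> dict[int, np.ndarray]:
    """Per reference synergy: (n_subjects, m) matrix of matched weights.

    If a subject has several synergies classified to the same reference,
    the one with the highest r represents that subject. Unclassified
    synergies are dropped; subjects without a match to a reference are
    absent from that reference's matrix.
    """
    per_ref: dict[int, dict[str, SynergyMatch]] = {r: {} for r in range(n_refs)}
    for m in matches:
        if not m.classified:
            continue
        sid = m.subject_id or f"synergy{m.synergy_index}"
        cur = per_ref[m.best_ref].get(sid)
        if cur is None or m.r > cur.r:
            per_ref[m.best_ref][sid] = m
    return {
        r: np.array([mm.weights for mm in sorted(d.values(), key=lambda x: str(x.subject_id))])
        for r, d in per_ref.items()
        if d
    }


def compare_group_weights(
    matches1: list[SynergyMatch],
    matches2: list[SynergyMatch],
    n_refs: int,
    muscle_names: tuple[str, ...],
    alpha: float = 0.05,
    group_names: tuple[str, str] = ("CAI", "healthy"),
) -> pd.DataFrame:
    """Reference-synergy x muscle comparison table between two groups.

    For every (reference synergy, muscle) cell: group means/SDs, the
    routed test and its p-value, and Cohen's d (group1 - group2 sign
    convention). References missing from either group are skipped with a
    warning.
    """
    w1 = weights_by_reference(matches1, n_refs)
    w2 = weights_by_reference(matches2, n_refs)
    rows = []
    for ref in range(n_refs):
        if ref not in w1 or ref not in w2:
            warnings.warn(
                f"reference synergy {ref} missing from a group; skipped", stacklevel=2
            )
            continue
        A, B = w1[ref], w2[ref]
        for mi, muscle in enumerate(muscle_names):
            a, b = A[:, mi], B[:, mi]
            try:
                test, stat, p = route_and_test(a, b, alpha)
                d = cohens_d_from_samples(a, b)
            except DataError:
                test, stat, p, d = "none", np.nan, np.nan, np.nan
            rows.append(
                {
                    "synergy": ref + 1,
                    "muscle": muscle,
                    f"mean_{group_names[0]}": a.mean(),
                    f"sd_{group_names[0]}": a.std(ddof=1) if a.size > 1 else np.nan,
                    f"n_{group_names[0]}": a.size,
                    f"mean_{group_names[1]}": b.mean(),
                    f"sd_{group_names[1]}": b.std(ddof=1) if b.size > 1 else np.nan,
                    f"n_{group_names[1]}": b.size,
                    "test": test,
                    "p": p,
                    "cohens_d": d,
                    "effect": effect_size_label(d) if np.isfinite(d) else "n/a",
                    "significant": bool(p < alpha) if np.isfinite(p) else False,
                }
            )
    return pd.DataFrame(rows)
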