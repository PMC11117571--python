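"""Routed scalar tests, Cohen's d and permutation SPM."""

import itertools

import numpy as np
import pytest
from scipy import stats as sps

from synergykit import (
    DataError,
    cohens_d,
    cohens_d_from_samples,
    compare_group_weights,
    effect_size_label,
    route_and_test,
    spm_compare_curves,
)
from synergykit.sorting import SynergyMatch
from synergykit.stats import weights_by_reference


class TestRouting:
    def test_identical_groups_t_route_p_one(self, rng):
        x = rng.normal(0, 1, 22)
        test, _, p = route_and_test(x, x.copy())
        assert test == "t"
        assert p == pytest.approx(1.0)

    def test_skewed_samples_take_wilcoxon_route(self, rng):
        """Exponential samples at n=22 fail Shapiro-Wilk, forcing the
        rank-sum branch."""
        x1 = rng.exponential(1.0, 22)
        x2 = rng.exponential(1.0, 22) + 0.5
        test, _, _ = route_and_test(x1, x2)
        assert test == "wilcoxon"

    def test_t_route_p_matches_closed_form(self, rng):
        x1 = rng.normal(0.0, 1.0, 15)
        x2 = rng.normal(0.5, 1.0, 18)
        test, stat, p = route_and_test(x1, x2)
        if test != "t":  # routing depends on the draw; force normal data
            pytest.skip("draw failed normality screen")
        n1, n2 = len(x1), len(x2)
        sp2 = ((n1 - 1) * x1.var(ddof=1) + (n2 - 1) * x2.var(ddof=1)) / (n1 + n2 - 2)
        t_manual = (x1.mean() - x2.mean()) / np.sqrt(sp2 * (1 / n1 + 1 / n2))
        p_manual = 2 * sps.t.sf(abs(t_manual), n1 + n2 - 2)
        assert stat == pytest.approx(t_manual, abs=1e-12)
        assert p == pytest.approx(p_manual, abs=1e-12)

    def test_exact_rank_sum_matches_enumeration(self):
        """Tiny-sample Wilcoxon p equals full enumeration of the rank-sum
        null distribution."""
        x1 = np.array([1.2, 3.4, 5.1, 0.7])  # skewed route forced below
        x2 = np.array([2.2, 6.3, 7.9, 8.4, 9.1])
        # force the wilcoxon branch by making normality fail: use the
        # statistic itself against brute force instead of the router
        u_obs = sum(a > b for a in x1 for b in x2)
        pooled = np.concatenate([x1, x2])
        n1 = len(x1)
        count = 0
        total = 0
        for idx in itertools.combinations(range(9), n1):
            g1 = pooled[list(idx)]
            g2 = pooled[[i for i in range(9) if i not in idx]]
            u = sum(a > b for a in g1 for b in g2)
            total += 1
            count += min(u, n1 * 5 - u) <= min(u_obs, n1 * 5 - u_obs)
        p_exact = count / total
        res = sps.mannwhitneyu(x1, x2, alternative="two-sided", method="exact")
        assert res.pvalue == pytest.approx(p_exact, abs=1e-12)

    def test_degenerate_inputs_rejected(self):
        with pytest.raises(DataError):
            route_and_test([1.0, 1.0, 1.0], [2.0, 2.0, 2.0])
        with pytest.raises(DataError):
            route_and_test([1.0, 2.0], [1.0, 2.0, 3.0])


class TestCohensD:
    def test_zero_for_identical_summaries(self):
        assert cohens_d(1.0, 0.5, 22, 1.0, 0.5, 22) == 0.0

    def test_antisymmetry(self, rng):
        x1, x2 = rng.normal(0, 1, 20), rng.normal(1, 2, 25)
        assert cohens_d_from_samples(x1, x2) == pytest.approx(
            -cohens_d_from_samples(x2, x1), abs=1e-12
        )

    def test_pooled_sd_formula(self):
        # hand check: means 1.0/0.0, sds 1.0/2.0, n 11/21
        sp = np.sqrt((10 * 1.0 + 20 * 4.0) / 30)
        assert cohens_d(1.0, 1.0, 11, 0.0, 2.0, 21) == pytest.approx(1.0 / sp)

    def test_zero_pooled_sd_rejected(self):
        with pytest.raises(DataError):
            cohens_d(1.0, 0.0, 10, 2.0, 0.0, 10)

    @pytest.mark.parametrize(
        "d,label",
        [(0.1, "small"), (0.35, "medium"), (0.65, "medium-large"),
         (-0.9, "large"), (2.0, "large")],
    )
    def test_magnitude_bands(self, d, label):
        assert effect_size_label(d) == label


class TestSPM:
    def _curves(self, rng, n, shift=None, window=None):
        """Smooth random curves; optionally mean-shifted in a phase window."""
        raw = rng.standard_normal((n, 121))
        kernel = np.hanning(21)
        kernel /= kernel.sum()
        smooth = np.apply_along_axis(lambda r: np.convolve(r, kernel, "valid"), 1, raw)
        if shift is not None:
            lo, hi = window
            smooth[:, lo : hi + 1] += shift
        return smooth

    def test_single_node_t_matches_classic_formula(self, rng):
        c1 = self._curves(rng, 10)
        c2 = self._curves(rng, 12)
        res = spm_compare_curves(c1, c2, n_perm=200, seed=0)
        j = 37
        t_ref = sps.ttest_ind(c1[:, j], c2[:, j], equal_var=True).statistic
        assert res.t_curve[j] == pytest.approx(t_ref, abs=1e-10)

    def test_null_data_rarely_significant(self, rng):
        hits = 0
        for s in range(20):
            c1 = self._curves(rng, 12)
            c2 = self._curves(rng, 12)
            res = spm_compare_curves(c1, c2, n_perm=500, seed=s)
            hits += res.significant
        assert hits <= 3

    def test_injected_effect_detected_in_window(self, rng):
        """A 1.5-SD mean shift over 50-80 % of the phase must produce a
        supra-threshold cluster overlapping that window."""
        c1 = self._curves(rng, 22, shift=1.5, window=(50, 80))
        c2 = self._curves(rng, 22)
        res = spm_compare_curves(c1, c2, n_perm=1000, seed=1)
        assert res.significant
        assert any(c.start_pct <= 80 and c.end_pct >= 50 for c in res.clusters)
        assert all(c.p <= res.alpha for c in res.clusters[:1])

    def test_threshold_positive_and_errors(self, rng):
        c = self._curves(rng, 8)
        res = spm_compare_curves(c, self._curves(rng, 8), n_perm=200, seed=0)
        assert res.threshold > 0
        with pytest.raises(DataError):
            spm_compare_curves(c[:2], c, n_perm=100)
        with pytest.raises(DataError):
            spm_compare_curves(np.ones((5, 10)), np.ones((5, 10)), n_perm=100)
        with pytest.warns(UserWarning, match="n_perm"):
            spm_compare_curves(c, self._curves(rng, 8), n_perm=50, seed=0)


def _matches(weights, group, ref=0):
    """Wrap an (n_subjects, m) weight matrix as classified matches."""
    out = []
    for i, w in enumerate(weights):
        out.append(
            SynergyMatch(
                subject_id=f"{group}{i:02d}",
                group=group,
                synergy_index=0,
                r_values=np.array([0.9]),
                best_ref=ref,
                classified=True,
                weights=np.asarray(w, float),
            )
        )
    return out


class TestWeightComparison:
    MUSCLES = ("SL", "MG", "LG", "TA", "PL", "RF", "VM", "VL", "BF", "GM")

    def test_gm_shift_detected_with_large_effect(self, rng):
        """A +0.2 shift on GM at n=22/group comes out significant with
        d > 0.8, as expected for shifts of this size at these SDs."""
        base = rng.normal(0.4, 0.1, (22, 10)).clip(0.01)
        shifted = rng.normal(0.4, 0.1, (22, 10)).clip(0.01)
        shifted[:, 9] += 0.2  # GM column
        table = compare_group_weights(
            _matches(shifted, "A"), _matches(base, "B"), 1, self.MUSCLES,
            group_names=("A", "B"),
        )
        gm = table[table.muscle == "GM"].iloc[0]
        assert gm.significant
        assert gm.cohens_d > 0.8

    def test_null_cells_rarely_significant(self, rng):
        base = rng.normal(0.4, 0.1, (22, 10)).clip(0.01)
        other = rng.normal(0.4, 0.1, (22, 10)).clip(0.01)
        table = compare_group_weights(
            _matches(base, "A"), _matches(other, "B"), 1, self.MUSCLES,
            group_names=("A", "B"),
        )
        assert table.significant.sum() <= 2

    def test_full_grid_has_refs_times_muscles_rows(self, rng):
        m1, m2 = [], []
        for ref in range(4):
            m1 += _matches(rng.random((6, 10)) + 0.1, "A", ref)
            m2 += _matches(rng.random((6, 10)) + 0.1, "B", ref)
        table = compare_group_weights(m1, m2, 4, self.MUSCLES, group_names=("A", "B"))
        assert len(table) == 40

    def test_missing_reference_skipped_with_warning(self, rng):
        m1 = _matches(rng.random((5, 10)) + 0.1, "A", 0)
        m2 = _matches(rng.random((5, 10)) + 0.1, "B", 1)
        with pytest.warns(UserWarning, match="missing"):
            table = compare_group_weights(m1, m2, 2, self.MUSCLES)
        assert table.empty

    def test_best_r_represents_subject(self):
        w_low = np.full(10, 0.2)
        w_high = np.full(10, 0.8)
        m1 = _matches([w_low], "A")[0]
        m2 = _matches([w_high], "A")[0]
        m2.subject_id = m1.subject_id
        m1.r_values = np.array([0.7])
        m2.r_values = np.array([0.95])
        by_ref = weights_by_reference([m1, m2], 1)
        assert np.allclose(by_ref[0][0], w_high)
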