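"""Per-wavenumber t-tests, BH correction, AUROC, band runs, annotations."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy import stats

from sersdisc.chemometrics import plsda_fit, vip_scores
from sersdisc.types import CONTROL, PATIENT
from sersdisc.univariate import (
    auroc_per_wavenumber,
    bh_correct,
    detect_peaks,
    mean_spectra_with_annotations,
    significant_bands,
    t_test_per_wavenumber,
)

from conftest import make_dataset


def _two_group(ctrl_rows, pat_rows):
    ctrl_rows = np.atleast_2d(np.asarray(ctrl_rows, float))
    pat_rows = np.atleast_2d(np.asarray(pat_rows, float))
    labels = [CONTROL] * ctrl_rows.shape[0] + [PATIENT] * pat_rows.shape[0]
    return make_dataset(np.vstack([ctrl_rows, pat_rows]), labels)


class TestTTest:
    def test_identical_groups_null(self):
        rows = [[1.0, 5.0], [2.0, 6.0], [3.0, 7.0]]
        ds = _two_group(rows, rows)
        prof = t_test_per_wavenumber(ds)
        np.testing.assert_allclose(prof.t_stat, 0.0, atol=1e-12)
        np.testing.assert_allclose(prof.p_value, 1.0, atol=1e-12)

    def test_separation_limit(self, rng):
        jitter = 1e-9 * rng.normal(size=(4, 1))
        ds = _two_group(np.zeros((4, 1)) + jitter,
                        np.ones((4, 1)) + 1e-9 * rng.normal(size=(4, 1)))
        prof = t_test_per_wavenumber(ds)
        assert prof.p_value[0] < 1e-12

    def test_student_hand_computation(self):
        """Patients (1..5) vs controls (2..6): pooled sd √2.5 gives t = −1."""
        ds = _two_group(np.array([[2.0], [3.0], [4.0], [5.0], [6.0]]),
                        np.array([[1.0], [2.0], [3.0], [4.0], [5.0]]))
        prof = t_test_per_wavenumber(ds, variant="student")
        assert prof.t_stat[0] == pytest.approx(-1.0, abs=1e-12)

    @pytest.mark.parametrize("variant,equal_var", [("welch", False),
                                                   ("student", True)])
    def test_matches_scipy_reference(self, rng, variant, equal_var):
        X = rng.normal(size=(20, 30))
        X[12:] += rng.normal(scale=0.5, size=(8, 30))
        ds = make_dataset(X, [CONTROL] * 12 + [PATIENT] * 8)
        prof = t_test_per_wavenumber(ds, variant=variant)
        ref = stats.ttest_ind(X[12:], X[:12], equal_var=equal_var, axis=0)
        np.testing.assert_allclose(prof.t_stat, ref.statistic, atol=1e-10)
        np.testing.assert_allclose(prof.p_value, ref.pvalue, atol=1e-10)

    def test_zero_variance_column_flagged(self):
        ds = _two_group([[5.0, 1.0], [5.0, 2.0]], [[5.0, 3.0], [5.0, 4.0]])
        prof = t_test_per_wavenumber(ds)
        assert prof.p_value[0] == 1.0
        assert list(prof.zero_variance_columns) == [0]


class TestBH:
    def test_step_up_by_hand(self):
        mask = bh_correct(np.array([0.01, 0.02, 0.03, 0.04]), fdr=0.05)
        assert mask.all()  # p_(4) = 0.04 ≤ 4·0.05/4

    def test_all_ones_rejects_none(self):
        assert not bh_correct(np.ones(10), fdr=0.05).any()

    def test_single_p_reduces_to_alpha(self):
        assert bh_correct(np.array([0.04]), fdr=0.05)[0]
        assert not bh_correct(np.array([0.06]), fdr=0.05)[0]

    def test_matches_statsmodels(self, rng):
        from statsmodels.stats.multitest import multipletests

        p = rng.uniform(size=200) ** 2
        mask = bh_correct(p, fdr=0.05)
        ref = multipletests(p, alpha=0.05, method="fdr_bh")[0]
        np.testing.assert_array_equal(mask, ref)

    @settings(max_examples=30, deadline=None, derandomize=True)
    @given(seed=st.integers(0, 10_000),
           alphas=st.tuples(st.floats(0.01, 0.2), st.floats(0.01, 0.2)))
    def test_monotone_in_fdr(self, seed, alphas):
        """BH at a larger FDR rejects a superset of BH at a smaller one."""
        lo, hi = sorted(alphas)
        p = np.random.default_rng(seed).uniform(size=50)
        small = bh_correct(p, fdr=lo)
        large = bh_correct(p, fdr=hi)
        assert np.all(large[small])

    def test_out_of_range_p_rejected(self):
        with pytest.raises(ValueError):
            bh_correct(np.array([0.5, 1.2]))


class TestAUROC:
    def test_perfect_separation(self):
        ds = _two_group([[1.0], [2.0]], [[3.0], [4.0]])
        assert auroc_per_wavenumber(ds)[0] == 1.0

    def test_all_ties(self):
        ds = _two_group([[2.0], [2.0]], [[2.0], [2.0]])
        assert auroc_per_wavenumber(ds)[0] == 0.5

    def test_brute_force_pairs(self):
        """Patients (3, 5) vs controls (1, 4): 3 of 4 pairs won → 0.75."""
        ds = _two_group([[1.0], [4.0]], [[3.0], [5.0]])
        assert auroc_per_wavenumber(ds)[0] == pytest.approx(0.75)

    def test_matches_sklearn_with_ties(self, rng):
        from sklearn.metrics import roc_auc_score

        X = np.round(rng.normal(size=(25, 40)), 1)  # rounding makes ties
        labels = [CONTROL] * 11 + [PATIENT] * 14
        ds = make_dataset(X, labels)
        mine = auroc_per_wavenumber(ds)
        y = (np.array(labels, dtype=object) == PATIENT).astype(int)
        ref = np.array([roc_auc_score(y, X[:, j]) for j in range(40)])
        np.testing.assert_allclose(mine, ref, atol=1e-12)

    @settings(max_examples=20, deadline=None, derandomize=True)
    @given(seed=st.integers(0, 10_000))
    def test_complement_identity(self, seed):
        """AUROC(x) + AUROC(−x) = 1 per column."""
        rng = np.random.default_rng(seed)
        X = rng.normal(size=(12, 8))
        labels = [CONTROL] * 5 + [PATIENT] * 7
        a = auroc_per_wavenumber(make_dataset(X, labels))
        b = auroc_per_wavenumber(make_dataset(-X, labels))
        np.testing.assert_allclose(a + b, 1.0, atol=1e-12)


class TestSignificantBands:
    GRID = np.arange(0.0, 30.0)

    def test_all_false_empty(self):
        assert significant_bands(np.zeros(30, bool), self.GRID).runs == ()

    def test_all_true_single_run(self):
        grid = np.arange(350.0, 2201.0)
        runs = significant_bands(np.ones(grid.size, bool), grid).runs
        assert runs == ((350.0, 2200.0),)

    def test_short_runs_dropped(self):
        mask = np.zeros(30, bool)
        mask[10:15] = True  # length 5 → kept
        mask[20:22] = True  # length 2 → dropped
        runs = significant_bands(mask, self.GRID, min_run_length=3).runs
        assert runs == ((10.0, 14.0),)


class TestAnnotations:
    def test_flat_classes_no_peaks(self):
        assert detect_peaks(np.arange(50.0), np.full(50, 2.0)).size == 0

    def test_lorentzian_apex_recovered(self):
        grid = np.arange(900.0, 1100.0)
        spec = 1.0 / (1.0 + ((grid - 1010.0) / 8.0) ** 2)
        peaks = detect_peaks(grid, spec)
        assert len(peaks) == 1
        assert abs(peaks[0] - 1010.0) <= 2.0

    def test_summary_reports_classwise_and_grouped_peaks(self, rng):
        import matplotlib.pyplot as plt

        grid = np.arange(400.0, 700.0)
        ctrl = np.exp(-0.5 * ((grid - 500.0) / 10.0) ** 2)
        pat = np.exp(-0.5 * ((grid - 510.0) / 10.0) ** 2)
        X = np.vstack(
            [np.tile(ctrl, (3, 1)) + 2e-3 * rng.normal(size=(3, 300)),
             np.tile(pat, (4, 1)) + 2e-3 * rng.normal(size=(4, 300))])
        ds = make_dataset(X, [CONTROL] * 3 + [PATIENT] * 4, grid=grid)
        prof = t_test_per_wavenumber(ds)
        vip = vip_scores(plsda_fit(ds.matrix, ds.labels, 2), wavenumber=grid)
        summary = mean_spectra_with_annotations(ds, prof, vip)
        assert set(summary["peaks"]) == {"control", "patient", "grouped"}
        assert np.min(np.abs(summary["peaks"]["control"] - 500.0)) <= 2.0
        assert np.min(np.abs(summary["peaks"]["patient"] - 510.0)) <= 2.0
        assert {"wavenumber", "t", "p", "bh_significant", "auroc", "vip",
                "vip_gt_1", "mean_control", "mean_patient"} <= set(
            summary["table"].columns
        )
        plt.close(summary["figure"])
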