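"""QC filters, TIC normalization and mean centering.

Each filter is checked against a one-line brute-force per-column predicate on
random small matrices, plus the boundary conventions (all thresholds strict).
"""

import numpy as np
import pandas as pd
import pytest

from lipidspot import (
    mean_center,
    normalize_tic,
    run_qc_pipeline,
    simulate_cohort,
)
from lipidspot.qc import (
    filter_blank_ratio,
    filter_mass_deviation,
    filter_missingness,
    filter_qc_linearity,
)
from lipidspot.spectra import Role, build_matrix, match_spectra
from tests.conftest import make_feature_matrix


class TestMassDeviationFilter:
    def _m(self, devs):
        devs = np.asarray(devs, dtype=float)
        return make_feature_matrix(np.ones_like(devs), devs)

    def test_boundary_five_ppm_retained(self):
        m = self._m([[5.0], [5.0]])  # mean |dev| exactly 5: "greater than 5" is strict
        out, entry = filter_mass_deviation(m)
        assert list(out.lipids) == ["lip0"]
        assert entry.lipids_removed == []

    def test_above_threshold_removed(self):
        out, entry = filter_mass_deviation(self._m([[5.1], [5.1]]))
        assert entry.lipids_removed == ["lip0"]

    def test_symmetric_errors_cancel_only_in_signed_mode(self):
        m = self._m([[4.0, 8.0], [-4.0, -8.0]])
        out_abs, _ = filter_mass_deviation(m, signed=False)
        assert list(out_abs.lipids) == ["lip0"]  # abs-mean 8 removes lip1
        out_signed, _ = filter_mass_deviation(m, signed=True)
        assert list(out_signed.lipids) == ["lip0", "lip1"]  # signed means are 0

    def test_never_matched_removed_distinctly(self):
        m = self._m([[np.nan], [np.nan]])
        out, entry = filter_mass_deviation(m)
        assert entry.lipids_removed == ["lip0"]
        assert entry.notes["never_matched"] == ["lip0"]


class TestBlankRatioFilter:
    def _pair(self, sample_means, blank_means):
        m = make_feature_matrix(np.tile(sample_means, (4, 1)).astype(float))
        b = make_feature_matrix(np.tile(blank_means, (2, 1)).astype(float),
                                roles=["blank", "blank"])
        return m, b

    def test_ratio_below_five_removed(self):
        m, b = self._pair([100.0], [25.0])  # ratio 4
        _, entry = filter_blank_ratio(m, b)
        assert entry.lipids_removed == ["lip0"]

    def test_ratio_exactly_five_retained(self):
        m, b = self._pair([100.0], [20.0])  # ratio 5, "less than 5x" is strict
        _, entry = filter_blank_ratio(m, b)
        assert entry.lipids_removed == []

    def test_zero_blank_retained(self):
        m, b = self._pair([50.0], [0.0])
        _, entry = filter_blank_ratio(m, b)
        assert entry.lipids_removed == []
        assert entry.notes["no_blank_signal"] == ["lip0"]


class TestMissingnessFilter:
    def _m(self, n, n_zero):
        col = np.ones((n, 1))
        col[:n_zero, 0] = 0.0
        return make_feature_matrix(col)

    def test_eleven_percent_removed(self):
        _, entry = filter_missingness(self._m(100, 11))
        assert entry.lipids_removed == ["lip0"]

    def test_exactly_ten_percent_retained(self):
        _, entry = filter_missingness(self._m(100, 10))
        assert entry.lipids_removed == []

    def test_complete_column_retained(self):
        _, entry = filter_missingness(self._m(100, 0))
        assert entry.lipids_removed == []


class TestDilutionLinearityFilter:
    def _qc(self, values):
        # one replicate per level, rows qc25/qc50/qc100
        arr = np.asarray(values, dtype=float).reshape(3, -1)
        return make_feature_matrix(arr, roles=["qc25", "qc50", "qc100"])

    def test_perfect_linearity_retained(self):
        m = make_feature_matrix(np.ones((3, 1)))
        _, entry = filter_qc_linearity(m, self._qc([1.0, 2.0, 4.0]))
        assert entry.lipids_removed == []

    def test_anticorrelated_removed(self):
        m = make_feature_matrix(np.ones((3, 1)))
        _, entry = filter_qc_linearity(m, self._qc([4.0, 2.0, 1.0]))
        assert entry.lipids_removed == ["lip0"]

    def test_flat_signal_removed_as_undefined(self):
        m = make_feature_matrix(np.ones((3, 1)))
        _, entry = filter_qc_linearity(m, self._qc([3.0, 3.0, 3.0]))
        assert entry.lipids_removed == ["lip0"]
        assert entry.notes["undefined_r"] == ["lip0"]


class TestFilterOracles:
    """Each filter equals a brute-force per-column predicate (100 random trials)."""

    def test_oracle_equivalence(self):
        rng = np.random.default_rng(99)
        for trial in range(100):
            n, p = rng.integers(3, 12), rng.integers(1, 8)
            intens = rng.uniform(0, 100, (n, p))
            intens[rng.random((n, p)) < 0.2] = 0.0
            devs = rng.normal(0, 4, (n, p))
            devs[intens == 0] = np.nan
            m = make_feature_matrix(intens, devs)
            blank = make_feature_matrix(
                rng.uniform(0, 30, (2, p)), roles=["blank", "blank"]
            )
            qc_roles = ["qc25", "qc50", "qc100"] * 2
            fracs = np.array([0.25, 0.5, 1.0] * 2)
            qc_vals = rng.uniform(0, 10, (6, p))
            qc = make_feature_matrix(qc_vals, roles=qc_roles)

            _, e1 = filter_mass_deviation(m)
            _, e2 = filter_blank_ratio(m, blank)
            _, e3 = filter_missingness(m)
            _, e4 = filter_qc_linearity(m, qc)

            for j, lip in enumerate(m.lipids):
                col_dev = devs[:, j][~np.isnan(devs[:, j])]
                want1 = col_dev.size == 0 or np.mean(np.abs(col_dev)) > 5.0
                assert (lip in e1.lipids_removed) == want1

                s_mean, b_mean = intens[:, j].mean(), blank.intensities.iloc[:, j].mean()
                want2 = b_mean > 0 and s_mean < 5.0 * b_mean
                assert (lip in e2.lipids_removed) == want2

                want3 = np.mean(intens[:, j] == 0) > 0.10
                assert (lip in e3.lipids_removed) == want3

                col = qc_vals[:, j]
                if np.std(col) == 0:
                    want4 = True
                else:
                    want4 = np.corrcoef(col, fracs)[0, 1] < 0.9
                assert (lip in e4.lipids_removed) == want4


class TestNormalizeCenter:
    def test_tic_rows_sum_to_one(self):
        m = make_feature_matrix(np.array([[2.0, 3.0, 5.0]]))
        out = normalize_tic(m)
        assert np.allclose(out.intensities.to_numpy(), [[0.2, 0.3, 0.5]])

    def test_single_lipid_all_ones(self):
        out = normalize_tic(make_feature_matrix(np.array([[7.0], [3.0]])))
        assert np.allclose(out.intensities.to_numpy(), 1.0)

    def test_idempotence(self):
        m = make_feature_matrix(np.random.default_rng(0).uniform(1, 9, (5, 4)))
        once = normalize_tic(m)
        twice = normalize_tic(once)
        pd.testing.assert_frame_equal(once.intensities, twice.intensities)

    def test_ratio_preservation(self):
        m = make_feature_matrix(np.random.default_rng(1).uniform(1, 9, (5, 4)))
        out = normalize_tic(m)
        before = m.intensities.iloc[:, 0] / m.intensities.iloc[:, 1]
        after = out.intensities.iloc[:, 0] / out.intensities.iloc[:, 1]
        assert np.allclose(before, after)

    def test_all_zero_sample_hard_error(self):
        m = make_feature_matrix(np.array([[1.0, 2.0], [0.0, 0.0]]))
        with pytest.raises(ValueError, match="s1"):
            normalize_tic(m)

    def test_mean_center_columns(self):
        m = make_feature_matrix(np.array([[0.2], [0.4]]))
        out = mean_center(m)
        assert np.allclose(out.intensities.to_numpy().ravel(), [-0.1, 0.1])
        again = mean_center(out)
        pd.testing.assert_frame_equal(out.intensities, again.intensities)

    def test_per_cohort_centering_semantics(self, rng):
        a = make_feature_matrix(rng.uniform(0, 1, (6, 3)), cohort_id="a")
        b = make_feature_matrix(rng.uniform(2, 3, (6, 3)), cohort_id="b")
        ca, cb = mean_center(a), mean_center(b)
        assert np.allclose(ca.intensities.mean(axis=0), 0, atol=1e-12)
        assert np.allclose(cb.intensities.mean(axis=0), 0, atol=1e-12)
        pooled = np.vstack([a.intensities.to_numpy(), b.intensities.to_numpy()])
        pooled_centered = np.vstack(
            [ca.intensities.to_numpy() + a.intensities.mean(axis=0).to_numpy(),
             cb.intensities.to_numpy() + b.intensities.mean(axis=0).to_numpy()]
        )
        assert np.allclose(pooled, pooled_centered)


class TestPipelineOnSyntheticCohort:
    def test_planted_failures_removed_and_clean_lipids_kept(self):
        cohort = simulate_cohort(
            __import__("lipidspot").CohortSpec(
                cohort_id="qc", n_subjects=120, n_lipids_detectable=60, seed=31
            )
        )
        signals = match_spectra(cohort.spectra, cohort.library, 10.0)
        roles = cohort.roles
        samples = build_matrix(signals, roles, Role.SAMPLE, "qc")
        blanks = build_matrix(signals, roles, Role.BLANK, "qc")
        qc_m = build_matrix(signals, roles, {Role.QC100, Role.QC50, Role.QC25}, "qc")
        processed, report = run_qc_pipeline(samples, blanks, qc_m)

        removed_by = {e.name: set(e.lipids_removed) for e in report.entries}
        assert set(cohort.fail_lipids["mass"]) <= removed_by["mass_deviation"]
        assert set(cohort.fail_lipids["blank"]) <= removed_by["blank_ratio"]
        assert set(cohort.fail_lipids["missing"]) <= removed_by["missingness"]
        assert set(cohort.fail_lipids["qc"]) <= removed_by["qc_linearity"]
        planted = set().union(*cohort.fail_lipids.values())
        clean = set(cohort.detectable) - planted
        assert clean <= set(processed.lipids)
        # order + monotone retention + normalized/centered output
        assert [e.name for e in report.entries] == [
            "mass_deviation", "blank_ratio", "missingness", "qc_linearity",
        ]
        sizes = [len(e.lipids_in) for e in report.entries] + [len(report.retained)]
        assert sizes == sorted(sizes, reverse=True)
        assert processed.transform_log[-2:] == ["tic_normalize", "mean_center"]
        assert np.allclose(processed.intensities.mean(axis=0), 0, atol=1e-12)

    def test_disabled_filters_pass_through(self):
        from lipidspot import CohortSpec

        cohort = simulate_cohort(
            CohortSpec(cohort_id="qc2", n_subjects=30, n_lipids_detectable=20,
                       n_fail_mass=1, n_fail_blank=1, n_fail_missing=1, n_fail_qc=1,
                       seed=7)
        )
        signals = match_spectra(cohort.spectra, cohort.library, 10.0)
        roles = cohort.roles
        samples = build_matrix(signals, roles, Role.SAMPLE, "qc2")
        blanks = build_matrix(signals, roles, Role.BLANK, "qc2")
        qc_m = build_matrix(signals, roles, {Role.QC100, Role.QC50, Role.QC25}, "qc2")
        processed, report = run_qc_pipeline(samples, blanks, qc_m, enabled=False)
        assert all(len(e.lipids_removed) == 0 for e in report.entries)
        assert list(processed.lipids) == list(samples.lipids)
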