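"""Synthetic-cohort generator: library spacing, clinical identities, spectra."""

import numpy as np
import pandas as pd
import pytest

from lipidspot import (
    CohortSpec,
    make_lipid_library,
    make_paired_cohorts,
    simulate_clinical,
    simulate_cohort,
)
from lipidspot.simulate import (
    DEFAULT_WINDOW_PPM,
    MZ_RANGE,
    default_association_map,
    friedewald_ldl,
    simulate_spectra,
)
from lipidspot.spectra import Role


class TestLipidLibrary:
    def test_single_target_in_range(self):
        (t,) = make_lipid_library(1, 1, seed=3)
        assert MZ_RANGE[0] <= t.expected_mz <= MZ_RANGE[1]

    def test_full_scale_library(self):
        lib = make_lipid_library(1649, 11, seed=1)
        assert len(lib) == 1649
        assert len({t.lipid_class for t in lib}) == 11
        assert len({t.name for t in lib}) == 1649
        mz = np.array([t.expected_mz for t in lib])
        assert np.all(np.diff(mz) > 0)
        assert mz.min() >= MZ_RANGE[0] and mz.max() <= MZ_RANGE[1]
        # adjacent spacing exceeds 3x the default match window
        rel_gap = np.diff(mz) / mz[:-1]
        assert rel_gap.min() > 3 * DEFAULT_WINDOW_PPM * 1e-6

    def test_seeded_determinism(self):
        a = make_lipid_library(10, 2, seed=7)
        b = make_lipid_library(10, 2, seed=7)
        assert a == b

    def test_oversized_library_rejected(self):
        with pytest.raises(ValueError, match="spacing"):
            make_lipid_library(200_000, 11, seed=0)

    def test_invalid_counts(self):
        with pytest.raises(ValueError):
            make_lipid_library(2, 5)


class TestSimulateClinical:
    def test_friedewald_exact_with_zero_variance(self):
        spec = CohortSpec(
            n_subjects=25,
            clinical_means={"TriG": 1.53, "HDL": 1.51, "TC": 5.83},
            clinical_sds={"TriG": 0.0, "HDL": 0.0, "TC": 0.0},
            seed=9,
        )
        clin = simulate_clinical(spec)
        expected_ldl = 5.83 - 1.51 - 1.53 / 2.2  # 3.62, Friedewald by hand
        assert np.allclose(clin["LDL"], expected_ldl)
        assert np.allclose(clin["LDL"], 3.62, atol=0.005)

    def test_zero_trig_degenerates_to_tc_minus_hdl(self):
        spec = CohortSpec(
            n_subjects=10,
            clinical_means={"TriG": 0.0, "HDL": 1.5, "TC": 5.0},
            clinical_sds={"TriG": 0.0, "HDL": 0.0, "TC": 0.0},
        )
        clin = simulate_clinical(spec)
        assert np.allclose(clin["LDL"], 5.0 - 1.5)

    def test_plasma_scale_moments(self):
        spec = CohortSpec(n_subjects=777, seed=42)
        clin = simulate_clinical(spec)
        se = 1.00 / np.sqrt(777)
        assert abs(clin["TriG"].mean() - 1.53) < 3 * se
        assert abs(clin["HDL"].mean() - 1.51) < 3 * 0.42 / np.sqrt(777)
        assert (clin[["TriG", "HDL", "LDL", "TC"]] > 0).all().all()

    def test_friedewald_linearity_of_means(self, rng):
        n = 500
        tc = rng.normal(5.8, 1.0, n)
        hdl = rng.normal(1.5, 0.3, n)
        trig = rng.lognormal(0.2, 0.4, n)
        ldl = friedewald_ldl(tc, hdl, trig)
        assert np.isclose(ldl.mean(), tc.mean() - hdl.mean() - trig.mean() / 2.2)

    def test_tc_mode_switch(self):
        base = dict(n_subjects=200, seed=3)
        hl = simulate_clinical(CohortSpec(tc_mode="hdl_plus_ldl", **base))
        pm = simulate_clinical(CohortSpec(tc_mode="premix", **base))
        assert np.allclose(hl["TC"], hl["HDL"] + hl["LDL"])
        # premix TC restores the standard identity TC = LDL + HDL + TriG/2.2
        assert np.allclose(pm["TC"], pm["LDL"] + pm["HDL"] + pm["TriG"] / 2.2)

    def test_seeded_determinism(self):
        spec = CohortSpec(n_subjects=50, seed=21)
        pd.testing.assert_frame_equal(simulate_clinical(spec), simulate_clinical(spec))


class TestSimulateSpectra:
    def _noiseless_spec(self, n_lipids=8, **kw):
        defaults = dict(
            cohort_id="t",
            n_subjects=6,
            n_lipids_detectable=n_lipids,
            noise_cv=0.0,
            bio_cv=0.0,
            missing_rate=0.0,
            mass_error_ppm_sd=0.0,
            n_fail_mass=0,
            n_fail_blank=0,
            n_fail_missing=0,
            n_fail_qc=0,
            seed=2,
        )
        defaults.update(kw)
        return CohortSpec(**defaults)

    def test_zero_noise_identity(self, small_library):
        spec = self._noiseless_spec()
        clin = simulate_clinical(spec)
        spectra, _ = simulate_spectra(clin, small_library, spec)
        subj = [s for s in spectra if s.role == Role.SAMPLE]
        expected = np.array([t.expected_mz for t in small_library[:8]])
        assert len(subj) == 6
        for s in subj:
            assert s.peaks.shape[0] == 8
            assert np.allclose(np.sort(s.mz), np.sort(expected))

    def test_qc_linear_dilution_zero_noise(self, small_library):
        spec = self._noiseless_spec()
        clin = simulate_clinical(spec)
        spectra, _ = simulate_spectra(clin, small_library, spec)
        qc100 = next(s for s in spectra if s.role == Role.QC100)
        qc50 = next(s for s in spectra if s.role == Role.QC50)
        assert np.allclose(qc50.intensity, 0.5 * qc100.intensity)

    def test_role_counts(self, small_library, tiny_cohort_spec):
        clin = simulate_clinical(tiny_cohort_spec)
        spectra, _ = simulate_spectra(clin, small_library, tiny_cohort_spec)
        roles = pd.Series([s.role.value for s in spectra]).value_counts()
        assert roles["sample"] == 40
        assert roles["blank"] >= 3
        assert roles["qc100"] >= 3 and roles["qc50"] >= 3 and roles["qc25"] >= 3

    def test_unknown_association_lipid_rejected(self, small_library):
        spec = self._noiseless_spec()
        spec.association_map = {"nope": ("TriG", 0.2)}
        clin = simulate_clinical(spec)
        with pytest.raises(ValueError, match="unknown lipid"):
            simulate_spectra(clin, small_library, spec)

    def test_planted_effect_recovery(self):
        # correlation(intensity, TriG) -> sqrt(f) as measurement noise -> 0
        f = 0.36
        lib = make_lipid_library(30, 2, seed=8)
        spec = CohortSpec(
            cohort_id="fx",
            n_subjects=800,
            n_lipids_detectable=30,
            association_map={lib[0].name: ("TriG", f)},
            noise_cv=0.0,
            missing_rate=0.0,
            mass_error_ppm_sd=0.0,
            n_fail_mass=0,
            n_fail_blank=0,
            n_fail_missing=0,
            n_fail_qc=0,
            seed=13,
        )
        clin = simulate_clinical(spec)
        spectra, _ = simulate_spectra(clin, lib, spec)
        subj = {s.sample_id: s for s in spectra if s.role == Role.SAMPLE}
        target_mz = lib[0].expected_mz
        inten = np.array(
            [
                subj[sid].intensity[np.argmin(np.abs(subj[sid].mz - target_mz))]
                for sid in clin.index
            ]
        )
        r = np.corrcoef(inten, clin["TriG"])[0, 1]
        assert r == pytest.approx(np.sqrt(f), abs=0.07)


class TestPairedCohorts:
    def test_shared_fraction_and_dropout(self):
        disc = CohortSpec(cohort_id="d", n_subjects=40, n_lipids_detectable=60, seed=1)
        val = CohortSpec(
            cohort_id="v",
            n_subjects=40,
            n_lipids_detectable=40,
            shared_lipid_fraction=0.71,
            seed=2,
        )
        d, v = make_paired_cohorts(disc, val, panel_dropout=[])
        shared = set(d.detectable) & set(v.detectable)
        assert len(shared) == round(0.71 * 40)
        assert len(v.detectable) == 40

    def test_dbs_like_overlap_is_84(self):
        # 118-lipid DBS set sharing 71% with a 163-lipid plasma set
        disc = CohortSpec(cohort_id="d", n_subjects=40, n_lipids_detectable=163, seed=1)
        val = CohortSpec(
            cohort_id="v", n_subjects=40, n_lipids_detectable=118,
            shared_lipid_fraction=0.71, seed=2,
        )
        d, v = make_paired_cohorts(disc, val)
        assert len(set(d.detectable) & set(v.detectable)) == 84

    def test_panel_dropout_excluded_from_validation(self):
        disc = CohortSpec(cohort_id="d", n_subjects=40, n_lipids_detectable=60, seed=1)
        val = CohortSpec(cohort_id="v", n_subjects=40, n_lipids_detectable=40, seed=2)
        d0, _ = make_paired_cohorts(disc, val)
        dropout = list(d0.association_map)[:2]
        d, v = make_paired_cohorts(disc, val, panel_dropout=dropout)
        assert set(dropout) <= set(d.detectable)
        assert not set(dropout) & set(v.detectable)

    def test_attenuation_zero_removes_signal(self):
        disc = CohortSpec(cohort_id="d", n_subjects=60, n_lipids_detectable=40, seed=1)
        val = CohortSpec(
            cohort_id="v", n_subjects=400, n_lipids_detectable=40,
            attenuation=0.0, seed=2, noise_cv=0.0, missing_rate=0.0,
        )
        _, v = make_paired_cohorts(disc, val)
        subj = {s.sample_id: s for s in v.spectra if s.role == Role.SAMPLE}
        by_name = {t.name: t for t in v.library}
        lip = next(l for l in v.association_map if v.association_map[l][0] == "TriG")
        mz0 = by_name[lip].expected_mz
        inten = np.array(
            [
                subj[sid].intensity[np.argmin(np.abs(subj[sid].mz - mz0))]
                for sid in v.clinical.index
            ]
        )
        r = np.corrcoef(inten, v.clinical["TriG"])[0, 1]
        assert abs(r) < 3.0 / np.sqrt(400)

    def test_cohort_determinism(self, tiny_cohort_spec):
        a = simulate_cohort(tiny_cohort_spec)
        b = simulate_cohort(tiny_cohort_spec)
        pd.testing.assert_frame_equal(a.clinical, b.clinical)
        assert len(a.spectra) == len(b.spectra)
        for sa, sb in zip(a.spectra, b.spectra):
            assert sa.sample_id == sb.sample_id
            np.testing.assert_array_equal(sa.peaks, sb.peaks)


def test_default_association_map_sizes_and_targets():
    names = [f"x{i}" for i in range(60)]
    amap = default_association_map(names)
    by_target = pd.Series([t for t, _ in amap.values()]).value_counts()
    assert by_target["TriG"] == 12
    assert by_target["HDL"] == 11
    assert by_target["LDL"] == 10
    assert by_target["TC"] == 11
    # effect-size ordering TriG > HDL > LDL ~ TC
    mean_f = {
        t: np.mean([f for tt, f in amap.values() if tt == t])
        for t in ("TriG", "HDL", "LDL", "TC")
    }
    assert mean_f["TriG"] > mean_f["HDL"] > mean_f["LDL"] >= mean_f["TC"] * 0.8
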