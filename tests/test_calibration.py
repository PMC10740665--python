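"""Training-K fits, exclusion rules, and calibration-line regression."""

import numpy as np
import pytest

from mabvisc.calibration import (
    DEFAULT_ACSINS_LINE,
    DEFAULT_DLS_LINE,
    CalibrationError,
    ExclusionConfig,
    MoleculeRecord,
    calibrate_cohort,
    detect_ht_outliers,
    fit_calibration_line,
    fit_training_K,
)
from mabvisc.core_model import KEstimate, viscosity
from mabvisc.synthetic_data import SyntheticConfig, generate_cohort


def _record(mol_id, K, concs=(110.0, 150.0), params=None):
    from mabvisc.core_model import DEFAULT_PARAMS

    params = params or DEFAULT_PARAMS
    return MoleculeRecord(
        molecule_id=mol_id,
        viscosity_points=[(c, viscosity(K, c, params)) for c in concs],
    )


class TestFitTrainingK:
    def test_noise_free_cohort_exact_recovery(self, params):
        ks = [1e-4, 5e-4, 2e-3, 8e-3]
        cohort = [_record(f"m{i}", k) for i, k in enumerate(ks)]
        fits = fit_training_K(cohort, params)
        for i, k in enumerate(ks):
            assert fits[f"m{i}"].value == pytest.approx(k, rel=1e-8)

    def test_below_baseline_molecule_flagged_non_entangled(self, params):
        rec = MoleculeRecord(
            molecule_id="weak",
            viscosity_points=[(150.0, 0.8 * viscosity(0.0, 150.0, params))],
        )
        fits = fit_training_K([rec], params)
        assert fits["weak"].value < 0
        assert "non_entangled" in fits["weak"].flags

    def test_all_dilute_molecule_skipped(self, params, caplog):
        rec = MoleculeRecord(
            molecule_id="dilute", viscosity_points=[(70.0, 3.0), (90.0, 4.0)]
        )
        with pytest.warns(UserWarning):
            fits = fit_training_K([rec], params)
        assert "dilute" not in fits
        assert any("dilute" in r.message for r in caplog.records)


class TestDetectHtOutliers:
    # consistency locus in (kd, dnp): dnp = (2045/15000)*kd + (4.9 - (2045/15000)*56.03)
    LOCUS_SLOPE = 2045.0 / 15000.0
    LOCUS_INTERCEPT = 4.9 - (2045.0 / 15000.0) * 56.03

    def test_unset_separator_returns_empty_with_warning(self, caplog):
        recs = [MoleculeRecord("a", dnp=3.0, kd=40.0)]
        assert detect_ht_outliers(recs, ExclusionConfig()) == set()
        assert any("separator" in r.message.lower() for r in caplog.records)

    def test_consistent_molecules_not_flagged(self):
        # exactly on the consistency locus of the two published lines
        exc = ExclusionConfig(
            ht_separator=(self.LOCUS_SLOPE, self.LOCUS_INTERCEPT + 1.0)
        )
        recs = []
        for k in (1e-4, 1e-3, 3e-3):
            recs.append(
                MoleculeRecord(
                    f"k{k}", dnp=4.9 - 2045 * k, kd=56.03 - 15000 * k
                )
            )
        assert detect_ht_outliers(recs, exc) == set()

    def test_injected_ht_molecule_flagged(self):
        # AC-SINS sees weak K, DLS sees 5x stronger: above the locus
        k, mult = 1e-3, 5.0
        rec = MoleculeRecord("ht", dnp=4.9 - 2045 * k, kd=56.03 - 15000 * mult * k)
        exc = ExclusionConfig(
            ht_separator=(self.LOCUS_SLOPE, self.LOCUS_INTERCEPT + 1.0)
        )
        assert detect_ht_outliers([rec], exc) == {"ht"}

    def test_empty_cohort(self):
        exc = ExclusionConfig(ht_separator=(0.1, 0.0))
        assert detect_ht_outliers([], exc) == set()

    def test_missing_measurement_ignored(self):
        exc = ExclusionConfig(ht_separator=(0.0, -100.0))  # everything above
        recs = [MoleculeRecord("nokd", dnp=3.0), MoleculeRecord("nodnp", kd=10.0)]
        assert detect_ht_outliers(recs, exc) == set()


class TestFitCalibrationLine:
    def test_exact_collinear_recovery(self):
        ks = np.array([1e-5, 5e-4, 1e-3, 1.5e-3])
        pts = [(f"m{i}", k, 4.9 - 2045.0 * k) for i, k in enumerate(ks)]
        line = fit_calibration_line(pts, "acsins")
        assert line.intercept == pytest.approx(4.9, rel=1e-8)
        assert line.slope == pytest.approx(2045.0, rel=1e-8)
        assert line.n_used == 4
        assert line.excluded_ids == ()

    def test_k_of_intercept_is_exactly_zero(self):
        pts = [(f"m{i}", k, 56.03 - 15000.0 * k) for i, k in enumerate([1e-4, 1e-3, 5e-3])]
        line = fit_calibration_line(pts, "dls")
        assert line.k_from(line.intercept) == 0.0

    def test_noisy_slope_within_three_standard_errors(self):
        rng = np.random.default_rng(42)
        n, sigma = 60, 0.3
        ks = 10 ** rng.uniform(-5, np.log10(1.8e-3), n)
        xs = 4.9 - 2045.0 * ks + rng.normal(0.0, sigma, n)
        line = fit_calibration_line(
            [(f"m{i}", ks[i], xs[i]) for i in range(n)], "acsins"
        )
        se_slope = line.residual_sd / (np.std(ks, ddof=1) * np.sqrt(n - 1))
        assert abs(line.slope - 2045.0) < 3 * se_slope

    def test_dls_branching_cutoff_excluded(self):
        ks = [1e-4, 1e-3, 5e-3]
        pts = [(f"m{i}", k, 56.03 - 15000.0 * k) for i, k in enumerate(ks)]
        # K above 0.01 mL/mg but with an in-range k_D reading: the branching
        # rule, not the plausibility rule, must remove it
        pts.append(("m3", 0.02, -50.0))
        line = fit_calibration_line(pts, "dls")
        assert line.n_used == 3
        assert ("m3", "K_above_branching_cutoff") in line.excluded_ids

    def test_dls_implausible_kd_excluded(self):
        pts = [("a", 1e-4, 54.5), ("b", 1e-3, 41.0), ("c", 2e-3, 26.0),
               ("d", 5e-4, 84.0)]  # 84 mL/g outside the plausible range
        line = fit_calibration_line(pts, "dls")
        assert ("d", "kd_outside_plausible_range") in line.excluded_ids
        assert line.n_used == 3

    def test_acsins_sensitivity_floor_and_ht_excluded(self):
        pts = [("a", 1e-4, 4.7), ("b", 5e-4, 3.9), ("c", 1e-3, 2.9),
               ("d", 3e-3, 0.8),   # dnp <= 1 um^2/s
               ("e", 1e-3, 4.5)]   # suspected HT
        line = fit_calibration_line(pts, "acsins", ht_ids=frozenset({"e"}))
        reasons = dict(line.excluded_ids)
        assert reasons["d"] == "dnp_at_or_below_sensitivity_floor"
        assert reasons["e"] == "suspected_ht_binder"
        assert line.n_used == 3

    def test_negative_K_excluded_both_sources(self):
        neg = KEstimate(value=-2e-4, flags=frozenset({"non_entangled"}))
        pts = [("a", 1e-4, 4.7), ("b", 5e-4, 3.9), ("c", 1e-3, 2.9), ("n", neg, 4.9)]
        for source in ("acsins", "dls"):
            line = fit_calibration_line(pts, source)
            assert ("n", "non_entangled") in line.excluded_ids

    def test_ledger_partitions_cohort(self):
        pts = [("a", 1e-4, 4.7), ("b", 5e-4, 3.9), ("c", 1e-3, 2.9),
               ("d", 3e-3, 0.5), ("e", -1e-4, 5.0), ("f", 1e-3, None)]
        line = fit_calibration_line(pts, "acsins")
        used_plus_excluded = line.n_used + len(line.excluded_ids)
        assert used_plus_excluded == len(pts)
        excluded_set = {m for m, _ in line.excluded_ids}
        assert excluded_set == {"d", "e", "f"}

    def test_order_invariance(self):
        rng = np.random.default_rng(3)
        ks = 10 ** rng.uniform(-5, -2.2, 20)
        pts = [(f"m{i}", k, 56.03 - 15000.0 * k + rng.normal(0, 1.0)) for i, k in enumerate(ks)]
        line1 = fit_calibration_line(pts, "dls")
        line2 = fit_calibration_line(list(reversed(pts)), "dls")
        assert line1.intercept == pytest.approx(line2.intercept, rel=1e-12)
        assert line1.slope == pytest.approx(line2.slope, rel=1e-12)

    def test_too_few_survivors_raises_with_ledger(self):
        pts = [("a", 1e-4, 4.7), ("b", -1e-3, 5.1), ("c", 2e-3, 0.4)]
        with pytest.raises(CalibrationError, match="ledger"):
            fit_calibration_line(pts, "acsins")


class TestCalibrateCohort:
    def test_noise_free_round_trip_recovers_published_lines(self, params):
        """Zero-noise cohorts generated from the published coefficients
        refit to (4.9, 2045) and (56.03, 15000) within 1e-6 relative."""
        cfg = SyntheticConfig(
            n_molecules=50, seed=7, dnp_noise_sd=0.0, kd_noise_sd=0.0,
            visc_lognoise_sd=0.0, ht_fraction=0.0, strong_binder_fraction=0.0,
        )
        cohort, _ = generate_cohort(cfg, params)
        report = calibrate_cohort(cohort, params)
        assert report.acsins.intercept == pytest.approx(4.9, rel=1e-6)
        assert report.acsins.slope == pytest.approx(2045.0, rel=1e-6)
        assert report.dls.intercept == pytest.approx(56.03, rel=1e-6)
        assert report.dls.slope == pytest.approx(15000.0, rel=1e-6)

    def test_every_molecule_used_or_excluded_once(self, params):
        cfg = SyntheticConfig(n_molecules=40, seed=5, strong_binder_fraction=0.1)
        cohort, _ = generate_cohort(cfg, params)
        report = calibrate_cohort(cohort, params)
        for line in (report.acsins, report.dls):
            ids_excluded = [m for m, _ in line.excluded_ids]
            assert len(ids_excluded) == len(set(ids_excluded))
            assert line.n_used + len(ids_excluded) + len(report.skipped_ids) == 40

    def test_default_lines_match_published_constants(self):
        assert (DEFAULT_ACSINS_LINE.intercept, DEFAULT_ACSINS_LINE.slope) == (4.9, 2045.0)
        assert (DEFAULT_DLS_LINE.intercept, DEFAULT_DLS_LINE.slope) == (56.03, 15000.0)
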