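"""Calibration fitting and default recovery from published overlaps."""

import numpy as np
import pytest
from sklearn.base import clone

from vo2overlap import (
    InsufficientDataError,
    InvalidInputError,
    RecoveryError,
    SigmaPolynomialRegression,
    TestRetestRecord,
    WorkedExampleConstraint,
    fit_calibration,
    ovl_normal,
    read_test_retest_csv,
    recover_default_calibrations,
    shipped_constraints,
)


def _noiseless_records(coeffs, mus):
    return [
        TestRetestRecord(mean_vo2=m, sd_vo2=float(np.polynomial.polynomial.polyval(m, coeffs)))
        for m in mus
    ]


class TestRecord:
    def test_from_pair_uses_n_minus_one_denominator(self):
        r = TestRetestRecord.from_pair(2.0, 2.2)
        assert r.mean_vo2 == pytest.approx(2.1)
        assert r.sd_vo2 == pytest.approx(0.2 / np.sqrt(2))

    def test_invalid_values_rejected(self):
        with pytest.raises(InvalidInputError):
            TestRetestRecord(mean_vo2=-1.0, sd_vo2=0.1)
        with pytest.raises(InvalidInputError):
            TestRetestRecord(mean_vo2=1.0, sd_vo2=-0.1)


class TestFitCalibration:
    def test_noiseless_quadratic_recovered_to_machine_precision(self):
        truth = (0.02, 0.01, 0.005)
        records = _noiseless_records(truth, np.linspace(1.0, 4.0, 10))
        cal = fit_calibration(records, "toy", order=2)
        assert cal.coefficients == pytest.approx(truth, abs=1e-10)

    def test_insufficient_records_rejected(self):
        records = _noiseless_records((0.05, 0.01), [1.0, 2.0, 3.0])
        with pytest.raises(InsufficientDataError):
            fit_calibration(records, "toy", order=3)

    def test_degenerate_mu_span_rejected(self):
        records = [TestRetestRecord(2.0, 0.1) for _ in range(6)]
        with pytest.raises(InsufficientDataError):
            fit_calibration(records, "toy", order=2)

    def test_provenance_reports_fit_diagnostics(self):
        records = _noiseless_records((0.05, 0.01), np.linspace(1.0, 4.0, 8))
        cal = fit_calibration(records, "toy", order=1)
        assert "RSS" in cal.provenance and "8" in cal.provenance

    def test_valid_range_is_record_span(self):
        records = _noiseless_records((0.05, 0.01), np.linspace(1.2, 3.8, 8))
        cal = fit_calibration(records, "toy", order=1)
        assert cal.valid_range == pytest.approx((1.2, 3.8))


class TestSigmaPolynomialRegression:
    def test_sklearn_param_interface(self):
        reg = SigmaPolynomialRegression(order=2)
        assert reg.get_params() == {"order": 2}
        assert clone(reg).order == 2
        reg.set_params(order=1)
        assert reg.order == 1

    def test_fit_predict_round_trip(self):
        mus = np.linspace(1.0, 4.0, 12)
        truth = (0.03, 0.02)
        y = np.polynomial.polynomial.polyval(mus, truth)
        reg = SigmaPolynomialRegression(order=1).fit(mus[:, None], y)
        assert reg.coefficients_ == pytest.approx(truth, abs=1e-12)
        assert reg.rss_ == pytest.approx(0.0, abs=1e-20)
        assert reg.predict([[2.5]])[0] == pytest.approx(0.08)


class TestCsvReader:
    def test_pair_and_summary_dialects_agree(self, tmp_path):
        p1 = tmp_path / "pairs.csv"
        p1.write_text(
            "subject_id,workload,day1_vo2,day2_vo2\nS1,W1,2.0,2.2\nS2,W1,3.0,2.9\n"
        )
        p2 = tmp_path / "summary.csv"
        p2.write_text(
            "subject_id,mean_vo2,sd_vo2\n"
            f"S1,2.1,{0.2 / np.sqrt(2)}\nS2,2.95,{0.1 / np.sqrt(2)}\n"
        )
        r1 = read_test_retest_csv(p1)
        r2 = read_test_retest_csv(p2)
        assert [r.mean_vo2 for r in r1] == pytest.approx([r.mean_vo2 for r in r2])
        assert [r.sd_vo2 for r in r1] == pytest.approx([r.sd_vo2 for r in r2])

    def test_missing_columns_rejected(self, tmp_path):
        p = tmp_path / "bad.csv"
        p.write_text("a,b\n1,2\n")
        with pytest.raises(InvalidInputError, match="columns"):
            read_test_retest_csv(p)


class TestDefaultRecovery:
    def test_parvo_constraints_reproduced_exactly(self):
        registry = recover_default_calibrations()
        cal = registry["parvo_2400"]
        for mu_a, mu_b, target in [(1.5, 1.7, 0.103), (3.3, 3.5, 0.358)]:
            got = ovl_normal(mu_a, cal.sigma(mu_a), mu_b, cal.sigma(mu_b))
            assert got == pytest.approx(target, abs=1e-6)

    def test_douglas_constraints_reproduced_within_rmse_bound(self):
        registry = recover_default_calibrations()
        cal = registry["douglas_bag"]
        targets = [
            (1.5, 1.7, 0.172),
            (3.3, 3.5, 0.467),
            (2.19, 2.48, 0.209),
            (2.19, 2.57, 0.105),
            (2.19, 2.51, 0.168),
        ]
        resid = [
            ovl_normal(a, cal.sigma(a), b, cal.sigma(b)) - t for a, b, t in targets
        ]
        assert np.sqrt(np.mean(np.square(resid))) <= 0.03

    def test_recovery_is_deterministic(self):
        r1 = recover_default_calibrations()
        r2 = recover_default_calibrations()
        for device in r1:
            assert r1[device].coefficients == r2[device].coefficients

    def test_shipped_registry_matches_fresh_recovery(self, registry):
        fresh = recover_default_calibrations()
        for device in registry:
            assert registry[device].coefficients == pytest.approx(
                fresh[device].coefficients, rel=1e-9
            )

    def test_holdout_constraint_never_enters_fitting(self):
        cons = shipped_constraints()
        cross = [c for c in cons if c.device_a != c.device_b]
        assert len(cross) == 1 and cross[0].role == "holdout"
        fit_cons = [c for c in cons if c.role == "fit"]
        assert all(c.device_a == c.device_b for c in fit_cons)

    def test_missing_parvo_constraint_is_underdetermined(self):
        cons = [c for c in shipped_constraints() if not (c.device_a == "parvo_2400" and c.mu_a == 1.5)]
        with pytest.raises(RecoveryError, match="ParvoMedics"):
            recover_default_calibrations(cons)

    def test_too_few_douglas_constraints_rejected(self):
        cons = [c for c in shipped_constraints() if c.device_a == "parvo_2400"]
        with pytest.raises(RecoveryError, match="Douglas"):
            recover_default_calibrations(cons)


class TestConstraintTable:
    def test_duplicated_followup_pair_enters_once(self):
        cons = shipped_constraints()
        pairs = [(c.mu_a, c.mu_b, c.device_a, c.device_b) for c in cons]
        assert len(pairs) == len(set(pairs))
        assert (2.19, 2.48, "douglas_bag", "douglas_bag") in pairs

    def test_constraint_validation(self):
        with pytest.raises(InvalidInputError):
            WorkedExampleConstraint(1.5, 1.7, "a", "a", target_ovl=1.0)
        with pytest.raises(InvalidInputError):
            WorkedExampleConstraint(-1.5, 1.7, "a", "a", target_ovl=0.5)
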