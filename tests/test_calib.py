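"""Calibration: curve parsing, density shape, back-calibration, HPD."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from palaeocoast import synthetic
from palaeocoast.calib import (
    C14Date,
    CalibratedDensity,
    CalibrationCurve,
    calibrate,
    curve_at,
    hpd_interval,
    load_curve,
    uncalibrate,
    write_curve,
)
from palaeocoast.errors import (
    CalibrationError,
    CurveFormatError,
    CurveRangeError,
    ValidationError,
)


# ---------------------------------------------------------------------------
# curve loading
# ---------------------------------------------------------------------------

class TestLoadCurve:
    def test_three_line_file(self, tmp_path):
        p = tmp_path / "c.14c"
        p.write_text("#hdr\n1000,1050,10\n2000,2040,12\n")
        c = load_curve(p)
        assert c.cal_age.tolist() == [1000.0, 2000.0]
        assert c.c14_age.tolist() == [1050.0, 2040.0]
        assert c.curve_sigma.tolist() == [10.0, 12.0]

    def test_descending_rows_sorted(self, tmp_path):
        """Curve files written oldest-first load identically."""
        a = tmp_path / "asc.14c"
        d = tmp_path / "desc.14c"
        a.write_text("1000 1050 10\n1500 1540 11\n2000 2040 12\n")
        d.write_text("2000 2040 12\n1500 1540 11\n1000 1050 10\n")
        ca, cd = load_curve(a), load_curve(d)
        assert np.array_equal(ca.cal_age, cd.cal_age)
        assert np.array_equal(ca.c14_age, cd.c14_age)

    def test_roundtrip_bit_identical(self, tmp_path):
        curve = synthetic.make_calcurve(span=(25000.0, 0.0), knot_step=5.0,
                                        seed=3)
        assert curve.cal_age.size == 5001
        p = tmp_path / "rt.14c"
        write_curve(curve, p)
        back = load_curve(p)
        assert np.array_equal(back.cal_age, curve.cal_age)
        assert np.array_equal(back.c14_age, curve.c14_age)
        assert np.array_equal(back.curve_sigma, curve.curve_sigma)

    def test_malformed_row_names_line(self, tmp_path):
        p = tmp_path / "bad.14c"
        p.write_text("1000,1050,10\n2000,oops,12\n")
        with pytest.raises(CurveFormatError, match=":2"):
            load_curve(p)

    def test_duplicate_cal_age_rejected(self, tmp_path):
        p = tmp_path / "dup.14c"
        p.write_text("1000,1050,10\n1000,1060,10\n2000,2040,12\n")
        with pytest.raises(ValidationError):
            load_curve(p)


# ---------------------------------------------------------------------------
# interpolation
# ---------------------------------------------------------------------------

class TestCurveAt:
    @pytest.fixture()
    def two_knots(self):
        return CalibrationCurve([1000, 2000], [1050, 2040], [10, 12])

    def test_knot_identity(self, two_knots):
        assert curve_at(two_knots, 1000) == (1050.0, 10.0)

    def test_midpoint(self, two_knots):
        # midpoint of the linear segment: means (1050+2040)/2, sigmas (10+12)/2
        assert curve_at(two_knots, 1500) == (1545.0, 11.0)

    def test_out_of_range(self, two_knots):
        with pytest.raises(CurveRangeError):
            curve_at(two_knots, 999)

    @settings(derandomize=True, deadline=None, max_examples=50)
    @given(st.floats(min_value=3000.0, max_value=9000.0))
    def test_matches_two_point_formula(self, q):
        curve = synthetic.make_calcurve(span=(9000.0, 3000.0), seed=11)
        mu, sig = curve_at(curve, q)
        # brute-force segment lookup
        i = int(np.clip(np.searchsorted(curve.cal_age, q, side="right") - 1,
                        0, curve.cal_age.size - 2))
        x0, x1 = curve.cal_age[i], curve.cal_age[i + 1]
        f = (q - x0) / (x1 - x0)
        assert mu == pytest.approx(
            curve.c14_age[i] * (1 - f) + curve.c14_age[i + 1] * f, rel=1e-12)
        assert sig == pytest.approx(
            curve.curve_sigma[i] * (1 - f) + curve.curve_sigma[i + 1] * f,
            rel=1e-12)


# ---------------------------------------------------------------------------
# calibrate
# ---------------------------------------------------------------------------

class TestCalibrate:
    def test_flat_curve_uniform_density(self):
        """A constant curve makes every calendar age equally likely."""
        theta = np.arange(4000.0, 6001.0, 100.0)
        curve = CalibrationCurve(theta, np.full(theta.size, 5000.0),
                                 np.zeros(theta.size))
        cd = calibrate(C14Date("flat", 5000, 50), curve, trim_mass=0.0)
        assert cd.mass.size == 2001
        assert np.allclose(cd.mass, 1.0 / 2001)

    def test_gaussian_limit(self, identity_curve):
        cd = calibrate(C14Date("g", 4500, 20), identity_curve)
        assert cd.mass.sum() == pytest.approx(1.0, abs=1e-12)
        assert cd.mode() == pytest.approx(4500, abs=0.5)
        assert cd.sd() == pytest.approx(20.0, abs=0.5)

    def test_matches_dense_grid_oracle(self, wiggly_curve):
        """Trimmed fast-path density equals a full-grid normalization."""
        date = C14Date("w", 4500, 30)
        cd = calibrate(date, wiggly_curve)
        grid, mu, sig = wiggly_curve.gridded(1.0)
        dens = np.exp(-((date.c14_age - mu) ** 2)
                      / (2.0 * (date.c14_error ** 2 + sig ** 2)))
        dens /= dens.sum()
        off = int(round(cd.grid_start - grid[0]))
        assert cd.mass.sum() == pytest.approx(1.0, abs=1e-9)
        assert np.abs(cd.mass - dens[off:off + cd.mass.size]).max() < 1e-6

    def test_inconsistent_date_raises(self, identity_curve):
        with pytest.raises(CalibrationError):
            calibrate(C14Date("off", 40000, 10), identity_curve)

    def test_marine_reservoir_offset_shifts_density(self, identity_curve):
        plain = calibrate(C14Date("p", 5000, 30), identity_curve)
        offset = calibrate(C14Date("m", 5400, 30, delta_r=400.0),
                           identity_curve)
        assert offset.median() == pytest.approx(plain.median(), abs=1)
        # reservoir uncertainty widens the density
        wide = calibrate(C14Date("mw", 5400, 30, delta_r=400.0,
                                 delta_r_error=40.0), identity_curve)
        assert wide.sd() == pytest.approx(np.hypot(30, 40), rel=0.05)

    def test_battery_mass_conservation(self, wiggly_curve):
        rng = np.random.default_rng(7)
        for i in range(100):
            d = C14Date(f"b{i}", float(rng.uniform(3500, 8500)),
                        float(rng.uniform(20, 90)))
            cd = calibrate(d, wiggly_curve)
            assert abs(cd.mass.sum() - 1.0) < 1e-9

    def test_monotone_linear_curve_median_inverts(self):
        """With a strictly monotone linear curve the median inverts mu."""
        theta = np.arange(3000.0, 9001.0, 100.0)
        curve = CalibrationCurve(theta, 2.0 * theta, np.zeros(theta.size))
        cd = calibrate(C14Date("inv", 10000, 40), curve)
        assert abs(cd.median() - 5000.0) <= 1.0

    def test_grid_refinement_moves_hpd_little(self, wiggly_curve):
        d = C14Date("ref", 4500, 30)
        h1 = hpd_interval(calibrate(d, wiggly_curve, grid_step=1.0))
        h2 = hpd_interval(calibrate(d, wiggly_curve, grid_step=0.5))
        assert len(h1) == len(h2)
        for (a1, b1), (a2, b2) in zip(h1, h2):
            assert abs(a1 - a2) <= 2.0 and abs(b1 - b2) <= 2.0


# ---------------------------------------------------------------------------
# uncalibrate
# ---------------------------------------------------------------------------

class TestUncalibrate:
    def test_noiseless_identity_limit(self, identity_curve):
        out = uncalibrate(6000.0, identity_curve, sigma_lab=1e-9, rng=0)
        assert out == pytest.approx(6000.0, abs=1e-6)

    def test_seed_determinism(self, wiggly_curve):
        a = uncalibrate(6000.0, wiggly_curve, 30.0, rng=42)
        b = uncalibrate(6000.0, wiggly_curve, 30.0, rng=42)
        assert a == b

    def test_monte_carlo_sd_matches_closed_form(self, identity_curve_sig20):
        draws = uncalibrate(np.full(10000, 6000.0), identity_curve_sig20,
                            sigma_lab=30.0, rng=1)
        expect = np.hypot(20.0, 30.0)
        se = expect / np.sqrt(2 * (10000 - 1))   # SE of a normal sample sd
        assert draws.std(ddof=1) == pytest.approx(expect, abs=3 * se)

    def test_out_of_range(self, identity_curve):
        with pytest.raises(CurveRangeError):
            uncalibrate(2000.0, identity_curve, 30.0, rng=0)

    def test_roundtrip_consistency(self, wiggly_curve):
        """Uniform ages -> uncalibrate -> calibrate: medians unbiased."""
        rng = np.random.default_rng(9)
        true_ages = rng.uniform(4000.0, 8000.0, size=500)
        c14 = uncalibrate(true_ages, wiggly_curve, sigma_lab=40.0, rng=rng)
        medians = np.array([
            calibrate(C14Date(f"r{i}", float(c14[i]), 40.0),
                      wiggly_curve).median()
            for i in range(500)])
        mc_se = medians.std(ddof=1) / np.sqrt(500)
        assert medians.mean() == pytest.approx(true_ages.mean(),
                                               abs=3 * mc_se)


# ---------------------------------------------------------------------------
# HPD intervals
# ---------------------------------------------------------------------------

class TestHPD:
    def test_symmetric_unimodal_single_interval(self, identity_curve):
        cd = calibrate(C14Date("s", 5000, 25), identity_curve)
        ints = hpd_interval(cd, 0.954)
        assert len(ints) == 1
        lo, hi = ints[0]
        assert abs((5000 - lo) - (hi - 5000)) <= 1.0

    def test_bimodal_two_intervals_matches_ranking_oracle(self):
        ages = np.arange(0.0, 200.0)
        m = np.exp(-0.5 * ((ages - 50) / 8) ** 2) \
            + np.exp(-0.5 * ((ages - 150) / 8) ** 2)
        cd = CalibratedDensity(0.0, 1.0, m / m.sum())
        ints = hpd_interval(cd, 0.9)
        assert len(ints) == 2
        # brute-force: smallest cell set by descending density
        order = np.argsort(-cd.mass, kind="stable")
        k = int(np.searchsorted(np.cumsum(cd.mass[order]), 0.9)) + 1
        sel = set(order[:k].tolist())
        covered = {i for a, b in ints for i in range(int(a), int(b) + 1)}
        assert covered == sel

    @settings(derandomize=True, deadline=None, max_examples=25)
    @given(st.floats(min_value=0.05, max_value=0.999))
    def test_coverage_bound(self, mass):
        rng = np.random.default_rng(5)
        m = rng.dirichlet(np.ones(300))
        cd = CalibratedDensity(0.0, 1.0, m)
        ints = hpd_interval(cd, mass)
        tot = sum(cd.mass[int(a):int(b) + 1].sum() for a, b in ints)
        assert tot >= mass - 1e-12
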