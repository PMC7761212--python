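import warnings

import numpy as np
import pytest
from hypothesis import given
from hypothesis import strategies as st
from scipy.optimize import brentq

import hemequil as hq
from hemequil.errors import (
    HemequilWarning,
    InsufficientDataError,
    NoAssociationError,
)

MIDPOINT_PERCENT_D = (225 - np.sqrt(10625)) / 2  # root of 0.04*(100-x)^2 = x


def bisection_percent_dimer(dtot, kd):
    """Independent oracle: solve Kd = Dtot*0.04*(100-x)^2/x for x by root
    bracketing, without the closed-form quadratic."""
    if kd == 0:
        return 100.0

    def g(x):
        return dtot * 0.04 * (100 - x) ** 2 / x - kd

    return brentq(g, 1e-12, 100 - 1e-12, xtol=1e-12, rtol=1e-15)


def noiseless_points(kd, dtots):
    return [
        hq.EquilibriumPoint(
            dtot_loaded_uM=d,
            dtot_corrected_uM=d,
            percent_dimer=hq.fraction_dimer(d, kd),
            ve_ml=0.0,
        )
        for d in dtots
    ]


class TestElutionRelations:
    def test_monomer_endpoint(self, column):
        assert hq.percent_dimer_from_elution(column.vm_ml, column) == 0.0

    def test_dimer_endpoint(self, column):
        assert hq.percent_dimer_from_elution(column.vd_ml, column) == pytest.approx(
            100.0, abs=1e-9
        )

    def test_volume_midpoint(self, column):
        mid = (column.vm_ml + column.vd_ml) / 2
        assert hq.percent_dimer_from_elution(mid, column) == pytest.approx(
            100 * (np.sqrt(2) - 1), abs=1e-9
        )

    def test_outside_window_clipped_with_warning(self, column):
        with pytest.warns(HemequilWarning, match="clipping"):
            assert hq.percent_dimer_from_elution(column.vm_ml + 0.2, column) == 0.0

    def test_inverse_examples(self, column):
        assert hq.elution_volume_from_percent_dimer(0, column) == column.vm_ml
        assert hq.elution_volume_from_percent_dimer(100, column) == pytest.approx(
            column.vd_ml, abs=1e-12
        )

    @given(st.floats(0, 100))
    def test_roundtrip_identity(self, pd_true):
        col = hq.DEFAULT_COLUMN
        ve = hq.elution_volume_from_percent_dimer(pd_true, col)
        assert hq.percent_dimer_from_elution(ve, col) == pytest.approx(
            pd_true, abs=1e-10
        )


class TestEffectiveMw:
    @pytest.mark.parametrize(
        "pd_, expected", [(0.0, 18.034), (100.0, 36.068), (50.0, 27.051)]
    )
    def test_examples(self, column, pd_, expected):
        assert hq.effective_mw(column, pd_) == pytest.approx(expected, abs=1e-9)

    @given(st.floats(0, 100))
    def test_bounded_between_monomer_and_dimer_mass(self, pd_):
        col = hq.DEFAULT_COLUMN
        mw = hq.effective_mw(col, pd_)
        assert col.monomer_mw_kda <= mw <= 2 * col.monomer_mw_kda


class TestFractionDimer:
    def test_zero_kd_is_all_dimer(self):
        assert hq.fraction_dimer(1.0, 0.0) == 100.0

    def test_dilute_limit_is_monomeric(self):
        assert hq.fraction_dimer(1e-9, 1.0) == pytest.approx(0.0, abs=1e-5)

    @pytest.mark.parametrize("value", [0.01, 1.2, 876.0])
    def test_dtot_equal_kd_fixed_point(self, value):
        assert hq.fraction_dimer(value, value) == pytest.approx(
            MIDPOINT_PERCENT_D, abs=1e-9
        )
        assert hq.fraction_dimer(value, value) == pytest.approx(60.96, abs=5e-3)

    @given(
        st.floats(1e-4, 1e4),
        st.floats(1e-4, 1e4),
    )
    def test_agrees_with_bisection_oracle(self, dtot, kd):
        assert hq.fraction_dimer(dtot, kd) == pytest.approx(
            bisection_percent_dimer(dtot, kd), abs=1e-6
        )

    @given(st.floats(1e-3, 1e3), st.floats(1e-3, 1e3), st.floats(1.01, 5.0))
    def test_monotone_in_dtot_and_kd(self, dtot, kd, factor):
        base = hq.fraction_dimer(dtot, kd)
        assert hq.fraction_dimer(dtot * factor, kd) > base
        assert hq.fraction_dimer(dtot, kd * factor) < base
        assert 0.0 <= base <= 100.0


class TestManningTransform:
    def test_zero_at_fixed_point(self):
        assert hq.manning_y(MIDPOINT_PERCENT_D) == pytest.approx(0.0, abs=1e-12)

    def test_half_dimer_value(self):
        assert hq.manning_y(50.0) == pytest.approx(np.log10(0.5), abs=1e-12)

    @pytest.mark.parametrize("bad", [0.0, 100.0, -5.0])
    def test_endpoints_excluded(self, bad):
        with pytest.raises(ValueError, match="excluded"):
            hq.manning_y(bad)


class TestKdEstimators:
    @pytest.mark.parametrize(
        "kd, lo, hi", [(1.2, 0.07, 85.0), (876.0, 50.0, 50000.0)]
    )
    def test_manning_noiseless_roundtrip(self, kd, lo, hi):
        pts = noiseless_points(kd, np.geomspace(lo, hi, 12))
        with warnings.catch_warnings():
            warnings.simplefilter("ignore", HemequilWarning)
            fit = hq.fit_kd_manning(pts)
        assert fit.kd_uM == pytest.approx(kd, rel=1e-6)
        assert fit.slope_unconstrained == pytest.approx(1.0, abs=1e-6)

    @given(st.floats(np.log10(1e-3), np.log10(1e4)))
    def test_manning_roundtrip_across_kd_decades(self, log_kd):
        kd = 10.0**log_kd
        # design spanning %D in [5, 95]: Dtot/Kd in [0.0139, 95]
        pts = noiseless_points(kd, kd * np.geomspace(0.014, 95, 8))
        fit = hq.fit_kd_manning(pts)
        assert fit.kd_uM == pytest.approx(kd, rel=1e-6)

    def test_free_slope_variant_matches_on_exact_data(self):
        pts = noiseless_points(11.0, np.geomspace(0.5, 500, 10))
        fixed = hq.fit_kd_manning(pts, fix_slope=True)
        free = hq.fit_kd_manning(pts, fix_slope=False)
        assert free.kd_uM == pytest.approx(fixed.kd_uM, rel=1e-9)

    def test_all_monomeric_series_raises_no_association(self):
        pts = noiseless_points(1e6, np.geomspace(0.01, 1.0, 6))
        assert all(p.percent_dimer < 1 for p in pts)
        with pytest.raises(NoAssociationError, match="no association"):
            with warnings.catch_warnings():
                warnings.simplefilter("ignore", HemequilWarning)
                hq.fit_kd_manning(pts)

    def test_too_few_usable_points(self):
        pts = noiseless_points(1.0, [1.0, 2.0])
        with pytest.raises(InsufficientDataError):
            hq.fit_kd_manning(pts)

    def test_exclusion_window_warns(self):
        pts = noiseless_points(1.0, np.geomspace(1e-4, 100, 10))
        with pytest.warns(HemequilWarning, match="excluded"):
            fit = hq.fit_kd_manning(pts)
        assert fit.n_points_used < len(pts)

    def test_hyperbolic_roundtrip_kd11(self):
        pts = noiseless_points(11.0, np.geomspace(0.1, 300, 12))
        with warnings.catch_warnings():
            warnings.simplefilter("ignore", HemequilWarning)
            fit = hq.fit_kd_hyperbolic(pts)
        assert fit.kd_uM == pytest.approx(11.0, rel=1e-6)

    def test_hyperbolic_consistent_with_manning(self):
        pts = noiseless_points(3.3, np.geomspace(0.05, 300, 10))
        with warnings.catch_warnings():
            warnings.simplefilter("ignore", HemequilWarning)
            manning = hq.fit_kd_manning(pts)
            hyper = hq.fit_kd_hyperbolic(pts)
        assert hyper.kd_uM == pytest.approx(manning.kd_uM, rel=1e-6)

    def test_hyperbolic_needs_four_points(self):
        with pytest.raises(InsufficientDataError):
            hq.fit_kd_hyperbolic(noiseless_points(1.0, [1.0]))


class TestDilutionCorrection:
    def test_points_from_chromatograms_apply_measured_dilution(self, column):
        preset = hq.SEC_PRESETS["AHb1_oxy"]
        from dataclasses import replace

        noiseless = replace(preset, noise_frac=0.0)
        chroms = hq.simulate_sec_series(noiseless, 0)
        pts = hq.equilibrium_points_from_chromatograms(chroms, noiseless.column)
        for chrom, pt in zip(chroms, pts):
            assert pt.dtot_corrected_uM == pytest.approx(
                chrom.loaded_conc_uM / 8.0, rel=0.02
            )
            assert pt.percent_dimer == pytest.approx(
                float(chrom.meta["truth_percent_dimer"]), abs=0.2
            )

    def test_fixed_override_bypasses_fwhm(self, column):
        preset = hq.SEC_PRESETS["AHb1_oxy"]
        chroms = hq.simulate_sec_series(preset, 1)
        pts = hq.equilibrium_points_from_chromatograms(
            chroms, preset.column, dilution_factor=10.0
        )
        for chrom, pt in zip(chroms, pts):
            assert pt.dtot_corrected_uM == pytest.approx(
                chrom.loaded_conc_uM / 10.0, rel=1e-12
            )
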