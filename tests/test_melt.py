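"""Two-state van't Hoff unfolding thermodynamics from CD melts."""

import numpy as np
import pytest

from splitscan.melt import (
    C_TO_K,
    R_CAL,
    MeltCurve,
    TwoStateFit,
    compare_variants,
    derive_thermo,
    fit_melt,
    fraction_folded,
    tm_from_curve,
    vant_hoff_fit,
)
from splitscan.simulate import gen_melt_curve

# printed unfolding parameters for each construct: (dH kcal/mol, dS cal/mol/K)
TABLE_PARAMS = {
    "CP12": (123.4, 343.4),
    "CP36": (120.7, 334.0),
    "SP12": (50.5, 149.4),
    "SP36": (77.3, 226.7),
    "SP102": (87.9, 241.1),
    "C1G": (163.5, 454.6),
}


def fit_from_params(name, dh, ds, tref=298.0):
    tds, dg, tm = derive_thermo(dh, ds, tref)
    return TwoStateFit(
        dh_kcal=dh, dh_se_kcal=0, ds_cal=ds, ds_se_cal=0, t_ref_k=tref,
        tds_kcal=tds, dg_kcal=dg, tm_vant_hoff_c=tm, construct=name,
    )


class TestFractionFolded:
    def test_noiseless_roundtrip_recovers_sigmoid(self):
        dh, ds = 77.3, 226.7
        curve = gen_melt_curve(dh, ds, folded_baseline=(0.0, 0.0),
                               denatured_baseline=(-1.0, 0.0))
        t_k = curve.temp_c + C_TO_K
        k = np.exp(-dh * 1000 / (R_CAL * t_k) + ds / R_CAL)
        expected = 1 / (1 + k)
        # fixed windows alone carry the residual-population bias of the
        # window edges ...
        ff = fraction_folded(curve, baselines=((25, 40), (88, 95)))
        assert np.allclose(ff.f, expected, atol=5e-3)
        # ... while the self-consistent refined fit recovers the generating
        # sigmoid essentially exactly
        fit = fit_melt(curve)
        assert np.allclose(fit.fraction.f, expected, atol=1e-6)

    def test_pretransition_points_are_folded(self):
        curve = gen_melt_curve(77.3, 226.7)
        ff = fraction_folded(curve)
        assert np.all(ff.f[curve.temp_c < 40] > 0.99)

    def test_flat_curve_degenerate_baselines(self):
        curve = MeltCurve(np.linspace(25, 95, 50), np.full(50, -10.0))
        with pytest.raises(ValueError, match="degenerate"):
            fraction_folded(curve)


class TestVantHoffFit:
    def test_derived_quantities_from_printed_cp12_row(self):
        tds, dg, _ = derive_thermo(123.4, 343.4)
        assert tds == pytest.approx(102.33, abs=0.005)
        assert dg == pytest.approx(21.07, abs=0.005)

    def test_unit_identity_closure(self):
        rng = np.random.default_rng(0)
        for _ in range(50):
            dh = rng.uniform(40, 170)
            ds = rng.uniform(120, 470)
            tds, dg, _ = derive_thermo(dh, ds)
            assert abs(dg - (dh - 298.0 * ds / 1000.0)) < 1e-9
            assert abs(tds - 298.0 * ds / 1000.0) < 1e-9

    def test_zero_entropy_degenerates_gracefully(self):
        tds, dg, tm = derive_thermo(50.0, 0.0)
        assert dg == 50.0 and tds == 0.0 and tm is None

    def test_noiseless_recovery_sp36(self):
        curve = gen_melt_curve(77.3, 226.7)
        fit = fit_melt(curve)
        assert fit.dh_kcal == pytest.approx(77.3, rel=1e-3)
        assert fit.ds_cal == pytest.approx(226.7, rel=1e-3)

    def test_antisymmetric_under_state_swap(self):
        curve = gen_melt_curve(77.3, 226.7)
        ff = fraction_folded(curve)
        fit = vant_hoff_fit(ff)
        ff.f = 1.0 - ff.f  # relabel folded as denatured
        flipped = vant_hoff_fit(ff)
        assert flipped.dh_kcal == pytest.approx(-fit.dh_kcal)
        assert flipped.ds_cal == pytest.approx(-fit.ds_cal)

    def test_narrowing_bounds_never_hurts_noiseless_fit(self):
        curve = gen_melt_curve(77.3, 226.7)
        ff = fraction_folded(curve)

        def resid_var(fb):
            fit = vant_hoff_fit(ff, f_bounds=fb)
            m = (ff.f > fb[0]) & (ff.f < fb[1])
            lnk = np.log((1 - ff.f[m]) / ff.f[m])
            pred = (-fit.dh_kcal * 1000 / (R_CAL * ff.temp_k[m])
                    + fit.ds_cal / R_CAL)
            return np.var(lnk - pred)

        assert resid_var((0.2, 0.8)) <= resid_var((0.1, 0.9)) <= resid_var((0.05, 0.95))

    def test_too_few_transition_points(self):
        curve = gen_melt_curve(77.3, 226.7, t_range_c=(25.0, 45.0))
        with pytest.raises(ValueError):
            ff = fraction_folded(curve)
            vant_hoff_fit(ff)

    def test_grid_recovery_noiseless(self):
        for dh in (40.0, 105.0, 170.0):
            for tm_c in (60.0, 78.0, 95.0):
                ds = dh * 1000 / (tm_c + C_TO_K)
                curve = gen_melt_curve(dh, ds, t_range_c=(tm_c - 40, tm_c + 20))
                fit = fit_melt(curve)
                assert abs(fit.dh_kcal - dh) / dh < 1e-3
                assert abs(fit.ds_cal - ds) / ds < 1e-3

    def test_noisy_recovery_median_under_5pct(self):
        errs = []
        for seed in range(100):
            curve = gen_melt_curve(77.3, 226.7, noise_sd=0.32, seed=seed)
            fit = fit_melt(curve)
            errs.append(abs(fit.dh_kcal - 77.3) / 77.3)
        assert np.median(errs) < 0.05


class TestTmFromCurve:
    def test_closed_form_midpoint(self):
        # dH/dS = 341.0 K -> midpoint ~ 67.8 C
        dh = 77.3
        ds = dh * 1000 / 341.0
        curve = gen_melt_curve(dh, ds)
        ff = fraction_folded(curve)
        assert tm_from_curve(ff) == pytest.approx(341.0 - C_TO_K, abs=0.3)

    def test_single_crossing_unique_value(self):
        # scan wide enough that both baselines are pure states
        curve = gen_melt_curve(120.7, 334.0, t_range_c=(45.0, 115.0))
        ff = fraction_folded(curve)
        tm = tm_from_curve(ff)
        assert tm == pytest.approx(120.7 * 1000 / 334.0 - C_TO_K, abs=0.3)

    def test_midpoint_beyond_scan_reported_absent(self):
        # a melt whose midpoint lies past the scanned range never crosses
        # f = 0.5: reported as absent, mirroring '>T_max' reporting
        from splitscan.melt import FractionFolded

        t_k = np.linspace(25, 85, 60) + C_TO_K
        k = np.exp(-87.9e3 / (R_CAL * t_k) + 241.1 / R_CAL)
        ff = FractionFolded(t_k, 1 / (1 + k), 0, (0, 0), (-1, 0))
        assert ff.f.min() > 0.5
        with pytest.warns(UserWarning, match="never crosses"):
            assert tm_from_curve(ff) is None


class TestCompareVariants:
    def test_single_chain_variants_rank_above_split(self):
        fits = [fit_from_params(n, *p) for n, p in TABLE_PARAMS.items()]
        report = compare_variants(fits)
        order = list(report["construct"])
        for single in ("CP12", "CP36", "C1G"):
            for split in ("SP12", "SP36"):
                assert order.index(single) < order.index(split)

    def test_single_fit_report(self):
        report = compare_variants([fit_from_params("SP36", 77.3, 226.7)])
        assert len(report) == 1

    def test_ordering_matches_sort_oracle(self):
        rng = np.random.default_rng(9)
        fits = []
        for i in rng.permutation(8):
            dh = 60 + 10 * float(i)
            fits.append(fit_from_params(f"V{i}", dh, dh * 1000 / (350 - i)))
        report = compare_variants(fits)
        expected = sorted(fits, key=lambda f: f.tm_c, reverse=True)
        assert list(report["construct"]) == [f.construct for f in expected]

    def test_sp_cp_pairs_flagged(self):
        fits = [fit_from_params(n, *TABLE_PARAMS[n]) for n in ("CP12", "SP12", "SP36")]
        report = compare_variants(fits)
        flags = dict(zip(report["construct"], report["paired_site"]))
        assert flags["CP12"] == "12" and flags["SP12"] == "12"
        assert flags["SP36"] is None
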