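"""Assay math: standard curves, rates, Michaelis-Menten, EC50, percent change."""

import numpy as np
import pandas as pd
import pytest
import scipy.optimize

import lcatpam as lp

# DHE well concentrations of the acyltransferase plate layout
S_LEVELS = np.array([6.4, 9.6, 14.4, 21.6, 32.5, 50.6])
# reference condition Michaelis-Menten parameters used as generating truth
VMAX_REF, KM_REF = 8.66, 11.59


class TestStandardCurve:
    def test_exact_line(self):
        conc = np.array([0.0, 10.0, 20.0, 40.0])
        curve = lp.fit_standard_curve(conc, 40.0 * conc + 5.0)
        assert curve.slope == pytest.approx(40.0, rel=1e-10)
        assert curve.intercept == pytest.approx(5.0, rel=1e-10)
        assert not curve.nonpositive_slope

    def test_matches_normal_equations(self, rng):
        conc = np.linspace(0, 50, 8)
        signal = 37.0 * conc + 12.0 + rng.normal(0, 5.0, 8)
        curve = lp.fit_standard_curve(conc, signal)
        X = np.column_stack([np.ones_like(conc), conc])
        beta = np.linalg.solve(X.T @ X, X.T @ signal)
        assert curve.slope == pytest.approx(beta[1], rel=1e-10)

    def test_negative_slope_flagged(self):
        conc = np.array([0.0, 10.0, 20.0])
        with pytest.warns(UserWarning, match="slope"):
            curve = lp.fit_standard_curve(conc, -2.0 * conc + 100.0)
        assert curve.nonpositive_slope

    def test_degenerate_conc_rejected(self):
        with pytest.raises(ValueError):
            lp.fit_standard_curve([5.0, 5.0, 5.0], [1.0, 2.0, 3.0])


def _plate(rows):
    return lp.PlateData(wells=pd.DataFrame(rows))


def _curve(slope=40.0):
    conc = np.array([0.0, 10.0, 20.0, 40.0])
    return lp.fit_standard_curve(conc, slope * conc)


class TestSignalToRate:
    def test_arithmetic(self):
        plate = _plate([
            dict(condition_label="LCAT", replicate_id="r1", substrate_conc=10.0,
                 signal=450.0, background_signal=50.0, time_h=1.0)
        ])
        rates = lp.signal_to_rate(plate, _curve(40.0))
        assert rates["rate"].iloc[0] == pytest.approx(10.0)

    def test_signal_equal_background_gives_zero(self):
        plate = _plate([
            dict(condition_label="LCAT", replicate_id="r1", substrate_conc=10.0,
                 signal=50.0, background_signal=50.0, time_h=2.0)
        ])
        assert lp.signal_to_rate(plate, _curve())["rate"].iloc[0] == 0.0

    def test_negative_net_signal_clipped_and_flagged(self):
        plate = _plate([
            dict(condition_label="LCAT", replicate_id="r1", substrate_conc=10.0,
                 signal=40.0, background_signal=50.0, time_h=1.0)
        ])
        rates = lp.signal_to_rate(plate, _curve())
        assert rates["rate"].iloc[0] == 0.0
        assert bool(rates["clipped"].iloc[0])

    def test_linear_in_net_signal(self):
        base = dict(condition_label="LCAT", replicate_id="r1",
                    substrate_conc=10.0, background_signal=50.0, time_h=1.0)
        single = _plate([dict(base, signal=150.0)])
        double = _plate([dict(base, signal=250.0)])
        r1 = lp.signal_to_rate(single, _curve())["rate"].iloc[0]
        r2 = lp.signal_to_rate(double, _curve())["rate"].iloc[0]
        assert r2 == pytest.approx(2.0 * r1)

    def test_missing_background_names_condition(self):
        plate = _plate([
            dict(condition_label="LCAT+cana", replicate_id="r1",
                 substrate_conc=10.0, signal=450.0,
                 background_signal=np.nan, time_h=1.0)
        ])
        with pytest.raises(ValueError, match="LCAT\\+cana"):
            lp.signal_to_rate(plate, _curve())

    def test_zero_noise_plate_inverts_generator(self):
        plate, truth = lp.gen_mm_assay(lp.AssaySpec(noise_sd_fraction=0.0, seed=1))
        curve = lp.fit_standard_curve(
            plate.standard_curve["conc"], plate.standard_curve["signal"]
        )
        rates = lp.signal_to_rate(plate, curve)
        nonzero = rates[rates["substrate_conc"] > 0]
        expected = truth["vmax"] * nonzero["substrate_conc"] / (
            truth["km"] + nonzero["substrate_conc"]
        )
        np.testing.assert_allclose(nonzero["rate"], expected, atol=1e-9)


class TestMichaelisMenten:
    def test_noiseless_reference_recovery(self):
        v = VMAX_REF * S_LEVELS / (KM_REF + S_LEVELS)
        fit = lp.fit_michaelis_menten(S_LEVELS, v)
        assert fit.vmax == pytest.approx(VMAX_REF, rel=1e-6)
        assert fit.km == pytest.approx(KM_REF, rel=1e-6)

    def test_saturated_rates_hit_km_boundary(self):
        v = np.full_like(S_LEVELS, 5.0)
        with pytest.warns(UserWarning, match="boundary"):
            fit = lp.fit_michaelis_menten(S_LEVELS, v)
        assert fit.km_at_bound

    def test_matches_grid_search_oracle(self, rng):
        v_true = VMAX_REF * S_LEVELS / (KM_REF + S_LEVELS)
        v = v_true + rng.normal(0, 0.15, len(S_LEVELS))
        fit = lp.fit_michaelis_menten(S_LEVELS, np.clip(v, 0, None))

        def ssr(p):
            vm, km = p
            return float(np.sum((np.clip(v, 0, None) - vm * S_LEVELS / (km + S_LEVELS)) ** 2))

        # coarse grid then Nelder-Mead polish: an independent optimizer route
        grid_v = np.linspace(1.0, 20.0, 60)
        grid_k = np.linspace(0.5, 60.0, 120)
        best = min(
            ((vm, km) for vm in grid_v for km in grid_k), key=lambda p: ssr(p)
        )
        polished = scipy.optimize.minimize(
            ssr, best, method="Nelder-Mead",
            options={"xatol": 1e-10, "fatol": 1e-14, "maxiter": 5000},
        ).x
        assert fit.vmax == pytest.approx(polished[0], rel=1e-4)
        assert fit.km == pytest.approx(polished[1], rel=1e-4)

    def test_scale_equivariance(self, rng):
        v = VMAX_REF * S_LEVELS / (KM_REF + S_LEVELS) + rng.normal(0, 0.1, len(S_LEVELS))
        v = np.clip(v, 0.01, None)
        f1 = lp.fit_michaelis_menten(S_LEVELS, v)
        f2 = lp.fit_michaelis_menten(S_LEVELS, 3.5 * v)
        assert f2.vmax == pytest.approx(3.5 * f1.vmax, rel=1e-9)
        assert f2.km == pytest.approx(f1.km, rel=1e-9)

    def test_parameter_recovery_with_plate_noise(self):
        # 2%-of-Vmax signal noise, triplicates, plate well concentrations
        vmax_err, km_err = [], []
        root = np.random.SeedSequence(321)
        for child in root.spawn(200):
            seed = int(child.generate_state(1)[0] % (2**31))
            plate, truth = lp.gen_mm_assay(
                lp.AssaySpec(noise_sd_fraction=0.02, seed=seed)
            )
            curve = lp.fit_standard_curve(
                plate.standard_curve["conc"], plate.standard_curve["signal"]
            )
            rates = lp.signal_to_rate(plate, curve)
            fit = lp.MichaelisMenten.from_rates(rates, "LCAT").fit()
            vmax_err.append(abs(fit.vmax - truth["vmax"]) / truth["vmax"])
            km_err.append(abs(fit.km - truth["km"]) / truth["km"])
        assert np.median(vmax_err) < 0.05
        assert np.median(km_err) < 0.15

    def test_too_few_substrate_levels_rejected(self):
        with pytest.raises(ValueError):
            lp.MichaelisMenten([1.0, 2.0, 3.0], [0.1, 0.2, 0.3])


class TestCatalyticEfficiency:
    def test_arithmetic(self):
        fit = lp.MMResults(vmax=10.0, km=5.0, vmax_se=0.1, km_se=0.1)
        eff = lp.catalytic_efficiency(fit, enzyme_conc=0.1)
        assert fit.kcat == pytest.approx(100.0)
        assert eff == pytest.approx(20.0)

    def test_efficiency_ratio_independent_of_enzyme_conc(self):
        a = lp.MMResults(vmax=10.0, km=5.0, vmax_se=0, km_se=0)
        b = lp.MMResults(vmax=15.0, km=4.0, vmax_se=0, km_se=0)
        ratios = []
        for e in (0.01, 0.1, 1.0):
            ratios.append(
                lp.catalytic_efficiency(a, e) / lp.catalytic_efficiency(b, e)
            )
        assert ratios[0] == pytest.approx(ratios[1]) == pytest.approx(ratios[2])

    def test_matches_direct_formula(self, rng):
        for _ in range(20):
            vmax = rng.uniform(1, 20)
            km = rng.uniform(1, 60)
            e = rng.uniform(0.01, 1.0)
            fit = lp.MMResults(vmax=vmax, km=km, vmax_se=0, km_se=0)
            assert lp.catalytic_efficiency(fit, e) == pytest.approx(
                (vmax / e) / km, rel=1e-12
            )

    def test_invalid_enzyme_conc(self):
        fit = lp.MMResults(vmax=10.0, km=5.0, vmax_se=0, km_se=0)
        with pytest.raises(ValueError):
            lp.catalytic_efficiency(fit, 0.0)


class TestPercentChange:
    @pytest.mark.parametrize(
        "treated, control, raw, rounded",
        [
            (15.70, 6.76, 132.2, 130.0),  # phospholipase Vmax, canagliflozin
            (11.68, 6.76, 72.8, 70.0),    # phospholipase Vmax, dapagliflozin
            (14.78, 8.66, 70.7, 70.0),    # acyltransferase Vmax, canagliflozin
        ],
    )
    def test_reference_vmax_percentages(self, treated, control, raw, rounded):
        assert lp.percent_change(treated, control, round_to=None) == pytest.approx(
            raw, abs=0.05
        )
        assert lp.percent_change(treated, control) == rounded

    def test_no_change_and_negative(self):
        assert lp.percent_change(5.0, 5.0) == 0.0
        assert lp.percent_change(4.0, 5.0, round_to=None) == pytest.approx(-20.0)
        assert lp.percent_change(4.25, 5.0) == -20.0  # round half away from zero

    def test_invalid_control(self):
        with pytest.raises(ValueError):
            lp.percent_change(1.0, 0.0)


PAM_CONCS = np.array([0.001, 0.01, 0.1, 1.0, 10.0])


def _four_pl(conc, bottom, top, ec50, hill):
    return bottom + (top - bottom) / (
        1.0 + 10.0 ** ((np.log10(ec50) - np.log10(conc)) * hill)
    )


class TestDoseResponse:
    def test_noiseless_recovery_at_titration_concs(self):
        resp = _four_pl(PAM_CONCS, 100.0, 250.0, 0.1, 1.0)
        fit = lp.fit_dose_response(PAM_CONCS, resp)
        assert fit.ec50 == pytest.approx(0.1, rel=1e-5)
        assert fit.top == pytest.approx(250.0, rel=1e-5)
        assert fit.bottom == pytest.approx(100.0, rel=1e-5)
        assert fit.hill == pytest.approx(1.0, rel=1e-5)
        assert not fit.no_effect

    def test_flat_response_flags_no_effect(self):
        fit = lp.fit_dose_response(PAM_CONCS, np.full_like(PAM_CONCS, 100.0))
        assert fit.no_effect
        assert np.isnan(fit.ec50)

    def test_fix_bottom_option(self):
        resp = _four_pl(PAM_CONCS, 100.0, 250.0, 0.1, 1.0)
        fit = lp.DoseResponse(PAM_CONCS, resp).fit(fix_bottom=100.0)
        assert fit.bottom == 100.0
        assert fit.ec50 == pytest.approx(0.1, rel=1e-5)

    def test_matches_log_grid_search_oracle(self, rng):
        resp = _four_pl(PAM_CONCS, 100.0, 250.0, 0.08, 1.0) + rng.normal(0, 4.0, 5)
        fit = lp.fit_dose_response(PAM_CONCS, resp)
        logc = np.log10(PAM_CONCS)

        def ssr_linearized(log_ec50, hill):
            # for fixed (ec50, hill) the model is linear in (bottom, top)
            f = 1.0 / (1.0 + 10.0 ** ((log_ec50 - logc) * hill))
            X = np.column_stack([1.0 - f, f])
            beta, *_ = np.linalg.lstsq(X, resp, rcond=None)
            return float(np.sum((resp - X @ beta) ** 2))

        grid = [
            (le, h)
            for le in np.linspace(-3, 1, 160)
            for h in np.linspace(0.3, 3.0, 60)
        ]
        best = min(grid, key=lambda p: ssr_linearized(*p))
        polished = scipy.optimize.minimize(
            lambda p: ssr_linearized(*p), best, method="Nelder-Mead",
            options={"xatol": 1e-10, "fatol": 1e-14, "maxiter": 5000},
        ).x
        assert fit.ec50 == pytest.approx(10.0 ** polished[0], rel=1e-3)

    def test_ec50_recovery_under_noise(self):
        # 10%-of-control response noise, triplicates: EC50 within 1.5x
        hits, n_runs = 0, 200
        root = np.random.SeedSequence(99)
        for child in root.spawn(n_runs):
            seed = int(child.generate_state(1)[0] % (2**31))
            table, truth = lp.gen_dose_response(
                ec50=0.1, top=250.0, bottom=100.0, hill=1.0,
                noise_sd=10.0, n_replicates=3, seed=seed,
            )
            try:
                fit = lp.fit_dose_response(table["conc"], table["response_pct"])
            except RuntimeError:
                continue
            if fit.no_effect or not np.isfinite(fit.ec50):
                continue
            ratio = fit.ec50 / truth["ec50"]
            if 1 / 1.5 <= ratio <= 1.5:
                hits += 1
        assert hits >= int(0.95 * n_runs)

    def test_extrapolated_ec50_warns(self):
        resp = _four_pl(PAM_CONCS, 100.0, 250.0, 40.0, 1.0)
        with pytest.warns(UserWarning, match="outside"):
            fit = lp.fit_dose_response(PAM_CONCS, resp)
        assert fit.extrapolated

    def test_narrow_dose_range_warns(self):
        concs = np.array([0.1, 0.2, 0.4, 0.8, 1.6])
        resp = _four_pl(concs, 100.0, 250.0, 0.4, 1.0)
        with pytest.warns(UserWarning, match="decades"):
            lp.DoseResponse(concs, resp)


class TestPerReplicateFits:
    def test_triplicate_summary_matches_per_replicate_fits(self):
        plate, truth = lp.gen_mm_assay(
            lp.AssaySpec(noise_sd_fraction=0.01, seed=12)
        )
        curve = lp.fit_standard_curve(
            plate.standard_curve["conc"], plate.standard_curve["signal"]
        )
        rates = lp.signal_to_rate(plate, curve)
        fits = lp.fit_mm_per_replicate(rates, "LCAT")
        assert len(fits) == 3
        assert set(fits["replicate_id"]) == {"rep1", "rep2", "rep3"}
        # all three replicate fits hover near truth
        np.testing.assert_allclose(fits["vmax"], truth["vmax"], rtol=0.15)

    def test_pooled_mode(self):
        plate, _ = lp.gen_mm_assay(lp.AssaySpec(noise_sd_fraction=0.0, seed=1))
        curve = lp.fit_standard_curve(
            plate.standard_curve["conc"], plate.standard_curve["signal"]
        )
        rates = lp.signal_to_rate(plate, curve)
        fits = lp.fit_mm_per_replicate(rates, "LCAT", pooled=True)
        assert len(fits) == 1
        assert fits["vmax"].iloc[0] == pytest.approx(VMAX_REF, rel=1e-6)
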