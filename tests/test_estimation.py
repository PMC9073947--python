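"""Efflux-clearance fitting: self-consistency, noise recovery, boundary
handling, AUC-ratio route and gestational extrapolation."""

import numpy as np
import pandas as pd
import pytest

import fetalkpuu as fk


class TestFitNoiseFree:
    def test_recovers_generating_clearance(
        self, noise_free_dyads, nelfinavir, nelfinavir_regimen, nelfinavir_placenta
    ):
        model = fk.PlacentalTransferModel(
            noise_free_dyads, nelfinavir, nelfinavir_regimen,
            placenta=nelfinavir_placenta.with_efflux(0.0),
        )
        res = model.fit()
        assert res.cl_int_efflux == pytest.approx(350.0, rel=0.01)
        assert res.afe == pytest.approx(1.0, abs=1e-6)
        assert res.aafe == pytest.approx(1.0, abs=1e-6)
        assert res.kpuu_fetal == pytest.approx(240 / 590, abs=0.005)
        assert not res.at_boundary

    def test_aafe_objective_agrees_at_perfect_fit(
        self, noise_free_dyads, nelfinavir, nelfinavir_regimen, nelfinavir_placenta
    ):
        model = fk.PlacentalTransferModel(
            noise_free_dyads, nelfinavir, nelfinavir_regimen,
            placenta=nelfinavir_placenta.with_efflux(0.0),
        )
        res = model.fit(objective="aafe")
        assert res.cl_int_efflux == pytest.approx(350.0, rel=0.01)
        assert res.aafe == pytest.approx(1.0, abs=1e-5)

    def test_three_routes_agree(
        self, noise_free_dyads, nelfinavir, nelfinavir_regimen, nelfinavir_placenta
    ):
        # closed form, AUC ratio from simulation, and the fitted estimate
        res = fk.fit_efflux(
            noise_free_dyads, nelfinavir, nelfinavir_regimen,
            placenta=nelfinavir_placenta.with_efflux(0.0),
        )
        closed = fk.steady_state_kpuu(nelfinavir_placenta)
        assert res.kpuu_fetal == pytest.approx(closed, rel=0.02)
        assert res.auc_ratio_unbound == pytest.approx(closed, rel=0.02)
        assert fk.kpuu_from_aucs(res.auc_ratio_unbound, 1.0) == pytest.approx(
            res.kpuu_fetal, rel=0.02
        )


class TestFitNoisy:
    def test_single_seed_recovery(self, nelfinavir, nelfinavir_regimen, nelfinavir_placenta):
        # tolerance established by the 200-replicate Monte-Carlo run in
        # test_acceptance (sigma_log10 = 0.3, n = 40)
        dyads = fk.generate_dyads(
            nelfinavir, nelfinavir_regimen, true_kpuu=0.41, n=40,
            sigma_log10=0.3, seed=7,
        )
        res = fk.fit_efflux(
            dyads, nelfinavir, nelfinavir_regimen,
            placenta=nelfinavir_placenta.with_efflux(0.0),
        )
        assert abs(res.kpuu_fetal - 0.41) < 0.05
        assert res.afe == pytest.approx(1.0, abs=1e-6)
        assert res.aafe > 1.0  # scattered data cannot fit perfectly

    def test_bootstrap_interval_covers_estimate(
        self, nelfinavir, nelfinavir_regimen, nelfinavir_placenta
    ):
        dyads = fk.generate_dyads(
            nelfinavir, nelfinavir_regimen, true_kpuu=0.41, n=40,
            sigma_log10=0.3, seed=7,
        )
        model = fk.PlacentalTransferModel(
            dyads, nelfinavir, nelfinavir_regimen,
            placenta=nelfinavir_placenta.with_efflux(0.0),
        )
        res = model.fit(bootstrap=50, seed=11)
        ci = res.conf_int()
        lo, hi = ci["kpuu_fetal"]
        assert lo < res.kpuu_fetal < hi
        assert ci["cl_int_efflux"][0] < res.cl_int_efflux < ci["cl_int_efflux"][1]

    def test_conf_int_requires_bootstrap(
        self, noise_free_dyads, nelfinavir, nelfinavir_regimen, nelfinavir_placenta
    ):
        res = fk.fit_efflux(
            noise_free_dyads, nelfinavir, nelfinavir_regimen,
            placenta=nelfinavir_placenta.with_efflux(0.0),
        )
        with pytest.raises(ValueError, match="bootstrap"):
            res.conf_int()


class TestBoundary:
    def test_observations_above_passive_prediction(
        self, nelfinavir, nelfinavir_regimen, nelfinavir_placenta
    ):
        # UV/MP centred well above 1: no efflux can explain it (no influx
        # transporter in the model) -> boundary estimate 0 with a flag
        rng = np.random.default_rng(5)
        n = 10
        dyads = pd.DataFrame(
            {
                "time_after_dose_h": rng.uniform(0, 12, n),
                "mp_conc": np.full(n, 1.0),
                "uv_conc": np.full(n, 1.5),
            }
        )
        res = fk.fit_efflux(
            dyads, nelfinavir, nelfinavir_regimen,
            placenta=nelfinavir_placenta.with_efflux(0.0),
        )
        assert res.at_boundary
        assert res.cl_int_efflux == 0.0
        assert res.kpuu_fetal == pytest.approx(1.0)


class TestValidation:
    def test_too_few_dyads(self, nelfinavir, nelfinavir_regimen):
        dyads = pd.DataFrame(
            {"time_after_dose_h": [1.0, 2.0], "uv_conc": [0.1, 0.2], "mp_conc": [1, 1]}
        )
        with pytest.raises(ValueError, match="at least 3"):
            fk.PlacentalTransferModel(dyads, nelfinavir, nelfinavir_regimen)

    def test_nonpositive_concentrations(self, nelfinavir, nelfinavir_regimen):
        dyads = pd.DataFrame(
            {
                "time_after_dose_h": [1.0, 2.0, 3.0],
                "uv_conc": [0.1, -0.2, 0.3],
                "mp_conc": [1.0, 1.0, 1.0],
            }
        )
        with pytest.raises(ValueError, match="nonpositive"):
            fk.PlacentalTransferModel(dyads, nelfinavir, nelfinavir_regimen)

    def test_missing_columns(self, nelfinavir, nelfinavir_regimen):
        with pytest.raises(ValueError, match="missing columns"):
            fk.PlacentalTransferModel(
                pd.DataFrame({"uv_conc": [1, 2, 3]}), nelfinavir, nelfinavir_regimen
            )

    def test_bad_objective(
        self, noise_free_dyads, nelfinavir, nelfinavir_regimen, nelfinavir_placenta
    ):
        model = fk.PlacentalTransferModel(
            noise_free_dyads, nelfinavir, nelfinavir_regimen,
            placenta=nelfinavir_placenta.with_efflux(0.0),
        )
        with pytest.raises(ValueError, match="objective"):
            model.fit(objective="rmse")


class TestKpuuFromAucs:
    def test_ratio_definition(self):
        assert fk.kpuu_from_aucs(4.1, 10.0) == pytest.approx(0.41)
        assert fk.kpuu_from_aucs(3.0, 3.0) == pytest.approx(1.0)

    def test_window_mismatch(self):
        with pytest.raises(ValueError, match="windows differ"):
            fk.kpuu_from_aucs(1.0, 2.0, window_fetal=(0, 12), window_maternal=(0, 24))

    def test_nonpositive(self):
        with pytest.raises(ValueError):
            fk.kpuu_from_aucs(0.0, 1.0)


class TestGestationalExtrapolation:
    def test_term_reference_returns_estimate_unchanged(self):
        curve = fk.default_abundance_curve("P-gp")
        k_term = fk.predict_kpuu_at_gw(240, 350, curve.term_gw, curve)
        assert k_term == pytest.approx(240 / 590, rel=1e-6)

    @pytest.mark.parametrize(
        "gw, expected", [(25, 0.34), (15, 0.23)]
    )
    def test_nelfinavir_default_curve_anchors(self, gw, expected):
        curve = fk.default_abundance_curve("P-gp")
        assert fk.predict_kpuu_at_gw(240, 350, gw, curve) == pytest.approx(
            expected, abs=0.005
        )

    def test_monotone_in_abundance(self):
        curve = fk.default_abundance_curve("P-gp")
        r = curve(25)
        k1 = 240 / (240 + r * 350)
        k2 = 240 / (240 + 2 * r * 350)
        assert k2 < k1

    def test_results_predict_at_gw(
        self, noise_free_dyads, nelfinavir, nelfinavir_regimen, nelfinavir_placenta
    ):
        res = fk.fit_efflux(
            noise_free_dyads, nelfinavir, nelfinavir_regimen,
            placenta=nelfinavir_placenta.with_efflux(0.0),
        )
        ks = [res.predict_at_gw(g) for g in (15, 25, 38)]
        assert ks == sorted(ks)  # strictly increasing towards term
        assert ks[2] == pytest.approx(res.kpuu_fetal, rel=1e-3)


def test_summary_and_row_report(
    noise_free_dyads, nelfinavir, nelfinavir_regimen, nelfinavir_placenta
):
    res = fk.fit_efflux(
        noise_free_dyads, nelfinavir, nelfinavir_regimen,
        placenta=nelfinavir_placenta.with_efflux(0.0),
    )
    text = res.summary()
    assert "Kp,uu,fetal" in text and "nelfinavir" in text
    row = res.to_row().iloc[0]
    assert row["kpuu_fetal"] == pytest.approx(0.41, abs=0.01)
    assert row["f_efflux"] == pytest.approx(0.59, abs=0.01)
    assert res.f_efflux == pytest.approx(1 - res.kpuu_fetal)
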