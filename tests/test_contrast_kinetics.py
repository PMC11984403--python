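"""Contrast-kinetics checks: AIF, Tofts leakage, R1 conversion, DCE forward."""

import numpy as np
import pytest
from scipy.integrate import quad

import wexdce as w
from wexdce.contrast_kinetics import frame_times
from wexdce.model_fitting import DEFAULT_R1_I, baseline_rates_from_t1


@pytest.fixture
def aif():
    return w.AIFSpec(bolus_times_s=(30.0,), dose_per_bolus=0.1)


class TestAifConcentration:
    def test_zero_before_first_bolus(self, aif):
        t = np.linspace(0.0, 29.9, 50)
        assert np.all(w.aif_concentration(t, aif) == 0.0)

    def test_linear_in_dose(self, aif):
        t = np.linspace(0.0, 400.0, 100)
        double = w.AIFSpec(bolus_times_s=(30.0,), dose_per_bolus=0.2)
        np.testing.assert_allclose(
            w.aif_concentration(t, double), 2.0 * w.aif_concentration(t, aif)
        )

    def test_auc_matches_quadrature(self, aif):
        """Numeric quadrature vs the analytic integral of the exponentials."""
        auc_ref, _ = quad(lambda t: w.aif_concentration(np.array([t]), aif)[0],
                          0.0, 600.0, limit=200)
        decays = np.asarray(aif.decays_per_min) / 60.0
        amps = np.asarray(aif.amplitudes) * aif.dose_per_bolus
        analytic = sum(
            a / m * (1.0 - np.exp(-m * 570.0)) for a, m in zip(amps, decays)
        )
        assert auc_ref == pytest.approx(analytic, rel=1e-6)

    def test_dual_bolus_superposition(self):
        single = w.AIFSpec(bolus_times_s=(30.0,), dose_per_bolus=0.25)
        dual = w.AIFSpec(bolus_times_s=(30.0, 330.0), dose_per_bolus=0.25)
        t = np.linspace(0.0, 700.0, 200)
        shifted = w.aif_concentration(np.clip(t - 300.0, 0.0, None), single)
        shifted[t < 330.0] = 0.0
        np.testing.assert_allclose(
            w.aif_concentration(t, dual),
            w.aif_concentration(t, single) + shifted,
            atol=1e-12,
        )


class TestTissueCa:
    def test_no_extravasation(self, aif):
        t = np.linspace(0.0, 300.0, 60)
        kin = w.CAKinetics(Ktrans=0.0, v_o=0.3)
        assert np.all(w.tissue_ca(t, aif, kin) == 0.0)

    def test_constant_plasma_equilibrates(self):
        spec = w.AIFSpec(
            model="measured",
            measured_t_s=np.array([0.0, 1e5]),
            measured_conc_mM=np.array([2.0, 2.0]),
        )
        kin = w.CAKinetics(Ktrans=0.3, v_o=0.3, hct=0.0)
        t = np.array([0.0, 3600.0])
        c_o = w.tissue_ca(t, spec, kin)
        assert c_o[-1] == pytest.approx(2.0, rel=1e-3)

    def test_matches_numeric_convolution(self, aif):
        kin = w.CAKinetics(Ktrans=0.1, v_o=0.3)
        t = np.arange(0.0, 400.0, 4.0)
        got = w.tissue_ca(t, aif, kin)
        # trapezoidal convolution oracle at dt = 0.01 s
        dt = 0.01
        ft = np.arange(0.0, t[-1] + dt, dt)
        cp = w.aif_concentration(ft, aif) / (1.0 - kin.hct)
        kep = kin.Ktrans / 60.0 / kin.v_o
        kernel = kep * np.exp(-kep * ft)
        conv = np.convolve(cp, kernel)[: ft.size] * dt
        ref = np.interp(t, ft, conv)
        scale = ref.max()
        assert np.max(np.abs(got - ref)) / scale < 1e-4

    def test_tissue_never_exceeds_peak_plasma(self, aif):
        t = np.arange(0.0, 500.0, 2.0)
        kin = w.CAKinetics(Ktrans=0.5, v_o=0.2)
        peak_plasma = (w.aif_concentration(t, aif) / (1.0 - kin.hct)).max()
        assert w.tissue_ca(t, aif, kin).max() <= peak_plasma + 1e-12


class TestCompartmentR1:
    def test_baselines_before_bolus(self, aif):
        r1_b, r1_o = w.compartment_r1(np.array([0.0, 10.0]), 0.7, 0.5, aif,
                                      w.CAKinetics())
        np.testing.assert_allclose(r1_b, 0.7)
        np.testing.assert_allclose(r1_o, 0.5)

    def test_linear_relaxivity_shift(self):
        # 5 mM extracellular CA at r1 = 4 raises R1_o by exactly 20 s^-1
        kin = w.CAKinetics(r1=4.0)
        assert 0.5 + kin.r1 * 5.0 == pytest.approx(20.5)

    def test_composes_from_aif_and_tissue_ca(self, aif):
        kin = w.CAKinetics(Ktrans=0.08, v_o=0.25)
        t = np.linspace(0.0, 300.0, 40)
        r1_b, r1_o = w.compartment_r1(t, 0.7, 0.5, aif, kin)
        np.testing.assert_allclose(r1_b, 0.7 + kin.r1 * w.aif_concentration(t, aif))
        np.testing.assert_allclose(r1_o, 0.5 + kin.r1 * w.tissue_ca(t, aif, kin))

    def test_dose_linearity_propagates_to_r1(self):
        t = np.linspace(0.0, 300.0, 40)
        kin = w.CAKinetics(Ktrans=0.08, v_o=0.25)
        a1 = w.AIFSpec(bolus_times_s=(30.0,), dose_per_bolus=0.1)
        a2 = w.AIFSpec(bolus_times_s=(30.0,), dose_per_bolus=0.2)
        rb1, ro1 = w.compartment_r1(t, 0.7, 0.5, a1, kin)
        rb2, ro2 = w.compartment_r1(t, 0.7, 0.5, a2, kin)
        np.testing.assert_allclose(rb2 - 0.7, 2.0 * (rb1 - 0.7), atol=1e-12)
        np.testing.assert_allclose(ro2 - 0.5, 2.0 * (ro1 - 0.5), atol=1e-10)


def three_site(k_io=5.0, t1_0=1.6, p_b=0.05, p_o=0.30, k_bo=2.0):
    base = baseline_rates_from_t1(t1_0, p_b, p_o)
    return w.ThreeSiteParams(
        p_b=p_b, p_o=p_o, p_i=1.0 - p_b - p_o, k_bo=k_bo, k_io=k_io,
        R1_b0=base, R1_o0=base, R1_i=DEFAULT_R1_I,
    )


class TestDceForward:
    def test_zero_dose_flat_baseline(self, human_protocol):
        spec = w.AIFSpec(bolus_times_s=(36.0,), dose_per_bolus=0.0)
        sig = w.dce_forward(human_protocol, three_site(), w.CAKinetics(), spec)
        assert np.ptp(sig) < 1e-12

    def test_dual_bolus_rat_protocol_two_onsets(self):
        prot = w.rat_dce_protocol()
        spec = w.bolus_spec(prot)
        sig = w.dce_forward(prot, three_site(), w.CAKinetics(Ktrans=0.1), spec)
        d = np.diff(sig)
        # enhancement begins exactly at the two bolus frames (20 and 120):
        # flat before the first, washing out before the second, and a
        # positive jump at each onset
        assert np.all(np.abs(d[:19]) < 1e-12)
        assert d[19] > 1e-4
        assert np.all(d[110:119] < 0)
        assert d[119] > 1e-4

    def test_few_prebolus_frames_warns(self):
        prot = w.AcquisitionProtocol(
            n_frames=30, frame_interval_s=4.5, bolus_frames=(1,),
            dose_mmol_per_kg=0.1, fa_deg=10.0,
        )
        spec = w.bolus_spec(prot)
        with pytest.warns(UserWarning, match="pre-bolus"):
            w.dce_forward(prot, three_site(), w.CAKinetics(), spec)

    def test_matches_end_to_end_pulse_train(self):
        """Per-frame steady state vs stepping every TR through the scan."""
        prot = w.human_dce_protocol(n_frames=40)
        spec = w.bolus_spec(prot)
        params = three_site()
        kin = w.CAKinetics(Ktrans=0.1, v_o=params.p_o)
        got = w.dce_forward(prot, params, kin, spec)

        t_mid = frame_times(prot)
        r1_b, r1_o = w.compartment_r1(t_mid, params.R1_b0, params.R1_o0, spec, kin)
        cos_a = np.cos(np.deg2rad(prot.fa_deg))
        sin_a = np.sin(np.deg2rad(prot.fa_deg))
        n_per_frame = int(round(prot.frame_interval_s / prot.tr_s))
        m = params.fractions.copy()
        ref = np.zeros(prot.n_frames)
        for k in range(prot.n_frames):
            for _ in range(n_per_frame):
                m = w.longitudinal_propagate(
                    params, r1_b[k], r1_o[k], cos_a * m, prot.tr_s
                )
            ref[k] = sin_a * m.sum()
        np.testing.assert_allclose(got, ref, rtol=1e-4)

    def test_post_bolus_signal_monotone_in_k_io(self, human_protocol):
        """Identifiability direction: k_io shifts the washout signal one way."""
        spec = w.bolus_spec(human_protocol)
        frame = 60  # well after the bolus
        levels = [
            w.dce_forward(
                human_protocol, three_site(k_io=k),
                w.CAKinetics(Ktrans=0.1, v_o=0.3), spec, normalize=True,
            )[frame]
            for k in [0.5, 2.0, 5.0, 10.0, 20.0]
        ]
        diffs = np.diff(levels)
        assert np.all(diffs > 0) or np.all(diffs < 0)

    def test_measured_aif_round_trip(self, tmp_path, human_protocol):
        import pandas as pd

        spec = w.bolus_spec(human_protocol)
        t = np.arange(0.0, human_protocol.duration_s, 0.1)
        pd.DataFrame(
            {"time_s": t, "concentration_mM": w.aif_concentration(t, spec)}
        ).to_csv(tmp_path / "aif.csv", index=False)
        from wexdce.contrast_kinetics import read_measured_aif

        measured = read_measured_aif(tmp_path / "aif.csv")
        params = three_site()
        kin = w.CAKinetics(Ktrans=0.1)
        sig_a = w.dce_forward(human_protocol, params, kin, spec)
        sig_b = w.dce_forward(human_protocol, params, kin, measured)
        np.testing.assert_allclose(sig_a, sig_b, rtol=1e-3)
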