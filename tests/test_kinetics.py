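"""Trait extraction: series derivation, exponential fits, slopes, PI, QC."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

from npqmap import traits as T
from npqmap.kinetics import (
    derive_series,
    extract_traits,
    fit_induction,
    fit_recovery,
    fit_relaxation,
    initial_slope,
    photoprotection_index,
    predicted_fvpfmp,
    qc_filter,
)
from npqmap.sim import simulate_trace
from npqmap.sim.traces import npq_relaxation, pure_npq_params

T_LIGHT = np.array([1 / 3, 2 / 3, 1, 2, 3, 4, 5, 6, 7, 8, 9, 10])
T_DARK = np.array([1 / 3, 2 / 3, 1, 2, 3, 4, 7, 10, 12])


class TestDeriveSeries:
    def test_definitions(self, panel_params):
        tr = simulate_trace(panel_params, noise_sd=0.0)
        s = derive_series(tr)
        # NPQ, Fv/Fm and PhiPSII from their defining ratios
        assert (1000 - 500) / 500 == 1.0  # NPQ with Fm=1000, Fm'=500
        assert s["fvfm"] == pytest.approx(0.75)
        light = tr[tr["phase"] == "light"].iloc[3]
        assert s["npq_light"][3] == pytest.approx(
            (light["Fm"] - light["Fm_prime"]) / light["Fm_prime"]
        )

    def test_manual_ratios(self):
        # F=300, Fm'=500 -> PhiPSII = 0.4; Fo=250, Fm=1000 -> Fv/Fm = 0.75
        rows = [
            dict(disc_id="d", time_min=0.0, phase="dark0", F=250, Fm_prime=1000,
                 Fo=250, Fm=1000),
        ]
        for i, t in enumerate(T_LIGHT):
            rows.append(dict(disc_id="d", time_min=t, phase="light", F=300,
                             Fm_prime=500, Fo=250, Fm=1000))
        for t in T_DARK:
            rows.append(dict(disc_id="d", time_min=10 + t, phase="dark", F=300,
                             Fm_prime=500, Fo=250, Fm=1000))
        s = derive_series(pd.DataFrame(rows))
        assert s["fvfm"] == pytest.approx(0.75)
        np.testing.assert_allclose(s["phi_dark"], 0.4)
        np.testing.assert_allclose(s["npq_light"], 1.0)

    def test_nonpositive_fluorescence_rejected(self, panel_params):
        tr = simulate_trace(panel_params)
        tr.loc[tr.index[5], "Fm_prime"] = -1.0
        with pytest.raises(ValueError, match="fluorescence"):
            derive_series(tr)


class TestFits:
    @pytest.mark.parametrize(
        "fitter,t,curve,truth",
        [
            # printed panel extremes/means round-trip through each model
            (fit_induction, T_LIGHT, lambda t: 2.8 * (1 - np.exp(-0.58 * t)),
             dict(amplitude=2.8, k=0.58)),
            (fit_induction, T_LIGHT, lambda t: 3.1 * (1 - np.exp(-0.84 * t)),
             dict(amplitude=3.1, k=0.84)),
            (fit_relaxation, T_DARK, lambda t: 2.0 * np.exp(-5.09 * t) + 0.89,
             dict(amplitude=2.0, k=5.09, offset=0.89)),
            (fit_recovery, T_DARK, lambda t: 0.3 * (1 - np.exp(-5.08 * t)) + 0.2,
             dict(amplitude=0.3, k=5.08, offset=0.2)),
        ],
    )
    def test_noiseless_round_trip(self, fitter, t, curve, truth):
        fit = fitter(t, curve(t))
        assert fit.converged
        for attr, val in truth.items():
            assert getattr(fit, attr) == pytest.approx(val, rel=1e-6)
        assert fit.r2 == pytest.approx(1.0, abs=1e-9)

    def test_flat_series_flagged(self):
        assert not fit_induction(T_LIGHT, np.zeros_like(T_LIGHT)).converged
        assert not fit_relaxation(T_DARK, np.full_like(T_DARK, 0.89)).converged

    def test_zero_offset_recovered(self):
        fit = fit_relaxation(T_DARK, 2.0 * np.exp(-5.09 * T_DARK))
        assert abs(fit.offset) < 1e-6

    def test_step_series_rate_capped_and_flagged(self):
        # effectively instantaneous recovery: best k runs into the bound
        y = 0.5 - 0.3 * np.exp(-45.0 * T_DARK)
        fit = fit_recovery(T_DARK, y)
        assert not fit.converged

    def test_shuffled_order_same_fit(self, rng):
        y = 0.3 * (1 - np.exp(-5.08 * T_DARK)) + 0.2
        perm = rng.permutation(len(T_DARK))
        a = fit_recovery(T_DARK, y)
        b = fit_recovery(T_DARK[perm], y[perm])
        assert a.k == pytest.approx(b.k, rel=1e-12)

    def test_too_few_points_rejected(self):
        with pytest.raises(ValueError):
            fit_induction([1, 2, 3], [0.1, 0.2, 0.3])


class TestInitialSlope:
    def test_exact_line(self):
        t = np.array([1 / 3, 2 / 3, 1.0])
        assert initial_slope(t, 1.29 * t, anchor_origin=True) == pytest.approx(1.29)

    def test_constant_series_zero(self):
        t = np.array([1 / 3, 2 / 3, 1.0])
        assert initial_slope(t, np.ones(3)) == pytest.approx(0.0)

    def test_matches_brute_force_ols(self):
        # curve points at 0, 1/3, 2/3, 1 min with the (0,0) anchor
        t = np.array([1 / 3, 2 / 3, 1.0])
        y = 2.8 * (1 - np.exp(-0.58 * t))
        ta = np.concatenate([[0.0], t])
        ya = np.concatenate([[0.0], y])
        X = np.column_stack([np.ones(4), ta])
        slope_oracle = np.linalg.lstsq(X, ya, rcond=None)[0][1]
        assert initial_slope(t, y, anchor_origin=True) == pytest.approx(
            slope_oracle, rel=1e-12
        )

    def test_too_few_points_undefined(self):
        assert np.isnan(initial_slope([2.0, 3.0], [1.0, 2.0]))


class TestPhotoprotectionIndex:
    def test_no_quenching_no_photoinhibition(self):
        assert photoprotection_index(0.75, 0.75, 0.0) == pytest.approx(1.0)

    def test_predicted_value_closed_form(self):
        assert predicted_fvpfmp(0.75, 0.89) == pytest.approx(0.61350, abs=1e-5)
        assert photoprotection_index(0.75, 0.61350, 0.89) == pytest.approx(
            1.0, abs=1e-4
        )

    def test_printed_panel_mean(self):
        assert photoprotection_index(0.75, 0.503, 0.89) == pytest.approx(
            0.8199, abs=1e-4
        )

    def test_pure_npq_trace_gives_exactly_one(self, panel_params):
        tr = simulate_trace(pure_npq_params(panel_params), noise_sd=0.0)
        rec = extract_traits(tr)
        assert rec[T.PI].iloc[0] == 1.0

    def test_invalid_inputs_rejected(self):
        with pytest.raises(ValueError):
            photoprotection_index(1.2, 0.5, 0.3)
        with pytest.raises(ValueError):
            photoprotection_index(0.75, 0.5, -0.1)


class TestExtractAndQC:
    def test_full_round_trip_all_traits(self, panel_params):
        tr = simulate_trace(panel_params, noise_sd=0.0)
        rec = extract_traits(tr).iloc[0]
        assert rec[T.IND_K] == pytest.approx(0.58, rel=1e-6)
        assert rec[T.IND_AMP] == pytest.approx(2.8, rel=1e-6)
        assert rec[T.REL_K] == pytest.approx(5.09, rel=1e-6)
        assert rec[T.REL_AMP] == pytest.approx(1.91, rel=1e-6)
        assert rec[T.REL_INTERCEPT] == pytest.approx(0.89, rel=1e-6)
        assert rec[T.REC_K] == pytest.approx(5.08, rel=1e-6)
        assert rec[T.FVFM] == pytest.approx(0.75, rel=1e-12)
        npqf_true = npq_relaxation(12.0, 1.91, 5.09, 0.89)
        assert rec[T.NPQF] == pytest.approx(npqf_true, rel=1e-9)
        assert rec[T.NPQF] <= rec[T.MAX_NPQ]

    def test_scale_invariance(self, panel_params, rng):
        tr = simulate_trace(panel_params, noise_sd=0.02, seed=7)
        scaled = tr.copy()
        for col in ("F", "Fm_prime", "Fo", "Fm"):
            scaled[col] *= 137.5
        a = extract_traits(tr)
        b = extract_traits(scaled)
        for col in T.TRAITS:
            assert a[col].iloc[0] == pytest.approx(b[col].iloc[0], rel=1e-9)

    @settings(max_examples=20, deadline=None, derandomize=True)
    @given(st.floats(min_value=3.0, max_value=12.0))
    def test_faster_relaxation_lowers_dark_npq(self, k_hi):
        # monotonicity: larger k_rel => strictly lower NPQ at every t > 0
        t = T_DARK
        lo = npq_relaxation(t, 1.91, 2.0, 0.89)
        hi = npq_relaxation(t, 1.91, 2.0 + k_hi, 0.89)
        assert (hi < lo).all()

    def test_qc_threshold_is_strict(self, panel_params):
        below = simulate_trace(dict(panel_params, fvfm=0.64), disc_id="low")
        at = simulate_trace(dict(panel_params, fvfm=0.65), disc_id="at")
        clean = simulate_trace(panel_params, disc_id="ok")
        rec = extract_traits(pd.concat([below, at, clean], ignore_index=True))
        kept, log = qc_filter(rec, fvfm_min=0.65)
        assert set(kept["disc_id"]) == {"at", "ok"}
        assert log.set_index("disc_id")["reason"]["low"] == "fvfm_below_threshold"

    def test_perfect_disc_retained_with_r2_one(self, panel_params):
        rec = extract_traits(simulate_trace(panel_params, noise_sd=0.0))
        kept, log = qc_filter(rec)
        assert len(kept) == 1 and log.empty
        assert kept["ind_r2"].iloc[0] == pytest.approx(1.0, abs=1e-9)

    def test_empty_input_warns(self):
        with pytest.warns(UserWarning, match="no discs"):
            kept, log = qc_filter(pd.DataFrame())
        assert kept.empty and log.empty
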