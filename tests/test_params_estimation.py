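"""Parameter estimation from infinite-dose permeation profiles."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from findose import (
    MembraneSpec,
    PermeationProfile,
    SamplingScheme,
    SteadyStateFitError,
    compute_D,
    compute_K,
    compute_kp,
    correct_cumulative_for_sampling,
    estimate_parameters,
    fit_steady_state,
    generate_infinite_profile,
    steady_state_window,
)
from findose.params_estimation import aggregate_replicates


def make_profile(times, cumulative, Cv=1e4, membrane=None, chemical="test"):
    membrane = membrane or MembraneSpec("porcine_skin", L=0.10)
    return PermeationProfile(chemical, np.asarray(times, float),
                             np.asarray(cumulative, float), Cv, membrane)


class TestWithdrawalCorrection:
    @pytest.mark.parametrize(
        "conc, expected",
        [
            ([1, 2, 3], [8.0, 16.5, 25.5]),
            ([0, 0, 0], [0.0, 0.0, 0.0]),
            ([5], [40.0]),
        ],
    )
    def test_mass_balance_examples(self, conc, expected):
        q = correct_cumulative_for_sampling(conc, SamplingScheme(8.0, 0.5), area=1.0)
        np.testing.assert_allclose(q, expected, rtol=1e-12)

    def test_negative_concentration_rejected(self):
        with pytest.raises(ValueError):
            correct_cumulative_for_sampling([1.0, -0.1], SamplingScheme())

    @given(
        conc=st.lists(st.floats(0, 100), min_size=1, max_size=10),
        aliquot=st.floats(0.1, 2.0),
        area=st.floats(0.5, 3.0),
    )
    @settings(deadline=None, max_examples=50)
    def test_mass_conservation(self, conc, aliquot, area):
        """Total analyte accounted (receiver + removed aliquots) equals A·Q_n."""
        scheme = SamplingScheme(receiver_volume=8.0, aliquot_volume=aliquot)
        q = correct_cumulative_for_sampling(conc, scheme, area)
        conc = np.asarray(conc)
        for n in range(len(conc)):
            accounted = conc[n] * scheme.receiver_volume + np.sum(
                conc[:n] * scheme.aliquot_volume
            )
            assert q[n] * area == pytest.approx(accounted, rel=1e-12, abs=1e-12)

    def test_nondecreasing_for_accumulating_system(self):
        # receiver concentrations of a system that only accumulates analyte
        conc = [1.0, 1.5, 2.2, 3.0]
        q = correct_cumulative_for_sampling(conc, SamplingScheme())
        assert np.all(np.diff(q) >= 0)


class TestSteadyStateFit:
    def test_exact_line(self):
        prof = make_profile([2, 4, 6, 8], [5, 15, 25, 35])
        flux, tlag, r2 = fit_steady_state(prof)
        assert flux == pytest.approx(5.0)
        assert tlag == pytest.approx(1.0)
        assert r2 == pytest.approx(1.0)

    def test_zero_slope_errors(self):
        prof = make_profile([2, 4], [10, 10])
        with pytest.raises(SteadyStateFitError, match="no positive steady-state flux"):
            fit_steady_state(prof)

    def test_negative_tlag_flagged_not_clamped(self):
        prof = make_profile([2, 4, 6], [5, 10, 15])  # intercept 0 at t=0 -> Tlag=0
        prof2 = make_profile([2, 4, 6], [6, 11, 16])  # positive intercept -> Tlag<0
        with pytest.warns(UserWarning, match="negative lag time"):
            _, tlag, _ = fit_steady_state(prof2)
        assert tlag < 0
        _, tlag0, _ = fit_steady_state(prof)
        assert tlag0 == pytest.approx(0.0, abs=1e-12)

    def test_deterministic(self):
        prof = make_profile([2, 4, 6, 8], [4.9, 15.2, 24.8, 35.1])
        assert fit_steady_state(prof) == fit_steady_state(prof)

    def test_default_window_by_membrane(self):
        t = np.array([2.0, 4.0, 6.0, 8.0])
        skin = make_profile(t, [1, 2, 3, 4])
        stratm = make_profile(t, [1, 2, 3, 4], membrane=MembraneSpec("strat_m", 0.03))
        assert steady_state_window(skin).tolist() == [0, 1, 2, 3]
        assert steady_state_window(stratm).tolist() == [1, 2, 3]

    def test_flux_from_series_solution_asymptote(self):
        """A noiseless slab-diffusion profile sampled past the lag transient
        recovers Flux = Kp·Cv within 2%."""
        prof = generate_infinite_profile(
            kp=2.0e-3, K=0.5, L=0.03, cv=1.0e4, times=(4, 6, 8)
        )
        flux, _, _ = fit_steady_state(prof, window=[0, 1, 2])
        assert flux == pytest.approx(2.0e-3 * 1.0e4, rel=0.02)


class TestLagTimeRelations:
    def test_kp_from_flux(self):
        # caffeine/porcine: Kp = 2.32e-3 cm/h at Cv = 1.00e4 µg/mL
        assert compute_kp(23.2, 1.00e4) == pytest.approx(2.32e-3)
        assert compute_kp(0.0, 1e4) == 0.0
        assert compute_kp(1.83, 1.83e3) == pytest.approx(1.0e-3)
        with pytest.raises(ValueError):
            compute_kp(1.0, 0.0)

    def test_diffusion_coefficient(self):
        assert compute_D(0.03, 1.0) == pytest.approx(1.5e-4)
        # kojic acid/porcine: Tlag back-computed from K=0.108, Kp=1.30e-3, L=0.10
        assert compute_D(0.10, 1.3846153846) == pytest.approx(1.2037037e-3, rel=1e-6)
        assert compute_D(0.06, 1.0) == pytest.approx(4 * compute_D(0.03, 1.0))
        with pytest.raises(ValueError, match="lag time non-positive"):
            compute_D(0.03, 0.0)

    def test_partition_coefficient(self):
        # kojic acid/porcine row: K ≈ 0.108
        assert compute_K(1.3846153846, 1.30e-3, 0.10) == pytest.approx(0.108, rel=1e-6)
        assert compute_K(0.0, 1e-3, 0.1) == 0.0
        with pytest.raises(ValueError):
            compute_K(1.0, 1e-3, 0.0)

    @given(
        tlag=st.floats(0.01, 10),
        flux=st.floats(0.01, 100),
        cv=st.floats(10, 1e5),
        L=st.floats(0.01, 0.2),
    )
    @settings(deadline=None, max_examples=50)
    def test_algebraic_identity(self, tlag, flux, cv, L):
        """Kp = K·D/L identically, from the three lag-time relations."""
        kp = compute_kp(flux, cv)
        K = compute_K(tlag, kp, L)
        D = compute_D(L, tlag)
        assert K * D / L == pytest.approx(kp, rel=1e-12)


class TestEstimateParameters:
    def test_roundtrip_noiseless_synthetic(self):
        """Parameters estimated from a noiseless slab-diffusion profile match
        the generating (Kp, K, D) within finite-window bias tolerances."""
        kp, K, L, cv = 1.0e-2, 1.5, 0.03, 1.83e3
        prof = generate_infinite_profile(kp, K, L, cv, times=(4, 6, 8))
        est = estimate_parameters(prof, window=[0, 1, 2])
        D_true = kp * L / K
        assert est.kp == pytest.approx(kp, rel=0.02)
        assert est.K == pytest.approx(K, rel=0.05)
        assert est.D == pytest.approx(D_true, rel=0.05)
        assert est.flux == pytest.approx(est.kp * cv, rel=1e-9)

    def test_bundle_identity(self):
        prof = generate_infinite_profile(2e-3, 0.5, 0.03, 1e4, times=(4, 6, 8))
        est = estimate_parameters(prof, window=[0, 1, 2])
        assert est.K * est.D / prof.membrane.L == pytest.approx(est.kp, rel=1e-12)

    def test_zero_lag_profile(self):
        """Exactly-linear profile through the origin: Kp finite, D undefined
        (NaN + warning recorded), K = 0."""
        prof = make_profile([2, 4, 6, 8], [10, 20, 30, 40], Cv=1e4)
        est = estimate_parameters(prof)
        assert est.kp == pytest.approx(5.0 / 1e4)
        assert np.isnan(est.D)
        assert est.K == pytest.approx(0.0, abs=1e-12)
        assert any("D undefined" in w for w in est.warnings)

    def test_empty_window_errors(self):
        prof = make_profile([2, 4, 6, 8], [5, 15, 25, 35])
        with pytest.raises(ValueError):
            estimate_parameters(prof, window=[])

    def test_aggregate_replicates(self):
        profs = [
            generate_infinite_profile(2e-3, 0.5, 0.03, 1e4, times=(4, 6, 8)),
            generate_infinite_profile(2.2e-3, 0.5, 0.03, 1e4, times=(4, 6, 8)),
        ]
        agg = aggregate_replicates(
            [estimate_parameters(p, window=[0, 1, 2]) for p in profs]
        )
        mean, se = agg["kp"]
        assert mean == pytest.approx(2.1e-3, rel=0.02)
        assert se > 0


class TestProfileValidation:
    def test_decreasing_times_rejected(self):
        with pytest.raises(ValueError):
            make_profile([4, 2], [1, 2])

    def test_negative_cumulative_rejected(self):
        with pytest.raises(ValueError):
            make_profile([2, 4], [1, -1])

    def test_length_mismatch_rejected(self):
        with pytest.raises(ValueError):
            make_profile([2, 4, 6], [1, 2])
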