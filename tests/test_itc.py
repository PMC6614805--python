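"""Equilibrium solvers, isotherm simulation and ITC model fits."""

import numpy as np
import pytest
from scipy.optimize import bisect

from selexkit.itc import (
    ITCExperiment,
    Isotherm,
    OneSiteParams,
    RacemicParams,
    correct_dilution,
    fit_one_site,
    fit_racemic,
    simulate_isotherm,
    solve_equilibrium_one_site,
    solve_equilibrium_racemic,
)

EXP = ITCExperiment(cell_volume=1400.0, cell_conc=20.0, syringe_conc=350.0,
                    injection_volumes=(10.0,) * 25)


def _bisection_oracle_one_site(m_t, l_t, kd, n):
    """Independent 1-D bisection on the one-site mass balance."""
    s_t = n * m_t

    def f(ml):
        return (s_t - ml) * (l_t - ml) - kd * ml

    hi = min(s_t, l_t)
    if hi == 0:
        return 0.0
    return bisect(f, 0.0, hi, xtol=1e-15)


def _grid_oracle_racemic(m_t, l1, l2, k1, k2, n, passes=12, points=64):
    """Brute-force grid scan with successive refinement on the free-site
    concentration (no root-finder involved)."""
    s_t = n * m_t

    def imbalance(s):
        return abs(s * (1 + l1 / (k1 + s) + l2 / (k2 + s)) - s_t)

    lo, hi = 0.0, s_t
    for _ in range(passes):
        grid = np.linspace(lo, hi, points)
        best = int(np.argmin([imbalance(s) for s in grid]))
        lo = grid[max(best - 1, 0)]
        hi = grid[min(best + 1, points - 1)]
    s = 0.5 * (lo + hi)
    return s * l1 / (k1 + s), s * l2 / (k2 + s)


class TestOneSiteEquilibrium:
    def test_zero_ligand_gives_zero_complex(self):
        assert solve_equilibrium_one_site(20, 0, 0.05) == 0.0

    def test_tight_binding_limit_is_stoichiometric(self):
        ml = solve_equilibrium_one_site(20, 10, 1e-9, n=1.0)
        assert ml == pytest.approx(10.0, rel=1e-6)

    def test_matches_bisection_oracle_at_aptamer_conditions(self):
        ml = solve_equilibrium_one_site(20, 10, 0.0465, n=1.0)
        oracle = _bisection_oracle_one_site(20, 10, 0.0465, 1.0)
        assert ml == pytest.approx(oracle, abs=1e-9)

    def test_negative_inputs_raise(self):
        with pytest.raises(ValueError):
            solve_equilibrium_one_site(-1, 10, 0.05)

    def test_oracle_agreement_on_100_seeded_random_cases(self):
        rng = np.random.default_rng(0)
        for _ in range(100):
            m = rng.uniform(0.1, 100)
            l = rng.uniform(0.0, 300)
            kd = 10 ** rng.uniform(-3, 2)
            n = rng.uniform(0.5, 2.0)
            ml = solve_equilibrium_one_site(m, l, kd, n)
            oracle = _bisection_oracle_one_site(m, l, kd, n)
            assert ml == pytest.approx(oracle, rel=1e-6, abs=1e-12)
            # mass conservation: free site * free ligand / complex == K_D
            free_l = l - ml
            free_s = n * m - ml
            if ml > 1e-12:
                assert free_s * free_l / ml == pytest.approx(kd, rel=1e-9)


class TestRacemicEquilibrium:
    def test_reduces_to_one_site_when_second_ligand_absent(self):
        ml1, ml2 = solve_equilibrium_racemic(20, 10, 0, 0.0465, 3.61)
        assert ml2 == 0.0
        assert ml1 == pytest.approx(
            solve_equilibrium_one_site(20, 10, 0.0465), rel=1e-12)

    def test_equal_affinities_split_in_proportion_to_totals(self):
        ml1, ml2 = solve_equilibrium_racemic(20, 6, 18, 1.0, 1.0)
        total = solve_equilibrium_one_site(20, 24, 1.0)
        assert ml1 + ml2 == pytest.approx(total, rel=1e-9)
        assert ml1 / ml2 == pytest.approx(6 / 18, rel=1e-9)

    def test_oracle_agreement_on_100_seeded_random_cases(self):
        rng = np.random.default_rng(1)
        for _ in range(100):
            m = rng.uniform(0.5, 50)
            l1 = rng.uniform(0, 100)
            l2 = rng.uniform(0, 100)
            k1 = 10 ** rng.uniform(-3, 2)
            k2 = 10 ** rng.uniform(-3, 2)
            n = rng.uniform(0.5, 2.0)
            ml1, ml2 = solve_equilibrium_racemic(m, l1, l2, k1, k2, n)
            o1, o2 = _grid_oracle_racemic(m, l1, l2, k1, k2, n)
            scale = max(n * m, 1.0)
            assert ml1 == pytest.approx(o1, rel=1e-6, abs=1e-6 * scale)
            assert ml2 == pytest.approx(o2, rel=1e-6, abs=1e-6 * scale)

    def test_mass_conservation_to_1e9_relative(self):
        rng = np.random.default_rng(2)
        for _ in range(100):
            m = rng.uniform(0.5, 50)
            l1, l2 = rng.uniform(0, 100, 2)
            k1, k2 = 10 ** rng.uniform(-3, 2, 2)
            ml1, ml2 = solve_equilibrium_racemic(m, l1, l2, k1, k2)
            s = m - ml1 - ml2  # free sites (n = 1)
            # each ligand's mass balance closes
            for lt, kd, ml in ((l1, k1, ml1), (l2, k2, ml2)):
                if lt > 0:
                    free = lt * kd / (kd + s)
                    assert free + ml == pytest.approx(lt, rel=1e-9)


class TestSimulateIsotherm:
    def test_zero_enthalpy_gives_pure_baseline(self):
        p = OneSiteParams(n=1.0, kd=1.0, dh=0.0, baseline=2.5)
        iso = simulate_isotherm(p, EXP)
        assert np.allclose(iso.heats, 2.5)

    def test_saturating_schedule_recovers_total_binding_enthalpy(self):
        # tight binding, small injections: cumulative heat approaches
        # V0 * N * M0 * dH (all aptamer ever in the cell gets bound)
        exp = ITCExperiment(cell_volume=1400.0, cell_conc=20.0,
                            syringe_conc=6000.0,
                            injection_volumes=(0.5,) * 20)
        p = OneSiteParams(n=1.0, kd=1e-4, dh=-50.0)
        iso = simulate_isotherm(p, exp)
        expected = exp.cell_volume * p.n * exp.cell_conc * p.dh * 1e-3
        assert iso.heats.sum() == pytest.approx(expected, rel=5e-3)

    def test_same_seed_reproduces_noise_exactly(self):
        p = OneSiteParams(n=0.92, kd=0.0465, dh=-40.0)
        a = simulate_isotherm(p, EXP, noise_sd=1.0, seed=9)
        b = simulate_isotherm(p, EXP, noise_sd=1.0, seed=9)
        assert np.array_equal(a.heats, b.heats)

    def test_noise_requires_seed(self):
        with pytest.raises(ValueError, match="seed"):
            simulate_isotherm(OneSiteParams(n=1, kd=1, dh=-40), EXP,
                              noise_sd=1.0)

    def test_racemic_collapses_to_one_site_on_equal_parameters(self):
        a = simulate_isotherm(
            RacemicParams(n=1.0, kd_minus=1.0, kd_plus=1.0,
                          dh_minus=-30.0, dh_plus=-30.0), EXP)
        b = simulate_isotherm(OneSiteParams(n=1.0, kd=1.0, dh=-30.0), EXP)
        assert np.max(np.abs(a.heats - b.heats)) < 1e-9

    def test_racemic_unequal_affinities_give_non_sigmoidal_isotherm(self):
        """With a 78-fold K_D split the racemic isotherm loses the single
        sharp transition: its normalized-heat profile has a wider
        transition (more injections between 10% and 90% of the heat
        range) than a matched one-site curve."""
        rac = simulate_isotherm(
            RacemicParams(n=0.93, kd_minus=0.0465, kd_plus=3.61,
                          dh_minus=-40.0, dh_plus=-25.0), EXP)
        one = simulate_isotherm(OneSiteParams(n=0.93, kd=0.0465, dh=-40.0),
                                EXP)

        def transition_width(q):
            span = q.max() - q.min()
            inside = (q < q.max() - 0.1 * span) & (q > q.min() + 0.1 * span)
            return int(inside.sum())

        assert transition_width(rac.heats) > transition_width(one.heats)


class TestCorrectDilution:
    def test_constant_heats_become_zero(self):
        iso = Isotherm(heats=np.full(10, 4.2), titrant_total=np.arange(10.0),
                       macromolecule=np.full(10, 20.0),
                       injection_volumes=np.full(10, 10.0))
        out = correct_dilution(iso)
        assert np.allclose(out.heats, 0.0)

    def test_trailing_mean_is_idempotent(self):
        p = OneSiteParams(n=0.92, kd=0.0465, dh=-40.0, baseline=5.0)
        iso = simulate_isotherm(p, EXP)
        once = correct_dilution(iso)
        twice = correct_dilution(once)
        assert np.allclose(once.heats, twice.heats)

    def test_fitted_baseline_recovered_within_2pct(self):
        p = OneSiteParams(n=0.92, kd=0.0465, dh=-40.0, baseline=5.0)
        iso = simulate_isotherm(p, EXP)
        out = correct_dilution(iso, method="fit-baseline", exp=EXP)
        # corrected heats should match the baseline-free model
        clean = simulate_isotherm(
            OneSiteParams(n=0.92, kd=0.0465, dh=-40.0), EXP)
        offset = iso.heats - out.heats
        assert np.allclose(offset, 5.0, rtol=0.02)
        assert np.allclose(out.heats, clean.heats, atol=0.02 * 5.0)

    def test_k_exceeding_injection_count_raises(self):
        iso = simulate_isotherm(OneSiteParams(n=1, kd=1, dh=-40), EXP)
        with pytest.raises(ValueError, match="k="):
            correct_dilution(iso, k=len(iso))


class TestFitOneSite:
    @pytest.mark.parametrize("kd,dh", [(0.01, -20.0), (0.5, -40.0),
                                       (5.0, -60.0)])
    def test_noiseless_round_trip_over_kd_dh_grid(self, kd, dh):
        p = OneSiteParams(n=0.9, kd=kd, dh=dh, baseline=1.0)
        iso = simulate_isotherm(p, EXP)
        res = fit_one_site(iso, EXP)
        assert res.params.kd == pytest.approx(kd, rel=1e-6)
        assert res.params.n == pytest.approx(0.9, rel=1e-6)
        assert res.params.dh == pytest.approx(dh, rel=1e-6)
        assert res.params.baseline == pytest.approx(1.0, abs=1e-6)

    def test_flat_isotherm_is_unidentifiable(self):
        iso = simulate_isotherm(OneSiteParams(n=1, kd=1, dh=0.0), EXP)
        with pytest.raises(ValueError, match="unidentifiable"):
            fit_one_site(iso, EXP)

    def test_median_kd_within_10pct_under_1pct_noise(self):
        p = OneSiteParams(n=0.92, kd=0.0465, dh=-40.0)
        clean = simulate_isotherm(p, EXP)
        sd = 0.01 * np.max(np.abs(clean.heats))
        kds = []
        for seed in range(100):
            iso = simulate_isotherm(p, EXP, noise_sd=sd, seed=seed)
            kds.append(fit_one_site(iso, EXP).params.kd)
        assert abs(np.median(kds) - p.kd) / p.kd < 0.10

    def test_binding_free_energy_reported_in_kj_per_mol(self):
        p = OneSiteParams(n=0.92, kd=0.0465, dh=-40.0)
        res = fit_one_site(simulate_isotherm(p, EXP), EXP)
        # RT ln K_D at 298.15 K for K_D = 46.5 nM
        expected = 8.314462618e-3 * 298.15 * np.log(46.5e-9)
        assert res.dg["dg"] == pytest.approx(expected, rel=1e-4)


class TestFitRacemic:
    def test_noiseless_round_trip_at_enantiomer_parameters(self):
        p = RacemicParams(n=0.93, kd_minus=0.0465, kd_plus=3.61,
                          dh_minus=-40.0, dh_plus=-25.0)
        iso = simulate_isotherm(p, EXP)
        res = fit_racemic(iso, EXP)
        assert res.params.kd_minus == pytest.approx(0.0465, rel=1e-4)
        assert res.params.kd_plus == pytest.approx(3.61, rel=1e-4)
        assert res.params.dh_minus == pytest.approx(-40.0, rel=1e-4)
        assert res.params.dh_plus == pytest.approx(-25.0, rel=1e-4)

    def test_degenerate_equal_kd_input_reproduces_isotherm(self):
        p = RacemicParams(n=1.0, kd_minus=1.0, kd_plus=1.0,
                          dh_minus=-30.0, dh_plus=-30.0)
        iso = simulate_isotherm(p, EXP)
        with pytest.warns(UserWarning, match="unidentifiable"):
            res = fit_racemic(iso, EXP)
        refit = simulate_isotherm(res.params, EXP)
        assert float(np.sum((refit.heats - iso.heats) ** 2)) < 1e-12

    def test_minority_kd_within_25pct_under_1pct_noise(self):
        p = RacemicParams(n=0.93, kd_minus=0.0465, kd_plus=3.61,
                          dh_minus=-40.0, dh_plus=-25.0)
        clean = simulate_isotherm(p, EXP)
        sd = 0.01 * np.max(np.abs(clean.heats))
        kds = []
        for seed in range(100):
            iso = simulate_isotherm(p, EXP, noise_sd=sd, seed=seed)
            kds.append(fit_racemic(iso, EXP).params.kd_plus)
        assert abs(np.median(kds) - p.kd_plus) / p.kd_plus < 0.25
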