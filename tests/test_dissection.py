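"""Factorial dissection: inclusion-exclusion identities and sweeps."""

import numpy as np
import pytest

from canophot.canopy import CanopyLayout
from canophot.config import make_bundle
from canophot.dissection import (
    SCENARIOS,
    SimulationConfig,
    run_dissection,
    sweep_architecture,
    sweep_photosynthesis,
)
from canophot.photosynthesis import LightResponseParams


def small_sim(hours=(12,), rays=2e3):
    layout = CanopyLayout(rows=2, plants_per_row=5, scoring_width_cm=55,
                          scoring_length_cm=45)
    return SimulationConfig(rays_per_m2=rays, hours=list(hours), layout=layout)


@pytest.fixture(scope="module")
def bundles():
    base = make_bundle("W64A", "erect", n_plants=2, spad=50.0, rng_seed=1)
    donor = make_bundle("A619", "spread", n_plants=2, spad=42.0, rng_seed=2)
    return base, donor


def toy_backend(values_by_group):
    """Backend scoring scenarios by group identity, ignoring simulation."""

    def backend(architecture, photosynthesis, optics, seed):
        s = values_by_group["S"][id(architecture)]
        p = values_by_group["P"][id(photosynthesis)]
        c = values_by_group["C"][id(optics)]
        return values_by_group["f"](s, p, c)

    return backend


def make_values(base, donor, s_vals, p_vals, c_vals, f):
    return {
        "S": {id(base.architecture): s_vals[0], id(donor.architecture): s_vals[1]},
        "P": {id(base.photosynthesis): p_vals[0],
              id(donor.photosynthesis): p_vals[1]},
        "C": {id(base.optics_map()): c_vals[0], id(donor.optics_map()): c_vals[1]},
        "f": f,
    }


class TestToyBackends:
    def test_additive_backend_no_interactions(self, bundles):
        base, donor = bundles
        # optics_map() returns fresh objects; pin them via closures instead
        def backend(arch, photo, optics, seed):
            s = 1.0 if arch is base.architecture else 2.5
            p = 3.0 if photo is base.photosynthesis else 4.0
            c = 0.5 if optics.spad == 50.0 else 0.9
            return s + p + c

        res = run_dissection(base, donor, small_sim(), replicates=1,
                             rng_seed=0, backend=backend)
        assert res.contributions["S"] == pytest.approx(1.5)
        assert res.contributions["P"] == pytest.approx(1.0)
        assert res.contributions["C"] == pytest.approx(0.4)
        for key in ("SP", "SC", "PC", "SPC"):
            assert res.contributions[key] == pytest.approx(0.0, abs=1e-12)

    def test_multiplicative_backend_pairwise_interaction(self, bundles):
        base, donor = bundles

        def backend(arch, photo, optics, seed):
            s = 1.0 if arch is base.architecture else 2.0
            p = 1.0 if photo is base.photosynthesis else 2.0
            return s * p

        res = run_dissection(base, donor, small_sim(), replicates=1,
                             rng_seed=0, backend=backend)
        assert res.contributions["S"] == pytest.approx(1.0)
        assert res.contributions["P"] == pytest.approx(1.0)
        assert res.contributions["SP"] == pytest.approx(1.0)  # (2-1)(2-1)
        assert res.contributions["C"] == pytest.approx(0.0, abs=1e-12)
        assert res.contributions["SPC"] == pytest.approx(0.0, abs=1e-12)

    def test_antisymmetry_of_main_effects(self, bundles):
        base, donor = bundles

        def backend(arch, photo, optics, seed):
            s = 1.0 if arch is base.architecture else 1.7
            p = 2.0 if photo is base.photosynthesis else 2.6
            c = 0.2 if optics.spad == 50.0 else 0.45
            return s + p + c

        fwd = run_dissection(base, donor, small_sim(), replicates=1,
                             rng_seed=0, backend=backend)
        rev = run_dissection(donor, base, small_sim(), replicates=1,
                             rng_seed=0, backend=backend)
        for key in ("S", "P", "C"):
            assert rev.contributions[key] == pytest.approx(
                -fwd.contributions[key], rel=1e-12
            )

    def test_inclusion_exclusion_identity_exact(self, bundles):
        base, donor = bundles
        rng = np.random.default_rng(3)
        table = {k: float(rng.uniform(0.5, 2.0)) for k in SCENARIOS}

        def backend(arch, photo, optics, seed):
            s = "d" if arch is donor.architecture else "b"
            p = "d" if photo is donor.photosynthesis else "b"
            c = "d" if optics.spad != 50.0 else "b"
            key = {"bbb": "O", "dbb": "S", "bdb": "P", "bbd": "C",
                   "ddb": "SP", "dbd": "SC", "bdd": "PC", "ddd": "SPC"}[s + p + c]
            return table[key]

        res = run_dissection(base, donor, small_sim(), replicates=1,
                             rng_seed=0, backend=backend)
        assert res.identity_residual() < 1e-12


class TestFullSimulator:
    def test_identical_bundles_zero_contributions(self, bundles):
        base, _ = bundles
        res = run_dissection(base, base, small_sim(), replicates=1, rng_seed=4)
        assert all(v == 0.0 for v in res.contributions.values())

    def test_shared_seed_identity_holds(self, bundles):
        base, donor = bundles
        res = run_dissection(base, donor, small_sim(), replicates=2, rng_seed=4)
        assert res.identity_residual() < 1e-10
        # photosynthesis-rich donor params must contribute positively
        assert res.contributions["P"] > 0

    def test_deterministic_across_runs(self, bundles):
        base, donor = bundles
        r1 = run_dissection(base, donor, small_sim(), replicates=1, rng_seed=9)
        r2 = run_dissection(base, donor, small_sim(), replicates=1, rng_seed=9)
        assert r1.A_cd == r2.A_cd


class TestSweeps:
    def test_factor_one_matches_baseline(self, bundles):
        base, _ = bundles
        sim = small_sim()
        table = sweep_photosynthesis(base, "P_max", factors=[1.0], sim=sim,
                                     rng_seed=1)
        from canophot.dissection import simulate_bundle_Acd

        a_ref, _, _ = simulate_bundle_Acd(
            base.architecture, base.photosynthesis, base.optics_map(), sim,
            rng_seed=(1 * 10007) & 0x7FFFFFFF,
        )
        assert table.A_cd.iloc[0] == pytest.approx(a_ref, rel=1e-12)

    def test_respiration_sweep_monotone_decreasing(self, bundles):
        base, _ = bundles
        table = sweep_photosynthesis(base, "R_d", factors=[0.6, 1.0, 1.4],
                                     sim=small_sim(), rng_seed=1)
        assert table.A_cd.is_monotonic_decreasing

    def test_phi_sweep_near_linear_in_low_light(self):
        """At low light the NRH is linear in phi, so A_cd ~ linear in factor."""
        bundle = make_bundle("W64A", "toy-flat", n_plants=1, spad=50.0, rng_seed=1)
        # dawn hour only: low PPFD keeps every facet on the linear branch
        layout = CanopyLayout(rows=1, plants_per_row=1, row_spacing_cm=120,
                              plant_spacing_cm=120, scoring_width_cm=120,
                              scoring_length_cm=120, randomize_azimuth=False)
        sim = SimulationConfig(rays_per_m2=5e3, hours=[6], layout=layout)
        factors = [0.6, 0.8, 1.0, 1.2, 1.4]
        table = sweep_photosynthesis(bundle, "phi", factors=factors, sim=sim,
                                     rng_seed=2)
        coeffs = np.polyfit(factors, table.A_cd, 1)
        resid = table.A_cd - np.polyval(coeffs, factors)
        ss_res = float((resid**2).sum())
        ss_tot = float(((table.A_cd - table.A_cd.mean()) ** 2).sum())
        assert 1 - ss_res / ss_tot > 0.99

    def test_theta_scaling_clipped_with_warning(self, bundles):
        base, _ = bundles
        with pytest.warns(UserWarning, match="clipped"):
            sweep_photosynthesis(base, "theta", factors=[1.4], sim=small_sim(),
                                 rng_seed=1)

    def test_architecture_identity_value(self, bundles):
        base, _ = bundles
        sim = small_sim()
        table, _ = sweep_architecture(base, "LL", [1.0], sim=sim, rng_seed=1)
        from canophot.dissection import simulate_bundle_Acd

        a_ref, _, _ = simulate_bundle_Acd(
            base.architecture, base.photosynthesis, base.optics_map(), sim,
            rng_seed=(1 * 10007) & 0x7FFFFFFF,
        )
        assert table.A_cd.iloc[0] == pytest.approx(a_ref, rel=1e-12)

    def test_width_sweep_lai_proportional(self):
        bundle = make_bundle("W64A", "toy-flat", n_plants=1, spad=50.0, rng_seed=3)
        layout = CanopyLayout(rows=1, plants_per_row=1, row_spacing_cm=150,
                              plant_spacing_cm=150, scoring_width_cm=150,
                              scoring_length_cm=150, randomize_azimuth=False)
        sim = SimulationConfig(rays_per_m2=1e3, hours=[12], layout=layout)
        factors = [0.6, 1.0, 1.6, 2.0]
        table, _ = sweep_architecture(bundle, "LW", factors, sim=sim, rng_seed=1)
        np.testing.assert_allclose(table.LAI, table.LAI.iloc[1] * np.array(factors),
                                   rtol=1e-9)

    def test_failed_adjustment_recorded_not_raised(self, bundles):
        base, _ = bundles
        n = len(base.architecture[0].leaves)
        table, opt = sweep_architecture(base, "LN", [-n, 0], sim=small_sim(),
                                        rng_seed=1)
        assert np.isnan(table.A_cd.iloc[0])
        assert table.error.iloc[0] != ""
        assert opt == 0
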