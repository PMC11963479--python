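"""Domain construction, the finite-volume Richards solver against
analytic oracles and conservation laws, and grid-convergence formulas."""

from __future__ import annotations

import math

import numpy as np
import pytest

from rockroot import richards2d as rz
from rockroot.constitutive import LinearMaterial, RHO_WATER
from rockroot.errors import (
    DegenerateConvergenceError,
    GeometryError,
    ParameterError,
)
from rockroot.richards2d import (
    ROCK,
    ROOT,
    SOIL,
    DomainGeometry,
    build_domain,
    gci,
    series_crossings,
    simulate,
    time_to_threshold,
)
from rockroot.synthetic_data import default_material_params


class TestBuildDomain:
    def test_published_discretization(self):
        g = build_domain(area_mm2=9.0, cell_um=100.0)
        assert (g.nx, g.ny) == (30, 30)
        assert g.dx == pytest.approx(100e-6)

    def test_root_disk_cell_count(self):
        g = build_domain(root_diameter_mm=1.0, cell_um=100.0)
        n_root = int((g.material_map == ROOT).sum())
        assert 69 <= n_root <= 89  # ideal disk area ~78.5 cells

    def test_pure_soil_domain(self):
        g = build_domain(rock_fraction=0.0)
        assert (g.material_map == ROCK).sum() == 0

    @pytest.mark.parametrize("contact", [True, False])
    @pytest.mark.parametrize("cell_um", [200.0, 100.0, 50.0])
    def test_rock_fraction_within_tolerance_at_all_resolutions(self, contact, cell_um):
        g = build_domain(contact=contact, cell_um=cell_um, seed=4)
        assert abs(g.rock_fraction - 0.4) <= 0.02

    def test_contact_and_no_contact_adjacency_invariants(self):
        from scipy import ndimage

        for contact in (True, False):
            g = build_domain(contact=contact, seed=2)
            rock = g.material_map == ROCK
            root = g.material_map == ROOT
            _, n_comp = ndimage.label(root)
            assert n_comp == 1  # single 4-connected root disk
            adj = rz._adjacency_count(rock, g.endodermis_mask)
            if contact:
                assert adj >= 1
            else:
                assert adj == 0
                near = rz._shift_or(root, np.ones_like(root, dtype=bool))
                assert not (rock & near).any()

    def test_deterministic_for_fixed_seed(self):
        a = build_domain(seed=9)
        b = build_domain(seed=9)
        assert np.array_equal(a.material_map, b.material_map)

    def test_infeasible_fraction_rejected(self):
        with pytest.raises(GeometryError):
            build_domain(rock_fraction=0.8, contact=False)
        with pytest.raises(GeometryError):
            build_domain(rock_fraction=0.9)

    def test_oversized_root_rejected(self):
        with pytest.raises(GeometryError):
            build_domain(root_diameter_mm=3.0)


class TestTimeToThreshold:
    @staticmethod
    def _result(times, psi_max=None, theta=None):
        n = len(times)
        return rz.SimResult(
            times=np.asarray(times, dtype=float),
            psi_max_soil_rock=np.asarray(
                psi_max if psi_max is not None else np.zeros(n)),
            theta_mean_total=np.asarray(
                theta if theta is not None else np.zeros(n)),
            theta_mean_by_material={"soil": np.zeros(n)},
            mass_balance_residual=0.0,
            snapshots=[],
            domain=None,
        )

    def test_exact_sample_hit(self):
        r = self._result([0.0, 1200.0, 2400.0], psi_max=[0.0, -1.0, -1.485])
        assert time_to_threshold(r, "psi_max", threshold=-1.485) == 2400.0

    def test_linear_interpolation_of_fractional_decrease(self):
        r = self._result([0.0, 1000.0], theta=[0.4, 0.2])
        t = time_to_threshold(r, "theta_mean_total", fraction_of_initial=0.75)
        assert t == pytest.approx(500.0)

    def test_never_crossed_returns_inf(self):
        r = self._result([0.0, 10.0], psi_max=[0.0, -0.5])
        assert time_to_threshold(r, "psi_max", threshold=-1.485) == math.inf

    def test_unknown_series_rejected(self):
        r = self._result([0.0, 1.0])
        with pytest.raises(KeyError):
            time_to_threshold(r, "no_such_series", threshold=0.0)


def linear_strip_domain(nx=64, dx=1e-3):
    """1D strip: a single root (Dirichlet) cell at the left end."""
    material = np.full((1, nx), SOIL, dtype=np.int8)
    material[0, 0] = ROOT
    ring = np.zeros((1, nx), dtype=bool)
    ring[0, 0] = True
    return DomainGeometry(
        nx=nx, ny=1, dx=dx, dy=dx, material_map=material, contact=False,
        rock_fraction_target=0.0, root_diameter=dx, endodermis_mask=ring,
    )


class TestSolverVerification:
    def test_equilibrium_initial_condition_is_steady(self, materials):
        g = build_domain(seed=1)
        res = simulate(g, materials("breccia"), psi_init=-1.5, psi_root=-1.5,
                       t_end=50.0)
        assert np.allclose(res.psi_max_soil_rock, -1.5, atol=1e-12)
        assert np.allclose(np.diff(res.theta_mean_total), 0.0, atol=1e-15)
        assert res.cumulative_root_uptake == pytest.approx(0.0, abs=1e-15)

    def test_matches_linear_diffusion_series_solution(self):
        """Constant-k, linear-retention medium against the closed-form
        1D diffusion solution with one Dirichlet and one no-flux end."""
        k, C = 1e-3, 0.1
        D = k / (RHO_WATER * C)
        nx, dx = 64, 1e-3
        psi0, psib = 0.0, -1.0
        g = linear_strip_domain(nx=nx, dx=dx)
        mat = LinearMaterial(k=k, c=C, theta_at_zero=0.3)
        L_eff = (nx - 1) * dx  # Dirichlet applied at the first cell center
        t_star = 0.1 * L_eff**2 / D
        res = simulate(g, {"soil": mat, "root": mat}, psi_init=psi0,
                       psi_root=psib, t_end=t_star, dt_init=1e-3,
                       dt_max=t_star / 80, picard_tol=1e-9,
                       snapshot_every=t_star)
        t_num, psi_num, _ = res.snapshots[-1]
        x_rel = np.arange(1, nx) * dx  # soil centers, from the Dirichlet cell
        u = np.zeros_like(x_rel)
        for j in range(200):
            lam = (2 * j + 1) * math.pi / (2 * L_eff)
            u += (4 / ((2 * j + 1) * math.pi)) * np.sin(lam * x_rel) * math.exp(
                -D * lam**2 * t_num)
        psi_exact = psib + (psi0 - psib) * u
        err = np.abs(psi_num[0, 1:] - psi_exact)
        assert err.max() <= 0.02 * abs(psi0 - psib)

    def test_missing_material_params_rejected(self, materials):
        g = build_domain(seed=1)
        with pytest.raises(ParameterError, match="missing material"):
            simulate(g, {"soil": default_material_params("soil")})

    def test_inverted_boundary_ordering_rejected(self, materials):
        g = build_domain(seed=1)
        with pytest.raises(ParameterError):
            simulate(g, materials("breccia"), psi_init=-1.5, psi_root=-0.5)

    def test_deterministic_rerun_bit_identical(self, materials):
        g = build_domain(seed=1)
        a = simulate(g, materials("breccia"), t_end=30.0)
        b = simulate(g, materials("breccia"), t_end=30.0)
        assert np.array_equal(a.times, b.times)
        assert np.array_equal(a.psi_max_soil_rock, b.psi_max_soil_rock)


class TestDryingRunInvariants:
    def test_mass_balance_closed(self, breccia_contact_run, dolostone_contact_run):
        assert breccia_contact_run.mass_balance_residual <= 1e-4
        assert dolostone_contact_run.mass_balance_residual <= 1e-4

    def test_maximum_principle_bounds_psi(self, breccia_contact_run):
        for _, psi, _ in breccia_contact_run.snapshots:
            assert psi.min() >= -1.5 - 1e-9
            assert psi.max() <= 0.0 + 1e-9
        assert np.all(breccia_contact_run.psi_max_soil_rock >= -1.5 - 1e-9)

    def test_psi_max_monotone_nonincreasing(self, breccia_contact_run):
        assert np.all(np.diff(breccia_contact_run.psi_max_soil_rock) <= 1e-12)

    def test_theta_within_material_bounds(self, breccia_contact_run):
        th_rock = breccia_contact_run.theta_mean_rock
        assert np.all((th_rock >= 0.0) & (th_rock <= 0.054 + 1e-12))
        th_soil = breccia_contact_run.theta_mean_soil
        assert np.all((th_soil >= 0.08) & (th_soil <= 0.42 + 1e-12))

    def test_breccia_reaches_wilting_before_dolostone(
        self, breccia_contact_run, dolostone_contact_run
    ):
        t_br = time_to_threshold(breccia_contact_run, "psi_max", threshold=-1.485)
        t_do = time_to_threshold(dolostone_contact_run, "psi_max", threshold=-1.485)
        assert t_br <= t_do
        assert np.isfinite(t_br)

    def test_breccia_rock_content_declines_faster(
        self, breccia_contact_run, dolostone_contact_run
    ):
        t_br = time_to_threshold(breccia_contact_run, "theta_mean_rock",
                                 fraction_of_initial=0.75)
        t_do = time_to_threshold(dolostone_contact_run, "theta_mean_rock",
                                 fraction_of_initial=0.75)
        assert t_br < t_do

    def test_contact_curves_cross_exactly_once(
        self, breccia_contact_run, breccia_nocontact_run
    ):
        """The contact and no-contact drying trajectories are genuinely
        different and exchange ranks exactly once before both settle at
        the root boundary potential."""
        band = 5e-4  # numerical resolution of the saved psi_max series
        crossings = series_crossings(
            breccia_contact_run, breccia_nocontact_run, band=band
        )
        assert len(crossings) == 1
        # the crossing separates two real excursions, not noise: the
        # difference exceeds the dead band on both sides of it
        tg = np.linspace(1.0, breccia_contact_run.times[-1], 4000)
        diff = np.interp(tg, breccia_contact_run.times,
                         breccia_contact_run.psi_max_soil_rock) - \
            np.interp(tg, breccia_nocontact_run.times,
                      breccia_nocontact_run.psi_max_soil_rock)
        t_cross = crossings[0]
        assert np.abs(diff[tg < t_cross]).max() > 2 * band
        assert np.abs(diff[tg > t_cross]).max() > 2 * band

    def test_conductivity_scaling_self_similarity(self, materials):
        """Doubling every conductivity halves the drying time scale."""
        from dataclasses import replace

        g = build_domain(seed=1)
        base = simulate(g, materials("breccia"), t_end=500.0)
        doubled = {k: replace(v, Ks=2 * v.Ks)
                   for k, v in materials("breccia").items()}
        fast = simulate(g, doubled, t_end=300.0)
        t1 = time_to_threshold(base, "psi_max", threshold=-0.75)
        t2 = time_to_threshold(fast, "psi_max", threshold=-0.75)
        assert t2 / t1 == pytest.approx(0.5, rel=0.05)


class TestGridConvergence:
    def test_hand_computed_first_order_example(self):
        rep = gci(f_coarse=0.94, f_medium=0.96, f_fine=0.97, r=2.0)
        assert rep.p == pytest.approx(1.0, abs=1e-12)
        assert rep.gci_fine == pytest.approx(1.289, abs=1e-3)

    def test_hand_computed_second_order_example(self):
        rep = gci(f_coarse=1.04, f_medium=1.01, f_fine=1.0025, r=2.0)
        assert rep.p == pytest.approx(2.0, abs=1e-12)

    def test_grid_independent_solutions_rejected(self):
        with pytest.raises(DegenerateConvergenceError):
            gci(1.0, 1.0, 1.0)

    def test_oscillatory_convergence_rejected(self):
        with pytest.raises(DegenerateConvergenceError):
            gci(f_coarse=1.0, f_medium=1.2, f_fine=1.1)

    def test_refinement_study_in_asymptotic_range(self, materials):
        """200/100/50 um refinements of the packaged Breccia contact run:
        mean water content at a fixed probe time converges with shrinking
        increments and an asymptotic ratio near 1."""
        t_probe = 600.0
        f = {}
        for cell in (200.0, 100.0, 50.0):
            g = build_domain(contact=True, cell_um=cell, seed=1)
            r = simulate(g, materials("breccia"), t_end=t_probe + 30.0,
                         dt_max=2.0, picard_tol=1e-7)
            f[cell] = float(np.interp(t_probe, r.times, r.theta_mean_total))
        d_coarse = f[100.0] - f[200.0]
        d_fine = f[50.0] - f[100.0]
        assert abs(d_fine) < abs(d_coarse)
        rep = gci(f_coarse=f[200.0], f_medium=f[100.0], f_fine=f[50.0], r=2.0)
        assert rep.p > 0
        assert 0.9 <= rep.asymptotic_ratio <= 1.1
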