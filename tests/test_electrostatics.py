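"""LPBE solver: maps, closed-form checks, focusing, energies, pKa cycle."""

import math

import numpy as np
import pytest

from helioproton.constants import COULOMB_KCAL, debye_kappa2
from helioproton.electrostatics import (
    DEFAULT_RADII,
    GridSpec,
    PointChargeSet,
    SiteDefinition,
    SolverSettings,
    born_energy,
    build_maps,
    make_focusing_grids,
    reaction_field_energy,
    site_energetics,
    solve_focused,
    solve_lpbe,
)

NO_ATOMS = (np.empty((0, 3)), np.empty(0))


def _uniform_spec(extent=24.0, h=0.5):
    n = int(extent / h) + 1
    return GridSpec(origin=(-extent / 2,) * 3, spacing=h, shape=(n, n, n))


class TestBuildMaps:
    def test_no_solute_gives_uniform_water(self):
        spec = _uniform_spec(10.0, 1.0)
        s = SolverSettings()
        eps, ions = build_maps(*NO_ATOMS, spec, s)
        assert np.all(eps.node == s.eps_water)
        assert np.all(ions.kappa2 == pytest.approx(s.kappa2_bulk))

    def test_interior_node_count_matches_sphere_scan(self):
        spec = GridSpec(origin=(-5.0,) * 3, spacing=0.5, shape=(21, 21, 21))
        eps, _ = build_maps(np.array([[0.0, 0.0, 0.0]]), np.array([2.0]), spec)
        ax = spec.axes
        count = 0
        for x in ax[0]:
            for y in ax[1]:
                for z in ax[2]:
                    if x * x + y * y + z * z <= 4.0:
                        count += 1
        assert int(np.sum(eps.node == SolverSettings().eps_protein)) == count

    def test_debye_length_closed_form(self):
        """100 mM 1:1 salt at 300 K in water: Debye length ~9.7 A."""
        kappa2 = debye_kappa2(0.1, 80.0, 300.0)
        n_per_a3 = 0.1 * 6.02214076e23 / 1e27
        expected = 8 * math.pi * COULOMB_KCAL * n_per_a3 / (80.0 * 1.987204258640832e-3 * 300.0)
        assert kappa2 == pytest.approx(expected, rel=1e-12)
        assert 1.0 / math.sqrt(kappa2) == pytest.approx(9.74, abs=0.05)

    def test_atom_outside_grid_errors(self):
        spec = _uniform_spec(10.0, 1.0)
        with pytest.raises(ValueError, match="enlarge"):
            build_maps(np.array([[50.0, 0.0, 0.0]]), np.array([2.0]), spec)


class TestSolver:
    def test_zero_charges_zero_potential(self):
        spec = _uniform_spec(10.0, 1.0)
        s = SolverSettings()
        eps, ions = build_maps(*NO_ATOMS, spec, s)
        charges = PointChargeSet(np.empty((0, 3)), np.empty(0))
        sol = solve_lpbe(eps, ions, charges, s, boundary=np.zeros(spec.shape))
        assert np.allclose(sol.phi, 0.0, atol=1e-9)

    def test_uniform_dielectric_matches_coulomb(self):
        s = SolverSettings(ionic_strength=0.0)
        spec = _uniform_spec(24.0, 0.5)
        charges = PointChargeSet([[0.0, 0.0, 0.0]], [1.0])
        sol = solve_focused(*NO_ATOMS, charges, [spec], s, uniform_eps=80.0)[-1]
        phi = sol.interpolate([[8.0, 0.0, 0.0]])[0]
        exact = COULOMB_KCAL / (80.0 * 8.0)
        assert phi == pytest.approx(exact, rel=0.02)

    def test_salt_matches_screened_coulomb(self):
        s = SolverSettings(ionic_strength=0.1)
        spec = _uniform_spec(24.0, 0.5)
        charges = PointChargeSet([[0.0, 0.0, 0.0]], [1.0])
        sol = solve_focused(*NO_ATOMS, charges, [spec], s)[-1]
        kappa = math.sqrt(s.kappa2_bulk)
        r = 8.0
        phi = sol.interpolate([[r, 0.0, 0.0]])[0]
        exact = COULOMB_KCAL * math.exp(-kappa * r) / (80.0 * r)
        assert phi == pytest.approx(exact, rel=0.03)

    def test_linearity_in_the_sources(self):
        s = SolverSettings(ionic_strength=0.1)
        spec = _uniform_spec(16.0, 0.8)
        centers = np.array([[0.0, 0.0, 0.0]])
        radii = np.array([2.0])
        qa = PointChargeSet([[0.5, 0.0, 0.0]], [1.0])
        qb = PointChargeSet([[-0.5, 0.5, 0.0]], [-0.7])
        eps, ions = build_maps(centers, radii, spec, s)
        pa = solve_lpbe(eps, ions, qa, s).phi
        pb = solve_lpbe(eps, ions, qb, s).phi
        pab = solve_lpbe(eps, ions, qa + qb, s).phi
        assert np.max(np.abs(pab - (pa + pb))) < 5e-5


class TestReactionField:
    def test_no_dielectric_contrast_gives_zero(self):
        s = SolverSettings(eps_water=4.0, eps_protein=4.0, ionic_strength=0.0)
        centers, radii = np.array([[0.0, 0.0, 0.0]]), np.array([2.0])
        charges = PointChargeSet([[0.0, 0.0, 0.0]], [1.0])
        sched = make_focusing_grids(centers, radii, spacings=(1.0, 0.5))
        e = reaction_field_energy(centers, radii, charges, sched, s)
        assert e == pytest.approx(0.0, abs=1e-6)

    def test_born_ion_with_focusing_schedule(self):
        """Centered unit charge, a = 2 A, eps 4 -> 80: within 5% of Born, and
        the error shrinks monotonically along 2.5 -> 1.0 -> 0.3 A."""
        s = SolverSettings(ionic_strength=0.0)
        centers, radii = np.array([[0.0, 0.0, 0.0]]), np.array([2.0])
        charges = PointChargeSet([[0.0, 0.0, 0.0]], [1.0])
        sched = make_focusing_grids(centers, radii, spacings=(2.5, 1.0, 0.3))
        e, levels = reaction_field_energy(
            centers, radii, charges, sched, s, return_levels=True
        )
        exact = born_energy(1.0, 2.0, 4.0, 80.0)
        rel = [abs(l - exact) / abs(exact) for l in levels]
        assert rel[0] > rel[1] > rel[2]
        assert rel[2] < 0.05

    def test_born_sign_and_magnitude(self):
        assert born_energy(1.0, 2.0, 4.0, 80.0) == pytest.approx(
            -166.03 * (1 / 4 - 1 / 80) / 2.0, rel=1e-6
        )


class TestSiteEnergetics:
    GLU = dict(
        id="GLU", kind="acid", reference_pKa=4.4,
        positions=np.array([[0.0, 0.0, 0.0], [1.2, 0.0, 0.0]]),
        radii=np.array([DEFAULT_RADII["O"], DEFAULT_RADII["C"]]),
        q_protonated=np.array([0.0, 0.0]),
        q_deprotonated=np.array([-0.7, -0.3]),
    )

    def test_identity_cycle_recovers_reference_pka(self):
        """'Protein' = model compound alone closes the thermodynamic cycle."""
        site = SiteDefinition(**self.GLU)
        sched = make_focusing_grids(site.positions, site.radii, spacings=(2.5, 1.0, 0.5))
        se = site_energetics(site.positions, site.radii, [site], schedule=sched)
        assert se.pKa_int[0] == pytest.approx(4.4, abs=0.01)
        assert se.dd_solvation[0] == pytest.approx(0.0, abs=1e-9)

    def test_burial_raises_acid_pka(self):
        """Moving an acid into a large low-dielectric cavity destabilizes the
        charged deprotonated form, raising pKa_int (sign-only check)."""
        site = SiteDefinition(
            id="ASP", kind="acid", reference_pKa=4.0,
            positions=np.array([[0.0, 0.0, 0.0]]), radii=np.array([1.52]),
            q_protonated=np.array([0.0]), q_deprotonated=np.array([-1.0]),
        )
        # cavity: shell of neutral atoms around the site
        shell = []
        for t in np.linspace(0, math.pi, 6)[1:-1]:
            for p in np.linspace(0, 2 * math.pi, 8, endpoint=False):
                shell.append([
                    4.0 * math.sin(t) * math.cos(p),
                    4.0 * math.sin(t) * math.sin(p),
                    4.0 * math.cos(t),
                ])
        shell = np.array(shell)
        centers = np.vstack([site.positions, shell])
        radii = np.concatenate([site.radii, np.full(len(shell), 2.2)])
        sched = make_focusing_grids(centers, radii, spacings=(2.0, 0.8))
        buried = site_energetics(centers, radii, [site], schedule=sched)
        sched0 = make_focusing_grids(site.positions, site.radii, spacings=(2.0, 0.8))
        free = site_energetics(site.positions, site.radii, [site], schedule=sched0)
        assert buried.pKa_int[0] > free.pKa_int[0] + 0.5

    def test_interaction_matrix_reciprocity(self):
        site1 = SiteDefinition(
            id="GLU", kind="acid", reference_pKa=4.4,
            positions=np.array([[0.0, 0.0, 0.0]]), radii=np.array([1.52]),
            q_protonated=np.array([0.0]), q_deprotonated=np.array([-1.0]),
        )
        site2 = SiteDefinition(
            id="LYS", kind="base", reference_pKa=10.4,
            positions=np.array([[4.5, 1.0, 0.0]]), radii=np.array([1.55]),
            q_protonated=np.array([1.0]), q_deprotonated=np.array([0.0]),
        )
        allpos = np.vstack([site1.positions, site2.positions, [[2.0, -1.5, 0.5]]])
        allrad = np.array([1.52, 1.55, 1.7])
        sched = make_focusing_grids(allpos, allrad, spacings=(2.0, 0.8))
        se = site_energetics(allpos, allrad, [site1, site2],
                             schedule=sched, max_asymmetry=0.05)
        assert se.W[0, 1] == se.W[1, 0]  # symmetrized after the reciprocity check
        assert se.W[0, 1] != 0.0

    def test_background_charge_shifts_pka_with_correct_sign(self):
        """A nearby fixed negative charge stabilizes the protonated acid,
        raising its intrinsic pKa."""
        site = SiteDefinition(
            id="GLU", kind="acid", reference_pKa=4.4,
            positions=np.array([[0.0, 0.0, 0.0]]), radii=np.array([1.52]),
            q_protonated=np.array([0.0]), q_deprotonated=np.array([-1.0]),
        )
        bg_pos = np.array([[3.0, 0.0, 0.0]])
        centers = np.vstack([site.positions, bg_pos])
        radii = np.array([1.52, 1.52])
        sched = make_focusing_grids(centers, radii, spacings=(2.0, 0.8))
        neg = site_energetics(centers, radii, [site],
                              background=PointChargeSet(bg_pos, [-1.0]), schedule=sched)
        pos = site_energetics(centers, radii, [site],
                              background=PointChargeSet(bg_pos, [+1.0]), schedule=sched)
        assert neg.pKa_int[0] > pos.pKa_int[0]


class TestFullChain:
    def test_model_compound_protein_feeds_microstate_model(self):
        """maps -> solve -> site_energetics -> titration reproduces the
        reference pKa end to end when the protein is the model compound."""
        from helioproton.microstates import MicrostateSystem, TitratableSite, titration_curve

        site = SiteDefinition(**TestSiteEnergetics.GLU)
        sched = make_focusing_grids(site.positions, site.radii, spacings=(2.5, 1.0, 0.5))
        se = site_energetics(site.positions, site.radii, [site], schedule=sched)
        system = MicrostateSystem(
            [TitratableSite(id="GLU", kind="acid", reference_pKa=4.4,
                            pKa_int=float(se.pKa_int[0]))],
            se.W,
        )
        curve = titration_curve(system, 0.0, 14.0, 0.05)
        assert curve.pKa_half[0] == pytest.approx(4.4, abs=0.01)
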