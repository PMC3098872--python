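"""Energy landscapes: synthetic three-state form, rigid-body transforms,
slab electrostatics with image charges, sterics, discretization error."""

import numpy as np
import pytest

from gatekin.grids import ConfigGrid
from gatekin.landscape import (
    DielectricModel,
    LandscapeParams,
    PenaltyWalls,
    StructureModel,
    Well,
    build_landscape_from_structure,
    discretization_error,
    electrostatic_energy,
    steric_energy,
    synthetic_landscape,
    transform_structure,
)
from gatekin.fixtures import toy_structure
from gatekin.units import coulomb_constant_kt, kt_millivolt

PRINTED_MINIMA = [(2.0, 0.2), (-5.0, 0.6), (-10.0, 0.7)]


class TestSyntheticLandscape:
    def test_no_gating_charge_no_voltage_dependence(self, default_grid):
        params = LandscapeParams(gating_charge=0.0)
        a = synthetic_landscape(params, default_grid, -100.0)
        b = synthetic_landscape(params, default_grid, 60.0)
        assert np.max(np.abs(a.phi_grid - b.phi_grid)) == 0.0

    def test_depolarisation_shifts_global_minimum_outward(
        self, landscape_hold, landscape_test
    ):
        z_hold = landscape_hold.grid.z_values[
            np.unravel_index(np.argmin(landscape_hold.phi_grid), landscape_hold.phi_grid.shape)[0]
        ]
        z_test = landscape_test.grid.z_values[
            np.unravel_index(np.argmin(landscape_test.phi_grid), landscape_test.phi_grid.shape)[0]
        ]
        assert z_test - z_hold > 0

    @pytest.mark.parametrize("vm", [-100.0, 60.0])
    def test_three_minima_near_state_centers(self, default_params, default_grid, vm):
        ls = synthetic_landscape(default_params, default_grid, vm)
        minima = ls.local_minima()
        assert len(minima) == 3
        for (zc, pc) in PRINTED_MINIMA:
            hit = [
                m
                for m in minima
                if abs(m[0] - zc) <= default_grid.dz + 1e-12
                and abs(m[1] - pc) <= default_grid.dphi + 1e-12
            ]
            assert hit, f"no minimum within one grid step of ({zc}, {pc}) at {vm} mV"

    def test_well_outside_grid_rejected(self, default_grid):
        params = LandscapeParams(
            wells=(Well(center=(30.0, 0.0), depth=5.0, widths=(1.0, 0.3)),)
        )
        with pytest.raises(ValueError, match="outside the grid"):
            synthetic_landscape(params, default_grid, 0.0)

    def test_normalised_minimum_zero(self, landscape_hold):
        assert landscape_hold.phi_grid.min() == 0.0


class TestTransform:
    def test_identity(self):
        s = toy_structure(0)
        t = transform_structure(s, 0.0, 0.0)
        assert np.max(np.abs(t.coords - s.coords)) < 1e-12

    def test_translation_composition(self):
        s = toy_structure(0)
        once = transform_structure(transform_structure(s, 1.3, 0.0), -0.5, 0.0)
        direct = transform_structure(s, 0.8, 0.0)
        assert np.allclose(once.coords, direct.coords, atol=1e-12)

    def test_axis_points_fixed_under_rotation(self):
        s = toy_structure(0)
        point, direction = s.rotation_axis
        # place a probe atom exactly on the axis
        coords = np.vstack([s.coords, point, point + 2.5 * direction])
        s2 = StructureModel(
            coords=coords,
            charges=np.append(s.charges, [0.0, 0.0]),
            lj_sigma=np.append(s.lj_sigma, [4.0, 4.0]),
            lj_epsilon=np.append(s.lj_epsilon, [0.2, 0.2]),
            segment=np.append(s.segment, ["S4S3", "S4S3"]),
            _axis_point=point,
            _axis_dir=direction,
        )
        t = transform_structure(s2, 0.0, 0.8)
        assert np.allclose(t.coords[-2:], coords[-2:], atol=1e-10)

    def test_rigid_transform_preserves_internal_distances(self):
        s = toy_structure(0)
        t = transform_structure(s, 2.7, 0.45)
        m = s.mobile_mask
        d0 = np.linalg.norm(s.coords[m][:, None] - s.coords[m][None], axis=-1)
        d1 = np.linalg.norm(t.coords[m][:, None] - t.coords[m][None], axis=-1)
        assert np.max(np.abs(d0 - d1)) < 1e-10


def _single_charge_structure(z0: float) -> StructureModel:
    # one mobile charge plus a distant uncharged static bead
    return StructureModel(
        coords=np.array([[0.0, 0.0, z0], [50.0, 0.0, 0.0]]),
        charges=np.array([1.0, np.nan]),
        lj_sigma=np.array([4.0, 4.0]),
        lj_epsilon=np.array([0.2, 0.2]),
        segment=np.array(["S4S3", "static"], dtype=object),
        membrane_thickness=30.0,
        membrane_z_upper=16.0,
    )


def _brute_force_image_energy(z0: float, dielectric: DielectricModel, n_terms: int) -> float:
    """Independent direct scalar summation of the two-plate image series
    for a single unit charge (oracle)."""
    off = dielectric.image_plane_offset
    zlo, zup = -14.0 - off, 16.0 + off
    length = zup - zlo
    u = z0 - zlo
    ke = coulomb_constant_kt(dielectric.eps_interior)
    total = 0.0
    for n in range(-n_terms, n_terms + 1):
        if n != 0:
            total += 1.0 / abs(2 * n * length)  # same-sign image at 2nL + z0
        total -= 1.0 / abs(2 * n * length - 2 * u)  # mirrored image
    return 0.5 * ke * total


class TestElectrostatics:
    def test_no_charges_zero(self):
        s = toy_structure(0)
        s = StructureModel(
            coords=s.coords,
            charges=np.zeros(s.n_atoms),
            lj_sigma=s.lj_sigma,
            lj_epsilon=s.lj_epsilon,
            segment=s.segment,
        )
        assert electrostatic_energy(s, DielectricModel(), -100.0) == 0.0

    def test_single_charge_image_series_vs_brute_force(self):
        """Charge at the slab centre: truncated image energy agrees with a
        10x-longer independent direct summation to < 1e-6 relative."""
        z_centre = 1.0  # slab spans [-14, 16]
        d = DielectricModel()
        s = _single_charge_structure(z_centre)
        ours = electrostatic_energy(s, d, 0.0)
        oracle = _brute_force_image_energy(z_centre, d, 10 * d.image_series_terms)
        assert abs(ours - oracle) / abs(oracle) < 1e-6

    def test_uniform_field_midpoint(self):
        """A charge exactly at mid-membrane picks up q*Vm/2 from the
        transmembrane field (image term subtracted via the Vm difference)."""
        s = _single_charge_structure(1.0)  # mid-slab of [-14, 16]
        d = DielectricModel()
        vm = 80.0
        delta = electrostatic_energy(s, d, vm) - electrostatic_energy(s, d, 0.0)
        assert np.isclose(delta, 1.0 * vm / kt_millivolt() / 2.0, rtol=1e-12)

    def test_charge_outside_slab_flagged(self):
        s = _single_charge_structure(25.0)  # above the extracellular face
        with pytest.warns(UserWarning, match="outside the membrane slab"):
            e = electrostatic_energy(s, DielectricModel(), 0.0)
        assert e == 0.0  # fully screened


class TestSterics:
    def _pair(self, r):
        return StructureModel(
            coords=np.array([[0.0, 0.0, 0.0], [0.0, 0.0, r]]),
            charges=np.array([np.nan, np.nan]),
            lj_sigma=np.array([4.0, 4.0]),
            lj_epsilon=np.array([0.5, 0.5]),
            segment=np.array(["S4S3", "static"], dtype=object),
        )

    def test_zero_at_sigma(self):
        assert abs(steric_energy(self._pair(4.0))) < 1e-12

    def test_minimum_depth_epsilon(self):
        r_min = 2 ** (1 / 6) * 4.0
        assert np.isclose(steric_energy(self._pair(r_min)), -0.5, rtol=1e-12)
        assert steric_energy(self._pair(r_min * 0.99)) > -0.5
        assert steric_energy(self._pair(r_min * 1.01)) > -0.5

    def test_tail_beyond_cutoff_negligible(self):
        """Doubling a separation beyond 2.5 sigma changes the pair energy
        by ~(2.5)^-6 * 4 eps ~ 2% of the well depth: a 2.5-sigma cutoff
        would be a fair approximation."""
        e_near = steric_energy(self._pair(2.5 * 4.0))
        e_far = steric_energy(self._pair(5.0 * 4.0))
        assert abs(e_near - e_far) < 0.5 * 2e-2  # < 2% of eps per pair

    def test_missing_parameters_reported(self):
        s = self._pair(5.0)
        s.lj_sigma = np.array([np.nan, 4.0])
        with pytest.raises(ValueError, match="missing Lennard-Jones"):
            steric_energy(s)


class TestStructureLandscape:
    @pytest.fixture(scope="class")
    @staticmethod
    def small_grid():
        return ConfigGrid(
            z_values=np.round(np.arange(-14, 7) * 1.0, 10),
            phi_values=np.round(np.arange(-2, 3) * 0.25, 10),
        )

    def test_toy_landscape_finite(self, small_grid):
        ls = build_landscape_from_structure(
            toy_structure(0), small_grid, DielectricModel(image_series_terms=30), -100.0
        )
        assert np.all(np.isfinite(ls.phi_grid))
        assert ls.phi_grid.min() == 0.0

    def test_voltage_sensitivity_monotone_in_z(self, small_grid):
        """With net positive mobile charge, dPhi/dVm decreases monotonically
        with z: outward conformations are favoured by depolarisation."""
        d = DielectricModel(image_series_terms=30)
        s = toy_structure(0)
        lo = build_landscape_from_structure(s, small_grid, d, 0.0, include_steric=False)
        hi = build_landscape_from_structure(s, small_grid, d, 40.0, include_steric=False)
        # un-normalise by comparing differences of differences along z
        sens = (hi.phi_grid - hi.phi_grid[0, 0]) - (lo.phi_grid - lo.phi_grid[0, 0])
        j = small_grid.nphi // 2
        col = sens[:, j]
        # restrict to conformations keeping every mobile charge clear of
        # the 3-A screening taper at the electrolyte interfaces, where the
        # effective gating charge is constant
        zv = small_grid.z_values
        inner = (zv >= -2.0) & (zv <= 4.0)
        assert np.all(np.diff(col[inner]) < 1e-9)

    def test_voltage_linearity(self, small_grid):
        """Phi(node; Vm) is affine in Vm: R^2 = 1 to machine precision."""
        d = DielectricModel(image_series_terms=30)
        s = toy_structure(0)
        vms = np.array([-100.0, -50.0, 0.0, 30.0, 60.0])
        stack = []
        for vm in vms:
            ls = build_landscape_from_structure(s, small_grid, d, vm, include_steric=False)
            stack.append(ls.phi_grid - ls.phi_grid[0, 0])  # fix the gauge
        stack = np.array(stack).reshape(len(vms), -1)
        coeffs = np.polyfit(vms, stack, 1)
        fit = np.outer(vms, coeffs[0]) + coeffs[1]
        assert np.max(np.abs(stack - fit)) < 1e-9

    def test_plumbing_identity_with_synthetic(self, default_grid):
        """With the structure contribution disabled (no charges, no
        sterics) the builder reduces to the synthetic landscape with no
        wells and zero gating charge: penalty walls only."""
        s = toy_structure(0)
        s = StructureModel(
            coords=s.coords,
            charges=np.zeros(s.n_atoms),
            lj_sigma=s.lj_sigma,
            lj_epsilon=s.lj_epsilon,
            segment=s.segment,
        )
        pen = PenaltyWalls()
        built = build_landscape_from_structure(
            s, default_grid, DielectricModel(image_series_terms=5), -100.0,
            penalty=pen, include_steric=False,
        )
        params = LandscapeParams(wells=(), gating_charge=0.0, penalty=pen)
        synth = synthetic_landscape(params, default_grid, -100.0)
        assert np.allclose(built.phi_grid, synth.phi_grid, atol=1e-12)


class TestDiscretizationError:
    def test_linear_landscape_exact(self, default_grid):
        phi = 3.0 * default_grid.z_values[:, None] + 0.0 * default_grid.phi_values
        from gatekin.grids import EnergyLandscape

        ls = EnergyLandscape(default_grid, 0.0, np.broadcast_to(phi, default_grid.shape).copy())
        err = discretization_error(ls)
        assert err["z"] < 1e-13

    def test_second_order_convergence(self, default_params):
        """Halving the grid step reduces the midpoint residual ~4x."""
        def build(step_scale):
            nz = int(round(20.0 / (0.2 * step_scale))) + 1
            npph = int(round(2.0 / (0.05 * step_scale))) + 1
            g = ConfigGrid(
                z_values=np.round(-14.0 + 0.2 * step_scale * np.arange(nz), 10),
                phi_values=np.round(-1.0 + 0.05 * step_scale * np.arange(npph), 10),
            )
            return discretization_error(synthetic_landscape(default_params, g, 0.0))

        coarse, fine = build(2.0), build(1.0)
        assert 2.5 < coarse["z"] / fine["z"] < 6.0
        assert 2.5 < coarse["phi"] / fine["phi"] < 6.0

    @pytest.mark.parametrize("vm", [-100.0, -40.0, -20.0, 0.0, 20.0, 40.0, 60.0])
    def test_default_landscape_within_printed_bounds(self, default_params, default_grid, vm):
        """At every protocol voltage the discretisation error stays below
        3% along z and 1% along phi."""
        err = discretization_error(synthetic_landscape(default_params, default_grid, vm))
        assert err["z"] < 0.03
        assert err["phi"] < 0.01
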