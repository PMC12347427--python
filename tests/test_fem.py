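import numpy as np
import pytest

from femrem.errors import InvalidParameterError, SolverError
from femrem.fem import (
    assemble,
    interface_band,
    solve,
    strain_energy_density,
)
from femrem.meshing import Region


def uniaxial_patch(rect_mesh, materials, sigma0=5.0, thickness=10.0, nx=10, ny=4):
    """Rectangle under uniform x-traction with roller supports (closed form)."""
    L, H = 10.0, 4.0
    mesh = rect_mesh(L, H, nx, ny)
    system = assemble(mesh, materials, thickness)
    f = np.zeros((mesh.n_nodes, 2))
    right = np.nonzero(np.isclose(mesh.nodes[:, 0], L))[0]
    ys = mesh.nodes[right, 1]
    w = np.full(len(right), H / ny)
    w[np.isclose(ys, 0.0) | np.isclose(ys, H)] = H / (2 * ny)
    f[right, 0] = sigma0 * thickness * w
    left = np.nonzero(np.isclose(mesh.nodes[:, 0], 0.0))[0]
    bottom_left = left[np.argmin(mesh.nodes[left, 1])]
    fixed_dofs = np.concatenate([2 * left, [2 * bottom_left + 1]])
    u = solve(system, f, fixed_dofs=fixed_dofs)
    return mesh, system, f, u


class TestAssemble:
    def test_symmetry(self, rect_mesh, materials):
        mesh = rect_mesh(10.0, 4.0, 6, 3)
        K = assemble(mesh, materials, 10.0).stiffness
        assert abs(K - K.T).max() / abs(K).max() < 1e-12

    def test_dimension(self, rect_mesh, materials):
        mesh = rect_mesh(10.0, 4.0, 6, 3)
        system = assemble(mesh, materials, 10.0)
        assert system.n_dofs == 2 * mesh.n_nodes

    def test_rigid_translation_nullspace(self, rect_mesh, materials):
        mesh = rect_mesh(10.0, 4.0, 6, 3)
        K = assemble(mesh, materials, 10.0).stiffness
        for t in (np.tile([1.0, 0.0], mesh.n_nodes), np.tile([0.0, 1.0], mesh.n_nodes)):
            assert np.abs(K @ t).max() / abs(K).max() < 1e-9

    def test_rigid_rotation_nullspace(self, rect_mesh, materials):
        mesh = rect_mesh(10.0, 4.0, 6, 3)
        K = assemble(mesh, materials, 10.0).stiffness
        rot = np.column_stack([-mesh.nodes[:, 1], mesh.nodes[:, 0]]).ravel()
        assert np.abs(K @ rot).max() / (abs(K).max() * np.abs(rot).max()) < 1e-9

    def test_thickness_scaling(self, rect_mesh, materials):
        mesh = rect_mesh(10.0, 4.0, 6, 3)
        K1 = assemble(mesh, materials, 10.0).stiffness
        K2 = assemble(mesh, materials, 20.0).stiffness
        assert abs(K2 - 2.0 * K1).max() < 1e-9 * abs(K1).max()

    def test_invalid_thickness(self, rect_mesh, materials):
        with pytest.raises(InvalidParameterError):
            assemble(rect_mesh(1.0, 1.0, 1, 1), materials, 0.0)


class TestSolve:
    def test_zero_loads(self, rect_mesh, materials):
        mesh = rect_mesh(10.0, 4.0, 6, 3)
        system = assemble(mesh, materials, 10.0)
        left = np.nonzero(np.isclose(mesh.nodes[:, 0], 0.0))[0]
        u = solve(system, np.zeros((mesh.n_nodes, 2)), left)
        assert np.abs(u.values).max() == 0.0

    def test_patch_test_uniform_stress(self, rect_mesh, materials):
        from femrem.fem import element_stress

        sigma0 = 5.0
        mesh, system, f, u = uniaxial_patch(rect_mesh, materials, sigma0)
        stress, strain = element_stress(mesh, materials, u)
        assert np.allclose(stress[:, 0], sigma0, rtol=1e-8)
        assert np.abs(stress[:, 1]).max() < 1e-8 * sigma0
        assert np.abs(stress[:, 2]).max() < 1e-8 * sigma0
        # displacement linear in position
        E = materials.cortical.youngs_modulus
        expected_ux = sigma0 / E * mesh.nodes[:, 0]
        assert np.allclose(u.values[:, 0], expected_ux, rtol=1e-8, atol=1e-12)

    def test_residual_small(self, rect_mesh, materials):
        mesh, system, f, u = uniaxial_patch(rect_mesh, materials)
        assert u.residual < 1e-9

    def test_fixed_nodes_zero(self, rect_mesh, materials):
        mesh = rect_mesh(10.0, 4.0, 6, 3)
        system = assemble(mesh, materials, 10.0)
        left = np.nonzero(np.isclose(mesh.nodes[:, 0], 0.0))[0]
        f = np.zeros((mesh.n_nodes, 2))
        f[-1, 1] = -100.0
        u = solve(system, f, left)
        assert np.abs(u.values[left]).max() == 0.0

    def test_underconstrained(self, rect_mesh, materials):
        mesh = rect_mesh(10.0, 4.0, 6, 3)
        system = assemble(mesh, materials, 10.0)
        with pytest.raises(SolverError):
            solve(system, np.zeros((mesh.n_nodes, 2)), fixed_dofs=np.array([0]))

    def test_cantilever_timoshenko(self, rect_mesh, materials):
        """Tip deflection of a clamped slender beam vs Timoshenko closed form."""
        L, H, t = 100.0, 10.0, 10.0
        E = materials.cortical.youngs_modulus
        nu = materials.cortical.poisson_ratio
        P = 100.0
        mesh = rect_mesh(L, H, 200, 20)  # element area 0.25 mm^2 <= 0.5
        system = assemble(mesh, materials, t)
        f = np.zeros((mesh.n_nodes, 2))
        right = np.nonzero(np.isclose(mesh.nodes[:, 0], L))[0]
        # parabolic shear traction (consistent with beam theory)
        ys = mesh.nodes[right, 1]
        q = 1.0 - ((ys - H / 2) / (H / 2)) ** 2
        w = q / q.sum()
        f[right, 1] = -P * w
        left = np.nonzero(np.isclose(mesh.nodes[:, 0], 0.0))[0]
        u = solve(system, f, left)
        tip = right[np.argmin(np.abs(mesh.nodes[right, 1] - H / 2))]
        I = t * H**3 / 12.0
        G = E / (2 * (1 + nu))
        kappa = 10.0 * (1 + nu) / (12.0 + 11.0 * nu)  # rectangular section
        delta = P * L**3 / (3 * E * I) + P * L / (kappa * G * H * t)
        assert abs(-u.values[tip, 1] - delta) / delta < 0.02

    def test_mirror_symmetry(self, rect_mesh, materials):
        mesh = rect_mesh(10.0, 4.0, 8, 4)
        system = assemble(mesh, materials, 10.0)
        bottom = np.nonzero(np.isclose(mesh.nodes[:, 1], 0.0))[0]
        f = np.zeros((mesh.n_nodes, 2))
        top_mid = np.nonzero(
            np.isclose(mesh.nodes[:, 1], 4.0) & np.isclose(mesh.nodes[:, 0], 5.0)
        )[0]
        f[top_mid, 1] = -50.0
        u = solve(system, f, bottom)
        # mirror about x = 5: displacement field mirrors (ux flips sign)
        for n in range(mesh.n_nodes):
            x, y = mesh.nodes[n]
            mirror = np.nonzero(
                np.isclose(mesh.nodes[:, 0], 10.0 - x) & np.isclose(mesh.nodes[:, 1], y)
            )[0][0]
            assert u.values[n, 0] == pytest.approx(-u.values[mirror, 0], abs=1e-8)
            assert u.values[n, 1] == pytest.approx(u.values[mirror, 1], abs=1e-8)


class TestSED:
    def test_zero_displacement(self, rect_mesh, materials):
        mesh = rect_mesh(10.0, 4.0, 4, 2)
        from femrem.fem import DisplacementField

        u = DisplacementField(
            values=np.zeros((mesh.n_nodes, 2)), fixed_nodes=np.array([0, 1]), residual=0.0
        )
        sed = strain_energy_density(mesh, materials, u)
        assert np.all(sed.sed == 0.0)

    def test_patch_closed_form(self, rect_mesh, materials):
        sigma0 = 5.0
        mesh, system, f, u = uniaxial_patch(rect_mesh, materials, sigma0)
        E = materials.cortical.youngs_modulus
        sed = strain_energy_density(mesh, materials, u)
        assert np.allclose(sed.sed, sigma0**2 / (2 * E), rtol=1e-8)

    def test_work_energy_identity(self, rect_mesh, materials):
        mesh, system, f, u = uniaxial_patch(rect_mesh, materials)
        sed = strain_energy_density(mesh, materials, u)
        internal = float((sed.sed * sed.areas).sum() * system.thickness)
        external = 0.5 * float(f.ravel() @ u.values.ravel())
        assert internal == pytest.approx(external, rel=1e-8)

    def test_quadratic_load_scaling(self, rect_mesh, materials):
        mesh, system, f, u1 = uniaxial_patch(rect_mesh, materials, sigma0=5.0)
        _, _, _, u2 = uniaxial_patch(rect_mesh, materials, sigma0=10.0)
        s1 = strain_energy_density(mesh, materials, u1).sed
        s2 = strain_energy_density(mesh, materials, u2).sed
        assert np.allclose(s2, 4.0 * s1, rtol=1e-9)

    def test_nonnegative(self, default_patient_result):
        assert (default_patient_result.elements.sed_mpa >= 0).all()


class TestInterfaceBand:
    def test_no_implant_elements(self, default_femur, placed_neutral):
        from femrem.geometry import StemType
        from femrem.meshing import triangulate

        placed = placed_neutral[StemType.PROXIMA]
        mesh = triangulate(default_femur, placed, 4.0)
        band = interface_band(mesh, placed, 3.0)
        assert not np.any(band & (mesh.region == Region.IMPLANT))
        assert band.sum() > 0

    def test_monotone_nesting(self, default_femur, placed_neutral):
        from femrem.geometry import StemType
        from femrem.meshing import triangulate

        placed = placed_neutral[StemType.PROXIMA]
        mesh = triangulate(default_femur, placed, 4.0)
        prev = None
        for bw in (1.0, 2.0, 4.0, 8.0):
            band = interface_band(mesh, placed, bw)
            if prev is not None:
                assert np.all(prev <= band)  # nesting
            prev = band

    def test_huge_band_is_all_bone(self, default_femur, placed_neutral):
        from femrem.geometry import StemType
        from femrem.meshing import triangulate

        placed = placed_neutral[StemType.PROXIMA]
        mesh = triangulate(default_femur, placed, 4.0)
        band = interface_band(mesh, placed, 1e6)
        assert np.array_equal(band, mesh.region != Region.IMPLANT)

    def test_invalid_width(self, default_femur, placed_neutral):
        from femrem.geometry import StemType
        from femrem.meshing import triangulate

        placed = placed_neutral[StemType.PROXIMA]
        mesh = triangulate(default_femur, placed, 4.0)
        with pytest.raises(InvalidParameterError):
            interface_band(mesh, placed, 0.0)
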