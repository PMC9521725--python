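import numpy as np
import pytest

from deepmap import DeEPPoint, generate_mesh
from deepmap.config import MapConfig
from deepmap.mapping import (build_voltage_map, export_map, place_deep_spheres,
                             read_ply, read_spheres, read_vtk)


@pytest.fixture(scope="module")
def sphere_mesh():
    mesh, _ = generate_mesh({}, radii=(30.0, 30.0, 30.0))
    return mesh


def _point(channel, value, pos, displayed=True):
    return DeEPPoint(channel=channel, position=np.asarray(pos, float),
                     deep_value=value, displayed=displayed)


class TestVoltageMap:
    def test_single_electrode_projects_its_amplitude(self, sphere_mesh):
        vert = np.asarray(sphere_mesh.vertices[0])
        values = build_voltage_map(sphere_mesh, {"E1": vert}, {"E1": 2.0})
        assert values[0] == pytest.approx(2.0)

    def test_midpoint_of_equidistant_electrodes(self, sphere_mesh):
        vert = np.asarray(sphere_mesh.vertices[0])
        offset = np.array([3.0, 0.0, 0.0])
        pos = {"E1": vert - offset, "E2": vert + offset}
        values = build_voltage_map(sphere_mesh, pos, {"E1": 1.0, "E2": 3.0})
        # equal inverse-distance weights by symmetry -> arithmetic mean
        assert values[0] == pytest.approx(2.0)

    def test_empty_electrode_set_all_no_data(self, sphere_mesh):
        with pytest.warns(UserWarning):
            values = build_voltage_map(sphere_mesh, {}, {})
        assert np.all(np.isnan(values))

    def test_constant_field_reproduced_exactly(self, sphere_mesh):
        pos = {f"E{i}": np.asarray(sphere_mesh.vertices[i * 7]) * 0.97
               for i in range(8)}
        values = build_voltage_map(sphere_mesh, pos,
                                   {n: 1.5 for n in pos})
        covered = np.isfinite(values)
        assert covered.any()
        assert np.allclose(values[covered], 1.5)


class TestSpheres:
    def test_radius_strictly_monotone_in_value(self, sphere_mesh):
        on_mesh = np.asarray(sphere_mesh.vertices[10])
        pts = [_point("B1", 15.0, on_mesh), _point("B2", 45.0, on_mesh)]
        spheres = place_deep_spheres(pts, sphere_mesh)
        assert spheres[1].radius > spheres[0].radius

    def test_hidden_point_yields_no_sphere(self, sphere_mesh):
        pts = [_point("B1", 15.0, sphere_mesh.vertices[0], displayed=False)]
        assert place_deep_spheres(pts, sphere_mesh) == []

    def test_off_mesh_point_excluded_with_warning(self, sphere_mesh):
        pts = [_point("B1", 20.0, [0.0, 0.0, 80.0])]  # 50 mm off surface
        with pytest.warns(UserWarning, match="off-mesh"):
            assert place_deep_spheres(pts, sphere_mesh) == []

    def test_centers_lie_on_mesh_vertices(self, sphere_mesh):
        pos = np.asarray(sphere_mesh.vertices[42]) * 0.95
        spheres = place_deep_spheres([_point("B1", 30.0, pos)], sphere_mesh)
        verts = np.asarray(sphere_mesh.vertices)
        d = np.linalg.norm(verts - np.asarray(spheres[0].center), axis=1)
        assert d.min() == pytest.approx(0.0, abs=1e-9)


class TestExport:
    @pytest.mark.parametrize("fmt,reader", [("vtk", read_vtk),
                                            ("ply", read_ply)])
    def test_round_trip_to_six_significant_digits(self, sphere_mesh, tmp_path,
                                                  fmt, reader):
        rng = np.random.default_rng(0)
        voltages = rng.uniform(0.1, 3.0, len(sphere_mesh.vertices))
        on_mesh = np.asarray(sphere_mesh.vertices[3])
        spheres = place_deep_spheres([_point("B1", 22.5, on_mesh)],
                                     sphere_mesh)
        paths = export_map(sphere_mesh, voltages, spheres, tmp_path / fmt,
                           fmt=fmt)
        verts, faces, scalars = reader(paths["geometry"])
        assert np.allclose(verts, sphere_mesh.vertices, rtol=1e-6)
        assert np.array_equal(faces, sphere_mesh.faces)
        assert np.allclose(scalars, voltages, rtol=1e-6)
        back = read_spheres(paths["spheres"])
        assert back[0].value == pytest.approx(22.5, rel=1e-6)
        assert back[0].radius == pytest.approx(spheres[0].radius, rel=1e-6)

    def test_empty_sphere_table_is_valid(self, sphere_mesh, tmp_path):
        voltages = np.zeros(len(sphere_mesh.vertices))
        paths = export_map(sphere_mesh, voltages, [], tmp_path, fmt="vtk")
        assert read_spheres(paths["spheres"]) == []

    def test_unknown_format_rejected(self, sphere_mesh, tmp_path):
        with pytest.raises(ValueError, match="vtk"):
            export_map(sphere_mesh, np.zeros(len(sphere_mesh.vertices)), [],
                       tmp_path, fmt="xyz")
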