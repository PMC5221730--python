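"""Mesh construction and monodomain numerics tests."""

import numpy as np
import pytest

from afpom.cell_model import CellParams, PacingProtocol, simulate_cell
from afpom.errors import ConfigurationError, ValidationError
from afpom.tissue_sim import (BlockSpec, build_mesh, initiate_reentry,
                              run_tissue)


class TestMeshes:
    def test_sheet_construction_and_row_sums(self):
        mesh = build_mesh("sheet", size=2.0, dx=0.025)
        assert mesh.shape == (81, 81)
        assert mesh.n_nodes == 81 * 81
        rowsums = np.asarray(mesh.laplacian.sum(axis=1)).ravel()
        assert np.abs(rowsums).max() < 1e-9 / 0.025 ** 2

    def test_sheet_laplacian_annihilates_linear_field(self):
        mesh = build_mesh("sheet", size=2.0, dx=0.05)
        f = mesh.points[:, 0]  # f = x
        lap_f = mesh.laplacian @ f
        nx = mesh.shape[0]
        interior = np.zeros((nx, nx), dtype=bool)
        interior[1:-1, 1:-1] = True
        assert np.abs(lap_f[interior.ravel()]).max() < 1e-9

    def test_icosphere_euler_characteristic(self):
        import trimesh

        for level in (1, 2, 3):
            mesh = build_mesh("sphere", radius=2.5, subdivisions=level)
            n_v = mesh.n_nodes
            n_f = mesh.faces.shape[0]
            edges = set()
            for tri in mesh.faces:
                for a, b in ((0, 1), (1, 2), (2, 0)):
                    edges.add(frozenset((tri[a], tri[b])))
            assert n_v - len(edges) + n_f == 2

    def test_sphere_laplacian_rows_sum_to_zero(self):
        mesh = build_mesh("sphere", radius=1.0, subdivisions=3)
        rowsums = np.asarray(mesh.laplacian.sum(axis=1)).ravel()
        assert np.abs(rowsums).max() < 1e-8 / mesh.spacing ** 2

    def test_degenerate_sizes_rejected(self):
        with pytest.raises(ValidationError):
            build_mesh("sheet", size=0.0)
        with pytest.raises(ValidationError):
            build_mesh("sphere", radius=-1.0)
        with pytest.raises(ConfigurationError):
            build_mesh("moebius")


class TestRunTissue:
    def test_d_zero_decouples_to_single_cell(self, baseline_params):
        """Every node of an uncoupled sheet follows the 0-D trajectory."""
        mesh = build_mesh("sheet", size=0.2, dx=0.05)  # 5x5 nodes
        mask = np.ones(mesh.n_nodes, dtype=bool)
        movie = run_tissue(mesh, baseline_params, None, duration_ms=400.0,
                           dt=0.02, dcoef=0.0,
                           stim=(mask, 25.0, 0.0, 2.0))
        proto = PacingProtocol(frequency_hz=2.5, amplitude=25.0, n_beats=1)
        trace = simulate_cell(baseline_params, proto, duration_ms=400.0,
                              dt=0.02, sample_ms=1.0)
        for node in range(mesh.n_nodes):
            assert np.abs(movie.frames[:, node].astype(float)
                          - trace.v).max() <= 1e-9

    def test_uniform_state_stays_uniform_with_diffusion(self, baseline_params):
        """Zero-flux conservation: diffusion vanishes on a uniform field."""
        for kind, kwargs in (("sheet", {"size": 0.4, "dx": 0.05}),
                             ("torus", {"size": 0.4, "dx": 0.05}),
                             ("sphere", {"radius": 1.0, "subdivisions": 2})):
            mesh = build_mesh(kind, **kwargs)
            flux = mesh.laplacian @ np.full(mesh.n_nodes, -81.18)
            assert np.abs(flux).max() < 1e-9 / mesh.spacing ** 2
        # and the coupled dynamics stay uniform to round-off
        mesh = build_mesh("sheet", size=0.4, dx=0.05)
        m_diff = run_tissue(mesh, baseline_params, None, duration_ms=100.0,
                            dcoef=1.0e-3)
        m_nodiff = run_tissue(mesh, baseline_params, None, duration_ms=100.0,
                              dcoef=0.0)
        np.testing.assert_allclose(m_diff.frames, m_nodiff.frames, atol=1e-9)
        spread = np.ptp(m_diff.frames, axis=1).max()
        assert spread < 1e-9

    def test_block_causality_and_log(self, baseline_params):
        mesh = build_mesh("sheet", size=0.4, dx=0.05)
        mask = mesh.points[:, 0] < 0.05
        stim = (mask, 25.0, 0.0, 2.0)
        block = BlockSpec("gCaL", 0.5, onset_ms=60.0)
        blocked = run_tissue(mesh, baseline_params, None, duration_ms=120.0,
                             stim=stim, block=block)
        control = run_tissue(mesh, baseline_params, None, duration_ms=120.0,
                             stim=stim)
        assert "block" in blocked.log
        np.testing.assert_array_equal(blocked.frames[:60], control.frames[:60])
        assert np.abs(blocked.frames[100] - control.frames[100]).max() > 0.01

    def test_unstable_discretization_rejected(self, baseline_params):
        mesh = build_mesh("sheet", size=0.4, dx=0.05)
        with pytest.raises(ValidationError):
            run_tissue(mesh, baseline_params, None, duration_ms=10.0,
                       dt=0.5, dcoef=1.0e-3)

    def test_block_spec_validation(self):
        with pytest.raises(ValidationError):
            BlockSpec("gCaL", 1.5)
        with pytest.raises(ConfigurationError):
            BlockSpec("gNope", 0.5)


class TestInitiation:
    def test_all_resting_state_has_no_singularities(self, baseline_params):
        from afpom.rotor_analysis import compute_phase, singularities_by_frame

        mesh = build_mesh("sheet", size=1.0, dx=0.05)
        movie = run_tissue(mesh, baseline_params, None, duration_ms=600.0)
        ps = singularities_by_frame(compute_phase(movie))
        assert all(len(frame) == 0 for frame in ps)

    def test_phase_seed_spawns_rotor(self, baseline_params):
        from afpom.rotor_analysis import compute_phase, singularities_by_frame

        mesh = build_mesh("sheet", size=3.0, dx=0.05)
        init = initiate_reentry(mesh, baseline_params, method="phase_seed")
        movie = run_tissue(mesh, baseline_params, init, duration_ms=300.0)
        ps = singularities_by_frame(compute_phase(movie))
        assert len(ps[200]) >= 1

    def test_cross_field_spawns_single_positive_rotor(self, baseline_params):
        """S1-S2 stimulation leaves exactly one charge-+1 core rotating."""
        from afpom.rotor_analysis import compute_phase, singularities_by_frame

        mesh = build_mesh("sheet", size=4.0, dx=0.05)
        init = initiate_reentry(mesh, baseline_params, method="cross_field")
        movie = run_tissue(mesh, baseline_params, init, duration_ms=250.0)
        ps = singularities_by_frame(compute_phase(movie))
        assert len(ps[200]) == 1
        assert ps[200][0].charge == +1

    def test_unknown_method_rejected(self, baseline_params):
        mesh = build_mesh("sheet", size=1.0, dx=0.05)
        with pytest.raises(ConfigurationError):
            initiate_reentry(mesh, baseline_params, method="wishful")


class TestSerialization:
    def test_voltage_trace_hdf5_roundtrip(self, baseline_params, tmp_path):
        from afpom.cell_model import VoltageTrace

        trace = simulate_cell(baseline_params, PacingProtocol(n_beats=1))
        path = tmp_path / "trace.h5"
        trace.to_hdf5(path)
        back = VoltageTrace.from_hdf5(path)
        np.testing.assert_array_equal(back.v, trace.v)
        np.testing.assert_array_equal(back.stim_times, trace.stim_times)
        assert back.dt == trace.dt

    def test_movie_hdf5_and_mesh_export(self, baseline_params, tmp_path):
        import h5py

        from afpom.tissue_sim import export_mesh

        mesh = build_mesh("sheet", size=0.4, dx=0.05)
        movie = run_tissue(mesh, baseline_params, None, duration_ms=50.0)
        movie.to_hdf5(tmp_path / "movie.h5")
        with h5py.File(tmp_path / "movie.h5") as f:
            assert f["V"].shape == movie.frames.shape
            assert f["mesh/points"].shape == mesh.points.shape
        export_mesh(mesh, tmp_path / "mesh.ply")
        assert (tmp_path / "mesh.ply").stat().st_size > 0

    def test_params_json_roundtrip(self, baseline_params):
        from afpom.cell_model import CellParams

        back = CellParams.from_json(baseline_params.to_json())
        np.testing.assert_array_equal(back.cond, baseline_params.cond)
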