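import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from kneestrain import (AppliedForce, ArticularSurface, BoundaryTimeSeries, Frame,
                        LoadCase, build_default_knee, contact_force,
                        extract_joint_angles, initialize_reference_lengths,
                        simulate_dynamic, solve_static)
from kneestrain.errors import ConfigurationError
from kneestrain.kinematics import jcs_angles, jcs_rotation
from toys import minimize_energy, point_mass_model, random_toy


class TestJointAngles:
    def test_identity_gives_zero_angles(self):
        assert jcs_angles(np.eye(3)) == pytest.approx((0.0, 0.0, 0.0))

    def test_pure_flexion_axis_rotation(self):
        r = jcs_rotation(30.0, 0.0, 0.0)
        assert jcs_angles(r) == pytest.approx((30.0, 0.0, 0.0), abs=1e-12)

    @given(f=st.floats(-85, 85), v=st.floats(-40, 40), i=st.floats(-40, 40))
    @settings(max_examples=200, derandomize=True, deadline=None)
    def test_angles_round_trip_through_composition(self, f, v, i):
        r = jcs_rotation(f, v, i)
        f2, v2, i2 = jcs_angles(r)
        assert np.allclose(jcs_rotation(f2, v2, i2), r, atol=1e-9)

    def test_extract_from_pose_with_moved_femur(self, rng):
        femur = Frame(rng.uniform(-10, 10, 3), jcs_rotation(12.0, 3.0, -5.0))
        rel = jcs_rotation(42.0, 4.0, -7.0)
        tibia = Frame(femur.point_to_world([5.0, -30.0, 0.0]), femur.rotation @ rel)
        ang = extract_joint_angles({"femur": femur, "tibia": tibia})
        assert (ang.flexion, ang.valgus, ang.introt) == pytest.approx(
            (42.0, 4.0, -7.0), abs=1e-9)
        assert ang.anterior_mm == pytest.approx(5.0, abs=1e-9)

    def test_gimbal_degenerate_pose_warns(self):
        with pytest.warns(UserWarning, match="gimbal"):
            jcs_angles(jcs_rotation(10.0, 90.0, 0.0))


class TestStaticSolver:
    def test_single_spring_hooke_displacement(self):
        # linear two-sided spring k=100 N/mm along X, anterior force 30 N
        model = point_mass_model(anchors=np.array([[-50.0, 0.0, 0.0]]),
                                 bundle_params=[{"k": 1.0, "eps_l": 0.03,
                                                 "reference_strain": -0.5}],
                                 springs=[((-50.0, 0.0, 0.0), 100.0, None, False)])
        initialize_reference_lengths(model)
        case = LoadCase(forces=[AppliedForce([0, 0, 0], [30.0, 0.0, 0.0], "joint")])
        res = solve_static(model, case, free=["tx"])
        assert res.coords[0] == pytest.approx(0.3, abs=1e-9)
        assert res.residual < 1e-6

    def test_two_dof_matches_energy_minimization_oracle(self):
        rng = np.random.default_rng(7)
        model, force, free_axes = random_toy(rng, n_dof=2)
        initialize_reference_lengths(model)
        names = [("tx", "ty", "tz")[i] for i in free_axes]
        case = LoadCase(forces=[AppliedForce([0, 0, 0], force, "joint")])
        res = solve_static(model, case, free=names)
        oracle = minimize_energy(model, force, free_axes)
        assert np.allclose(res.coords[:3], oracle, atol=1e-4)

    def test_unloaded_default_knee_equilibrium(self, knee):
        res = solve_static(knee, LoadCase(prescribed={"flexion": 0.0}))
        assert res.residual < 1e-6
        # equilibrium stays close to the seated reference pose
        assert abs(res.coords[0] - knee.reference_coords[0]) < 5.0

    def test_solution_independent_of_guess(self):
        rng = np.random.default_rng(3)
        model, force, free_axes = random_toy(rng, n_dof=3)
        initialize_reference_lengths(model)
        case = LoadCase(forces=[AppliedForce([0, 0, 0], force, "joint")])
        r1 = solve_static(model, case, free=["tx", "ty", "tz"])
        r2 = solve_static(model, case, free=["tx", "ty", "tz"],
                          guess=np.array([2.0, -1.5, 1.0, 0, 0, 0]))
        assert np.allclose(r1.coords, r2.coords, atol=1e-6)

    def test_frame_objectivity_under_scene_rotation(self):
        case = LoadCase(prescribed={"flexion": 20.0}, quad_N=500.0, compression_N=800.0)
        plain = solve_static(initialize_reference_lengths(build_default_knee()), case)
        rotated = initialize_reference_lengths(build_default_knee())
        rot = jcs_rotation(0.0, 0.0, 35.0)
        shift = np.array([15.0, -8.0, 4.0])
        rotated.bodies["femur"].frame = Frame(shift, rot)
        res = solve_static(rotated, case)
        # joint coordinates are invariant; world tibia frame co-rotates
        assert np.allclose(res.coords, plain.coords, atol=1e-6)
        assert np.allclose(res.pose["tibia"].position,
                           rot @ plain.pose["tibia"].position + shift, atol=1e-6)

    def test_loaded_and_prescribed_dof_conflict(self):
        with pytest.raises(ConfigurationError, match="both loaded and prescribed"):
            LoadCase(moments={"valgus": 1000.0}, prescribed={"valgus": 2.0})


class TestContact:
    def plane_pair(self, kc=1000.0):
        sph = ArticularSurface("ball", "femur", "sphere", kc,
                               center=np.array([0.0, 0.0, 0.0]), radius=10.0)
        pl = ArticularSurface("floor", "tibia", "plane", kc,
                              point=np.array([0.0, -10.0, 0.0]),
                              normal=np.array([0.0, 1.0, 0.0]))
        return sph, pl

    def test_separation_gives_zero_force(self):
        sph, pl = self.plane_pair()
        pose = {"femur": Frame([0.0, 1.0, 0.0]), "tibia": Frame(np.zeros(3))}
        res = contact_force((sph, pl), pose)
        assert res.penetration < 0
        assert np.allclose(res.force_on_plane_body, 0.0)

    def test_penalty_force_is_stiffness_times_penetration(self):
        sph, pl = self.plane_pair(kc=1000.0)
        pose = {"femur": Frame([0.0, -0.1, 0.0]), "tibia": Frame(np.zeros(3))}
        res = contact_force((sph, pl), pose)
        assert res.penetration == pytest.approx(0.1)
        # force on the plane body points along -normal with magnitude k*pen
        assert np.allclose(res.force_on_plane_body, [0.0, -100.0, 0.0], atol=1e-9)

    def test_newtons_third_law(self):
        sph, pl = self.plane_pair()
        pose = {"femur": Frame([0.3, -0.25, 0.0]), "tibia": Frame(np.zeros(3))}
        res = contact_force((sph, pl), pose)
        assert np.allclose(res.force_on_sphere_body, -res.force_on_plane_body)

    def test_socket_contact_engages_beyond_clearance(self):
        sph = ArticularSurface("ball", "femur", "sphere", 1000.0,
                               center=np.zeros(3), radius=24.0)
        sock = ArticularSurface("cup", "tibia", "socket", 1000.0,
                                center=np.array([0.0, 10.0, 0.0]), radius=34.0)
        seated = {"femur": Frame(np.zeros(3)), "tibia": Frame(np.zeros(3))}
        assert contact_force((sph, sock), seated).penetration == pytest.approx(0.0)
        pressed = {"femur": Frame(np.zeros(3)), "tibia": Frame([0.0, 0.2, 0.0])}
        res = contact_force((sph, sock), pressed)
        assert res.penetration == pytest.approx(0.2)
        assert res.force_on_plane_body[1] == pytest.approx(-200.0)  # pushed distally

    def test_same_body_pair_rejected(self):
        sph, pl = self.plane_pair()
        pl.body = "femur"
        with pytest.raises(ConfigurationError):
            contact_force((sph, pl), {"femur": Frame(np.zeros(3))})


class TestDynamics:
    def constant_bc(self, times, quad=300.0, hams=150.0, flexion=20.0):
        ones = np.ones_like(times)
        return BoundaryTimeSeries(times=times, quad_N=quad * ones, hams_N=hams * ones,
                                  prescribed_flexion_deg=flexion * ones)

    def test_settles_to_static_solution(self, fresh_knee):
        times = np.linspace(0.0, 0.8, 321)
        bc = self.constant_bc(times)
        traj = simulate_dynamic(fresh_knee, bc, dt=1e-4, settle=False)
        st_res = solve_static(fresh_knee, LoadCase(prescribed={"flexion": 20.0},
                                                   quad_N=300.0, hams_N=150.0))
        assert np.allclose(traj.coords[-1][:3], st_res.coords[:3], atol=1e-3)

    def test_zero_loads_zero_velocity_stays_constant(self, fresh_knee):
        times = np.linspace(0.0, 0.05, 26)
        bc = BoundaryTimeSeries(times=times)
        traj = simulate_dynamic(fresh_knee, bc, dt=1e-4, settle=True)
        assert np.allclose(traj.coords[0], traj.coords[-1], atol=1e-6)

    def test_energy_ledger_closes_within_two_percent(self, fresh_knee):
        times = np.linspace(0.0, 0.4, 161)
        traj = simulate_dynamic(fresh_knee, self.constant_bc(times), dt=1e-4,
                                settle=False)
        assert traj.energy["imbalance_fraction"] < 0.02

    def test_oversized_timestep_rejected(self, fresh_knee):
        times = np.linspace(0.0, 0.1, 51)
        with pytest.raises(ConfigurationError, match="stability bound"):
            simulate_dynamic(fresh_knee, self.constant_bc(times), dt=5e-3)

    def test_nonuniform_grid_rejected(self):
        with pytest.raises(ConfigurationError, match="uniform"):
            BoundaryTimeSeries(times=np.array([0.0, 0.1, 0.15]))

    def test_trajectory_csv_columns(self, fresh_knee, tmp_path):
        import pandas as pd
        times = np.linspace(0.0, 0.02, 11)
        traj = simulate_dynamic(fresh_knee, self.constant_bc(times), dt=1e-4)
        path = tmp_path / "traj.csv"
        traj.to_csv(path)
        df = pd.read_csv(path)
        assert {"time_s", "tx_mm", "flexion_deg", "strain_ACL_AM",
                "force_ACL_AM_N"} <= set(df.columns)
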