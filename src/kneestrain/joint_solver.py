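"""Tibiofemoral mechanics: quasi-static equilibrium and explicit dynamics.

The femur is the grounded body (its frame defines the joint frame) and the
tibia carries six joint coordinates

    q = (tx, ty, tz, flexion, valgus, internal rotation)

translations in mm, angles in the floating-axis convention of
:mod:`kneestrain.kinematics` (degrees at the API, radians inside). Any
coordinate may be prescribed (displacement boundary condition); the solver
works on the remaining free coordinates.

Statics solves the generalized force residual with a quasi-Newton root
finder plus a damped-Newton polish; dynamics uses semi-implicit Euler with
viscous damping sized from the local stiffness estimate (near-critical by
default, since the interest is in the quasi-static strain response, not in
ringing). An energy ledger (work in = kinetic + elastic + dissipated) is
accumulated alongside the integration.

Muscle transmissions (reduced-order, all lines of action documented in the
model's ``muscle_geometry``):

* quadriceps -- transmitted to the tibial tubercle through a rigid patellar
  tendon whose angle to the tibial shaft decreases linearly with flexion
  (anterior shear at low flexion, posterior past the crossover);
* hamstrings  -- tension from a proximal posterior tibial site toward a
  femoral-shaft point;
* gastrocnemius -- tension from a distal shank site toward its femoral
  condylar origin (knee compression + flexion moment);
* ankle plantar-flexion moment -- statically equivalent posterior force
  ``M / lever`` on the proximal tibia, the reduced-order stand-in for the
  soleus mechanism that pushes the proximal tibia posteriorly.

Linear springs attached to the patella (patellar ligament, MPFL/LPFL) are
carried in the model but do not enter the residual: the patellar mechanism
is condensed into the rigid-tendon quadriceps transmission above.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import scipy.optimize

from .errors import ConfigurationError, SolverError, StateError
from .kinematics import COORD_NAMES, coord_rotation, jcs_angles, rotation_axes
from .knee_geometry import ArticularSurface, Frame, KneeModel

_ANGLE_IDX = {"flexion": 3, "valgus": 4, "introt": 5}
_TRANS_IDX = {"tx": 0, "ty": 1, "tz": 2}
_COORD_IDX = {**_TRANS_IDX, **_ANGLE_IDX}


@dataclass
class AppliedForce:
    """Constant force (N) applied at a tibia-fixed point.

    ``frame`` selects the basis of ``vector``: ``"tibia"`` (rotates with the
    tibia, e.g. an anterior drawer force) or ``"joint"`` (femur frame)."""
    site: np.ndarray
    vector: np.ndarray
    frame: str = "tibia"

    def __post_init__(self):
        self.site = np.asarray(self.site, dtype=float).reshape(3)
        self.vector = np.asarray(self.vector, dtype=float).reshape(3)
        if self.frame not in ("tibia", "joint"):
            raise ConfigurationError(f"unknown force frame {self.frame!r}")


@dataclass
class LoadCase:
    """Static loads, prescribed coordinates and muscle-force magnitudes."""

    forces: list[AppliedForce] = field(default_factory=list)
    moments: dict[str, float] = field(default_factory=dict)   # N*mm, per angle coord
    prescribed: dict[str, float] = field(default_factory=dict)  # mm / degrees
    quad_N: float = 0.0
    hams_N: float = 0.0
    gastroc_N: float = 0.0
    ankle_moment_Nm: float = 0.0
    compression_N: float = 0.0    # axial load transmitted up the shank (e.g. GRF)

    def __post_init__(self):
        for k in self.moments:
            if k not in _ANGLE_IDX:
                raise ConfigurationError(f"moment on unknown coordinate {k!r}")
        for k in self.prescribed:
            if k not in _COORD_IDX:
                raise ConfigurationError(f"prescribed unknown coordinate {k!r}")
        clash = set(self.moments) & set(self.prescribed)
        if clash:
            raise ConfigurationError(
                f"coordinates both loaded and prescribed: {sorted(clash)}")


@dataclass
class JointAngles:
    """Clinical joint angles (degrees) and anterior tibial position (mm)."""
    flexion: float
    valgus: float
    introt: float
    anterior_mm: float


class Pose(dict):
    """Mapping body name -> :class:`Frame`, with the tibia joint coordinates
    (mm / degrees) attached when produced by the solver."""

    coords: np.ndarray | None = None


# ---------------------------------------------------------------------------
# Compiled mechanics
# ---------------------------------------------------------------------------

@dataclass
class _Eval:
    Q: np.ndarray             # generalized force, (6,), N / N*mm
    Q_applied: np.ndarray     # applied (non-elastic) part
    strains: np.ndarray
    bundle_forces: np.ndarray
    pe: float                 # elastic + contact potential energy, N*mm


class CompiledKnee:
    """Stacked-array form of a model for fast force evaluation.

    Everything is evaluated in the femur (joint) frame; conversion to world
    happens only when building output poses, so rigidly moving the femur
    frame rigidly moves every solution with it.
    """

    def __init__(self, model: KneeModel):
        if not model.initialized():
            raise StateError("model bundles are uninitialized; "
                             "run initialize_reference_lengths first")
        self.model = model
        self.bundle_names = [b.name for b in model.bundles]
        self.bf = np.array([b.femur_site.local_position for b in model.bundles])
        self.bt = np.array([b.tibia_site.local_position for b in model.bundles])
        self.k = np.array([b.k for b in model.bundles])
        self.eps_l = np.array([b.eps_l for b in model.bundles])
        self.L0 = np.array([b.reference_length for b in model.bundles])

        fs, ts, ks, rest, tens, names = [], [], [], [], [], []
        for s in model.linear_springs:
            ends = {s.site_a.body: s.site_a, s.site_b.body: s.site_b}
            if set(ends) == {"femur", "tibia"} and s.rest_length is not None:
                fs.append(ends["femur"].local_position)
                ts.append(ends["tibia"].local_position)
                ks.append(s.k)
                rest.append(s.rest_length)
                tens.append(s.tension_only)
                names.append(s.name)
        self.spring_names = names
        self.sf = np.array(fs).reshape(-1, 3)
        self.st = np.array(ts).reshape(-1, 3)
        self.sk = np.array(ks)
        self.srest = np.array(rest)
        self.stens = np.array(tens, dtype=bool)

        surf = {s.name: s for s in model.surfaces}
        self.contacts = []       # ("plane"|"socket", sphere params, counterface params)
        for a, b in model.contact_pairs:
            sa, sb = surf[a], surf[b]
            sph, other = (sa, sb) if sa.kind == "sphere" else (sb, sa)
            if sph.kind != "sphere" or other.kind not in ("plane", "socket"):
                raise ConfigurationError(
                    f"contact pair ({a}, {b}) must be sphere-on-plane or sphere-in-socket")
            if sph.body != "femur" or other.body != "tibia":
                raise ConfigurationError(
                    "solver supports femoral spheres against tibial counterfaces")
            kc = 0.5 * (sph.contact_stiffness + other.contact_stiffness)
            if other.kind == "plane":
                self.contacts.append(("plane", sph.center, sph.radius,
                                      other.point, other.normal, kc))
            else:
                self.contacts.append(("socket", sph.center, sph.radius,
                                      other.center, other.radius, kc))

        mg = model.muscle_geometry
        self.quad = mg.get("quad")
        self.ham = mg.get("hamstrings")
        self.gas = mg.get("gastrocnemius")
        self.ankle_lever = mg.get("ankle", {}).get("lever_mm", 400.0)
        self.femur_frame = model.bodies["femur"].frame

    # -- core evaluation ----------------------------------------------------
    def eval(self, q: np.ndarray, case: LoadCase) -> _Eval:
        R = coord_rotation(q)
        t = q[:3]
        pts: list[np.ndarray] = []
        fvs: list[np.ndarray] = []
        pe = 0.0

        # nonlinear bundles
        xt = t + self.bt @ R.T
        d = self.bf - xt
        L = np.linalg.norm(d, axis=1)
        strains = L / self.L0 - 1.0
        e, k, el = strains, self.k, self.eps_l
        fmag = np.where(e <= 0.0, 0.0,
                        np.where(e <= 2.0 * el, k * e**2 / (4.0 * el), k * (e - el)))
        u = d / L[:, None]
        pe += float(np.sum(np.where(
            e <= 0.0, 0.0,
            np.where(e <= 2.0 * el, k * e**3 / (12.0 * el),
                     0.5 * k * (e - el) ** 2 + k * el**2 / 6.0)) * self.L0))
        pts.append(xt)
        fvs.append(fmag[:, None] * u)

        # linear springs (femur-tibia)
        if len(self.sk):
            xs = t + self.st @ R.T
            ds = self.sf - xs
            Ls = np.linalg.norm(ds, axis=1)
            ext = Ls - self.srest
            fs = self.sk * ext
            fs = np.where(self.stens & (ext < 0.0), 0.0, fs)
            pe += float(np.sum(np.where(self.stens & (ext < 0.0), 0.0,
                                        0.5 * self.sk * ext**2)))
            pts.append(xs)
            fvs.append((fs / Ls)[:, None] * ds)

        # penalty contact (frictionless, normal force only)
        for kind, center, radius, p1, p2, kc in self.contacts:
            if kind == "plane":
                n = R @ p2
                ppl = t + R @ p1
                dist = float(n @ (center - ppl))
                pen = radius - dist
                if pen > 0.0:
                    pts.append((center - dist * n)[None, :])
                    fvs.append((-kc * pen * n)[None, :])
                    pe += 0.5 * kc * pen**2
            else:  # concave socket: contact when center distance exceeds R - r
                csock = t + R @ p1
                dvec = center - csock
                dist = float(np.linalg.norm(dvec))
                pen = dist + radius - p2
                if pen > 0.0 and dist > 1e-12:
                    n = dvec / dist          # cup center -> sphere center
                    pts.append((csock + p2 * n)[None, :])
                    fvs.append((kc * pen * n)[None, :])   # pushes tibia away
                    pe += 0.5 * kc * pen**2

        # applied loads (muscles + external) tracked separately for the ledger
        napp = 0
        flex_deg = np.rad2deg(q[3])
        if case.quad_N and self.quad:
            ang = np.deg2rad(self.quad["tendon_angle0_deg"]
                             - self.quad["tendon_angle_slope"] * flex_deg)
            dirn = R @ np.array([np.sin(ang), np.cos(ang), 0.0])
            pts.append((t + R @ np.asarray(self.quad["tubercle_site"]))[None, :])
            fvs.append((case.quad_N * self.quad.get("effectiveness", 1.0) * dirn)[None, :])
            napp += 1
        if case.hams_N and self.ham:
            x = t + R @ np.asarray(self.ham["tibia_site"])
            v = np.asarray(self.ham["femur_point"]) - x
            pts.append(x[None, :])
            fvs.append((case.hams_N * v / np.linalg.norm(v))[None, :])
            napp += 1
        if case.gastroc_N and self.gas:
            x = t + R @ np.asarray(self.gas["tibia_site"])
            v = np.asarray(self.gas["femur_point"]) - x
            pts.append(x[None, :])
            fvs.append((case.gastroc_N * v / np.linalg.norm(v))[None, :])
            napp += 1
        if case.ankle_moment_Nm:
            pts.append(t[None, :])
            fvs.append((-(case.ankle_moment_Nm * 1000.0 / self.ankle_lever)
                        * (R @ np.array([1.0, 0.0, 0.0])))[None, :])
            napp += 1
        if case.compression_N:
            pts.append(t[None, :])
            fvs.append((case.compression_N * (R @ np.array([0.0, 1.0, 0.0])))[None, :])
            napp += 1
        for af in case.forces:
            vec = R @ af.vector if af.frame == "tibia" else af.vector
            pts.append((t + R @ af.site)[None, :])
            fvs.append(vec[None, :])
            napp += 1

        p = np.vstack(pts)
        f = np.vstack(fvs)
        axes = rotation_axes(q)

        def reduce(pp, ff):
            ftot = ff.sum(axis=0)
            m = np.cross(pp - t, ff).sum(axis=0)
            return np.concatenate([ftot, axes @ m])

        Q = reduce(p, f)
        if napp:
            Qapp = reduce(p[-napp:], f[-napp:])
        else:
            Qapp = np.zeros(6)
        for name, idx in _ANGLE_IDX.items():
            mz = case.moments.get(name, 0.0)
            if mz:
                Q[idx] += mz
                Qapp[idx] += mz
        return _Eval(Q=Q, Q_applied=Qapp, strains=strains, bundle_forces=fmag, pe=pe)

    def potential_energy(self, q: np.ndarray, case: LoadCase) -> float:
        """Total potential: elastic + contact - work of the applied loads.

        Valid for load cases without follower ambiguity concerns on toy
        problems; used by energy-based cross-checks."""
        ev = self.eval(q, case)
        # work potential of applied loads: integrate numerically is overkill;
        # for constant joint-frame forces it is -F.x; muscle/tibia-frame loads
        # are follower forces and have no global potential, so this helper is
        # only meaningful when such loads are absent.
        pot = ev.pe
        for af in case.forces:
            if af.frame == "joint":
                x = q[:3] + coord_rotation(q) @ af.site
                pot -= float(af.vector @ x)
        return pot

    def world_pose(self, q: np.ndarray) -> Pose:
        fem = self.femur_frame
        R = coord_rotation(q)
        pose = Pose()
        pose["femur"] = fem
        pose["tibia"] = Frame(fem.point_to_world(q[:3]), fem.rotation @ R)
        for name, body in self.model.bodies.items():
            pose.setdefault(name, body.frame)
        qq = q.copy()
        qq[3:] = np.rad2deg(qq[3:])
        pose.coords = qq
        return pose


def _coords_to_internal(coords: np.ndarray) -> np.ndarray:
    q = np.asarray(coords, dtype=float).copy().reshape(6)
    q[3:] = np.deg2rad(q[3:])
    return q


def _coords_to_public(q: np.ndarray) -> np.ndarray:
    c = q.copy()
    c[3:] = np.rad2deg(c[3:])
    return c


# ---------------------------------------------------------------------------
# Static equilibrium
# ---------------------------------------------------------------------------

def _scale_case(case: LoadCase, fac: float) -> LoadCase:
    """The load case with all applied loads scaled by ``fac`` (constraints kept)."""
    return LoadCase(
        forces=[AppliedForce(af.site, fac * af.vector, af.frame) for af in case.forces],
        moments={k: fac * v for k, v in case.moments.items()},
        prescribed=dict(case.prescribed),
        quad_N=fac * case.quad_N, hams_N=fac * case.hams_N,
        gastroc_N=fac * case.gastroc_N,
        ankle_moment_Nm=fac * case.ankle_moment_Nm,
        compression_N=fac * case.compression_N)


@dataclass
class StaticResult:
    coords: np.ndarray           # mm / degrees
    pose: Pose
    residual: float
    strains: dict[str, float]
    bundle_forces: dict[str, float]
    angles: JointAngles


def solve_static(model: KneeModel, case: LoadCase,
                 guess: np.ndarray | None = None,
                 free: list[str] | None = None,
                 tol: float = 1e-6, max_iter: int = 60) -> StaticResult:
    """Solve quasi-static equilibrium of the tibia.

    ``guess`` are public coordinates (mm / degrees); by default the model's
    reference pose. ``free`` restricts the solved coordinates (defaults to
    all six minus the prescribed ones). The generalized force residual on
    every free coordinate is driven below ``tol`` (N or N*mm); failure
    raises :class:`SolverError` carrying the last residual.
    """
    mech = model if isinstance(model, CompiledKnee) else CompiledKnee(model)
    if guess is None:
        q = _coords_to_internal(mech.model.reference_coords)
    else:
        q = _coords_to_internal(np.asarray(guess, dtype=float))
    for name, val in case.prescribed.items():
        idx = _COORD_IDX[name]
        q[idx] = np.deg2rad(val) if idx >= 3 else val
    if free is None:
        free_idx = [i for i, n in enumerate(COORD_NAMES) if n not in case.prescribed]
    else:
        bad = set(free) & set(case.prescribed)
        if bad:
            raise ConfigurationError(f"coordinates both free and prescribed: {sorted(bad)}")
        free_idx = [_COORD_IDX[n] for n in free]
    fi = np.array(free_idx, dtype=int)
    # unit scaling: express angles in "equivalent mm" so hybr sees comparable
    # magnitudes (moment residuals divided by a 30 mm characteristic lever)
    lever = 30.0
    scale = np.where(fi >= 3, 1.0 / lever, 1.0)

    def residual(x):
        qq = q.copy()
        qq[fi] = np.where(fi >= 3, x / lever, x)
        return mech.eval(qq, case).Q[fi] * scale

    x0 = np.where(fi >= 3, q[fi] * lever, q[fi])

    def metric_at(x):
        return float(np.max(np.abs(residual(x) / scale)))  # N / N*mm

    def newton_polish(x):
        """Damped Newton with backtracking; returns (x, stalled)."""
        for _ in range(max_iter):
            r = residual(x)
            if np.max(np.abs(r / scale)) < tol:
                return x, False
            h = 1e-6
            J = np.empty((len(fi), len(fi)))
            for j in range(len(fi)):
                xp = x.copy(); xm = x.copy()
                xp[j] += h; xm[j] -= h
                J[:, j] = (residual(xp) - residual(xm)) / (2 * h)
            try:
                step = np.linalg.solve(J, -r)
            except np.linalg.LinAlgError:
                return x, True
            alpha, base = 1.0, np.linalg.norm(r)
            for _ in range(30):
                xn = x + alpha * step
                if np.linalg.norm(residual(xn)) < base:
                    break
                alpha *= 0.5
            else:
                return x, True       # no descent: landscape kink
            x = xn
        return x, True

    def solve_chain(xs):
        sol = scipy.optimize.root(residual, xs, method="hybr",
                                  options={"xtol": 1e-13,
                                           "maxfev": 400 * (len(fi) + 1)})
        x, _ = newton_polish(sol.x)
        if metric_at(x) >= tol:
            # tension-only elements and contact make the residual piecewise
            # smooth; a trust-region restart steps across the kinks that
            # stall Newton
            ls = scipy.optimize.least_squares(residual, x, method="trf",
                                              xtol=3e-16, ftol=3e-16, gtol=3e-16)
            x, _ = newton_polish(ls.x)
        return x

    def relax(x, iters=4000, cap=0.5):
        """Overdamped pseudo-dynamic relaxation: follow the generalized force
        with steps scaled by a diagonal stiffness estimate. Descends the
        potential energy, so it escapes the spurious local minima of ||r||
        that strand gradient-based root finders behind slack/taut kinks."""
        k = np.ones(len(fi))
        for it in range(iters):
            r = residual(x)                       # scaled units
            if np.max(np.abs(r / scale)) < 10.0 * tol:
                break
            if it % 25 == 0:
                h = 1e-4
                for j in range(len(fi)):
                    xp = x.copy(); xm = x.copy()
                    xp[j] += h; xm[j] -= h
                    dj = (residual(xp)[j] - residual(xm)[j]) / (2 * h)
                    k[j] = max(abs(dj), 1e-2)     # |d r_j / d x_j|
            step = r / k                          # x units (diagonal Newton)
            nrm = np.linalg.norm(step)
            if nrm > cap:
                step *= cap / nrm
            x = x + 0.8 * step
        return x

    x = solve_chain(x0)
    if metric_at(x) >= tol:
        x = solve_chain(relax(x0))
    if metric_at(x) >= tol:
        # load continuation: ramp the applied loads, warm-starting each step
        full_case = case
        x = x0
        for fac in (0.25, 0.5, 0.75, 1.0):
            case = _scale_case(full_case, fac)
            x = solve_chain(relax(x) if metric_at(x) >= tol else x)
        case = full_case
    final = metric_at(x)
    if final >= tol:
        raise SolverError("static solve did not converge", residual=final)

    q[fi] = np.where(fi >= 3, x / lever, x)
    ev = mech.eval(q, case)
    pose = mech.world_pose(q)
    return StaticResult(
        coords=_coords_to_public(q), pose=pose,
        residual=float(np.max(np.abs(ev.Q[fi]))),
        strains=dict(zip(mech.bundle_names, ev.strains)),
        bundle_forces=dict(zip(mech.bundle_names, ev.bundle_forces)),
        angles=extract_joint_angles(pose))


def extract_joint_angles(pose) -> JointAngles:
    """Clinical angles from the relative femur->tibia rotation.

    Inverse-consistent with :func:`kneestrain.kinematics.jcs_rotation`;
    ``anterior_mm`` is the anterior (X) component of the tibia origin in the
    femur frame.
    """
    fem, tib = pose["femur"], pose["tibia"]
    r_rel = fem.rotation.T @ tib.rotation
    flexion, valgus, introt = jcs_angles(r_rel)
    anterior = float((fem.rotation.T @ (tib.position - fem.position))[0])
    return JointAngles(flexion, valgus, introt, anterior)


@dataclass
class ContactResult:
    force_on_sphere_body: np.ndarray
    force_on_plane_body: np.ndarray
    point: np.ndarray
    penetration: float


def contact_force(surface_pair: tuple[ArticularSurface, ArticularSurface],
                  pose) -> ContactResult:
    """Normal-only penalty force between a sphere and a plane or socket.

    Magnitude = contact stiffness x penetration, zero at separation, no
    tangential component; forces on the two bodies are equal and opposite.
    """
    sa, sb = surface_pair
    sph, other = (sa, sb) if sa.kind == "sphere" else (sb, sa)
    if sph.kind != "sphere" or other.kind not in ("plane", "socket"):
        raise ConfigurationError("contact_force needs a sphere and a plane or socket")
    if sph.body == other.body:
        raise ConfigurationError("contact surfaces must sit on distinct bodies")
    c = pose[sph.body].point_to_world(sph.center)
    kc = 0.5 * (sph.contact_stiffness + other.contact_stiffness)
    if other.kind == "plane":
        p = pose[other.body].point_to_world(other.point)
        n = pose[other.body].vector_to_world(other.normal)
        dist = float(n @ (c - p))
        pen = sph.radius - dist
        point = c - dist * n
        f_on_other = -kc * pen * n
    else:
        csock = pose[other.body].point_to_world(other.center)
        dvec = c - csock
        dist = float(np.linalg.norm(dvec))
        pen = dist + sph.radius - other.radius
        n = dvec / dist if dist > 1e-12 else np.array([0.0, 1.0, 0.0])
        point = csock + other.radius * n
        f_on_other = kc * pen * n
    if pen <= 0.0:
        return ContactResult(np.zeros(3), np.zeros(3), point, pen)
    return ContactResult(-f_on_other, f_on_other, point, pen)


# ---------------------------------------------------------------------------
# Explicit dynamics
# ---------------------------------------------------------------------------

@dataclass
class BoundaryTimeSeries:
    """Time-varying boundary conditions on a uniform grid."""

    times: np.ndarray
    quad_N: np.ndarray | None = None
    hams_N: np.ndarray | None = None
    gastroc_N: np.ndarray | None = None
    ankle_moment_Nm: np.ndarray | None = None
    compression_N: np.ndarray | None = None
    prescribed_flexion_deg: np.ndarray | None = None
    case: LoadCase = field(default_factory=LoadCase)

    def __post_init__(self):
        self.times = np.asarray(self.times, dtype=float)
        dts = np.diff(self.times)
        if len(dts) and not np.allclose(dts, dts[0], rtol=1e-6):
            raise ConfigurationError("boundary time series must be on a uniform grid")

    def channel(self, name, sim_times):
        arr = getattr(self, name)
        if arr is None:
            return np.zeros_like(sim_times)
        return np.interp(sim_times, self.times, np.asarray(arr, dtype=float))


DEFAULT_DYNAMICS = {
    "mass_kg": 3.6,               # shank + foot
    "inertia_flexion_kgm2": 0.35,  # about the knee
    "inertia_valgus_kgm2": 0.35,
    "inertia_introt_kgm2": 0.03,
    "zeta": 0.9,                  # damping ratio vs. local stiffness estimate
}


@dataclass
class Trajectory:
    times: np.ndarray
    coords: np.ndarray            # (n, 6), mm / degrees
    strains: np.ndarray           # (n, n_bundles), absolute (slack-length) gauge
    bundle_forces: np.ndarray
    bundle_names: list[str]
    reference_lengths: np.ndarray
    energy: dict

    def lengths(self, bundle: str) -> np.ndarray:
        i = self.bundle_names.index(bundle)
        return self.reference_lengths[i] * (1.0 + self.strains[:, i])

    def to_frame(self):
        import pandas as pd
        cols = {"time_s": self.times}
        for i, name in enumerate(COORD_NAMES):
            suffix = "_mm" if i < 3 else "_deg"
            cols[f"{name}{suffix}"] = self.coords[:, i]
        for i, name in enumerate(self.bundle_names):
            cols[f"strain_{name}"] = self.strains[:, i]
        for i, name in enumerate(self.bundle_names):
            cols[f"force_{name}_N"] = self.bundle_forces[:, i]
        return pd.DataFrame(cols)

    def to_csv(self, path):
        self.to_frame().to_csv(path, index=False)


def simulate_dynamic(model: KneeModel, bc: BoundaryTimeSeries, dt: float = 2e-4,
                     damping: dict | None = None, settle: bool = True,
                     record_every: int = 1) -> Trajectory:
    """Explicit (semi-implicit Euler) time stepping under time-varying loads.

    Rotational dynamics use a diagonal generalized inertia on the joint
    coordinates (a reduced-order simplification of full rigid-body dynamics,
    adequate at the near-critically damped, quasi-static-tracking regime the
    model operates in). The energy ledger accumulates applied work,
    constraint work on the prescribed flexion coordinate, kinetic, elastic
    and dissipated energy; an ``imbalance_fraction`` summarizes closure.
    """
    mech = CompiledKnee(model)
    cfg = {**DEFAULT_DYNAMICS, **(damping or {})}
    m = cfg["mass_kg"] * 1e-3                     # N s^2 / mm
    M = np.array([m, m, m,
                  cfg["inertia_flexion_kgm2"] * 1e3,
                  cfg["inertia_valgus_kgm2"] * 1e3,
                  cfg["inertia_introt_kgm2"] * 1e3])

    base = bc.case
    flex_presc = bc.prescribed_flexion_deg is not None
    prescribed = dict(base.prescribed)
    if flex_presc:
        if "flexion" in prescribed:
            raise ConfigurationError("flexion prescribed both as constant and trajectory")
        prescribed["flexion"] = float(np.asarray(bc.prescribed_flexion_deg)[0])
    free = np.array([i for i, n in enumerate(COORD_NAMES) if n not in prescribed])

    sim_t = np.arange(bc.times[0], bc.times[-1] + 0.5 * dt, dt)
    nt = len(sim_t)
    ch = {name: bc.channel(name, sim_t)
          for name in ("quad_N", "hams_N", "gastroc_N", "ankle_moment_Nm",
                       "compression_N")}
    if flex_presc:
        flex = np.deg2rad(np.interp(sim_t, bc.times, np.asarray(bc.prescribed_flexion_deg,
                                                                dtype=float)))
        flex_rate = np.gradient(flex, dt)
    else:
        flex = flex_rate = None

    def case_at(i) -> LoadCase:
        return LoadCase(forces=base.forces, moments=base.moments,
                        prescribed={},  # handled via q directly
                        quad_N=ch["quad_N"][i], hams_N=ch["hams_N"][i],
                        gastroc_N=ch["gastroc_N"][i],
                        ankle_moment_Nm=base.ankle_moment_Nm + ch["ankle_moment_Nm"][i],
                        compression_N=base.compression_N + ch["compression_N"][i])

    # initial state: static equilibrium under the first-sample loads
    case0 = case_at(0)
    presc0 = dict(prescribed)
    if settle:
        st = solve_static(model, LoadCase(forces=case0.forces, moments=case0.moments,
                                          prescribed=presc0, quad_N=case0.quad_N,
                                          hams_N=case0.hams_N, gastroc_N=case0.gastroc_N,
                                          ankle_moment_Nm=case0.ankle_moment_Nm,
                                          compression_N=case0.compression_N))
        q = _coords_to_internal(st.coords)
    else:
        q = _coords_to_internal(model.reference_coords)
        for name, val in presc0.items():
            idx = _COORD_IDX[name]
            q[idx] = np.deg2rad(val) if idx >= 3 else val
    v = np.zeros(6)
    if flex_presc:
        v[3] = flex_rate[0]

    # local stiffness estimate -> damping and stability bound
    khat = np.zeros(6)
    ev0 = mech.eval(q, case0)
    for i in free:
        h = 1e-4 if i < 3 else 1e-6
        qp = q.copy(); qm = q.copy()
        qp[i] += h; qm[i] -= h
        khat[i] = max((mech.eval(qm, case0).Q[i] - mech.eval(qp, case0).Q[i]) / (2 * h), 1e-6)
    omega = np.sqrt(khat[free] / M[free])
    dt_max = 2.0 / max(float(np.max(omega)), 1e-9)
    if dt > 0.5 * dt_max:
        raise ConfigurationError(
            f"dt={dt:g} exceeds half the stability bound {dt_max:g} s")
    c = 2.0 * cfg["zeta"] * np.sqrt(khat * M)

    n_rec = (nt + record_every - 1) // record_every
    rec_t = np.empty(n_rec)
    rec_q = np.empty((n_rec, 6))
    rec_s = np.empty((n_rec, len(mech.bundle_names)))
    rec_f = np.empty((n_rec, len(mech.bundle_names)))

    w_app = 0.0
    w_con = 0.0
    diss = 0.0
    ke0 = 0.5 * float(M @ (v * v))
    pe0 = ev0.pe
    pe_scale = max(abs(pe0), 1.0)
    ev = ev0
    j = 0
    for i in range(nt):
        if i % record_every == 0:
            rec_t[j] = sim_t[i]
            rec_q[j] = _coords_to_public(q)
            rec_s[j] = ev.strains
            rec_f[j] = ev.bundle_forces
            j += 1
        if i == nt - 1:
            break
        q_old = q.copy()
        # free coordinates: semi-implicit Euler with implicit viscous term
        a = ev.Q[free] / M[free]
        v_new = (v[free] + dt * a) / (1.0 + dt * c[free] / M[free])
        q = q.copy()
        q[free] = q[free] + dt * v_new
        v = v.copy()
        v[free] = v_new
        # prescribed flexion follows its trajectory exactly
        if flex_presc:
            r_con = M[3] * (flex_rate[i + 1] - flex_rate[i]) / dt - ev.Q[3]
            q[3] = flex[i + 1]
            v[3] = flex_rate[i + 1]
            w_con += r_con * (flex[i + 1] - flex[i])
        dq = q - q_old
        w_app += float(ev.Q_applied @ dq)
        diss += float((c[free] * v[free]) @ dq[free])
        ev = mech.eval(q, case_at(i + 1))
        pe_scale = max(pe_scale, abs(ev.pe))
        ke = 0.5 * float(M @ (v * v))
        if not np.all(np.isfinite(q)) or ke > 1e4 * (pe_scale + abs(w_app) + 1.0):
            raise SolverError(
                f"dynamic integration unstable at t={sim_t[i + 1]:.4f}s "
                f"(kinetic energy {ke:.3g} N*mm)")

    ke1 = 0.5 * float(M @ (v * v))
    pe1 = ev.pe
    lhs = w_app + w_con
    rhs = (ke1 - ke0) + (pe1 - pe0) + diss
    denom = max(abs(lhs), abs(rhs), diss, pe_scale * 1e-3, 1e-9)
    energy = {
        "work_applied": w_app, "work_constraint": w_con,
        "kinetic_initial": ke0, "kinetic_final": ke1,
        "elastic_initial": pe0, "elastic_final": pe1,
        "dissipated": diss,
        "imbalance": lhs - rhs,
        "imbalance_fraction": abs(lhs - rhs) / denom,
    }
    return Trajectory(times=rec_t[:j], coords=rec_q[:j], strains=rec_s[:j],
                      bundle_forces=rec_f[:j], bundle_names=mech.bundle_names,
                      reference_lengths=mech.L0, energy=energy)
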