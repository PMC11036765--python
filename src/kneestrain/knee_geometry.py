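"""Reduced-order knee geometry: rigid bodies, insertion sites, surfaces.

The knee is represented desk-scale: rigid femur, tibia and patella frames,
straight-line ligament bundles between digitized-style insertion points,
linear springs for the patellar/patellofemoral ligaments and meniscal horn
attachments, and frictionless sphere-on-plane articular contact standing in
for the cartilage layers.

Coordinate convention (right knee): X anterior, Y proximal, Z lateral;
units mm / N / N*mm, degrees at the API surface. The femur frame is the
joint frame; the tibia's reference coordinates are expressed in it. In the
reference (full-extension) pose the femoral condylar spheres rest on the
tibial plateau plane, which carries a posterior slope.

Because the original specimen geometry (digitized insertion sites) is not
published, :func:`build_default_knee` provides a parametric generic knee
placed from published anatomical ranges. It is deliberately generic, not
subject-specific. Insertion placements encode the classic flexion behaviour
of the cruciate bundles: the ACL anteromedial (AM) bundle sits close to the
flexion axis (near-isometric), the posterolateral (PL) bundle farther from
it (slack in flexion).
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from typing import Iterable

import numpy as np

from .errors import ConfigurationError, ModelValidationError, SchemaError
from .kinematics import jcs_rotation
from .ligament_mechanics import LigamentBundle, LinearSpring, load_bundle_parameters

ROTATION_TOL = 1e-9


def _check_rotation(r: np.ndarray, where: str = "rotation") -> np.ndarray:
    r = np.asarray(r, dtype=float)
    if r.shape != (3, 3):
        raise ModelValidationError(f"{where}: expected 3x3 matrix, got shape {r.shape}")
    if not np.allclose(r.T @ r, np.eye(3), atol=1e-6) or np.linalg.det(r) < 0:
        raise ModelValidationError(f"{where}: not a proper rotation matrix")
    return r


@dataclass
class Frame:
    """Position (mm) + orientation of a body-fixed frame relative to ground."""

    position: np.ndarray
    rotation: np.ndarray = field(default_factory=lambda: np.eye(3))

    def __post_init__(self):
        self.position = np.asarray(self.position, dtype=float).reshape(3)
        self.rotation = _check_rotation(self.rotation)
        # Re-orthonormalize so downstream checks hold to tight tolerance.
        u, _, vt = np.linalg.svd(self.rotation)
        r = u @ vt
        if np.linalg.det(r) < 0:
            raise ModelValidationError("rotation has determinant -1")
        self.rotation = r

    def point_to_world(self, local) -> np.ndarray:
        return self.position + self.rotation @ np.asarray(local, dtype=float)

    def vector_to_world(self, local) -> np.ndarray:
        return self.rotation @ np.asarray(local, dtype=float)

    def transformed(self, rotation, translation) -> "Frame":
        """This frame after a rigid transform x -> R x + t of the whole body."""
        rot = np.asarray(rotation, dtype=float)
        return Frame(rot @ self.position + np.asarray(translation, dtype=float),
                     rot @ self.rotation)


@dataclass
class RigidBody:
    name: str
    frame: Frame


@dataclass
class InsertionSite:
    """A ligament attachment point fixed to exactly one body."""

    body: str
    local_position: np.ndarray

    def __post_init__(self):
        self.local_position = np.asarray(self.local_position, dtype=float).reshape(3)
        if not np.all(np.isfinite(self.local_position)):
            raise ModelValidationError(f"insertion site on {self.body}: non-finite position")


@dataclass
class ArticularSurface:
    """Frictionless contact primitive fixed to a body.

    ``kind`` is ``"sphere"`` (convex, e.g. a femoral condyle), ``"socket"``
    (concave spherical cup, e.g. a tibial plateau facet) or ``"plane"``.
    """

    name: str
    body: str
    kind: str                       # "sphere" | "socket" | "plane"
    contact_stiffness: float        # N/mm penalty stiffness
    center: np.ndarray | None = None
    radius: float | None = None
    point: np.ndarray | None = None
    normal: np.ndarray | None = None

    def __post_init__(self):
        if self.kind not in ("sphere", "socket", "plane"):
            raise ModelValidationError(f"surface {self.name}: unknown kind {self.kind!r}")
        if self.contact_stiffness <= 0:
            raise ModelValidationError(f"surface {self.name}: contact_stiffness must be > 0")
        if self.kind in ("sphere", "socket"):
            if self.radius is None or self.radius <= 0:
                raise ModelValidationError(f"surface {self.name}: radius must be > 0")
            self.center = np.asarray(self.center, dtype=float).reshape(3)
        else:
            self.point = np.asarray(self.point, dtype=float).reshape(3)
            n = np.asarray(self.normal, dtype=float).reshape(3)
            nn = np.linalg.norm(n)
            if nn < 1e-12:
                raise ModelValidationError(f"surface {self.name}: zero-length plane normal")
            self.normal = n / nn


@dataclass
class KneeModel:
    """The assembled reduced-order knee.

    ``reference_coords`` are the tibia joint coordinates
    (tx, ty, tz in mm; flexion, valgus, internal rotation in degrees)
    at the full-extension reference pose, expressed in the femur frame.
    """

    bodies: dict[str, RigidBody]
    bundles: list[LigamentBundle]
    linear_springs: list[LinearSpring]
    surfaces: list[ArticularSurface]
    contact_pairs: list[tuple[str, str]]
    muscle_geometry: dict
    reference_coords: np.ndarray
    options: dict = field(default_factory=dict)
    schema_version: str = "1.0"

    def __post_init__(self):
        self.reference_coords = np.asarray(self.reference_coords, dtype=float).reshape(6)

    # -- structural invariants -------------------------------------------------
    EXPECTED_BUNDLES = {"ACL": 2, "PCL": 2, "MCL": 3, "LCL": 3}

    def validate(self) -> None:
        """Check anatomical completeness; raises ModelValidationError."""
        for req in ("femur", "tibia"):
            if req not in self.bodies:
                raise ModelValidationError(f"model must contain a body named {req!r}")
        counts: dict[str, int] = {}
        for b in self.bundles:
            counts[b.ligament] = counts.get(b.ligament, 0) + 1
            for site in (b.femur_site, b.tibia_site):
                if site.body not in self.bodies:
                    raise ModelValidationError(
                        f"bundle {b.name}: endpoint body {site.body!r} undefined")
        for lig, n in self.EXPECTED_BUNDLES.items():
            if counts.get(lig, 0) != n:
                raise ModelValidationError(
                    f"{lig} must have exactly {n} bundles, found {counts.get(lig, 0)}")
        acl_names = {b.name.split("_")[-1] for b in self.bundles if b.ligament == "ACL"}
        if acl_names != {"AM", "PL"}:
            raise ModelValidationError("ACL bundles must be the AM and PL pair")
        for s in self.linear_springs:
            for site in (s.site_a, s.site_b):
                if site.body not in self.bodies:
                    raise ModelValidationError(
                        f"spring {s.name}: endpoint body {site.body!r} undefined")
        for srf in self.surfaces:
            if srf.body not in self.bodies:
                raise ModelValidationError(f"surface {srf.name}: body {srf.body!r} undefined")

    # -- poses -----------------------------------------------------------------
    def reference_pose(self) -> dict[str, Frame]:
        """Frames of all bodies at the full-extension reference pose."""
        femur = self.bodies["femur"].frame
        q = self.reference_coords
        rot = jcs_rotation(q[3], q[4], q[5], degrees=True)
        tibia = Frame(femur.point_to_world(q[:3]), femur.rotation @ rot)
        pose = {"femur": femur, "tibia": tibia}
        for name, body in self.bodies.items():
            pose.setdefault(name, body.frame)
        return pose

    def bundle(self, name: str) -> LigamentBundle:
        for b in self.bundles:
            if b.name == name:
                return b
        raise KeyError(name)

    def initialized(self) -> bool:
        return all(b.reference_length is not None for b in self.bundles)

    # -- serialization ---------------------------------------------------------
    def to_dict(self) -> dict:
        return {
            "schema_version": self.schema_version,
            "bodies": [
                {"name": b.name,
                 "frame": {"position": [float(v) for v in b.frame.position],
                           "rotation": [[float(v) for v in row] for row in b.frame.rotation]}}
                for b in self.bodies.values()
            ],
            "bundles": [
                {"name": b.name, "ligament": b.ligament, "k_N": float(b.k),
                 "reference_strain": float(b.reference_strain), "eps_l": float(b.eps_l),
                 "femur_site": [float(v) for v in b.femur_site.local_position],
                 "tibia_site": [float(v) for v in b.tibia_site.local_position],
                 "reference_length": (None if b.reference_length is None
                                      else float(b.reference_length))}
                for b in self.bundles
            ],
            "linear_springs": [
                {"name": s.name, "k_N_per_mm": float(s.k),
                 "body_a": s.site_a.body,
                 "site_a": [float(v) for v in s.site_a.local_position],
                 "body_b": s.site_b.body,
                 "site_b": [float(v) for v in s.site_b.local_position],
                 "rest_length": None if s.rest_length is None else float(s.rest_length),
                 "tension_only": bool(s.tension_only)}
                for s in self.linear_springs
            ],
            "surfaces": [
                {"name": s.name, "body": s.body, "kind": s.kind,
                 "contact_stiffness": float(s.contact_stiffness),
                 **({"center": [float(v) for v in s.center], "radius": float(s.radius)}
                    if s.kind in ("sphere", "socket") else
                    {"point": [float(v) for v in s.point],
                     "normal": [float(v) for v in s.normal]})}
                for s in self.surfaces
            ],
            "contact_pairs": [list(p) for p in self.contact_pairs],
            "muscle_geometry": self.muscle_geometry,
            "reference_coords": [float(v) for v in self.reference_coords],
            "options": self.options,
        }


# ---------------------------------------------------------------------------
# Default parametric knee
# ---------------------------------------------------------------------------

_ALLOWED_OPTIONS = {
    "eps_l",                      # override transition strain for every bundle
    "bundle_params_path",         # alternative parameter CSV
    "bundle_params",              # dict of per-bundle overrides
    "plateau_slope_deg",          # posterior slope of the tibial plateau
    "contact_stiffness",          # N/mm penalty stiffness per condyle
    "condyle_radius",             # mm
    "condyle_spacing",            # half distance between condylar centers, mm
    "socket_clearance",           # socket radius minus condyle radius, mm
    "patellar_tendon_angle0_deg",     # tendon-shaft angle at full extension
    "patellar_tendon_angle_slope",    # deg of tendon angle per deg of flexion
    "quad_effectiveness",         # patellar tendon force per unit quad force
    "shank_lever_mm",             # knee-to-ankle lever for the ankle moment
}

# Bundle insertion coordinates (mm, unscaled) in femur / tibia local frames.
# Cruciate femoral sites are placed relative to the condylar (flexion) axis so
# that AM is near-isometric and PL slackens with flexion; collaterals span
# epicondyles to the distal tibia / fibular head region.
_BUNDLE_SITES = {
    "ACL_AM": ((-0.67, -0.44, 5.0), (14.0, -2.0, 1.0)),
    "ACL_PL": ((-5.50, 4.33, 6.5), (10.0, -2.0, 1.0)),
    "PCL_AL": ((2.0, -2.0, -6.0), (-12.0, -6.0, 0.0)),
    "PCL_PM": ((0.0, -1.0, -7.0), (-13.0, -7.0, -3.0)),
    "MCL_ANT": ((4.0, 3.0, -45.0), (6.0, -58.0, -34.0)),
    "MCL_CEN": ((0.0, 4.0, -46.0), (1.0, -62.0, -35.0)),
    "MCL_POS": ((-5.0, 3.0, -45.0), (-6.0, -50.0, -34.0)),
    "LCL_ANT": ((3.0, 4.0, 45.0), (-6.0, -45.0, 38.0)),
    "LCL_CEN": ((0.0, 5.0, 46.0), (-8.0, -47.0, 39.0)),
    "LCL_POS": ((-4.0, 4.0, 45.0), (-10.0, -44.0, 38.0)),
}

# Meniscal horn attachment stand-ins: femur-side point, tibia-side point.
_HORN_SITES = {
    "HORN_MED_ANT": ((10.0, -8.0, -18.0), (10.0, -2.0, -18.0)),
    "HORN_MED_POST": ((-10.0, -8.0, -18.0), (-10.0, -2.0, -18.0)),
    "HORN_LAT_ANT": ((10.0, -8.0, 18.0), (10.0, -2.0, 18.0)),
    "HORN_LAT_POST": ((-10.0, -8.0, 18.0), (-10.0, -2.0, 18.0)),
}


def build_default_knee(scale: float = 1.0, options: dict | None = None) -> KneeModel:
    """Construct the parametric default knee (deterministic and pure).

    ``scale`` multiplies every length; stiffnesses are left untouched, so
    scaling the model doubles inter-insertion distances without changing
    material parameters.
    """
    if scale <= 0:
        raise ConfigurationError(f"scale must be > 0, got {scale}")
    opts = dict(options or {})
    for key in opts:
        if key not in _ALLOWED_OPTIONS:
            raise ConfigurationError(f"unknown option {key!r}; allowed: "
                                     + ", ".join(sorted(_ALLOWED_OPTIONS)))

    slope = np.deg2rad(opts.get("plateau_slope_deg", 10.0))
    r_cond = opts.get("condyle_radius", 24.0) * scale
    z_cond = opts.get("condyle_spacing", 22.0) * scale
    kc = opts.get("contact_stiffness", 8000.0)

    params = load_bundle_parameters(opts.get("bundle_params_path"))
    for name, override in opts.get("bundle_params", {}).items():
        params.setdefault(name, {})
        params[name].update(override)

    def site(body: str, xyz: Iterable[float]) -> InsertionSite:
        return InsertionSite(body, np.asarray(xyz, dtype=float) * scale)

    bundles = []
    for name, (fs, ts) in _BUNDLE_SITES.items():
        p = params[name]
        bundles.append(LigamentBundle(
            name=name, ligament=name.split("_")[0],
            k=p["k"], reference_strain=p["reference_strain"],
            eps_l=opts.get("eps_l", p["eps_l"]),
            femur_site=site("femur", fs), tibia_site=site("tibia", ts)))

    springs = [
        LinearSpring("PATELLAR_LIG", 545.0, site("patella", (0.0, -15.0, 0.0)),
                     site("tibia", (18.0, -40.0, 0.0))),
        LinearSpring("MPFL", 16.0, site("femur", (5.0, 8.0, -40.0)),
                     site("patella", (0.0, 0.0, -12.0))),
        LinearSpring("LPFL", 12.0, site("femur", (5.0, 8.0, 40.0)),
                     site("patella", (0.0, 0.0, 12.0))),
    ]
    for name, (fs, ts) in _HORN_SITES.items():
        springs.append(LinearSpring(name, 180.0, site("femur", fs), site("tibia", ts)))

    # Tibial facets are concave sockets congruent with the condylar spheres.
    # A posterior plateau slope means the surface falls toward the posterior
    # edge, i.e. its normal is tilted posteriorly in the tibia frame -- this
    # is what converts axial joint compression into the physiologic anterior
    # tibial shear.
    clearance = opts.get("socket_clearance", 45.0) * scale
    r_sock = r_cond + clearance
    nrm = np.array([-np.sin(slope), np.cos(slope), 0.0])
    # Reference pose: both condyles exactly seated (zero penetration).
    p0 = -r_cond * nrm
    cond_centers = {"med": np.array([0.0, 0.0, -z_cond]),
                    "lat": np.array([0.0, 0.0, z_cond])}
    surfaces = []
    contact_pairs = []
    for side, cc in cond_centers.items():
        # cup center of curvature sits proximal to the condyle center by the
        # clearance, along the tilted socket axis
        sock_center_world = cc + clearance * nrm
        surfaces.append(ArticularSurface(f"{side}_condyle", "femur", "sphere", kc,
                                         center=cc, radius=r_cond))
        surfaces.append(ArticularSurface(f"{side}_plateau", "tibia", "socket", kc,
                                         center=sock_center_world - p0, radius=r_sock))
        contact_pairs.append((f"{side}_condyle", f"{side}_plateau"))

    reference_coords = np.array([p0[0], p0[1], p0[2], 0.0, 0.0, 0.0])

    muscle_geometry = {
        "quad": {
            "tubercle_site": [v * scale for v in (18.0, -40.0, 0.0)],
            "tendon_angle0_deg": opts.get("patellar_tendon_angle0_deg", 28.0),
            "tendon_angle_slope": opts.get("patellar_tendon_angle_slope", 0.4),
            "effectiveness": opts.get("quad_effectiveness", 1.0),
        },
        "hamstrings": {
            "tibia_site": [v * scale for v in (-25.0, -35.0, -8.0)],
            "femur_point": [v * scale for v in (-70.0, 200.0, 0.0)],
        },
        "gastrocnemius": {
            "tibia_site": [v * scale for v in (-10.0, -300.0, 0.0)],
            "femur_point": [v * scale for v in (-22.0, 0.0, 0.0)],
        },
        "ankle": {"lever_mm": opts.get("shank_lever_mm", 300.0) * scale},
    }

    bodies = {
        "femur": RigidBody("femur", Frame(np.zeros(3))),
        "tibia": RigidBody("tibia", Frame(p0, jcs_rotation(0, 0, 0))),
        "patella": RigidBody("patella", Frame(np.array([40.0, 5.0, 0.0]) * scale)),
    }

    model = KneeModel(bodies=bodies, bundles=bundles, linear_springs=springs,
                      surfaces=surfaces, contact_pairs=contact_pairs,
                      muscle_geometry=muscle_geometry,
                      reference_coords=reference_coords,
                      options={"scale": scale, **opts})
    model.validate()
    return model


# ---------------------------------------------------------------------------
# JSON serialization
# ---------------------------------------------------------------------------

def save_model(model: KneeModel, path) -> None:
    """Write the model JSON (full double precision, round-trip stable)."""
    with open(path, "w") as fh:
        json.dump(model.to_dict(), fh, indent=1)


def _require(obj: dict, key: str, pointer: str):
    if key not in obj:
        raise SchemaError(f"{pointer}/{key}", "missing required key")
    return obj[key]


def model_from_dict(data: dict) -> KneeModel:
    if not isinstance(data, dict):
        raise SchemaError("/", "model JSON must be an object")
    bodies_raw = _require(data, "bodies", "")
    bundles_raw = _require(data, "bundles", "")

    bodies: dict[str, RigidBody] = {}
    for i, b in enumerate(bodies_raw):
        name = _require(b, "name", f"/bodies/{i}")
        frame = _require(b, "frame", f"/bodies/{i}")
        bodies[name] = RigidBody(name, Frame(
            _require(frame, "position", f"/bodies/{i}/frame"),
            _require(frame, "rotation", f"/bodies/{i}/frame")))

    bundles = []
    for i, b in enumerate(bundles_raw):
        ptr = f"/bundles/{i}"
        name = _require(b, "name", ptr)
        bundles.append(LigamentBundle(
            name=name,
            ligament=b.get("ligament", name.split("_")[0]),
            k=_require(b, "k_N", ptr),
            reference_strain=_require(b, "reference_strain", ptr),
            eps_l=b.get("eps_l", 0.03),
            femur_site=InsertionSite("femur", _require(b, "femur_site", ptr)),
            tibia_site=InsertionSite("tibia", _require(b, "tibia_site", ptr)),
            reference_length=b.get("reference_length")))

    springs = []
    for i, s in enumerate(data.get("linear_springs", [])):
        ptr = f"/linear_springs/{i}"
        springs.append(LinearSpring(
            name=_require(s, "name", ptr), k=_require(s, "k_N_per_mm", ptr),
            site_a=InsertionSite(s.get("body_a", "femur"), _require(s, "site_a", ptr)),
            site_b=InsertionSite(s.get("body_b", "tibia"), _require(s, "site_b", ptr)),
            rest_length=s.get("rest_length"),
            tension_only=s.get("tension_only", True)))

    surfaces = []
    for i, s in enumerate(data.get("surfaces", [])):
        ptr = f"/surfaces/{i}"
        kind = _require(s, "kind", ptr)
        kwargs = {}
        if kind in ("sphere", "socket"):
            kwargs = {"center": _require(s, "center", ptr),
                      "radius": _require(s, "radius", ptr)}
        elif kind == "plane":
            kwargs = {"point": _require(s, "point", ptr),
                      "normal": _require(s, "normal", ptr)}
        surfaces.append(ArticularSurface(
            name=_require(s, "name", ptr), body=_require(s, "body", ptr), kind=kind,
            contact_stiffness=_require(s, "contact_stiffness", ptr), **kwargs))

    return KneeModel(
        bodies=bodies, bundles=bundles, linear_springs=springs, surfaces=surfaces,
        contact_pairs=[tuple(p) for p in data.get("contact_pairs", [])],
        muscle_geometry=data.get("muscle_geometry", {}),
        reference_coords=data.get("reference_coords", np.zeros(6)),
        options=data.get("options", {}),
        schema_version=data.get("schema_version", "1.0"))


def load_model(path) -> KneeModel:
    """Load a model JSON. Structural schema errors carry a JSON pointer;
    anatomical completeness is checked separately via ``model.validate()``
    (a hand-written minimal model is allowed to be partial)."""
    with open(path) as fh:
        data = json.load(fh)
    return model_from_dict(data)
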