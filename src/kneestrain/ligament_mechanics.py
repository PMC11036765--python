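"""Constitutive laws and strain kinematics for the 1D ligament elements.

Every ligament is a straight, tension-only line element between one femoral
and one tibial insertion. The nonlinear bundles follow the piecewise
force--strain law of Blankevoort-type 1D elements:

    f(e) = 0                      e <= 0          (slack)
    f(e) = k e^2 / (4 eps_l)      0 < e <= 2eps_l (quadratic toe)
    f(e) = k (e - eps_l)          e > 2eps_l      (linear)

with ``k`` the linear-region stiffness in N per unit strain and ``eps_l``
the toe-to-linear transition strain. The law is continuous and C1 at
``e = 2 eps_l``.

Pre-strain initialization follows the usual slack-length convention: a
bundle carrying reference strain ``e_r`` at the full-extension reference
pose has slack length ``L0 = Lr / (1 + e_r)`` where ``Lr`` is the
inter-insertion distance at that pose.
"""

from __future__ import annotations

import csv
import importlib.resources
from dataclasses import dataclass, field
from typing import TYPE_CHECKING, Mapping

import numpy as np

from .errors import DegenerateGeometryError, ParameterError, StateError

if TYPE_CHECKING:  # pragma: no cover
    from .knee_geometry import Frame, InsertionSite


@dataclass
class LigamentBundle:
    """One tension-only nonlinear bundle of a capsular ligament.

    ``ligament`` names the parent structure (``ACL``, ``PCL``, ``MCL``,
    ``LCL``); ``name`` identifies the bundle (e.g. ``ACL_AM``).
    ``reference_length`` (the slack length L0, mm) is ``None`` until
    :func:`initialize_reference_lengths` has been run.
    """

    name: str
    ligament: str
    k: float                      # N per unit strain
    reference_strain: float       # dimensionless pre-strain at full extension
    eps_l: float                  # toe-to-linear transition strain
    femur_site: "InsertionSite" = None
    tibia_site: "InsertionSite" = None
    reference_length: float | None = field(default=None)

    def __post_init__(self):
        if self.k <= 0:
            raise ParameterError(f"bundle {self.name}: k must be > 0, got {self.k}")
        if self.eps_l <= 0:
            raise ParameterError(f"bundle {self.name}: eps_l must be > 0, got {self.eps_l}")
        if self.reference_strain <= -1:
            raise ParameterError(
                f"bundle {self.name}: reference_strain must be > -1, got {self.reference_strain}")
        if self.reference_length is not None and self.reference_length <= 0:
            raise ParameterError(f"bundle {self.name}: reference_length must be > 0")


@dataclass
class LinearSpring:
    """Linear (optionally tension-only) spring, k in N/mm."""

    name: str
    k: float
    site_a: "InsertionSite" = None
    site_b: "InsertionSite" = None
    rest_length: float | None = None
    tension_only: bool = True

    def __post_init__(self):
        if self.k <= 0:
            raise ParameterError(f"spring {self.name}: k must be > 0, got {self.k}")
        if self.rest_length is not None and self.rest_length <= 0:
            raise ParameterError(f"spring {self.name}: rest_length must be > 0")


def blankevoort_force(strain, k: float, eps_l: float):
    """Tension-only nonlinear bundle force (N) at the given strain.

    Accepts scalars or arrays. See the module docstring for the law.
    """
    if k <= 0 or eps_l <= 0:
        raise ParameterError(f"k and eps_l must be positive (k={k}, eps_l={eps_l})")
    e = np.asarray(strain, dtype=float)
    toe = k * e**2 / (4.0 * eps_l)
    lin = k * (e - eps_l)
    f = np.where(e <= 0.0, 0.0, np.where(e <= 2.0 * eps_l, toe, lin))
    if np.ndim(strain) == 0:
        return float(f)
    return f


def blankevoort_energy(strain, k: float, eps_l: float):
    """Strain energy per unit slack length, i.e. the integral of
    :func:`blankevoort_force` over strain (N, multiply by L0 for N*mm).
    """
    if k <= 0 or eps_l <= 0:
        raise ParameterError(f"k and eps_l must be positive (k={k}, eps_l={eps_l})")
    e = np.asarray(strain, dtype=float)
    toe = k * e**3 / (12.0 * eps_l)
    lin = 0.5 * k * (e - eps_l) ** 2 + k * eps_l**2 / 6.0
    u = np.where(e <= 0.0, 0.0, np.where(e <= 2.0 * eps_l, toe, lin))
    if np.ndim(strain) == 0:
        return float(u)
    return u


def _site_world(site: "InsertionSite", pose: Mapping[str, "Frame"]) -> np.ndarray:
    return pose[site.body].point_to_world(site.local_position)


def bundle_length(bundle: LigamentBundle, pose: Mapping[str, "Frame"]) -> float:
    """World-frame inter-insertion distance (mm) at the given pose."""
    a = _site_world(bundle.femur_site, pose)
    b = _site_world(bundle.tibia_site, pose)
    return float(np.linalg.norm(a - b))


def bundle_strain(bundle: LigamentBundle, pose: Mapping[str, "Frame"]) -> float:
    """Engineering strain (L - L0)/L0; negative values mean slack."""
    if bundle.reference_length is None:
        raise StateError(
            f"bundle {bundle.name} is uninitialized; run initialize_reference_lengths first")
    return bundle_length(bundle, pose) / bundle.reference_length - 1.0


def bundle_force(bundle: LigamentBundle, pose: Mapping[str, "Frame"]) -> float:
    """Tension (N) carried by the bundle at the given pose."""
    return blankevoort_force(bundle_strain(bundle, pose), bundle.k, bundle.eps_l)


def initialize_reference_lengths(model, pose: Mapping[str, "Frame"] | None = None,
                                 prestrains: Mapping[str, float] | None = None):
    """Set every bundle's slack length from its pre-strain at the reference pose.

    ``L0 = Lr / (1 + e_r)`` so that ``bundle_strain`` at the reference pose
    reproduces the assigned reference strain exactly. Re-running with the
    same pose and pre-strains is a no-op. Linear springs without an explicit
    rest length get their reference-pose length (zero pre-tension).
    Returns the model for chaining.
    """
    if pose is None:
        pose = model.reference_pose()
    for b in model.bundles:
        if prestrains is not None and b.name in prestrains:
            if prestrains[b.name] <= -1:
                raise ParameterError(f"bundle {b.name}: pre-strain must be > -1")
            b.reference_strain = float(prestrains[b.name])
        lr = bundle_length(b, pose)
        if lr <= 1e-9:
            raise DegenerateGeometryError(
                f"bundle {b.name}: zero inter-insertion distance at the reference pose")
        b.reference_length = lr / (1.0 + b.reference_strain)
    for s in model.linear_springs:
        if s.rest_length is None:
            a = _site_world(s.site_a, pose)
            c = _site_world(s.site_b, pose)
            lr = float(np.linalg.norm(a - c))
            if lr <= 1e-9:
                raise DegenerateGeometryError(
                    f"spring {s.name}: zero length at the reference pose")
            s.rest_length = lr
    return model


def spring_length(spring: LinearSpring, pose: Mapping[str, "Frame"]) -> float:
    a = _site_world(spring.site_a, pose)
    b = _site_world(spring.site_b, pose)
    return float(np.linalg.norm(a - b))


def linear_spring_force(spring: LinearSpring, pose: Mapping[str, "Frame"]) -> float:
    """Axial force (N): k*(L - rest), clamped at 0 when slack if tension-only."""
    if spring.rest_length is None:
        raise StateError(f"spring {spring.name} has no rest length; initialize the model first")
    f = spring.k * (spring_length(spring, pose) - spring.rest_length)
    if spring.tension_only and f < 0.0:
        return 0.0
    return float(f)


def load_bundle_parameters(path=None) -> dict[str, dict[str, float]]:
    """Read the per-bundle parameter CSV (name, k_N, reference_strain, eps_l).

    Lines starting with ``#`` are comments. Defaults to the parameter file
    shipped with the package.
    """
    if path is None:
        ref = importlib.resources.files("kneestrain.data") / "bundle_parameters.csv"
        text = ref.read_text()
    else:
        with open(path) as fh:
            text = fh.read()
    rows = [ln for ln in text.splitlines() if ln.strip() and not ln.lstrip().startswith("#")]
    out: dict[str, dict[str, float]] = {}
    for rec in csv.DictReader(rows):
        out[rec["name"]] = {
            "k": float(rec["k_N"]),
            "reference_strain": float(rec["reference_strain"]),
            "eps_l": float(rec["eps_l"]),
        }
    return out
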