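"""Toy mechanical models and an independent energy-minimization oracle.

The oracle evaluates total potential energy directly from the element
definitions (its own implementation of the constitutive energies, not the
package's), minimizes it by grid search plus a derivative-free polish, and
is used to cross-check the force-balance static solver.
"""

import numpy as np
import scipy.optimize

from kneestrain import Frame, InsertionSite, KneeModel, LigamentBundle, LinearSpring
from kneestrain.knee_geometry import RigidBody


def point_mass_model(anchors, bundle_params, springs=()):
    """Mobile point body ('tibia') tied to fixed anchors on the 'femur'.

    ``anchors``: (m, 3) anchor positions; ``bundle_params``: list of dicts
    with k, eps_l, reference_strain per anchor; ``springs``: list of
    (anchor_xyz, k, rest, tension_only).
    """
    bodies = {"femur": RigidBody("femur", Frame(np.zeros(3))),
              "tibia": RigidBody("tibia", Frame(np.zeros(3)))}
    bundles = []
    for i, (a, p) in enumerate(zip(anchors, bundle_params)):
        bundles.append(LigamentBundle(
            name=f"B{i}", ligament="TOY", k=p["k"], eps_l=p["eps_l"],
            reference_strain=p["reference_strain"],
            femur_site=InsertionSite("femur", np.asarray(a, dtype=float)),
            tibia_site=InsertionSite("tibia", np.zeros(3))))
    lsprings = []
    for i, (a, k, rest, tension_only) in enumerate(springs):
        lsprings.append(LinearSpring(
            name=f"S{i}", k=k, rest_length=rest, tension_only=tension_only,
            site_a=InsertionSite("femur", np.asarray(a, dtype=float)),
            site_b=InsertionSite("tibia", np.zeros(3))))
    return KneeModel(bodies=bodies, bundles=bundles, linear_springs=lsprings,
                     surfaces=[], contact_pairs=[], muscle_geometry={},
                     reference_coords=np.zeros(6))


def toy_energy(model, force, x3):
    """Total potential at translation x3 (3,): elastic minus force work.

    Independent re-derivation of the element energies (piecewise bundle law
    integrated by hand; quadratic springs)."""
    e_total = -float(np.asarray(force) @ x3)
    for b in model.bundles:
        a = b.femur_site.local_position
        lr0 = np.linalg.norm(a)            # anchored at origin in reference
        l0 = lr0 / (1.0 + b.reference_strain)
        length = np.linalg.norm(a - x3)
        eps = length / l0 - 1.0
        k, el = b.k, b.eps_l
        if eps <= 0:
            u = 0.0
        elif eps <= 2 * el:
            u = k * eps**3 / (12.0 * el)
        else:
            u = 0.5 * k * (eps - el) ** 2 + k * el**2 / 6.0
        e_total += u * l0
    for s in model.linear_springs:
        a = s.site_a.local_position
        rest = s.rest_length if s.rest_length is not None else np.linalg.norm(a)
        ext = np.linalg.norm(a - x3) - rest
        if not (s.tension_only and ext < 0):
            e_total += 0.5 * s.k * ext**2
    return e_total


def minimize_energy(model, force, free_axes, half_width=4.0, n_grid=13):
    """Grid search over the free translation axes + Nelder-Mead/Powell polish."""
    free_axes = list(free_axes)

    def embed(x):
        x3 = np.zeros(3)
        x3[free_axes] = x
        return x3

    grids = np.meshgrid(*[np.linspace(-half_width, half_width, n_grid)
                          for _ in free_axes], indexing="ij")
    pts = np.stack([g.ravel() for g in grids], axis=1)
    energies = np.array([toy_energy(model, force, embed(p)) for p in pts])
    x0 = pts[int(np.argmin(energies))]
    res = scipy.optimize.minimize(lambda x: toy_energy(model, force, embed(x)), x0,
                                  method="Powell",
                                  options={"xtol": 1e-12, "ftol": 1e-14,
                                           "maxiter": 20000})
    res = scipy.optimize.minimize(lambda x: toy_energy(model, force, embed(x)), res.x,
                                  method="Nelder-Mead",
                                  options={"xatol": 1e-10, "fatol": 1e-14})
    return embed(res.x)


def random_toy(rng, n_dof):
    """Random well-posed toy: anchors spread around the origin, a stabilizing
    two-sided spring, and a bounded external force."""
    m = rng.integers(4, 8)
    dirs = rng.standard_normal((m, 3))
    dirs /= np.linalg.norm(dirs, axis=1, keepdims=True)
    anchors = dirs * rng.uniform(25.0, 60.0, (m, 1))
    params = [{"k": rng.uniform(500.0, 5000.0), "eps_l": rng.uniform(0.01, 0.06),
               "reference_strain": rng.uniform(0.0, 0.08)} for _ in range(m)]
    spring_anchor = rng.standard_normal(3)
    spring_anchor *= rng.uniform(30.0, 50.0) / np.linalg.norm(spring_anchor)
    springs = [(spring_anchor, rng.uniform(20.0, 80.0), None, False)]
    model = point_mass_model(anchors, params, springs)
    free_axes = sorted(rng.choice(3, size=n_dof, replace=False).tolist())
    force = np.zeros(3)
    force[free_axes] = rng.uniform(-60.0, 60.0, n_dof)
    return model, force, free_axes
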