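"""Scripted reproductions of the classic bench/clinical knee tests.

Four protocols exercise the model the way physical validation experiments
load a knee:

* passive flexion under a 600 N hamstring force with the femur grounded
  (cruciate-bundle strain pattern and tibial internal rotation),
* Lachman and anterior drawer tests (anterior tibial force at 30 and 90
  degrees of flexion),
* abduction (valgus) moment at 25 degrees of flexion.

Reference experimental curves are not shipped; they can be supplied as
two-column CSV files and compared against model output with
:func:`compare_curves` (Pearson r and RMSE after linear resampling onto
the model abscissa). Qualitative trend assertions live in the test suite.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
import scipy.stats

from .errors import InsufficientDataError, SolverError
from .joint_solver import AppliedForce, LoadCase, solve_static
from .knee_geometry import KneeModel

DEFAULT_SWEEP_POINTS = 21


def _sweep(model: KneeModel, cases, labels, label_name):
    rows = []
    guess = None
    for label, case in zip(labels, cases):
        try:
            res = solve_static(model, case, guess=guess)
        except SolverError as exc:
            raise SolverError(f"{label_name}={label:g}: {exc}",
                              residual=exc.residual) from exc
        guess = res.coords
        rows.append((label, res))
    return rows


def run_flexion_test(model: KneeModel, max_flexion: float = 90.0,
                     hamstring_force: float = 600.0,
                     n_points: int = DEFAULT_SWEEP_POINTS) -> pd.DataFrame:
    """Passive flexion sweep under a constant hamstring force.

    Returns a frame with flexion angle, AM/PL bundle strain and tibial
    internal rotation. ``max_flexion`` is capped at 90 degrees, the range
    over which the reduced contact geometry is meaningful.
    """
    if max_flexion > 90.0:
        raise ValueError("max_flexion must be <= 90 degrees")
    angles = np.linspace(0.0, max_flexion, n_points)
    cases = [LoadCase(prescribed={"flexion": a}, hams_N=hamstring_force) for a in angles]
    rows = _sweep(model, cases, angles, "flexion_deg")
    return pd.DataFrame({
        "flexion_deg": angles,
        "am_strain": [r.strains["ACL_AM"] for _, r in rows],
        "pl_strain": [r.strains["ACL_PL"] for _, r in rows],
        "internal_rotation_deg": [r.angles.introt for _, r in rows],
    })


def _anterior_force_sweep(model, flexion, min_force, max_force, n_points, label):
    forces = np.linspace(min_force, max_force, n_points)
    if not (forces.min() <= 0.0 <= forces.max()):
        raise ValueError("force sweep must include 0 N")
    cases = [LoadCase(prescribed={"flexion": flexion},
                      forces=[AppliedForce(site=[0.0, 0.0, 0.0],
                                           vector=[f, 0.0, 0.0], frame="tibia")])
             for f in forces]
    rows = _sweep(model, cases, forces, label)
    return pd.DataFrame({
        "anterior_force_N": forces,
        "am_strain": [r.strains["ACL_AM"] for _, r in rows],
        "pl_strain": [r.strains["ACL_PL"] for _, r in rows],
        "anterior_translation_mm": [r.angles.anterior_mm for _, r in rows],
    })


def run_lachman(model: KneeModel, flexion: float = 30.0, max_force: float = 200.0,
                min_force: float = 0.0,
                n_points: int = DEFAULT_SWEEP_POINTS) -> pd.DataFrame:
    """Lachman test: anterior tibial force sweep at (default) 30 deg flexion."""
    return _anterior_force_sweep(model, flexion, min_force, max_force,
                                 n_points, "anterior_force_N")


def run_drawer(model: KneeModel, flexion: float = 90.0, max_force: float = 200.0,
               min_force: float = 0.0,
               n_points: int = DEFAULT_SWEEP_POINTS) -> pd.DataFrame:
    """Anterior drawer test: like Lachman but at 90 deg flexion."""
    return _anterior_force_sweep(model, flexion, min_force, max_force,
                                 n_points, "anterior_force_N")


def run_abduction(model: KneeModel, flexion: float = 25.0, max_moment: float = 50.0,
                  n_points: int = DEFAULT_SWEEP_POINTS) -> pd.DataFrame:
    """Abduction (valgus) moment sweep (N*m) at fixed flexion.

    Pure abduction: axial tibial rotation is constrained to zero (as in a
    bench test that grips the tibia), flexion is held, and the remaining
    translations equilibrate. Valgus rotation is reported relative to the
    zero-moment equilibrium; ACL strain is the larger of the two bundle
    strains.
    """
    moments = np.linspace(0.0, max_moment, n_points)
    cases = [LoadCase(prescribed={"flexion": flexion, "introt": 0.0},
                      moments={"valgus": m * 1000.0}) for m in moments]
    rows = _sweep(model, cases, moments, "abduction_Nm")
    valgus = np.array([r.angles.valgus for _, r in rows])
    return pd.DataFrame({
        "abduction_moment_Nm": moments,
        "valgus_deg": valgus - valgus[0],
        "am_strain": [r.strains["ACL_AM"] for _, r in rows],
        "pl_strain": [r.strains["ACL_PL"] for _, r in rows],
        "acl_strain": [max(r.strains["ACL_AM"], r.strains["ACL_PL"]) for _, r in rows],
    })


# ---------------------------------------------------------------------------
# Curve comparison
# ---------------------------------------------------------------------------

def _as_xy(curve) -> tuple[np.ndarray, np.ndarray]:
    if isinstance(curve, pd.DataFrame):
        arr = curve.iloc[:, :2].to_numpy(dtype=float)
    else:
        arr = np.asarray(curve, dtype=float)
    if arr.ndim != 2 or arr.shape[1] < 2:
        raise ValueError("curve must be (n, 2): abscissa, ordinate")
    order = np.argsort(arr[:, 0])
    return arr[order, 0], arr[order, 1]


def compare_curves(model_curve, reference_curve) -> tuple[float, float]:
    """Pearson r and RMSE between a model curve and a reference curve.

    The reference is linearly resampled onto the model abscissa restricted
    to the overlapping range; fewer than 3 common points is an error. RMSE
    is in the ordinate's units.
    """
    xm, ym = _as_xy(model_curve)
    xr, yr = _as_xy(reference_curve)
    lo, hi = max(xm.min(), xr.min()), min(xm.max(), xr.max())
    mask = (xm >= lo - 1e-12) & (xm <= hi + 1e-12)
    if mask.sum() < 3:
        raise InsufficientDataError(
            f"only {int(mask.sum())} common abscissa points; need at least 3")
    x = xm[mask]
    y_model = ym[mask]
    y_ref = np.interp(x, xr, yr)
    if np.std(y_model) == 0.0 or np.std(y_ref) == 0.0:
        r = np.nan
    else:
        r = float(scipy.stats.pearsonr(y_model, y_ref).statistic)
    rmse = float(np.sqrt(np.mean((y_model - y_ref) ** 2)))
    return r, rmse


def read_reference_curve(path) -> pd.DataFrame:
    """Read a two-column reference CSV; ``#`` lines are unit/header comments."""
    return pd.read_csv(path, comment="#", header=None, names=["x", "y"])
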