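"""Dynamic single-leg landing on the knee model and peak ACL strain extraction.

The landing is driven per participant profile: knee flexion follows the
profile's flexion trajectory (a displacement boundary condition, as the
hip-side kinematics are absorbed into the knee flexion history of an
isolated-knee model), while muscle forces and (optionally) the ankle
plantar-flexion moment load the free tibial degrees of freedom.

Strain reporting uses the touch-down gauge: the ACL bundle length at the
touch-down instant (first GRF sample above threshold) is the gauge length,
and the reported peak relative strain is

    max over the landing window of (L(t) - L_td) / L_td

for the governing (larger-peak) ACL bundle. The landing window is
touch-down to 250 ms after by default; the on/off ankle-moment comparison
isolates the posterior soleus mechanism's strain-relief effect.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .errors import InsufficientDataError, KneeStrainError, SolverError
from .joint_solver import BoundaryTimeSeries, LoadCase, Trajectory, simulate_dynamic
from .knee_geometry import KneeModel
from .ligament_mechanics import initialize_reference_lengths
from .synthetic_profiles import ParticipantProfile

LANDING_WINDOW_S = 0.250
ACL_BUNDLES = ("ACL_AM", "ACL_PL")


@dataclass
class LandingResult:
    profile_id: str
    trajectory: Trajectory
    ankle_moment_applied: bool
    touch_down_time: float
    touch_down_lengths: dict[str, float]          # mm per ACL bundle
    relative_strain: dict[str, np.ndarray]        # touch-down gauge, per bundle
    peak_relative_strain_by_bundle: dict[str, float]
    peak_relative_strain: float                   # max over the two bundles
    time_of_peak: float


def peak_relative_strain(lengths: np.ndarray, touch_down_index: int) -> float:
    """Peak of (L(t) - L_td)/L_td over t >= touch-down."""
    lengths = np.asarray(lengths, dtype=float)
    if not 0 <= touch_down_index < len(lengths):
        raise InsufficientDataError("touch-down index outside the trajectory")
    window = lengths[touch_down_index:]
    if len(window) == 0:
        raise InsufficientDataError("empty landing window")
    l_td = lengths[touch_down_index]
    return float(np.max((window - l_td) / l_td))


def run_landing(model: KneeModel, profile: ParticipantProfile,
                ankle_moment: bool = True, dt: float = 2e-4,
                damping: dict | None = None,
                landing_window_s: float = LANDING_WINDOW_S) -> LandingResult:
    """Simulate one landing profile and extract relative ACL strain.

    Deterministic for fixed inputs. Both AM and PL relative strains are
    reported; the headline ``peak_relative_strain`` is the larger bundle
    peak (the aggregate convention).
    """
    if not model.initialized():
        initialize_reference_lengths(model)
    c = profile.curves
    bc = BoundaryTimeSeries(
        times=profile.time,
        quad_N=c["quad_N"], hams_N=c["hams_N"], gastroc_N=c["gastroc_N"],
        ankle_moment_Nm=c["ankle_moment_Nm"] if ankle_moment else None,
        compression_N=c["grf_N"],
        prescribed_flexion_deg=c["knee_flexion_deg"],
        case=LoadCase())
    try:
        traj = simulate_dynamic(model, bc, dt=dt, damping=damping)
    except SolverError as exc:
        raise SolverError(f"landing profile {profile.id}: {exc}",
                          residual=exc.residual) from exc

    td_time = float(profile.time[profile.touchdown_index()])
    td_idx = int(np.searchsorted(traj.times, td_time))
    end_idx = int(np.searchsorted(traj.times, td_time + landing_window_s, side="right"))

    touch_down_lengths = {}
    relative = {}
    peaks = {}
    t_peak = {}
    for name in ACL_BUNDLES:
        lengths = traj.lengths(name)
        l_td = lengths[td_idx]
        rel = lengths[td_idx:end_idx] / l_td - 1.0
        touch_down_lengths[name] = float(l_td)
        relative[name] = rel
        peaks[name] = float(np.max(rel))
        t_peak[name] = float(traj.times[td_idx + int(np.argmax(rel))])
    governing = max(peaks, key=peaks.get)
    return LandingResult(
        profile_id=profile.id, trajectory=traj, ankle_moment_applied=ankle_moment,
        touch_down_time=td_time, touch_down_lengths=touch_down_lengths,
        relative_strain=relative, peak_relative_strain_by_bundle=peaks,
        peak_relative_strain=peaks[governing], time_of_peak=t_peak[governing])


def cohort_landing_summary(results: list[LandingResult]) -> dict:
    """Cohort mean/sd of peak relative strain per ankle-moment arm and the
    percent reduction attributable to the ankle moment.

    Requires >= 2 results per arm, and matched profile ids across arms.
    Strains are reported in percent; ``reduction_percent`` is
    ``(1 - mean_on/mean_off) * 100``.
    """
    on = sorted((r for r in results if r.ankle_moment_applied), key=lambda r: r.profile_id)
    off = sorted((r for r in results if not r.ankle_moment_applied), key=lambda r: r.profile_id)
    if len(on) < 2 or len(off) < 2:
        raise InsufficientDataError("need at least 2 landings per ankle-moment arm")
    if [r.profile_id for r in on] != [r.profile_id for r in off]:
        raise KneeStrainError("ankle-moment arms cover different profiles")
    p_on = np.array([r.peak_relative_strain for r in on]) * 100.0
    p_off = np.array([r.peak_relative_strain for r in off]) * 100.0
    mean_on, mean_off = float(np.mean(p_on)), float(np.mean(p_off))
    return {
        "n": len(on),
        "mean_on_pct": mean_on,
        "sd_on_pct": float(np.std(p_on, ddof=1)),
        "mean_off_pct": mean_off,
        "sd_off_pct": float(np.std(p_off, ddof=1)),
        "reduction_percent": (1.0 - mean_on / mean_off) * 100.0,
    }


def cohort_table(profiles: list[ParticipantProfile],
                 results: list[LandingResult]) -> pd.DataFrame:
    """Assemble the regression input table: one row per profile with the peak
    relative ACL strain (percent) and the candidate sagittal-plane predictors."""
    by_id = {p.id: p for p in profiles}
    rows = []
    for r in results:
        p = by_id[r.profile_id]
        rows.append({
            "id": p.id,
            "peak_strain_pct": r.peak_relative_strain * 100.0,
            **{k: v for k, v in p.summary.items() if k != "time_of_max_grf_s"},
        })
    return pd.DataFrame(rows)
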