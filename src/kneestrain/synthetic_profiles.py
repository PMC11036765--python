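"""Synthetic single-leg jump-landing boundary-condition profiles.

The original study drove its knee model with muscle-force and joint
kinematic/kinetic time histories derived from motion capture of ten
participants. Those recordings are not deposited, so this module generates
surrogate profiles with the same qualitative structure: single-burst
quadriceps / hamstrings / gastrocnemius force curves peaking early in the
landing phase, smooth hip / knee / ankle / trunk angle excursions, hip and
ankle moment bursts, and a vertical ground reaction force (GRF) spike
after touch-down.

A cohort is parameterized by envelope statistics (peak mean +/- sd,
time-to-peak mean +/- sd) per curve plus scalar descriptors of the landing
posture. A latent "landing softness" factor couples the postural angles
(a participant who lands soft flexes trunk, hip, knee and ankle together),
which is what gives the downstream regression realistic collinearity
structure. All random draws are truncated at +/-2.5 sd. Envelope defaults
are desk-scale surrogates chosen from typical single-leg-landing
biomechanics; they are not the original study's data.

Profiles are deterministic given (cohort seed, participant index); summary
descriptors are always recomputed from the generated curves.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.interpolate import PchipInterpolator

from .errors import CohortSpecError

#: documented column order of the profile CSV
PROFILE_COLUMNS = [
    "time_s", "quad_N", "hams_N", "gastroc_N",
    "hip_angle_deg", "ankle_angle_deg", "hip_moment_Nm", "ankle_moment_Nm",
    "trunk_flexion_deg", "knee_flexion_deg", "grf_N",
]

TOUCHDOWN_GRF_N = 10.0   # GRF threshold defining the touch-down instant


@dataclass
class CurveSpec:
    """Envelope of one burst curve: peak (units of the curve) and time-to-peak (s)."""
    peak_mean: float
    peak_sd: float
    t_peak_mean: float
    t_peak_sd: float

    def check(self, name):
        if self.peak_mean < 0:
            raise CohortSpecError(f"{name}: negative peak mean")
        if self.peak_sd < 0 or self.t_peak_sd < 0:
            raise CohortSpecError(f"{name}: negative sd")
        if self.peak_mean - 2.5 * self.peak_sd < 0:
            raise CohortSpecError(
                f"{name}: envelope reaches negative peaks (mean {self.peak_mean}, "
                f"sd {self.peak_sd})")


@dataclass
class ScalarSpec:
    """One scalar descriptor; ``loading`` couples it to the latent softness factor."""
    mean: float
    sd: float
    loading: float = 0.0

    def check(self, name):
        if self.sd < 0:
            raise CohortSpecError(f"{name}: negative sd")
        if not -1.0 <= self.loading <= 1.0:
            raise CohortSpecError(f"{name}: loading must be in [-1, 1]")


@dataclass
class CohortSpec:
    """Statistical envelopes of a synthetic landing cohort."""

    n: int = 10
    seed: int = 0
    t_start: float = -0.05
    t_end: float = 0.30
    dt: float = 0.002
    forces: dict[str, CurveSpec] = field(default_factory=dict)
    moments: dict[str, CurveSpec] = field(default_factory=dict)
    scalars: dict[str, ScalarSpec] = field(default_factory=dict)
    activation_at_touchdown: float = 0.10   # muscle pre-activation, fraction of peak
    #: Latin-hypercube cohort design: every envelope variable is sampled from
    #: independently permuted quantile strata across the n participants, so a
    #: cohort spans the envelope the way a designed participant panel would,
    #: instead of drifting with the luck of iid draws. Set False for plain
    #: iid sampling.
    stratified: bool = True

    def __post_init__(self):
        if self.n < 1:
            raise CohortSpecError("cohort size must be >= 1")
        for name, c in {**self.forces, **self.moments}.items():
            c.check(name)
        for name, s in self.scalars.items():
            s.check(name)


def default_cohort_spec(n: int = 10, seed: int = 0) -> CohortSpec:
    """Envelope defaults for a recreational single-leg-landing cohort."""
    return CohortSpec(
        n=n, seed=seed,
        forces={
            "quad": CurveSpec(2600.0, 500.0, 0.070, 0.012),
            "hams": CurveSpec(900.0, 250.0, 0.080, 0.015),
            "gastroc": CurveSpec(1100.0, 300.0, 0.055, 0.010),
        },
        moments={
            "hip": CurveSpec(120.0, 30.0, 0.060, 0.010),
            "ankle": CurveSpec(200.0, 35.0, 0.055, 0.010),
        },
        scalars={
            "body_weight_N": ScalarSpec(700.0, 80.0),
            "grf_peak_bw": ScalarSpec(3.25, 0.4, -0.4),
            "t_grf_peak_s": ScalarSpec(0.045, 0.008),
            "trunk_flexion_at_maxgrf": ScalarSpec(15.0, 8.0, 0.8),
            "hip_flexion_at_maxgrf": ScalarSpec(40.0, 10.0, 0.8),
            "ankle_flexion_at_maxgrf": ScalarSpec(20.0, 7.0, 0.6),
            "knee_flexion_touchdown": ScalarSpec(18.0, 4.0, 0.3),
            "max_knee_flexion": ScalarSpec(55.0, 8.0, 0.8),
            "t_max_knee_flexion_s": ScalarSpec(0.13, 0.02),
        })


@dataclass
class ParticipantProfile:
    """One participant's landing boundary conditions plus summary descriptors."""

    id: str
    time: np.ndarray
    curves: dict[str, np.ndarray]
    summary: dict[str, float]

    def touchdown_index(self) -> int:
        """First sample with GRF above threshold; a profile whose GRF never
        crosses it (e.g. a null/flight-only profile) touches down at t = 0."""
        idx = np.nonzero(self.curves["grf_N"] > TOUCHDOWN_GRF_N)[0]
        if len(idx) == 0:
            return int(np.searchsorted(self.time, 0.0))
        return int(idx[0])

    def to_frame(self) -> pd.DataFrame:
        cols = {"time_s": self.time}
        cols.update({c: self.curves[c] for c in PROFILE_COLUMNS if c != "time_s"})
        return pd.DataFrame(cols)

    def to_csv(self, path) -> None:
        self.to_frame().to_csv(path, index=False)

    @classmethod
    def from_csv(cls, path, id: str | None = None) -> "ParticipantProfile":
        df = pd.read_csv(path)
        time = df["time_s"].to_numpy(dtype=float)
        curves = {c: df[c].to_numpy(dtype=float) for c in PROFILE_COLUMNS if c != "time_s"}
        prof = cls(id=id or str(path), time=time, curves=curves, summary={})
        prof.summary = compute_summary(prof)
        return prof


def _truncnorm(rng, sd_limit=2.5):
    while True:
        z = rng.standard_normal()
        if abs(z) <= sd_limit:
            return z


class _CohortDraws:
    """Standard-normal draws for one participant, optionally stratified.

    Stratified mode implements a Latin hypercube over the cohort: for each
    named variable a seed-determined permutation assigns participant
    ``index`` a quantile stratum, and the participant's own stream jitters
    the position within the stratum. Every variable's marginal stays
    N(0, 1) truncated at +/-2.5 sd.
    """

    def __init__(self, spec: CohortSpec, index: int, rng):
        self.rng = rng
        self.stratified = spec.stratified
        self.n = spec.n
        self.index = index % spec.n
        if self.stratified:
            # permutations depend only on (seed, n): identical for all
            # participants of a cohort, so each (seed, index) stays
            # deterministic
            prng = np.random.default_rng(
                [abs(int(spec.seed)) % (2**31), spec.n, 424242])
            self._perm_rng = prng

    def draw(self, _name: str) -> float:
        if not self.stratified:
            return _truncnorm(self.rng)
        from scipy.stats import norm
        stratum = int(self._perm_rng.permutation(self.n)[self.index])
        u = (stratum + self.rng.uniform()) / self.n
        return float(np.clip(norm.ppf(u), -2.5, 2.5))


def _draw_scalar(spec: ScalarSpec, softness: float, draws: "_CohortDraws",
                 name: str) -> float:
    lam = spec.loading
    z = lam * softness + np.sqrt(max(0.0, 1.0 - lam**2)) * draws.draw(name)
    return spec.mean + spec.sd * z


def _burst(time, t_start, t_end, peak, t_peak, v0_frac, td_frac, tail_frac):
    """Single-peaked C1 burst via a monotone-segment cubic (pchip) spline."""
    t_peak = float(np.clip(t_peak, 0.02, 0.60 * t_end))
    knots_t = [t_start, -0.01, 0.0, t_peak, min(t_peak + 0.08, 0.85 * t_end), t_end]
    knots_v = [v0_frac * peak, 0.85 * td_frac * peak, td_frac * peak,
               peak, 0.45 * peak, tail_frac * peak]
    f = PchipInterpolator(knots_t, knots_v)(time)
    return np.clip(f, 0.0, None)


def _angle_curve(time, t_start, knots):
    ts, vs = zip(*knots)
    return PchipInterpolator(ts, vs)(time)


def _grf_curve(time, peak, t_peak, bw, t_end):
    """Zero before touch-down, half-cosine rise to the impact peak, then
    exponential decay toward body weight."""
    t_peak = float(np.clip(t_peak, 0.02, 0.10))
    g = np.zeros_like(time)
    rise = (time > 0) & (time <= t_peak)
    g[rise] = peak * np.sin(0.5 * np.pi * time[rise] / t_peak) ** 2
    after = time > t_peak
    tau = 0.06
    g[after] = bw + (peak - bw) * np.exp(-(time[after] - t_peak) / tau)
    return g


def generate_profile(spec: CohortSpec, index: int) -> ParticipantProfile:
    """Generate participant ``index`` of the cohort (deterministic per seed/index)."""
    rng = np.random.default_rng([abs(int(spec.seed)) % (2**31), int(index)])
    draws = _CohortDraws(spec, index, rng)
    softness = draws.draw("softness")
    time = np.arange(spec.t_start, spec.t_end + 0.5 * spec.dt, spec.dt)

    sc = {name: _draw_scalar(s, softness, draws, name)
          for name, s in spec.scalars.items()}
    bw = max(sc["body_weight_N"], 300.0)
    grf_peak = max(sc["grf_peak_bw"], 1.2) * bw
    t_grf = float(np.clip(sc["t_grf_peak_s"], 0.02, 0.08))
    t_kmax = float(np.clip(sc["t_max_knee_flexion_s"], 0.09, 0.20))
    knee_td = sc["knee_flexion_touchdown"]
    knee_max = max(sc["max_knee_flexion"], knee_td + 10.0)
    hipg = sc["hip_flexion_at_maxgrf"]
    trunkg = sc["trunk_flexion_at_maxgrf"]
    ankleg = sc["ankle_flexion_at_maxgrf"]

    curves: dict[str, np.ndarray] = {}
    curves["grf_N"] = _grf_curve(time, grf_peak, t_grf, bw, spec.t_end)
    for name, key in (("quad", "quad_N"), ("hams", "hams_N"), ("gastroc", "gastroc_N")):
        c = spec.forces[name]
        peak = max(c.peak_mean + c.peak_sd * draws.draw(f"{name}_peak"), 0.0)
        tpk = c.t_peak_mean + c.t_peak_sd * draws.draw(f"{name}_tpk")
        curves[key] = _burst(time, spec.t_start, spec.t_end, peak, tpk,
                             v0_frac=0.05, td_frac=spec.activation_at_touchdown,
                             tail_frac=0.25)
    for name, key in (("hip", "hip_moment_Nm"), ("ankle", "ankle_moment_Nm")):
        c = spec.moments[name]
        peak = max(c.peak_mean + c.peak_sd * draws.draw(f"{name}_peak"), 0.0)
        tpk = c.t_peak_mean + c.t_peak_sd * draws.draw(f"{name}_tpk")
        curves[key] = _burst(time, spec.t_start, spec.t_end, peak, tpk,
                             v0_frac=0.0, td_frac=0.10, tail_frac=0.30)

    t0, t1 = spec.t_start, spec.t_end
    curves["knee_flexion_deg"] = _angle_curve(time, t0, [
        (t0, knee_td - 3.0), (0.0, knee_td), (t_kmax, knee_max), (t1, knee_max - 8.0)])
    curves["hip_angle_deg"] = _angle_curve(time, t0, [
        (t0, hipg - 12.0), (0.0, hipg - 8.0), (t_grf, hipg),
        (t_kmax, hipg + 10.0), (t1, hipg + 6.0)])
    curves["trunk_flexion_deg"] = _angle_curve(time, t0, [
        (t0, trunkg - 6.0), (0.0, trunkg - 4.0), (t_grf, trunkg),
        (t_kmax, trunkg + 5.0), (t1, trunkg + 3.0)])
    curves["ankle_angle_deg"] = _angle_curve(time, t0, [
        (t0, ankleg - 25.0), (0.0, ankleg - 18.0), (t_grf, ankleg),
        (t_kmax, ankleg + 8.0), (t1, ankleg + 5.0)])

    prof = ParticipantProfile(id=f"P{index + 1:02d}", time=time, curves=curves,
                              summary={"body_weight_N": bw})
    prof.summary = {"body_weight_N": bw, **compute_summary(prof)}
    return prof


def compute_summary(profile: ParticipantProfile) -> dict[str, float]:
    """Recompute the scalar descriptors from the stored curves.

    ``*_at_maxgrf`` values are the angle curves sampled at the instant of
    peak vertical GRF; velocities are peak absolute finite-difference rates.
    """
    c = profile.curves
    t = profile.time
    i_max = int(np.argmax(c["grf_N"]))
    dt = float(t[1] - t[0])
    knee_rate = np.gradient(c["knee_flexion_deg"], dt)
    out = {
        "peak_grf_N": float(c["grf_N"][i_max]),
        "time_of_max_grf_s": float(t[i_max]),
        "trunk_flexion_at_maxgrf": float(c["trunk_flexion_deg"][i_max]),
        "hip_flexion_at_maxgrf": float(c["hip_angle_deg"][i_max]),
        "ankle_flexion_at_maxgrf": float(c["ankle_angle_deg"][i_max]),
        "max_knee_flexion": float(np.max(c["knee_flexion_deg"])),
        "peak_knee_flexion_velocity_dps": float(np.max(np.abs(knee_rate))),
        "peak_quad_N": float(np.max(c["quad_N"])),
        "peak_hams_N": float(np.max(c["hams_N"])),
        "peak_gastroc_N": float(np.max(c["gastroc_N"])),
        "peak_hip_moment_Nm": float(np.max(c["hip_moment_Nm"])),
        "peak_ankle_moment_Nm": float(np.max(c["ankle_moment_Nm"])),
    }
    if "body_weight_N" in profile.summary:
        out["body_weight_N"] = profile.summary["body_weight_N"]
    for v in out.values():
        if not np.isfinite(v):
            raise CohortSpecError(f"profile {profile.id}: non-finite summary value")
    return out


def sample_cohort(spec: CohortSpec, out_dir=None) -> list[ParticipantProfile]:
    """Generate the full cohort; optionally write one CSV per profile plus a
    ``cohort_summary.csv`` table (one row per participant)."""
    profiles = [generate_profile(spec, i) for i in range(spec.n)]
    if out_dir is not None:
        from pathlib import Path
        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        for p in profiles:
            p.to_csv(out / f"profile_{p.id}.csv")
        cohort_summary_table(profiles).to_csv(out / "cohort_summary.csv", index=False)
    return profiles


def cohort_summary_table(profiles: list[ParticipantProfile]) -> pd.DataFrame:
    rows = [{"id": p.id, **p.summary} for p in profiles]
    return pd.DataFrame(rows)
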