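"""Synthetic blink-reflex induction sessions.

Generates the data the analysis pipeline consumes: per-stimulus EMG sweeps
(200 ms at 10 kHz) containing an early R1 burst (onset ~10 ms, brief) and a
late R2 burst (onset ~30 ms, prolonged) over 20-Hz high-passed Gaussian
noise; a monotone aRASS sedation staircase; and an effect-site propofol
trajectory from the study's 3.3 mL/kg/h infusion protocol.

Each component's amplitude fades linearly with effect-site concentration and
is abolished at a patient-specific threshold.  The population calibration for
the three thresholds is the studied cohort's summary: Ce at loss of R2
1.45 ± 0.85, at loss of R1 2.99 ± 1.19, and at loss of responsiveness
4.22 ± 1.24 µg/mL (mean ± SD), with abolition thresholds tied to the drawn
LOR2/LOR1 values so cohort statistics are directly calibrated.

The burst ``latency`` is the component *onset* (the clinical convention);
the Gaussian envelope is centred two envelope SDs after onset, which keeps
more than 99% of R1 energy inside 10-25 ms and of R2 energy inside
25-200 ms, the analysis windows downstream.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace

import numpy as np
from scipy import signal
from scipy import stats as _stats

from .pkpd import (
    ConcentrationTrajectory,
    Demographics,
    protocol_infusion,
    schnider_parameters,
    simulate_infusion,
)

__all__ = [
    "ReflexComponent",
    "PatientProfile",
    "Sweep",
    "SedationRecord",
    "SimulatedSession",
    "EndpointTruth",
    "PopulationConfig",
    "DEFAULT_POPULATION",
    "draw_patient",
    "component_scale",
    "synth_sweep",
    "arass_at",
    "simulate_session",
]

SWEEP_FS_HZ = 10_000.0
SWEEP_DURATION_S = 0.200
SWEEP_SAMPLES = int(SWEEP_FS_HZ * SWEEP_DURATION_S)  # 2000
HIGHPASS_HZ = 20.0
STIM_INTERVAL_S = 6.0
N_BASELINE_SWEEPS = 4

#: Envelope centre sits this many envelope SDs after the onset latency.
ENVELOPE_CENTER_SDS = 2.0

ARASS_LEVELS = (0, -1, -2, -3, -4, -5)


# ---------------------------------------------------------------------------
# Domain types
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class ReflexComponent:
    """One blink-reflex EMG component (R1 or R2) and its fade parameters.

    ``latency`` is the onset of the burst in ms; ``env_width`` the Gaussian
    envelope SD in ms; ``abolition_ce`` the effect-site concentration at
    which the component disappears; ``gamma`` the attenuation exponent of
    the fade law ``max(0, 1 - ce/abolition_ce)**gamma``.
    """

    name: str  # "R1" | "R2"
    latency_ms: float
    duration_ms: float
    center_freq_hz: float
    env_width_ms: float
    baseline_amp_uv: float
    abolition_ce: float
    gamma: float = 1.0

    def __post_init__(self) -> None:
        if self.name not in ("R1", "R2"):
            raise ValueError(f"component name must be R1 or R2, got {self.name!r}")
        if self.abolition_ce <= 0:
            raise ValueError("abolition_ce must be > 0")

    @property
    def envelope_center_ms(self) -> float:
        return self.latency_ms + ENVELOPE_CENTER_SDS * self.env_width_ms


# default burst geometry; amplitudes are per-profile
R1_DEFAULTS = dict(latency_ms=10.5, env_width_ms=1.5, center_freq_hz=150.0,
                   duration_ms=6.0)
R2_DEFAULTS = dict(latency_ms=32.0, env_width_ms=12.0, center_freq_hz=60.0,
                   duration_ms=48.0)


@dataclass(frozen=True)
class PatientProfile:
    """One simulated patient: demographics, thresholds, and noise settings.

    ``arass_fractions`` are five ascending fractions of ``ce_lorp``; sedation
    score -k is reached once Ce >= fractions[k-1] * ce_lorp.  The defaults
    (0.45, 0.62, 0.78, 0.92, 1.00) put the LOR2 threshold (34% of LORP at the
    population means) in the score-0 band and the LOR1 threshold (71%) in the
    score −2 band, reproducing the cohort's median scores at those endpoints.
    """

    demographics: Demographics
    ce_lor2: float
    ce_lor1: float
    ce_lorp: float
    arass_fractions: tuple[float, ...] = (0.45, 0.62, 0.78, 0.92, 1.00)
    noise_sd_uv: float = 2.0
    r1_amp_uv: float = 80.0
    r2_amp_uv: float = 50.0
    latency_jitter_ms: float = 0.3
    rng_seed: int | None = None

    def __post_init__(self) -> None:
        if not (0.0 < self.ce_lor2 < self.ce_lor1 < self.ce_lorp):
            raise ValueError(
                "thresholds must satisfy 0 < ce_lor2 < ce_lor1 < ce_lorp, got "
                f"({self.ce_lor2}, {self.ce_lor1}, {self.ce_lorp})"
            )
        f = self.arass_fractions
        if len(f) != 5 or any(b <= a for a, b in zip(f, f[1:])) or f[-1] != 1.0:
            raise ValueError("arass_fractions must be 5 strictly ascending values ending at 1.0")
        if self.noise_sd_uv < 0:
            raise ValueError("noise_sd_uv must be >= 0")

    @property
    def components(self) -> tuple[ReflexComponent, ReflexComponent]:
        """R1/R2 with abolition thresholds tied to the drawn LOR1/LOR2 Ce."""
        r1 = ReflexComponent(name="R1", baseline_amp_uv=self.r1_amp_uv,
                             abolition_ce=self.ce_lor1, **R1_DEFAULTS)
        r2 = ReflexComponent(name="R2", baseline_amp_uv=self.r2_amp_uv,
                             abolition_ce=self.ce_lor2, **R2_DEFAULTS)
        return (r1, r2)


@dataclass(frozen=True)
class Sweep:
    """One 200-ms, 10-kHz EMG trace evoked by one supraorbital stimulus."""

    stim_time_s: float  # negative = pre-infusion baseline
    fs_hz: float
    samples: np.ndarray  # µV
    true_ce: float

    def __post_init__(self) -> None:
        if len(self.samples) != int(round(self.fs_hz * SWEEP_DURATION_S)):
            raise ValueError(
                f"sweep must hold {self.fs_hz * SWEEP_DURATION_S:.0f} samples "
                f"({SWEEP_DURATION_S * 1e3:.0f} ms at {self.fs_hz:.0f} Hz), "
                f"got {len(self.samples)}"
            )
        if not np.all(np.isfinite(self.samples)):
            raise ValueError("sweep samples must be finite")


@dataclass(frozen=True)
class SedationRecord:
    time_s: float
    arass: int
    ce: float

    def __post_init__(self) -> None:
        if self.arass not in ARASS_LEVELS:
            raise ValueError(f"aRASS must be in {ARASS_LEVELS}, got {self.arass}")


@dataclass(frozen=True)
class EndpointTruth:
    """Generator ground truth: times (s) and Ce (µg/mL) at the endpoints."""

    lor2_time: float
    lor2_ce: float
    lor1_time: float
    lor1_ce: float
    lorp_time: float
    lorp_ce: float


@dataclass(frozen=True)
class SimulatedSession:
    profile: PatientProfile
    sweeps: tuple[Sweep, ...]
    sedation: tuple[SedationRecord, ...]
    truth: EndpointTruth
    trajectory: ConcentrationTrajectory

    def __post_init__(self) -> None:
        if not (self.truth.lor2_time < self.truth.lor1_time < self.truth.lorp_time):
            raise ValueError("truth endpoints must be ordered LOR2 < LOR1 < LORP")


# ---------------------------------------------------------------------------
# Population
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class PopulationConfig:
    """Cohort-level distributions for patient draws.

    Threshold and demographic means/SDs default to the studied cohort's
    summaries (Ce thresholds 1.45/2.99/4.22 ± 0.85/1.19/1.24 µg/mL; age
    61 ± 13 y, weight 72 ± 11 kg, height 162 ± 9 cm, 16/25 female).
    """

    ce_lor2_mean: float = 1.45
    ce_lor2_sd: float = 0.85
    ce_lor1_mean: float = 2.99
    ce_lor1_sd: float = 1.19
    ce_lorp_mean: float = 4.22
    ce_lorp_sd: float = 1.24
    age_mean: float = 61.0
    age_sd: float = 13.0
    weight_mean: float = 72.0
    weight_sd: float = 11.0
    height_mean: float = 162.0
    height_sd: float = 9.0
    p_female: float = 16 / 25
    noise_sd_uv: float = 2.0
    ce_floor: float = 0.1  # lower truncation of the threshold normals, µg/mL
    max_redraws: int = 1000
    #: "correlated" (default): a shared drug-sensitivity factor induces an
    #: equicorrelated Gaussian copula (``threshold_rho``) over the three
    #: truncated-normal thresholds.  The marginals match the cohort
    #: means/SDs exactly for any rho; rho = 1 is the comonotone limit where
    #: ordering holds by construction, smaller rho leaves residual
    #: between-threshold variability (ordering violations are redrawn).
    #: "independent": independent truncated normals, the whole triple
    #: redrawn until ordered (the heavy ordering-rejection then shifts the
    #: conditional means well away from the calibration).
    threshold_sampling: str = "correlated"
    threshold_rho: float = 0.9


DEFAULT_POPULATION = PopulationConfig()


def _truncated_normal(rng: np.random.Generator, mean: float, sd: float,
                      low: float, high: float = math.inf,
                      max_redraws: int = 1000) -> float:
    if sd == 0.0:
        if not (low <= mean <= high):
            raise ValueError(f"degenerate draw: mean {mean} outside [{low}, {high}] with sd 0")
        return mean
    for _ in range(max_redraws):
        x = rng.normal(mean, sd)
        if low <= x <= high:
            return float(x)
    raise ValueError(
        f"exceeded {max_redraws} redraws sampling N({mean},{sd}) in [{low}, {high}]")


def _threshold_quantile(u: float, mean: float, sd: float, floor: float) -> float:
    """Quantile of a normal truncated below at ``floor``."""
    if sd == 0.0:
        if mean < floor:
            raise ValueError(f"degenerate threshold: mean {mean} below floor {floor}")
        return mean
    a = (floor - mean) / sd
    u = min(max(u, 1e-12), 1.0 - 1e-12)  # guard against ppf(0)/ppf(1)
    return float(_stats.truncnorm.ppf(u, a, np.inf, loc=mean, scale=sd))


def draw_patient(rng: np.random.Generator,
                 population: PopulationConfig = DEFAULT_POPULATION) -> PatientProfile:
    """Draw one patient from the population.

    Each Ce threshold is marginally a normal truncated below at ``ce_floor``
    with the configured cohort mean/SD.  In the default ``comonotone`` mode
    a single latent sensitivity quantile per patient drives all three
    thresholds (a patient sensitive to propofol loses R2, R1 and
    responsiveness all at low concentrations), which keeps the cohort
    marginal means/SDs exactly at their calibrated values while guaranteeing
    LOR2 < LOR1 < LORP.  The ``independent`` mode draws the three thresholds
    independently and redraws the whole triple until strictly ordered; the
    ordering rejection then shifts the conditional means away from the
    calibration (documented behaviour, kept for reference).  Demographics
    come from truncated normals with the cohort means/SDs.

    Raises
    ------
    ValueError
        If an ordered triple is not obtained within ``max_redraws`` draws
        (degenerate population configuration).
    """
    p = population
    if p.threshold_sampling == "correlated":
        if not 0.0 <= p.threshold_rho <= 1.0:
            raise ValueError("threshold_rho must be in [0, 1]")
        r = math.sqrt(p.threshold_rho)
        s = math.sqrt(1.0 - p.threshold_rho)
        for _ in range(p.max_redraws):
            z0 = rng.normal()
            us = [float(_stats.norm.cdf(r * z0 + s * rng.normal()))
                  for _ in range(3)]
            lor2 = _threshold_quantile(us[0], p.ce_lor2_mean, p.ce_lor2_sd, p.ce_floor)
            lor1 = _threshold_quantile(us[1], p.ce_lor1_mean, p.ce_lor1_sd, p.ce_floor)
            lorp = _threshold_quantile(us[2], p.ce_lorp_mean, p.ce_lorp_sd, p.ce_floor)
            if lor2 < lor1 < lorp:
                break
        else:
            raise ValueError(
                f"could not draw an ordered threshold triple in {p.max_redraws} "
                "attempts; population means/SDs are inconsistent with "
                "LOR2 < LOR1 < LORP"
            )
    elif p.threshold_sampling == "independent":
        for _ in range(p.max_redraws):
            lor2 = _truncated_normal(rng, p.ce_lor2_mean, p.ce_lor2_sd, p.ce_floor)
            lor1 = _truncated_normal(rng, p.ce_lor1_mean, p.ce_lor1_sd, p.ce_floor)
            lorp = _truncated_normal(rng, p.ce_lorp_mean, p.ce_lorp_sd, p.ce_floor)
            if lor2 < lor1 < lorp:
                break
        else:
            raise ValueError(
                f"could not draw an ordered threshold triple in {p.max_redraws} "
                "attempts; population means/SDs are inconsistent with "
                "LOR2 < LOR1 < LORP"
            )
    else:
        raise ValueError(
            f"unknown threshold_sampling mode {p.threshold_sampling!r}")
    # upper age clip keeps the age-adjusted V2 of the PK model positive
    age = _truncated_normal(rng, p.age_mean, p.age_sd, 18.0, 100.0)
    weight = _truncated_normal(rng, p.weight_mean, p.weight_sd, 35.0)
    height = _truncated_normal(rng, p.height_mean, p.height_sd, 120.0)
    sex = "female" if rng.random() < p.p_female else "male"
    demo = Demographics(age=age, weight=weight, height=height, sex=sex)
    return PatientProfile(
        demographics=demo, ce_lor2=lor2, ce_lor1=lor1, ce_lorp=lorp,
        noise_sd_uv=p.noise_sd_uv,
    )


# ---------------------------------------------------------------------------
# Sweep synthesis
# ---------------------------------------------------------------------------

def component_scale(component: ReflexComponent, ce: float) -> float:
    """Amplitude attenuation of a component at effect-site concentration ``ce``.

    Linear fade by default (gamma = 1): exactly 1 at ce = 0 and exactly 0 at
    and above the abolition threshold.
    """
    if ce < 0:
        raise ValueError("ce must be >= 0")
    base = 1.0 - ce / component.abolition_ce
    if base <= 0.0:
        return 0.0
    return base ** component.gamma


_HP_SOS = None


def _highpass_sos(fs_hz: float):
    global _HP_SOS
    if _HP_SOS is None or _HP_SOS[0] != fs_hz:
        sos = signal.butter(4, HIGHPASS_HZ, btype="highpass", fs=fs_hz, output="sos")
        _HP_SOS = (fs_hz, sos)
    return _HP_SOS[1]


def _burst(t_ms: np.ndarray, component: ReflexComponent, scale: float,
           jitter_ms: float) -> np.ndarray:
    center = component.envelope_center_ms + jitter_ms
    env = np.exp(-0.5 * ((t_ms - center) / component.env_width_ms) ** 2)
    carrier = np.cos(2.0 * np.pi * component.center_freq_hz * (t_ms - center) * 1e-3)
    return scale * component.baseline_amp_uv * env * carrier


def synth_sweep(profile: PatientProfile, ce: float, rng: np.random.Generator,
                stim_time_s: float = 0.0) -> Sweep:
    """Synthesize one sweep at the given effect-site concentration.

    20-Hz high-passed (4th-order Butterworth, zero-phase) white Gaussian
    noise plus the attenuated R1/R2 bursts, each with a small random latency
    jitter.
    """
    t_ms = np.arange(SWEEP_SAMPLES) / SWEEP_FS_HZ * 1e3
    samples = np.zeros(SWEEP_SAMPLES)
    for comp in profile.components:
        jitter = (rng.normal(0.0, profile.latency_jitter_ms)
                  if profile.latency_jitter_ms > 0 else 0.0)
        scale = component_scale(comp, ce)
        if scale > 0.0:
            samples += _burst(t_ms, comp, scale, jitter)
    if profile.noise_sd_uv > 0:
        noise = rng.normal(0.0, profile.noise_sd_uv, SWEEP_SAMPLES)
        samples += signal.sosfiltfilt(_highpass_sos(SWEEP_FS_HZ), noise)
    return Sweep(stim_time_s=stim_time_s, fs_hz=SWEEP_FS_HZ,
                 samples=samples, true_ce=ce)


# ---------------------------------------------------------------------------
# aRASS staircase and session assembly
# ---------------------------------------------------------------------------

def arass_at(profile: PatientProfile, ce: float) -> int:
    """Sedation score at concentration ``ce``: the staircase over the
    per-patient fractions of ce_lorp; −5 exactly when ce >= ce_lorp."""
    if ce < 0:
        raise ValueError("ce must be >= 0")
    score = 0
    for k, frac in enumerate(profile.arass_fractions, start=1):
        if ce >= frac * profile.ce_lorp:
            score = -k
    return score


def simulate_session(profile: PatientProfile, rng: np.random.Generator,
                     dt_s: float = 0.1, horizon_s: float = 3600.0,
                     ke0_per_min: float | None = None) -> SimulatedSession:
    """Run one full induction: PK trajectory, sweeps, sedation, and truth.

    Stimulation and sedation assessment share a 6-s cadence, starting with
    four drug-free baseline sweeps before t = 0; the infusion runs from t = 0
    and is stopped at the first aRASS = −5 record, which ends the session.

    Raises
    ------
    RuntimeError
        If Ce never reaches the patient's LORP threshold within ``horizon_s``.
    """
    kwargs = {} if ke0_per_min is None else {"ke0_per_min": ke0_per_min}
    model = schnider_parameters(profile.demographics, **kwargs)
    t_start = -N_BASELINE_SWEEPS * STIM_INTERVAL_S

    # most inductions finish well inside 400 s; integrate a short trajectory
    # first and extend to the full horizon only when the threshold is unmet
    t_lorp = None
    for h in sorted({min(horizon_s, 400.0), horizon_s}):
        schedule = protocol_infusion(profile.demographics, stop_time_s=h)
        traj = simulate_infusion(model, schedule, dt_s=dt_s, t_end_s=h,
                                 t_start_s=t_start)
        t = 0.0  # first 6-s stimulus instant at which the staircase hits −5
        while t <= h:
            if arass_at(profile, traj.ce_at(t)) == -5:
                t_lorp = t
                break
            t += STIM_INTERVAL_S
        if t_lorp is not None:
            break
    if t_lorp is None:
        raise RuntimeError(
            f"Ce never reached the LORP threshold {profile.ce_lorp:.2f} µg/mL "
            f"within {horizon_s:.0f} s"
        )

    # truncate the trajectory at the stop (post-LORP kinetics are unused)
    keep = traj.times <= t_lorp + 1e-9
    traj = ConcentrationTrajectory(times=traj.times[keep], cp=traj.cp[keep],
                                   ce=traj.ce[keep])

    sweeps: list[Sweep] = []
    sedation: list[SedationRecord] = []
    t = t_start
    while t <= t_lorp + 1e-9:
        ce = traj.ce_at(t) if t >= 0 else 0.0
        sweeps.append(synth_sweep(profile, ce, rng, stim_time_s=t))
        sedation.append(SedationRecord(time_s=t, arass=arass_at(profile, ce), ce=ce))
        t += STIM_INTERVAL_S

    lor2_t = traj.first_crossing(profile.ce_lor2)
    lor1_t = traj.first_crossing(profile.ce_lor1)
    truth = EndpointTruth(
        lor2_time=lor2_t, lor2_ce=profile.ce_lor2,
        lor1_time=lor1_t, lor1_ce=profile.ce_lor1,
        lorp_time=t_lorp, lorp_ce=profile.ce_lorp,
    )
    return SimulatedSession(profile=profile, sweeps=tuple(sweeps),
                            sedation=tuple(sedation), truth=truth,
                            trajectory=traj)


def session_rng(master_seed: int, patient_index: int) -> np.random.Generator:
    """Per-patient RNG stream: independent of how many patients are drawn."""
    return np.random.default_rng(np.random.SeedSequence((master_seed, patient_index)))
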