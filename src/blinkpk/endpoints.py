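"""Detection of LOR2, LOR1 and LORP, and Table-style cohort summaries.

Component presence replaces expert marking with an automatic amplitude
criterion: a component is present in its analysis window (T1 for R1, T2 for
R2) when the window's peak absolute amplitude exceeds the 0-9 ms pre-reflex
baseline mean plus k baseline SDs, measured on the same 4-sweep average.

The default k = 6 is calibrated by extreme-value statistics: the expected
peak of 1750 white-noise samples (the T2 window) is about 4 SDs, so a
threshold must sit well above that to keep the per-window false-alarm
probability small (~1e-3 at k = 6) while a burst only a few times the noise
SD still stands far above it.

The component vanishes between two successive stimuli, never exactly at one,
so endpoint time and Ce are interval-censored at the 6-s cadence.  Each LOR
endpoint is reported at the midpoint of the bracketing stimulus pair (last
seen, first absent), which is mean-unbiased under a locally linear Ce rise;
LORP is likewise the midpoint between the last responsive record and the
first aRASS = −5 record.  The raw last-seen values are kept on the record.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
from scipy import stats as _stats

from .preprocess import extract_windows, sliding_averages
from .synth import STIM_INTERVAL_S, SimulatedSession, Sweep

__all__ = [
    "EndpointRecord",
    "CohortSummary",
    "component_present",
    "detect_endpoints",
    "summarize_cohort",
    "DEFAULT_PRESENCE_K",
]

DEFAULT_PRESENCE_K = 6.0
BASELINE_SPAN_MS = (0.0, 9.0)  # pre-R1 segment of the same averaged sweep
_ZERO_BASELINE_FLOOR_UV = 1e-9


@dataclass(frozen=True)
class EndpointRecord:
    """Detected endpoints for one session (times s, Ce µg/mL)."""

    patient_id: str
    lor2_time: float
    lor1_time: float
    lorp_time: float
    lor2_ce: float
    lor1_ce: float
    lorp_ce: float
    arass_at_lor2: int
    arass_at_lor1: int
    # raw (uncorrected) last-seen stimulus values
    lor2_last_seen_time: float
    lor1_last_seen_time: float

    def __post_init__(self) -> None:
        if not (self.lor2_time <= self.lor1_time <= self.lorp_time):
            raise ValueError(
                "detected endpoints out of order: "
                f"LOR2 {self.lor2_time} s, LOR1 {self.lor1_time} s, "
                f"LORP {self.lorp_time} s"
            )


@dataclass(frozen=True)
class CohortSummary:
    n: int
    time_mean_sd: dict[str, tuple[float, float]]  # endpoint -> (mean, sd), s
    ce_mean_sd: dict[str, tuple[float, float]]  # endpoint -> (mean, sd), µg/mL
    arass_median_range: dict[str, tuple[int, int, int]]  # (median, min, max)
    ce_lorp_minus_lor1_mean: float
    paired_tests: dict[str, tuple[str, float, float]]  # name -> (test, stat, p)
    degenerate: tuple[str, ...] = ()

    def to_text(self) -> str:
        lines = [f"Cohort summary (n = {self.n})", ""]
        lines.append(f"{'':14s}{'LOR2':>18s}{'LOR1':>18s}{'LORP':>18s}")
        t = self.time_mean_sd
        lines.append("Time (s)      " + "".join(
            f"{t[e][0]:9.2f} ± {t[e][1]:5.2f} " for e in ("LOR2", "LOR1", "LORP")))
        c = self.ce_mean_sd
        lines.append("Ce (µg/mL)    " + "".join(
            f"{c[e][0]:9.2f} ± {c[e][1]:5.2f} " for e in ("LOR2", "LOR1", "LORP")))
        a = self.arass_median_range
        lines.append("aRASS         " + "".join(
            f"{a[e][0]:6d} [{a[e][1]}, {a[e][2]}]   " for e in ("LOR2", "LOR1"))
            + f"{-5:6d}")
        lines.append("")
        lines.append(f"Mean Ce(LORP) − Ce(LOR1): {self.ce_lorp_minus_lor1_mean:.2f} µg/mL")
        for name, (test, stat, p) in self.paired_tests.items():
            lines.append(f"{name}: {test} statistic = {stat:.3f}, p = {p:.3g}")
        for name in self.degenerate:
            lines.append(f"{name}: degenerate (zero variance), test skipped")
        return "\n".join(lines)


def component_present(averaged_sweep: Sweep, window_id: str,
                      k: float = DEFAULT_PRESENCE_K) -> bool:
    """Automatic presence criterion for R1 (T1 window) or R2 (T2 window).

    True iff the window's max |amplitude| exceeds
    ``mean(baseline) + k * SD(baseline)`` where the baseline is the 0-9 ms
    pre-reflex segment of the same averaged sweep.  A zero-variance
    (noise-free) baseline falls back to an absolute floor just above the
    baseline's own peak.
    """
    fs = averaged_sweep.fs_hz
    i0 = int(round(BASELINE_SPAN_MS[0] * fs / 1e3))
    i1 = int(round(BASELINE_SPAN_MS[1] * fs / 1e3))
    baseline = averaged_sweep.samples[i0:i1]
    if not np.all(np.isfinite(baseline)):
        raise ValueError("non-finite baseline segment")
    t1, t2 = extract_windows(averaged_sweep)
    window = {"T1": t1, "T2": t2}[window_id]
    peak = float(np.abs(window.samples).max())
    sd = float(baseline.std())
    if sd == 0.0:
        return peak > float(np.abs(baseline).max()) + _ZERO_BASELINE_FLOOR_UV
    return peak > float(baseline.mean()) + k * sd


def _interval_midpoint(sweeps, i_last: int):
    """Midpoint time/Ce of the (last-seen, first-absent) stimulus pair."""
    s0 = sweeps[i_last]
    if i_last + 1 < len(sweeps):
        s1 = sweeps[i_last + 1]
        return (0.5 * (s0.stim_time_s + s1.stim_time_s),
                0.5 * (s0.true_ce + s1.true_ce))
    return s0.stim_time_s, s0.true_ce


def _last_present_index(present: list[bool], confirm_run: int = 4) -> int | None:
    """Index of the last genuine presence in a presence/absence sequence.

    The fade of a component is monotone, so absence is confirmed by the
    first run of ``confirm_run`` consecutive absent averages (a run cut
    short by the end of the session also counts).  Isolated presences after
    a confirmed absence are noise and are ignored.
    """
    n = len(present)
    for j in range(n):
        if present[j]:
            continue
        if not any(present[j:j + confirm_run]):
            earlier = [i for i in range(j) if present[i]]
            return max(earlier) if earlier else None
    return max((i for i in range(n) if present[i]), default=None)


def detect_endpoints(session: SimulatedSession, k: float = DEFAULT_PRESENCE_K,
                     patient_id: str = "patient") -> EndpointRecord:
    """Detect LOR2/LOR1 from the sweep train and LORP from the sedation trace.

    Presence is evaluated on the raw sliding 4-sweep averages (no global
    conditioning; see above).  When the average after the last present one
    is absent, the only constituent that can still carry the component is
    the oldest, so the last-seen individual stimulus is the oldest
    constituent of the last present average; the reported endpoint is the
    midpoint of that stimulus and the next (see module docstring).

    Raises
    ------
    ValueError
        If a component is not detected at baseline, or the sedation trace
        never reaches −5.
    """
    return detect_endpoints_parts(session.sweeps, session.sedation, k=k,
                                  patient_id=patient_id)


def detect_endpoints_parts(sweeps, sedation, k: float = DEFAULT_PRESENCE_K,
                           patient_id: str = "patient") -> EndpointRecord:
    """Endpoint detection on raw (sweeps, sedation) parts; see detect_endpoints."""
    if len(sweeps) < 4:
        raise ValueError("need at least 4 sweeps")
    # raw averages: global detrending spreads a sliver of burst energy over
    # the whole record, which would masquerade as late R2 presence
    averages = sliding_averages(sweeps, condition=False)

    last_present = {}
    for comp, window_id in (("R1", "T1"), ("R2", "T2")):
        present = [component_present(avg, window_id, k=k) for _, avg in averages]
        if not present[0]:
            raise ValueError(
                f"no baseline reflex: component {comp} not detected in the "
                "first averaged record"
            )
        last_present[comp] = _last_present_index(present)

    lorp_idx = next((i for i, rec in enumerate(sedation) if rec.arass == -5), None)
    if lorp_idx is None:
        raise ValueError("sedation trace never reaches aRASS = -5")
    if lorp_idx > 0:
        prev = sedation[lorp_idx - 1]
        lorp_time = 0.5 * (prev.time_s + sedation[lorp_idx].time_s)
        lorp_ce = 0.5 * (prev.ce + sedation[lorp_idx].ce)
    else:
        lorp_time = sedation[lorp_idx].time_s
        lorp_ce = sedation[lorp_idx].ce

    out = {}
    for comp in ("R1", "R2"):
        # averages[pos] covers sweeps pos..pos+3, so the oldest constituent
        # of the last present average is the position index itself
        i_seen = last_present[comp]
        t_mid, ce_mid = _interval_midpoint(sweeps, i_seen)
        out[comp] = (t_mid, ce_mid, i_seen)

    lor1_t, lor1_ce, i1_seen = out["R1"]
    lor2_t, lor2_ce, i2_seen = out["R2"]
    return EndpointRecord(
        patient_id=patient_id,
        lor2_time=lor2_t, lor1_time=lor1_t, lorp_time=lorp_time,
        lor2_ce=lor2_ce, lor1_ce=lor1_ce, lorp_ce=lorp_ce,
        arass_at_lor2=sedation[i2_seen].arass,
        arass_at_lor1=sedation[i1_seen].arass,
        lor2_last_seen_time=sweeps[i2_seen].stim_time_s,
        lor1_last_seen_time=sweeps[i1_seen].stim_time_s,
    )


def _paired(name: str, a: np.ndarray, b: np.ndarray,
            tests: dict, degenerate: list) -> None:
    diff = a - b
    if np.ptp(diff) == 0:
        degenerate.append(name)
        return
    # normality pre-test on the paired differences picks the test
    p_norm = _stats.kstest(diff, "norm", args=(diff.mean(), diff.std(ddof=1))).pvalue
    if p_norm > 0.05:
        stat, p = _stats.ttest_rel(a, b)
        tests[name] = ("paired t", float(stat), float(p))
    else:
        stat, p = _stats.wilcoxon(a, b)
        tests[name] = ("Wilcoxon signed-rank", float(stat), float(p))


def summarize_cohort(records: list[EndpointRecord]) -> CohortSummary:
    """Mean ± SD of endpoint times/Ce, median [min, max] aRASS, paired tests.

    Compares Ce at LORP vs LOR1 and the three endpoint times pairwise,
    choosing paired t vs Wilcoxon signed-rank by a normality pre-test on
    the differences.  Identical-value (zero-variance) comparisons are
    flagged as degenerate, not crashed.
    """
    if len(records) < 3:
        raise ValueError("need at least 3 records to summarize")
    times = {e: np.array([getattr(r, f"{e.lower()}_time") for r in records])
             for e in ("LOR2", "LOR1", "LORP")}
    ces = {e: np.array([getattr(r, f"{e.lower()}_ce") for r in records])
           for e in ("LOR2", "LOR1", "LORP")}
    ar = {
        "LOR2": [r.arass_at_lor2 for r in records],
        "LOR1": [r.arass_at_lor1 for r in records],
    }
    tests: dict = {}
    degenerate: list = []
    _paired("Ce LORP vs LOR1", ces["LORP"], ces["LOR1"], tests, degenerate)
    _paired("time LOR1 vs LOR2", times["LOR1"], times["LOR2"], tests, degenerate)
    _paired("time LORP vs LOR1", times["LORP"], times["LOR1"], tests, degenerate)
    _paired("time LORP vs LOR2", times["LORP"], times["LOR2"], tests, degenerate)
    return CohortSummary(
        n=len(records),
        time_mean_sd={e: (float(v.mean()), float(v.std(ddof=1)))
                      for e, v in times.items()},
        ce_mean_sd={e: (float(v.mean()), float(v.std(ddof=1)))
                    for e, v in ces.items()},
        arass_median_range={e: (int(np.median(v)), int(min(v)), int(max(v)))
                            for e, v in ar.items()},
        ce_lorp_minus_lor1_mean=float((ces["LORP"] - ces["LOR1"]).mean()),
        paired_tests=tests,
        degenerate=tuple(degenerate),
    )
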