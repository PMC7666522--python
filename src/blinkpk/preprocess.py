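"""Sweep conditioning and T1/T2 analysis-window extraction.

The fixed conditioning order is: DC removal -> linear detrend -> (4-sweep
average) -> window extraction -> rectify/normalize, where the last step
applies only to the time-domain branch; spectral features are computed on
the detrended, un-rectified window.

Windows are half-open in milliseconds with 0-based sample indices:
T1 = [10, 25) ms (samples 100..249 at 10 kHz, where the early R1 component
is expected) and T2 = [25, 200) ms (samples 250..1999, where the late R2
component is expected).  The 25-ms boundary sample belongs to T2.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np
from scipy import signal as _signal

from .synth import SWEEP_FS_HZ, SWEEP_SAMPLES, Sweep

__all__ = [
    "AnalysisWindow",
    "T1_SPAN_MS",
    "T2_SPAN_MS",
    "remove_dc",
    "detrend_linear",
    "average_sweeps",
    "extract_windows",
    "rectify_normalize",
    "sliding_averages",
]

T1_SPAN_MS = (10.0, 25.0)
T2_SPAN_MS = (25.0, 200.0)


@dataclass(frozen=True)
class AnalysisWindow:
    """A T1 or T2 segment of one (averaged) sweep."""

    window_id: str  # "T1" | "T2"
    t_start_ms: float
    t_end_ms: float
    samples: np.ndarray
    fs_hz: float

    def __post_init__(self) -> None:
        if self.window_id not in ("T1", "T2"):
            raise ValueError(f"window_id must be T1 or T2, got {self.window_id!r}")
        expected = int(round((self.t_end_ms - self.t_start_ms) * self.fs_hz / 1e3))
        if len(self.samples) != expected:
            raise ValueError(
                f"{self.window_id} spans {self.t_start_ms}-{self.t_end_ms} ms and "
                f"must hold {expected} samples, got {len(self.samples)}"
            )
        if not np.all(np.isfinite(self.samples)):
            raise ValueError("window samples must be finite")


def remove_dc(sweep: Sweep) -> Sweep:
    """Subtract the mean amplitude."""
    if len(sweep.samples) == 0:
        raise ValueError("empty sweep")
    return replace(sweep, samples=sweep.samples - sweep.samples.mean())


def detrend_linear(sweep: Sweep) -> Sweep:
    """Remove the least-squares straight-line fit."""
    if len(sweep.samples) < 2:
        raise ValueError("need >= 2 samples to detrend")
    return replace(sweep, samples=_signal.detrend(sweep.samples, type="linear"))


def average_sweeps(sweeps: list[Sweep] | tuple[Sweep, ...]) -> Sweep:
    """Pointwise mean of exactly 4 sweeps.

    The averaged record carries the stimulus time of the last constituent
    and the mean of the four effect-site concentrations.
    """
    if len(sweeps) != 4:
        raise ValueError(f"averaging requires exactly 4 sweeps, got {len(sweeps)}")
    fs = sweeps[0].fs_hz
    n = len(sweeps[0].samples)
    for s in sweeps[1:]:
        if s.fs_hz != fs or len(s.samples) != n:
            raise ValueError("sweeps must share sampling rate and length")
    mean = np.mean([s.samples for s in sweeps], axis=0)
    return Sweep(
        stim_time_s=sweeps[-1].stim_time_s,
        fs_hz=fs,
        samples=mean,
        true_ce=float(np.mean([s.true_ce for s in sweeps])),
    )


def extract_windows(sweep: Sweep) -> tuple[AnalysisWindow, AnalysisWindow]:
    """Split a conditioned sweep into its T1 and T2 analysis windows."""
    if sweep.fs_hz != SWEEP_FS_HZ or len(sweep.samples) != SWEEP_SAMPLES:
        raise ValueError(
            f"expected a {SWEEP_SAMPLES}-sample sweep at {SWEEP_FS_HZ:.0f} Hz, got "
            f"{len(sweep.samples)} at {sweep.fs_hz:.0f} Hz"
        )

    def _cut(window_id, span):
        i0 = int(round(span[0] * sweep.fs_hz / 1e3))
        i1 = int(round(span[1] * sweep.fs_hz / 1e3))
        return AnalysisWindow(window_id=window_id, t_start_ms=span[0],
                              t_end_ms=span[1], samples=sweep.samples[i0:i1],
                              fs_hz=sweep.fs_hz)

    return _cut("T1", T1_SPAN_MS), _cut("T2", T2_SPAN_MS)


def rectify_normalize(window: AnalysisWindow) -> AnalysisWindow:
    """Full-wave rectify and scale to a maximum of exactly 1.

    Raises
    ------
    ValueError
        On an all-zero ("silent") window; the caller decides how to handle
        an absent component.
    """
    rect = np.abs(window.samples)
    peak = rect.max()
    if peak == 0.0:
        raise ValueError(f"silent window {window.window_id}: all samples are zero")
    return replace(window, samples=rect / peak)


def sliding_averages(sweeps: list[Sweep] | tuple[Sweep, ...],
                     condition: bool = True) -> list[tuple[int, Sweep]]:
    """Sliding 4-sweep averages, one per stimulus from the 4th onward.

    Each element is ``(last_constituent_index, averaged_sweep)``.  When
    ``condition`` is true each constituent is DC-removed and detrended
    before averaging.
    """
    prepared = [detrend_linear(remove_dc(s)) if condition else s for s in sweeps]
    out = []
    for j in range(3, len(prepared)):
        out.append((j, average_sweeps(prepared[j - 3:j + 1])))
    return out
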