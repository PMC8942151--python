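"""Retrospective cardiorespiratory gating.

Models the acquisition scheme in which the ECG R wave triggers an assisted
breath through a square signal of duration ``T`` (R-wave detection is
disabled while the square signal is high), so that each respiratory cycle
spans a whole number of heartbeats ``n_ECG``.  Continuously acquired
projections, each characterized by an angle alpha = omega * (t - t0) and a
phase time t* = t - t_j (time since the start of its respiratory cycle), are
then sorted retrospectively into phase bins of width ``Delta_t``.

With the experimental values T = 0.75 s, T_ECG = 0.39 s this gives
n_ECG = 2 heartbeats per cycle, a 0.78 s nominal cycle, and 78 bins at
Delta_t = 10 ms.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd


@dataclass
class GatingConfig:
    """Acquisition timing parameters.

    T : trigger square-signal duration, s (R-wave detection disabled while high)
    Delta_t : phase-bin width, s
    omega : rotation speed, degrees/s
    t0 : rotation start time, s
    duty_cycle : ventilator square-signal duty cycle (metadata only)
    """

    T: float = 0.75
    Delta_t: float = 0.010
    omega: float = 0.34
    t0: float = 0.0
    duty_cycle: float = 0.5

    def __post_init__(self) -> None:
        if self.T <= 0:
            raise ValueError("T must be > 0")
        if self.Delta_t <= 0:
            raise ValueError("Delta_t must be > 0")
        if self.omega < 0:
            raise ValueError("omega must be >= 0")


@dataclass
class EcgStream:
    """Sorted R-wave detection times in seconds."""

    r_wave_times: np.ndarray

    def __post_init__(self) -> None:
        self.r_wave_times = np.asarray(self.r_wave_times, dtype=float)
        if self.r_wave_times.size == 0:
            raise ValueError("empty ECG stream")
        if np.any(np.diff(self.r_wave_times) <= 0):
            raise ValueError("R-wave times must be strictly increasing")

    @classmethod
    def periodic(cls, period: float, n_beats: int, start: float = 0.0,
                 jitter: float = 0.0, seed: int | None = None) -> "EcgStream":
        """Synthesize a (possibly jittered) periodic R-wave stream."""
        if jitter > 0:
            rng = np.random.default_rng(seed)
            intervals = rng.normal(period, jitter, n_beats - 1)
            times = start + np.concatenate([[0.0], np.cumsum(intervals)])
        else:
            times = start + period * np.arange(n_beats)
        return cls(times)


@dataclass
class ProjectionTable:
    """Phase-sorted projections plus binning metadata."""

    records: pd.DataFrame  # columns: t, alpha, cycle, t_star, bin (bin = -1 if unassigned)
    n_bins: int
    n_bins_nominal: int
    bin_counts: np.ndarray
    n_unassigned: int


def simulate_triggers(ecg: EcgStream, cfg: GatingConfig) -> np.ndarray:
    """Breath-start times under the square-signal trigger-disable logic.

    The first R wave triggers; any R wave within ``(trigger, trigger + T]``
    is ignored; the next R wave strictly after the window triggers again.
    """
    triggers = []
    disabled_until = -np.inf
    for t in ecg.r_wave_times:
        if t > disabled_until:
            triggers.append(t)
            disabled_until = t + cfg.T
    return np.asarray(triggers)


def n_ecg(ecg: EcgStream, cfg: GatingConfig) -> int:
    """Whole heartbeats per triggered respiratory cycle (mode over cycles)."""
    triggers = simulate_triggers(ecg, cfg)
    if triggers.size < 2:
        raise ValueError("need at least two triggers to count beats per cycle")
    counts = np.searchsorted(ecg.r_wave_times, triggers[1:], side="left") - \
        np.searchsorted(ecg.r_wave_times, triggers[:-1], side="left")
    vals, freq = np.unique(counts, return_counts=True)
    return int(vals[np.argmax(freq)])


def assign_phase(
    projection_times: np.ndarray,
    angles: np.ndarray | None,
    triggers: np.ndarray,
    cfg: GatingConfig,
) -> ProjectionTable:
    """Assign each projection to (cycle, phase bin).

    Each projection acquired at time t inside cycle j gets
    t* = t - t_j and bin = floor(t*/Delta_t); the boundary t = t_j is
    assigned to cycle j, bin 0 (half-open convention, no projection lost).
    Projections before the first trigger, or later than the last trigger
    plus the longest observed cycle, are flagged unassigned (bin = -1)
    rather than dropped.
    """
    t = np.asarray(projection_times, dtype=float)
    triggers = np.asarray(triggers, dtype=float)
    if triggers.size == 0:
        raise ValueError("no triggers supplied")
    if angles is None:
        angles = cfg.omega * (t - cfg.t0)
    alpha = np.asarray(angles, dtype=float)

    durations = np.diff(triggers)
    if durations.size:
        max_cycle = float(durations.max())
        mean_cycle = float(durations.mean())
    else:
        max_cycle = mean_cycle = np.inf
    # half-open bins: t == trigger maps to that cycle, bin 0
    cycle = np.searchsorted(triggers, t, side="right") - 1
    unassigned = cycle < 0
    cycle_c = np.clip(cycle, 0, triggers.size - 1)
    t_star = t - triggers[cycle_c]
    # past the end of the recording: beyond last trigger + longest cycle
    if np.isfinite(max_cycle):
        unassigned |= (cycle_c == triggers.size - 1) & (t_star >= max_cycle)
    bins = np.floor(t_star / cfg.Delta_t).astype(int)
    bins[unassigned] = -1
    t_star = np.where(unassigned, np.nan, t_star)

    eps = 1e-9  # guard against float fuzz at exact multiples of Delta_t
    n_bins = int(np.ceil(max_cycle / cfg.Delta_t - eps)) if np.isfinite(max_cycle) else 0
    n_bins_nominal = int(np.ceil(mean_cycle / cfg.Delta_t - eps)) if np.isfinite(mean_cycle) else 0

    records = pd.DataFrame(
        {"t": t, "alpha": alpha, "cycle": np.where(unassigned, -1, cycle_c),
         "t_star": t_star, "bin": bins}
    )
    n_total_bins = max(n_bins, int(bins.max()) + 1 if bins.size else 0)
    bin_counts = np.bincount(bins[bins >= 0], minlength=max(n_total_bins, 1))
    return ProjectionTable(records, n_bins, n_bins_nominal, bin_counts,
                           int(np.count_nonzero(unassigned)))


def scan_summary(
    cfg: GatingConfig,
    ecg: EcgStream,
    n_projections: int | None = None,
    integration_time: float | None = None,
) -> dict:
    """Timing summary of a half-rotation scan.

    Reports the 180-degree scan duration, the expected number of respiratory
    cycles (duration / mean cycle length, also rounded to the nearest
    hundred), and the mean angular sampling density per phase bin.
    """
    if cfg.omega <= 0:
        raise ValueError("omega must be > 0 for a scan summary")
    duration = 180.0 / cfg.omega
    triggers = simulate_triggers(ecg, cfg)
    if triggers.size >= 2:
        mean_cycle = float(np.diff(triggers).mean())
    else:
        mean_cycle = cfg.T
    n_cycles = duration / mean_cycle
    summary = {
        "duration_s": duration,
        "duration_min": round(duration / 60.0, 1),
        "mean_cycle_s": mean_cycle,
        "n_cycles": n_cycles,
        "n_cycles_nearest_hundred": int(round(n_cycles / 100.0) * 100),
        "n_bins_nominal": int(np.ceil(mean_cycle / cfg.Delta_t - 1e-9)),
    }
    if n_projections is not None:
        n_bins = summary["n_bins_nominal"]
        summary["projections_per_bin"] = n_projections / n_bins
        summary["angular_step_per_bin_deg"] = duration * cfg.omega / (n_projections / n_bins)
    if integration_time is not None:
        summary["angular_blur_deg"] = cfg.omega * integration_time
    return summary
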