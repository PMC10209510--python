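"""Spike rasters, analysis epochs, windowed firing rates, and PSTHs.

The canonical analysis windows are 500 ms long: the movement ("move")
window starts 200 ms after the Go cue, the planning ("plan") window
200 ms after the delay-screen onset, the cue window 200 ms after cue
onset, and the ITI window is the last 500 ms of the inter-trial
interval.  Firing rates are spike counts divided by the window duration,
with windows half-open ``[start, end)`` so abutting windows never double
count a spike.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .datasets import SessionData, TrialDataset
from .errors import ConfigError, DataError

#: phase order for each task variant
PHASES = {
    "delay_task": ("iti", "cue", "delay", "go"),
    "reaction_task": ("iti", "cue", "go"),
}


@dataclass(frozen=True)
class EpochWindow:
    """A window anchored to a trial phase onset.

    ``anchor`` is a phase name (or ``"start"`` for absolute trial time);
    the window covers ``[onset + start_offset, onset + start_offset +
    duration)``.
    """

    anchor: str
    start_offset: float
    duration: float

    def __post_init__(self) -> None:
        if self.duration <= 0:
            raise ConfigError(f"window duration must be > 0, got {self.duration}")

    def bounds(self, onsets: pd.Series | dict) -> tuple[float, float]:
        if self.anchor == "start":
            t0 = 0.0
        else:
            try:
                t0 = float(onsets[self.anchor])
            except KeyError:
                raise DataError(f"trial lacks phase onset {self.anchor!r}") from None
        start = t0 + self.start_offset
        return start, start + self.duration

    def describe(self) -> str:
        return (
            f"{self.anchor}{self.start_offset:+.3f}s"
            f"+{self.duration:.3f}s"
        )


@dataclass
class RasterSet:
    """Per-trial per-unit spike times for one session.

    ``spikes[t][u]`` is a sorted array of spike times (s, relative to
    trial start) for unit ``u`` on trial ``t``.  ``phase_onsets`` has one
    row per trial with a column per phase onset plus ``trial_end``.
    """

    session_id: str
    unit_ids: list[str]
    spikes: list[list[np.ndarray]]
    phase_onsets: pd.DataFrame
    labels: pd.DataFrame           # hand, finger_type, cue_variant

    def __post_init__(self) -> None:
        n = len(self.spikes)
        if len(self.phase_onsets) != n or len(self.labels) != n:
            raise DataError(
                f"session {self.session_id}: {n} raster trials but "
                f"{len(self.phase_onsets)} onset rows / {len(self.labels)} label rows"
            )
        if "trial_end" not in self.phase_onsets.columns:
            raise DataError("phase_onsets must include a trial_end column")
        self.phase_onsets = self.phase_onsets.reset_index(drop=True)
        self.labels = self.labels.reset_index(drop=True)

    @property
    def n_trials(self) -> int:
        return len(self.spikes)

    @property
    def n_units(self) -> int:
        return len(self.unit_ids)


def canonical_epochs(task_variant: str) -> dict[str, EpochWindow]:
    """The standard 500 ms analysis windows for a task variant.

    ``delay_task`` has move/plan/cue/iti windows; ``reaction_task`` lacks
    a delay phase and therefore has no plan window.  The ITI window ends
    exactly at cue onset (the end of the ITI phase).
    """
    if task_variant == "delay_task":
        return {
            "move": EpochWindow("go", 0.2, 0.5),
            "plan": EpochWindow("delay", 0.2, 0.5),
            "cue": EpochWindow("cue", 0.2, 0.5),
            "iti": EpochWindow("cue", -0.5, 0.5),
        }
    if task_variant == "reaction_task":
        return {
            "move": EpochWindow("go", 0.2, 0.5),
            "cue": EpochWindow("cue", 0.2, 0.5),
            "iti": EpochWindow("cue", -0.5, 0.5),
        }
    raise ConfigError(
        f"unknown task variant {task_variant!r}; expected 'delay_task' or 'reaction_task'"
    )


def _window_counts(raster: RasterSet, window: EpochWindow) -> np.ndarray:
    counts = np.zeros((raster.n_trials, raster.n_units), dtype=float)
    for t in range(raster.n_trials):
        onsets = raster.phase_onsets.iloc[t]
        start, end = window.bounds(onsets)
        if start < -1e-12 or end > float(onsets["trial_end"]) + 1e-12:
            raise DataError(
                f"window [{start:.3f}, {end:.3f}) exceeds bounds of trial {t} "
                f"(session {raster.session_id}, trial_end={onsets['trial_end']:.3f})"
            )
        for u in range(raster.n_units):
            st = raster.spikes[t][u]
            # half-open [start, end): spike at start included, at end excluded
            counts[t, u] = np.count_nonzero((st >= start) & (st < end))
    return counts


def window_rates(raster: RasterSet, window: EpochWindow) -> SessionData:
    """Firing rates (counts / duration) in ``window`` for every trial."""
    counts = _window_counts(raster, window)
    return SessionData(
        session_id=raster.session_id,
        rates=counts / window.duration,
        labels=raster.labels.copy(),
        unit_ids=list(raster.unit_ids),
    )


def windowed_dataset(
    rasters: list[RasterSet], window: EpochWindow, meta: dict | None = None
) -> TrialDataset:
    """Apply :func:`window_rates` to every session."""
    return TrialDataset(
        sessions=[window_rates(r, window) for r in rasters],
        window=window.describe(),
        meta=dict(meta or {}),
    )


def _gauss_kernel(sigma_s: float, dt: float) -> np.ndarray:
    half = int(np.ceil(4 * sigma_s / dt))
    x = np.arange(-half, half + 1) * dt
    k = np.exp(-0.5 * (x / sigma_s) ** 2)
    return k / (k.sum() * dt)          # integrates to 1 over time


def smooth_psth(
    raster: RasterSet,
    sigma_s: float = 0.05,
    condition: dict[str, str] | None = None,
    dt: float = 0.01,
) -> dict:
    """Gaussian-smoothed trial-averaged firing rates with 95% CIs.

    Each trial's spike train is convolved with a Gaussian kernel
    (truncated at +/-4 sigma, renormalized), then averaged across the
    selected trials.  The CI is the pointwise normal-approximation 95%
    interval across trials.  Returns ``{"time", "mean", "ci_low",
    "ci_high", "n_trials"}`` with rate arrays of shape (units, time).
    """
    if sigma_s <= 0:
        raise ConfigError("sigma_s must be > 0")
    sel = np.ones(raster.n_trials, dtype=bool)
    if condition:
        for col, val in condition.items():
            sel &= (raster.labels[col] == val).to_numpy()
    idx = np.flatnonzero(sel)
    if idx.size == 0:
        raise DataError(f"no trials match condition {condition!r}")

    t_end = float(raster.phase_onsets["trial_end"].iloc[idx].min())
    grid = np.arange(0, t_end, dt)
    edges = np.append(grid, t_end)
    kern = _gauss_kernel(sigma_s, dt)
    traces = np.empty((idx.size, raster.n_units, grid.size))
    for j, t in enumerate(idx):
        for u in range(raster.n_units):
            binned, _ = np.histogram(raster.spikes[t][u], bins=edges)
            traces[j, u] = np.convolve(binned, kern, mode="same")  # spikes/s
    mean = traces.mean(axis=0)
    sem = traces.std(axis=0, ddof=1) / np.sqrt(idx.size) if idx.size > 1 else np.zeros_like(mean)
    return {
        "time": grid,
        "mean": mean,
        "ci_low": mean - 1.96 * sem,
        "ci_high": mean + 1.96 * sem,
        "n_trials": int(idx.size),
    }


def filter_low_rate_units(train_rates: np.ndarray, threshold_hz: float) -> np.ndarray:
    """Boolean mask keeping units whose mean rate >= ``threshold_hz``.

    Applied per training fold (1 Hz) before decoding, and over the whole
    recording (0.5 Hz) before single-unit statistics.  The mask must be
    computed on training trials only; the cross-validation harness in
    :mod:`fingercode.decode` enforces that.
    """
    if threshold_hz < 0:
        raise ConfigError("threshold_hz must be >= 0")
    rates = np.asarray(train_rates, dtype=float)
    return rates.mean(axis=0) >= threshold_hz
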