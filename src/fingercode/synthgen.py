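"""Synthetic multi-session spike-count generator with factorized tuning.

Condition means decompose additively per unit *i*::

    mu_i(hand, finger) = max(0, b_i + H_i(hand) + F_i(finger) + lambda * G_i(hand, finger))

with baseline ``b_i`` drawn from a Gamma distribution (right-skewed, as
cortical rate distributions are), hand and finger offsets i.i.d.
zero-mean Gaussian with configurable SDs, and ``G`` a unit-SD Gaussian
interaction scaled by ``lambda`` (Hz).  At ``lambda = 0`` the code is
perfectly factorized: every left->right difference vector is identical
across finger types, which is the ground truth the geometry and CCGP
analyses are validated against.

Each session draws a fresh set of units (day-to-day population
turnover), matching how pseudo-populations treat sessions' neurons as
distinct.  The No-Go condition fires at baseline — it is the contrast
reference for selectivity statistics.  Trial-by-trial noise is Poisson
on counts: ``count ~ Poisson(mu * epoch_gain * window_s)``.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from .datasets import FINGERS, HANDS, NOGO, SessionData, TrialDataset, condition_label
from .errors import ConfigError
from .ratewin import PHASES, RasterSet
from .seeding import stream

DEFAULT_EPOCH_GAINS = {"iti": 1.0, "cue": 1.1, "delay": 1.2, "go": 1.5}

#: representative phase durations (s) for the instructed-delay task
DEFAULT_PHASE_DURATIONS = {"iti": 2.0, "cue": 1.5, "delay": 1.5, "go": 2.0}


@dataclass(frozen=True)
class GeneratorConfig:
    """Study-condition parameters for the synthetic generator.

    Defaults emulate the ten-finger interleaved task: 10 sessions of
    ~110 units, 5 finger types x 2 hands, 10 trials per condition.
    """

    n_sessions: int = 10
    n_units_per_session: int = 110
    finger_types: tuple[str, ...] = FINGERS
    hands: tuple[str, ...] = HANDS
    include_nogo: bool = False
    trials_per_condition: int = 10
    baseline_rate: float = 10.0          # Hz, population mean baseline
    hand_effect_sd: float = 2.0          # Hz
    finger_effect_sd: float = 2.0        # Hz
    interaction_strength: float = 0.0    # lambda, Hz per unit-SD interaction draw
    epoch_gains: dict = field(default_factory=lambda: dict(DEFAULT_EPOCH_GAINS))
    window_s: float = 0.5
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_sessions < 1 or self.n_units_per_session < 1:
            raise ConfigError("n_sessions and n_units_per_session must be positive")
        if self.trials_per_condition < 2:
            raise ConfigError("trials_per_condition must be >= 2 (cross-validation)")
        for name in ("baseline_rate", "hand_effect_sd", "finger_effect_sd",
                     "interaction_strength", "window_s"):
            v = float(getattr(self, name))
            if not np.isfinite(v) or v < 0:
                raise ConfigError(f"{name} must be finite and >= 0, got {v}")
        if self.window_s <= 0:
            raise ConfigError("window_s must be > 0")
        if not self.hands or not self.finger_types:
            raise ConfigError("hands and finger_types must be non-empty")
        for h in self.hands:
            if h not in HANDS:
                raise ConfigError(f"unknown hand {h!r}; allowed: {HANDS}")
        for f in self.finger_types:
            if f not in FINGERS:
                raise ConfigError(f"unknown finger type {f!r}; allowed: {FINGERS}")

    @classmethod
    def contralateral_delay(cls, **over) -> "GeneratorConfig":
        """Right-hand instructed-delay task preset: 4 sessions, 118
        units, 5 fingers + No-Go, 20 trials per condition."""
        base = dict(
            n_sessions=4, n_units_per_session=118, hands=("right",),
            include_nogo=True, trials_per_condition=20,
        )
        base.update(over)
        return cls(**base)

    def conditions(self) -> list[str]:
        conds = [condition_label(h, f) for h in self.hands for f in self.finger_types]
        if self.include_nogo:
            conds.append(NOGO)
        return conds

    def replace(self, **kw) -> "GeneratorConfig":
        return replace(self, **kw)


@dataclass
class TuningMap:
    """Per-session ground-truth condition means.

    ``baseline[s]`` has shape (units,); offsets are dicts keyed by hand /
    finger / (hand, finger).  ``condition_mean`` applies the additive
    model and rectifies at zero.
    """

    config: GeneratorConfig
    baseline: list[np.ndarray]
    hand_offsets: list[dict[str, np.ndarray]]
    finger_offsets: list[dict[str, np.ndarray]]
    interaction: list[dict[tuple[str, str], np.ndarray]]

    @property
    def n_sessions(self) -> int:
        return len(self.baseline)

    def condition_mean(self, session: int, cond: str) -> np.ndarray:
        """Rectified mean rate vector (Hz) for one condition."""
        b = self.baseline[session]
        if cond == NOGO:
            return np.maximum(b, 0.0)
        hand, finger = cond.split("_")
        lam = self.config.interaction_strength
        mu = (
            b
            + self.hand_offsets[session][hand]
            + self.finger_offsets[session][finger]
            + lam * self.interaction[session][(hand, finger)]
        )
        return np.maximum(mu, 0.0)

    def mean_matrix(self, session: int) -> tuple[list[str], np.ndarray]:
        """(conditions, units) matrix of rectified means."""
        conds = self.config.conditions()
        return conds, np.stack([self.condition_mean(session, c) for c in conds])


def make_factorized_tuning(config: GeneratorConfig) -> TuningMap:
    """Draw a fresh additive tuning structure for every session."""
    rng = stream(config.seed, "tuning")
    n = config.n_units_per_session
    baseline, hand_off, finger_off, inter = [], [], [], []
    for _ in range(config.n_sessions):
        # Gamma(shape=2) keeps baselines positive and right-skewed with
        # mean = baseline_rate
        if config.baseline_rate > 0:
            b = rng.gamma(2.0, config.baseline_rate / 2.0, size=n)
        else:
            b = np.zeros(n)
        baseline.append(b)
        hand_off.append(
            {h: rng.normal(0.0, config.hand_effect_sd, size=n) for h in config.hands}
        )
        finger_off.append(
            {f: rng.normal(0.0, config.finger_effect_sd, size=n) for f in config.finger_types}
        )
        inter.append(
            {
                (h, f): rng.normal(0.0, 1.0, size=n)
                for h in config.hands
                for f in config.finger_types
            }
        )
    return TuningMap(config, baseline, hand_off, finger_off, inter)


def _trial_order(conds: list[str], reps: int, rng: np.random.Generator) -> list[str]:
    trials = [c for c in conds for _ in range(reps)]
    rng.shuffle(trials)
    return trials


def simulate_counts(
    tuning: TuningMap, config: GeneratorConfig, epoch: str = "go"
) -> TrialDataset:
    """Poisson spike-count dataset in one analysis epoch.

    Per trial and unit, ``count ~ Poisson(mu * gain_epoch * window_s)``
    and rate = count / window_s.  Trials are balanced per condition and
    presented in randomized order; everything is deterministic given the
    config seed.
    """
    if epoch not in config.epoch_gains:
        raise ConfigError(f"no epoch gain configured for {epoch!r}")
    gain = float(config.epoch_gains[epoch])
    conds = config.conditions()
    sessions = []
    for s in range(config.n_sessions):
        rng = stream(config.seed, "counts", s)
        order = _trial_order(conds, config.trials_per_condition, rng)
        mu = {c: tuning.condition_mean(s, c) for c in conds}
        counts = np.stack(
            [rng.poisson(mu[c] * gain * config.window_s) for c in order]
        ).astype(float)
        hands, fingers = [], []
        for c in order:
            if c == NOGO:
                # hand label of a no-go trial is uninformative; fixed for determinism
                hands.append(config.hands[0])
                fingers.append(NOGO)
            else:
                h, f = c.split("_")
                hands.append(h)
                fingers.append(f)
        labels = pd.DataFrame(
            {"hand": hands, "finger_type": fingers, "cue_variant": "text"}
        )
        sessions.append(
            SessionData(
                session_id=f"s{s:02d}",
                rates=counts / config.window_s,
                labels=labels,
                unit_ids=[f"s{s:02d}_u{u:03d}" for u in range(config.n_units_per_session)],
            )
        )
    return TrialDataset(
        sessions=sessions,
        window=f"simulated:{epoch}+{config.window_s}s",
        meta={"generator_seed": config.seed, "epoch": epoch},
    )


def _phase_rate(tuning: TuningMap, config: GeneratorConfig, s: int, cond: str,
                phase: str) -> np.ndarray:
    """Piecewise rate: ITI carries no condition information (the cue has
    not appeared yet), so it runs at baseline; later phases use the full
    tuned mean scaled by the phase gain."""
    gain = float(config.epoch_gains[phase])
    if phase == "iti":
        return np.maximum(tuning.baseline[s], 0.0) * gain
    return tuning.condition_mean(s, cond) * gain


def simulate_raster(
    tuning: TuningMap,
    config: GeneratorConfig,
    phase_durations: dict[str, float] | None = None,
    task_variant: str = "delay_task",
) -> list[RasterSet]:
    """Piecewise-constant-Poisson spike times for every trial.

    Within each phase the process rate is ``mu * gain_phase`` (baseline
    only during ITI); spike times are uniform within the phase.  Phase
    onsets are recorded per trial.
    """
    durations = dict(phase_durations or DEFAULT_PHASE_DURATIONS)
    phases = PHASES[task_variant]
    for p in phases:
        if p not in durations:
            raise ConfigError(f"missing phase duration for {p!r}")
        if durations[p] <= 0:
            raise ConfigError(f"phase duration for {p!r} must be > 0")
        if p not in config.epoch_gains:
            raise ConfigError(f"missing epoch gain for phase {p!r}")
    onset, t = {}, 0.0
    for p in phases:
        onset[p] = t
        t += durations[p]
    trial_end = t

    conds = config.conditions()
    rasters = []
    for s in range(config.n_sessions):
        rng = stream(config.seed, "raster", s)
        order = _trial_order(conds, config.trials_per_condition, rng)
        spikes, hands, fingers = [], [], []
        for c in order:
            trial = []
            rates = {p: _phase_rate(tuning, config, s, c, p) for p in phases}
            for u in range(config.n_units_per_session):
                times = []
                for p in phases:
                    lam = rates[p][u] * durations[p]
                    n_sp = rng.poisson(lam)
                    if n_sp:
                        times.append(onset[p] + rng.uniform(0, durations[p], size=n_sp))
                trial.append(
                    np.sort(np.concatenate(times)) if times else np.empty(0)
                )
            spikes.append(trial)
            if c == NOGO:
                hands.append(config.hands[0])
                fingers.append(NOGO)
            else:
                h, f = c.split("_")
                hands.append(h)
                fingers.append(f)
        n_tr = len(order)
        onsets = pd.DataFrame(
            {**{p: onset[p] for p in phases}, "trial_end": trial_end},
            index=range(n_tr),
        )
        labels = pd.DataFrame(
            {"hand": hands, "finger_type": fingers, "cue_variant": "text"}
        )
        rasters.append(
            RasterSet(
                session_id=f"s{s:02d}",
                unit_ids=[f"s{s:02d}_u{u:03d}" for u in range(config.n_units_per_session)],
                spikes=spikes,
                phase_onsets=onsets,
                labels=labels,
            )
        )
    return rasters
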