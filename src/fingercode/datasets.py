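"""In-memory containers for trial-structured recordings.

A recording session holds a trials x units firing-rate matrix plus one
label row per trial (hand, finger type, cue variant).  Unit identities
are session-local: day-to-day recordings sample different neurons, so a
multi-session :class:`TrialDataset` is an ordered list of sessions, and
cross-session analyses either iterate sessions or concatenate units into
a pseudo-population (see :mod:`fingercode.decode`).

Conditions are canonical lowercase strings: ``"<hand>_<finger>"`` for
movement conditions and ``"nogo"`` for the withheld-movement catch
condition.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from .errors import DataError

HANDS = ("left", "right")
FINGERS = ("thumb", "index", "middle", "ring", "little")
NOGO = "nogo"

#: finger order used for adjacency (thumb < index < middle < ring < little)
FINGER_INDEX = {f: i for i, f in enumerate(FINGERS)}

LABEL_COLUMNS = ("hand", "finger_type", "cue_variant")


def condition_label(hand: str, finger_type: str) -> str:
    """Canonical condition string for one trial."""
    if finger_type == NOGO:
        return NOGO
    return f"{hand}_{finger_type}"


def parse_condition(label: str) -> tuple[str | None, str]:
    """Split a condition label into (hand, finger_type).

    ``"nogo"`` parses to ``(None, "nogo")``.
    """
    if label == NOGO:
        return None, NOGO
    try:
        hand, finger = label.split("_")
    except ValueError:
        raise DataError(f"unparseable condition label {label!r}") from None
    if hand not in HANDS or finger not in FINGERS:
        raise DataError(
            f"unparseable condition label {label!r}; expected '<hand>_<finger>' "
            f"with hand in {HANDS} and finger in {FINGERS}, or 'nogo'"
        )
    return hand, finger


def condition_order(conditions: set[str] | list[str]) -> list[str]:
    """Deterministic display/class order: right hand, then left, fingers
    thumb..little, No-Go last."""

    def key(c: str):
        hand, finger = parse_condition(c)
        if finger == NOGO:
            return (2, 0, 0)
        return (0 if hand == "right" else 1, FINGER_INDEX[finger], 0)

    return sorted(set(conditions), key=key)


@dataclass
class SessionData:
    """One session: a trials x units rate matrix with aligned labels."""

    session_id: str
    rates: np.ndarray              # (n_trials, n_units), Hz
    labels: pd.DataFrame           # columns: hand, finger_type, cue_variant
    unit_ids: list[str]

    def __post_init__(self) -> None:
        self.rates = np.asarray(self.rates, dtype=float)
        if self.rates.ndim != 2:
            raise DataError("rates must be a 2-D trials x units matrix")
        if len(self.labels) != self.rates.shape[0]:
            raise DataError(
                f"session {self.session_id}: {self.rates.shape[0]} rate rows "
                f"but {len(self.labels)} label rows"
            )
        if len(self.unit_ids) != self.rates.shape[1]:
            raise DataError(
                f"session {self.session_id}: {self.rates.shape[1]} rate columns "
                f"but {len(self.unit_ids)} unit ids"
            )
        if not np.all(np.isfinite(self.rates)) or np.any(self.rates < 0):
            raise DataError(f"session {self.session_id}: rates must be finite and >= 0")
        missing = [c for c in ("hand", "finger_type") if c not in self.labels.columns]
        if missing:
            raise DataError(f"session {self.session_id}: missing label columns {missing}")
        self.labels = self.labels.reset_index(drop=True)

    @property
    def n_trials(self) -> int:
        return self.rates.shape[0]

    @property
    def n_units(self) -> int:
        return self.rates.shape[1]

    @property
    def conditions(self) -> np.ndarray:
        """Per-trial condition label array."""
        return np.array(
            [
                condition_label(h, f)
                for h, f in zip(self.labels["hand"], self.labels["finger_type"])
            ]
        )

    def condition_set(self) -> list[str]:
        return condition_order(set(self.conditions))


@dataclass
class TrialDataset:
    """Ordered collection of sessions plus analysis-window provenance."""

    sessions: list[SessionData]
    window: str = ""               # free-form provenance, e.g. "move[go+0.2,+0.7s)"
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if not self.sessions:
            raise DataError("TrialDataset needs at least one session")
        ids = [s.session_id for s in self.sessions]
        if len(set(ids)) != len(ids):
            raise DataError(f"duplicate session ids: {ids}")

    @property
    def session_ids(self) -> list[str]:
        return [s.session_id for s in self.sessions]

    def condition_set(self) -> list[str]:
        conds: set[str] = set()
        for s in self.sessions:
            conds.update(s.conditions)
        return condition_order(conds)

    def with_sessions(self, sessions: list[SessionData]) -> "TrialDataset":
        return replace(self, sessions=sessions)
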