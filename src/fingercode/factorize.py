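"""Cross-condition generalization performance (CCGP).

A population code is factorized along hand and finger-type dimensions
when linear classifiers generalize across the orthogonal factor:

* hand dimension — train left-vs-right on four finger types, test on
  the held-out type (5 leave-one-type-out splits); chance 1/2;
* finger-type dimension — train the 5-way finger classifier on one
  hand's trials, test on the other hand, both directions; chance 1/5.

The classifier is the diagonal LDA of :mod:`fingercode.decode`.
Standard cross-validation accuracy at a matched training-set size is
the best-case upper bound on CCGP: reaching it implies perfect
factorization.  Significance comes from a label-permutation test
(default N = 1001 shuffles, one-sided with the add-one correction, so
p is never 0).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .datasets import FINGERS, HANDS, NOGO, SessionData, TrialDataset
from .decode import (
    DECODE_RATE_THRESHOLD,
    DEFAULT_K,
    build_pseudopopulation,
    fit_dlda,
    predict_dlda,
    stratified_folds,
)
from .errors import ConfigError, DataError
from .ratewin import filter_low_rate_units
from .seeding import stream

CHANCE = {"hand": 0.5, "finger_type": 0.2}


@dataclass
class CCGPResult:
    dimension: str
    accuracy: float
    chance: float
    within_condition_bound: float | None
    train_size: int
    p_value: float | None
    null_n: int
    null_mean: float
    null_max: float
    n_units: int


def _movement_trials(session: SessionData) -> SessionData:
    keep = (session.labels["finger_type"] != NOGO).to_numpy()
    if keep.all():
        return session
    return SessionData(
        session.session_id,
        session.rates[keep],
        session.labels.loc[keep].reset_index(drop=True),
        session.unit_ids,
    )


def _check_full_grid(session: SessionData) -> None:
    have = set(zip(session.labels["hand"], session.labels["finger_type"]))
    want = {(h, f) for h in HANDS for f in FINGERS}
    missing = want - have
    if missing:
        raise DataError(f"missing conditions for CCGP: {sorted(missing)}")


def _dlda_accuracy(xtr, ytr, xte, yte, rate_threshold) -> tuple[int, int]:
    mask = filter_low_rate_units(xtr, rate_threshold)
    if mask.sum() == 0:
        raise DataError("no units pass the training rate screen")
    model = fit_dlda(xtr, ytr, unit_mask=mask)
    pred, _, _ = predict_dlda(model, xte)
    return int(np.sum(pred == np.asarray(yte))), len(yte)


def ccgp(
    pseudo: TrialDataset,
    dimension: str,
    rate_threshold: float = DECODE_RATE_THRESHOLD,
) -> tuple[float, int]:
    """Generalization accuracy and the per-split training-set size.

    Accuracy pools correct/total over the leave-one-group-out splits.
    """
    if dimension not in CHANCE:
        raise ConfigError(f"dimension must be one of {sorted(CHANCE)}")
    session = _movement_trials(pseudo.sessions[0])
    _check_full_grid(session)
    hands = session.labels["hand"].to_numpy()
    fingers = session.labels["finger_type"].to_numpy()
    correct = total = 0
    train_sizes = []
    if dimension == "hand":
        for held in FINGERS:
            tr = fingers != held
            te = ~tr
            c, t = _dlda_accuracy(
                session.rates[tr], hands[tr], session.rates[te], hands[te],
                rate_threshold,
            )
            correct += c
            total += t
            train_sizes.append(int(tr.sum()))
    else:
        for train_hand, test_hand in (("right", "left"), ("left", "right")):
            tr = hands == train_hand
            te = hands == test_hand
            c, t = _dlda_accuracy(
                session.rates[tr], fingers[tr], session.rates[te], fingers[te],
                rate_threshold,
            )
            correct += c
            total += t
            train_sizes.append(int(tr.sum()))
    return correct / total, int(round(float(np.mean(train_sizes))))


def within_condition_bound(
    pseudo: TrialDataset,
    dimension: str,
    train_size: int,
    k: int = DEFAULT_K,
    seed: int = 0,
    rate_threshold: float = DECODE_RATE_THRESHOLD,
) -> float:
    """Standard CV accuracy on the dimension's labels with training
    folds subsampled (class-stratified, seeded) to ``train_size``."""
    if dimension not in CHANCE:
        raise ConfigError(f"dimension must be one of {sorted(CHANCE)}")
    session = _movement_trials(pseudo.sessions[0])
    _check_full_grid(session)
    y = session.labels[
        "hand" if dimension == "hand" else "finger_type"
    ].to_numpy()
    conds = session.conditions  # stratify folds by full condition
    folds = stratified_folds(conds, k)
    rng = stream(seed, "within-bound", dimension)
    correct = total = 0
    for f in range(k):
        tr = np.flatnonzero(folds != f)
        te = np.flatnonzero(folds == f)
        if train_size > tr.size:
            raise ConfigError(
                f"train_size={train_size} exceeds available training trials ({tr.size})"
            )
        if train_size < tr.size:
            # stratified subsample: proportional per class, seeded
            chosen = []
            classes = np.unique(y[tr])
            per = train_size // classes.size
            for c in classes:
                pool = tr[y[tr] == c]
                take = min(per, pool.size)
                chosen.append(rng.choice(pool, size=take, replace=False))
            chosen = np.concatenate(chosen)
            # top up to the exact size from the remainder
            if chosen.size < train_size:
                rest = np.setdiff1d(tr, chosen)
                chosen = np.concatenate(
                    [chosen, rng.choice(rest, size=train_size - chosen.size,
                                        replace=False)]
                )
            tr = np.sort(chosen)
        c, t = _dlda_accuracy(
            session.rates[tr], y[tr], session.rates[te], y[te], rate_threshold
        )
        correct += c
        total += t
    return correct / total


def _shuffled_dataset(dataset: TrialDataset, rng: np.random.Generator) -> TrialDataset:
    """Jointly shuffle (hand, finger_type) label pairs across trials
    within each session, destroying both factor structures while
    preserving marginal condition counts."""
    sessions = []
    for s in dataset.sessions:
        perm = rng.permutation(s.n_trials)
        labels = s.labels.copy()
        labels[["hand", "finger_type"]] = (
            s.labels[["hand", "finger_type"]].iloc[perm].to_numpy()
        )
        sessions.append(SessionData(s.session_id, s.rates, labels, s.unit_ids))
    return dataset.with_sessions(sessions)


def permutation_pvalue(
    dataset: TrialDataset,
    dimension: str,
    observed: float,
    n_perm: int = 1001,
    seed: int = 0,
    rate_threshold: float = DECODE_RATE_THRESHOLD,
) -> tuple[float, dict]:
    """One-sided permutation p-value for a CCGP accuracy.

    Labels are shuffled within session before pseudo-population
    pairing; the full CCGP is recomputed per shuffle.  p = (1 + #{null
    >= observed}) / (n_perm + 1), bounded below by 1/(n_perm+1).
    """
    if n_perm < 1:
        raise ConfigError("n_perm must be >= 1")
    rng = stream(seed, "ccgp-permutation", dimension)
    null = np.empty(n_perm)
    for i in range(n_perm):
        shuffled = _shuffled_dataset(dataset, rng)
        pseudo = (
            shuffled
            if len(shuffled.sessions) == 1 and shuffled.sessions[0].session_id == "pseudo"
            else build_pseudopopulation(shuffled)
        )
        null[i], _ = ccgp(pseudo, dimension, rate_threshold=rate_threshold)
    p = (1 + int(np.sum(null >= observed))) / (n_perm + 1)
    return p, {"n": n_perm, "mean": float(null.mean()), "max": float(null.max())}


def ccgp_analysis(
    dataset: TrialDataset,
    dimension: str,
    n_perm: int = 1001,
    k: int = DEFAULT_K,
    seed: int = 0,
    rate_threshold: float = DECODE_RATE_THRESHOLD,
) -> CCGPResult:
    """Full CCGP analysis: accuracy, matched within-condition bound, and
    permutation significance, from per-session data (pseudo-population
    built internally) or an existing single-session pseudo-population."""
    pseudo = (
        dataset
        if len(dataset.sessions) == 1
        else build_pseudopopulation(dataset)
    )
    acc, train_size = ccgp(pseudo, dimension, rate_threshold=rate_threshold)
    bound = within_condition_bound(
        pseudo, dimension, train_size, k=k, seed=seed, rate_threshold=rate_threshold
    )
    if n_perm > 0:
        p, null = permutation_pvalue(
            dataset, dimension, acc, n_perm=n_perm, seed=seed,
            rate_threshold=rate_threshold,
        )
    else:
        p, null = None, {"n": 0, "mean": float("nan"), "max": float("nan")}
    return CCGPResult(
        dimension=dimension,
        accuracy=acc,
        chance=CHANCE[dimension],
        within_condition_bound=bound,
        train_size=train_size,
        p_value=p,
        null_n=null["n"],
        null_mean=null["mean"],
        null_max=null["max"],
        n_units=pseudo.sessions[0].n_units,
    )


def ccgp_table(results: list[CCGPResult]) -> pd.DataFrame:
    return pd.DataFrame([vars(r) for r in results])
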