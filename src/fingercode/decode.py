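"""Diagonal-LDA decoding with stratified cross-validation and capacity curves.

The classifier is diagonal-covariance linear discriminant analysis:
Gaussian naive Bayes with a single per-unit variance vector pooled
within classes and shared across them.  Cross-validation is stratified
K-fold (default K=8) with trials assigned to folds round-robin in
within-class order (no shuffling), unit screening (mean training-fold
rate >= 1 Hz) and all model parameters derived from training folds only.
Session results are pooled by summing correct trials over sessions.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .datasets import (
    NOGO,
    FINGER_INDEX,
    SessionData,
    TrialDataset,
    condition_order,
    parse_condition,
)
from .errors import ComputationError, ConfigError, DataError
from .ratewin import EpochWindow, RasterSet, filter_low_rate_units, windowed_dataset
from .seeding import stream

DEFAULT_K = 8
DECODE_RATE_THRESHOLD = 1.0  # Hz, training-fold mean
VARIANCE_FLOOR = 1e-6        # Hz^2


@dataclass
class DldaModel:
    classes: list[str]
    means: np.ndarray          # (classes, kept units), Hz
    variances: np.ndarray      # (kept units,), Hz^2, shared across classes
    log_priors: np.ndarray     # (classes,)
    unit_mask: np.ndarray      # bool over original units


def fit_dlda(
    rates: np.ndarray,
    labels: np.ndarray,
    unit_mask: np.ndarray | None = None,
    classes: list[str] | None = None,
) -> DldaModel:
    """Fit class means, pooled per-unit variances, empirical priors."""
    x = np.asarray(rates, dtype=float)
    labels = np.asarray(labels)
    if unit_mask is None:
        unit_mask = np.ones(x.shape[1], dtype=bool)
    unit_mask = np.asarray(unit_mask, dtype=bool)
    if unit_mask.sum() == 0:
        raise DataError("empty feature set after unit masking")
    x = x[:, unit_mask]
    if classes is None:
        classes = list(np.unique(labels))
    if len(classes) < 2:
        raise DataError("need >= 2 classes")
    means, sq = [], np.zeros(x.shape[1])
    priors = []
    n = 0
    for c in classes:
        xc = x[labels == c]
        if xc.shape[0] < 2:
            raise DataError(f"class {c!r} has {xc.shape[0]} trials; need >= 2")
        means.append(xc.mean(axis=0))
        sq += ((xc - xc.mean(axis=0)) ** 2).sum(axis=0)
        priors.append(xc.shape[0])
        n += xc.shape[0]
    variances = np.maximum(sq / (n - len(classes)), VARIANCE_FLOOR)
    priors = np.array(priors, dtype=float) / n
    return DldaModel(
        classes=list(classes),
        means=np.stack(means),
        variances=variances,
        log_priors=np.log(priors),
        unit_mask=unit_mask,
    )


def predict_dlda(
    model: DldaModel, rates: np.ndarray
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Labels, per-class log scores, and tie flags for each trial.

    score(c) = log prior_c - 1/2 sum_i (x_i - mu_ci)^2 / sigma_i^2.
    Exact ties resolve to the lowest class index and are flagged.
    """
    x = np.asarray(rates, dtype=float)
    if x.ndim == 1:
        x = x[None, :]
    if x.shape[1] != model.unit_mask.size:
        raise DataError(
            f"expected {model.unit_mask.size} units, got {x.shape[1]}"
        )
    x = x[:, model.unit_mask]
    d = x[:, None, :] - model.means[None, :, :]          # (trials, classes, units)
    scores = model.log_priors[None, :] - 0.5 * (d**2 / model.variances).sum(axis=2)
    best = scores.argmax(axis=1)                          # first (lowest) argmax
    ties = (scores == scores[np.arange(len(best)), best][:, None]).sum(axis=1) > 1
    labels = np.array([model.classes[i] for i in best])
    return labels, scores, ties


def stratified_folds(labels: np.ndarray, k: int) -> np.ndarray:
    """Fold index per trial: round-robin within each class in trial order.

    Deterministic ("no shuffling"); preserves class proportions per fold.
    """
    labels = np.asarray(labels)
    if k < 2:
        raise ConfigError("k must be >= 2")
    folds = np.empty(labels.size, dtype=int)
    for c in np.unique(labels):
        idx = np.flatnonzero(labels == c)
        if idx.size < k:
            raise DataError(
                f"class {c!r} has {idx.size} trials; needs >= k={k} for stratified folds"
            )
        folds[idx] = np.arange(idx.size) % k
    return folds


@dataclass
class ConfusionMatrix:
    classes: list[str]
    counts: np.ndarray           # (true, predicted) ints
    session_id: str
    fold_accuracies: list[float] = field(default_factory=list)

    @property
    def n_trials(self) -> int:
        return int(self.counts.sum())

    @property
    def accuracy(self) -> float:
        total = self.counts.sum()
        if total == 0:
            raise ComputationError("empty confusion matrix")
        return float(np.trace(self.counts) / total)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.counts, index=self.classes, columns=self.classes)


@dataclass
class CurveResult:
    """Accuracy as a function of one swept variable."""

    variable: str
    values: np.ndarray
    accuracy: np.ndarray
    ci_low: np.ndarray
    ci_high: np.ndarray
    provenance: str              # "folds/sessions" or "resamples"

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                self.variable: self.values,
                "accuracy": self.accuracy,
                "ci_low": self.ci_low,
                "ci_high": self.ci_high,
            }
        )


def _fold_ci(accs: list[float]) -> tuple[float, float]:
    a = np.asarray(accs, dtype=float)
    if a.size < 2:
        return float("nan"), float("nan")
    half = 1.96 * a.std(ddof=1) / np.sqrt(a.size)
    return float(a.mean() - half), float(a.mean() + half)


def crossval_confusion(
    session: SessionData,
    k: int = DEFAULT_K,
    rate_threshold: float = DECODE_RATE_THRESHOLD,
    train_truncate: int | None = None,
    classes: list[str] | None = None,
) -> ConfusionMatrix:
    """Stratified K-fold cross-validated confusion matrix for one session.

    Per fold, the low-rate unit screen and the classifier are derived
    from the training fold only; predictions on the held-out fold are
    pooled into one confusion matrix.  ``train_truncate`` optionally
    keeps only the first n trials per class of each training fold
    (learning-curve support).
    """
    conds = session.conditions
    if classes is None:
        classes = condition_order(set(conds))
    folds = stratified_folds(conds, k)
    counts = np.zeros((len(classes), len(classes)), dtype=int)
    cls_idx = {c: i for i, c in enumerate(classes)}
    fold_accs = []
    for f in range(k):
        tr, te = folds != f, folds == f
        xtr, ytr = session.rates[tr], conds[tr]
        if train_truncate is not None:
            keep_rows = np.zeros(ytr.size, dtype=bool)
            for c in classes:
                pos = np.flatnonzero(ytr == c)[:train_truncate]
                keep_rows[pos] = True
            xtr, ytr = xtr[keep_rows], ytr[keep_rows]
        mask = filter_low_rate_units(xtr, rate_threshold)
        if mask.sum() == 0:
            raise DataError(
                f"session {session.session_id}, fold {f}: no units pass the "
                f"{rate_threshold} Hz training-fold screen"
            )
        model = fit_dlda(xtr, ytr, unit_mask=mask, classes=classes)
        pred, _, _ = predict_dlda(model, session.rates[te])
        true = conds[te]
        for t_lbl, p_lbl in zip(true, pred):
            counts[cls_idx[t_lbl], cls_idx[p_lbl]] += 1
        fold_accs.append(float(np.mean(pred == true)))
    return ConfusionMatrix(classes, counts, session.session_id, fold_accs)


def aggregate_sessions(
    confusions: list[ConfusionMatrix],
) -> tuple[ConfusionMatrix, float, float]:
    """Pool confusions: summed counts, pooled accuracy, trial-weighted SD."""
    if not confusions:
        raise DataError("no confusion matrices to aggregate")
    classes = confusions[0].classes
    for c in confusions[1:]:
        if c.classes != classes:
            raise DataError(f"class-list mismatch: {c.classes} vs {classes}")
    total = np.sum([c.counts for c in confusions], axis=0)
    pooled = ConfusionMatrix(classes, total, "pooled")
    w = np.array([c.n_trials for c in confusions], dtype=float)
    a = np.array([c.accuracy for c in confusions])
    acc = pooled.accuracy
    sd = float(np.sqrt(np.sum(w * (a - acc) ** 2) / w.sum())) if len(a) > 1 else 0.0
    return pooled, acc, sd


def crossval_dataset(
    dataset: TrialDataset, k: int = DEFAULT_K, **kw
) -> tuple[ConfusionMatrix, float, float, list[ConfusionMatrix]]:
    """Per-session CV then cross-session pooling."""
    per = [crossval_confusion(s, k=k, **kw) for s in dataset.sessions]
    pooled, acc, sd = aggregate_sessions(per)
    return pooled, acc, sd, per


def learning_curve(
    dataset: TrialDataset,
    train_fractions: np.ndarray,
    k: int = DEFAULT_K,
) -> CurveResult:
    """Accuracy vs training-set size within each stratified split.

    Training folds are truncated (first n per class in fold order) to
    the requested fraction; test folds are untouched.  Intervals are
    normal-approximation 95% CIs over the pooled fold x session
    accuracy list.
    """
    fracs = np.asarray(train_fractions, dtype=float)
    if np.any((fracs <= 0) | (fracs > 1)):
        raise ConfigError("train_fractions must lie in (0, 1]")
    values, accs, lo, hi = [], [], [], []
    # per-class training count at fraction 1 (balanced tasks)
    for frac in fracs:
        per_acc, fold_accs = [], []
        n_cor = n_tot = 0
        skip = False
        for s in dataset.sessions:
            counts = pd.Series(s.conditions).value_counts()
            per_class_train = int(np.floor(frac * counts.min() * (k - 1) / k))
            if frac < 1 and per_class_train < 2:
                warnings.warn(
                    f"fraction {frac} yields <2 training trials per class "
                    "(dLDA variance undefined); point skipped"
                )
                skip = True
                break
            cm = crossval_confusion(
                s, k=k, train_truncate=None if frac == 1.0 else per_class_train
            )
            n_cor += int(np.trace(cm.counts))
            n_tot += cm.n_trials
            fold_accs.extend(cm.fold_accuracies)
        if skip:
            continue
        values.append(frac)
        accs.append(n_cor / n_tot)
        l, h = _fold_ci(fold_accs)
        lo.append(l)
        hi.append(h)
    return CurveResult(
        "train_fraction", np.array(values), np.array(accs),
        np.array(lo), np.array(hi), "folds/sessions",
    )


def build_pseudopopulation(dataset: TrialDataset) -> TrialDataset:
    """Concatenate sessions' units by pairing trials within condition.

    The j-th trial of a condition in each session becomes one
    pseudo-trial; per-condition counts trim to the cross-session
    minimum, and the unit count is the sum over sessions.
    """
    sessions = dataset.sessions
    cond_sets = [set(s.conditions) for s in sessions]
    common = cond_sets[0]
    for cs in cond_sets[1:]:
        if cs != common:
            missing = (common | cs) - (common & cs)
            raise DataError(f"sessions disagree on conditions: {sorted(missing)}")
    conds = condition_order(common)
    blocks, labels_out = [], []
    for c in conds:
        per = [np.flatnonzero(s.conditions == c) for s in sessions]
        t_min = min(len(p) for p in per)
        block = np.concatenate(
            [s.rates[p[:t_min]] for s, p in zip(sessions, per)], axis=1
        )
        blocks.append(block)
        hand, finger = parse_condition(c)
        labels_out.extend(
            {"hand": hand or sessions[0].labels["hand"].iloc[0],
             "finger_type": finger, "cue_variant": "pseudo"}
            for _ in range(t_min)
        )
    rates = np.concatenate(blocks, axis=0)
    unit_ids = [u for s in sessions for u in s.unit_ids]
    pseudo = SessionData(
        session_id="pseudo",
        rates=rates,
        labels=pd.DataFrame(labels_out),
        unit_ids=unit_ids,
    )
    return TrialDataset([pseudo], window=dataset.window,
                        meta={**dataset.meta, "pseudo_from": dataset.session_ids})


def neuron_dropping_curve(
    pseudo: TrialDataset,
    m_values: np.ndarray,
    n_resamples: int = 40,
    k: int = DEFAULT_K,
    seed: int = 0,
) -> CurveResult:
    """Accuracy vs number of randomly subsampled units (without
    replacement), with 95% percentile intervals over resamples."""
    session = pseudo.sessions[0]
    m_values = np.asarray(m_values, dtype=int)
    if np.any(m_values < 1):
        raise ConfigError("m_values must be >= 1")
    if m_values.max() > session.n_units:
        raise ConfigError(
            f"M={m_values.max()} exceeds available units ({session.n_units})"
        )
    rng = stream(seed, "neuron-dropping")
    accs, lo, hi = [], [], []
    for m in m_values:
        sub_accs = []
        for _ in range(n_resamples):
            units = rng.choice(session.n_units, size=m, replace=False)
            sub = SessionData(
                session.session_id,
                session.rates[:, units],
                session.labels,
                [session.unit_ids[u] for u in units],
            )
            sub_accs.append(crossval_confusion(sub, k=k).accuracy)
        accs.append(float(np.mean(sub_accs)))
        l, h = np.percentile(sub_accs, [2.5, 97.5])
        lo.append(float(l))
        hi.append(float(h))
    return CurveResult(
        "n_units", m_values.astype(float), np.array(accs),
        np.array(lo), np.array(hi), "resamples",
    )


def window_duration_sweep(
    rasters: list[RasterSet],
    durations: np.ndarray,
    k: int = DEFAULT_K,
) -> CurveResult:
    """Accuracy vs decode-window duration, window = [go+0.2, go+0.2+d)."""
    durations = np.asarray(durations, dtype=float)
    accs, lo, hi = [], [], []
    for d in durations:
        win = EpochWindow("go", 0.2, float(d))
        ds = windowed_dataset(rasters, win)
        _, acc, _, per = crossval_dataset(ds, k=k)
        accs.append(acc)
        l, h = _fold_ci([a for cm in per for a in cm.fold_accuracies])
        lo.append(l)
        hi.append(h)
    return CurveResult(
        "window_duration_s", durations, np.array(accs),
        np.array(lo), np.array(hi), "folds/sessions",
    )


def sliding_timecourse(
    rasters: list[RasterSet],
    bin_s: float = 0.5,
    step_s: float = 0.25,
    k: int = DEFAULT_K,
) -> CurveResult:
    """Accuracy in a sliding window across the trial (bin centers)."""
    t_end = min(float(r.phase_onsets["trial_end"].min()) for r in rasters)
    centers = np.arange(bin_s / 2, t_end - bin_s / 2 + 1e-9, step_s)
    accs, lo, hi = [], [], []
    for c in centers:
        win = EpochWindow("start", float(c - bin_s / 2), bin_s)
        ds = windowed_dataset(rasters, win)
        _, acc, _, per = crossval_dataset(ds, k=k)
        accs.append(acc)
        l, h = _fold_ci([a for cm in per for a in cm.fold_accuracies])
        lo.append(l)
        hi.append(h)
    return CurveResult(
        "window_center_s", centers, np.array(accs),
        np.array(lo), np.array(hi), "folds/sessions",
    )


def error_breakdown(confusion: ConfusionMatrix, mode: str = "ten_finger") -> dict:
    """Anatomy of classification errors.

    Adjacent errors confuse neighbouring fingers of the same hand
    (|finger index difference| = 1, thumb<index<middle<ring<little);
    matching-across-hand errors confuse the same finger type on opposite
    hands (ten-finger mode only).  Fractions are of total errors; with
    zero errors the fractions are not applicable (NaN).
    """
    if mode not in ("within_hand", "ten_finger"):
        raise ConfigError(f"unknown mode {mode!r}")
    parsed = [parse_condition(c) for c in confusion.classes]
    total_err = adj = match = 0
    for i, (hi_, fi) in enumerate(parsed):
        for j, (hj, fj) in enumerate(parsed):
            if i == j:
                continue
            n = int(confusion.counts[i, j])
            if n == 0:
                continue
            total_err += n
            if fi != NOGO and fj != NOGO:
                same_hand = (hi_ == hj) or (hi_ is None) or (hj is None)
                if same_hand and abs(FINGER_INDEX[fi] - FINGER_INDEX[fj]) == 1:
                    adj += n
                elif mode == "ten_finger" and hi_ != hj and fi == fj:
                    match += n
    out = {
        "n_errors": total_err,
        "adjacent_fraction": adj / total_err if total_err else float("nan"),
    }
    if mode == "ten_finger":
        out["matching_across_hand_fraction"] = (
            match / total_err if total_err else float("nan")
        )
        out["adjacent_or_matching_fraction"] = (
            (adj + match) / total_err if total_err else float("nan")
        )
    return out
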