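"""Cross-validated Mahalanobis (crossnobis) representational geometry.

The crossnobis estimator of the squared Mahalanobis distance between
conditions j and k averages, over independent trial partitions A != B::

    d_jk^2 = (b_j - b_k)_A [ (Sigma_A + Sigma_B) / 2 ]^{-1} (b_j - b_k)_B^T / N

where b are fold-wise condition mean rate vectors, Sigma the fold's
noise covariance (within-condition residuals, shrunk toward the
diagonal), and N the unit count.  Because the two difference estimates
come from independent folds the estimator is unbiased: E[d^2] = 0 for
statistically identical patterns, and individual estimates can be
slightly negative.  Units of d^2 are unitless^2 / neuron.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from itertools import combinations

import numpy as np
import pandas as pd
from scipy import linalg
from sklearn.manifold import MDS

from .datasets import SessionData, TrialDataset, condition_order, parse_condition
from .decode import DEFAULT_K, stratified_folds
from .errors import ComputationError, ConfigError, DataError
from .seeding import stream


@dataclass
class RDM:
    """Condition x condition crossnobis squared distances for one session."""

    conditions: list[str]
    matrix: np.ndarray
    session_id: str
    fold_scheme: str

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.matrix, index=self.conditions, columns=self.conditions)

    def pair_value(self, c1: str, c2: str) -> float:
        i, j = self.conditions.index(c1), self.conditions.index(c2)
        return float(self.matrix[i, j])


def fold_condition_means(
    session: SessionData, folds: np.ndarray
) -> tuple[list[str], np.ndarray, list[np.ndarray]]:
    """Fold-wise condition means and within-fold residuals.

    Returns (conditions, means[fold, cond, unit], residuals per fold
    where each residual row is a trial minus its own fold-condition
    mean).
    """
    conds = condition_order(set(session.conditions))
    labels = session.conditions
    n_folds = int(folds.max()) + 1
    means = np.empty((n_folds, len(conds), session.n_units))
    residuals = []
    for f in range(n_folds):
        rows = []
        for ci, c in enumerate(conds):
            sel = (folds == f) & (labels == c)
            if not sel.any():
                raise DataError(f"condition {c!r} missing from fold {f}")
            xc = session.rates[sel]
            means[f, ci] = xc.mean(axis=0)
            rows.append(xc - xc.mean(axis=0))
        residuals.append(np.concatenate(rows, axis=0))
    return conds, means, residuals


def noise_covariance(
    residuals: np.ndarray,
    shrinkage: str | float = "analytic",
    ddof: int = 1,
) -> np.ndarray:
    """Residual covariance shrunk toward its diagonal.

    ``shrinkage='analytic'`` uses the Schafer-Strimmer closed-form
    intensity for off-diagonal shrinkage, guaranteeing an invertible,
    positive-definite estimate even with fewer trials than units;
    ``'full'`` returns the diagonal matrix; a float in [0, 1] fixes the
    intensity.  ``ddof`` is the degrees of freedom already consumed by
    the mean(s) removed from the residuals.
    """
    r = np.asarray(residuals, dtype=float)
    if r.ndim != 2 or r.shape[0] < 2:
        raise DataError("need >= 2 residual rows")
    n = r.shape[0]
    denom = max(n - ddof, 1)
    s = r.T @ r / denom
    diag = np.diag(np.diag(s))
    if shrinkage == "full":
        lam = 1.0
    elif shrinkage == "analytic":
        off = s - diag
        denom2 = float((off**2).sum())
        if denom2 <= 0:
            lam = 1.0
        else:
            # var of each off-diagonal entry from the trial-wise products
            w = r[:, :, None] * r[:, None, :]            # (n, u, u)
            var_s = (n / denom**2 / max(n - 1, 1)) * ((w - w.mean(0)) ** 2).sum(0)
            np.fill_diagonal(var_s, 0.0)
            lam = float(np.clip(var_s.sum() / denom2, 0.0, 1.0))
    else:
        lam = float(shrinkage)
        if not 0.0 <= lam <= 1.0:
            raise ConfigError("shrinkage intensity must lie in [0, 1]")
    sigma = (1.0 - lam) * s + lam * diag
    # Units silent within a fold have ~zero residual variance; inverting
    # that would let a single unit dominate every distance.  Floor the
    # diagonal at 1% of the mean unit variance (plus a tiny absolute
    # floor for the all-silent corner case).
    floor = max(1e-2 * float(np.trace(sigma)) / sigma.shape[0], 1e-6)
    np.fill_diagonal(sigma, np.maximum(np.diag(sigma), floor))
    return sigma


def crossnobis_from_folds(
    means: np.ndarray, covs: np.ndarray | list[np.ndarray]
) -> np.ndarray:
    """Crossnobis squared-distance matrix from fold statistics.

    ``means`` is (folds, conditions, units); ``covs`` one covariance per
    fold.  Each condition pair averages the bilinear form over unordered
    fold pairs; the result is symmetric with a zero diagonal.
    """
    means = np.asarray(means, dtype=float)
    n_folds, n_cond, n_units = means.shape
    if n_folds < 2:
        raise DataError("crossnobis needs >= 2 folds")
    covs = [np.asarray(c, dtype=float) for c in covs]
    if len(covs) != n_folds:
        raise DataError("one covariance per fold required")
    d2 = np.zeros((n_cond, n_cond))
    pairs = list(combinations(range(n_folds), 2))
    for a, b in pairs:
        sig = 0.5 * (covs[a] + covs[b])
        try:
            cf = linalg.cho_factor(sig)
        except linalg.LinAlgError as e:  # pragma: no cover - guarded by shrinkage
            raise ComputationError(
                "averaged noise covariance is singular despite shrinkage; "
                "this indicates a bug upstream"
            ) from e
        for i in range(n_cond):
            for j in range(i + 1, n_cond):
                da = means[a, i] - means[a, j]
                db = means[b, i] - means[b, j]
                d2[i, j] += float(da @ linalg.cho_solve(cf, db)) / n_units
    d2 = (d2 + d2.T) / len(pairs)
    np.fill_diagonal(d2, 0.0)
    return d2


def crossnobis_rdm(
    session: SessionData,
    k: int = DEFAULT_K,
    shrinkage: str | float = "analytic",
) -> RDM:
    """Crossnobis RDM for one session with stratified K folds.

    The fold count is capped so every condition keeps >= 2 trials per
    fold: a fold whose conditions are singletons has zero residual
    degrees of freedom and no usable noise covariance.
    """
    counts = pd.Series(session.conditions).value_counts()
    k_eff = int(min(k, counts.min() // 2))
    if k_eff < 2:
        raise DataError(
            "crossnobis needs >= 2 folds with >= 2 trials per condition each; "
            f"smallest condition has {counts.min()} trials"
        )
    folds = stratified_folds(session.conditions, k_eff)
    conds, means, residuals = fold_condition_means(session, folds)
    covs = [
        noise_covariance(r, shrinkage=shrinkage, ddof=len(conds)) for r in residuals
    ]
    d2 = crossnobis_from_folds(means, covs)
    return RDM(conds, d2, session.session_id, f"stratified-{k_eff}fold")


def crossnobis_rdms(dataset: TrialDataset, k: int = DEFAULT_K, **kw) -> list[RDM]:
    return [crossnobis_rdm(s, k=k, **kw) for s in dataset.sessions]


def average_rdm(rdms: list[RDM]) -> RDM:
    """Unweighted mean RDM across sessions (conditions must match)."""
    conds = rdms[0].conditions
    for r in rdms[1:]:
        if r.conditions != conds:
            raise DataError("RDM condition lists differ")
    return RDM(
        conds,
        np.mean([r.matrix for r in rdms], axis=0),
        "mean",
        rdms[0].fold_scheme,
    )


def _cross_hand_pairs(conditions: list[str]) -> tuple[list, list]:
    """(matching, non-matching) cross-hand condition index pairs."""
    parsed = [parse_condition(c) for c in conditions]
    matching, nonmatching = [], []
    for i, j in combinations(range(len(conditions)), 2):
        (h1, f1), (h2, f2) = parsed[i], parsed[j]
        if None in (h1, h2) or "nogo" in (f1, f2):
            continue
        if h1 != h2:
            (matching if f1 == f2 else nonmatching).append((i, j))
    return matching, nonmatching


def matching_contrast(
    rdms: list[RDM], n_boot: int = 5000, seed: int = 0
) -> tuple[float, tuple[float, float], pd.DataFrame]:
    """Mean(non-matching cross-hand d^2) - mean(matching d^2).

    Positive values mean same-finger pairs across hands are closer than
    different-finger pairs, i.e. finger representations are shared
    across hands.  The 95% CI bootstraps over session x pair entries.
    """
    records = []
    for rdm in rdms:
        matching, nonmatching = _cross_hand_pairs(rdm.conditions)
        if not matching:
            raise DataError(
                f"RDM for session {rdm.session_id} does not span both hands"
            )
        for kind, pairs in (("matching", matching), ("nonmatching", nonmatching)):
            for i, j in pairs:
                records.append(
                    {
                        "session_id": rdm.session_id,
                        "pair": f"{rdm.conditions[i]}|{rdm.conditions[j]}",
                        "kind": kind,
                        "d2": float(rdm.matrix[i, j]),
                    }
                )
    df = pd.DataFrame(records)
    match = df.loc[df["kind"] == "matching", "d2"].to_numpy()
    non = df.loc[df["kind"] == "nonmatching", "d2"].to_numpy()
    diff = float(non.mean() - match.mean())
    rng = stream(seed, "matching-contrast")
    boots = (
        non[rng.integers(0, non.size, size=(n_boot, non.size))].mean(axis=1)
        - match[rng.integers(0, match.size, size=(n_boot, match.size))].mean(axis=1)
    )
    lo, hi = np.percentile(boots, [2.5, 97.5])
    return diff, (float(lo), float(hi)), df


def mds_embed(rdm: RDM, dim: int = 2, seed: int = 0) -> tuple[np.ndarray, float]:
    """Metric MDS of sqrt(max(d^2, 0)); returns (coords, stress).

    Negative squared distances (legitimate under the unbiased estimator)
    are clipped to zero before the square root.
    """
    if dim < 1:
        raise ConfigError("dim must be >= 1")
    d2 = rdm.matrix
    if np.allclose(d2, 0.0):
        warnings.warn("all-zero RDM: returning zero embedding")
        return np.zeros((len(rdm.conditions), dim)), 0.0
    d = np.sqrt(np.maximum(d2, 0.0))
    mds = MDS(
        n_components=dim,
        metric="precomputed",
        metric_mds=True,
        init="classical_mds",
        n_init=1,
        max_iter=1000,
        eps=1e-9,
        normalized_stress=False,
        random_state=seed % (2**32),
    )
    coords = mds.fit_transform(d)
    return coords, float(mds.stress_)


@dataclass
class EmbeddingSet:
    """Aligned per-session condition embeddings."""

    conditions: list[str]
    coords: np.ndarray               # (sessions, conditions, dim)
    mean_shape: np.ndarray           # (conditions, dim)
    dispersion: np.ndarray | None    # (conditions,), across-session SE, None if <2 sessions
    session_ids: list[str]
    note: str = ""


def procrustes_align(
    embeddings: list[np.ndarray],
    session_ids: list[str],
    conditions: list[str],
    scaling: bool = True,
    tol: float = 1e-9,
    max_iter: int = 100,
) -> EmbeddingSet:
    """Generalized Procrustes alignment of per-session MDS embeddings.

    Iteratively aligns every configuration (translation, rotation /
    reflection, optional isotropic scale) to the evolving mean shape
    until the mean shape moves less than ``tol``.  With a single
    session the identity alignment is returned and the standard error
    is undefined.
    """
    X = [np.asarray(e, dtype=float) for e in embeddings]
    if len(X) < 2:
        return EmbeddingSet(
            conditions,
            np.stack(X) if X else np.empty((0, 0, 0)),
            X[0] if X else np.empty((0, 0)),
            None,
            session_ids,
            note="fewer than 2 sessions: identity alignment, SE undefined",
        )
    X = [x - x.mean(axis=0) for x in X]
    if scaling:
        X = [x / max(np.linalg.norm(x), 1e-30) for x in X]
    mean = X[0].copy()
    for _ in range(max_iter):
        aligned = []
        for x in X:
            r, sc = linalg.orthogonal_procrustes(x, mean)
            aligned.append((x @ r) * (sc / (x**2).sum() if scaling else 1.0))
        new_mean = np.mean(aligned, axis=0)
        if scaling:
            new_mean = new_mean / max(np.linalg.norm(new_mean), 1e-30)
        shift = np.linalg.norm(new_mean - mean)
        mean = new_mean
        X = aligned
        if shift < tol:
            break
    stacked = np.stack(X)
    se = stacked.std(axis=0, ddof=1) / np.sqrt(len(X))     # (cond, dim)
    dispersion = np.linalg.norm(se, axis=1)
    return EmbeddingSet(conditions, stacked, mean, dispersion, session_ids)
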