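"""Single-unit selectivity statistics.

A unit is called finger-selective when a one-way ANOVA across movement
conditions survives Benjamini-Hochberg FDR correction (q < 0.05) with
the correction applied across all m = N recorded units.  Effect size is
eta^2 = SS_between / SS_total, with eta^2 > 0.14 the conventional
"large" threshold.  Per-finger contrasts against the No-Go baseline use
Dunnett's many-to-one test (familywise 0.05) and bootstrap Hedges' g.
"""

from __future__ import annotations

from dataclasses import dataclass
from functools import lru_cache

import numpy as np
import pandas as pd
from scipy import stats

from .datasets import FINGERS, NOGO, TrialDataset
from .errors import ConfigError, DataError
from .seeding import stream

Q_THRESHOLD = 0.05
LARGE_ETA_SQ = 0.14
SELECTIVITY_RATE_THRESHOLD = 0.5  # Hz, whole-recording mean


def anova_selectivity(
    rates: np.ndarray, labels: np.ndarray
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """One-way fixed-effects ANOVA per unit, vectorized over units.

    ``rates`` is (trials,) or (trials, units); ``labels`` gives the
    condition of each trial.  Returns (F, p, eta^2) arrays.  Degenerate
    all-constant units are reported as F=0, p=1, eta^2=0 rather than
    raising, so population summaries stay computable; units with zero
    within-group variance but distinct group means get p=0, eta^2=1.
    """
    x = np.asarray(rates, dtype=float)
    squeeze = x.ndim == 1
    if squeeze:
        x = x[:, None]
    labels = np.asarray(labels)
    groups, codes = np.unique(labels, return_inverse=True)
    k, n = groups.size, x.shape[0]
    if k < 2:
        raise DataError("ANOVA needs >= 2 groups")
    counts = np.bincount(codes, minlength=k).astype(float)
    if np.any(counts < 2):
        raise DataError("ANOVA needs >= 2 trials in every group")

    grand = x.mean(axis=0)
    gsum = np.zeros((k, x.shape[1]))
    np.add.at(gsum, codes, x)
    gmean = gsum / counts[:, None]
    ss_between = (counts[:, None] * (gmean - grand) ** 2).sum(axis=0)
    ss_total = ((x - grand) ** 2).sum(axis=0)
    ss_within = ss_total - ss_between

    tiny = 1e-12 * np.maximum(1.0, np.abs(grand)) ** 2 * n
    F = np.full(x.shape[1], 0.0)
    p = np.ones(x.shape[1])
    eta2 = np.zeros(x.shape[1])

    ok = ss_total > tiny
    eta2[ok] = ss_between[ok] / ss_total[ok]
    with np.errstate(divide="ignore", invalid="ignore"):
        f_ok = (ss_between[ok] / (k - 1)) / (ss_within[ok] / (n - k))
    F[ok] = f_ok
    sep = ok & (ss_within <= tiny)          # perfectly separated groups
    F[sep] = np.inf
    p[ok] = stats.f.sf(F[ok], k - 1, n - k)
    p[sep] = 0.0
    eta2 = np.clip(eta2, 0.0, 1.0)
    if squeeze:
        return F[0], p[0], eta2[0]
    return F, p, eta2


def fdr_bh(p_values: np.ndarray, m: int | None = None) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted q-values.

    ``m`` is the number of comparisons corrected for (default
    ``len(p_values)``); it may exceed the number of supplied p-values —
    e.g. when correcting across all recorded units but tabulating a
    subset — but never be smaller.
    """
    p = np.asarray(p_values, dtype=float)
    if p.ndim != 1:
        raise DataError("p_values must be 1-D")
    if np.any((p < 0) | (p > 1) | ~np.isfinite(p)):
        raise DataError("p-values must lie in [0, 1]")
    if m is None:
        m = p.size
    if m < p.size:
        raise ConfigError(f"m={m} smaller than the number of p-values ({p.size})")
    order = np.argsort(p, kind="stable")
    ranked = p[order] * m / np.arange(1, p.size + 1)
    q_sorted = np.minimum.accumulate(ranked[::-1])[::-1]
    q = np.empty_like(p)
    q[order] = np.minimum(q_sorted, 1.0)
    return q


@lru_cache(maxsize=32)
def _dunnett_null_max_t(k: int, df: int, n_draws: int = 100_000) -> np.ndarray:
    """Monte Carlo null distribution of max_i |t_i| for a balanced
    many-to-one design with k treatment groups and residual df.

    Group-mean contrasts share the control sample, giving the classic
    0.5 correlation; the pooled variance is a scaled chi^2.  Fixed seed:
    the table is part of the method, not a per-run random quantity.
    """
    rng = stream(20_240_601, "dunnett-null", k, df)
    z0 = rng.standard_normal(n_draws)
    zi = rng.standard_normal((n_draws, k))
    s = np.sqrt(rng.chisquare(df, size=n_draws) / df)
    t = np.abs(zi - z0[:, None]) / (np.sqrt(2.0) * s[:, None])
    return np.sort(t.max(axis=1))


def dunnett_vs_nogo(
    rates: np.ndarray,
    labels: np.ndarray,
    control: str = NOGO,
    alpha: float = 0.05,
) -> pd.DataFrame:
    """Dunnett many-to-one comparisons of each finger against No-Go.

    Vectorized over units: ``rates`` may be (trials,) or (trials,
    units).  Adjusted p-values come from a seeded 100k-draw Monte Carlo
    null of the max-|t| statistic (balanced-design approximation with
    the harmonic-mean group size).  Returns a tidy frame with columns
    ``unit, group, t, p_adj, significant``.
    """
    x = np.asarray(rates, dtype=float)
    if x.ndim == 1:
        x = x[:, None]
    labels = np.asarray(labels)
    groups = [g for g in np.unique(labels) if g != control]
    if control not in labels:
        raise DataError(f"control group {control!r} missing")
    if not groups:
        raise DataError("need at least one non-control group")
    n0 = int((labels == control).sum())
    if n0 < 2:
        raise DataError(f"control group {control!r} needs >= 2 trials")

    ns = np.array([(labels == g).sum() for g in groups])
    if np.any(ns < 2):
        raise DataError("every group needs >= 2 trials")
    n_total = n0 + ns.sum()
    df = int(n_total - (len(groups) + 1))

    m0 = x[labels == control].mean(axis=0)
    ss = ((x[labels == control] - m0) ** 2).sum(axis=0)
    t_num = []
    for g, ng in zip(groups, ns):
        xg = x[labels == g]
        mg = xg.mean(axis=0)
        ss = ss + ((xg - mg) ** 2).sum(axis=0)
        t_num.append(mg - m0)
    s2 = ss / df
    s2 = np.maximum(s2, 1e-12)
    null = _dunnett_null_max_t(len(groups), df)

    rows = []
    for g, num, ng in zip(groups, t_num, ns):
        t = np.atleast_1d(num / np.sqrt(s2 * (1.0 / ng + 1.0 / n0)))
        p_adj = 1.0 - np.searchsorted(null, np.abs(t), side="left") / null.size
        p_adj = np.maximum(p_adj, 1.0 / null.size)
        for u in range(x.shape[1]):
            rows.append(
                {
                    "unit": u,
                    "group": g,
                    "t": float(t[u]),
                    "p_adj": float(p_adj[u]),
                    "significant": bool(p_adj[u] < alpha),
                }
            )
    return pd.DataFrame(rows)


def hedges_g(
    group_a: np.ndarray,
    group_b: np.ndarray,
    n_boot: int = 5000,
    seed: int = 0,
) -> tuple[float, tuple[float, float]]:
    """Hedges' g (bias-corrected standardized mean difference) of A - B
    with a nonparametric bootstrap percentile 95% CI."""
    a = np.asarray(group_a, dtype=float)
    b = np.asarray(group_b, dtype=float)
    if a.size < 2 or b.size < 2:
        raise DataError("both groups need >= 2 values")

    def g_of(a_, b_):
        na, nb = a_.shape[-1], b_.shape[-1]
        df = na + nb - 2
        va = a_.var(axis=-1, ddof=1)
        vb = b_.var(axis=-1, ddof=1)
        sp = np.sqrt(((na - 1) * va + (nb - 1) * vb) / df)
        J = 1.0 - 3.0 / (4.0 * df - 1.0)
        return J * (a_.mean(axis=-1) - b_.mean(axis=-1)) / sp

    sp_check = np.sqrt(
        ((a.size - 1) * a.var(ddof=1) + (b.size - 1) * b.var(ddof=1))
        / (a.size + b.size - 2)
    )
    if sp_check <= 0:
        raise DataError("zero pooled SD: effect size undefined")
    g = float(g_of(a, b))
    rng = stream(seed, "hedges-boot")
    ra = rng.choice(a, size=(n_boot, a.size), replace=True)
    rb = rng.choice(b, size=(n_boot, b.size), replace=True)
    with np.errstate(divide="ignore", invalid="ignore"):
        boots = g_of(ra, rb)
    boots = boots[np.isfinite(boots)]
    lo, hi = np.percentile(boots, [2.5, 97.5])
    return g, (float(lo), float(hi))


@dataclass
class SelectivityTable:
    """Per-unit statistics for one session and epoch."""

    session_id: str
    epoch: str
    table: pd.DataFrame  # unit_id, F, p, q, eta2, n per-finger columns


def selectivity_table(
    dataset: TrialDataset,
    epoch: str = "move",
    rate_threshold: float = SELECTIVITY_RATE_THRESHOLD,
    n_boot: int = 1000,
    seed: int = 0,
    with_effect_sizes: bool = True,
) -> list[SelectivityTable]:
    """Full per-unit selectivity statistics for every session.

    The FDR correction uses m = number of units passing the 0.5 Hz
    whole-recording rate screen, pooled across the dataset's sessions
    (one experiment-wide family per the m = N convention).
    """
    # first pass: ANOVA p-values for all screened units across sessions
    per_session = []
    for s in dataset.sessions:
        conds = s.conditions
        keep = s.rates.mean(axis=0) >= rate_threshold
        move_conds = conds  # includes nogo if present; ANOVA is across all cues
        F, p, eta2 = anova_selectivity(s.rates[:, keep], move_conds)
        per_session.append((s, keep, F, p, eta2))

    all_p = np.concatenate([p for (_, _, _, p, _) in per_session])
    q_all = fdr_bh(all_p, m=all_p.size)

    tables = []
    offset = 0
    for s, keep, F, p, eta2 in per_session:
        nk = int(keep.sum())
        q = q_all[offset: offset + nk]
        offset += nk
        rows = pd.DataFrame(
            {
                "unit_id": np.array(s.unit_ids)[keep],
                "F": F,
                "p": p,
                "q": q,
                "eta2": eta2,
                "selective": q < Q_THRESHOLD,
                "large_effect": eta2 > LARGE_ETA_SQ,
            }
        )
        conds = s.conditions
        if with_effect_sizes and NOGO in conds:
            dn = dunnett_vs_nogo(s.rates[:, keep], conds)
            nogo_rates = s.rates[conds == NOGO][:, keep]
            fingers_here = sorted(
                {f for f in s.labels["finger_type"].unique() if f != NOGO},
                key=FINGERS.index,
            )
            n_sig = np.zeros(nk, dtype=int)
            for f in fingers_here:
                cond_names = [c for c in np.unique(conds) if c.endswith("_" + f)]
                flags = np.zeros(nk, dtype=bool)
                for c in cond_names:
                    sub = dn[dn["group"] == c]
                    flags |= sub.sort_values("unit")["significant"].to_numpy()
                rows[f"dunnett_{f}"] = flags
                n_sig += flags
                g_vals, g_lo, g_hi = [], [], []
                for u in range(nk):
                    fr = s.rates[np.isin(conds, cond_names)][:, keep][:, u]
                    try:
                        g, (lo, hi) = hedges_g(
                            fr, nogo_rates[:, u], n_boot=n_boot,
                            seed=seed + 7919 * u,
                        )
                    except DataError:
                        g, lo, hi = np.nan, np.nan, np.nan
                    g_vals.append(g)
                    g_lo.append(lo)
                    g_hi.append(hi)
                rows[f"g_{f}"] = g_vals
                rows[f"g_{f}_lo"] = g_lo
                rows[f"g_{f}_hi"] = g_hi
            rows["n_significant_fingers"] = n_sig
        tables.append(SelectivityTable(s.session_id, epoch, rows))
    return tables


def selectivity_summary(
    tables: dict[str, list[SelectivityTable]]
) -> dict:
    """Pooled population summary across sessions and epochs.

    ``tables`` maps epoch name -> per-session tables.  Units are pooled
    across sessions.  Reports the percentage of selective units
    (q < 0.05), mean number of Dunnett-significant fingers (both among
    selective units and among all units), the complementary ECDF support
    of eta^2, the fraction of large effects, and plan/move overlap of
    strongly tuned units where both epochs are present.
    """
    if not tables:
        raise DataError("need at least one epoch table")
    out: dict = {"epochs": {}}
    strong: dict[str, set] = {}
    for epoch, tlist in tables.items():
        pooled = pd.concat([t.table for t in tlist], ignore_index=True)
        sel = pooled["selective"]
        rec = {
            "n_units": int(len(pooled)),
            "pct_selective": 100.0 * float(sel.mean()),
            "pct_large_effect": 100.0 * float(pooled["large_effect"].mean()),
            "eta2_sorted": np.sort(pooled["eta2"].to_numpy()),
        }
        if "n_significant_fingers" in pooled:
            rec["mean_sig_fingers_all"] = float(pooled["n_significant_fingers"].mean())
            rec["mean_sig_fingers_selective"] = (
                float(pooled.loc[sel, "n_significant_fingers"].mean())
                if sel.any()
                else float("nan")
            )
        out["epochs"][epoch] = rec
        strong[epoch] = {
            (t.session_id, uid)
            for t in tlist
            for uid in t.table.loc[
                t.table["selective"] & t.table["large_effect"], "unit_id"
            ]
        }
    if "plan" in strong and "move" in strong:
        out["overlap_plan_move"] = {
            "plan_only": len(strong["plan"] - strong["move"]),
            "move_only": len(strong["move"] - strong["plan"]),
            "both": len(strong["plan"] & strong["move"]),
        }
    return out


def eta2_ccdf(eta2_sorted: np.ndarray, x: float) -> float:
    """Complementary ECDF: fraction of units with eta^2 > x."""
    return float(np.mean(eta2_sorted > x))
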