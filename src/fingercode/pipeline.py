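"""End-to-end analysis pipeline: simulate -> selectivity -> decode ->
geometry -> CCGP, emitting one report directory of CSV tables.

Every table starts with comment lines recording the master seed and the
config hash, so each artifact is traceable; no timestamps are written,
so identical configs produce byte-identical reports.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import decode, factorize, geometry, io, selectivity, synthgen
from .datasets import TrialDataset
from .errors import ConfigError, FingercodeError
from .ratewin import RasterSet, canonical_epochs, windowed_dataset

log = logging.getLogger("fingercode")


@dataclass
class RunConfig:
    """Declarative configuration of one pipeline run."""

    input_path: str | None = None            # dataset dir; None => simulate
    generator: dict = field(default_factory=dict)  # GeneratorConfig overrides
    task_variant: str = "delay_task"
    epoch: str = "move"
    k_folds: int = 8
    decode_rate_threshold_hz: float = 1.0
    selectivity_rate_threshold_hz: float = 0.5
    q_threshold: float = 0.05
    eta2_threshold: float = 0.14
    learning_fractions: tuple = (0.2, 0.4, 0.6, 0.8, 1.0)
    ndc_unit_counts: tuple = ()              # empty => skip neuron dropping
    ndc_resamples: int = 40
    n_perm: int = 1001
    seed: int = 0
    output_path: str = "report"

    def __post_init__(self) -> None:
        for name in ("k_folds", "n_perm"):
            if getattr(self, name) < 0:
                raise ConfigError(f"{name} must be >= 0")
        for name in ("decode_rate_threshold_hz", "selectivity_rate_threshold_hz",
                     "q_threshold", "eta2_threshold"):
            if getattr(self, name) <= 0:
                raise ConfigError(f"{name} must be positive")

    def config_hash(self) -> str:
        # identifies the analysis, not where it is written
        fields = {k: v for k, v in asdict(self).items() if k != "output_path"}
        blob = json.dumps(fields, sort_keys=True, default=str)
        return hashlib.sha256(blob.encode()).hexdigest()[:12]


def _write_table(path: Path, df: pd.DataFrame, cfg: RunConfig, index=False) -> None:
    header = f"# seed={cfg.seed} config={cfg.config_hash()}\n"
    path.write_text(header + df.to_csv(index=index), encoding="utf-8")


def run_pipeline(cfg: RunConfig) -> dict:
    """Execute all stages; returns a summary dict of headline numbers."""
    out = Path(cfg.output_path)
    out.mkdir(parents=True, exist_ok=True)
    summary: dict = {"seed": cfg.seed, "config_hash": cfg.config_hash()}
    stage = "load"
    try:
        rasters: list[RasterSet] | None = None
        if cfg.input_path is None:
            stage = "simulate"
            gcfg = synthgen.GeneratorConfig(**{"seed": cfg.seed, **cfg.generator})
            tuning = synthgen.make_factorized_tuning(gcfg)
            dataset = synthgen.simulate_counts(tuning, gcfg)
            log.info("simulate: %d sessions x %d units, %d trials/session",
                     gcfg.n_sessions, gcfg.n_units_per_session,
                     dataset.sessions[0].n_trials)
        else:
            data = io.read_dataset(cfg.input_path)
            if isinstance(data, TrialDataset):
                dataset = data
            else:
                rasters = data
                epochs = canonical_epochs(cfg.task_variant)
                if cfg.epoch not in epochs:
                    raise ConfigError(
                        f"epoch {cfg.epoch!r} not defined for {cfg.task_variant!r}"
                    )
                dataset = windowed_dataset(rasters, epochs[cfg.epoch])
            log.info("load: %d sessions from %s", len(dataset.sessions), cfg.input_path)

        stage = "selectivity"
        tables = selectivity.selectivity_table(
            dataset, epoch=cfg.epoch,
            rate_threshold=cfg.selectivity_rate_threshold_hz,
            seed=cfg.seed,
        )
        pooled = pd.concat(
            [t.table.assign(session_id=t.session_id) for t in tables],
            ignore_index=True,
        )
        _write_table(out / "selectivity.csv", pooled, cfg)
        summ = selectivity.selectivity_summary({cfg.epoch: tables})
        epoch_summ = summ["epochs"][cfg.epoch]
        summary["pct_selective"] = epoch_summ["pct_selective"]
        summary["pct_large_effect"] = epoch_summ["pct_large_effect"]
        log.info("selectivity: %.1f%% of %d units q<%.2f",
                 epoch_summ["pct_selective"], epoch_summ["n_units"], cfg.q_threshold)

        stage = "decode"
        pooled_cm, acc, sd, per = decode.crossval_dataset(
            dataset, k=cfg.k_folds,
            rate_threshold=cfg.decode_rate_threshold_hz,
        )
        _write_table(out / "confusion_pooled.csv", pooled_cm.to_frame(), cfg, index=True)
        per_rows = pd.DataFrame(
            [{"session_id": c.session_id, "n_trials": c.n_trials,
              "accuracy": c.accuracy} for c in per]
        )
        _write_table(out / "accuracy_per_session.csv", per_rows, cfg)
        summary["decode_accuracy"] = acc
        summary["decode_accuracy_sd"] = sd
        n_classes = len(pooled_cm.classes)
        summary["decode_chance"] = 1.0 / n_classes
        err = decode.error_breakdown(
            pooled_cm,
            mode="ten_finger" if any("left" in c for c in pooled_cm.classes)
            else "within_hand",
        )
        _write_table(out / "error_breakdown.csv", pd.DataFrame([err]), cfg)
        summary.update({f"error_{k}": v for k, v in err.items()})
        log.info("decode: pooled accuracy %.3f (chance %.3f) over %d trials",
                 acc, 1.0 / n_classes, pooled_cm.n_trials)

        lc = decode.learning_curve(dataset, np.array(cfg.learning_fractions),
                                   k=cfg.k_folds)
        _write_table(out / "learning_curve.csv", lc.to_frame(), cfg)

        pseudo = None
        if len(dataset.sessions) > 1:
            pseudo = decode.build_pseudopopulation(dataset)
            if cfg.ndc_unit_counts:
                ndc = decode.neuron_dropping_curve(
                    pseudo, np.array(cfg.ndc_unit_counts),
                    n_resamples=cfg.ndc_resamples, k=cfg.k_folds, seed=cfg.seed,
                )
                _write_table(out / "neuron_dropping.csv", ndc.to_frame(), cfg)

        stage = "geometry"
        conds = dataset.condition_set()
        two_hands = any(c.startswith("left") for c in conds) and any(
            c.startswith("right") for c in conds
        )
        rdms = geometry.crossnobis_rdms(dataset, k=cfg.k_folds)
        mean_rdm = geometry.average_rdm(rdms)
        _write_table(out / "rdm_mean.csv", mean_rdm.to_frame(), cfg, index=True)
        if two_hands:
            diff, (lo, hi), pairs = geometry.matching_contrast(rdms, seed=cfg.seed)
            _write_table(out / "matching_contrast.csv", pairs, cfg)
            summary["matching_contrast"] = diff
            summary["matching_contrast_ci"] = (lo, hi)
            log.info("geometry: matching contrast %.3f [%.3f, %.3f]", diff, lo, hi)
        embeds, ids = [], []
        for rdm in rdms:
            coords, _ = geometry.mds_embed(rdm, dim=2, seed=cfg.seed)
            embeds.append(coords)
            ids.append(rdm.session_id)
        aligned = geometry.procrustes_align(embeds, ids, mean_rdm.conditions)
        coord_rows = []
        for si, sid in enumerate(aligned.session_ids):
            for ci, c in enumerate(aligned.conditions):
                coord_rows.append(
                    {"session_id": sid, "condition": c,
                     "x": aligned.coords[si, ci, 0], "y": aligned.coords[si, ci, 1]}
                )
        _write_table(out / "mds_coords.csv", pd.DataFrame(coord_rows), cfg)

        stage = "factorize"
        if two_hands:
            if cfg.n_perm == 0:
                log.info("factorize: n_perm=0, permutation test skipped")
            results = []
            for dim in ("hand", "finger_type"):
                res = factorize.ccgp_analysis(
                    dataset, dim, n_perm=cfg.n_perm, k=cfg.k_folds, seed=cfg.seed,
                    rate_threshold=cfg.decode_rate_threshold_hz,
                )
                results.append(res)
                summary[f"ccgp_{dim}"] = res.accuracy
                summary[f"ccgp_{dim}_bound"] = res.within_condition_bound
                summary[f"ccgp_{dim}_p"] = res.p_value
                log.info("factorize: %s CCGP %.3f (chance %.2f, bound %.3f)",
                         dim, res.accuracy, res.chance, res.within_condition_bound)
            _write_table(out / "ccgp.csv", factorize.ccgp_table(results), cfg)

        srows = pd.DataFrame([
            {"key": k, "value": json.dumps(v) if isinstance(v, (list, tuple)) else v}
            for k, v in summary.items()
        ])
        _write_table(out / "summary.csv", srows, cfg)
        return summary
    except FingercodeError as e:
        raise type(e)(f"stage {stage!r}: {e}") from e
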