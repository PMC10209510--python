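"""Dataset directory format: plain CSV plus a flat key=value manifest.

A dataset directory contains:

* ``trials.csv`` — session_id, trial_index, hand, finger_type,
  cue_variant and, for raster datasets, one column per phase onset plus
  trial_end;
* ``rates.csv`` — one row per trial (session_id, trial_index, then one
  column per unit id; units from other sessions are blank) for
  rate datasets, or
* ``spikes.csv`` — long form (session_id, trial_index, unit_id,
  spike_time_s) for raster datasets;
* ``units.csv`` — unit_id, session_id;
* ``manifest.txt`` — schema version, dataset kind, window provenance,
  generator seed/config when synthetic, and per-file SHA-256 checksums.

Everything is UTF-8, comma-separated, '.' decimal — inspectable and
language-portable.
"""

from __future__ import annotations

import hashlib
import json
import os
from pathlib import Path

import numpy as np
import pandas as pd

from .datasets import FINGERS, HANDS, NOGO, SessionData, TrialDataset
from .errors import DataError
from .ratewin import RasterSet

SCHEMA_VERSION = "1"
_VOCAB_HAND = set(HANDS)
_VOCAB_FINGER = set(FINGERS) | {NOGO}


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    h.update(path.read_bytes())
    return h.hexdigest()


def _write_atomic(path: Path, text: str) -> None:
    tmp = path.with_suffix(path.suffix + ".tmp")
    tmp.write_text(text, encoding="utf-8")
    os.replace(tmp, path)


def _check_vocab(trials: pd.DataFrame) -> None:
    bad_h = set(trials["hand"]) - _VOCAB_HAND
    if bad_h:
        raise DataError(
            f"unknown hand labels {sorted(bad_h)}; allowed: {sorted(_VOCAB_HAND)}"
        )
    bad_f = set(trials["finger_type"]) - _VOCAB_FINGER
    if bad_f:
        raise DataError(
            f"unknown finger labels {sorted(bad_f)}; allowed: {sorted(_VOCAB_FINGER)}"
        )


def write_manifest(path: Path, entries: dict) -> None:
    lines = [f"{k}={v}" for k, v in entries.items()]
    _write_atomic(path / "manifest.txt", "\n".join(lines) + "\n")


def read_manifest(path: Path) -> dict:
    mf = path / "manifest.txt"
    if not mf.exists():
        raise DataError(f"missing manifest.txt in {path}")
    out = {}
    for line in mf.read_text(encoding="utf-8").splitlines():
        if not line.strip():
            continue
        k, _, v = line.partition("=")
        out[k] = v
    return out


def write_dataset(
    data: TrialDataset | list[RasterSet],
    path: str | Path,
    seed: int | None = None,
    config: dict | None = None,
    overwrite: bool = False,
) -> dict:
    """Write a dataset directory; returns the manifest entries."""
    path = Path(path)
    if path.exists() and any(path.iterdir()) and not overwrite:
        raise DataError(
            f"output directory {path} is not empty (pass overwrite=True to replace)"
        )
    path.mkdir(parents=True, exist_ok=True)

    if isinstance(data, TrialDataset):
        kind = "rates"
        trial_rows, rate_rows = [], []
        all_units = [u for s in data.sessions for u in s.unit_ids]
        for s in data.sessions:
            for t in range(s.n_trials):
                lab = s.labels.iloc[t]
                trial_rows.append(
                    {
                        "session_id": s.session_id,
                        "trial_index": t,
                        "hand": lab["hand"],
                        "finger_type": lab["finger_type"],
                        "cue_variant": lab.get("cue_variant", ""),
                    }
                )
                row = {"session_id": s.session_id, "trial_index": t}
                row.update(dict(zip(s.unit_ids, s.rates[t])))
                rate_rows.append(row)
        trials = pd.DataFrame(trial_rows)
        rates = pd.DataFrame(rate_rows, columns=["session_id", "trial_index"] + all_units)
        units = pd.DataFrame(
            [{"unit_id": u, "session_id": s.session_id}
             for s in data.sessions for u in s.unit_ids]
        )
        _write_atomic(path / "trials.csv", trials.to_csv(index=False))
        _write_atomic(path / "rates.csv", rates.to_csv(index=False))
        _write_atomic(path / "units.csv", units.to_csv(index=False))
        data_files = ["trials.csv", "rates.csv", "units.csv"]
        window = data.window
    else:
        kind = "spikes"
        trial_rows, spike_rows, unit_rows = [], [], []
        for r in data:
            phase_cols = [c for c in r.phase_onsets.columns]
            for t in range(r.n_trials):
                lab = r.labels.iloc[t]
                row = {
                    "session_id": r.session_id,
                    "trial_index": t,
                    "hand": lab["hand"],
                    "finger_type": lab["finger_type"],
                    "cue_variant": lab.get("cue_variant", ""),
                }
                row.update({c: r.phase_onsets.iloc[t][c] for c in phase_cols})
                trial_rows.append(row)
                for uid, st in zip(r.unit_ids, r.spikes[t]):
                    for s_t in st:
                        spike_rows.append(
                            {
                                "session_id": r.session_id,
                                "trial_index": t,
                                "unit_id": uid,
                                "spike_time_s": s_t,
                            }
                        )
            unit_rows.extend(
                {"unit_id": u, "session_id": r.session_id} for u in r.unit_ids
            )
        _write_atomic(path / "trials.csv", pd.DataFrame(trial_rows).to_csv(index=False))
        _write_atomic(path / "spikes.csv", pd.DataFrame(spike_rows).to_csv(index=False))
        _write_atomic(path / "units.csv", pd.DataFrame(unit_rows).to_csv(index=False))
        data_files = ["trials.csv", "spikes.csv", "units.csv"]
        window = ""

    entries = {
        "schema_version": SCHEMA_VERSION,
        "kind": kind,
        "window": window,
    }
    if seed is not None:
        entries["seed"] = seed
    if config is not None:
        entries["config"] = json.dumps(config, sort_keys=True)
    for f in data_files:
        entries[f"sha256_{f}"] = _sha256(path / f)
    write_manifest(path, entries)
    return entries


def read_dataset(path: str | Path) -> TrialDataset | list[RasterSet]:
    """Read and validate a dataset directory written by :func:`write_dataset`."""
    path = Path(path)
    manifest = read_manifest(path)
    if manifest.get("schema_version") != SCHEMA_VERSION:
        raise DataError(
            f"unsupported schema version {manifest.get('schema_version')!r} "
            f"(expected {SCHEMA_VERSION})"
        )
    kind = manifest.get("kind")
    for fname in ("trials.csv", "units.csv"):
        if not (path / fname).exists():
            raise DataError(f"missing {fname} in {path}")
    trials = pd.read_csv(path / "trials.csv")
    units = pd.read_csv(path / "units.csv")
    _check_vocab(trials)
    unknown = set(trials["session_id"]) - set(units["session_id"])
    if unknown:
        raise DataError(f"trials reference unknown sessions: {sorted(unknown)}")

    if kind == "rates":
        if not (path / "rates.csv").exists():
            raise DataError(f"missing rates.csv in {path}")
        rates = pd.read_csv(path / "rates.csv")
        if len(rates) != len(trials):
            raise DataError(
                f"rates.csv has {len(rates)} rows but trials.csv has {len(trials)}"
            )
        sessions = []
        for sid, tgrp in trials.groupby("session_id", sort=False):
            uids = units.loc[units["session_id"] == sid, "unit_id"].tolist()
            rgrp = rates[rates["session_id"] == sid].sort_values("trial_index")
            tgrp = tgrp.sort_values("trial_index")
            if len(rgrp) != len(tgrp):
                raise DataError(
                    f"session {sid}: {len(rgrp)} rate rows vs {len(tgrp)} trial rows"
                )
            mat = rgrp[uids].to_numpy(dtype=float)
            if np.isnan(mat).any():
                raise DataError(f"session {sid}: missing rate values")
            sessions.append(
                SessionData(
                    sid,
                    mat,
                    tgrp[["hand", "finger_type", "cue_variant"]].reset_index(drop=True),
                    uids,
                )
            )
        return TrialDataset(sessions, window=manifest.get("window", ""),
                            meta={"manifest": manifest})

    if kind == "spikes":
        if not (path / "spikes.csv").exists():
            raise DataError(f"missing spikes.csv in {path}")
        spikes = pd.read_csv(path / "spikes.csv")
        phase_cols = [
            c for c in trials.columns
            if c not in ("session_id", "trial_index", "hand", "finger_type",
                         "cue_variant")
        ]
        if "trial_end" not in phase_cols:
            raise DataError("trials.csv of a spikes dataset must carry trial_end")
        rasters = []
        for sid, tgrp in trials.groupby("session_id", sort=False):
            uids = units.loc[units["session_id"] == sid, "unit_id"].tolist()
            uidx = {u: i for i, u in enumerate(uids)}
            tgrp = tgrp.sort_values("trial_index")
            n_tr = len(tgrp)
            spk = [[[] for _ in uids] for _ in range(n_tr)]
            sgrp = spikes[spikes["session_id"] == sid]
            bad_units = set(sgrp["unit_id"]) - set(uids)
            if bad_units:
                raise DataError(f"session {sid}: spikes for unknown units {sorted(bad_units)}")
            for (t, u), grp in sgrp.groupby(["trial_index", "unit_id"]):
                spk[int(t)][uidx[u]] = grp["spike_time_s"].tolist()
            rasters.append(
                RasterSet(
                    sid,
                    uids,
                    [[np.sort(np.asarray(ulist, dtype=float)) for ulist in trial]
                     for trial in spk],
                    tgrp[phase_cols].reset_index(drop=True),
                    tgrp[["hand", "finger_type", "cue_variant"]].reset_index(drop=True),
                )
            )
        return rasters

    raise DataError(f"unknown dataset kind {kind!r} in manifest")
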