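"""Trial-level data model, CSV readers/writers, configuration and reports.

File convention: plain UTF-8 CSV with a header, one trial per row, latencies
in milliseconds.  Model code works in seconds; the conversion happens at the
boundary between this module and the likelihood code.
"""
from __future__ import annotations

import dataclasses
import json
import logging
import zlib
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional

import numpy as np
import pandas as pd
import yaml

logger = logging.getLogger("gonogo_ddm")

GROUPS = ("PSP", "PD", "CONTROL")
CONDITIONS = ("GO", "NOGO")
SIDES = ("LEFT", "RIGHT")

REQUIRED_COLUMNS = ("participant_id", "group", "condition", "responded", "latency_ms")


class FormatError(ValueError):
    """Malformed input table (missing column, bad cell, inconsistent row)."""


@dataclass(frozen=True)
class TrialRecord:
    """One Go/No-Go trial.

    ``latency_ms`` is present iff ``responded`` and must lie in (0, 1500]
    (the response window closes at the 1500 ms deadline). ``valid`` marks
    trials that passed preprocessing; invalid trials are retained but never
    enter the likelihood or the behavioural measures.
    """

    participant_id: str
    group: str
    condition: str
    responded: bool
    latency_ms: Optional[float] = None
    target_side: Optional[str] = None
    valid: bool = True
    foreperiod_ms: Optional[float] = None  # cosmetic; never used downstream

    def __post_init__(self):
        if self.condition not in CONDITIONS:
            raise ValueError(f"unknown condition {self.condition!r}")
        if self.responded and self.latency_ms is None:
            raise ValueError("responded trial requires latency_ms")
        if not self.responded and self.latency_ms is not None:
            raise ValueError("withheld trial must not carry a latency")
        if self.target_side is not None and self.target_side not in SIDES:
            raise ValueError(f"unknown target_side {self.target_side!r}")


@dataclass
class StudyDataset:
    """Trials plus the participant roster (participant_id, group)."""

    trials: list[TrialRecord]
    participants: list[tuple[str, str]]

    def __post_init__(self):
        known = {p for p, _ in self.participants}
        for t in self.trials:
            if t.participant_id not in known:
                raise ValueError(f"trial references unknown participant {t.participant_id!r}")

    def group_of(self, pid: str) -> str:
        for p, g in self.participants:
            if p == pid:
                return g
        raise KeyError(pid)

    def trials_of(self, pid: str) -> list[TrialRecord]:
        return [t for t in self.trials if t.participant_id == pid]

    def to_frame(self) -> pd.DataFrame:
        rows = []
        for t in self.trials:
            rows.append({
                "participant_id": t.participant_id, "group": t.group,
                "condition": t.condition, "target_side": t.target_side or "",
                "responded": t.responded,
                "latency_ms": "" if t.latency_ms is None else t.latency_ms,
                "valid": t.valid,
                "foreperiod_ms": "" if t.foreperiod_ms is None else t.foreperiod_ms,
            })
        return pd.DataFrame(rows)


@dataclass
class PipelineConfig:
    """Run configuration; every random stage derives its stream from ``seed``."""

    seed: int = 0
    n_samples: int = 15000
    n_burnin: int = 5000
    variant: int = 4
    min_latency_ms: float = 50.0
    max_latency_ms: float = 1500.0
    n_ppc_sims: int = 500
    n_permutations: int = 100000
    classifier_c: float = 1.0
    output_dir: str = "output"

    def __post_init__(self):
        if not self.n_burnin < self.n_samples:
            raise ValueError("n_burnin must be smaller than n_samples")
        self.seed = int(self.seed)

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(raw) - known
        if unknown:
            raise FormatError(f"unknown config keys: {sorted(unknown)}")
        return cls(**raw)

    def stage_seed(self, stage: str) -> int:
        """Deterministic per-stage substream of the top-level seed."""
        tag = zlib.crc32(stage.encode("utf-8"))
        ss = np.random.SeedSequence([self.seed, tag])
        return int(ss.generate_state(1)[0] % (2 ** 31))


def _parse_bool(x, row):
    s = str(x).strip().lower()
    if s in ("true", "1", "yes"):
        return True
    if s in ("false", "0", "no"):
        return False
    raise FormatError(f"row {row}: cannot parse boolean {x!r}")


def read_trials(path, config: PipelineConfig | None = None) -> StudyDataset:
    """Read a trial CSV into a StudyDataset, applying the latency-bounds
    validity filter (default 50-1500 ms, emulating blink/artefact rejection).

    Target sides are read and retained but never used downstream (data are
    pooled over leftward and rightward targets).  Rows are numbered from 1
    (header excluded) in error messages.
    """
    config = config or PipelineConfig()
    df = pd.read_csv(path, dtype=str, keep_default_na=False)
    for col in REQUIRED_COLUMNS:
        if col not in df.columns:
            raise FormatError(f"missing required column {col!r}")
    trials = []
    for i, rec in enumerate(df.itertuples(index=False), start=1):
        responded = _parse_bool(rec.responded, i)
        lat_raw = str(rec.latency_ms).strip()
        latency = None
        if lat_raw != "":
            try:
                latency = float(lat_raw)
            except ValueError:
                raise FormatError(f"row {i}: malformed latency cell {lat_raw!r}") from None
        if not responded and latency is not None:
            raise FormatError(f"row {i}: latency present on a withheld trial")
        if responded and latency is None:
            raise FormatError(f"row {i}: responded trial without latency")
        if responded and not (0.0 < latency <= 1500.0):
            raise FormatError(f"row {i}: latency {latency} outside (0, 1500] ms")
        valid = True
        if "valid" in df.columns:
            valid = _parse_bool(getattr(rec, "valid"), i)
        if responded and not (config.min_latency_ms <= latency <= config.max_latency_ms):
            valid = False
        side = str(getattr(rec, "target_side", "")).strip() or None if "target_side" in df.columns else None
        fp = None
        if "foreperiod_ms" in df.columns:
            fp_raw = str(getattr(rec, "foreperiod_ms")).strip()
            fp = float(fp_raw) if fp_raw else None
        try:
            trials.append(TrialRecord(
                participant_id=str(rec.participant_id), group=str(rec.group),
                condition=str(rec.condition).strip().upper(), responded=responded,
                latency_ms=latency, target_side=side, valid=valid, foreperiod_ms=fp))
        except ValueError as e:
            raise FormatError(f"row {i}: {e}") from None
    roster = []
    seen = set()
    for t in trials:
        if t.participant_id not in seen:
            seen.add(t.participant_id)
            roster.append((t.participant_id, t.group))
    ds = StudyDataset(trials=trials, participants=roster)
    return drop_unusable_participants(ds)


def drop_unusable_participants(ds: StudyDataset) -> StudyDataset:
    """Drop participants lacking at least one valid trial per condition,
    with a logged warning (they cannot enter the hierarchical likelihood)."""
    keep = []
    for pid, grp in ds.participants:
        tr = [t for t in ds.trials if t.participant_id == pid and t.valid]
        n_go = sum(1 for t in tr if t.condition == "GO")
        n_nogo = sum(1 for t in tr if t.condition == "NOGO")
        if n_go >= 1 and n_nogo >= 1:
            keep.append((pid, grp))
        else:
            logger.warning("excluding participant %s: %d valid GO, %d valid NOGO trials",
                           pid, n_go, n_nogo)
    kept = {p for p, _ in keep}
    return StudyDataset(trials=[t for t in ds.trials if t.participant_id in kept],
                        participants=keep)


def write_trials(ds: StudyDataset, path) -> None:
    """Write a StudyDataset as CSV (exact round trip with read_trials)."""
    df = ds.to_frame()
    df.to_csv(path, index=False)


def _to_jsonable(obj):
    if isinstance(obj, (np.floating, np.integer)):
        return obj.item()
    if isinstance(obj, np.ndarray):
        return obj.tolist()
    if isinstance(obj, pd.DataFrame):
        return obj.to_dict(orient="list")
    if dataclasses.is_dataclass(obj) and not isinstance(obj, type):
        return {f.name: _to_jsonable(getattr(obj, f.name)) for f in dataclasses.fields(obj)}
    if isinstance(obj, dict):
        return {str(k): _to_jsonable(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_to_jsonable(v) for v in obj]
    return obj


def write_report(results: dict, path, config: PipelineConfig | None = None) -> Path:
    """Write a machine-readable summary of whatever stage outputs are present.

    ``results`` maps section names (e.g. "parameters", "dic", "classification")
    to DataFrames or dataclasses.  The config and seed are logged alongside so
    a re-run under the same settings is byte-identical.
    """
    if not results:
        raise ValueError("no stage outputs to report")
    outdir = Path(path)
    outdir.mkdir(parents=True, exist_ok=True)
    payload = {"config": _to_jsonable(config) if config else None,
               "sections": sorted(results)}
    for name, obj in results.items():
        if isinstance(obj, pd.DataFrame):
            obj.to_csv(outdir / f"{name}.csv", index=False, float_format="%.12g")
        payload[name] = _to_jsonable(obj)
    report = outdir / "report.json"
    with open(report, "w") as fh:
        json.dump(payload, fh, indent=2, sort_keys=True, default=str)
    return report
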