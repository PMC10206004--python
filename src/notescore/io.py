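"""File formats and run configuration.

Notes travel as line-delimited JSON records (one object per line with keys
note_id, patient_id, date, author_role, text); prescriptions and cognitive
scores as RFC-4180 CSV with ISO-8601 dates; flags as semicolon-joined
tokens.  Output CSVs carry the run's seed and config hash in a leading
"#" comment so results are traceable to their configuration.
"""

from __future__ import annotations

import dataclasses
import datetime as dt
import hashlib
import json
import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional, Sequence

import pandas as pd
import yaml

from .annotate import AUTHOR_ROLES, ClinicalNote
from .episodes import PrescriptionRecord, WASHOUT_DAYS
from .scoring import CognitiveScoreRecord, MMSE_WINDOW_DAYS, TARGET_DAYS

__all__ = [
    "RowError",
    "SchemaError",
    "RunConfig",
    "read_notes",
    "write_notes",
    "read_prescriptions",
    "write_prescriptions",
    "read_cognitive",
    "write_cognitive",
    "write_table",
    "read_table",
]


class SchemaError(ValueError):
    """A required column or key is missing."""


@dataclass(frozen=True)
class RowError:
    line: int
    message: str


@dataclass
class RunConfig:
    """Paths, constants and seed for one pipeline run."""

    notes_path: Optional[Path] = None
    prescriptions_path: Optional[Path] = None
    cognitive_path: Optional[Path] = None
    lexicon_path: Optional[Path] = None
    output_dir: Path = Path("notescore-output")
    washout_days: int = WASHOUT_DAYS
    target_days: int = TARGET_DAYS
    mmse_window_days: int = MMSE_WINDOW_DAYS
    bootstrap_reliability: int = 500
    bootstrap_correlation: int = 10_000
    seed: int = 0
    fail_fast: bool = True
    log_level: str = "INFO"

    def __post_init__(self) -> None:
        for name in ("washout_days", "target_days", "mmse_window_days",
                     "bootstrap_reliability", "bootstrap_correlation"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(raw) - known
        if unknown:
            raise SchemaError(f"unknown config keys: {sorted(unknown)}")
        for key in ("notes_path", "prescriptions_path", "cognitive_path",
                    "lexicon_path", "output_dir"):
            if key in raw and raw[key] is not None:
                raw[key] = Path(raw[key])
        return cls(**raw)

    def config_hash(self) -> str:
        """Hash of the run's constants and seed (paths excluded, so the
        same analysis written to two places carries the same hash)."""
        payload = json.dumps(
            {
                f.name: getattr(self, f.name)
                for f in dataclasses.fields(self)
                if not f.name.endswith(("_path", "_dir"))
            },
            sort_keys=True,
            default=str,
        )
        return hashlib.sha1(payload.encode()).hexdigest()[:12]


def _parse_date(value: str, line: int, column: str) -> dt.date:
    try:
        return dt.date.fromisoformat(str(value).strip())
    except ValueError as exc:
        raise ValueError(f"line {line}: bad {column} {value!r}: {exc}") from exc


# ---------------------------------------------------------------------------
# Notes (JSON lines)
# ---------------------------------------------------------------------------

_NOTE_KEYS = ("note_id", "patient_id", "date", "author_role", "text")


def read_notes(path, fail_fast: bool = True) -> tuple[list[ClinicalNote], list[RowError]]:
    """Read line-delimited note records.

    Unknown author roles map to "unknown" with a warning.  With
    ``fail_fast`` a bad row raises; otherwise it is collected and skipped.
    """
    notes: list[ClinicalNote] = []
    errors: list[RowError] = []
    with open(path, encoding="utf-8") as fh:
        for line_no, raw in enumerate(fh, start=1):
            raw = raw.strip()
            if not raw:
                continue
            try:
                obj = json.loads(raw)
                missing = [k for k in _NOTE_KEYS if k not in obj]
                if missing:
                    raise SchemaError(f"line {line_no}: missing keys {missing}")
                role = str(obj["author_role"]).strip().lower()
                if role not in AUTHOR_ROLES:
                    warnings.warn(
                        f"line {line_no}: unknown author_role {role!r} "
                        "mapped to 'unknown'",
                        stacklevel=2,
                    )
                    role = "unknown"
                notes.append(
                    ClinicalNote(
                        note_id=str(obj["note_id"]),
                        patient_id=str(obj["patient_id"]),
                        date=_parse_date(obj["date"], line_no, "date"),
                        author_role=role,
                        text=str(obj["text"]),
                    )
                )
            except SchemaError:
                raise
            except (ValueError, TypeError) as exc:
                if fail_fast:
                    raise ValueError(f"notes line {line_no}: {exc}") from exc
                errors.append(RowError(line_no, str(exc)))
    return notes, errors


def write_notes(notes: Sequence[ClinicalNote], path) -> None:
    with open(path, "w", encoding="utf-8") as fh:
        for n in notes:
            fh.write(
                json.dumps(
                    {
                        "note_id": n.note_id,
                        "patient_id": n.patient_id,
                        "date": n.date.isoformat(),
                        "author_role": n.author_role,
                        "text": n.text,
                    }
                )
                + "\n"
            )


# ---------------------------------------------------------------------------
# Prescriptions / cognitive scores (CSV)
# ---------------------------------------------------------------------------

_RX_REQUIRED = ("patient_id", "drug_name", "order_date")
_RX_OPTIONAL = (
    "reported_start_date",
    "reported_stop_date",
    "flags",
    "prior_snri_end_date",
    "record_id",
)


def read_prescriptions(
    path, fail_fast: bool = True
) -> tuple[list[PrescriptionRecord], list[RowError]]:
    df = pd.read_csv(path, dtype=str, comment="#").fillna("")
    missing = [c for c in _RX_REQUIRED if c not in df.columns]
    if missing:
        raise SchemaError(f"prescriptions missing columns {missing}")
    records: list[PrescriptionRecord] = []
    errors: list[RowError] = []
    for i, row in enumerate(df.itertuples(index=False), start=2):
        try:
            d = row._asdict()

            def opt_date(col: str) -> Optional[dt.date]:
                v = d.get(col, "")
                return _parse_date(v, i, col) if v else None

            records.append(
                PrescriptionRecord(
                    patient_id=d["patient_id"],
                    drug_name=d["drug_name"],
                    order_date=_parse_date(d["order_date"], i, "order_date"),
                    reported_start_date=opt_date("reported_start_date"),
                    reported_stop_date=opt_date("reported_stop_date"),
                    flags=frozenset(
                        t.strip() for t in d.get("flags", "").split(";") if t.strip()
                    ),
                    prior_snri_end_date=opt_date("prior_snri_end_date"),
                    record_id=d.get("record_id") or None,
                )
            )
        except ValueError as exc:
            if fail_fast:
                raise ValueError(f"prescriptions row {i}: {exc}") from exc
            errors.append(RowError(i, str(exc)))
    return records, errors


def write_prescriptions(records: Sequence[PrescriptionRecord], path) -> None:
    rows = [
        {
            "patient_id": r.patient_id,
            "drug_name": r.drug_name,
            "order_date": r.order_date.isoformat(),
            "reported_start_date": r.reported_start_date.isoformat()
            if r.reported_start_date
            else "",
            "reported_stop_date": r.reported_stop_date.isoformat()
            if r.reported_stop_date
            else "",
            "flags": ";".join(sorted(r.flags)),
            "prior_snri_end_date": r.prior_snri_end_date.isoformat()
            if r.prior_snri_end_date
            else "",
            "record_id": r.record_id or "",
        }
        for r in records
    ]
    pd.DataFrame(rows, columns=_RX_REQUIRED + _RX_OPTIONAL).to_csv(path, index=False)


def read_cognitive(
    path, fail_fast: bool = True
) -> tuple[list[CognitiveScoreRecord], list[RowError]]:
    df = pd.read_csv(path, dtype=str, comment="#").fillna("")
    required = ("patient_id", "date", "instrument", "raw_score")
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise SchemaError(f"cognitive scores missing columns {missing}")
    records: list[CognitiveScoreRecord] = []
    errors: list[RowError] = []
    for i, row in enumerate(df.itertuples(index=False), start=2):
        d = row._asdict()
        try:
            records.append(
                CognitiveScoreRecord(
                    patient_id=d["patient_id"],
                    date=_parse_date(d["date"], i, "date"),
                    instrument=d["instrument"].strip(),
                    raw_score=int(d["raw_score"]),
                )
            )
        except ValueError as exc:
            if fail_fast:
                raise ValueError(f"cognitive row {i}: {exc}") from exc
            errors.append(RowError(i, str(exc)))
    return records, errors


def write_cognitive(records: Sequence[CognitiveScoreRecord], path) -> None:
    rows = [
        {
            "patient_id": r.patient_id,
            "date": r.date.isoformat(),
            "instrument": r.instrument,
            "raw_score": r.raw_score,
        }
        for r in records
    ]
    pd.DataFrame(
        rows, columns=["patient_id", "date", "instrument", "raw_score"]
    ).to_csv(path, index=False)


# ---------------------------------------------------------------------------
# Output tables with provenance header
# ---------------------------------------------------------------------------

def write_table(df: pd.DataFrame, path, config: Optional[RunConfig] = None) -> None:
    """Write a CSV with a provenance comment line."""
    with open(path, "w", encoding="utf-8", newline="") as fh:
        if config is not None:
            fh.write(f"# seed={config.seed} config_hash={config.config_hash()}\n")
        df.to_csv(fh, index=False)


def read_table(path) -> pd.DataFrame:
    return pd.read_csv(path, comment="#")
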