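"""Schema-validated CSV/JSON plumbing shared by the pipelines.

CSV dialect: comma-separated, '.' decimal, UTF-8, '#' comment lines.
Concentration columns always carry an ``_M`` suffix and are in molar;
times are seconds; polarization is mP.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

log = logging.getLogger(__name__)

__all__ = [
    "TableSchema",
    "ParseError",
    "RunConfig",
    "read_table",
    "write_table",
    "write_json",
    "read_json",
    "run_report",
    "PLATE_SCHEMA",
    "ISOTHERM_SCHEMA",
    "DWELL_SCHEMA",
    "TRACE_SCHEMA",
]


class ParseError(ValueError):
    """A table failed schema validation; the message names the offence."""


@dataclass(frozen=True)
class TableSchema:
    name: str
    columns: tuple[str, ...]
    numeric: tuple[str, ...]


PLATE_SCHEMA = TableSchema(
    "fpcd_plate",
    ("condition_id", "competitor_M", "replicate", "time_s", "polarization_mP"),
    ("competitor_M", "time_s", "polarization_mP"),
)
ISOTHERM_SCHEMA = TableSchema(
    "isotherm", ("protein_M", "polarization_mP"), ("protein_M", "polarization_mP"),
)
DWELL_SCHEMA = TableSchema(
    "dwells",
    ("condition_id", "competitor_M", "duration_s", "censored"),
    ("competitor_M", "duration_s"),
)
TRACE_SCHEMA = TableSchema(
    "traces",
    ("particle_id", "channel", "frame", "intensity"),
    ("frame", "intensity"),
)


def read_table(path: str | Path, schema: TableSchema) -> pd.DataFrame:
    """Read a CSV, skipping '#' comments, and validate against ``schema``.

    Errors name the missing column or the first non-numeric cell with its
    line number.  Unit conventions are part of the column names (``_M``,
    ``_s``, ``_mP``), so a renamed column is treated as a unit mismatch.
    """
    path = Path(path)
    if not path.exists():
        raise ParseError(f"{path}: file does not exist")
    df = pd.read_csv(path, comment="#")
    missing = [c for c in schema.columns if c not in df.columns]
    if missing:
        raise ParseError(
            f"{path}: missing column(s) {missing} for schema '{schema.name}' "
            f"(unit suffixes _M/_s/_mP are required); found {list(df.columns)}"
        )
    for col in schema.numeric:
        coerced = pd.to_numeric(df[col], errors="coerce")
        bad = coerced.isna() & df[col].notna()
        if bad.any():
            # +2: one for the header, one for 1-based lines (comments shift this)
            line = int(bad.idxmax()) + 2
            raise ParseError(
                f"{path}: non-numeric value {df[col][bad.idxmax()]!r} in "
                f"column '{col}' near line {line}"
            )
        if coerced.isna().any():
            raise ParseError(f"{path}: empty cells in numeric column '{col}'")
        df[col] = coerced
    return df


def write_table(df: pd.DataFrame, path: str | Path, header_comment: str = "") -> None:
    """Write a CSV with an optional '#' header comment block."""
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    with open(path, "w", encoding="utf-8") as fh:
        for line in filter(None, header_comment.splitlines()):
            fh.write(f"# {line}\n")
        df.to_csv(fh, index=False)


class _NumpyEncoder(json.JSONEncoder):
    def default(self, obj):
        if isinstance(obj, (np.integer,)):
            return int(obj)
        if isinstance(obj, (np.floating,)):
            return float(obj)
        if isinstance(obj, np.ndarray):
            return obj.tolist()
        if dataclasses.is_dataclass(obj) and not isinstance(obj, type):
            return dataclasses.asdict(obj)
        return super().default(obj)


def write_json(obj, path: str | Path) -> None:
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    path.write_text(json.dumps(obj, indent=2, cls=_NumpyEncoder) + "\n",
                    encoding="utf-8")


def read_json(path: str | Path):
    return json.loads(Path(path).read_text(encoding="utf-8"))


# ---------------------------------------------------------------------------
# run configuration


_CONFIG_FIELDS = {
    "seed": 0,
    "out_dir": ".",
    "strict": False,
    "koff_convention": "initial_slope",  # or "rate"
    "robust_normalization": False,
    "dead_time_s": 90.0,
    "min_range_mP": 5.0,
    "delta_bic_threshold": 2.0,
    "ternary_window_s": 0.15,
    "sm_t_min_s": 0.4,
    "integrator_method": "LSODA",
    "integrator_rtol": 1e-8,
    "integrator_atol": 1e-12,
}


@dataclass
class RunConfig:
    """Validated stage parameters; unknown keys are rejected."""

    seed: int = 0
    out_dir: str = "."
    strict: bool = False
    koff_convention: str = "initial_slope"
    robust_normalization: bool = False
    dead_time_s: float = 90.0
    min_range_mP: float = 5.0
    delta_bic_threshold: float = 2.0
    ternary_window_s: float = 0.15
    sm_t_min_s: float = 0.4
    integrator_method: str = "LSODA"
    integrator_rtol: float = 1e-8
    integrator_atol: float = 1e-12
    extras: dict = field(default_factory=dict)

    @classmethod
    def from_dict(cls, d: dict) -> "RunConfig":
        unknown = set(d) - set(_CONFIG_FIELDS)
        if unknown:
            raise ParseError(f"unknown config key(s): {sorted(unknown)}; "
                             f"known: {sorted(_CONFIG_FIELDS)}")
        if "koff_convention" in d and d["koff_convention"] not in ("initial_slope", "rate"):
            raise ParseError("koff_convention must be 'initial_slope' or 'rate'")
        return cls(**d)

    @classmethod
    def from_file(cls, path: str | Path) -> "RunConfig":
        return cls.from_dict(read_json(path))

    def snapshot(self, out_dir: str | Path | None = None) -> Path:
        """Write the resolved configuration next to the outputs."""
        d = dataclasses.asdict(self)
        d.pop("extras")
        d["config_hash"] = hashlib.sha256(
            json.dumps(d, sort_keys=True).encode()
        ).hexdigest()[:16]
        target = Path(out_dir or self.out_dir) / "resolved_config.json"
        write_json(d, target)
        return target


# ---------------------------------------------------------------------------
# reporting


def run_report(results_dir: str | Path) -> dict:
    """Aggregate the JSON results in a directory into one summary.

    Counts model selections, collects footnote flags, and flags corrupted
    files; ``ok`` is False when anything failed to parse.
    """
    results_dir = Path(results_dir)
    files = sorted(results_dir.glob("*.json"))
    files = [f for f in files if f.name != "resolved_config.json"]
    if not files:
        raise FileNotFoundError(f"no result JSON files in {results_dir}")
    summary = {"n_results": 0, "model_counts": {}, "flags": [],
               "corrupted": [], "results": {}, "ok": True}
    for f in files:
        try:
            obj = read_json(f)
        except (json.JSONDecodeError, UnicodeDecodeError):
            summary["corrupted"].append(f.name)
            summary["ok"] = False
            continue
        summary["n_results"] += 1
        summary["results"][f.name] = obj
        sel = obj.get("selected") if isinstance(obj, dict) else None
        if sel:
            summary["model_counts"][sel] = summary["model_counts"].get(sel, 0) + 1
        for w in (obj.get("warnings") or []) if isinstance(obj, dict) else []:
            summary["flags"].append(f"{f.name}: {w}")
    return summary
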