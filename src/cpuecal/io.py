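"""Table formats, validation, and metadata-stamped CSV round trips.

Interchange format is plain CSV with ISO-8601 dates. Every emitted file starts
with ``#``-prefixed metadata lines (at minimum the run seed); readers skip
them. Months serialize as 'YYYY-MM'.
"""

from __future__ import annotations

import io as _io
import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .simulate import CAPTURE_COLUMNS, EFFORT_COLUMNS, SimConfig

PANEL_MONTH_COL = "month"


def write_table(df: pd.DataFrame, path, metadata: dict | None = None) -> None:
    """Write a CSV with '# key=value' metadata header lines."""
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    out = df.copy()
    for col in out.columns:
        if isinstance(out[col].dtype, pd.PeriodDtype):
            out[col] = out[col].astype(str)
        elif pd.api.types.is_datetime64_any_dtype(out[col]):
            out[col] = out[col].dt.strftime("%Y-%m-%d")
    buf = _io.StringIO()
    for key, value in (metadata or {}).items():
        buf.write(f"# {key}={value}\n")
    out.to_csv(buf, index=False)
    path.write_text(buf.getvalue())


def read_table(path, month_cols=(), date_cols=()) -> pd.DataFrame:
    df = pd.read_csv(path, comment="#")
    for col in month_cols:
        if col in df.columns:
            df[col] = pd.PeriodIndex(df[col], freq="M")
    for col in date_cols:
        if col in df.columns:
            df[col] = pd.to_datetime(df[col])
    return df


def read_metadata(path) -> dict:
    meta = {}
    with open(path) as fh:
        for line in fh:
            if not line.startswith("#"):
                break
            key, _, value = line.lstrip("# ").rstrip("\n").partition("=")
            meta[key] = value
    return meta


def write_captures(df, path, metadata=None):
    write_table(df[CAPTURE_COLUMNS], path, metadata)


def read_captures(path):
    return read_table(path, date_cols=("date",))


def write_effort(df, path, metadata=None):
    write_table(df[EFFORT_COLUMNS], path, metadata)


def read_effort(path):
    return read_table(path, date_cols=("date",))


def read_panel(path):
    return read_table(path, month_cols=(PANEL_MONTH_COL,))


def write_fits(fits: dict, path, metadata=None) -> None:
    """fits.json: mapping of fit label -> GLMFit.to_dict()."""
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    payload = {"metadata": metadata or {}, "fits": fits}
    path.write_text(json.dumps(payload, indent=2, sort_keys=True))


# ---------------------------------------------------------------------------
# validation

SEVERITIES = ("error", "warning")


@dataclass
class ValidationReport:
    violations: list = field(default_factory=list)  # (severity, row, message)

    def add(self, severity: str, row, message: str) -> None:
        self.violations.append((severity, row, message))

    @property
    def errors(self):
        return [v for v in self.violations if v[0] == "error"]

    @property
    def warnings(self):
        return [v for v in self.violations if v[0] == "warning"]

    def __bool__(self):  # truthy when clean
        return not self.errors


def validate_tables(
    captures: pd.DataFrame,
    effort: pd.DataFrame,
    config: SimConfig | None = None,
    svl_slack_mm: float = 15.0,
) -> ValidationReport:
    """Schema, referential-integrity, and sanity checks on the raw tables.

    Hard errors: missing columns, unparseable dates, unknown methods, capture
    nights without a matching effort record, location ids outside the
    geometry. Warnings: SVL decreasing between successive captures of one
    individual beyond *svl_slack_mm* (measurement noise tolerance).
    """
    report = ValidationReport()
    for name, df, required in (
        ("captures", captures, CAPTURE_COLUMNS),
        ("effort", effort, EFFORT_COLUMNS),
    ):
        missing = [c for c in required if c not in df.columns]
        if missing:
            report.add("error", None, f"{name} table missing columns {missing}")
    if report.errors:
        return report

    def _dates(df, name):
        try:
            return pd.to_datetime(df["date"])
        except (ValueError, TypeError) as err:
            report.add("error", None, f"unparseable dates in {name}: {err}")
            return None

    cap_dates = _dates(captures, "captures")
    eff_dates = _dates(effort, "effort")
    if cap_dates is None or eff_dates is None:
        return report

    for i, m in captures["method"].items():
        if m not in ("visual", "trap"):
            report.add("error", i, f"unknown capture method {m!r}")
    for i, m in effort["method"].items():
        if m not in ("visual", "trap"):
            report.add("error", i, f"unknown effort method {m!r}")
    for i, svl in captures["svl_mm"].items():
        if not np.isfinite(svl) or svl <= 0:
            report.add("error", i, f"non-positive or non-finite svl_mm {svl!r}")

    # every capture night needs an effort record of the same method
    eff_keys = set(zip(eff_dates.dt.normalize(), effort["method"]))
    for i, (d, m) in enumerate(zip(cap_dates.dt.normalize(), captures["method"])):
        if (d, m) not in eff_keys:
            report.add(
                "error", i, f"capture on {d.date()} ({m}) has no matching effort record"
            )

    if config is not None:
        for i, (m, loc) in enumerate(zip(captures["method"], captures["location_id"])):
            num = "".join(ch for ch in str(loc) if ch.isdigit())
            if not num:
                report.add("error", i, f"location id {loc!r} has no index")
                continue
            bound = config.n_transects if m == "visual" else config.n_traps
            if not 1 <= int(num) <= bound:
                report.add("error", i, f"location id {loc!r} outside geometry (1..{bound})")

    caps = captures.assign(_date=cap_dates).sort_values(["individual_id", "_date"])
    for iid, grp in caps.groupby("individual_id"):
        svl = grp["svl_mm"].to_numpy(float)
        drops = np.flatnonzero(np.diff(svl) < -svl_slack_mm)
        for j in drops:
            report.add(
                "warning",
                grp.index[j + 1],
                f"individual {iid}: SVL fell {svl[j]:.0f}->{svl[j+1]:.0f} mm between captures",
            )
    return report
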