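"""Delimited-text I/O for the four input tables and the result tables.

All tables are comma-separated UTF-8 with ISO-8601 timestamps and dot
decimals.  Readers validate headers against the schemas below, coerce
types, and reject malformed rows individually with line-numbered log
entries rather than failing the whole file.  A UTF-8 BOM and CRLF line
endings are tolerated transparently.
"""

from __future__ import annotations

import logging
from pathlib import Path
from typing import Optional, Sequence

import numpy as np
import pandas as pd

from .fluxes import BagSample, ClosureEvent

logger = logging.getLogger(__name__)


class SchemaError(ValueError):
    """Header does not match the expected table schema."""


# column name -> numeric? (non-numeric columns pass through as strings)
BAG_SCHEMA = {
    "chamber_id": False, "treatment": False, "timestamp": False,
    "analyzer_id": False, "t_fill_min": True, "conc_n2o_ppb": True,
    "d15n_alpha": True, "d15n_beta": True, "d18o": True,
    "air_temp_c": True, "pressure_pa": True, "chamber_height_m": True,
}
VWC_SCHEMA = {"timestamp": False, "plot_id": False, "vwc": True}
WEATHER_SCHEMA = {"date": False, "tmin_c": True, "tmax_c": True,
                  "precip_mm": True}
MODEL_DAILY_SCHEMA = {"date": False, "n2o_total": True, "n2o_nit": True,
                      "n2o_denit": True, "n2": True, "wfps_sim": True}

#: columns that may be empty per-row without rejecting the row
_OPTIONAL_VALUES = {"d15n_alpha", "d15n_beta", "d18o"}


def read_table(path, schema: dict[str, bool],
               row_check=None) -> pd.DataFrame:
    """Read and validate one delimited table.

    ``row_check(row) -> str | None`` may veto individual rows with a
    reason; vetoed and unparseable rows are dropped with a log entry
    naming the 1-based file line.
    """
    df = pd.read_csv(path, encoding="utf-8-sig")
    df.columns = [c.strip() for c in df.columns]
    missing = set(schema) - set(df.columns)
    if missing:
        raise SchemaError(
            f"{path}: missing mandatory column(s) {sorted(missing)}")
    bad = pd.Series(False, index=df.index)
    reasons: dict[int, str] = {}
    for col, numeric in schema.items():
        if not numeric:
            continue
        coerced = pd.to_numeric(df[col], errors="coerce")
        invalid = coerced.isna() & df[col].notna()
        if col not in _OPTIONAL_VALUES:
            invalid |= df[col].isna()
        for idx in df.index[invalid & ~bad]:
            reasons[idx] = f"unparseable {col}"
        bad |= invalid
        df[col] = coerced
    if row_check is not None:
        for idx, row in df[~bad].iterrows():
            reason = row_check(row)
            if reason:
                reasons[idx] = reason
                bad[idx] = True
    for idx in sorted(reasons):
        logger.warning("%s line %d rejected: %s", path, idx + 2, reasons[idx])
    return df[~bad].reset_index(drop=True)


def _bag_row_check(row) -> Optional[str]:
    if row["conc_n2o_ppb"] <= 0:
        return "non-positive N2O concentration"
    if row["t_fill_min"] <= 0:
        return "non-positive fill time"
    return None


def read_bag_table(path) -> pd.DataFrame:
    return read_table(path, BAG_SCHEMA, row_check=_bag_row_check)


def read_vwc_table(path) -> pd.DataFrame:
    return read_table(path, VWC_SCHEMA,
                      row_check=lambda r: "negative VWC" if r["vwc"] < 0 else None)


def read_weather_table(path) -> pd.DataFrame:
    return read_table(path, WEATHER_SCHEMA)


def read_model_daily_table(path) -> pd.DataFrame:
    return read_table(path, MODEL_DAILY_SCHEMA)


def events_to_table(events: Sequence[ClosureEvent]) -> pd.DataFrame:
    """Flatten closure events to the bag-sample table layout."""
    rows = []
    for ev in events:
        for bag in ev.bags:
            rows.append(dict(
                chamber_id=ev.chamber_id, treatment=ev.treatment,
                timestamp=ev.timestamp.isoformat(),
                analyzer_id=bag.analyzer_id, t_fill_min=bag.t_fill,
                conc_n2o_ppb=bag.conc_n2o, d15n_alpha=bag.d15a,
                d15n_beta=bag.d15b, d18o=bag.d18o,
                air_temp_c=ev.air_temp, pressure_pa=ev.pressure,
                chamber_height_m=ev.chamber_height))
    return pd.DataFrame(rows, columns=list(BAG_SCHEMA))


def table_to_events(df: pd.DataFrame) -> list[ClosureEvent]:
    """Group bag rows by (chamber, closure timestamp) into closure events."""
    events = []
    for (chamber, ts), sub in df.groupby(["chamber_id", "timestamp"], sort=True):
        sub = sub.sort_values(["analyzer_id", "t_fill_min"])
        bags = [BagSample(t_fill=row["t_fill_min"], conc_n2o=row["conc_n2o_ppb"],
                          d15a=_nan_to_none(row["d15n_alpha"]),
                          d15b=_nan_to_none(row["d15n_beta"]),
                          d18o=_nan_to_none(row["d18o"]),
                          analyzer_id=str(row["analyzer_id"]))
                for _, row in sub.iterrows()]
        first = sub.iloc[0]
        events.append(ClosureEvent(
            chamber_id=str(chamber), treatment=str(first["treatment"]),
            timestamp=pd.Timestamp(ts).to_pydatetime(), bags=bags,
            air_temp=float(first["air_temp_c"]),
            pressure=float(first["pressure_pa"]),
            chamber_height=float(first["chamber_height_m"])))
    events.sort(key=lambda e: (e.timestamp, e.chamber_id))
    return events


def _nan_to_none(x) -> Optional[float]:
    return None if pd.isna(x) else float(x)


def write_table(df: pd.DataFrame, path) -> Path:
    """Write a result table deterministically (fixed float format, LF)."""
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    df.to_csv(path, index=False, float_format="%.10g", lineterminator="\n")
    return path
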