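"""CSV readers/writers for sensor logs, NDVI series and epoch tables.

Sensor logs follow the field-logger layout: a row counter, the three
probe readings and an ISO-8601 timestamp. All files are plain CSV.
"""

from __future__ import annotations

import json
from dataclasses import asdict
from pathlib import Path

import pandas as pd

from .synthetic import TruthParams

SOIL_HEADER = ["no", "st_c", "smc_pct", "sec_us_cm", "timestamp"]


def write_soil_csv(soil: pd.DataFrame, path) -> None:
    out = pd.DataFrame(
        {
            "no": range(1, len(soil) + 1),
            "st_c": soil["st"].round(6),
            "smc_pct": soil["smc"].round(6),
            "sec_us_cm": soil["sec"].round(6),
            "timestamp": pd.to_datetime(soil["timestamp"]).dt.strftime(
                "%Y-%m-%dT%H:%M:%S"
            ),
        }
    )
    out.to_csv(path, index=False)


def read_soil_csv(path) -> pd.DataFrame:
    raw = pd.read_csv(path)
    missing = set(SOIL_HEADER) - set(raw.columns)
    if missing:
        raise ValueError(f"{path}: missing soil-log columns {sorted(missing)}")
    return pd.DataFrame(
        {
            "timestamp": pd.to_datetime(raw["timestamp"]),
            "st": raw["st_c"].astype(float),
            "smc": raw["smc_pct"].astype(float),
            "sec": raw["sec_us_cm"].astype(float),
        }
    )


def write_ndvi_csv(ndvi: pd.DataFrame, path) -> None:
    out = pd.DataFrame(
        {
            "date": pd.to_datetime(ndvi["date"]).dt.strftime("%Y-%m-%d"),
            "ndvi": ndvi["ndvi"].round(8),
        }
    )
    out.to_csv(path, index=False)


def read_ndvi_csv(path) -> pd.DataFrame:
    raw = pd.read_csv(path)
    if not {"date", "ndvi"}.issubset(raw.columns):
        raise ValueError(f"{path}: NDVI CSV needs columns date, ndvi")
    return pd.DataFrame(
        {"date": pd.to_datetime(raw["date"]), "ndvi": raw["ndvi"].astype(float)}
    )


def write_epoch_table(table: pd.DataFrame, path) -> None:
    out = table.copy()
    out["date"] = pd.to_datetime(out["date"]).dt.strftime("%Y-%m-%d")
    out.to_csv(path, index=False)


def read_epoch_table(path) -> pd.DataFrame:
    table = pd.read_csv(path)
    table["date"] = pd.to_datetime(table["date"])
    return table


def write_truth(truth: TruthParams, path) -> None:
    Path(path).write_text(json.dumps(asdict(truth), indent=2) + "\n")


def read_truth(path) -> TruthParams:
    payload = json.loads(Path(path).read_text())
    for key in ("sst", "ssmc", "ssec", "ternary"):
        payload[key] = tuple(payload[key])
    return TruthParams(**payload)
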