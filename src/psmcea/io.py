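"""CSV/JSON dialects shared by the pipeline stages.

IPD files carry columns ``time,event,arm,endpoint,subgroup`` (time in
cycles, event in {0,1}); KM curves are ``time,surv``; risk tables are
``time,n_at_risk``. Every CSV the pipeline writes opens with a provenance
comment (config hash + seed) so outputs are traceable to their inputs.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd

from .km import KMCurve, RiskTable

IPD_COLUMNS = ["time", "event", "arm", "endpoint", "subgroup"]


def write_csv(df: pd.DataFrame, path, header_comment: str | None = None) -> None:
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    with open(path, "w") as fh:
        if header_comment:
            fh.write(f"# {header_comment}\n")
        df.to_csv(fh, index=False, float_format="%.10g", lineterminator="\n")


def read_csv(path) -> pd.DataFrame:
    return pd.read_csv(path, comment="#")


def write_ipd(df: pd.DataFrame, path, header_comment: str | None = None) -> None:
    write_csv(df[IPD_COLUMNS], path, header_comment)


def read_ipd(path) -> pd.DataFrame:
    df = read_csv(path)
    missing = set(IPD_COLUMNS) - set(df.columns)
    if missing:
        raise ValueError(f"{path}: IPD file missing columns {sorted(missing)}")
    return df


def write_km_curve(curve: KMCurve, path, header_comment: str | None = None) -> None:
    write_csv(curve.to_frame(), path, header_comment)


def read_km_curve(path) -> KMCurve:
    df = read_csv(path)
    return KMCurve(df["time"].to_numpy(), df["surv"].to_numpy())


def write_risk_table(risk: RiskTable, path, header_comment: str | None = None) -> None:
    write_csv(
        pd.DataFrame({"time": risk.times, "n_at_risk": risk.n_at_risk}), path, header_comment
    )


def read_risk_table(path) -> RiskTable:
    df = read_csv(path)
    return RiskTable(df["time"].to_numpy(), df["n_at_risk"].to_numpy())


def write_json(obj, path) -> None:
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)

    def default(o):
        if isinstance(o, (np.floating, np.integer)):
            return o.item()
        if isinstance(o, np.ndarray):
            return o.tolist()
        raise TypeError(f"not JSON serializable: {type(o)}")

    path.write_text(json.dumps(obj, indent=2, sort_keys=True, default=default) + "\n")
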