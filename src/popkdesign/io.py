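"""Dataset and report I/O.

Datasets are exchanged as NONMEM-style long-format CSV: one dosing record
(EVID=1, AMT set) followed by observation records (EVID=0, DV set) per
subject, with covariate columns WT, AGE and a GROUP label.  A tidy dialect
(one observation row per record, AMT carried on every row) is also
supported.  Times are hours internally; an explicit ``time_unit`` flag
converts minutes exactly on read/write.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd

from .simulate import REQUIRED_COLUMNS, TrialDataset

NONMEM_COLUMNS = ("ID", "TIME", "DV", "AMT", "EVID", "WT", "AGE", "GROUP")


def _to_hours(t, unit: str):
    if unit == "hours":
        return t
    if unit == "minutes":
        return t / 60.0
    raise ValueError(f"unknown time unit {unit!r}")


def write_dataset(ds: TrialDataset, path, dialect: str = "nonmem",
                  time_unit: str = "hours") -> None:
    """Write a trial dataset as CSV (``nonmem`` or ``tidy`` dialect)."""
    path = Path(path)
    df = ds.df.copy()
    factor = 60.0 if time_unit == "minutes" else 1.0
    if dialect == "tidy":
        df["TIME"] = df["TIME"] * factor
        df.to_csv(path, index=False)
    elif dialect == "nonmem":
        rows = []
        for sid, sub in df.groupby("ID", sort=True):
            first = sub.iloc[0]
            rows.append({"ID": sid, "TIME": 0.0, "DV": ".",
                         "AMT": first["AMT"], "EVID": 1, "WT": first["WT"],
                         "AGE": first["AGE"], "GROUP": first["GROUP"]})
            for _, r in sub.sort_values("TIME").iterrows():
                rows.append({"ID": sid, "TIME": r["TIME"] * factor, "DV": r["DV"],
                             "AMT": ".", "EVID": 0, "WT": r["WT"],
                             "AGE": r["AGE"], "GROUP": r["GROUP"]})
        pd.DataFrame(rows, columns=list(NONMEM_COLUMNS)).to_csv(path, index=False)
    else:
        raise ValueError(f"unknown dialect {dialect!r}")
    meta = {"dialect": dialect, "time_unit": time_unit,
            "group_scaling": ds.group_scaling}
    path.with_suffix(path.suffix + ".meta.json").write_text(json.dumps(meta))


def read_dataset(path, dialect: str = None, time_unit: str = None) -> TrialDataset:
    """Read a dataset CSV; validates required columns and basic sanity."""
    path = Path(path)
    meta_path = path.with_suffix(path.suffix + ".meta.json")
    meta = json.loads(meta_path.read_text()) if meta_path.exists() else {}
    dialect = dialect or meta.get("dialect", "nonmem")
    time_unit = time_unit or meta.get("time_unit", "hours")
    df = pd.read_csv(path)

    if dialect == "nonmem":
        missing = [c for c in ("ID", "TIME", "DV", "AMT", "EVID") if c not in df.columns]
        if missing:
            raise ValueError(f"dataset missing column(s) {missing}")
        for c in ("WT", "AGE"):
            if c not in df.columns:
                df[c] = np.nan
        if "GROUP" not in df.columns:
            df["GROUP"] = ""
        doses = df[df["EVID"] == 1].set_index("ID")["AMT"].astype(float)
        obs = df[df["EVID"] == 0].copy()
        obs["DV"] = pd.to_numeric(obs["DV"], errors="coerce")
        if obs["DV"].isna().any():
            raise ValueError("non-numeric DV in observation records")
        obs["AMT"] = obs["ID"].map(doses)
        if obs["AMT"].isna().any():
            raise ValueError("observation subject without a dosing record")
        out = obs[["ID", "GROUP", "TIME", "DV", "AMT", "WT", "AGE"]].copy()
    elif dialect == "tidy":
        missing = [c for c in REQUIRED_COLUMNS if c not in df.columns]
        if missing:
            raise ValueError(f"dataset missing column(s) {missing}")
        out = df[list(REQUIRED_COLUMNS)].copy()
    else:
        raise ValueError(f"unknown dialect {dialect!r}")

    out["TIME"] = _to_hours(out["TIME"].astype(float), time_unit)
    if (out["DV"].astype(float) < 0).any():
        raise ValueError("negative DV values")
    mono = out.groupby("ID")["TIME"].apply(lambda s: bool((s.diff().dropna() >= 0).all()))
    if not mono.all():
        raise ValueError("non-monotone within-subject times")
    return TrialDataset(df=out.reset_index(drop=True),
                        group_scaling=meta.get("group_scaling", {}))


def write_json(obj, path) -> None:
    Path(path).write_text(json.dumps(obj, indent=2, default=_json_default))


def _json_default(o):
    if isinstance(o, (np.floating, np.integer)):
        return o.item()
    if isinstance(o, np.ndarray):
        return o.tolist()
    if isinstance(o, pd.DataFrame):
        return o.to_dict(orient="records")
    raise TypeError(f"not JSON serialisable: {type(o)}")
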