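"""Schema-validated readers for the standards / candidates / features tables.

CSV dialect: UTF-8, comma separator, ``.`` decimal, mandatory header; a
``.tsv``/``.txt`` extension switches to tab separation. Units are fixed in
the column names (rt_min, ccs_A2, mz) to prevent silent unit errors.
Row-level problems are collected into a rejects frame, never silently
dropped.
"""

from __future__ import annotations

import pathlib

import numpy as np
import pandas as pd

from .annotator import Feature
from .chem_core import MetaboliteRecord, normalize_adduct_label
from .errors import SchemaError

STANDARDS_COLUMNS = ["id", "name", "formula", "smiles", "adduct", "polarity", "mz", "ccs_A2", "rt_min"]
CANDIDATES_COLUMNS = ["id", "name", "formula", "smiles"]
FEATURES_COLUMNS = ["feature_id", "mz", "polarity", "rt_min"]


def _read_table(path) -> pd.DataFrame:
    path = pathlib.Path(path)
    sep = "\t" if path.suffix.lower() in (".tsv", ".txt") else ","
    return pd.read_csv(path, sep=sep)


def _require(df: pd.DataFrame, columns: list[str], what: str) -> None:
    missing = [c for c in columns if c not in df.columns]
    if missing:
        raise SchemaError(f"{what} table missing mandatory column(s): {', '.join(missing)}")


def read_standards(path) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Standards table with measured Rt/CCS per (compound, adduct).

    Returns (valid, rejects); rejected rows carry a ``reject_reason``.
    """
    df = _read_table(path)
    _require(df, STANDARDS_COLUMNS, "standards")
    reasons = pd.Series("", index=df.index)
    reasons[df["rt_min"] < 0] = "negative rt_min"
    reasons[df["ccs_A2"] <= 0] = "non-positive ccs_A2"
    reasons[df["mz"] <= 0] = "non-positive mz"
    reasons[~df["polarity"].isin(["positive", "negative"])] = "bad polarity"
    reasons[df["smiles"].isna() | (df["smiles"].astype(str).str.len() == 0)] = "empty smiles"
    bad = reasons != ""
    rejects = df[bad].assign(reject_reason=reasons[bad])
    good = df[~bad].copy()
    good["adduct"] = good["adduct"].map(normalize_adduct_label)
    return good.reset_index(drop=True), rejects.reset_index(drop=True)


def read_candidates(path) -> tuple[list[MetaboliteRecord], pd.DataFrame]:
    """Candidate metabolite list -> records; unusable rows go to rejects."""
    df = _read_table(path)
    _require(df, CANDIDATES_COLUMNS, "candidates")
    records, rej = [], []
    for _, row in df.iterrows():
        rec = MetaboliteRecord.from_row(row["id"], row["name"], row["formula"], row["smiles"])
        if rec.usable:
            records.append(rec)
        else:
            rej.append({**row.to_dict(), "reject_reason": "unparseable formula or structure"})
    return records, pd.DataFrame(rej)


def read_features(path) -> tuple[list[Feature], pd.DataFrame]:
    """Untargeted feature table -> Feature objects; invalid rows rejected."""
    df = _read_table(path)
    _require(df, FEATURES_COLUMNS, "features")
    feats, rej = [], []
    for _, row in df.iterrows():
        try:
            ccs = row.get("ccs_A2", np.nan)
            feats.append(
                Feature(
                    feature_id=str(row["feature_id"]),
                    mz=float(row["mz"]),
                    polarity=str(row["polarity"]),
                    rt=float(row["rt_min"]),
                    ccs=None if pd.isna(ccs) else float(ccs),
                    intensity=float(row.get("intensity", 0.0) or 0.0),
                )
            )
        except (ValueError, TypeError) as exc:
            rej.append({**row.to_dict(), "reject_reason": str(exc)})
    return feats, pd.DataFrame(rej)


def read_smiles_list(path) -> list[tuple[str, str]]:
    """Plain-text SMILES list: one per line, optional tab-separated id."""
    out = []
    for i, line in enumerate(pathlib.Path(path).read_text().splitlines()):
        line = line.strip()
        if not line or line.startswith("#"):
            continue
        parts = line.split("\t")
        smi = parts[0]
        ident = parts[1] if len(parts) > 1 else f"S{i}"
        out.append((ident, smi))
    return out
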