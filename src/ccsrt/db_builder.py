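"""Assembly of the predicted (metabolite, adduct) annotation database.

One row per (metabolite, adduct): m/z from exact adduct arithmetic, CCS from
the cluster-regression model, Rt from the QSRR model. Rt is a property of the
neutral molecule, so it is computed once per metabolite and repeated across
its adduct rows; every adduct row of one metabolite shares the Rt but has its
own CCS. Measured standards, when supplied, override predictions row-by-row
(``source="measured"``), reflecting that matches against authentic standards
carry the highest identification confidence.
"""

from __future__ import annotations

import io
import logging

import numpy as np
import pandas as pd

from . import chem_core
from .ccs_cluster import CcsModel, _predict_one
from .chem_core import DEFAULT_ADDUCTS, MetaboliteRecord, adduct_mz, get_adduct
from .errors import MergeError, PredictionUnavailable, StructureError
from .rt_qsrr import RtModel, predict_rt

logger = logging.getLogger(__name__)

DB_COLUMNS = [
    "metabolite_id", "name", "formula", "adduct", "polarity",
    "mz", "ccs_A2", "rt_min", "ccs_flag", "rt_flag", "source",
]

#: Fixed CSV float formats: m/z to 4 decimals, CCS to 2, Rt to 3.
_FLOAT_FORMATS = {"mz": "{:.4f}", "ccs_A2": "{:.2f}", "rt_min": "{:.3f}"}


def build_database(
    candidates: list[MetaboliteRecord],
    ccs_model: CcsModel,
    rt_model: RtModel,
    adducts: tuple[str, ...] | list[str] = DEFAULT_ADDUCTS,
    polarity: str | None = None,
    chunk_size: int = 10_000,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Predicted database rows for every candidate x applicable adduct.

    ``polarity`` restricts the adduct set to one ionization mode. Returns
    (database, rejects); a candidate whose structure fails or whose
    descriptors are incomplete contributes no rows and one reject record.
    Rt predictions outside [0, run_length] are clipped to the boundary and
    flagged, never dropped.
    """
    specs = [get_adduct(a) for a in adducts]
    specs = [a for a in specs if a.label in ccs_model.adduct_labels]
    if polarity is not None:
        specs = [a for a in specs if a.polarity == polarity]
    rows, rejects = [], []
    n_clipped = 0
    for start in range(0, len(candidates), chunk_size):
        for met in candidates[start : start + chunk_size]:
            if not met.usable:
                rejects.append({"metabolite_id": met.id, "reason": "unusable record (formula/structure)"})
                continue
            try:
                rt, rt_flag = predict_rt(rt_model, met.smiles)
                dv = chem_core.compute_descriptors(met.smiles)
            except (PredictionUnavailable, StructureError) as exc:
                rejects.append({"metabolite_id": met.id, "reason": str(exc)})
                continue
            clipped = min(max(rt, 0.0), rt_model.run_length)
            if clipped != rt:
                rt_flag = True
                n_clipped += 1
            try:
                for add in specs:
                    mz = adduct_mz(met.neutral_mass, add)
                    ccs, ccs_flag = _predict_one(ccs_model, dv.values, mz, add.label)
                    rows.append(
                        {
                            "metabolite_id": met.id,
                            "name": met.name,
                            "formula": met.formula,
                            "adduct": add.label,
                            "polarity": add.polarity,
                            "mz": mz,
                            "ccs_A2": ccs,
                            "rt_min": clipped,
                            "ccs_flag": ccs_flag,
                            "rt_flag": rt_flag,
                            "source": "predicted",
                        }
                    )
            except PredictionUnavailable as exc:
                rejects.append({"metabolite_id": met.id, "reason": str(exc)})
    if n_clipped:
        logger.info("clipped %d Rt predictions to the chromatographic window", n_clipped)
    db = pd.DataFrame(rows, columns=DB_COLUMNS)
    rej = pd.DataFrame(rejects, columns=["metabolite_id", "reason"])
    return db, rej


def merge_measured(db: pd.DataFrame, measured: pd.DataFrame) -> pd.DataFrame:
    """Measured standards override predicted rows on (metabolite_id, adduct).

    Output row count = len(db) + new measured keys − overlapping keys.
    Duplicate measured keys with conflicting values raise MergeError listing
    the offending keys. Idempotent for a fixed measured table.
    """
    if measured.empty:
        return db.copy()
    measured = measured.copy()
    measured["source"] = "measured"
    for col in DB_COLUMNS:
        if col not in measured.columns:
            measured[col] = False if col in ("ccs_flag", "rt_flag") else np.nan
    measured = measured[DB_COLUMNS]
    keys = list(zip(measured["metabolite_id"], measured["adduct"]))
    dup_mask = measured.duplicated(subset=["metabolite_id", "adduct"], keep=False)
    if dup_mask.any():
        dups = measured[dup_mask].drop_duplicates(subset=["metabolite_id", "adduct", "mz", "ccs_A2", "rt_min"])
        conflict = dups.duplicated(subset=["metabolite_id", "adduct"], keep=False)
        if conflict.any():
            bad = sorted(set(zip(dups.loc[conflict, "metabolite_id"], dups.loc[conflict, "adduct"])))
            raise MergeError(f"conflicting duplicate measured rows for keys: {bad}")
        measured = measured.drop_duplicates(subset=["metabolite_id", "adduct"], keep="first")
        keys = list(zip(measured["metabolite_id"], measured["adduct"]))
    db_keys = set(zip(db["metabolite_id"], db["adduct"]))
    overlap = [k in db_keys for k in keys]
    keep_db = db[~pd.Series(list(zip(db["metabolite_id"], db["adduct"])), index=db.index).isin(set(keys))]
    out = pd.concat([keep_db, measured], ignore_index=True)
    logger.info("merged %d measured rows (%d overriding predictions)", len(measured), sum(overlap))
    return out.reset_index(drop=True)


def write_database(db: pd.DataFrame, path) -> None:
    """Write the database CSV with fixed column order and float formatting,
    so write -> read -> write is byte-identical."""
    out = db[DB_COLUMNS].copy()
    for col, fmt in _FLOAT_FORMATS.items():
        out[col] = out[col].map(lambda v, f=fmt: "" if pd.isna(v) else f.format(v))
    out.to_csv(path, index=False)


def read_database(path) -> pd.DataFrame:
    df = pd.read_csv(path, dtype={"metabolite_id": str, "name": str, "formula": str})
    missing = [c for c in DB_COLUMNS if c not in df.columns]
    if missing:
        from .errors import SchemaError

        raise SchemaError(f"database file missing columns: {missing}")
    for col in ("ccs_flag", "rt_flag"):
        df[col] = df[col].astype(bool)
    return df[DB_COLUMNS]


def database_csv_bytes(db: pd.DataFrame) -> bytes:
    buf = io.StringIO()
    write_database(db, buf)
    return buf.getvalue().encode()
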