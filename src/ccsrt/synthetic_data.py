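"""Synthetic standards libraries, candidate databases, and feature tables.

The generator stands in for a commercial standards plate and an untargeted
toxicology feature export, with full ground truth so every pipeline stage is
testable without any download. The statistical structure mirrors what the
analysis assumes:

* Retention follows a logistic function of a standardized
  hydrophobicity-dominated descriptor combination, mapped into the
  chromatographic window [0.7, 17.0] min — polar compounds elute early,
  lipids late, as on a reversed-phase T3 column.
* CCS follows a per-class square-root mass law, CCS = A_c * (M + shift)^0.5
  + delta_adduct, with the latent class c given by the compound's chemical
  family (polar / aromatic / lipid), so classes are genuinely separated in
  descriptor space.
* Measurement noise is Gaussian: Rt SD 0.3 min, CCS SD 2 Å², m/z jitter
  1 mDa by default.

Feature simulation plants three kinds of rows: true features (database rows
plus small jitter), decoy database rows (within the m/z window of a feature
but displaced beyond at least one of the CCS/Rt windows by a 1.5x factor),
and noise features matching nothing. The bookkeeping in
:class:`SyntheticTruth` records every intended pairing, so filter evaluation
is against construction, not circularity.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from rdkit import Chem
from rdkit.Chem import Crippen, rdMolDescriptors
from rdkit.Chem.rdMolDescriptors import CalcMolFormula

from ._structure_pool import structure_pool
from .annotator import MatchStrategy
from .chem_core import (
    DEFAULT_ADDUCTS,
    MEASURED_ADDUCTS,
    MetaboliteRecord,
    adduct_mz,
    get_adduct,
)
from .errors import DecoyConstructionError

# Chromatographic window of the emulated gradient (min).
RT_LOWER = 0.7
RT_UPPER = 17.0
RUN_LENGTH = 23.0

# Per-class CCS power-law coefficients, Å² / Da^0.5. Classes are ordered
# (polar, aromatic, lipid); a compact polar metabolite packs tighter than an
# extended lipid of the same mass, hence increasing A_c.
CLASS_NAMES = ("polar", "aromatic", "lipid")
DEFAULT_A = {"polar": 9.0, "aromatic": 10.2, "lipid": 11.8}
DEFAULT_B = 0.5
# Per-adduct CCS offsets (Å²): heavier/bulkier cation adducts ride higher.
DEFAULT_DELTA = {
    "[M+H]+": 0.0, "[M+Na]+": 2.0, "[M+K]+": 3.0, "[M+NH4]+": 1.5, "[M]+": -0.5,
    "[M-H]-": -1.0, "[M+Na-2H]-": 1.0, "[M+Cl]-": 2.5, "[M+HCOO]-": 3.5,
    "[M+CH3COO]-": 4.5, "[M]-": -0.5,
}

DEFAULT_RT_NOISE = 0.3  # min
DEFAULT_CCS_NOISE = 2.0  # Å²
DEFAULT_MZ_JITTER = 0.001  # Th
#: Fraction of standards flagged descriptor-incomplete (exercises exclusion).
DESCRIPTOR_INCOMPLETE_FRACTION = 7 / 204


@dataclass
class SyntheticTruth:
    """Ground truth for one generated library / feature table."""

    rt_params: dict  # logistic Rt law: weights over (logP, TPSA), L, U, w
    ccs_params: dict  # A per class, b, delta per adduct
    noise: dict  # rt_noise, ccs_noise, mz_jitter
    classes: dict[str, str] = field(default_factory=dict)  # metabolite id -> class
    true_rt: dict[str, float] = field(default_factory=dict)
    true_ccs: dict[tuple[str, str], float] = field(default_factory=dict)
    descriptor_incomplete: set[str] = field(default_factory=set)
    true_pairs: pd.DataFrame | None = None  # feature_id -> (metabolite_id, adduct)
    decoy_rows: pd.DataFrame | None = None


def _hydrophobicity_z(mols: list[Chem.Mol]) -> np.ndarray:
    """Standardized hydrophobicity-dominated combination: 0.8*z(logP) +
    0.2*z(-TPSA). Drives the synthetic retention law."""
    logp = np.array([Crippen.MolLogP(m) for m in mols])
    tpsa = np.array([rdMolDescriptors.CalcTPSA(m) for m in mols])

    def z(v):
        s = v.std()
        return (v - v.mean()) / (s if s > 0 else 1.0)

    return 0.8 * z(logp) + 0.2 * z(-tpsa)


def true_rt_from_z(z: np.ndarray, L: float = RT_LOWER, U: float = RT_UPPER, w: float = 1.6) -> np.ndarray:
    return L + (U - L) / (1.0 + np.exp(-w * z))


def generate_library(n: int, seed: int = 0) -> tuple[list[MetaboliteRecord], SyntheticTruth]:
    """Sample n structures from the bundled pool and assign ground truth.

    Latent CCS class = chemical family of the pooled structure. True Rt is the
    logistic law of the hydrophobicity score (bounded in [0.7, 17.0] min);
    true CCS per adduct is the per-class square-root mass law. A small
    fraction of records is flagged descriptor-incomplete in the truth so the
    downstream exclusion path is exercised.
    """
    if n <= 0:
        raise ValueError("n must be positive")
    pool = structure_pool()
    if n > len(pool):
        raise ValueError(f"n={n} exceeds structure pool size {len(pool)}")
    rng = np.random.default_rng(seed)
    idx = rng.choice(len(pool), size=n, replace=False)
    chosen = [pool[i] for i in idx]
    mols = [Chem.MolFromSmiles(s) for _, s, _ in chosen]
    z = _hydrophobicity_z(mols)
    rt_true = true_rt_from_z(z)
    records: list[MetaboliteRecord] = []
    truth = SyntheticTruth(
        rt_params={"L": RT_LOWER, "U": RT_UPPER, "w": 1.6, "combination": "0.8*z(logP)+0.2*z(-TPSA)"},
        ccs_params={"A": dict(DEFAULT_A), "b": DEFAULT_B, "delta": dict(DEFAULT_DELTA)},
        noise={
            "rt_noise": DEFAULT_RT_NOISE,
            "ccs_noise": DEFAULT_CCS_NOISE,
            "mz_jitter": DEFAULT_MZ_JITTER,
        },
    )
    for k, ((name, smi, family), mol) in enumerate(zip(chosen, mols)):
        mid = f"SYN{k:04d}"
        formula = CalcMolFormula(mol)
        # strip any charge annotation from zwitterionic formulas
        formula = formula.replace("+", "").replace("-", "")
        rec = MetaboliteRecord.from_row(mid, name, formula, smi)
        records.append(rec)
        truth.classes[mid] = family
        truth.true_rt[mid] = float(rt_true[k])
        A = truth.ccs_params["A"][family]
        for adduct in DEFAULT_ADDUCTS:
            spec = get_adduct(adduct)
            m_ion = rec.neutral_mass + spec.mass_shift
            truth.true_ccs[(mid, spec.label)] = float(
                A * m_ion**DEFAULT_B + truth.ccs_params["delta"][spec.label]
            )
    n_incomplete = int(round(DESCRIPTOR_INCOMPLETE_FRACTION * n))
    if n_incomplete:
        marked = rng.choice(n, size=n_incomplete, replace=False)
        truth.descriptor_incomplete = {records[i].id for i in marked}
    return records, truth


def simulate_measurements(
    library: list[MetaboliteRecord],
    truth: SyntheticTruth,
    seed: int = 0,
    adducts: tuple[str, ...] = MEASURED_ADDUCTS,
    adduct_prob: float = 0.8,
) -> pd.DataFrame:
    """Measured standards table: one Rt per compound, one CCS per observed
    (compound, adduct).

    Columns: id, name, formula, smiles, adduct, polarity, mz, ccs_A2, rt_min,
    descriptor_incomplete. Each compound is observed with each adduct with
    probability ``adduct_prob`` (at least one adduct always retained).
    Gaussian noise: Rt SD ``truth.noise['rt_noise']``, CCS SD
    ``truth.noise['ccs_noise']``.
    """
    rng = np.random.default_rng(seed)
    rt_noise = truth.noise["rt_noise"]
    ccs_noise = truth.noise["ccs_noise"]
    rows = []
    for rec in library:
        rt_meas = truth.true_rt[rec.id] + (rng.normal(0, rt_noise) if rt_noise > 0 else 0.0)
        drawn = [a for a in adducts if rng.random() < adduct_prob]
        if not drawn:
            drawn = [adducts[int(rng.integers(len(adducts)))]]
        for adduct in drawn:
            spec = get_adduct(adduct)
            ccs_meas = truth.true_ccs[(rec.id, spec.label)] + (
                rng.normal(0, ccs_noise) if ccs_noise > 0 else 0.0
            )
            rows.append(
                {
                    "id": rec.id,
                    "name": rec.name,
                    "formula": rec.formula,
                    "smiles": rec.smiles,
                    "adduct": spec.label,
                    "polarity": spec.polarity,
                    "mz": adduct_mz(rec.neutral_mass, spec),
                    "ccs_A2": ccs_meas,
                    "rt_min": rt_meas,
                    "descriptor_incomplete": rec.id in truth.descriptor_incomplete,
                }
            )
    return pd.DataFrame(rows)


def simulate_feature_table(
    db: pd.DataFrame,
    truth: SyntheticTruth,
    n_true: int,
    n_decoy: int,
    n_noise: int,
    seed: int = 0,
    strategy: MatchStrategy | None = None,
    displacement_factor: float = 1.5,
) -> tuple[pd.DataFrame, pd.DataFrame, pd.DataFrame]:
    """Features + augmented database + truth labels.

    Returns (features, db_with_decoys, labels):

    * n_true features are distinct-metabolite database rows jittered by
      N(0, 1 mDa) in m/z, N(0, 0.1 min) in Rt, N(0, 1 Å²) in CCS — small
      against any realistic tolerance, so a correct filter keeps them.
    * n_decoy extra database rows are planted within the m/z window of a true
      feature but displaced by >= displacement_factor x tolerance in CCS, Rt,
      or both, so a correct filter removes them while an m/z-only strategy
      hits them.
    * n_noise features match nothing within the m/z window.

    ``labels`` has one row per feature (kind in {true, noise}) with the
    intended (metabolite_id, adduct) for true features; decoy rows are listed
    in ``truth.decoy_rows`` and carry ids DECOY####.
    """
    strategy = strategy or MatchStrategy(use_ccs=True, use_rt=True)
    rng = np.random.default_rng(seed)
    mz_jit, rt_jit, ccs_jit = truth.noise["mz_jitter"], 0.1, 1.0
    distinct = db.drop_duplicates(subset="metabolite_id")
    if n_true > len(distinct):
        raise ValueError(f"n_true={n_true} exceeds distinct metabolites in db ({len(distinct)})")

    feat_rows, label_rows = [], []
    chosen_mets = rng.choice(distinct["metabolite_id"].to_numpy(), size=n_true, replace=False)
    for i, mid in enumerate(chosen_mets):
        sub = db[db["metabolite_id"] == mid]
        row = sub.iloc[int(rng.integers(len(sub)))]
        fid = f"F{i:04d}"
        feat_rows.append(
            {
                "feature_id": fid,
                "mz": row["mz"] + rng.normal(0, mz_jit),
                "polarity": row["polarity"],
                "rt_min": max(0.0, row["rt_min"] + rng.normal(0, rt_jit)),
                "ccs_A2": row["ccs_A2"] + rng.normal(0, ccs_jit),
                "intensity": float(rng.lognormal(10, 1)),
            }
        )
        label_rows.append(
            {"feature_id": fid, "kind": "true", "metabolite_id": mid, "adduct": row["adduct"]}
        )

    decoy_rows = []
    if n_decoy and not feat_rows:
        raise DecoyConstructionError("cannot plant decoys without any true feature")
    for j in range(n_decoy):
        feat = feat_rows[j % len(feat_rows)]
        mode = rng.integers(3)  # 0: ccs off, 1: rt off, 2: both off
        ccs = feat["ccs_A2"]
        rt = feat["rt_min"]
        if mode in (0, 2):
            ccs = ccs + rng.choice([-1, 1]) * displacement_factor * strategy.ccs_tol
            if ccs <= 0:
                ccs = feat["ccs_A2"] + displacement_factor * strategy.ccs_tol
        if mode in (1, 2):
            shift = displacement_factor * strategy.rt_tol
            rt = rt + shift if rt + shift <= RUN_LENGTH or rt - shift < 0 else rt - shift
            if rt < 0:
                raise DecoyConstructionError("decoy Rt window exhausted")
        decoy_rows.append(
            {
                "metabolite_id": f"DECOY{j:04d}",
                "name": f"decoy {j}",
                "formula": "",
                "adduct": feat_polarity_adduct(feat["polarity"]),
                "polarity": feat["polarity"],
                "mz": feat["mz"] + rng.uniform(-0.4, 0.4) * strategy.mz_window(feat["mz"]),
                "ccs_A2": ccs,
                "rt_min": rt,
                "ccs_flag": False,
                "rt_flag": False,
                "source": "predicted",
            }
        )

    all_mz = np.sort(db["mz"].to_numpy())
    lo_mz, hi_mz = all_mz.min(), all_mz.max()
    for k in range(n_noise):
        for _ in range(1000):
            mz = rng.uniform(lo_mz, hi_mz)
            pos = np.searchsorted(all_mz, mz)
            near = min(
                abs(mz - all_mz[max(0, pos - 1)]),
                abs(mz - all_mz[min(len(all_mz) - 1, pos)]),
            )
            if near > 2 * strategy.mz_window(mz):
                break
        else:
            raise DecoyConstructionError("could not place a noise feature away from db rows")
        fid = f"N{k:04d}"
        feat_rows.append(
            {
                "feature_id": fid,
                "mz": mz,
                "polarity": "positive" if rng.random() < 0.5 else "negative",
                "rt_min": float(rng.uniform(RT_LOWER, RT_UPPER)),
                "ccs_A2": float(rng.uniform(110, 260)),
                "intensity": float(rng.lognormal(9, 1)),
            }
        )
        label_rows.append({"feature_id": fid, "kind": "noise", "metabolite_id": "", "adduct": ""})

    features = pd.DataFrame(feat_rows)
    decoys = pd.DataFrame(decoy_rows, columns=db.columns if decoy_rows else None)
    db_aug = pd.concat([db, decoys], ignore_index=True) if decoy_rows else db.copy()
    labels = pd.DataFrame(label_rows)
    truth.true_pairs = labels[labels["kind"] == "true"].copy()
    truth.decoy_rows = decoys
    return features, db_aug, labels


def feat_polarity_adduct(polarity: str) -> str:
    return "[M+H]+" if polarity == "positive" else "[M-H]-"


def write_simulation(out_dir, library, truth, measured: pd.DataFrame, features: pd.DataFrame | None = None, labels: pd.DataFrame | None = None) -> None:
    """Emit standards/candidates CSVs (and optional features + labels)."""
    import pathlib

    out = pathlib.Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    cand = pd.DataFrame(
        [{"id": r.id, "name": r.name, "formula": r.formula, "smiles": r.smiles} for r in library]
    )
    cand.to_csv(out / "candidates.csv", index=False)
    measured.to_csv(out / "standards.csv", index=False)
    if features is not None:
        features.to_csv(out / "features.csv", index=False)
    if labels is not None:
        labels.to_csv(out / "truth_labels.csv", index=False)
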