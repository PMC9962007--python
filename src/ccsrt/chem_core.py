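"""Structure handling, molecular descriptors, and monoisotopic/adduct mass arithmetic.

All masses are monoisotopic (most-abundant isotope per element), never average.
Adduct mass shifts are derived from elemental compositions plus the electron
mass, so every shift constant is consistent with :func:`monoisotopic_mass` by
construction. m/z values are conventionally reported to 4 decimal places and
neutral masses to 6; nothing here rounds — formatting happens at I/O time.
"""

from __future__ import annotations

import math
import re
from dataclasses import dataclass, field

import numpy as np
from pyteomics import mass as _ptmass
from rdkit import Chem, RDLogger
from rdkit.Chem import Descriptors

from .errors import AdductError, FormulaError, StructureError

RDLogger.DisableLog("rdApp.*")

#: Rest mass of the electron, Da (CODATA).
ELECTRON_MASS = 0.00054857990924

_FORMULA_TOKEN = re.compile(r"([A-Z][a-z]?)(\d*)")
_FORMULA_VALID = re.compile(r"^(?:[A-Z][a-z]?\d*)+$")


def parse_formula(formula: str) -> dict[str, int]:
    """Parse a Hill-notation elemental formula into an element -> count map.

    Charges, isotope labels, parentheses and dots are rejected rather than
    guessed at; every count must be >= 1.
    """
    if not formula or not _FORMULA_VALID.match(formula):
        raise FormulaError(f"unparseable formula: {formula!r}")
    counts: dict[str, int] = {}
    for el, num in _FORMULA_TOKEN.findall(formula):
        if el not in _ptmass.nist_mass:
            raise FormulaError(f"unknown element {el!r} in formula {formula!r}")
        counts[el] = counts.get(el, 0) + (int(num) if num else 1)
    return counts


def monoisotopic_mass(formula: str) -> float:
    """Monoisotopic mass (Da) of a Hill-notation formula.

    Sum over elements of most-abundant-isotope mass x count; the isotope mass
    table is NIST-derived (>= 9 significant decimals).
    """
    counts = parse_formula(formula)
    return sum(_ptmass.nist_mass[el][0][0] * n for el, n in counts.items())


@dataclass(frozen=True)
class AdductSpec:
    """An ionization adduct: what is added/removed and the resulting charge.

    ``mass_shift`` already includes the electron-mass correction, so
    m/z = (M + mass_shift) / charge_magnitude for the singly-charged adducts
    supported here.
    """

    label: str
    polarity: str  # "positive" | "negative"
    charge_magnitude: int
    mass_shift: float

    def __post_init__(self):
        if self.polarity not in ("positive", "negative"):
            raise AdductError(f"bad polarity {self.polarity!r}")
        if self.charge_magnitude < 1:
            raise AdductError("charge magnitude must be >= 1")
        if not math.isfinite(self.mass_shift):
            raise AdductError("mass shift must be finite")


def _shift(added: str | None, removed: str | None, charge: int) -> float:
    """Mass shift for (add `added`, remove `removed`, net charge `charge`)."""
    s = 0.0
    if added:
        s += monoisotopic_mass(added)
    if removed:
        s -= monoisotopic_mass(removed)
    return s - charge * ELECTRON_MASS


#: (added formula, removed formula, signed charge) per supported adduct label.
_ADDUCT_RECIPES: dict[str, tuple[str | None, str | None, int]] = {
    "[M+H]+": ("H", None, +1),
    "[M+Na]+": ("Na", None, +1),
    "[M+K]+": ("K", None, +1),
    "[M+NH4]+": ("NH4", None, +1),
    "[M]+": (None, None, +1),
    "[M-H]-": (None, "H", -1),
    "[M+Na-2H]-": ("Na", "H2", -1),
    "[M+Cl]-": ("Cl", None, -1),
    "[M+HCOO]-": ("CHO2", None, -1),
    "[M+CH3COO]-": ("C2H3O2", None, -1),
    "[M]-": (None, None, -1),
}

#: Vendor-notation aliases; "[M+CH3OO]-" is the acetate adduct in Unifi exports.
ADDUCT_ALIASES = {"[M+CH3OO]-": "[M+CH3COO]-", "[M+HCOOH-H]-": "[M+HCOO]-"}

ADDUCTS: dict[str, AdductSpec] = {
    label: AdductSpec(
        label=label,
        polarity="positive" if charge > 0 else "negative",
        charge_magnitude=abs(charge),
        mass_shift=_shift(add, rem, charge),
    )
    for label, (add, rem, charge) in _ADDUCT_RECIPES.items()
}

#: Adducts measured on the travelling-wave IMS platform (vendor software set).
MEASURED_ADDUCTS = ("[M+H]+", "[M+K]+", "[M+Na]+", "[M+Cl]-", "[M+HCOO]-", "[M+CH3COO]-")
#: Adducts covered by the cluster-based CCS predictor.
PREDICTED_ADDUCTS = (
    "[M+H]+", "[M+K]+", "[M+Na]+", "[M+Na-2H]-", "[M+NH4]+", "[M]+", "[M-H]-", "[M]-",
)
#: Default database adduct set: union of measured and predicted sets.
DEFAULT_ADDUCTS = tuple(dict.fromkeys(MEASURED_ADDUCTS + PREDICTED_ADDUCTS))


def normalize_adduct_label(label: str) -> str:
    lab = label.strip().replace("−", "-").replace(" ", "")
    return ADDUCT_ALIASES.get(lab, lab)


def get_adduct(label: str) -> AdductSpec:
    lab = normalize_adduct_label(label)
    try:
        return ADDUCTS[lab]
    except KeyError:
        raise AdductError(f"unsupported adduct label: {label!r}") from None


def adduct_mz(neutral_mass: float, adduct: AdductSpec | str) -> float:
    """m/z (Th) of the given adduct of a neutral molecule of mass M (Da)."""
    if isinstance(adduct, str):
        adduct = get_adduct(adduct)
    if neutral_mass <= 0:
        raise ValueError(f"neutral mass must be positive, got {neutral_mass}")
    return (neutral_mass + adduct.mass_shift) / adduct.charge_magnitude


@dataclass
class MetaboliteRecord:
    """One candidate or standard compound.

    ``usable`` is False when the SMILES failed to parse; such records are
    carried along (never silently dropped) so that rejects can be reported.
    """

    id: str
    name: str
    formula: str
    smiles: str
    neutral_mass: float = field(default=float("nan"))
    usable: bool = True

    @classmethod
    def from_row(cls, id: str, name: str, formula: str, smiles: str) -> "MetaboliteRecord":
        rec = cls(id=str(id), name=str(name), formula=str(formula), smiles=str(smiles))
        try:
            rec.neutral_mass = monoisotopic_mass(rec.formula)
        except FormulaError:
            rec.usable = False
            return rec
        if rec.neutral_mass <= 0:
            rec.usable = False
        if Chem.MolFromSmiles(rec.smiles) is None:
            rec.usable = False
        return rec


@dataclass
class DescriptorVector:
    """Ordered descriptor values with a per-entry missing mask."""

    values: np.ndarray
    names: list[str]
    missing_mask: np.ndarray

    def __post_init__(self):
        assert len(self.values) == len(self.names) == len(self.missing_mask)

    @property
    def n_missing(self) -> int:
        return int(self.missing_mask.sum())


# Descriptor panel: the full RDKit 2D panel (constitutional counts, topological
# indices, logP/MR estimates, H-bond donor/acceptor counts, TPSA, EState and
# partial-charge descriptors), minus Ipc whose raw value overflows for larger
# structures. Panel membership is configuration recorded in model artifacts.
DESCRIPTOR_NAMES: list[str] = [n for n, _ in Descriptors._descList if n != "Ipc"]
_DESCRIPTOR_FUNCS = {n: f for n, f in Descriptors._descList if n != "Ipc"}


def compute_descriptors(smiles: str) -> DescriptorVector:
    """Compute the configured 2D descriptor panel for one structure.

    Referentially transparent: the same SMILES always yields the identical
    vector within one environment. Descriptors the structure cannot support
    (NaN/inf/exception) are flagged in ``missing_mask`` rather than zeroed, so
    downstream training can exclude the compound explicitly.
    """
    mol = Chem.MolFromSmiles(smiles)
    if mol is None:
        raise StructureError(f"unparseable SMILES: {smiles!r}")
    n = len(DESCRIPTOR_NAMES)
    values = np.empty(n, dtype=float)
    missing = np.zeros(n, dtype=bool)
    for i, name in enumerate(DESCRIPTOR_NAMES):
        try:
            v = float(_DESCRIPTOR_FUNCS[name](mol))
        except Exception:
            v = float("nan")
        if not math.isfinite(v):
            missing[i] = True
            v = float("nan")
        values[i] = v
    return DescriptorVector(values=values, names=list(DESCRIPTOR_NAMES), missing_mask=missing)


def descriptor_matrix(smiles_list: list[str]) -> tuple[np.ndarray, list[int]]:
    """Descriptor matrix for many structures.

    Returns (matrix, failed_indices); rows for unparseable structures are
    all-NaN and their indices listed in ``failed_indices``.
    """
    mat = np.full((len(smiles_list), len(DESCRIPTOR_NAMES)), np.nan)
    failed: list[int] = []
    for i, smi in enumerate(smiles_list):
        try:
            dv = compute_descriptors(smi)
        except StructureError:
            failed.append(i)
            continue
        mat[i] = dv.values
    return mat, failed
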