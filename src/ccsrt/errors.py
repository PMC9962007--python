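"""Exception hierarchy shared across the pipeline stages."""


class CcsrtError(Exception):
    """Base class for all package-specific errors."""


class FormulaError(CcsrtError):
    """Elemental formula could not be parsed or contains unknown elements."""


class AdductError(CcsrtError):
    """Unsupported or malformed adduct label."""


class StructureError(CcsrtError):
    """SMILES string could not be parsed into a valid structure."""


class InsufficientDataError(CcsrtError):
    """Too few observations for the requested fit or statistic."""


class DegenerateInputError(CcsrtError):
    """Input degenerate for the requested operation (e.g. constant vector)."""


class FoldError(CcsrtError):
    """Invalid cross-validation fold specification."""


class MergeError(CcsrtError):
    """Conflicting rows while merging measured entries into the database."""


class SchemaError(CcsrtError):
    """Input table is missing a mandatory column or has an invalid layout."""


class StageError(CcsrtError):
    """A pipeline stage failed; carries the stage name."""

    def __init__(self, stage: str, message: str):
        self.stage = stage
        super().__init__(f"stage '{stage}': {message}")


class DecoyConstructionError(CcsrtError):
    """Decoy placement window exhausted during feature simulation."""


class PredictionUnavailable(CcsrtError):
    """Descriptors required by a trained model cannot be computed."""
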