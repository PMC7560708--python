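"""Exception types shared across the package."""


class SamcliffError(Exception):
    """Base class for all package-specific errors."""


class InvalidStructure(SamcliffError):
    """A SMILES string could not be parsed or sanitized.

    Curation counts these as exclusions; they are never silently kept.
    """


class UnknownUnits(SamcliffError):
    """A concentration unit outside the accepted set (nM, uM/µM, M)."""


class DuplicateStructure(SamcliffError):
    """Two input compounds share a canonical key.

    Pair enumeration requires structurally unique inputs; the caller must
    deduplicate by canonical key first.
    """


class MissingPotency(SamcliffError):
    """A pair member lacks a potency for the pair's (target, measurement)."""


class SizeLimit(SamcliffError):
    """A molecule exceeds the exhaustive-oracle size bound."""


class WriteFailure(SamcliffError):
    """An output path could not be written."""
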