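"""Exception hierarchy shared across the package."""


class PlantChemError(Exception):
    """Base class for all package-specific errors."""


class ValidationError(PlantChemError):
    """A data-contract violation (e.g. a POS unit without triggers)."""


class IntegrityError(PlantChemError):
    """Cross-reference or offset inconsistency in a corpus file."""


class CorpusParseError(PlantChemError):
    """Malformed input file (XML, sheet, lexicon, or CoNLL)."""
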