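"""Exception hierarchy shared across the package."""


class PhylodynError(Exception):
    """Base class for all package errors."""


class ParseError(PhylodynError):
    """Malformed input text (Newick, NEXUS, tables)."""


class ValidationError(PhylodynError):
    """Structurally valid input that violates a model/data contract."""
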