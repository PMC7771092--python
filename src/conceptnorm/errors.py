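"""Exception hierarchy shared across the package."""


class ConceptNormError(Exception):
    """Base class for all package errors."""


class ValidationError(ConceptNormError):
    """Bad user input: malformed files, missing paths, invalid parameters."""


class OntologyError(ValidationError):
    """Structural problem in an ontology (cycles, dangling references)."""


class FormatError(ValidationError):
    """Malformed input file (OBO, word2vec, standoff)."""
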