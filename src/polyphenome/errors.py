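"""Exception hierarchy shared across the pipeline stages."""


class PolyphenomeError(Exception):
    """Base class for all package errors."""


class StructureError(PolyphenomeError):
    """A SMILES/SDF record could not be parsed or standardized."""


class FormatError(PolyphenomeError):
    """An input file does not conform to its declared dialect."""


class ValidationError(PolyphenomeError):
    """Input data violates a contract (duplicate ids, bad library, ...)."""


class ParameterError(PolyphenomeError):
    """A numeric or configuration parameter is out of range."""


class ConfigError(PolyphenomeError):
    """A pipeline run configuration is invalid or incomplete."""
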