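"""Exception hierarchy for her2ia."""


class Her2iaError(Exception):
    """Base class for all package errors."""


class ConfigError(Her2iaError):
    """Invalid configuration (colour definition, thresholds, parameters)."""


class FormatError(Her2iaError):
    """Input data in an unexpected format (wrong channel count, bad CSV)."""


class ValidationError(Her2iaError):
    """Input data fails a semantic precondition (bad polygon, empty table)."""
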