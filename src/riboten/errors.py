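"""Exception hierarchy shared across the pipeline stages."""


class RibotenError(Exception):
    """Base class for all package errors."""


class ConfigurationError(RibotenError):
    """Invalid simulation or pipeline configuration."""


class DataError(RibotenError):
    """Malformed or inconsistent input data (hard error; exit code 2 in the CLI)."""
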