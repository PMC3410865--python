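"""Exception hierarchy; the CLI maps these onto exit codes."""


class TrajmixError(Exception):
    """Base class for package errors."""


class ConfigError(TrajmixError):
    """Invalid configuration (CLI exit code 2)."""


class DataError(TrajmixError):
    """Malformed or inconsistent input data (CLI exit code 3)."""


class NumericalError(TrajmixError):
    """Numerical failure during inference or design (CLI exit code 4)."""
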