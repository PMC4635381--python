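"""Exception hierarchy shared across the pipeline.

The CLI maps these onto exit codes: configuration problems exit 2,
malformed or missing inputs exit 3, quality-control failures exit 4.
"""


class ArchaeotypeError(Exception):
    """Base class for all package-specific errors."""


class ConfigError(ArchaeotypeError, ValueError):
    """A parameter or configuration document is invalid."""


class InputError(ArchaeotypeError, ValueError):
    """An input file or in-memory input violates its contract."""


class SpectrumParseError(InputError):
    """A spectrum or peak-list file could not be parsed."""


class QCError(ArchaeotypeError, RuntimeError):
    """A quality-control rule rejected all usable data."""
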