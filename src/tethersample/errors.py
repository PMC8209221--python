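"""Exception hierarchy.

Each class maps to a distinct CLI exit code so scripted callers can tell
configuration mistakes apart from bad input files and from numerical
failures during sampling.
"""


class TetherSampleError(Exception):
    """Base class for all package errors."""


class ConfigurationError(TetherSampleError):
    """A model / estimation / run configuration is internally inconsistent."""


class InvalidSpecError(TetherSampleError):
    """A structure or domain specification violates its invariants."""


class InputError(TetherSampleError):
    """An input file or dataset is malformed or inconsistent."""


class SamplingError(TetherSampleError):
    """Structure generation failed numerically (e.g. rejection cap exceeded)."""
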