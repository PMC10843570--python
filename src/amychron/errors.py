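"""Exception hierarchy shared across the pipeline.

Input-shaped problems (bad values, malformed tables) and model-shaped problems
(not enough longitudinal data, degenerate fitted curves) are kept distinct so
the command-line layer can map them to different exit codes.
"""


class AmychronError(Exception):
    """Base class for all package-specific errors."""


class InputError(AmychronError, ValueError):
    """Invalid argument values or malformed input data."""


class SchemaError(InputError):
    """A table does not conform to the expected column schema."""


class ConfigError(InputError):
    """Inconsistent configuration (e.g. distribution counts vs. n_subjects)."""


class ModelFitError(AmychronError, RuntimeError):
    """The model cannot be fit from the data provided."""


class DegenerateCurveError(ModelFitError):
    """The rate field is non-positive at the anchor; no trajectory exists."""
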