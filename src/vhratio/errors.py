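"""Exception hierarchy for the vhratio pipeline.

All errors derive from :class:`VhratioError` so callers can catch one base.
Validation and configuration problems are also ``ValueError`` subclasses,
matching the convention of numpy/scipy for bad inputs.
"""


class VhratioError(Exception):
    """Base class for all vhratio errors."""


class FormatError(VhratioError, ValueError):
    """An input file does not conform to the expected schema."""


class ValidationError(VhratioError, ValueError):
    """Input values violate a domain constraint (e.g. negative abundance)."""


class ConfigurationError(VhratioError, ValueError):
    """A parameter is outside its legal range."""


class DegenerateFitError(VhratioError, ValueError):
    """A statistic is undefined on the given data (e.g. constant x)."""
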