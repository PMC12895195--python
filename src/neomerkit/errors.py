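"""Exception hierarchy.

All neomerkit errors derive from :class:`NeomerkitError` so the CLI can map
them to exit code 1 (data/parameter problems) while genuine bugs propagate.
"""


class NeomerkitError(Exception):
    """Base class for all neomerkit errors."""


class ParameterError(NeomerkitError, ValueError):
    """An argument violates a documented precondition."""


class FormatError(NeomerkitError, ValueError):
    """An input file is malformed."""


class DataIntegrityError(NeomerkitError, ValueError):
    """Inputs are internally inconsistent (e.g. ref allele mismatch)."""


class FeasibilityError(NeomerkitError, ValueError):
    """The request exceeds a configured resource guard."""


class ConfigurationError(NeomerkitError, ValueError):
    """A run configuration is unusable (e.g. no controls in a fold)."""
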