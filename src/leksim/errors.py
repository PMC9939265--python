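"""Exception types shared across the package."""


class LeksimError(Exception):
    """Base class for all package errors."""


class ConfigurationError(LeksimError, ValueError):
    """A parameter or configuration file field is missing or invalid.

    The message always names the offending field (and, for file input,
    the line or key where it was found).
    """


class SchemaError(LeksimError, ValueError):
    """A CSV table does not conform to its declared schema.

    The message carries the 1-based row number of the first bad row.
    """


class UndefinedMetricError(LeksimError, ValueError):
    """A statistic is undefined on the given input (too few events,
    no overlap, degenerate ranks).  Raised instead of returning a
    misleading 0.
    """
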