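"""Exception hierarchy shared across the toolkit."""


class GeosigError(Exception):
    """Base class for all package-specific errors."""


class ParseError(GeosigError):
    """A study/GMT/JSON file could not be parsed; message names line/field."""


class IntegrityError(GeosigError):
    """A structural invariant of a domain object is violated."""


class SchemaError(GeosigError):
    """A serialized record is missing a mandatory field or has a bad type."""


class DegenerateContrastError(GeosigError):
    """Control and treatment class means are identical; no direction exists."""


class InsufficientReplicatesError(GeosigError):
    """Fewer than two samples in a class; scatter is not estimable."""


class UndefinedAttributionError(GeosigError):
    """Variance attribution requested with a single batch and single condition."""


class UndefinedROCError(GeosigError):
    """ROC requested with an empty positive or negative class."""


class DegenerateVarianceError(GeosigError):
    """DeLong variance estimate is zero while AUCs differ."""
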