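"""Exception hierarchy shared across the package."""


class RegioncoordError(Exception):
    """Base class for all package errors."""


class ValidationError(RegioncoordError):
    """Input data violates a structural contract (missing/duplicate cells)."""


class SchemaError(RegioncoordError):
    """Input refers to indicators or groups unknown to the scheme."""


class IntegrityError(RegioncoordError):
    """A packaged fixture failed its checksum."""


class DomainError(RegioncoordError):
    """A numeric argument lies outside its mathematical domain."""


class CalibrationError(RegioncoordError):
    """Fuzzy-set calibration anchors are degenerate or mis-ordered."""


class DegenerateDataError(RegioncoordError):
    """Every indicator column is constant; no information to weight."""
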