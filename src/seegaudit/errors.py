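"""Exception hierarchy shared across the pipeline."""


class SeegAuditError(Exception):
    """Base class for all package errors."""


class GeometryError(SeegAuditError, ValueError):
    """A spatial precondition is violated (degenerate affine, empty trajectory...)."""


class VolumeParseError(SeegAuditError, ValueError):
    """A volume file exists but cannot be interpreted."""


class ParameterError(SeegAuditError, ValueError):
    """An operation received an out-of-range or inconsistent parameter."""


class PhantomSizingError(SeegAuditError, ValueError):
    """The requested phantom geometry does not fit the requested grid."""


class InfeasibleTrajectoryError(SeegAuditError, ValueError):
    """No straight electrode path satisfying the constraints exists."""


class NoVesselAtPointError(SeegAuditError, ValueError):
    """A vessel-local measurement was requested away from any segmented vessel."""


class EstimationError(SeegAuditError, RuntimeError):
    """A statistical estimate could not be formed (e.g. zero valid rays)."""
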