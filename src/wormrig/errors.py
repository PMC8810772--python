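"""Exception hierarchy for the rig simulator and controller."""


class WormRigError(Exception):
    """Base class for all package errors."""


class InvalidParameterError(WormRigError, ValueError):
    """A parameter violates a documented precondition."""


class CalibrationError(WormRigError):
    """Texel-to-pixel calibration could not be fitted."""


class TravelLimitError(WormRigError):
    """A commanded carriage/head move exceeds the configured axis travel."""


class AcquisitionError(WormRigError):
    """The laser spot could not be detected during goal acquisition."""


class LostTargetError(WormRigError):
    """No worm silhouette found in the micro frame during microtracking."""


class FocusFailureError(WormRigError):
    """Autofocus could not rank candidate Z positions (featureless frames)."""


class InsufficientSampleError(WormRigError, ValueError):
    """A statistical comparison was requested with too few worms or strains."""
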