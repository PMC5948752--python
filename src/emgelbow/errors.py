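"""Exception types raised across the elbow-model pipeline."""


class EmgElbowError(Exception):
    """Base class for all package errors."""


class InvalidParameterError(EmgElbowError, ValueError):
    """A parameter is outside its admissible range (e.g. filter cut-offs)."""


class DegenerateCalibrationError(EmgElbowError, ValueError):
    """MVC calibration with emg_max == emg_min cannot normalize anything."""


class TooShortInputError(EmgElbowError, ValueError):
    """Series shorter than the filter warm-up length."""


class SynchronizationError(EmgElbowError, ValueError):
    """Channels have no overlapping time range."""


class IndeterminateStateError(EmgElbowError, ValueError):
    """Hill-model inversion attempted at a near-singular kinematic state."""


class InvalidGeometryError(EmgElbowError, ValueError):
    """Muscle geometry polynomial produced a non-positive length."""


class InfeasibleTrajectoryError(EmgElbowError, ValueError):
    """The requested motion demands muscle activation above 1 (slow the motion)."""


class DatasetFormatError(EmgElbowError, ValueError):
    """A cohort directory or CSV file does not match the documented layout."""
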