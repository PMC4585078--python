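"""Exception hierarchy for the fourlink package."""


class FourlinkError(Exception):
    """Base class for all package-specific errors."""


class SingularSystemError(FourlinkError):
    """The 20x20 equation system is singular at some time step."""

    def __init__(self, message: str, step: int | None = None):
        super().__init__(message)
        self.step = step


class DivergenceError(FourlinkError):
    """Forward simulation blew up (angular velocity beyond the sanity bound)."""

    def __init__(self, message: str, step: int | None = None):
        super().__init__(message)
        self.step = step


class ReachabilityError(FourlinkError):
    """Two-circle triangulation target outside the reachable annulus."""


class DegenerateMarkerError(FourlinkError):
    """A segment's marker pair coincides; its angle is undefined."""


class NoSwingError(FourlinkError):
    """No sustained toe elevation found; swing onset undetectable."""


class InsufficientElevationError(FourlinkError):
    """Toe never reaches the heights needed for the trajectory-slope metric."""


class PostureError(FourlinkError):
    """Requested toe placement is outside the synthetic posture family."""


class NoBurstError(FourlinkError):
    """EMG envelope never exceeds the burst-onset threshold."""


class NyquistError(FourlinkError):
    """EMG sampling rate too low for the requested low-pass cutoff."""


class TruncationError(FourlinkError):
    """Integration window extends past the end of the trace."""


class DegenerateRegressionError(FourlinkError):
    """Regressor is constant; an OLS line is not estimable."""
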