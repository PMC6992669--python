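"""Package-wide exception types."""


class EarwaveError(Exception):
    """Base class for all earwave errors."""


class InvalidInputError(EarwaveError, ValueError):
    """An argument is outside its physical or documented domain."""


class NonAbsorbingMediumError(InvalidInputError):
    """A loss-dependent quantity was requested for a lossless medium."""


class InvalidGeometryError(EarwaveError, ValueError):
    """A phantom geometry request cannot be realised on the voxel grid."""


class InvalidSourceError(EarwaveError, ValueError):
    """An excitation definition violates its validity constraints."""


class SolverInstabilityError(EarwaveError, RuntimeError):
    """The time-domain solver produced non-finite fields."""

    def __init__(self, step: int, message: str | None = None):
        self.step = step
        super().__init__(message or f"FDTD fields became non-finite at step {step}")


class SensorPlacementError(EarwaveError, ValueError):
    """A sensor could not be resolved to a location inside the grid."""


class DataIntegrityError(EarwaveError, RuntimeError):
    """A bundled data file does not match its embedded checksum."""
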