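"""Exception and warning types shared across the package."""


class AlignmentError(ValueError):
    """Raster layers do not share a common grid."""


class OutOfBoundsError(ValueError):
    """A coordinate falls outside the grid extent."""


class MissingDataError(ValueError):
    """All values requested from a raster are missing."""


class SimulationError(RuntimeError):
    """The dispersal simulator could not proceed (e.g. resampling cap hit)."""


class SeparationWarning(UserWarning):
    """The conditional likelihood appears unbounded (complete separation)."""
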