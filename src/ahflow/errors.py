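"""Exception types shared across the package."""


class AhflowError(Exception):
    """Base class for all package-specific errors."""


class ConfigurationError(AhflowError):
    """A parameter combination violates a stability bound or schema rule."""


class GeometryError(AhflowError):
    """A geometry specification produces an invalid simulation domain."""


class SegmentationError(AhflowError):
    """Contour extraction from an edge map failed."""


class DivergenceError(AhflowError):
    """The lattice-Boltzmann iteration produced non-finite populations."""

    def __init__(self, tick: int, max_speed: float):
        self.tick = tick
        self.max_speed = max_speed
        super().__init__(
            f"solver diverged at tick {tick} (max lattice speed {max_speed:.3g})"
        )
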