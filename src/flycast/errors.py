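"""Exception hierarchy shared across the pipeline."""


class FlycastError(Exception):
    """Base class for all package errors."""


class FormatError(FlycastError):
    """A structure file could not be parsed."""


class EmptyStructureError(FlycastError):
    """No atoms remained after filtering."""


class UnknownChainError(FlycastError):
    """A selection referenced a chain id absent from the structure."""


class OverflowFieldError(FlycastError):
    """A coordinate does not fit the fixed-width PDB columns."""


class DegenerateFitError(FlycastError):
    """Superposition requested on fewer than 3 non-collinear points."""


class BuildError(FlycastError):
    """A coarse-grained system could not be constructed."""


class ConfigError(FlycastError):
    """A run configuration is inconsistent or incomplete."""


class IntegrationDivergedError(FlycastError):
    """Coordinates exceeded the configured bound during integration."""

    def __init__(self, step: int, bound: float):
        self.step = step
        self.bound = bound
        super().__init__(
            f"integration diverged at step {step}: |coordinate| > {bound}"
        )


class GenerationError(FlycastError):
    """A synthetic fixture spec was infeasible."""


class SelectionError(FlycastError):
    """A selection resolved empty where atoms were required."""
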