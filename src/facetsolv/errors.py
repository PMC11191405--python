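"""Exception hierarchy shared across the package."""


class FacetsolvError(Exception):
    """Base class for all package-specific errors."""


class ParseError(FacetsolvError):
    """A structure document could not be interpreted."""


class StructureError(FacetsolvError):
    """A crystal structure violates a geometric sanity constraint."""


class GeometryError(FacetsolvError):
    """A geometric computation received degenerate input."""


class ParameterError(FacetsolvError):
    """A force-field atom type has no tabulated parameters."""


class NearSingularityError(FacetsolvError):
    """Two atoms are close enough that the potential diverges."""


class AnalysisError(FacetsolvError):
    """A statistic was requested on an empty or undefined selection."""


class ConvergenceError(FacetsolvError):
    """A lattice summation failed to converge within the allowed extent."""

    def __init__(self, message: str, residual: float | None = None):
        super().__init__(message)
        self.residual = residual


class ConfigError(FacetsolvError):
    """A run configuration is incomplete or inconsistent."""


class OracleError(FacetsolvError):
    """A test oracle was asked to exceed its size guard."""
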