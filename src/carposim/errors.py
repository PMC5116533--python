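"""Exception hierarchy for carposim."""


class CarposimError(Exception):
    """Base class for all carposim errors."""


class InvalidGeometryError(CarposimError):
    """A profile, mesh, or vascular curve violates a geometric precondition."""


class UnsupportedCellError(CarposimError):
    """A mesh file contains cells other than linear tetrahedra."""


class StateError(CarposimError):
    """A simulation state is inconsistent (NaN, negative mass, missing radii)."""


class IntegrationError(CarposimError):
    """The stiff ODE solver failed to advance the coupled system."""
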