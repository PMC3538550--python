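"""Exception hierarchy.

``InputError`` covers malformed user input (files, point lists, constraint
indices, out-of-range parameters); ``GeometryError`` covers geometric
degeneracies (zero tangents, curves shorter than one base-pair spacing).
The CLI maps them to exit codes 2 and 3 respectively.
"""


class DnaxisError(Exception):
    """Base class for all dnaxis errors."""


class InputError(DnaxisError, ValueError):
    """Malformed or out-of-domain user input."""


class GeometryError(DnaxisError, ValueError):
    """Geometric degeneracy that prevents the requested construction."""


class DegenerateCurveError(GeometryError):
    """The curve tangent is undefined (zero derivative) somewhere."""


class CurveTooShortError(GeometryError):
    """The curve is shorter than the requested sample spacing."""
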