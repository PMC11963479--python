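"""Exception hierarchy shared across rockroot modules."""


class RockrootError(Exception):
    """Base class for all rockroot errors."""


class ParameterError(RockrootError, ValueError):
    """Invalid constitutive parameter set."""


class DomainError(RockrootError, ValueError):
    """Input outside the physical domain of an operation (e.g. positive
    water potential passed to a retention curve)."""


class CalibrationError(RockrootError, ValueError):
    """Retention-curve calibration cannot satisfy the given anchors."""


class GeometryError(RockrootError, ValueError):
    """Requested simulation domain is geometrically infeasible."""


class SolverError(RockrootError, RuntimeError):
    """Nonlinear solver failed to converge at the minimum time step."""


class DegenerateConvergenceError(RockrootError, ValueError):
    """Grid-convergence analysis is undefined (identical or oscillatory
    solutions across refinements)."""


class MeasurementError(RockrootError, ValueError):
    """Invalid measurement record or empty retained set."""


class ConfigError(RockrootError, ValueError):
    """Malformed or unknown-key run configuration."""
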