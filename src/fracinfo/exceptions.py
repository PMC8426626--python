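"""Exception hierarchy for fracinfo."""


class FracinfoError(Exception):
    """Base class for all package errors."""


class ConfigurationError(FracinfoError):
    """Invalid model/mechanism/run configuration supplied by the user."""


class EmptyDataError(FracinfoError):
    """No usable rows remain after dropping all-missing cases."""


class InadmissibleMomentsError(FracinfoError):
    """A model-implied covariance matrix is not positive definite."""

    def __init__(self, message: str, min_eigenvalue: float | None = None):
        super().__init__(message)
        self.min_eigenvalue = min_eigenvalue


class MechanismError(ConfigurationError):
    """Missing-data mechanism configuration violates its constraints."""


class DifferentiationError(FracinfoError):
    """A finite-difference stencil evaluation returned a non-finite value."""

    def __init__(self, message: str, coordinate: int | None = None):
        super().__init__(message)
        self.coordinate = coordinate
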