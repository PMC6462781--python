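"""Exception hierarchy shared across the package.

Exit-code mapping used by the CLI: format/parse problems -> 2,
feature computation problems -> 3, storage problems -> 4.
"""


class FermkitError(Exception):
    """Base class for all package errors."""


class IdentifierParseError(FermkitError):
    """A flat trial-identifier string could not be parsed."""


class FormatError(FermkitError):
    """A raw input file violates its declared dialect."""


class AssemblyError(FermkitError):
    """Time points could not be assembled into the experiment hierarchy."""


class FeatureError(FermkitError):
    """A derived feature could not be computed from the given courses."""


class FitError(FeatureError):
    """A growth-model fit failed to converge or had invalid inputs.

    Carries the last parameter iterate when the optimizer stalled.
    """

    def __init__(self, message, last_iterate=None):
        super().__init__(message)
        self.last_iterate = last_iterate


class FluxError(FermkitError):
    """Stoichiometric-model constraint or solve failure."""


class GeneratorError(FermkitError):
    """A synthetic-data configuration is physically inconsistent."""


class StoreError(FermkitError):
    """Relational-store I/O, schema-version, or lookup failure."""
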