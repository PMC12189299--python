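"""Exception hierarchy for extractopt."""


class ExtractOptError(Exception):
    """Base class for all extractopt errors."""


class ValidationError(ExtractOptError, ValueError):
    """Invalid user input (bad parameter, malformed table, out-of-range value)."""


class UnsupportedDesignError(ValidationError):
    """Requested a design this package does not generate (only 3-factor Box-Behnken)."""


class SingularFitError(ExtractOptError):
    """Rank-deficient model matrix; carries the names of the collinear columns."""

    def __init__(self, columns):
        self.columns = list(columns)
        super().__init__(
            f"model matrix is rank deficient; collinear columns: {self.columns}"
        )


class AlignmentError(ExtractOptError):
    """Design runs and response rows do not match one-to-one."""


class DegenerateReferenceError(ExtractOptError):
    """White and dark reference coincide at one or more bands."""

    def __init__(self, bands):
        self.bands = list(bands)
        super().__init__(
            f"white reference equals dark reference at band indices {self.bands}"
        )


class NoContrastError(ExtractOptError):
    """Hypercube is spectrally constant; segmentation has nothing to separate."""


class FixtureNotFoundError(ExtractOptError, KeyError):
    """Unknown fixture name; message lists the available fixtures."""
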