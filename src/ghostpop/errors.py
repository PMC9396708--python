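"""Exception and warning types shared across the package."""


class GhostpopError(Exception):
    """Base class for all package errors."""


class VCFParseError(GhostpopError):
    """A VCF record could not be interpreted; the message names the line."""


class ConfigError(GhostpopError):
    """An option value (e.g. an unknown locus-id rule) is not recognised."""


class ScenarioValidationError(GhostpopError):
    """A demographic scenario is internally inconsistent."""


class EmptyFilterError(GhostpopError):
    """A filter stage removed every remaining site or sample."""

    def __init__(self, stage: int, what: str):
        self.stage = stage
        super().__init__(f"empty after stage {stage}: no {what} remain")


class PriorError(GhostpopError):
    """Prior constraints are unsatisfiable or nearly so."""


class DegenerateStatisticWarning(UserWarning):
    """A statistic is undefined for the given data (e.g. no variation)."""
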