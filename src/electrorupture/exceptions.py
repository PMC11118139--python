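"""Exception hierarchy for the electrorupture package."""


class ElectroruptureError(Exception):
    """Base class for all package-specific errors."""


class DataValidationError(ElectroruptureError):
    """Input tables, traces, or events violate the documented schema."""


class GridResolutionError(ElectroruptureError):
    """The simulation time step is too coarse for the hazard being sampled."""


class ModelFitError(ElectroruptureError):
    """The Bell-line fit is inconsistent with the model (e.g. non-positive slope)."""


class SpontaneousRuptureError(ElectroruptureError):
    """Most-probable-tension requested in the regime where the mode sits at zero tension."""
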