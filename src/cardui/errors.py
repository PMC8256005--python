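"""Exception types shared across the package."""


class CarduiError(Exception):
    """Base class for package errors."""


class GridFormatError(CarduiError):
    """A gridded input file is missing a variable or coordinate axis."""


class EmptyRegionError(CarduiError):
    """A region geometry intersects no grid cells."""


class DegenerateCovariateError(CarduiError):
    """A covariate series has zero variance and cannot be standardized."""


class SeasonConfigError(CarduiError):
    """Season windows for one region overlap."""


class MissingYearError(CarduiError):
    """A year inside the study span has no counts at any site."""


class DegenerateFitError(CarduiError):
    """The response is degenerate (e.g. all-zero counts); no model can be fit."""


class CollinearityError(CarduiError):
    """A model spec contains a covariate pair with |r| >= 0.7."""


class ConvergenceError(CarduiError):
    """An iterative fit failed to converge."""


class ResolutionError(CarduiError):
    """The correlation map grid is coarser than the expected fine-cell size."""


class BoundaryError(CarduiError):
    """A subregion boundary latitude falls outside the kernel's span."""


class PolarSingularityError(CarduiError):
    """A trajectory step was requested at |lat| >= 89 degrees."""


class LaunchError(CarduiError):
    """A trajectory launch point lies outside the atmosphere hull."""


class PipelineConfigError(CarduiError):
    """The pipeline configuration is invalid or inputs are missing."""
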