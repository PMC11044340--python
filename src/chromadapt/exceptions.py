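"""Exception hierarchy for chromadapt."""


class ChromadaptError(Exception):
    """Base class for all chromadapt errors."""


class GamutError(ChromadaptError):
    """A planted CIELAB colour falls outside the sRGB gamut."""

    def __init__(self, lab, message=None):
        self.lab = tuple(float(v) for v in lab)
        super().__init__(message or f"CIELAB colour {self.lab} is outside the sRGB gamut")


class GeometryError(ChromadaptError):
    """ROI polygon is inconsistent with the image it annotates."""


class SamplingError(ChromadaptError):
    """Not enough material to draw the requested sample."""


class InsufficientPoolError(ChromadaptError):
    """Pooled colour table too small to support the centroid model."""


class DegenerateDataError(ChromadaptError):
    """Input data carry no variation to fit against."""


class NotFittedError(ChromadaptError, AttributeError):
    """Model used before fit()."""


class ConditioningError(ChromadaptError):
    """A covariance matrix is numerically singular or not positive definite."""


class LabellingError(ChromadaptError):
    """Species labels in the data do not match the tree tips."""
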