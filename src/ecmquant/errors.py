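"""Exception types shared across the quantification stages."""


class EcmQuantError(ValueError):
    """Base class for all quantification errors."""


class MissingChannelError(EcmQuantError):
    """A required image channel is absent."""


class EmptyMaskError(EcmQuantError):
    """A region-of-interest mask has no member pixels where some are required."""


class UndefinedStatisticError(EcmQuantError):
    """A requested statistic is undefined on the given input (e.g. no valid pixels)."""


class ZeroVarianceError(EcmQuantError):
    """An input channel or sample is constant where variation is required."""


class ShapeMismatchError(EcmQuantError):
    """Rasters that must share a shape do not."""
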