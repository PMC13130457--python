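"""Exception hierarchy shared by all pipelines."""


class FiberQuantError(Exception):
    """Base class for all fiberquant errors."""


class ValidationError(FiberQuantError, ValueError):
    """An argument or table violates a documented precondition."""


class FormatError(FiberQuantError):
    """An input file parses but has an unsupported layout (e.g. axis count)."""


class ChannelLookupError(FiberQuantError, KeyError):
    """A requested channel or gene is not present."""


class DegenerateInputError(FiberQuantError):
    """An image has (near-)zero intensity variance, so no threshold exists."""


class DegenerateOutputError(FiberQuantError):
    """An operation produced an empty result where a non-empty one is required."""


class SegmentationError(FiberQuantError):
    """Segmentation produced no usable foreground."""


class CapacityError(FiberQuantError):
    """Synthetic object placement failed after bounded retries."""


class ComputationError(FiberQuantError):
    """A derived quantity is undefined (e.g. zero normalization constant)."""


class UnresolvedSignError(FiberQuantError):
    """A sign-determining fold change is exactly zero."""
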